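import numpy as np
import pytest

from evplankton.io import EventStream
from evplankton.tracking import ClusterTrack


def random_stream(rng, n_events=150, size=64, duration_ms=300) -> EventStream:
    """A random sparse event stream for stress/oracle tests."""
    t = np.sort(rng.integers(0, duration_ms * 1000, n_events))
    x = rng.integers(0, size, n_events)
    y = rng.integers(0, size, n_events)
    p = np.where(rng.random(n_events) < 0.5, 1, -1)
    return EventStream.from_arrays(t, x, y, p, (size, size))


def make_track(events_by_tick, track_id=0) -> ClusterTrack:
    """Build a ClusterTrack directly from per-tick event lists.

    ``events_by_tick`` is a list (one entry per 1 ms tick) of lists of
    (x, y, p) tuples.  Live summaries are filled with the per-tick event
    centroids (adequate for feature computations, which work from the
    per-tick new events).
    """
    n = len(events_by_tick)
    ev_x, ev_y, ev_p, offsets = [], [], [], [0]
    inc_pos, inc_neg, cx, cy, size = [], [], [], [], []
    last = (0.0, 0.0)
    for tick in events_by_tick:
        for x, y, p in tick:
            ev_x.append(x)
            ev_y.append(y)
            ev_p.append(p)
        offsets.append(len(ev_x))
        inc_pos.append(sum(1 for e in tick if e[2] > 0))
        inc_neg.append(sum(1 for e in tick if e[2] < 0))
        if tick:
            last = (
                float(np.mean([e[0] for e in tick])),
                float(np.mean([e[1] for e in tick])),
            )
        cx.append(last[0])
        cy.append(last[1])
        size.append(len(tick))
    return ClusterTrack(
        track_id=track_id,
        t_ms=np.arange(1, n + 1, dtype=np.int64),
        centre=np.column_stack([cx, cy]),
        size=np.asarray(size, np.int64),
        n_pos_live=np.asarray(inc_pos, np.int64),
        n_neg_live=np.asarray(inc_neg, np.int64),
        cluster_id=np.full(n, track_id, np.int64),
        members=[(track_id,)] * n,
        inc_pos=np.asarray(inc_pos, np.int64),
        inc_neg=np.asarray(inc_neg, np.int64),
        ev_x=np.asarray(ev_x, np.int32),
        ev_y=np.asarray(ev_y, np.int32),
        ev_p=np.asarray(ev_p, np.int8),
        ev_offsets=np.asarray(offsets, np.int64),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
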