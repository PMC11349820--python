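"""Streaming event -> subcluster -> cluster particle tracker.

The tracker turns a time-ordered event stream into per-particle tracks in
three repeated steps:

1. **Assignment** — each new event is merged into an existing *subcluster* if
   that subcluster has a live event within a ``search_window`` x
   ``search_window`` pixel neighbourhood (default 5x5) *and* absorbing the
   event would keep the subcluster's bounding box within the
   ``subcluster_cap`` (default 20x20 px).  Otherwise the event seeds a fresh
   subcluster with a new, never-reused id.  When several subclusters qualify,
   the one whose live-event centroid is nearest wins; exact ties go to the
   lowest id.

2. **Expiry** — at every sample tick (default 1 ms) all events older than
   ``event_lifetime`` (default 100 ms) are removed; subclusters left empty
   are retired.  This sliding window is what makes subclusters follow a
   moving particle: trailing events fall out while leading events join.

3. **Merging** — subclusters whose bounding boxes overlap or sit within
   ``merge_gap`` pixels of each other form connected components; each
   component is one *cluster*, identified by the smallest member subcluster
   id.  A particle larger than the cap therefore shows up as several
   subclusters but exactly one cluster.

Cluster identities are linked across consecutive sample ticks through shared
subcluster membership, yielding :class:`ClusterTrack` objects that carry the
centre trajectory, per-tick member ids, live-event summaries and — for the
downstream feature computations — the coordinates of every newly absorbed
event per tick.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, OrderingError
from .io import EventStream

__all__ = [
    "TrackerConfig",
    "ClusterTrack",
    "TrackResult",
    "Tracker",
    "track_events",
    "tracks_to_frame",
]


@dataclass
class TrackerConfig:
    """Tunable parameters of the tracker (defaults follow the method's study values)."""

    event_lifetime_ms: float = 100.0  # sliding-window age limit for live events
    search_window: int = 5  # odd side length of the assignment neighbourhood
    subcluster_cap: int = 20  # max bbox side length of one subcluster
    sample_period_ms: float = 1.0  # tick at which summaries are emitted
    merge_gap: int = 1  # max bbox separation for merging (1 = touch/overlap)
    min_track_ticks: int = 2  # shorter tracks are dropped (velocity needs 2 centres)

    def validate(self) -> "TrackerConfig":
        if self.event_lifetime_ms <= 0:
            raise ConfigError("event_lifetime_ms must be positive")
        if self.search_window <= 0 or self.search_window % 2 == 0:
            raise ConfigError("search_window must be a positive odd integer")
        if self.subcluster_cap < self.search_window:
            raise ConfigError("subcluster_cap must be >= search_window")
        if self.sample_period_ms <= 0:
            raise ConfigError("sample_period_ms must be positive")
        if self.merge_gap < 0:
            raise ConfigError("merge_gap must be non-negative")
        if self.min_track_ticks < 1:
            raise ConfigError("min_track_ticks must be >= 1")
        return self


class _SubCluster:
    """Mutable tracker-internal subcluster state.

    Live events are kept in insertion (= time) order in parallel deques so
    expiry pops from the left.  Bounding box and centroid are maintained
    incrementally: per-coordinate occupancy counters allow the box to shrink
    exactly when a boundary event expires.
    """

    __slots__ = (
        "sid", "ts", "xs", "ys", "ps", "idxs",
        "cnt_x", "cnt_y", "min_x", "max_x", "min_y", "max_y",
        "sum_x", "sum_y", "n", "n_pos", "n_neg",
        "new_x", "new_y", "new_p",
    )

    def __init__(self, sid: int):
        self.sid = sid
        self.ts = deque()
        self.xs = deque()
        self.ys = deque()
        self.ps = deque()
        self.idxs = deque()
        self.cnt_x: dict[int, int] = {}
        self.cnt_y: dict[int, int] = {}
        self.min_x = self.max_x = self.min_y = self.max_y = 0
        self.sum_x = 0
        self.sum_y = 0
        self.n = 0
        self.n_pos = 0
        self.n_neg = 0
        # events absorbed since the last sample tick (drained by the tracker)
        self.new_x: list[int] = []
        self.new_y: list[int] = []
        self.new_p: list[int] = []

    def add(self, t: int, x: int, y: int, p: int, idx: int) -> None:
        self.ts.append(t)
        self.xs.append(x)
        self.ys.append(y)
        self.ps.append(p)
        self.idxs.append(idx)
        cx = self.cnt_x
        cx[x] = cx.get(x, 0) + 1
        cy = self.cnt_y
        cy[y] = cy.get(y, 0) + 1
        if self.n == 0:
            self.min_x = self.max_x = x
            self.min_y = self.max_y = y
        else:
            if x < self.min_x:
                self.min_x = x
            elif x > self.max_x:
                self.max_x = x
            if y < self.min_y:
                self.min_y = y
            elif y > self.max_y:
                self.max_y = y
        self.sum_x += x
        self.sum_y += y
        self.n += 1
        if p > 0:
            self.n_pos += 1
        else:
            self.n_neg += 1
        self.new_x.append(x)
        self.new_y.append(y)
        self.new_p.append(p)

    def expire(self, cutoff: int, grid: dict, width: int) -> None:
        """Remove events with t <= cutoff, keeping box/centroid exact."""
        ts = self.ts
        while ts and ts[0] <= cutoff:
            t = ts.popleft()
            x = self.xs.popleft()
            y = self.ys.popleft()
            p = self.ps.popleft()
            self.idxs.popleft()
            c = self.cnt_x[x] - 1
            if c:
                self.cnt_x[x] = c
            else:
                del self.cnt_x[x]
                if x == self.min_x and self.n > 1:
                    mx = x + 1
                    while mx not in self.cnt_x:
                        mx += 1
                    self.min_x = mx
                elif x == self.max_x and self.n > 1:
                    mx = x - 1
                    while mx not in self.cnt_x:
                        mx -= 1
                    self.max_x = mx
            c = self.cnt_y[y] - 1
            if c:
                self.cnt_y[y] = c
            else:
                del self.cnt_y[y]
                if y == self.min_y and self.n > 1:
                    my = y + 1
                    while my not in self.cnt_y:
                        my += 1
                    self.min_y = my
                elif y == self.max_y and self.n > 1:
                    my = y - 1
                    while my not in self.cnt_y:
                        my -= 1
                    self.max_y = my
            self.sum_x -= x
            self.sum_y -= y
            self.n -= 1
            if p > 0:
                self.n_pos -= 1
            else:
                self.n_neg -= 1
            key = y * width + x
            d = grid.get(key)
            if d is not None:
                if d.get(self.sid) == t:
                    del d[self.sid]
                    if not d:
                        del grid[key]


class _Track:
    """Accumulates one cluster's per-tick history until the track closes."""

    __slots__ = (
        "order", "track_id", "t_ms", "members", "cluster_id",
        "cx", "cy", "size", "n_pos_live", "n_neg_live",
        "inc_pos", "inc_neg", "ev_x", "ev_y", "ev_p", "ev_offsets",
        "last_members",
    )

    def __init__(self, order: int, first_members):
        self.order = order
        self.track_id = min(first_members)
        self.t_ms: list[int] = []
        self.members: list[tuple[int, ...]] = []
        self.cluster_id: list[int] = []
        self.cx: list[float] = []
        self.cy: list[float] = []
        self.size: list[int] = []
        self.n_pos_live: list[int] = []
        self.n_neg_live: list[int] = []
        self.inc_pos: list[int] = []
        self.inc_neg: list[int] = []
        self.ev_x: list[int] = []
        self.ev_y: list[int] = []
        self.ev_p: list[int] = []
        self.ev_offsets: list[int] = [0]
        self.last_members: frozenset = frozenset()


@dataclass
class ClusterTrack:
    """One tracked particle: trajectory, live summaries and per-tick new events.

    ``t_ms`` holds the sample times (integer ms since the stream start);
    ``centre`` the live-event centroid at each tick; ``inc_pos``/``inc_neg``
    the per-tick increments of newly absorbed events.  The raw coordinates of
    those new events are stored CSR-style: events of tick ``k`` occupy
    ``ev_x[ev_offsets[k]:ev_offsets[k+1]]`` (likewise ``ev_y``, ``ev_p``).
    """

    track_id: int
    t_ms: np.ndarray
    centre: np.ndarray  # (n_ticks, 2) float
    size: np.ndarray
    n_pos_live: np.ndarray
    n_neg_live: np.ndarray
    cluster_id: np.ndarray  # min member subcluster id per tick
    members: list
    inc_pos: np.ndarray
    inc_neg: np.ndarray
    ev_x: np.ndarray
    ev_y: np.ndarray
    ev_p: np.ndarray
    ev_offsets: np.ndarray

    @property
    def birth_ms(self) -> int:
        return int(self.t_ms[0])

    @property
    def death_ms(self) -> int:
        return int(self.t_ms[-1])

    @property
    def duration_ms(self) -> int:
        return self.death_ms - self.birth_ms

    @property
    def n_ticks(self) -> int:
        return len(self.t_ms)

    def tick_events(self, k: int):
        """(x, y, p) arrays of events newly absorbed during tick ``k``."""
        a, b = self.ev_offsets[k], self.ev_offsets[k + 1]
        return self.ev_x[a:b], self.ev_y[a:b], self.ev_p[a:b]


@dataclass
class TrackResult:
    tracks: list
    dropped_short: int
    config: TrackerConfig
    state_log: list | None = None  # per-tick (memberships, components) if recorded


class Tracker:
    """Incremental tracker; :func:`track_events` is the one-shot front end."""

    def __init__(self, config: TrackerConfig, width: int, record_state: bool = False):
        config.validate()
        self.config = config
        self.width = width
        self.lifetime_us = int(round(config.event_lifetime_ms * 1000))
        self.period_us = int(round(config.sample_period_ms * 1000))
        self.reach = (config.search_window - 1) // 2
        self.cap = config.subcluster_cap
        self.gap = config.merge_gap
        self.record_state = record_state
        self.subs: dict[int, _SubCluster] = {}
        self.grid: dict[int, dict[int, int]] = {}  # pixel key -> {sid: latest t}
        self.next_sid = 0
        self.next_order = 0
        self.active: dict[int, _Track] = {}  # keyed by order
        self.closed: list[ClusterTrack] = []
        self.dropped_short = 0
        self.state_log: list = []
        self.t0: int | None = None
        self.next_sample: int | None = None
        self.last_t: int | None = None

    # ------------------------------------------------------------------ assign
    def assign(self, t: int, x: int, y: int, p: int, idx: int = -1) -> int:
        """Absorb one event; returns the id of the receiving subcluster."""
        grid = self.grid
        width = self.width
        reach = self.reach
        cap1 = self.cap - 1
        cand: set[int] = set()
        for dy in range(-reach, reach + 1):
            row = (y + dy) * width + x
            for dx in range(-reach, reach + 1):
                d = grid.get(row + dx)
                if d:
                    cand.update(d)
        best_sid = -1
        if cand:
            best = None
            for sid in cand:
                sc = self.subs[sid]
                nmin_x = x if x < sc.min_x else sc.min_x
                nmax_x = x if x > sc.max_x else sc.max_x
                if nmax_x - nmin_x > cap1:
                    continue
                nmin_y = y if y < sc.min_y else sc.min_y
                nmax_y = y if y > sc.max_y else sc.max_y
                if nmax_y - nmin_y > cap1:
                    continue
                cx = sc.sum_x / sc.n
                cy = sc.sum_y / sc.n
                d2 = (cx - x) ** 2 + (cy - y) ** 2
                key = (d2, sid)
                if best is None or key < best:
                    best = key
                    best_sid = sid
        if best_sid < 0:
            best_sid = self.next_sid
            self.next_sid += 1
            self.subs[best_sid] = _SubCluster(best_sid)
        self.subs[best_sid].add(t, x, y, p, idx)
        key = y * width + x
        d = grid.get(key)
        if d is None:
            grid[key] = {best_sid: t}
        else:
            d[best_sid] = t
        return best_sid

    # ------------------------------------------------------------------ expiry
    def expire(self, now: int) -> None:
        """Retire events aged >= lifetime at sample time ``now`` (us)."""
        cutoff = now - self.lifetime_us
        dead = []
        for sid, sc in self.subs.items():
            if sc.ts and sc.ts[0] <= cutoff:
                sc.expire(cutoff, self.grid, self.width)
            if sc.n == 0:
                dead.append(sid)
        for sid in dead:
            del self.subs[sid]

    # ----------------------------------------------------------------- merging
    def components(self) -> list[tuple[int, ...]]:
        """Connected components of bbox adjacency (overlap/touch within merge_gap)."""
        subs = self.subs
        if not subs:
            return []
        sids = list(subs)
        parent = {s: s for s in sids}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        # spatial hash with buckets wide enough that neighbours share a cell ring
        cell = self.cap + self.gap + 1
        buckets: dict[tuple[int, int], list[int]] = {}
        gap = self.gap
        for s in sids:
            sc = subs[s]
            bx0 = (sc.min_x - gap) // cell
            bx1 = (sc.max_x + gap) // cell
            by0 = (sc.min_y - gap) // cell
            by1 = (sc.max_y + gap) // cell
            for by in range(by0, by1 + 1):
                for bx in range(bx0, bx1 + 1):
                    lst = buckets.setdefault((bx, by), [])
                    for other in lst:
                        if other == s:
                            continue
                        oc = subs[other]
                        if (
                            oc.min_x - sc.max_x <= gap
                            and sc.min_x - oc.max_x <= gap
                            and oc.min_y - sc.max_y <= gap
                            and sc.min_y - oc.max_y <= gap
                        ):
                            ra, rb = find(s), find(other)
                            if ra != rb:
                                parent[ra] = rb
                    if s not in lst:
                        lst.append(s)
        groups: dict[int, list[int]] = {}
        for s in sids:
            groups.setdefault(find(s), []).append(s)
        return [tuple(sorted(g)) for g in groups.values()]

    # ------------------------------------------------------------------- ticks
    def flush(self, now: int) -> None:
        """Run expiry + merging at sample time ``now`` and extend the tracks."""
        self.expire(now)
        # claim order: the component absorbing the most new events this tick
        # is where the particle currently is, so it keeps the track identity
        # when a cluster splits (e.g. a fast body outrunning its event trail);
        # ties go to the larger live component, then the lowest id
        comps = sorted(
            self.components(),
            key=lambda c: (
                -sum(len(self.subs[s].new_x) for s in c),
                -sum(self.subs[s].n for s in c),
                c[0],
            ),
        )
        t_ms = (now - self.t0) // 1000
        sid2track: dict[int, _Track] = {}
        for tr in self.active.values():
            for sid in tr.last_members:
                sid2track[sid] = tr
        claimed: set[int] = set()
        new_active: dict[int, _Track] = {}
        for comp in comps:
            cands = sorted(
                {sid2track[s].order for s in comp if s in sid2track}
            )
            tr = None
            for order in cands:
                if order not in claimed:
                    tr = self.active[order]
                    break
            if tr is None:
                tr = _Track(self.next_order, comp)
                self.next_order += 1
            claimed.add(tr.order)
            new_active[tr.order] = tr
            # per-tick record
            sum_x = sum_y = n = npos = nneg = 0
            ip = ineg = 0
            for s in comp:
                sc = self.subs[s]
                sum_x += sc.sum_x
                sum_y += sc.sum_y
                n += sc.n
                npos += sc.n_pos
                nneg += sc.n_neg
                for pp in sc.new_p:
                    if pp > 0:
                        ip += 1
                    else:
                        ineg += 1
                tr.ev_x.extend(sc.new_x)
                tr.ev_y.extend(sc.new_y)
                tr.ev_p.extend(sc.new_p)
            tr.t_ms.append(int(t_ms))
            tr.members.append(comp)
            tr.cluster_id.append(comp[0])
            tr.cx.append(sum_x / n)
            tr.cy.append(sum_y / n)
            tr.size.append(n)
            tr.n_pos_live.append(npos)
            tr.n_neg_live.append(nneg)
            tr.inc_pos.append(ip)
            tr.inc_neg.append(ineg)
            tr.ev_offsets.append(len(tr.ev_x))
            tr.last_members = frozenset(comp)
        # clear new-event buffers (including subclusters in no component: none,
        # every live subcluster is in exactly one component)
        for sc in self.subs.values():
            sc.new_x.clear()
            sc.new_y.clear()
            sc.new_p.clear()
        for order, tr in list(self.active.items()):
            if order not in claimed:
                self._close(tr)
        self.active = new_active
        if self.record_state:
            memberships = {
                sid: tuple(sorted(sc.idxs)) for sid, sc in self.subs.items()
            }
            self.state_log.append(
                (int(t_ms), memberships, frozenset(frozenset(c) for c in comps))
            )

    def _close(self, tr: _Track) -> None:
        if len(tr.t_ms) < self.config.min_track_ticks:
            self.dropped_short += 1
            return
        self.closed.append(
            ClusterTrack(
                track_id=tr.track_id,
                t_ms=np.asarray(tr.t_ms, np.int64),
                centre=np.column_stack(
                    [np.asarray(tr.cx, float), np.asarray(tr.cy, float)]
                ),
                size=np.asarray(tr.size, np.int64),
                n_pos_live=np.asarray(tr.n_pos_live, np.int64),
                n_neg_live=np.asarray(tr.n_neg_live, np.int64),
                cluster_id=np.asarray(tr.cluster_id, np.int64),
                members=tr.members,
                inc_pos=np.asarray(tr.inc_pos, np.int64),
                inc_neg=np.asarray(tr.inc_neg, np.int64),
                ev_x=np.asarray(tr.ev_x, np.int32),
                ev_y=np.asarray(tr.ev_y, np.int32),
                ev_p=np.asarray(tr.ev_p, np.int8),
                ev_offsets=np.asarray(tr.ev_offsets, np.int64),
            )
        )

    # --------------------------------------------------------------- streaming
    def process(self, stream: EventStream) -> None:
        ev = stream.events
        n = len(ev)
        if n == 0:
            return
        ts = ev["t"].tolist()
        xs = ev["x"].tolist()
        ys = ev["y"].tolist()
        ps = ev["p"].tolist()
        if self.t0 is None:
            self.t0 = ts[0]
            self.next_sample = self.t0 + self.period_us
        assign = self.assign
        for i in range(n):
            t = ts[i]
            if self.last_t is not None and t < self.last_t:
                raise OrderingError(f"event {i} out of order")
            while t >= self.next_sample:
                self.flush(self.next_sample)
                self.next_sample += self.period_us
            assign(t, xs[i], ys[i], ps[i], i)
            self.last_t = t

    def finish(self) -> TrackResult:
        if self.t0 is not None:
            self.flush(self.next_sample)
        for tr in self.active.values():
            self._close(tr)
        self.active = {}
        tracks = sorted(self.closed, key=lambda c: (c.birth_ms, c.track_id))
        return TrackResult(
            tracks=tracks,
            dropped_short=self.dropped_short,
            config=self.config,
            state_log=self.state_log if self.record_state else None,
        )


def track_events(
    stream: EventStream,
    config: TrackerConfig | None = None,
    record_state: bool = False,
) -> TrackResult:
    """Run the full assign/expire/merge pipeline over a stream.

    ``record_state=True`` additionally logs, at every sample tick, the exact
    live-event membership of each subcluster and the cluster components —
    used to cross-check the incremental tracker against naive recomputation.
    """
    config = config or TrackerConfig()
    tracker = Tracker(config, stream.width, record_state=record_state)
    tracker.process(stream.validate())
    return tracker.finish()


def tracks_to_frame(tracks) -> pd.DataFrame:
    """Flatten tracks into the per-tick export table."""
    rows = {
        "cluster_id": [],
        "t_ms": [],
        "centre_x": [],
        "centre_y": [],
        "n_pos_inc": [],
        "n_neg_inc": [],
        "n_subclusters": [],
    }
    for tr in tracks:
        k = tr.n_ticks
        rows["cluster_id"].extend([tr.track_id] * k)
        rows["t_ms"].extend(tr.t_ms.tolist())
        rows["centre_x"].extend(tr.centre[:, 0].tolist())
        rows["centre_y"].extend(tr.centre[:, 1].tolist())
        rows["n_pos_inc"].extend(tr.inc_pos.tolist())
        rows["n_neg_inc"].extend(tr.inc_neg.tolist())
        rows["n_subclusters"].extend([len(m) for m in tr.members])
    return pd.DataFrame(rows)
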