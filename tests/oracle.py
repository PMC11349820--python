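"""Brute-force reference tracker used to cross-check the incremental one.

Replays the event-to-subcluster assignment rule naively (full scans, list
filtering, exhaustive pairwise bounding-box adjacency) with no shared code
or state with ``evplankton.tracking``.
"""

from __future__ import annotations

import itertools


def naive_state_log(stream, config):
    """Replay a stream; returns [(t_ms, memberships, components), ...].

    ``memberships`` maps subcluster id -> sorted tuple of live event
    indices; ``components`` is a frozenset of frozensets of subcluster ids.
    """
    lifetime_us = int(round(config.event_lifetime_ms * 1000))
    period_us = int(round(config.sample_period_ms * 1000))
    reach = (config.search_window - 1) // 2
    cap = config.subcluster_cap
    gap = config.merge_gap

    subs: dict[int, list] = {}  # sid -> [(idx, t, x, y), ...]
    next_sid = 0
    log = []

    ev = stream.events
    if not len(ev):
        return log
    t0 = int(ev["t"][0])
    next_s = t0 + period_us

    def bbox(events):
        xs = [e[2] for e in events]
        ys = [e[3] for e in events]
        return min(xs), max(xs), min(ys), max(ys)

    def flush(now):
        nonlocal subs
        cutoff = now - lifetime_us
        subs = {
            sid: [e for e in events if e[1] > cutoff]
            for sid, events in subs.items()
        }
        subs = {sid: events for sid, events in subs.items() if events}
        memberships = {
            sid: tuple(sorted(e[0] for e in events))
            for sid, events in subs.items()
        }
        sids = sorted(subs)
        adj = {s: set() for s in sids}
        for a, b in itertools.combinations(sids, 2):
            ax0, ax1, ay0, ay1 = bbox(subs[a])
            bx0, bx1, by0, by1 = bbox(subs[b])
            if (
                max(bx0 - ax1, ax0 - bx1, 0) <= gap
                and max(by0 - ay1, ay0 - by1, 0) <= gap
            ):
                adj[a].add(b)
                adj[b].add(a)
        comps = []
        seen = set()
        for s in sids:
            if s in seen:
                continue
            comp, queue = set(), [s]
            while queue:
                c = queue.pop()
                if c in comp:
                    continue
                comp.add(c)
                queue.extend(adj[c] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        log.append(((now - t0) // 1000, memberships, frozenset(comps)))

    for i in range(len(ev)):
        t, x, y = int(ev["t"][i]), int(ev["x"][i]), int(ev["y"][i])
        while t >= next_s:
            flush(next_s)
            next_s += period_us
        best = None
        for sid, events in subs.items():
            if not any(
                abs(e[2] - x) <= reach and abs(e[3] - y) <= reach for e in events
            ):
                continue
            xs = [e[2] for e in events] + [x]
            ys = [e[3] for e in events] + [y]
            if max(xs) - min(xs) > cap - 1 or max(ys) - min(ys) > cap - 1:
                continue
            n = len(events)
            cx = sum(e[2] for e in events) / n
            cy = sum(e[3] for e in events) / n
            d2 = (cx - x) ** 2 + (cy - y) ** 2
            if best is None or (d2, sid) < best:
                best = (d2, sid)
        if best is None:
            sid = next_sid
            next_sid += 1
            subs[sid] = []
        else:
            sid = best[1]
        subs[sid].append((i, t, x, y))
    flush(next_s)
    return log
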