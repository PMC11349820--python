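"""End-to-end orchestration: simulate/track/featurize/classify and
ground-truth evaluation helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CategoryLabel, classify_category
from .exceptions import InsufficientDataError
from .features import FeatureConfig, compute_features, features_to_frame
from .synth import GroundTruth, SceneSpec, simulate
from .tracking import TrackerConfig, TrackResult, track_events

__all__ = [
    "analyse_stream",
    "run_scene",
    "match_tracks",
    "SceneEvaluation",
    "evaluate_scene",
]


def analyse_stream(
    stream, tracker_config=None, feature_config=None, min_events: int = 20
):
    """Track a stream and compute features + categories for every usable track.

    Returns (track_result, table) where the table has one row per track
    with F01..F22, the validity mask and the assigned category.  Tracks too
    short or degenerate for features, or with fewer than ``min_events``
    events (isolated sensor noise, not particles), are skipped from the
    table but stay in ``track_result.tracks``.
    """
    tracker_config = tracker_config or TrackerConfig()
    feature_config = (feature_config or FeatureConfig()).validate()
    result = track_events(stream, tracker_config)
    fvs, ids, cats, kept = [], [], [], []
    for i, tr in enumerate(result.tracks):
        if len(tr.ev_x) < min_events:
            continue
        try:
            fv = compute_features(tr, feature_config)
        except InsufficientDataError:
            continue
        fvs.append(fv)
        ids.append(tr.track_id)
        cats.append(str(classify_category(fv, feature_config)))
        kept.append(i)
    table = features_to_frame(fvs, ids) if fvs else features_to_frame([], [])
    table["category"] = cats
    table["track_index"] = kept
    return result, table


def run_scene(scene: SceneSpec, tracker_config=None, feature_config=None):
    """Simulate a scene and analyse it; returns (stream, truth, result, table)."""
    stream, truth = simulate(scene)
    result, table = analyse_stream(stream, tracker_config, feature_config)
    return stream, truth, result, table


def match_tracks(
    result: TrackResult,
    truth: GroundTruth,
    stream,
    max_distance: float = 25.0,
    lag_ms: float | None = None,
) -> dict[int, int]:
    """Greedy one-to-one match of ground-truth particles to tracks.

    A track centre is the centroid of its live events, which trail the true
    centre by roughly half the event lifetime along the motion; truth is
    therefore evaluated ``lag_ms`` (default: half the lifetime) earlier.
    Returns {particle index -> track index} for pairs whose median distance
    is below ``max_distance`` pixels.
    """
    if lag_ms is None:
        lag_ms = result.config.event_lifetime_ms / 2
    if not len(stream.events) or not result.tracks:
        return {}
    t0_ms = float(stream.events["t"][0]) / 1000.0
    pairs = []
    for pid, (traj_t, traj_xy) in enumerate(truth.trajectories):
        if len(traj_t) == 0:
            continue
        for tidx, tr in enumerate(result.tracks):
            t_abs = t0_ms + tr.t_ms.astype(float)
            query = t_abs[::20] - lag_ms
            lo, hi = traj_t[0], traj_t[-1]
            sel = (query >= lo) & (query <= hi)
            if sel.sum() < 3:
                continue
            tx = np.interp(query[sel], traj_t, traj_xy[:, 0])
            ty = np.interp(query[sel], traj_t, traj_xy[:, 1])
            d = np.hypot(
                tr.centre[::20][sel, 0] - tx, tr.centre[::20][sel, 1] - ty
            )
            med = float(np.median(d))
            if med <= max_distance:
                # prefer the track covering most of the particle's life, then
                # the spatially closest — fragments lose to the main track
                pairs.append((-int(sel.sum()), med, pid, tidx))
    pairs.sort()
    matched: dict[int, int] = {}
    used_tracks: set[int] = set()
    for _neg_overlap, med, pid, tidx in pairs:
        if pid in matched or tidx in used_tracks:
            continue
        matched[pid] = tidx
        used_tracks.add(tidx)
    return matched


@dataclass
class SceneEvaluation:
    n_particles: int
    n_matched: int
    n_correct: int
    per_particle: pd.DataFrame  # particle, true/predicted category, track id

    @property
    def recovery(self) -> float:
        """Fraction of particles matched to a track AND given their true category."""
        return self.n_correct / self.n_particles if self.n_particles else float("nan")


def evaluate_scene(
    scene: SceneSpec, tracker_config=None, feature_config=None
) -> SceneEvaluation:
    """Full pipeline + ground-truth comparison for one scene."""
    stream, truth, result, table = run_scene(scene, tracker_config, feature_config)
    matched = match_tracks(result, truth, stream)
    track_cat = dict(zip(table["track_index"], table["category"]))
    rows = []
    n_correct = 0
    for pid, true_cat in enumerate(truth.categories):
        tidx = matched.get(pid)
        pred = track_cat.get(tidx) if tidx is not None else None
        ok = pred == str(true_cat)
        n_correct += ok
        rows.append(
            {
                "particle": pid,
                "true_category": str(true_cat),
                "predicted_category": pred,
                "track_index": tidx,
                "correct": ok,
            }
        )
    return SceneEvaluation(
        n_particles=len(truth.categories),
        n_matched=len(matched),
        n_correct=n_correct,
        per_particle=pd.DataFrame(rows),
    )
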