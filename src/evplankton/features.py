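"""The 22 per-cluster characteristic features (F01-F22).

A tracked cluster is summarised by 22 numbers describing its movement
(average speed F01, acceleration peaks F05, speed variance F06), its shape in
a velocity-aligned frame (length F02, width F03, antenna indicator F04,
polarity-resolved roughness ratios F07-F12) and its periodicity (event-rate
FFT peak counts F13-F18 at 1 ms resolution; detrended centre-coordinate FFT
peak counts F19-F22 at 4 ms resolution).

All spectra use a rectangular window over the whole track duration (no
zero-padding), power in dB, and a peak is a strict local maximum rising at
least ``peak_threshold_db`` (default 15 dB) above the background level, taken
as the median of the non-DC power.  Peak frequencies are pooled over the
positive-, negative- and total-event spectra and binned into half-open
frequency segments: [0,1), [1,2.2), [2.2,4.6), [4.6,10), [10,22), [22,inf) Hz
for F13-F18 and [0,1), [1,2.2), [2.2,4.6), [4.6,inf) Hz for F19-F22.

Velocity units are pixels per millisecond (pxl/ms); lengths are pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft

from .exceptions import ConfigError, InsufficientDataError
from .tracking import ClusterTrack

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "PowerSpectrum",
    "FEATURE_NAMES",
    "centre_trajectory",
    "velocity_features",
    "shape_features",
    "event_increment_series",
    "coordinate_series",
    "power_spectrum",
    "count_peaks",
    "event_fft_features",
    "coord_fft_features",
    "compute_features",
    "features_to_frame",
]

FEATURE_NAMES = tuple(f"F{i:02d}" for i in range(1, 23))

_DB_FLOOR = -400.0  # stands in for -inf on exactly-zero spectral power


@dataclass
class FeatureConfig:
    """Parameters of the feature computation (defaults are the study values)."""

    segment_period_ms: float = 4.0  # trajectory segmentation / coordinate series
    increment_period_ms: float = 1.0  # event-increment series resolution
    accel_peak_factor: float = 5.0  # F05: peaks > factor x mean acceleration
    peak_threshold_db: float = 15.0  # spectral peak height above background
    event_fft_edges: tuple = (1.0, 2.2, 4.6, 10.0, 22.0)  # Hz, 6 segments
    coord_fft_edges: tuple = (1.0, 2.2, 4.6)  # Hz, 4 segments
    velocity_floor: float = 0.025  # pxl/ms, below which F06 is not consulted
    f06_threshold: float = 0.14  # variance-of-velocity split
    antenna_reach: float = 2.0  # px beyond half-width for F04 eligibility
    background: str = "local_median"  # or "median"/"mean" (global) for peaks
    min_series_len: int = 8  # shortest series admitted to the FFT

    def validate(self) -> "FeatureConfig":
        for name in (
            "segment_period_ms", "increment_period_ms", "accel_peak_factor",
            "peak_threshold_db", "velocity_floor", "f06_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for edges in (self.event_fft_edges, self.coord_fft_edges):
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ConfigError("frequency bin edges must increase strictly")
        if self.background not in ("local_median", "median", "mean"):
            raise ConfigError(
                "background must be 'local_median', 'median' or 'mean'"
            )
        ratio = self.segment_period_ms / self.increment_period_ms
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigError(
                "segment_period_ms must be an integer multiple of increment_period_ms"
            )
        return self

    @property
    def ticks_per_segment(self) -> int:
        return int(round(self.segment_period_ms / self.increment_period_ms))


@dataclass
class FeatureVector:
    """The 22 feature values plus a per-field validity mask.

    A feature whose preconditions failed (e.g. no negative events for
    F09-F12, zero velocity for the shape frame) is 0 with ``valid`` False.
    """

    values: np.ndarray  # shape (22,)
    valid: np.ndarray  # shape (22,), bool

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES))

    @property
    def peak_count(self) -> int:
        """Total FFT peaks, sum of F13-F22."""
        return int(round(self.values[12:22].sum()))


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz, 0 .. Nyquist
    power_db: np.ndarray
    source: str = ""


# --------------------------------------------------------------------- series


def _segment_groups(track: ClusterTrack, config: FeatureConfig):
    """Slice a track's new events into whole segments of ticks_per_segment.

    Returns (n_seg, list of (x, y, p) arrays per segment).  A trailing
    partial segment is dropped.
    """
    m = config.ticks_per_segment
    n_seg = track.n_ticks // m
    groups = []
    off = track.ev_offsets
    for s in range(n_seg):
        a, b = off[s * m], off[(s + 1) * m]
        groups.append((track.ev_x[a:b], track.ev_y[a:b], track.ev_p[a:b]))
    return n_seg, groups


def _segment_centres(groups, select=None):
    """Per-segment event centroids with carry-forward over empty segments.

    ``select`` filters events by polarity (+1, -1 or None for all).  Returns
    (centres (n,2), observed mask); leading empties copy the first observed
    centre.
    """
    n = len(groups)
    centres = np.zeros((n, 2))
    observed = np.zeros(n, bool)
    for i, (x, y, p) in enumerate(groups):
        if select is not None:
            keep = p == select
            x, y = x[keep], y[keep]
        if len(x):
            centres[i] = (x.mean(), y.mean())
            observed[i] = True
    if not observed.any():
        return centres, observed
    first = int(np.argmax(observed))
    centres[:first] = centres[first]
    for i in range(first + 1, n):
        if not observed[i]:
            centres[i] = centres[i - 1]
    return centres, observed


def centre_trajectory(track: ClusterTrack, config: FeatureConfig | None = None):
    """Cluster-centre positions at segment resolution (default 4 ms).

    The centre of a segment is the centroid of all events absorbed during
    it; segments with no events carry the previous centre (flagged False in
    the returned mask).  Returns (t_ms, centres (n,2), observed).
    """
    config = (config or FeatureConfig()).validate()
    n_seg, groups = _segment_groups(track, config)
    if n_seg < 2:
        raise InsufficientDataError(
            f"track spans {n_seg} segment(s); need at least 2"
        )
    centres, observed = _segment_centres(groups)
    if not observed.any():
        raise InsufficientDataError("track contains no events")
    t_ms = track.t_ms[0] + config.segment_period_ms * np.arange(n_seg)
    return t_ms, centres, observed


# ------------------------------------------------------------------- velocity


def velocity_features(centres: np.ndarray, config: FeatureConfig | None = None):
    """(F01, F05, F06) from a centre trajectory at segment resolution.

    Per-segment speed is |Delta centre| / segment_period; F01 is the mean
    speed, F06 the population variance of speed, and F05 counts accelerations
    (|Delta speed| / segment_period) exceeding ``accel_peak_factor`` times the
    mean acceleration.
    """
    config = (config or FeatureConfig()).validate()
    centres = np.asarray(centres, float)
    if len(centres) < 2:
        raise InsufficientDataError("need >= 2 centres for velocity")
    dt = config.segment_period_ms
    disp = np.diff(centres, axis=0)
    speeds = np.hypot(disp[:, 0], disp[:, 1]) / dt
    f01 = float(speeds.mean())
    f06 = float(speeds.var())  # population variance
    if len(speeds) < 2:
        f05 = None  # acceleration needs >= 3 centres; caller flags invalid
    else:
        accel = np.abs(np.diff(speeds)) / dt
        mean_accel = accel.mean()
        f05 = (
            int((accel > config.accel_peak_factor * mean_accel).sum())
            if mean_accel > 0
            else 0
        )
    return f01, f05, f06, speeds


# ---------------------------------------------------------------------- shape


def shape_features(
    track: ClusterTrack,
    centres: np.ndarray,
    config: FeatureConfig | None = None,
):
    """(F02, F03, F04, F07..F12, valid mask) in a velocity-aligned frame.

    For each trajectory segment the events are projected onto the unit
    vector of that segment's velocity (parallel axis) and its normal
    (orthogonal axis) through the segment centre.  F02/F03 are the mean
    pixel extents (max - min + 1) along the two axes.  F07-F10 are the mean
    per-segment variances of positive/negative event projections divided by
    F02/F03, F11/F12 the mean |positive - negative centroid| components
    divided by F02/F03, and F04 accumulates, over events whose orthogonal
    offset exceeds F03/2 + antenna_reach, the inner product of the segment
    velocity with the centre-to-event vector, divided by F02.
    """
    config = (config or FeatureConfig()).validate()
    n_seg, groups = _segment_groups(track, config)
    centres = np.asarray(centres, float)
    dt = config.segment_period_ms
    valid = np.ones(9, bool)  # F02,F03,F04,F07..F12

    par_ext, orth_ext = [], []
    var_pp, var_po, var_np_, var_no = [], [], [], []
    dist_par, dist_orth = [], []
    antenna_terms = []  # (segment velocity, offsets) deferred until F03 known
    for s in range(min(n_seg - 1, len(centres) - 1)):
        v = (centres[s + 1] - centres[s]) / dt
        speed = float(np.hypot(v[0], v[1]))
        if speed <= 0:
            continue
        u = v / speed
        w = np.array([-u[1], u[0]])
        x, y, p = groups[s]
        if not len(x):
            continue
        rel = np.column_stack([x - centres[s, 0], y - centres[s, 1]])
        proj_par = rel @ u
        proj_orth = rel @ w
        par_ext.append(proj_par.max() - proj_par.min() + 1)
        orth_ext.append(proj_orth.max() - proj_orth.min() + 1)
        pos = p > 0
        neg = ~pos
        if pos.any():
            var_pp.append(proj_par[pos].var())
            var_po.append(proj_orth[pos].var())
        if neg.any():
            var_np_.append(proj_par[neg].var())
            var_no.append(proj_orth[neg].var())
        if pos.any() and neg.any():
            dpar = proj_par[pos].mean() - proj_par[neg].mean()
            dorth = proj_orth[pos].mean() - proj_orth[neg].mean()
            dist_par.append(abs(dpar))
            dist_orth.append(abs(dorth))
        antenna_terms.append((v, rel, proj_orth))

    if not par_ext:
        # zero velocity (or no usable segment): axis undefined
        return np.zeros(9), np.zeros(9, bool)

    f02 = float(np.mean(par_ext))
    f03 = float(np.mean(orth_ext))
    half_width = f03 / 2 + config.antenna_reach
    acc = 0.0
    for v, rel, proj_orth in antenna_terms:
        far = np.abs(proj_orth) > half_width
        if far.any():
            acc += float((rel[far] @ v).sum())
    f04 = acc / f02

    def _ratio(values, denom, idx):
        if values:
            return float(np.mean(values)) / denom
        valid[idx] = False
        return 0.0

    f07 = _ratio(var_pp, f02, 3)
    f08 = _ratio(var_po, f03, 4)
    f09 = _ratio(var_np_, f02, 5)
    f10 = _ratio(var_no, f03, 6)
    f11 = _ratio(dist_par, f02, 7)
    f12 = _ratio(dist_orth, f03, 8)
    return np.array([f02, f03, f04, f07, f08, f09, f10, f11, f12]), valid


# -------------------------------------------------------------------- spectra


def event_increment_series(track: ClusterTrack, config: FeatureConfig | None = None):
    """Counts of newly absorbed events per 1 ms tick: (positive, negative, total)."""
    if track.n_ticks < 2:
        raise InsufficientDataError("track alive < 2 ticks")
    pos = track.inc_pos.astype(float)
    neg = track.inc_neg.astype(float)
    return pos, neg, pos + neg


def coordinate_series(track: ClusterTrack, config: FeatureConfig | None = None):
    """Detrended x/y centre series of positive, negative and total events.

    Six series at segment (4 ms) resolution.  Each has the unique linear
    function through its endpoints subtracted, so both endpoints are exactly
    0 — ballistic drift is removed and only deviations from straight-line
    motion remain.  Returns dict name -> series, e.g. ``"pos_x"``.
    """
    config = (config or FeatureConfig()).validate()
    n_seg, groups = _segment_groups(track, config)
    if n_seg < 4:
        raise InsufficientDataError("need >= 4 segments for coordinate series")
    out = {}
    for label, select in (("pos", 1), ("neg", -1), ("total", None)):
        centres, observed = _segment_centres(groups, select)
        if not observed.any():
            continue
        for axis, name in ((0, "x"), (1, "y")):
            out[f"{label}_{name}"] = _detrend_endpoints(centres[:, axis])
    return out


def _detrend_endpoints(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, float)
    n = len(series)
    ramp = np.linspace(series[0], series[-1], n)
    out = series - ramp
    out[0] = 0.0  # exact by construction; pin against rounding
    out[-1] = 0.0
    return out


def power_spectrum(
    series, sampling_period_ms: float, source: str = ""
) -> PowerSpectrum:
    """Rectangular-window power spectrum of a uniformly sampled series.

    Power is 10*log10(|X(f)|^2) on the one-sided DFT of the raw series (no
    zero padding), so the frequency grid depends on the track length; the
    grid spans 0 to the Nyquist frequency of the sampling rate.
    """
    series = np.asarray(series, float)
    if len(series) < 8:
        raise InsufficientDataError(
            f"series of {len(series)} samples; need >= 8 for a spectrum"
        )
    spec = scipy.fft.rfft(series)
    power = np.abs(spec) ** 2
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    power_db[~np.isfinite(power_db)] = _DB_FLOOR
    freqs = scipy.fft.rfftfreq(len(series), d=sampling_period_ms / 1000.0)
    return PowerSpectrum(freqs, power_db, source)


def count_peaks(spectrum: PowerSpectrum, config: FeatureConfig | None = None):
    """Count strict local maxima >= background + threshold; DC excluded.

    The default background level at each bin is the median of the non-DC
    power in dB over a sliding window around it (a local spectral floor):
    it is robust to the peaks themselves and follows any broadband
    colouration of the spectrum, in particular the 1/k^2 low-frequency
    baseline that endpoint-pinned detrending of a noisy series injects.
    ``background='median'``/``'mean'`` fall back to the global statistic.
    Adjacent super-threshold bins within one lobe count once because only
    the strict maximum qualifies.  Returns (count, peak frequencies in Hz).
    """
    config = (config or FeatureConfig()).validate()
    p = spectrum.power_db
    if len(p) < 3:
        return 0, np.empty(0)
    # bins more than 120 dB below the spectral maximum are numerical
    # round-off, not signal; they can never qualify as peaks
    dynamic_floor = p.max() - 120.0
    non_dc = p[1:]
    n = len(non_dc)
    thr = np.empty_like(non_dc)
    if config.background == "local_median":
        half = max(5, n // 40)
        for j in range(n):
            lo = max(0, j - half)
            hi = min(n, j + half + 1)
            thr[j] = np.median(non_dc[lo:hi])
    elif config.background == "median":
        thr[:] = np.median(non_dc)
    else:
        thr[:] = non_dc.mean()
    thr += config.peak_threshold_db
    interior = np.arange(1, len(p) - 1)
    is_peak = (
        (p[interior] > p[interior - 1])
        & (p[interior] > p[interior + 1])
        & (p[interior] >= thr[interior - 1])
        & (p[interior] >= dynamic_floor)
    )
    idx = interior[is_peak]
    return int(len(idx)), spectrum.frequencies[idx]


def _bin_peaks(freqs, edges, n_bins) -> np.ndarray:
    counts = np.zeros(n_bins, int)
    for f in freqs:
        counts[int(np.searchsorted(edges, f, side="right"))] += 1
    return counts


def event_fft_features(track: ClusterTrack, config: FeatureConfig | None = None):
    """(F13..F18, peak frequencies) from the 1 ms event-increment spectra.

    Peaks from the positive, negative and total spectra are pooled; each
    peak frequency falls in exactly one half-open segment.
    """
    config = (config or FeatureConfig()).validate()
    pos, neg, tot = event_increment_series(track, config)
    all_freqs = []
    for series, src in ((pos, "positive"), (neg, "negative"), (tot, "total")):
        if len(series) < config.min_series_len:
            raise InsufficientDataError("increment series too short for FFT")
        _, freqs = count_peaks(
            power_spectrum(series, config.increment_period_ms, src), config
        )
        all_freqs.append(freqs)
    freqs = np.concatenate(all_freqs) if all_freqs else np.empty(0)
    return _bin_peaks(freqs, config.event_fft_edges, 6), freqs


def dominant_event_peak(
    track: ClusterTrack, config: FeatureConfig | None = None
) -> float | None:
    """Frequency (Hz) of the highest-power detected event-FFT peak.

    Pools the detected peaks of the positive/negative/total increment
    spectra and returns the frequency of the most powerful one, or None if
    no peak crosses the threshold anywhere.
    """
    config = (config or FeatureConfig()).validate()
    pos, neg, tot = event_increment_series(track, config)
    best = None
    for series, src in ((pos, "positive"), (neg, "negative"), (tot, "total")):
        spec = power_spectrum(series, config.increment_period_ms, src)
        _, freqs = count_peaks(spec, config)
        for f in freqs:
            idx = int(np.argmin(np.abs(spec.frequencies - f)))
            p = spec.power_db[idx]
            if best is None or p > best[0]:
                best = (p, float(f))
    return None if best is None else best[1]


def coord_fft_features(track: ClusterTrack, config: FeatureConfig | None = None):
    """(F19..F22, peak frequencies) from the 4 ms detrended coordinate spectra."""
    config = (config or FeatureConfig()).validate()
    series = coordinate_series(track, config)
    all_freqs = []
    for name, s in series.items():
        if len(s) < config.min_series_len:
            raise InsufficientDataError("coordinate series too short for FFT")
        _, freqs = count_peaks(
            power_spectrum(s, config.segment_period_ms, name), config
        )
        all_freqs.append(freqs)
    freqs = np.concatenate(all_freqs) if all_freqs else np.empty(0)
    return _bin_peaks(freqs, config.coord_fft_edges, 4), freqs


# ------------------------------------------------------------------- assembly


def compute_features(
    track: ClusterTrack, config: FeatureConfig | None = None
) -> FeatureVector:
    """Assemble the full 22-value feature vector for one track.

    Deterministic: recomputation on the same track is bit-identical.
    Component features whose preconditions fail are 0 and flagged invalid;
    a track too short for even the centre trajectory raises
    :class:`InsufficientDataError`.
    """
    config = (config or FeatureConfig()).validate()
    values = np.zeros(22)
    valid = np.zeros(22, bool)

    _, centres, _ = centre_trajectory(track, config)

    f01, f05, f06, _ = velocity_features(centres, config)
    values[0], values[5] = f01, f06
    valid[[0, 5]] = True
    if f05 is not None:
        values[4] = f05
        valid[4] = True

    shape_vals, shape_valid = shape_features(track, centres, config)
    values[[1, 2, 3, 6, 7, 8, 9, 10, 11]] = shape_vals
    valid[[1, 2, 3, 6, 7, 8, 9, 10, 11]] = shape_valid

    try:
        ev_counts, _ = event_fft_features(track, config)
        values[12:18] = ev_counts
        valid[12:18] = True
    except InsufficientDataError:
        pass
    try:
        co_counts, _ = coord_fft_features(track, config)
        values[18:22] = co_counts
        valid[18:22] = True
    except InsufficientDataError:
        pass
    return FeatureVector(values, valid)


def features_to_frame(feature_vectors, cluster_ids=None) -> pd.DataFrame:
    """Stack feature vectors into the export table (F01..F22 + validity mask)."""
    rows = [fv.values for fv in feature_vectors]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if cluster_ids is not None:
        df.insert(0, "cluster_id", list(cluster_ids))
    df["valid_mask"] = [
        "".join("1" if v else "0" for v in fv.valid) for fv in feature_vectors
    ]
    return df
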