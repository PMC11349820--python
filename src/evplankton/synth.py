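"""Synthetic event-stream simulator with ground truth.

Generates the kinds of scenes an underwater event camera records, with
known per-particle ground truth so every pipeline stage is testable:

* **drifter** — a rigid body carried passively by the flow;
* **beater** — a body whose event rate is modulated by a sawtooth at the
  appendage-beat frequency (rhythmic limb motion changes how much of the
  body edge moves per unit time);
* **oscillator** — a body whose centre oscillates sinusoidally orthogonal
  to its drift (lateral swimming undulation);
* **spiral** — a body whose centre follows a circular orbit superimposed on
  the drift (helical larval swimming seen in 2-D projection).

Event generation is Poisson per 1 ms tick at the (possibly modulated) base
rate.  Events on the leading half of the body ellipse are mostly positive
(brightness rises as the bright body advances over dark background), the
trailing half mostly negative.  Optional forward-angled antenna rays place
events outside the body width.  Sensor background noise is uniform in space
and time with equiprobable polarity.

All randomness flows from the scene seed through per-particle child seeds,
so scenes are reproducible piecewise regardless of particle order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import sawtooth
from scipy.special import erf

from .classify import CategoryLabel
from .exceptions import ConfigError
from .features import FeatureConfig
from .io import EventStream

__all__ = [
    "ParticleSpec",
    "SceneSpec",
    "GroundTruth",
    "simulate",
    "true_category",
    "make_benchmark_suite",
    "make_species_feature_benchmark",
    "scene_from_dict",
    "scene_to_dict",
]

_NOISE_STREAM = 999983  # child-seed slot reserved for background noise


@dataclass
class ParticleSpec:
    """Generative parameters of one simulated particle."""

    kind: str = "drifter"  # drifter | beater | oscillator | spiral
    start: tuple = (100.0, 100.0)  # initial centre, px
    half_axes: tuple = (5.0, 3.0)  # body semi-axes (along/across heading), px
    velocity: tuple = (0.0, 0.0)  # own drift, pxl/ms (flow is added on top)
    freq_hz: float = 0.0  # modulation frequency for beater/oscillator/spiral
    beat_depth: float = 0.0  # fractional event-rate modulation depth
    osc_amplitude_px: float = 0.0  # centre-oscillation amplitude
    rate: float = 8.0  # base event rate, events/ms
    leading_pos_fraction: float = 0.9  # P(positive) on the leading body half
    speed_jitter: float = 0.0  # pxl/ms std of along-heading speed noise (per 4 ms)
    pulse_prob: float = 0.0  # P(speed pulse) per 4 ms block (hop-and-sink jumps)
    pulse_speed: float = 0.0  # exponential scale of pulse magnitude, pxl/ms
    start_ms: float = 0.0
    lifetime_ms: float = 1000.0
    antenna_px: float = 0.0  # forward antenna ray length
    antenna_fraction: float = 0.15  # fraction of events placed on the antenna

    def validate(self) -> "ParticleSpec":
        if self.kind not in ("drifter", "beater", "oscillator", "spiral"):
            raise ConfigError(f"unknown particle kind {self.kind!r}")
        if self.rate < 0 or self.freq_hz < 0:
            raise ConfigError("rate and freq_hz must be >= 0")
        if self.lifetime_ms <= 0:
            raise ConfigError("lifetime_ms must be positive")
        if not 0 <= self.leading_pos_fraction <= 1:
            raise ConfigError("leading_pos_fraction must be in [0,1]")
        return self


@dataclass
class SceneSpec:
    """A full scene: geometry, duration, particles, noise, flow and seed."""

    geometry: tuple = (1280, 720)
    duration_ms: float = 1000.0
    particles: list = field(default_factory=list)
    noise_rate: float = 0.0  # events/ms over the whole frame
    flow: tuple = (0.0, 0.0)  # global velocity added to every particle, pxl/ms
    seed: int = 0

    def validate(self) -> "SceneSpec":
        if self.duration_ms <= 0:
            raise ConfigError("duration_ms must be positive")
        if self.noise_rate < 0:
            raise ConfigError("noise_rate must be >= 0")
        for p in self.particles:
            p.validate()
        return self


@dataclass
class GroundTruth:
    """Per-particle truth plus an event -> particle provenance map."""

    trajectories: list  # per particle: (t_ms array, centres (n,2))
    categories: list  # CategoryLabel per particle
    frequencies: list  # modulation frequency per particle (0 if none)
    provenance: np.ndarray  # per stream event: particle index, -1 for noise
    clipped: int = 0  # events clipped to the frame boundary


def _heading(vx, vy):
    s = math.hypot(vx, vy)
    if s == 0:
        return np.array([0.0, 1.0]), np.array([-1.0, 0.0])
    u = np.array([vx / s, vy / s])
    return u, np.array([-u[1], u[0]])


def _particle_events(spec: ParticleSpec, scene: SceneSpec, rng):
    """Simulate one particle; returns (t_us, x, y, p, traj_t_ms, traj_xy, clipped)."""
    n_ticks = int(round(spec.lifetime_ms))
    v0 = np.array(spec.velocity, float) + np.array(scene.flow, float)
    u, w = _heading(*v0)
    speed0 = float(np.hypot(*v0))

    # per-tick speed along the heading; noise is held for 4 ms stretches
    speeds = np.full(n_ticks, speed0)
    n_seg = (n_ticks + 3) // 4
    if spec.speed_jitter > 0:
        jit = rng.normal(0.0, spec.speed_jitter, n_seg)
        speeds = speeds + np.repeat(jit, 4)[:n_ticks]
    if spec.pulse_prob > 0 and spec.pulse_speed > 0:
        # intermittent forward speed pulses (escape-jump style locomotion)
        pulse = rng.exponential(spec.pulse_speed, n_seg) * (
            rng.random(n_seg) < spec.pulse_prob
        )
        speeds = speeds + np.repeat(pulse, 4)[:n_ticks]
    vel = speeds[:, None] * u  # pxl/ms

    t_ms = spec.start_ms + np.arange(n_ticks, dtype=float)
    base = np.array(spec.start, float) + np.concatenate(
        [np.zeros((1, 2)), np.cumsum(vel, axis=0)[:-1]]
    )
    # reflect off a margin so jittered walks stay in frame
    margin = max(spec.half_axes) + spec.antenna_px + 2
    for axis, limit in ((0, scene.geometry[0]), (1, scene.geometry[1])):
        lo, hi = margin, limit - margin
        if hi <= lo:
            raise ConfigError("particle too large for the scene geometry")
        span = hi - lo
        folded = np.mod(base[:, axis] - lo, 2 * span)
        base[:, axis] = lo + np.where(folded <= span, folded, 2 * span - folded)

    phase = 2 * math.pi * spec.freq_hz * t_ms / 1000.0
    centres = base.copy()
    if spec.kind == "oscillator" and spec.osc_amplitude_px > 0:
        centres = centres + spec.osc_amplitude_px * np.sin(phase)[:, None] * w
    elif spec.kind == "spiral" and spec.osc_amplitude_px > 0:
        centres = centres + spec.osc_amplitude_px * np.column_stack(
            [np.cos(phase), np.sin(phase)]
        )

    rates = np.full(n_ticks, spec.rate)
    if spec.kind == "beater" and spec.beat_depth > 0 and spec.freq_hz > 0:
        rates = spec.rate * np.maximum(0.0, 1.0 + spec.beat_depth * sawtooth(phase))

    counts = rng.poisson(rates)
    total = int(counts.sum())
    if total == 0:
        return (
            np.empty(0, np.int64), np.empty(0, int), np.empty(0, int),
            np.empty(0, int), t_ms, centres, 0,
        )
    tick_of = np.repeat(np.arange(n_ticks), counts)
    t_us = (
        (spec.start_ms * 1000).__int__()
        + tick_of * 1000
        + rng.integers(0, 1000, total)
    ).astype(np.int64)

    a, b = spec.half_axes
    r = np.sqrt(rng.random(total))
    ang = rng.uniform(0, 2 * math.pi, total)
    off_par = a * r * np.cos(ang)
    off_orth = b * r * np.sin(ang)
    if spec.antenna_px > 0 and spec.antenna_fraction > 0:
        on_ant = rng.random(total) < spec.antenna_fraction
        n_ant = int(on_ant.sum())
        if n_ant:
            d = rng.uniform(0, spec.antenna_px, n_ant)
            side = np.where(rng.random(n_ant) < 0.5, 1.0, -1.0)
            off_par[on_ant] = d * math.cos(math.pi / 4)
            off_orth[on_ant] = side * d * math.sin(math.pi / 4)
    offsets = off_par[:, None] * u + off_orth[:, None] * w
    pos = centres[tick_of] + offsets

    leading = off_par >= 0
    draw = rng.random(total)
    p = np.where(
        leading,
        np.where(draw < spec.leading_pos_fraction, 1, -1),
        np.where(draw < spec.leading_pos_fraction, -1, 1),
    )

    xi = np.rint(pos[:, 0]).astype(int)
    yi = np.rint(pos[:, 1]).astype(int)
    clip_x = np.clip(xi, 0, scene.geometry[0] - 1)
    clip_y = np.clip(yi, 0, scene.geometry[1] - 1)
    clipped = int(((clip_x != xi) | (clip_y != yi)).sum())
    # ticks generate events unordered within the tick; sort the particle stream
    order = np.argsort(t_us, kind="stable")
    return t_us[order], clip_x[order], clip_y[order], p[order], t_ms, centres, clipped


def simulate(scene: SceneSpec) -> tuple[EventStream, GroundTruth]:
    """Render a scene into a time-ordered event stream plus ground truth."""
    scene.validate()
    parts = []
    trajectories = []
    categories = []
    frequencies = []
    clipped = 0
    for pid, spec in enumerate(scene.particles):
        rng = np.random.default_rng([scene.seed, pid])
        t, x, y, p, traj_t, traj_xy, nclip = _particle_events(spec, scene, rng)
        parts.append((t, x, y, p, np.full(len(t), pid)))
        trajectories.append((traj_t, traj_xy))
        categories.append(true_category(spec, scene))
        frequencies.append(spec.freq_hz)
        clipped += nclip

    rng = np.random.default_rng([scene.seed, _NOISE_STREAM])
    n_noise = rng.poisson(scene.noise_rate * scene.duration_ms)
    if n_noise:
        t = np.sort(rng.integers(0, int(scene.duration_ms * 1000), n_noise)).astype(
            np.int64
        )
        x = rng.integers(0, scene.geometry[0], n_noise)
        y = rng.integers(0, scene.geometry[1], n_noise)
        p = np.where(rng.random(n_noise) < 0.5, 1, -1)
        parts.append((t, x, y, p, np.full(n_noise, -1)))

    if parts:
        t = np.concatenate([q[0] for q in parts])
        x = np.concatenate([q[1] for q in parts])
        y = np.concatenate([q[2] for q in parts])
        p = np.concatenate([q[3] for q in parts])
        prov = np.concatenate([q[4] for q in parts])
        order = np.argsort(t, kind="stable")
        stream = EventStream.from_arrays(
            t[order], x[order], y[order], p[order], scene.geometry
        )
        prov = prov[order]
    else:
        stream = EventStream.from_arrays([], [], [], [], scene.geometry)
        prov = np.empty(0, int)
    return stream, GroundTruth(trajectories, categories, frequencies, prov, clipped)


def _folded_normal_stats(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and variance of |N(mu, sigma^2)|."""
    if sigma == 0:
        return abs(mu), 0.0
    m = sigma * math.sqrt(2 / math.pi) * math.exp(
        -(mu**2) / (2 * sigma**2)
    ) + mu * erf(mu / (sigma * math.sqrt(2)))
    return m, mu**2 + sigma**2 - m**2


def true_category(
    spec: ParticleSpec,
    scene: SceneSpec | None = None,
    config: FeatureConfig | None = None,
) -> CategoryLabel:
    """Category implied by the generative parameters (construction-level truth).

    The per-segment speed of a jittered particle is |N(v0, jitter^2)| along
    its heading, so the expected mean speed and speed variance follow the
    folded-normal formulas; these are compared against the velocity floor
    and the variance-of-velocity threshold exactly as the classifier does.
    """
    config = config or FeatureConfig()
    flow = np.array(scene.flow, float) if scene is not None else np.zeros(2)
    v0 = float(np.hypot(*(np.array(spec.velocity, float) + flow)))
    mean_speed, var_speed = _folded_normal_stats(v0, spec.speed_jitter)
    if spec.pulse_prob > 0 and spec.pulse_speed > 0:
        q, s = spec.pulse_prob, spec.pulse_speed
        mean_speed += q * s
        var_speed += s * s * q * (2 - q)
    # the pipeline measures speed on segments misaligned with the 4 ms noise
    # blocks, which mixes adjacent blocks and roughly halves the variance
    var_speed *= 0.5
    modulated = spec.kind != "drifter" and spec.freq_hz > 0 and (
        spec.beat_depth > 0 or spec.osc_amplitude_px > 0
    )
    if mean_speed > config.velocity_floor and var_speed > config.f06_threshold:
        return CategoryLabel.ACTIVE if modulated else CategoryLabel.DYNAMIC
    return CategoryLabel.BEATING if modulated else CategoryLabel.PASSIVE


# ----------------------------------------------------------------- benchmark

BEAT_SWEEP_HZ = (0.5, 1.5, 3.0, 7.0, 15.0, 30.0)


def make_beater_scene(freq_hz: float, seed: int, duration_ms: float = 4200.0) -> SceneSpec:
    """One slowly drifting beater; ~4 s so the spectrum resolves 0.5 Hz."""
    return SceneSpec(
        geometry=(320, 240),
        duration_ms=duration_ms,
        particles=[
            ParticleSpec(
                kind="beater",
                start=(60.0, 60.0),
                velocity=(0.04, 0.02),
                freq_hz=freq_hz,
                beat_depth=0.5,
                rate=8.0,
                lifetime_ms=duration_ms,
            )
        ],
        noise_rate=0.2,
        seed=seed,
    )


def make_lake_scene(seed: int) -> SceneSpec:
    """Synthetic lake-like scene: a field of drifters sharing a downward flow,
    four rhythmic swimmers heading against it, and two erratic (jittered)
    particles.  Swimmer and jittered lanes are kept clear of drifter columns
    so trajectories never intersect."""
    flow = (0.0, 0.18)
    duration = 1500.0
    particles = []
    swimmer_x = (60.0, 230.0, 400.0, 570.0)
    dynamic_x = (740.0, 910.0)
    reserved = swimmer_x + dynamic_x
    cols = [
        x
        for x in range(100, 1260, 60)
        if all(abs(x - r) >= 40 for r in reserved)
    ][:12]
    rows = [80.0 + 40.0 * k for k in range(8)]
    for cx in cols:
        for cy in rows:
            particles.append(
                ParticleSpec(
                    kind="drifter",
                    start=(float(cx), cy),
                    lifetime_ms=duration,
                )
            )
    for sx in swimmer_x:
        particles.append(
            ParticleSpec(
                kind="beater",
                start=(sx, 600.0),
                velocity=(0.0, -0.49),  # net -0.31 pxl/ms against the flow
                half_axes=(7.0, 4.0),  # larger, brighter body: dense trail
                freq_hz=7.0,
                beat_depth=0.7,
                rate=12.0,
                pulse_prob=0.4,
                pulse_speed=0.8,
                lifetime_ms=duration,
            )
        )
    for dx in dynamic_x:
        particles.append(
            ParticleSpec(
                kind="drifter",
                start=(dx, 400.0),
                velocity=(0.0, -0.2),
                pulse_prob=0.35,
                pulse_speed=1.0,
                lifetime_ms=duration,
            )
        )
    return SceneSpec(
        geometry=(1280, 720),
        duration_ms=duration,
        particles=particles,
        noise_rate=5.0,
        flow=flow,
        seed=seed,
    )


def make_deep_sea_scene(seed: int) -> SceneSpec:
    """Sparse deep-sea-like scene: few resuspended drifters rising slowly,
    one fast rhythmic swimmer on a distinct heading, one beating particle.
    Lanes are laid out so trajectories never intersect (track crossings need
    manual curation, which this benchmark deliberately avoids)."""
    flow = (0.0, -0.08)
    duration = 3000.0
    particles = [
        ParticleSpec(
            kind="drifter",
            start=(60.0 + 60.0 * k, 380.0 + 5.0 * k),
            lifetime_ms=duration,
        )
        for k in range(8)
    ]
    # horizontal lane at y=100, far above the rising drifters (y >= 140)
    particles.append(
        ParticleSpec(
            kind="beater",
            start=(80.0, 100.0),
            velocity=(0.2, 0.08),  # net (0.2, 0) after the upward flow
            freq_hz=20.0,
            beat_depth=0.7,
            pulse_prob=0.35,
            pulse_speed=1.0,
            lifetime_ms=duration,
        )
    )
    # horizontal lane at y=300, right of the drifter columns (x <= 480)
    particles.append(
        ParticleSpec(
            kind="beater",
            start=(530.0, 300.0),
            velocity=(0.03, 0.08),  # net (0.03, 0)
            freq_hz=20.0,
            beat_depth=0.5,
            lifetime_ms=duration,
        )
    )
    return SceneSpec(
        geometry=(640, 480),
        duration_ms=duration,
        particles=particles,
        noise_rate=1.0,
        flow=flow,
        seed=seed,
    )


def make_benchmark_suite(seed: int) -> dict[str, SceneSpec]:
    """Deterministic scene suite covering all four categories and all
    frequency bins: one beater scene per sweep frequency, a multi-particle
    lake-like scene and a sparse deep-sea-like scene."""
    scenes = {
        f"beater_{f:g}hz": make_beater_scene(f, seed + i)
        for i, f in enumerate(BEAT_SWEEP_HZ)
    }
    scenes["lake_like"] = make_lake_scene(seed + 100)
    scenes["deep_sea_like"] = make_deep_sea_scene(seed + 200)
    return scenes


# ------------------------------------------------- species feature benchmark

# class-conditional feature distributions for the 5-way species benchmark:
# (mean, std) for F01..F12, then peak-generation rules for F13-F22.
_SPECIES_PARAMS = {
    # small copepod nauplius: quick hops, small body, little periodicity
    "Pcra_N": {
        "cont": [(0.45, 0.08), (9, 1.2), (7, 1.0), (0.6, 0.2), (3, 1.2),
                 (0.45, 0.10), (0.30, 0.06), (0.28, 0.06), (0.30, 0.06),
                 (0.28, 0.06), (0.35, 0.08), (0.18, 0.05)],
        "event_peak": (0.068, 15),  # (probability, peak frequency Hz)
        "coord_peak": (0.068, 2.0),
    },
    # copepodite/adult: large, fast, long antennae, no event periodicity
    "Pcra_C": {
        "cont": [(1.30, 0.20), (17, 2.0), (8, 1.0), (1.8, 0.4), (5, 1.5),
                 (0.75, 0.15), (0.22, 0.05), (0.20, 0.05), (0.22, 0.05),
                 (0.20, 0.05), (0.30, 0.07), (0.12, 0.04)],
        "event_peak": (0.0, 0.0),
        "coord_peak": (0.065, 1.8),
    },
    # limpet veliger: slow spiral swimming, ~1.5 Hz coordinate periodicity
    "Nfus": {
        "cont": [(0.16, 0.04), (12, 1.5), (10, 1.2), (0.1, 0.1), (0.5, 0.6),
                 (0.05, 0.015), (0.40, 0.07), (0.42, 0.07), (0.40, 0.07),
                 (0.42, 0.07), (0.12, 0.04), (0.28, 0.06)],
        "event_peak": (0.333, 8.0),
        "coord_peak": (0.233, 1.5),
    },
    # sea-star bipinnaria: near-still, high-frequency ciliary event peaks
    "Ppec": {
        "cont": [(0.07, 0.02), (14, 1.6), (13, 1.4), (0.05, 0.08), (0.3, 0.5),
                 (0.02, 0.008), (0.55, 0.08), (0.55, 0.08), (0.55, 0.08),
                 (0.55, 0.08), (0.08, 0.03), (0.08, 0.03)],
        "event_peak": (0.455, 24.6),
        "coord_peak": (0.0, 0.0),
    },
    # dust and non-swimmers: smooth, inert
    "Passive": {
        "cont": [(0.20, 0.10), (7, 2.0), (6, 1.8), (0.0, 0.05), (0.5, 0.7),
                 (0.05, 0.03), (0.10, 0.04), (0.10, 0.04), (0.10, 0.04),
                 (0.10, 0.04), (0.05, 0.02), (0.05, 0.02)],
        "event_peak": (0.059, 5.0),
        "coord_peak": (0.059, 1.2),
    },
}

_EVENT_EDGES = (1.0, 2.2, 4.6, 10.0, 22.0)
_COORD_EDGES = (1.0, 2.2, 4.6)


def _species_rows(name: str, n: int, rng) -> np.ndarray:
    params = _SPECIES_PARAMS[name]
    X = np.zeros((n, 22))
    for j, (mu, sd) in enumerate(params["cont"]):
        X[:, j] = np.maximum(0.0, rng.normal(mu, sd, n))
    X[:, 4] = np.round(X[:, 4])  # F05 is a count
    p_ev, f_ev = params["event_peak"]
    hit = rng.random(n) < p_ev
    if hit.any() and f_ev > 0:
        seg = int(np.searchsorted(_EVENT_EDGES, f_ev, side="right"))
        X[hit, 12 + seg] = 1 + (rng.random(int(hit.sum())) < 0.3)
    p_co, f_co = params["coord_peak"]
    hit = rng.random(n) < p_co
    if hit.any() and f_co > 0:
        seg = int(np.searchsorted(_COORD_EDGES, f_co, side="right"))
        X[hit, 18 + seg] = 1 + (rng.random(int(hit.sum())) < 0.3)
    return X


def make_species_feature_benchmark(
    seed: int,
    n_train: int = 138,
    n_test: int = 119,
    label_noise: float = 0.0,
):
    """Synthetic 5-class feature benchmark emulating the in-vitro study design.

    Draws 22-dimensional feature vectors from class-conditional
    distributions for the five classes (near-balanced splits of 138
    teaching and 119 test clusters).  ``label_noise`` flips that fraction of
    teaching labels uniformly at random (for overfitting experiments).
    Returns (X_train, y_train, X_test, y_test, class_names).
    """
    from .classify import SPECIES_LABELS

    rng = np.random.default_rng([seed, 424243])
    k = len(SPECIES_LABELS)

    def _split(total):
        base = total // k
        extra = total - base * k
        return [base + (1 if i < extra else 0) for i in range(k)]

    def _draw(counts):
        Xs, ys = [], []
        for ci, name in enumerate(SPECIES_LABELS):
            Xs.append(_species_rows(name, counts[ci], rng))
            ys.append(np.full(counts[ci], ci))
        X = np.vstack(Xs)
        y = np.concatenate(ys)
        order = rng.permutation(len(y))
        return X[order], y[order]

    X_train, y_train = _draw(_split(n_train))
    X_test, y_test = _draw(_split(n_test))
    if label_noise > 0:
        flip = rng.random(len(y_train)) < label_noise
        y_train = y_train.copy()
        y_train[flip] = rng.integers(0, k, int(flip.sum()))
    return X_train, y_train, X_test, y_test, SPECIES_LABELS


# ------------------------------------------------------------- serialisation

_PARTICLE_FIELDS = (
    "kind", "start", "half_axes", "velocity", "freq_hz", "beat_depth",
    "osc_amplitude_px", "rate", "leading_pos_fraction", "speed_jitter",
    "pulse_prob", "pulse_speed", "start_ms", "lifetime_ms", "antenna_px",
    "antenna_fraction",
)


def scene_to_dict(scene: SceneSpec) -> dict:
    return {
        "geometry": list(scene.geometry),
        "duration_ms": scene.duration_ms,
        "noise_rate": scene.noise_rate,
        "flow": list(scene.flow),
        "seed": scene.seed,
        "particles": [
            {f: _plain(getattr(p, f)) for f in _PARTICLE_FIELDS}
            for p in scene.particles
        ],
    }


def _plain(v):
    return list(v) if isinstance(v, tuple) else v


def scene_from_dict(d: dict) -> SceneSpec:
    particles = [
        ParticleSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in pd.items()})
        for pd in d.get("particles", [])
    ]
    return SceneSpec(
        geometry=tuple(d.get("geometry", (1280, 720))),
        duration_ms=d.get("duration_ms", 1000.0),
        particles=particles,
        noise_rate=d.get("noise_rate", 0.0),
        flow=tuple(d.get("flow", (0.0, 0.0))),
        seed=d.get("seed", 0),
    ).validate()
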