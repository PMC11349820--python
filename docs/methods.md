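# Methods

`evplankton` converts the raw output of an event-based vision sensor (EVS) —
an asynchronous stream of per-pixel brightness-change records
`(t, x, y, polarity)` — into tracked particles, behavioural feature vectors
and class labels.  This note documents the model and procedure, the
parameters that matter, what the bundled simulator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Event streams

Timestamps are integer microseconds; coordinates are 0-based, origin at the
top-left (image-sensor convention); polarity is +1 for a brightness
increase, −1 for a decrease.  The default geometry is 1280×720 pixels.
Out-of-order input is an error, never silently re-sorted, so upstream
corruption surfaces immediately.  Two dialects are supported: a
`t_us,x,y,p` CSV and a compact binary format (8-byte magic `EVSTRM01`,
uint16 width/height, then 16-byte little-endian records).  Pseudo-frames —
per-pixel polarity sums over half-open windows `[k·Δ, (k+1)·Δ)` anchored at
the first event — exist purely for visual confirmation; all analysis runs
on the raw records.

## Tracking: events → subclusters → clusters

The tracker is a streaming algorithm with three repeated steps:

1. **Assignment.** Each event joins an existing *subcluster* if that
   subcluster holds a live event within a 5×5 pixel window around the new
   event *and* absorbing it would keep the subcluster's bounding box within
   20×20 pixels; otherwise it seeds a new subcluster with a fresh,
   never-reused id.  When several subclusters qualify the nearest
   live-event centroid wins; exact ties go to the lowest id.  The cap
   rejects membership rather than truncating the box, which approximates
   deterministically the competition between neighbouring subclusters that
   stops growth in the original design.
2. **Expiry.** At every 1 ms sample tick, events aged ≥ 100 ms are removed
   (the boundary is closed: an event exactly 100 ms old is out) and empty
   subclusters retire.  The sliding window is what makes a subcluster
   follow a moving particle: trailing events fall out while leading events
   join.
3. **Merging.** Live subclusters whose bounding boxes overlap or touch
   (coordinate separation ≤ `merge_gap`, default 1, on both axes) form
   connected components; each component is one *cluster*, identified by the
   smallest member subcluster id.  A particle larger than the cap appears
   as several subclusters but exactly one cluster.

Cluster identity over time is resolved by shared subcluster membership
between consecutive ticks.  When a cluster momentarily splits — typical for
a fast swimmer whose 100 ms event trail stretches far behind the body — the
component that absorbed the most *new* events in the current tick keeps the
track (that is where the particle physically is), with ties broken by live
size and then lowest id.  A merged component facing several candidate
tracks continues the oldest one; the others close.  Tracks alive for fewer
than 2 sample ticks are dropped and counted.

Because the shape features need per-event coordinates, each track also
records the coordinates and polarities of every event it absorbed, indexed
by tick (CSR layout).  This goes beyond the original memory-frugal design,
which stored only per-subcluster summaries, but is the only way the
projection-based features below are computable from a finished track.

The incremental implementation (occupancy-counter bounding boxes, a
pixel-to-subcluster grid index, spatially hashed component search) is
validated against a naive replay — full scans, list filtering, exhaustive
pairwise adjacency — which must agree bin-for-bin on randomized scenes at
every sample tick.

## The 22 features

Units: velocities in pxl/ms, lengths in pixels.  Computed per track:

* **F01 average velocity** — the track is cut into 4 ms segments; the
  centre of a segment is the centroid of the events absorbed during it
  (empty segments carry the previous centre and are flagged); per-segment
  speed is |Δcentre|/4 ms and F01 is its mean.
* **F02/F03 length and width** — events of each segment are projected onto
  the unit vector of that segment's velocity (parallel axis) and its normal
  (orthogonal axis); F02/F03 are the mean pixel extents (max − min + 1).
  The per-segment velocity, not the global mean, defines the axes so a
  turning body keeps a body-aligned frame.
* **F04 antenna indicator** — over events whose orthogonal offset exceeds
  F03/2 + 2 px, the inner product of the segment velocity with the
  centre-to-event vector is accumulated and divided by F02.  Appendages
  that project beyond the body width ahead of the motion push F04 up.
* **F05 large acceleration peaks** — accelerations |Δspeed|/4 ms exceeding
  5× their mean are counted.
* **F06 variance of velocity** — population variance of the per-segment
  speed.  The classification threshold is 0.14.
* **F07–F10 roughness** — mean per-segment variance of positive (F07/F08)
  and negative (F09/F10) event projections on the parallel/orthogonal axis,
  divided by F02/F03 respectively.  These scale linearly under a coordinate
  rescaling (variance over length); only F11/F12 are scale-free.
* **F11/F12 polarity split** — mean |centroid(positive) −
  centroid(negative)| component along the parallel/orthogonal axis, divided
  by F02/F03.
* **F13–F18 event-FFT peaks** — the per-1 ms counts of newly absorbed
  positive, negative and total events are transformed with a rectangular
  window over the whole track (no zero-padding; the frequency grid is
  track-length dependent).  Detected peaks from the three spectra are
  pooled and counted into six half-open segments [0,1), [1,2.2), [2.2,4.6),
  [4.6,10), [10,22), [22,∞) Hz.
* **F19–F22 coordinate-FFT peaks** — x and y centre series of positive,
  negative and total events at 4 ms resolution (six series) are detrended
  by subtracting the line through their endpoints (endpoints exactly zero),
  transformed the same way, and the pooled peaks counted into [0,1),
  [1,2.2), [2.2,4.6), [4.6,∞) Hz.

**Peak detection.** Power is `10·log10|X(f)|²` with the DC bin excluded.  A
peak is a strict local maximum at least 15 dB above the background level.
The background at each bin is the *median of the non-DC power over a
sliding window* around it (half-width `max(5, n/40)` bins).  A local rather
than global background was chosen because endpoint-pinned detrending of a
noisy series injects a ramp whose 1/k² spectrum lifts the lowest bins by
10–16 dB; a global median would flag that deterministic baseline as
periodicity on perfectly ballistic particles, while a local floor follows
it.  The global median and mean remain available as configuration options.
Two further guards: adjacent super-threshold bins inside one lobe count
once (only the strict maximum qualifies), and bins more than 120 dB below
the spectral maximum are treated as numerical round-off, not signal.

Features whose preconditions fail (no negative events, zero velocity, a
track too short for a spectrum) are zero and flagged in a validity mask;
recomputation is bit-identical.

## Classification

**Four categories.** With P = ΣF13–F22 and the thresholds above:

| P     | F06 ≤ 0.14 | F06 > 0.14 |
|-------|------------|------------|
| 0     | Passive    | Dynamic    |
| ≥ 1   | Beating    | Active     |

Clusters whose F01 is at or below 0.025 pxl/ms are too slow for the
variance test to mean anything and take the low-variance branch (Passive or
Beating by peak count).  This routing for slow clusters is a documented
interpretation and is configurable.

**Species network.** A fully connected 22-20-5 network, sigmoid on both
layers, sum-of-squared-error loss against one-hot targets, trained by
full-batch gradient descent.  Weights initialise uniform(−0.5, 0.5) from
the seed.  The update uses the SSE gradient divided by the number of
training samples, so the default learning rate 0.1 is batch-size invariant;
the reported loss is the plain SSE.  Features are min-max normalised to
[0, 1] with bounds fitted on the teaching set; applied values are clipped
and constant features map to 0.  Prediction is the argmax of the five
sigmoid outputs (no softmax), ties to the lowest index.  The default budget
is 5000 epochs with the full learning curve retained, because the quantity
of interest is the best-epoch test accuracy, not the final one.  Analytic
gradients are verified against central finite differences (step 1e-5,
near the float64 optimum; relative error < 1e-6).

## The simulator

The generator produces scenes with known ground truth: body ellipses
emitting Poisson event counts per 1 ms tick (base rate 8 events/ms for a
~10×6 px body), positive polarity on the leading half and negative on the
trailing half (a bright body advancing over a dark background), uniform
background noise with equiprobable polarity, and a global flow added to all
particles.  Particle kinds:

* **drifter** — constant velocity (flow + own drift);
* **beater** — event rate modulated by `1 + depth·sawtooth(2πft)`
  (appendage beating changes how much body edge moves per unit time;
  default depth 0.5 so the trough rate stays well above zero);
* **oscillator / spiral** — sinusoidal lateral offset / circular orbit of
  the centre at frequency f;
* any kind may carry intermittent forward **speed pulses** (per 4 ms block,
  probability q, exponential magnitude s), emulating hop-and-sink escape
  jumps.  Pulses are non-negative, so — unlike Gaussian speed jitter, which
  folds at zero and loses most of its variance — they keep the measured
  per-segment speed variance near its analytic value s²q(2−q), safely away
  from the 0.14 threshold on both sides.

All randomness flows from the scene seed through per-particle child seeds,
so scenes are reproducible regardless of particle order.  Ground truth
includes per-ms trajectories, the event→particle provenance map, and the
category implied by the generative parameters (computed with the
folded-normal/pulse variance formulas and a factor 0.5 for the mixing of
adjacent 4 ms noise blocks by misaligned measurement segments).

The benchmark suite contains one 4.2 s single-beater scene per frequency in
{0.5, 1.5, 3, 7, 15, 30} Hz, a lake-like scene (96 drifters sharing a
downward flow, four 7 Hz swimmers heading against it, two pulsing
non-rhythmic particles; 1280×720, 1.5 s) and a sparse deep-sea-like scene
(eight rising drifters, one fast 20 Hz swimmer, one slow 20 Hz beater;
640×480, 3 s).  Problem sizes (scene durations, particle counts, event
rates) were chosen so that a full suite evaluation stays around 1–2 minutes
on one core while every spectral quantity retains a ≥15 dB detection
margin.  Swimmers and pulsing particles run in lanes that drifter columns
never cross: trajectory intersections corrupt both tracks' centroids, and
disentangling them is out of scope (the field practice is manual curation).
The planted swimmers are larger and brighter (7×4 px half-axes, 12
events/ms) than the drifters, so their 100 ms event trail stays connected
at beat troughs.

What the simulator does **not** emulate: optics and photometric realism,
hydrodynamics, camera shake (beyond the constant-flow term), occlusions and
trajectory crossings, vendor event formats, and pixel-level sensor noise
models (hot pixels, refractory periods).  Passing the suite therefore shows
the pipeline recovers the constructs it defines — not that these conditions
match any particular instrument deployment.  One known artefact is shared
with real data: integer pixel quantisation of a slowly translating body
puts a faint coherent tone in the centre coordinate series (at the
sub-pixel crossing frequency, aliased into the 125 Hz band), which
occasionally (≈4% of drifters in the lake-like scene) yields a legitimate
≥15 dB coordinate peak and flips a Passive particle to Beating — comparable
to the ~6% false-peak rate reported for passive particles in laboratory
data analysed with this class of method.

The species feature benchmark draws 22-dimensional vectors directly from
class-conditional distributions (near-balanced 138 teaching / 119 test
split) whose structure mirrors the in-vitro classes: small fast nauplii,
large fast copepodites with antennae, slow spiralling veligers with
~1.5 Hz coordinate peaks, near-still sea-star larvae with ~25 Hz event
peaks, and smooth passive particles.  Class separations were set for a
Bayes accuracy well above 0.9; event/coordinate peak incidences follow the
published per-class percentages.

## Numerical and degenerate-input choices

* F06 uses the population (not sample) variance — fixed for determinism.
* Empty 4 ms segments carry the previous centre and are flagged; flagged
  samples stay in the series because the FFT needs gap-free sampling.
* A trailing partial segment is dropped.
* Peak frequencies sit on half-open bin edges: a peak at exactly 4.6 Hz
  counts toward the higher segment.
* Zero-velocity segments contribute nothing to the shape frame; a track
  with no usable segment reports zeroed, flagged shape features.
* The tracker's nearest-centroid distance uses exact integer sums divided
  at the last step, so incremental and naive computations agree bitwise.
* `analyse_stream` skips tracks with fewer than 20 events: a lone noise
  event otherwise survives as a 100-tick "track" of one event.

## Known limitations

* Track identity through genuine trajectory crossings is unresolved
  (fragments are emitted); re-identification after breaks is out of scope.
* F02/F03 average per-segment extents (not per-event statistics); the
  extent convention (max − min + 1) makes a single-pixel body width 1.
* The antenna indicator F04 accumulates per event within each segment;
  alternative accumulation orders are plausible readings of the original
  description.
* Spectral peak counts depend on track length through the frequency grid;
  very short tracks cannot resolve sub-Hz structure at all.
* The category flow inherits the sensitivity of F06 to any shared motion
  of the camera or medium; in flowing water most passive particles exceed
  the 0.14 threshold and come out Dynamic, as field deployments of this
  method observe.
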