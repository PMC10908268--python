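# Methods

## Signal model

A triaxial accelerometer on the outward face of the metatarsus measures
proper acceleration in units of g on three sensor axes. After import
the channels are renamed to body-relative axes defined for a standing
cow — *forward*, *upward* (along the leg toward the torso), *right* —
via a signed permutation supplied by the user (`AxisMap`). The
measurement is modeled as

    a(t) = g(t) + d(t) + ε(t)

with g(t) the unit-magnitude static gravity component set by leg
orientation, d(t) dynamic body acceleration, and ε sensor noise.
Standing implies g ≈ (0, 1, 0); lying rotates g toward the horizontal
plane, which is what both the posture and the laterality rules exploit.

## Posture classification

Three steps on the upward channel:

1. *Gravity filtering.* Default: centered moving median over 10 s.
   The window length in samples is `round(window/interval)`, bumped to
   the next odd count so the center sample is unambiguous; at the
   series edges the window shrinks to the available samples rather
   than padding with missing values, so posture stays defined at the
   recording boundaries (edge bouts are flagged incomplete downstream
   anyway). Alternative: bidirectional Butterworth low-pass (default
   order 1, cutoff 0.1 Hz) applied forward and backward (zero phase),
   with odd-symmetric edge extension of 3·(order+1) samples per end.
   With a 0.1 Hz cutoff that extension is short relative to the filter
   time constant, so a few seconds at each recording edge carry a
   residual transient; this only affects samples that belong to
   incomplete edge bouts.
2. *Thresholding.* Lying iff filtered upward < `crit_lie` (default
   0.5 g ≙ 60° leg angle). A value exactly at the threshold counts as
   standing, standing being defined as "not lying".
3. *Minimum duration.* Interior lying bouts shorter than
   `minimum_duration_lying` (default 30 s) are relabeled standing and
   merged with their neighbors in a single pass; an optional second
   pass does the same for standing bouts (off by default — brief
   standing bouts are real, e.g. when changing lying side). Passes are
   not iterated to a fixed point: iteration could cascade removals in a
   way the single removal step is not meant to. Edge bouts are exempt
   because their observed duration is only a lower bound. Durations
   are computed from timestamps, not sample counts, so the rule is
   sampling-rate independent.

Bout boundaries use one convention everywhere: a transition is stamped
at the first sample of the new posture, which is reproducible and at
worst one sample late. Bouts tile the recording exactly; the last
bout ends at the final timestamp.

The default 30 s minimum balances false positives (leg lifts during
standing, typically ≤ half a minute) against false negatives (true
micro-bouts, rarely down to ~8 s, which the default intentionally
sacrifices; lowering `minimum_duration_lying` to ~5 s recovers them at
the cost of artifact sensitivity).

## Laterality

Per lying bout, side = left iff the median of the *raw* right-axis
samples in the bout exceeds `crit_left` (default +0.5 g left-leg
sensor, −0.5 g right-leg). The raw signal is used rather than the
filtered trace: a bout-length median is already extremely robust. An
exact tie is assigned to the side away from the sensor, with a warning,
since the free-leg geometry makes values near the threshold more
plausible for the opposite side.

## Activity proxies

DBA subtracts the per-axis gravity estimate (same filter options and
defaults as posture). Jerk is the backward finite difference of the
*raw* acceleration — differencing itself removes the static component,
so pre-filtering would be redundant and would distort the high
frequencies jerk is meant to capture; the first sample is missing, not
zero, to avoid biasing bout means. Jerk across a data gap uses the
actual timestamp difference (gaps are warned about at load time).
Norms: L1 = Σ|v_k|, L2 = √Σv_k². L2 of a vector is invariant under
rotations of the axes; for the full pipeline this invariance is exact
when the gravity filter is linear (Butterworth), while the per-axis
moving median is only approximately rotation-equivariant — the
invariance test therefore uses the Butterworth filter. Adjusted
activity is exactly 0 on lying samples and identical to the unadjusted
trace elsewhere; the unadjusted values are kept alongside the result so
`adjust=False` reruns need no recomputation.

## Summaries

Intervals are half-open [start, start+Δ), anchored at midnight of the
first date observed unless an anchor is given (midnight matches the
daily-lying-time convention). Durations are exact bout∩interval
overlaps, so lying + standing durations reconstruct the interval's
covered span and side-specific durations sum to total lying time.
Weighted bout count = Σ overlap-fractions; weighted mean bout duration
= Σ w·d / Σ w. Any weighted quantity touching an edge-incomplete bout
is missing unless `calc_for_incomplete` is set (which declares edge
bouts complete); missing values propagate rather than being silently
dropped. In per-bout summaries only the duration (a quantity undefined
for a truncated bout) is suppressed; start, end, side and mean
activity describe the observed samples and are reported. Mean activity
per interval is the plain mean over samples in the interval, since the
per-sample trace is already uniform in time.

## Synthetic data generator

`sample_schedule` draws a daily schedule inside the typical ranges for
lactating dairy cows: 9–11 lying bouts, bout durations 60–100 min,
total lying 8–13 h per 24 h day, the remainder split into standing
episodes of at least 5 min. Within those constraints the total lying
time is drawn uniformly from the feasible range, then partitioned into
bout durations by bounded zero-sum jitter around the mean; sides are
drawn uniformly per bout. Optional features: true micro-bouts (8 s),
side switches via a short (4 s) standing bout, and standing leg-lift
artifacts (5–25 s, leg tilted to 80° from vertical) that mimic the
main false-lying confounder.

`render_accel` renders gravity as (0,1,0) standing; lying on the
sensor side as (0,0,±1); lying on the free-leg side as a per-bout draw
on the arc between the right axis (magnitude 1) and the forward axis
(right-axis reading → 0), reflecting that the free leg is placed bent
toward the head and then held — the direction is redrawn per bout, not
per sample. Posture transitions are 5 s spherical interpolations of
the gravity vector, so transition windows contain realistic ramps, and
|g| = 1 exactly in the noise-free signal. Noise: standing samples get
gait-like band-limited Gaussian noise (0.5–3 Hz, σ = 0.2 g by default;
white when the sampling rate cannot carry that band), lying samples
white noise with σ = 0.02 g. These defaults stress the 10 s/0.1 Hz
gravity filters without a biomechanical gait model; the simulator does
not emulate rumination, grazing head movement, walking bout structure,
or sampling drift, so passing recovery tests demonstrate correctness of
the algorithms under the stated signal model, not field accuracy on
real cows.

Ground truth (per-sample posture/side labels and an episode table) is
returned with every rendered series, and the fixture writer emits raw
text files (9 decimal places, hence round-trip error < 1e-9 g) that the
importer parses back bit-faithfully.

## Problem sizes and numerical choices

The recovery checks in the test suite run 100 simulated days rendered
at 1 Hz — the low end of the supported 1–20 Hz range, chosen because
posture and laterality accuracy are driven by the 10 s filter window
and bout durations, not the sampling rate; artifact/micro-bout checks
use 10 Hz where sub-window timing matters. Interval conservation is
asserted to 1e-6 s (timestamp arithmetic in ns). Sampling interval is
the median of successive differences, robust to isolated gaps; gaps
>10× the nominal interval trigger a warning and are otherwise treated
as contiguous for filtering — silent interpolation would fabricate
data. Duplicate timestamps are an error, not deduplicated. Timestamps
are timezone-naive throughout (loggers record local time).

## Known limitations

* No walking-vs-stationary discrimination within standing; no
  sternal-vs-lateral recumbency.
* No resampling or gap interpolation; irregular sampling beyond mild
  jitter degrades the seconds-based filter windows.
* Parameter defaults are tailored to adult cows; for calves or other
  species they must be revalidated, and only the parameters — not the
  algorithms — are exposed for such off-label use.
* Whole recordings are processed in memory; multi-day high-rate files
  are bounded by available RAM.
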