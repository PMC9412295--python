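# Methods

This note documents the models, algorithms and design choices behind
`motionval`: what each algorithm assumes, which parameters matter, what the
synthetic generators do and do not emulate, and the numerical conventions.

## Conventions

Time is Unix seconds as floats and every window is half-open, `[t0, t1)`.
This makes sample counts exact: a 10 s window resampled to 30 Hz contains
exactly 300 samples at instants `t0 + i/30`, `i = 0..299`. Resampling is
linear interpolation onto the uniform grid rather than decimation, so
irregular phone timestamps are handled uniformly; the low-pass filter applied
by every downstream algorithm removes interpolation artifacts. Duplicate
timestamps in input CSVs keep the first occurrence (deterministic and
order-stable). Accelerometer axes are in g, gyroscope axes in rad/s.

All filtering is a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`), i.e. zero-phase with unit DC gain. Zero phase matters
because bout boundaries are read off the filtered signal; a causal filter
would shift every boundary by its group delay. Cutoffs: 10 Hz for
accelerometry (gait dynamics live well below 10 Hz), 20 Hz for gyroscope
data, which requires a gyroscope sample rate above 40 Hz (we assume ≥ 50 Hz
for rotation tasks and ≥ 20 Hz for accelerometry).

The autocorrelation is the biased, mean-removed estimator normalized to
ρ[0] = 1: ρ[k] = Σ(vᵢ−v̄)(vᵢ₊ₖ−v̄)/Σ(vᵢ−v̄)². The bias (a factor ≈ 1−k/N
on periodic signals) keeps values in [−1, 1] and damps spurious long-lag
peaks, so fixed height thresholds have a scale-free meaning. Peak finding
returns strict local maxima; plateaus report their leftmost sample
(determinism).

## Walk detection

The detector operates on the acceleration magnitude, which is invariant to
any fixed device orientation — the property that makes it wear-position
agnostic. Overlapping 10 s epochs with a 1 s hop are each scored by three
tests, all exposed in `WalkDetectionConfig`:

| parameter | default | why |
|---|---|---|
| `epoch_s` | 10 s | long enough for ~5–10 stride cycles |
| `hop_s` | 1 s | boundary resolution at the ~1 s scale |
| `sd_threshold_g` | 0.05 g | walking has ~0.25 g dynamic amplitude (SD ≈ 0.18 g); tremor-scale motion (~0.05 g peak) fails |
| `stride_period_range_s` | 0.5–2.0 s | plausible human stride periods |
| `autocorr_threshold` | 0.4 | a genuinely repetitive epoch scores ≳ 0.8; noise stays ≪ 0.15 |
| `min_period_s` | 5 s | drops transient artifacts; bouts of interest are ≥ 10 s |

Within an epoch the SD is computed on the filtered, mean-removed magnitude
before windowing; the autocorrelation on the Hamming-windowed (mean removed
first), filtered epoch. The repeat-period test uses the highest
autocorrelation peak whose lag falls **inside** the stride range rather than
the globally highest peak: walking has near-maximal autocorrelation at the
stride lag regardless of left/right symmetry, whereas for nearly symmetric
gait at cadence above 2 Hz the globally highest peak sits at the step lag
(< 0.5 s) and would spuriously fail the range test.

Consecutive walking epochs (adjacent start times, one hop apart) merge into a
region; a single non-walking epoch splits a run. Epoch union alone has ±10 s
resolution, so boundaries are refined: within the region padded by one epoch,
the bout is the contiguous span where the centered 1 s RMS envelope of the
filtered, mean-removed magnitude stays above a snap level. The snap level is
the half-power point — 1/√2 of the bout's plateau RMS (median of the
envelope samples above the vigour floor), floored at `sd_threshold_g`. For an
ideal step envelope the 1 s RMS crosses the half-power level exactly at the
true boundary, so this choice removes the systematic bout expansion that
snapping at the low vigour floor would cause (about 0.4 s per side, i.e.
~1.6 extra steps per bout). Raising `sd_threshold_g` can only shrink or drop
bouts, never grow them.

## Gait measures

The step period is the lag of the first autocorrelation peak at lag ≥ 0.25 s
with height ≥ 0.2 (below 0.2, cadence is indistinguishable from noise in
5–20 s windows). The stride period is the lag of the highest peak within
1.5–2.5 × the step lag **that rises above the step peak** — a
stride-distinct periodicity produced by left/right asymmetry. Absent one
(perfectly symmetric gait, where every even-lag peak is just a cadence
harmonic damped by the estimator bias), the stride period is imputed as
exactly twice the step period and flagged.

Steps are duration / step period, rounded: the algorithm derives periods from
autocorrelation and never detects individual step events, which also matches
the rater-side convention (rater stride period = duration / (steps/2)).

Distance and speed use an amplitude-based step-length model
L = K·h^¼ with h the average per-step-cycle peak-to-peak range of the
filtered vertical acceleration (in g, vertical axis from PCA) and
K = 0.41 m·g^(−1/4). This is the least-assumption inverted-pendulum-style
choice for a body-worn sensor without position information; K is
calibratable per cohort. The synthetic generator defines its ground-truth
distance through the same model, so distance tests exercise orientation
handling and plumbing, while step-count and stride tests exercise the
cadence mathematics proper.

Orientation for gait: gravity is taken as the normalized **mean**
acceleration (gravity dominates the mean, not the variance), the forward
axis is the first principal component of the gravity-removed signal
projected onto the horizontal plane, and lateral = vertical × forward closes
a right-handed triad. Forward's sign is arbitrary; it is fixed
deterministically (largest-magnitude component positive).

## Pronation/supination

Gyroscope axes are low-passed at 20 Hz, the rotation axis is the first
principal component of the mean-retained angular-velocity samples (sign such
that the mean projection is ≥ 0; for zero-mean oscillation the sign is
inherently ambiguous and all downstream measures are sign-invariant), and
the rotation angle is the trapezoidal integral of ω·axis. Tasks last ≤ 20 s,
so gyroscope drift is negligible and no drift correction is applied.

Turns are alternating maxima/minima of the angle whose successive change is
at least 60° (configurable); one adjacent max/min pair is one turn, i.e. one
palm-up ↔ palm-down transition, and an unpaired trailing extremum does not
count. The rotation rate divides the turn count by the full task duration by
default (matching a rater timing the whole test); an `active_span`
denominator (first to last extremum) is available because the two
conventions diverge exactly when a participant stops early, which is also
where rate agreement is least interpretable.

A still device yields zero turns (the degenerate-axis guard is caught in the
composed measure), and the count is invariant to the sign of the axis and to
any fixed re-orientation of the device.

## Agreement statistics

`icc_absolute_single` is ICC(A,1) — two-way ANOVA, absolute agreement,
single rating — computed from explicit sums of squares:
icc = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)). A matrix with zero
total variance raises an explicit undefined-ICC error rather than returning
NaN; report assembly converts that into a `degenerate` category (the fate of
any fixed-by-design measure such as test duration). The implementation is
cross-checked against pingouin's independent ICC(A,1) on random matrices to
1e−9. Koo bands assign boundary values to the lower category (0.9 → good).

MAPE is reported as undefined whenever any reference value is zero —
percentages of Unix timestamps are meaningless.

Repeat planning uses the large-sample variance of the one-way ICC estimator,
half-width = 1.96·√(2(1−ρ)²(1+(k−1)ρ)²/(k(k−1)(n−1))), and searches the
smallest k ≤ 12 meeting both precision criteria (ρ + hw ≤ 1 and
ρ − hw ≥ 0.75). At ρ = 0.9, n = 10 this gives k = 4, with the upper
criterion binding. Note the search is **not** monotone in ρ: as ρ → 1 the
upper criterion binds ever harder under a symmetric (untruncated) CI, so
very high anticipated ICCs formally demand more repeats. An asymmetric or
truncated interval would remove this artifact; the symmetric form is kept
because it is the standard closed form.

Bench verification compares a device series against the table reference on a
common 30 Hz grid (300 samples per 10 s test), after aligning by the
cross-correlation lag within ±1 s (ties broken toward zero lag, which
matters for periodic signals where full-period shifts tie). The ICC then
treats samples as subjects and the two series as k = 2 raters.

## Synthetic generators

The walking model is a two-harmonic sinusoid riding on gravity: vertical
1 + a·sin(2πft) + b·sin(πft + φ) with a the dynamic amplitude (default
0.25 g, i.e. ~0.5 g peak-to-peak as in normal walking), b = asymmetry·a the
stride-frequency component from left/right asymmetry (default asymmetry 0.2),
plus smaller forward and lateral components; the whole body-frame signal is
rotated by an arbitrary orthonormal orientation and Gaussian noise is added
(default 0.02 g per axis, 50 Hz). This is the minimal structure that gives
the autocorrelation pipeline distinct step and stride peaks with closed-form
ground truth. It does **not** emulate cycle-to-cycle cadence variability,
turning, stair climbing or tremor, so passing tests demonstrate correct
mechanics of the algorithms, not free-living performance.

The rotation model completes `n_turns` full oscillation cycles of the
rotation angle (amplitude in degrees) over the active, non-paused time about
a seed-fixed random axis, with exact analytic angular velocity, optional
cross-axis contamination (arm raise/lower) and noise. One full cycle yields
one max/min pair downstream, so the ground-truth count equals `n_turns`.

The bench model generates the table reference a(t) = (2πf)²A·sin(2πft)/9860
in g and a device channel with additive bias and noise. Idle-mode gating
freezes the device output whenever every sample of the trailing 1 s window
deviates from the window mean by less than the threshold — a deliberately
simple emulation of firmware that pauses recording under low motion; only
the qualitative breakpoint (good agreement above the gate, poor below) is
meaningful, not the exact freeze dynamics.

Simulated raters perturb true values with Gaussian noise (defaults: timing
sd 0.2 s, step-count sd 0.5, distance sd 0.1 m — plausible human precision),
rounding counts to integers and times to 0.1 s. These defaults exist to make
agreement statistics non-degenerate, not to model any particular rater pool.

## Problem sizes

Tests and the acceptance script use desk-scale designs chosen to exercise
every code path with stable statistics: 10 subjects × 4 repeats for ICC
studies, 20 simulation seeds × 2 alternating protocols (6×10 s, 4×20 s) for
passive-detection error statistics, 8 bench configurations × 4 repeats
spanning 0.005–0.5 g, and 50 randomized pronation tasks cycling through the
deliberate-deviation variants (mid-task pauses, stop after two turns,
cross-axis contamination at 30% of the intended angular-velocity amplitude —
i.e. signal-to-interference ≥ 10 in power).

## Known limitations

* Step counts derive from cadence, so half-steps and irregular gait are
  invisible; there are no per-step timestamps.
* The step-length coefficient K is a fixed default; absolute distances are
  only as good as its calibration for a given cohort and wear position.
* Walk detection is tuned for sustained level walking; stairs and
  unstructured activity are out of scope.
* The ICC confidence half-width is a large-sample approximation; no exact or
  F-based intervals are provided, and reported ICCs are point estimates.
* Gyroscope integration assumes a fixed rotation axis per test; slowly
  precessing axes would need attitude tracking, which is out of scope.
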