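# Methods

## Scope and data model

The package operates on per-patient multichannel vital-sign series — heart
rate (BPM), respiration rate (BPM), systolic/diastolic/mean arterial blood
pressure (mmHg) and oxygen saturation (%) — unified to 1 Hz.  Body
temperature is carried in the threshold table for completeness but never
scored or predicted: the wearable data this pipeline targets has no
temperature channel.  Aggregate (total) EWS and alarm logic are likewise out
of scope; the pipeline emits per-vital component scores only.

## Signal conditioning

Raw series are linearly interpolated onto an exact 1 Hz grid
(`resample_uniform`); grid points falling inside an input gap wider than 5 s
are flagged low-quality rather than trusted, and nothing is interpolated
across such gaps downstream — segments touching flagged samples keep their
values but carry `quality=False`.

Denoising is a fourth-order Butterworth low-pass applied forward and
backward (zero phase; amplitude response the squared Butterworth magnitude
1/(1+(f/f_c)^8)) on consecutive non-overlapping 60-sample segments.  The
default cut-off is 0.035 Hz — the midpoint of the 0.03–0.04 Hz band — and is
overridable per channel.  Edge handling per segment is reflective ("even")
padding of 3×order = 12 samples, the standard contract for zero-phase
filtering of short segments; segments shorter than the padding requirement
pass through unfiltered with a warning.  A trailing partial segment is left
unfiltered and flagged.  Whether per-minute denoising means independent
segments or one continuous pass is a genuine design fork; independent
segments is the default and a `continuous=True` flag provides the other
reading.

A note on attenuation scale: a 3 s spike of amplitude A on an otherwise
constant segment survives with peak ≈ 2·f_c·3·A ≈ 0.21·A (the spike's
impulse area times the filter's impulse-response peak), i.e. roughly 79%
suppression — strong, but a large artefact is reduced, not erased.

## EWS component scoring

Threshold bands are closed intervals on each vital's resolution grid (1 unit
for HR/RR/SBP/SpO2, 0.1 °C for temperature).  Continuous inputs are rounded
half-up to that grid before lookup, which makes the table total over the
reals (e.g. HR 50.4 → 50 → score 1, HR 50.5 → 51 → score 0).  The shipped
ZOL table's SBP row prints 180 in two adjacent bands; the lower-score band
is listed first and wins (180 → 0).  The SBP row fills six printed bands
left-to-right, leaving the high-score-3 slot unused (>200 → 2).  The
respiration-rate row is right-anchored (the layout that matches standard
MEWS convention): <9 → 2, 9–14 → 0, 15–20 → 1, 21–30 → 2, >30 → 3.

The per-minute stream scores the four segment statistics independently.
Because threshold tables are V-shaped (high scores at both value extremes),
the score of the segment mean/median is bounded above by the worse of the
min-/max-based scores but can fall below both — score is not monotone in
value.  A moving-median variant (60-sample window, 1-sample step) is
provided; it smooths over segment boundaries and can miss brief one-minute
score excursions, which is the trade-off it exists to illustrate.

## Feature windows and targets

An instance emitted at minute t_end summarises [t_end−70, t_end) via two
one-hour windows, A = [t_end−70, t_end−10) and B = [t_end−60, t_end),
sharing 3000 samples.  Per window and channel the 11 features are, in fixed
order: min, max, mean, median, standard deviation, variance, energy (sum of
squared samples) of the signal, and min, max, mean, standard deviation of
its first difference.  The stated feature list (seven statistics of signal
and derivative, minus derivative energy) sums to 13; the implemented
4-feature derivative block (dropping derivative median and variance) honours
the stated total of 11 and keeps standard deviation over its redundant
square.  Standard deviations are population (ddof 0).  Seven channels are
featurized — HR, RR, SBP, DBP, MAP, SpO2 and the derived pulse pressure
PP = SBP − DBP — giving 77 dimensions per window and 2 × 77 = 154 per
instance.

Targets are the {min, max, mean} of HR, SBP, SpO2, RR, PP over the future
window [t_end+(h−1)·60, t_end+h·60) for horizons h ∈ {1, 2, 3} (dialysis:
{1} only, matching the ~4 h sessions); target statistics are computed on the
per-minute denoised series, consistent with the treatment of the observed
statistics.  Instances are emitted every 10 min starting at t_end = 70,
while at least one requested horizon's window still fits.

## Localized LS-SVM

Each target (vital × statistic × horizon) is a separate scalar regression;
no multi-output formulation is used.  Features are standardized by the
training pool's per-feature mean and standard deviation before both the
neighbour search and the kernel — raw features mix BPM, mmHg and
sum-of-squares scales, on which unscaled Euclidean distance is degenerate.
Constant features get unit scale (zero distance contribution).

The neighbour criterion is binary: the K rows within the K-th smallest
distance, ties at the boundary broken by lowest original index (making
predictions invariant to pool row order).  Euclidean distance is the
default; Chebyshev and a shrinkage-regularized Mahalanobis are available.
The local LS-SVM dual system is solved directly (LAPACK); a singular system
is retried once with a 1e-10 ridge jitter and a warning.  The Gaussian
kernel bandwidth defaults to σ₀ = √d on the standardized scale, where
typical inter-point distances are O(√d); the regularization constant
defaults to γ = 10.  Both, along with K, can be grid-searched by
cross-validated mean absolute error (`tune_hyperparameters`; default grids
K ∈ {5,15,25,35}, γ ∈ {1…10⁴}, σ₀ ∈ {0.5,1,2,5,10}·√d, ties toward the
smaller model).  With k = N the localized fit reduces exactly to the global
LS-SVM; with k = 1 it returns the nearest neighbour's target.

## Evaluation protocol

Leave-one-instance-out: every instance is held out in turn and all remaining
instances — any patient, including temporally overlapping instances of the
same patient — form the pool.  Same-patient neighbours are a deliberate
feature of the localized approach (personalisation through similar
instances), not leakage of the held-out row itself, which is audited out of
its own neighbourhood on every prediction.  The NaiveMean baseline predicts
every future mean as the window-B mean and is defined for the mean statistic
only.  MAPE excludes zero-valued truths with a logged count (they cannot
occur in the synthetic physiological ranges).  EWS-error histograms compare
the scores of predicted vs actual *mean* values per scoreable vital
(configurable); paired t-tests are two-sided on per-instance absolute-error
differences, per vital and horizon, at α = 0.01.  All-zero differences
report t = 0, p = 1; constant nonzero differences are degenerate
(t = ±∞, p = 0) and flagged.

## Synthetic cohort

Each latent channel (HR, RR, DBP, pulse pressure, SpO2) follows a
stationary unit-variance Ornstein–Uhlenbeck process (exact AR(1)
discretisation at 1 Hz), scaled by a per-channel trend amplitude around a
per-channel baseline.  Blood pressure is generated coupled: SBP = DBP + PP
with PP floored at 10 mmHg, MAP = DBP + PP/3, so SBP > DBP holds at every
clean sample.  SpO2 is capped at 100 %.  Measurement noise is white
Gaussian per channel; motion artefacts are signed additive bursts of 5–30 s
with Poisson-distributed counts per recording.  The dialysis profile adds a
within-session linear SBP drift (−12 mmHg over the session by default) to
emulate the more dynamic haemodialysis behaviour, and uses a shorter trend
correlation time (1 h vs 3 h).

Ward defaults: baselines HR 75, RR 14, SBP 124, DBP 72, SpO2 97 (near the
reported ward averages), trend amplitudes spanning the adjacent scoring
bands so nonzero components occur, 4 artefact bursts/hour; cardiology and
postsurgical run 23 h, dialysis 4 h.  Seeding uses one master seed spawned
into independent per-channel and per-patient streams, so identical specs
give bit-identical recordings.

The learnable cohort used for skill testing fixes 10 patients × 6 h,
correlation time 3 h (≥ 2 h, so the next hour's mean is a smooth function
of the preceding 70 min), observation noise at trend_amplitude/snr with
snr = 5, and no artefacts — the skill comparison should reflect the
dynamics, not artefact handling.  That yields 240 leave-one-instance-out
instances at horizon +1 h.  What the generator does *not* emulate: abrupt
clinical state changes, circadian structure, device dropouts longer than
seconds, or cross-channel physiological coupling beyond the blood-pressure
identity.  Passing the skill test therefore shows the estimator recovers
smooth mean-reverting structure that persistence misses; it does not certify
clinical-grade accuracy on real patients, whose headline error rates cannot
be reproduced without the original (non-deposited) ward recordings.

## Numerical choices and degenerate inputs

- Dual-system residual and Σα = 0 are asserted to 1e-8 in tests; the solver
  falls back to a 1e-10 ridge jitter only on an exactly singular system.
- Recordings shorter than one scoring segment, pools smaller than k+1,
  empty cohorts, non-monotone timestamps, non-finite inputs and unknown
  vitals are rejected with messages; sub-minute tails and oversized gaps are
  flagged rather than dropped, preserving alignment.
- Rounding to the threshold grid is half-up, not banker's.
- Problem sizes in the test suite (6–10 patients, 3–6 h recordings, ≤ 240
  LOIO instances) are the package's default desk-scale study conditions;
  the pipeline itself is linear in recording length and quadratic only in
  the (small, fixed) neighbourhood size.

## Known limitations

- The forecaster's strong skill margin on the synthetic cohort partly
  reflects the pool containing temporally adjacent instances of the same
  patient — the protocol's intended personalisation, but a caveat when
  extrapolating to sparse pools.
- The 11-feature derivative-block composition and the right-anchored RR row
  of the threshold table are documented conventions chosen from ambiguous
  sources, configurable via the feature module and the yaml table.
- The EWS stream emits component scores only; without temperature and
  neurological responsiveness no total EWS is defined here.
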