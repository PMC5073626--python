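# Methods

`papwv` estimates pulmonary pulse wave velocity (PWV) — the propagation
speed of the systolic pressure/flow pulse along the pulmonary arteries, a
pressure-free surrogate for wall stiffness — from the flow Q(t) and
cross-sectional area A(t) curves that phase-contrast MRI produces at the
main, right and left pulmonary arteries (MPA/RPA/LPA). This note records
the models, conventions and numerical choices behind each stage, and what
the synthetic validation does and does not demonstrate.

## Units

One convention is fixed package-wide and removes every conversion factor
from the estimators: time in ms, flow in mL/s, area in mm², velocity in
cm/s (the VENC convention). Then

* a flow–area slope, (mL/s)/mm², is numerically m/s, and
* a distance/transit-time ratio, mm/ms, is numerically m/s.

## Estimators

**Transit time (TT).** PWV = Δd/Δt. Δd is the inter-plane path length:
horizontal centreline distance measured in-plane, combined with the
vertical offset (slice thickness × slice count) by Pythagoras. Δt is the
difference in pulse-foot arrival time between the MPA and a branch plane.
The foot of a flow curve is located geometrically: a least-squares line
through the ascending-limb samples lying between 20% and 80% of the flow
maximum (band inclusive at both ends), intersected with the horizontal
baseline, defined as the minimum flow between cycle start and the first
upward 20% crossing. The intersection is continuous — not snapped to the
frame grid — because at 7 ms sampling the transit times of interest are
only a few frames long. The ascending limb is delimited by the deepest
pre-peak minimum (its last attainment): on smooth or bimodal curves this
is exactly the last local minimum before the peak, while on noisy curves
it prevents a one-frame dip part-way up the upstroke from truncating the
20–80% band. Fits with fewer than two band samples or non-positive slope
fail; a foot outside [cycle start, peak time] and a non-positive Δt are
flagged invalid rather than raised, mirroring how physically impossible
transit times are discarded case-wise in practice.

**Flow–area (QA).** During early systole, before reflected waves return,
the linearized water-hammer relation gives dQ = PWV·dA. Early systole is
detected as the period in which area and flow increase simultaneously:
among the runs of consecutive frames with strictly positive ΔQ and ΔA
within the first 200 ms of the cycle, the earliest of the longest runs is
taken (ties in either series terminate a run, so an area plateau caused by
pixel quantization ends the window; a window of fewer than 3 frames is an
error). Three estimators operate on the window:

* `QA_Trad` — least-squares slope of Q on A over all window points;
* `QA_3` — the same slope over exactly the first three window points,
  which usually predate the reflected wave;
* `QA_Inv` — the reflection-insensitive kinematic estimator
  PWV = √(ΣΔQ²/ΣΔA²) over consecutive-frame increments, the flow–area
  analogue of the reciprocal pressure–velocity loop technique. It uses
  every window point and is exactly unbiased whenever the backward-wave
  increments are orthogonal to the forward-wave increments
  (Σ ΔA_f·ΔA_b = 0); under a temporally correlated early reflection it is
  biased in the same direction as `QA_Trad` but less.

Increments are plain first differences; no smoothing or resampling is
applied anywhere. A validity screen flags non-positive estimates and
estimates above a configurable cap (default 20 m/s, far above any
physiological pulmonary value) before they reach statistics.

## Statistics

Agreement between paired estimates uses Bland–Altman analysis with limits
of agreement at mean ± 2·SD of the differences (the multiplier is
configurable; 2 exactly, not 1.96). Sample SDs use n−1 throughout; the 95%
CI of the mean difference uses the t distribution. Dependent-sample
comparisons use the two-sided paired t-test, group comparisons one-way
ANOVA (with two groups, F equals the squared pooled t statistic, which the
tests assert to 1e−10). The `variability_table` pairs replicate estimates
per (method, site, sequence) with pairwise-complete deletion — an invalid
estimate drops its pair, never the subject's other configurations — and
ranks configurations by the SD of paired differences. scipy.stats provides
the distributions and reference tests; the assembly and pairing logic is
the package's own.

## The synthetic generator

The generator produces ground-truthed curves that embody exactly the
physics the estimators assume, plus the acquisition artefacts that degrade
them. It is deliberately the smallest such model:

* **Forward wave**: half-sinusoid ejection, peak 400 mL/s, systole 300 ms,
  cycle 900 ms (heart rate ≈ 65/min), zero diastolic flow. Ejection
  starts `onset_ms` (default 60 ms, a normal electromechanical delay)
  after the trigger, giving the pre-systolic baseline the foot detector
  intersects.
* **Branches**: the RPA/LPA receive fixed fractions (0.55/0.45) of MPA
  flow and baseline area (MPA 600 mm²), and the forward wave arrives
  delayed by distance/PWV (defaults 50 and 45 mm at the cohort level).
* **Reflection**: a single discrete backward wave — a scaled, delayed copy
  of the forward wave. An *expansion* reflection adds to observed flow and
  subtracts from area (observed Q = Q_f + Q_b, A = A0 + (Q_f − Q_b)/c), so
  it steepens the apparent Q–A slope, reproducing the overestimation of
  the whole-window slope; a *compression* wave does the reverse. Cohort
  default: expansion, coefficient 0.3, delay uniform in 40–80 ms.
* **Acquisition emulation**: sampling at the sequence's temporal
  resolution (7 ms/128 phases for the high-temporal preset, 12 ms/80 for
  the high-spatial preset); area quantization to an integer number of
  in-plane pixels (1.25² or 0.625² mm²); additive Gaussian noise; optional
  RR-interval jitter (truncated at ±3 SD) applied to the cycle length;
  a warning flag when Q/A exceeds the 150 cm/s velocity-encoding limit
  (aliasing itself is not simulated). Acquisitions longer than one cycle
  are truncated to the frames that fit; beats are not wrapped.
* **Noise model**: curve-level noise SDs (defaults 4 mL/s flow, 2 mm²
  area, ≈1% of peak flow) are quoted at the 1.25 mm reference pixel size
  and scale like 1/pixel_spacing, because per-pixel SNR scales with voxel
  volume and an ROI sum over proportionally more, noisier pixels inherits
  the factor. This single physical scaling is what makes the
  high-temporal sequence the more reproducible one for `QA_Inv` despite
  its coarser pixels — with resolution-independent noise the conclusion
  would invert, since coarser temporal sampling enjoys larger
  per-increment signal.
* **Rendering**: optional synthetic phase-contrast frames. Each frame is a
  centred disc whose pixel count equals the quantized area (pixels
  admitted by ascending distance from the centre with a deterministic
  tie-break) with uniform plug velocity Q/A inside; magnitude is bright
  inside the disc. Plug flow makes Q = v·A exact, so mask-based
  extraction has a closed-form oracle.

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (one stream per subject, replicate
and site); identical seeds give bit-identical curves, images and result
tables.

## What the synthetic validation shows — and what it cannot

Passing tests demonstrate that the estimators are implemented correctly
(they recover known wave speeds exactly in the reflection-free limit and
degrade as theory predicts under reflections, noise, quantization and
coarse sampling) and that the reported empirical orderings (whole-window
slope biased highest; the increment estimator most precise; the
high-temporal sequence more reproducible under volume-scaled SNR) are
reproduced under the stated model. The generator does not model
through-plane or respiratory motion (which is believed to favour the RPA
over the MPA in vivo), partial-volume or segmentation-shape error, phase
aliasing, eddy currents or background phase, diastolic/regurgitant flow,
or full 1-D wave propagation with distributed reflection sites. Agreement
with the model is therefore necessary, not sufficient, evidence of
real-data performance.

## Numerical and design notes

* Foot detection is equivariant under time translation and invariant under
  positive flow scaling; both are tested.
* The 20–80% thresholds are relative to the sampled maximum; exact ties at
  the thresholds are included (deterministic, maximizes points).
* "Simultaneously increasing" is strict (> 0); this makes window detection
  deterministic on quantized area data.
* Whether the early-systole window should be the literal first qualifying
  run or the longest one is a genuine ambiguity: the literal first run
  lets a single spurious increment in the pre-systolic baseline abort the
  estimate, so the earliest-longest run is used; the `window_too_short`
  error is kept for curves whose best run is under 3 frames.
* The baseline rule is applied to the flow curve (the procedure is
  otherwise flow-based); whether a clinical package would use the velocity
  curve instead is unknowable from curve data alone and the difference
  vanishes for plug flow.
* The upstroke line is fitted by least squares over all band points rather
  than a two-point secant.
* Degenerate inputs (zero area variance, zero ΔA sum, fewer than two band
  points, empty masks, non-monotone trigger times) raise typed errors at
  the library level; the pipeline folds estimator failures into invalid
  estimates with a reason code so one bad acquisition never aborts a study
  run, and the run manifest counts exclusions by reason.
* Problem sizes used by the test-suite ensembles and the acceptance script
  (200 subjects for bias/precision orderings, 1000 repetitions for the
  t-test calibration, 0.1 ms sampling for the dense foot oracle) were
  chosen so Monte-Carlo error is far below the effect sizes being
  asserted while a full run stays in the seconds range.
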