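# Methods

## Generative model of an acquisition

A specimen is described by a ground-truth field `μ(x, y)` of continuous
pre-clipping mean intensities; values outside `[0, 255]` are legitimate
and represent signal beyond the dynamic range.  One acquisition draws
`n_scans` frames (default 8).  Per pixel and frame:

1. raw signal `X ~ Normal(μ, var(μ))` with the between-scan noise law
   `var(μ) = noise_a · exp(gain_V / g0) · μ + noise_b`;
2. offset subtraction `V = X − c_b`, where `c_b = |offset_pct| ·
   offset_units_per_pct` intensity units;
3. clipping to `[0, c_a]` with `c_a = 255`;
4. rounding to an integer (8-bit file).

The averaged image is the full-precision per-pixel mean of the frames.

The Normal is used as the standard approximation to the Poisson photon
statistics at the moderate-to-high counts where clipping matters.  The
noise-law constants default to `noise_a = 0.05`, `noise_b = 1`,
`g0 = 100 V`.  Real instruments do not publish these constants; the
defaults are chosen so that variance is linear in intensity, spans a
factor `e^5` over a 500 V gain sweep, and gives per-frame standard
deviations of roughly 10–60 grayscale units in the 300–600 V band where
the simulation experiments operate.  All constants are configurable.
Simulation experiments in the test-suite and the acceptance script use
gains in the 300–600 V band (and a 300 V base for the largest planted
gain-shift), where these constants produce realistic partial clipping
rather than total saturation.

The exact per-pixel clipping errors of an acquisition are available in
closed form (`expected_clipping_error`: Normal partial expectations) and
by Monte Carlo under the full generative model including rounding
(`true_clipping_error`); the two agree wherever rounding is negligible,
and every estimator in the package is validated against them.

## Censoring estimators

A frame value is *censored* iff it equals `c_a` exactly (upper) or 0
exactly (lower); a true value coincidentally at the boundary is
indistinguishable and counted, consistent with the censoring model.

**Upper (Gaussian).**  The observed per-pixel sample is `Y = min(X, c_a)`
(boundary-concentrated clipping).  Writing `α = (μ − c_a)/σ`, the scaled
variable `W = (Y − c_a)/σ = min(Z + α, 0)` has moments depending on `α`
alone, and the normalized ratio `Var(W)/E[W]²` is strictly increasing in
`α`.  Matching it to the sample ratio `s²/(c_a − m)²` therefore reduces
the two-moment system to one monotone scalar equation, solved by
bisection on `α ∈ [−12, 12]`; `σ = (c_a − m)/E[(Z − α)⁺]` and
`μ = c_a + σα` follow.  The Mills ratio is evaluated through `erfcx` so
the heavy-censoring tail does not cancel numerically.  With no censored
value the equations reduce to the plain sample moments; with every value
censored the pixel is infeasible and excluded; a sample ratio outside the
attainable range raises an estimation failure.  The upper pixel error is
the closed-form partial expectation `U = σ·h(α)`, `h(a) = a·Φ(a) + φ(a)`.

**Lower (Weibull).**  The raw (pre-offset-subtraction) low-intensity
signal is modelled as two-parameter Weibull; observed zeros represent
raw values at or below `c_b`.  The excess `O = (X − c_b)⁺` has moments
in terms of regularized incomplete gamma functions,

    E[O]  = λ Γ(1+1/k) Q(1/k, t),        t = (c_b/λ)^k ,
    E[O²] = λ² Γ(1+2/k) Q(2/k, t) − 2 c_b E[O],

and the system is solved by nested log-space bisection: the outer loop
on the shape `k` matches the normalized second moment (decreasing in
`k`), the inner loop finds the scale matching the mean (increasing in
`λ`).  With no censored value this reduces to the classical Weibull
method of moments (shape from the coefficient of variation).  The lower
pixel error `L = E[(c_b − X)⁺]` is computed by adaptive quadrature in the
scalar API and by the equivalent incomplete-gamma form in the vectorized
path; the two routes agree to 1e-7 and are cross-checked in the tests.

**Profile.**  Per pixel, the Gaussian model is fitted when any frame sits
at `c_a` and the Weibull model when any frame sits at 0 (a pixel is
normally corrupted by one kind of saturation only; both models are fitted
if both occur, neither — zero error — otherwise).  Eight-frame integer
samples realize few distinct (mean, variance) pairs, so each moment
system is solved once per unique pair.  Individual 8-point fits are
noisy; reliability comes from averaging `U` and `L` over all pixels whose
rounded averaged intensity equals `k`.  Pixels whose fit is infeasible or
fails are excluded from the level means and counted.  Levels above the
estimability ceiling (default 250) are flagged unreliable: the topmost
intensities are present in few pixels and so strongly clipped that the
moment equations carry little information.

## Calibration

Identical PMT settings produce different noise on different instruments,
but the noise level at a given intensity is what fixes the clipping
error, so instruments are mapped onto a common scale.

*Offset*: one specimen scanned twice at the same gain and two offsets;
the mean pixel difference (excluding pixels clipped at zero in either
image) divided by the offset difference gives intensity units per
percent.  Exact on noise-free pairs, unbiased on noisy ones.

*Gain*: a zero-offset scan series yields a log-variance-vs-intensity
curve; the additive voltage shift Δ minimizing the mean squared
difference to the reference table interpolated at `gain + Δ` is found by
a 5 V grid search plus bounded local refinement.  Least squares on the
log scale equalizes relative error across the exponential range (the
matching objective is a design choice; only the correspondence itself is
prescribed by the method).  Levels within 2 standard deviations of either
clipping threshold are excluded from the match — there the variance
collapse reflects clipping, not the PMT.  A multiplicative noise factor
`exp(Δ/g0)` planted in simulation is recovered as an additive shift Δ
within one grid step across Δ ∈ {−100, 0, +80, +280} V.

The packaged reference table (`data/reference_noise.tsv`) is generated by
`build_reference_table()` — simulated zero-offset stacks on a full-range
intensity gradient at gains 250–750 V in 25 V steps, every other
intensity level, fixed seed — and users may substitute a table measured
on their own reference instrument.

## Regression system

Per intensity level `k ≤ ceiling` with at least `n_min = 5` observations
and a full-rank design, ordinary least squares of `E_k` on
`(1, offset_units, exp(gain_V/g0))`.  The exponential gain regressor
keeps the known exponential noise–gain relation linear in parameters;
`g0 = 100 V` keeps `exp()` in double range over realistic voltages.
Coefficient standard errors, R² and 99% confidence intervals are stored
per level.  Predictions are clamped at zero (errors are magnitudes);
unfitted interior levels are served by linear interpolation between the
nearest fitted levels and constant extension beyond the outermost ones,
so a pattern spanning the whole grayscale range can always be corrected.

The correction direction is the *training-set dominance sign* `s_k`: +1
where the mean upper error exceeds the mean lower error (bright levels —
correction raises the intensity), −1 otherwise (dim levels — correction
lowers it).  This reproduces the raise-high/lower-low behaviour without a
hard-coded threshold.

Model adequacy is summarized by the median R² over *signal levels* —
fitted levels whose mean training error is at least 0.5 units.  Levels
with `E_k ≈ 0` at every design point have noise-dominated R² by
construction and say nothing about the model; on the reference acquisition grid the
signal-level median is ≈ 0.96 while the all-level median is ≈ 0.73.

Validation uses grouped leave-one-out: all images sharing one nominal
(gain, offset) setting are held out together, the model is refitted, and
per-level absolute deviations between computed and predicted errors are
recorded.

## Correction of expression patterns

Nuclei are 8-connected components of a binary mask; each is reduced to
centroid (x = column, y = row, 0-based pixel centres) and mean intensity.
Correction modes:

* `object_mean` (default): evaluate the prediction at the level equal to
  the nucleus' rounded mean intensity;
* `pixel_average`: average per-pixel predictions over the nucleus (needs
  the image and mask).

The corrected value is `observed + s_k · Ê_k`, clamped to `[0, c_a]`.
The two modes agree closely (mean discrepancy well under one unit on the
synthetic embryo); `object_mean` is the default because per-pixel
averaging slightly over-corrects under a convex error curve.

## What the synthetic data does and does not emulate

The simulator reproduces signal-dependent between-scan noise with the
exponential gain law, offset subtraction, clipping at both thresholds,
frame averaging, integer quantization, and embryo-like patterns of
disk-shaped nuclei on a smooth expression profile.  It does not model
optics (PSF, pinhole), photobleaching, spatially correlated noise,
non-Gaussian photon statistics at very low counts, 3-D stacks,
multi-channel crosstalk, or real nuclear segmentation; masks are inputs
by design.  Passing tests therefore demonstrate correctness of the
estimators and the pipeline under the stated noise model, not robustness
to every property of real micrographs — on real data the learning sample
must come from the same instrument, laser and staining protocol as the
images being corrected.

## Numerical choices and problem sizes

* Between-scan variance uses the n−1 denominator (with n = 8 frames, an
  n-denominator convention would differ by up to 14%).
* Integer rounding of frames adds ≈ 1/12 to the per-frame variance; the
  noise-law tests account for it, the censored fits absorb it.
* Bisection brackets: `α ∈ [−12, 12]` (Gaussian), shape `∈ [0.08, 80]`
  (Weibull); out-of-bracket targets are flagged, not extrapolated.
* Profile-level validation uses 8-frame 512×512 stacks; regression and
  end-to-end experiments use a 3-gain × 3-offset grid over two 192×192
  full-range gradients plus a 100-nucleus synthetic embryo — sizes at
  which level occupancies (≥ 500 pixels per validated level) make the
  level means stable while a full run stays around a minute.
* Grouped leave-one-out requires ≥ 3 parameter groups; regression
  requires ≥ 3 distinct (offset, gain) design points per level and
  refuses rank-deficient designs per level rather than aborting.

## Known limitations

* The censored-moment fits are slightly biased on 8-point samples under
  heavy censoring (> ~70% clipped frames); level means inherit a small
  bias there, which is why levels with > 90% clipped fractions and the
  top grayscale levels are flagged unreliable.
* The lower-error model assumes a Weibull-shaped low-intensity signal;
  under the simulator's Normal noise this is a deliberate model
  mismatch, and the measured profile error (≈ 0.03 units mean absolute
  deviation) bounds its practical cost.
* Only 8-bit images are supported in this version; `c_a` is carried
  symbolically throughout so a 12/16-bit generalization does not change
  interfaces.
* The regression is honest only within the convex hull of the training
  design; predictions far outside the calibrated gain/offset range are
  extrapolations.
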