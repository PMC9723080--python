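# Methods

## Generative model of the simulated trial

Each subject carries a tumor whose true volume is piecewise linear and
continuous at treatment start (t = 0, months):

* baseline volume ~ Normal(`baseline_mean` = 10 mL, `baseline_sd` = 0.5 mL)
  at the earliest nominal scan (−`window_months` = −6);
* slope `growth_rate` = 1/3 mL/month before t = 0 (1 mL per 3 months), so
  the true treatment-start volume is ≈ 12 mL;
* an arm-specific slope afterwards: 1/3 mL/month for the ineffective
  control arm, 0 for the cytostatic arm.

Scans are nominally every `scan_interval` = 3 months across both 6-month
windows ({−6, −3, 0, +3, +6}). Every non-anchor scan date is perturbed by
Normal(0, `scan_jitter_sd` = 0.5 months ≈ 2 weeks); the anchor scan at
t = 0 is never jittered, because treatment start defines both evaluation
windows. Jitter moves the *true acquisition time*: the recorded timestamp
and the volume are both taken at the perturbed time, mimicking real
scheduling variability. The observed volume adds Normal(0,
`noise_sd` = 0.25 mL) measurement noise and is floored at 0 mL (floors are
counted in the log; they are negligible at these sizes but matter for the
small-volume cohorts used in the Levin concordance tests). Baseline
variability is placed on the −6-month volume, so the "12 ± 0.5 mL at
treatment start" is emergent, not imposed.

Randomization is deterministic-by-index (first `randomization_ratio[0]`
subjects control), and each subject draws from a PRNG substream keyed by
(seed, subject index), so cohorts are bitwise reproducible and any subject
can be regenerated in isolation.

Survival times come from the PID hazard h(t) = h₀·exp(β₁·∫₀ᵗV dt′ +
β₂·V(t) + β₃·dV/dt) with the three covariates held piecewise-constant
between scans (last value carried to the administrative-censoring horizon),
which makes the cumulative hazard piecewise linear and inverse-transform
sampling exact under the discretized model.

What the generator does **not** emulate: nonlinear (exponential/Gompertz)
growth, missed visits and dropout, inter-rater segmentation variability,
multifocal lesions, and imaging-level artifacts. Passing tests therefore
show that the estimators recover the parameters of this idealized process,
not that they are robust to real-world volumetry error structure.

## PID estimation

The evaluation windows are [−6, 0] and [0, +6] months. Scans within
`tolerance` = 1.5 months (half the nominal interval) of a window boundary
still count toward the window, so a jittered boundary scan is not lost.

**λ₁ (tumor control).** Quadrature of (V(t′) − V(ref)) *over the window
itself*: the piecewise-linear curve through the in-window scans is linearly
clipped or extended to the exact window bounds before integration.
Integrating over the jittered scan span instead would bias the integral
upward by slope·Var(jitter)/2 on average. The reference volume is the
observed volume of the scan nearest the window's reference time: the
earliest ("historic") in-window scan for the pre window, the anchor scan
for the post window. Three quadrature rules are provided for unevenly
spaced samples: trapezoid (default; exact for linear V), pairwise-panel
midpoint of the linear interpolant (order 2), and composite Simpson with
three-point Newton–Cotes weights for arbitrary nodes (order 4; exact for
quadratics on any nodes and for cubics on symmetric panels; odd panels fall
back to a trapezoid, deterministically).

**λ₂ (burden).** The observed volume of the in-window scan nearest the
window end (ties break to the earlier scan). The standalone
`tumor_burden` lookup enforces the strict 1.5-month tolerance and raises
when no scan qualifies.

**λ₃ (growth rate).** The OLS slope of volume on recorded time over the
in-window scans.

**Δλₙ = λₙ(post) − λₙ(pre)**, per subject. Units: λ₁ in mL·months, λ₂ in
mL, λ₃ in mL/month.

### Variance of difference parameters

Differencing two *independent* equally-noisy estimates doubles the
variance. For Δλ₃ under the default design the pre and post windows share
the anchor scan, whose noise enters the two 3-point OLS slopes with
opposite-sign weights (±1/6 with Sxx = 18), adding Cov(pre, post) =
−σ²/36; the variance ratio Var(Δλ₃)/Var(λ₃) is therefore 3 analytically,
not 2, and the 10,000-subject simulation measures ≈ 2.97. The classical
doubling (ratio 2) is recovered exactly when the slopes are fitted on
disjoint scan subsets, and both facts are asserted as property tests.

## Cox PID hazard model

Covariates are step functions updated at scan times (left-continuous):
running trapezoid integral of V from 0, current volume, and the OLS slope
of the full observation history up to the interval start (expanding window
— less noisy than a two-scan slope; the two-point slope is used when only
two observations exist). Records follow the standard counting-process
format; the partial likelihood uses the Breslow convention for ties (ties
have probability ~0 under continuous simulated times). The fit is a Newton
iteration with step halving on internally z-scored covariates (gradient
max-norm < 1e−8 or 100 iterations), with coefficients and standard errors
(inverse observed information) reported in natural units. Constant
covariate columns are excluded and reported as 0 with SE NaN. Coefficients
exceeding 10 per covariate SD (hazard ratio e¹⁰ across one SD) are treated
as monotone-likelihood divergence, i.e. complete separation.

The model is proposed rather than fitted to any published cohort, so its
validation is recovery-based: the acceptance suite fits 50 replicate
cohorts of 400 subjects simulated at β = (0, 0.05 per mL, 0). The recovery
study uses `baseline_sd` = 3 mL, h₀ = 0.05/month and a 24-month follow-up:
the default trial's 0.5-mL baseline spread leaves the burden covariate with
almost no cross-subject variation and per-fit standard errors (~0.09) that
would swamp a 0.05 signal for any estimator, so the recovery cohort widens
the covariate distribution rather than weakening the check.

## Modified Levin engine

Score semantics, compartment combination (PD if *either* compartment
≤ −2; PR/CR only if *every* assessed compartment qualifies), 4-week
confirmation, and PFS are implemented as described in the package README.
Decisions where the scale's prose is open:

* PD confirmation accepts any follow-up whose worst compartment score is
  still ≤ −1 (a still-worse-or-worse-leaning scan sustains the call).
* A −3 (new lesion) also requires confirmation for PFS by default, by
  symmetry with −2; `confirm_new_lesion=False` makes it immediate.
* PFS is dated at the **first** assessment of the confirmed pair (standard
  trial convention).
* Multifocal disease is scored as a single gestalt score per compartment;
  per-lesion tracking is out of scope.
* Compartments are combined per-timepoint, not summed into a total score.

Score series digitize into a pseudo-volume signal Ṽ(tₖ) = Ṽ(tₖ₋₁) − sₖ
(worsening drives Ṽ up), usable by the PID estimators in score units.

The synthetic rater maps scan-to-scan percent volume change to scores with
monotone cutpoints, by default ≥ +50% → −2, ≥ +15% → −1, > −20% → 0,
> −40% → +1, else +2. The +15% and −20% cutoffs are the progression and
response operating points reported for retrospective FLAIR data, and the
±50%/−40% levels sit near the reported score medians; all cutpoints are
configurable, since both calibration sources are small real-data studies.
Rater noise is a discrete ±1 perturbation applied with probability
`rater_noise_sd`² (matching its variance), clipped to [−2, +2]; the ±3
levels are reserved for explicit new-lesion/disappearance flags so noise
can never fabricate a new lesion.

## Trial statistics

Per-arm Δλ distributions are tested against 0 with a two-sided one-sample
t-test (the deltas are near-normal by construction); a sign-flip
permutation alternative is provided, and arm-vs-arm comparison uses
Welch's t-test with an optional one-sided orientation (the working
hypothesis is that effective treatment *lowers* the parameters). A zero
sample SD is reported as an "exactly determined" flag rather than a
p-value from a degenerate test. No multiplicity control is applied across
the three Δλ parameters (single-comparison reporting).

Combination-vs-single-agent benefit is the all-pairs empirical probability
p(Δλ^{A+B} < Δλ^A) with ties counted ½ — the Mann–Whitney statistic
normalized by the number of pairs — and the ROC module sweeps all observed
percent-change cutoffs, integrates the staircase by trapezoid (equal to
that same probability), and selects the cutoff maximizing Youden's J
(highest cutoff on ties).

## Flipbooks

Mosaics take rows x columns axial slices at a fixed mm spacing from
inferior to superior (positions beyond the volume render black), windowed
to the 2nd–98th intensity percentiles (a degenerate window is widened so
constant volumes still render). Frames export to multipage PDF, animated
GIF, or an image directory with the frame index and label burned in.
Registration, skull stripping and bias correction are delegated to
external tools; the module compares shapes/affines and warns on mismatch.

## Problem sizes and numerical choices

The shipped test suite uses 10,000-subject cohorts for distributional
checks (SD and variance-ratio assertions at 3% / ±0.2 tolerance), 10,000
draws for the exponential-survival Kolmogorov–Smirnov check (α = 0.01),
and 50 x 400 subjects for Cox recovery — sizes at which the Monte Carlo
error is comfortably below each assertion's tolerance while the whole
suite runs in well under a minute per module. All simulations are seeded;
hypothesis-based property tests run derandomized. Quadrature tie-breaks
(odd Simpson panels, equidistant burden scans) are deterministic and
documented above.

## Known limitations

* Linear growth only; the PID parameters remain well-defined for nonlinear
  trajectories but the simulator cannot generate them.
* The Cox fit estimates no baseline hazard (h₀ is used only for
  simulation) and offers no frailty or regularization.
* Levin scoring assumes one rating per timepoint per compartment; reader
  panels and adjudication are not modeled.
* PFS comparisons between the qualitative and quantitative routes are
  exact only for a zero-noise rater; with rater noise the two routes
  diverge by design.
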