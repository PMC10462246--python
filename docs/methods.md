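# Methods

`predose` implements the organ-level (MIRD-schema) protocol for preclinical
radiopharmaceutical dosimetry: from per-animal biodistribution measurements
to absorbed, equivalent, effective and RBE-weighted dose coefficients on a
computational phantom. This note records the model, the assumptions it
rests on, the numerical choices made where the design was open, and what
the synthetic-data tests do and do not demonstrate.

## Model and pipeline

The absorbed dose coefficient of a target region rT is

    d(rT) = sum_rS  ã(rS) · S(rT ← rS)            [Gy/Bq]

where ã(rS) is the time-integrated activity coefficient (TIAC) of source
region rS — the number of nuclear transformations in rS per unit
administered activity, in hours — and S(rT ← rS) is the absorbed dose rate
per unit source activity, supplied by the user as a table exported from
organ-level dosimetry software. The hours→seconds conversion happens exactly
once, inside the dose engine; every upstream quantity stays in hours.

The pipeline to ã is:

1. **Measurements → SUV.** %IA/g readings are converted per animal as
   SUV = %IA/g · M_body / 100 (volume concentrations are divided by tissue
   density first; default 1 g/mL). Replicates at each time point are
   averaged; the spread is reported as the sample standard deviation
   (n−1 denominator — replicates are a sample, and downstream weighting
   uses these SDs). The population-mean-mass shortcut is available as an
   explicitly flagged option; the per-animal exact form is the default
   because the shortcut is only an approximation valid for uniform cohorts.
2. **SUV → phantom activity fractions.** Under the first-order assumption
   that SUV is equivalent across species and phantoms, the decay-uncorrected
   fraction of administered activity in a phantom source region is
   a(rS, t) = SUV(rS, t) · M(rS)/M(TB) · e^(−λp·t), with both masses from
   the phantom (inclusive of blood, matching how tissue is assayed). Red
   marrow uses the blood curve as a surrogate with the phantom marrow mass.
   Total-body curves can come from a whole-body SUV series, from carcass +
   excised-organ composition (masses from the phantom; duplicated organs
   rejected to prevent double counting), or directly from dose-calibrator
   whole-body readings normalized to the time-of-administration reading
   (those are already decay-uncorrected and are used as-is).
3. **Integration.** Either trapezoidal integration with the conventional
   closures — a(0) ≈ a(T1) before the first point, physical decay only
   after the last — or weighted nonlinear least-squares regression of
   a(t) = Σψ cψ·e^(−(λbψ+λp)·t) followed by the exact integral
   ã = Σψ cψ/(λbψ+λp). λp is fixed by the radionuclide, never fitted.
4. **Excreta and closure.** The urinary bladder TIAC comes from the voiding
   model (below); the rest of body receives ã(TB) − Σ ã(explicit sources),
   with a hard error (or opt-in clamp to zero) on negative remainders.

Dose integration always runs to complete decay (TD = ∞); a finite
integration period is deliberately not exposed.

## Voiding-bladder model

Between voids the bladder fills at the urinary share of the biological
total-body clearance, fu_ψ·λb_ψ·e^(−(λb_ψ+λp)t) per clearance component,
its content decays physically, and it empties instantaneously every TV
hours. Summing the per-cycle integrals (each cycle is the first one scaled
by e^(−Λψ·TV), Λψ = λbψ + λp) gives the closed form

    ã(bladder) = Σψ fuψ · [ (1−e^(−λp·TV))/λp − (1−e^(−Λψ·TV))/Λψ ]
                        / (1−e^(−Λψ·TV))

The urinary fractions fuψ are user inputs; no estimation procedure is
offered. Because published renderings of this expression are easy to
mis-bracket, the implementation is certified in the test suite against a
discrete fill/decay/void simulation (independent numerical integration of
the bladder content), to 1e−4 relative over a random grid of
(λb ∈ [0.01, 1] h⁻¹, λp ∈ [0.01, 1] h⁻¹, fu ∈ [0, 1], TV ∈ [0.5, 12] h),
and at the analytic limits TV → 0 (continuously emptied bladder, ã → 0)
and TV → ∞ (ã → fu·(1/λp − 1/Λ)). For Λ·TV < 1e−3 the bracket is evaluated
by series expansion; the direct form loses all significant digits to
cancellation there.

## Curve fitting

- **Weights.** w_i = 1/SD_i² when every point carries a positive SD,
  otherwise unweighted.
- **Degrees of freedom.** Every fit must keep n_points − 2Ψ ≥ 1. A
  bi-exponential (4 parameters) therefore needs at least 5 time points;
  requesting it on 4 is an error, not a warning.
- **Positivity.** Amplitudes are constrained non-negative by default, which
  ignores a brief uptake phase (it contributes little to the integral); a
  flag releases the constraint for curves where the rising portion matters.
  Biological rates are constrained non-negative: accumulation beyond the
  administered amount is unphysical in this model class.
- **Initialization.** Deterministic multi-start: candidate rate vectors
  log-spaced between 1/(10·Tn) (slower than the window can resolve) and
  10/T1 (faster than the first point can see), thinned to at most 16
  starts; amplitudes at fixed rates from a non-negative linear solve
  (NNLS). No randomness enters the fitting path.
- **Optimization.** Bounded trust-region least squares with an analytic
  Jacobian: a cheap screening pass over all starts, a refinement of the
  winning basin at xtol 1e−10 (which also decides the convergence verdict),
  and a precision polish at 5e−14 that may only lower the cost. A fitted
  rate with λb·Tn < 1e−3 — indistinguishable from pure physical decay over
  the sampled window — is snapped to exactly 0 when that does not increase
  the cost; this is what makes the no-biological-clearance case reproduce
  ã = 1/λp to machine precision instead of 1e−7.
- **Model selection.** `n_components="auto"` compares Ψ ∈ {1, 2, 3} by
  AICc with k = 2Ψ + 1 (residual variance counted as a parameter). A Ψ can
  pass the degrees-of-freedom rule yet leave the AICc correction undefined
  (n − k − 1 < 1, e.g. Ψ = 2 at n = 5); such models can be requested
  explicitly but are excluded from automatic selection — with that little
  data the selection statistic has no support. Score ties (Δ < 2) resolve
  toward fewer components.
- **Uncertainty.** A delta-method standard error of ã from the local
  least-squares covariance is attached when available. It reflects
  parameter scatter only and is not part of the core protocol; treat it as
  indicative.

## Time-point planning

Two schedule generators: the empirical power-1.5 rule
Ti = Tmin + (Tmax−Tmin)·((i−1)/(n−1))^1.5 with Tmin = Te/(n−1) and
Tmax = 1.5·n·Te/(0.15·n+1), and the ICRU multiples {Te/3, 2Te/3, 3Te/2,
3Te, 5Te}. Both are homogeneous in the effective half-life Te; Te may be
given directly or computed as ln2/(λb+λp). Times are rounded only for
display, never in computation.

## Dose engine

Per-target absorbed dose is the S-weighted sum over sources, with the
per-source breakdown retained (it must re-sum to the total to 1e−12
relative, and the suite checks linearity of the whole report in the TIAC
vector). Equivalent dose applies radiation weighting factors wR and
RBE-weighted dose applies user RBE factors, both over a per-radiation-type
dose partition that comes either from a typed S-value table or from the
radionuclide's declared dose fractions — no emission-spectrum physics is
computed. Effective dose is the tissue-weighted, sex-averaged sum of
equivalent doses and is emitted only for human-labelled phantoms; for
animal phantoms the package refuses and reports absorbed/RBE-weighted
coefficients instead, since effective dose is defined for reference humans.
The self-dose sanity check approximates each region's coefficient as
ã·Δnp/M (complete local absorption of non-penetrating emissions) and flags
ratios to the reported value beyond half a decade.

S-value files may be sparse: absent cross-fire pairs read as 0 with a load
warning, but a self-dose (diagonal) entry is mandatory for every
source-capable region, because self-dose dominates organ dose for
particulate emitters. Unknown region names and negative values are errors.

## Synthetic data generator

The generator realizes exactly the model class the fitting stage assumes:
per-region sums of decaying exponentials, with regions disjoint and
covering the body so that the total-body curve is their sum and one ground
truth serves the organ, carcass-composition and dose-calibrator routes
consistently. The forward model inverts the analysis chain (true fraction →
decay-corrected SUV via phantom masses → per-animal %IA/g via sampled body
mass) and multiplies by unit-mean log-normal noise — counting measurements
are positive with roughly constant CV. Defaults model a well-run mouse
study: 25 ± 1.5 g cohort, 3 animals per time point, 5% measurement CV.

What passing the closed-loop tests shows: the pipeline's algebra and
estimators are correct and unbiased enough to recover known kinetics of its
own model class at realistic noise. What it does not show: robustness to
model misspecification (kinetics outside the exponential family, uptake
phases), inter-animal biological variability beyond body mass, partial
organ sampling, or assay-specific systematics (counter efficiency,
spillover, segmentation error) — all of which are out of scope here.

## Numerical and edge-case policy

- Trapezoidal integration of points on a convex decay curve sits on chords
  *above* the curve, so sparse pure-decay data can integrate to slightly
  more than the hard physical bound 1/λp (complete local decay of all
  administered activity). The trapezoid route warns when this happens
  rather than silently clipping; the regression route cannot exceed the
  bound when amplitudes sum to ≤ 1.
- The trapezoid method refuses single-point series (use the exponential or
  physical-decay-only route), unsorted times, and λp ≤ 0.
- Whole-body dose-calibrator ratios > 1 after administration are retained
  with a warning (physically inconsistent but sometimes observed with
  uncalibrated geometries).
- Masses are validated strictly positive and strictly below the total-body
  mass; carcass + excised masses must close on the body mass within 0.5%
  or a warning is emitted.
- An activity-closure audit warns when simultaneously transposed source
  regions sum to more than the administered activity beyond 2 propagated
  SDs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use: 10 random half-lives for
the physical-decay limit; a 100-point random grid for the bladder oracle;
grids of 8–128 intervals for the trapezoid convergence order; and 200
Monte Carlo repeats of a 3-animal × 5-time-point bi-exponential study for
TIAC recovery. These sizes give stable statistics while keeping a full run
in well under a minute on one CPU.
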