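# Methods

`electroperm` models and analyses the selective permeabilization of
urothelial cancer cells by nanosecond pulsed electric fields (nsPEF). This
note documents the models, their assumptions, the defaults that matter, and
the choices made where the design was genuinely open.

## Electroporation threshold model (`biophysics`)

A spherical cell of radius R in a uniform field E develops an induced
transmembrane potential (TMP) at its electrode-facing poles; at steady state
the Schwan relation gives ΔV = (3/2) E R cosθ. Electroporation is assumed to
begin when the pole TMP (cosθ = 1, the cathode-facing pole) reaches a
threshold ΔV_th, taken as 0.2 V — an experimentally established value across
many mammalian cell types. Membrane charging is not instantaneous: during a
pulse of duration t the TMP reaches only the fraction 1 − exp(−t/τ_c) of its
steady-state value, with charging constant τ_c = 2 µs (mammalian default).
The threshold field is therefore

    E_th(R, t) = (2/3) (ΔV_th / R) / (1 − exp(−t/τ_c)).

Consequences tested throughout: E_th scales as 1/R, so the ratio of
thresholds for two cell sizes equals the inverse radius ratio at *every*
pulse duration (a 20-µm-diameter cell needs 1.5× the field of a 30-µm cell);
E_th decreases monotonically in t and converges to the steady-state value
(within 0.1% for t ≥ 14 τ_c). Angular TMP variation, non-spherical shapes
and pore-density dynamics are out of scope.

`permeabilized_fraction` applies the threshold pointwise to a population of
radii — a deliberately simple step-function dose model with no stochastic
pore component.

### Electrode field model

The experimental exposure uses two parallel 0.5-mm tungsten rods at 1.5 mm
center-to-center spacing touching the coverslip at 45°. We model the field
in the imaging plane with the closed-form 2-D solution for two infinite
parallel cylinders: the pair is electrostatically equivalent to two opposite
line charges at x = ±s, s = √((d/2)² − a²), with λ/(πε) = U / acosh(d/2a)
fixing the inter-electrode potential difference at the applied voltage U.
The 1-V solution is scaled linearly to the experimental amplitude, exactly
as a finite-element solution would be. This analytic model reproduces the
qualitative monotone decay of intensity away from the electrode gap and is
exactly testable against independent superposition, but it idealizes the
true 3-D 45° contact geometry; computed sub-ROI intensities are therefore
used as *relative* exposure levels, not calibrated absolute ones. The
800 × 600 µm imaging ROI is placed with its long edge on the line through
the electrode tips and split into three 800 × 200 µm strips; per-strip
mean/min/max fields are sampled on a uniform 21 × 21 grid per strip
(41 × 41 changes means by < 1%).

## Dye-uptake kinetics (`traces`)

After the pulse train, uptake of the membrane-impermeant dye YO-PRO-1 rises
and saturates as the membrane reseals. The mean trace is modelled as

    F(t) = A (1 − exp(−(t − t0)/τ)),   t ≥ t0,

with plateau A (total uptake) and resealing time constant τ. Choices:

* **t0 is fixed** at the recorded exposure time (10 s into a 180-s
  monolayer acquisition) rather than fitted — the pulse delivery time is
  known, and freeing t0 makes (t0, τ) nearly degenerate at this window.
* **Sampling interval** defaults to 3 s (configurable; 4-s grids are fully
  supported — both intervals appear in the source descriptions of the
  acquisition).
* **Fitting** is bounded nonlinear least squares (τ ∈ [1, 10⁴] s,
  A ∈ [0, 10·max F]) with A₀ = last value, τ₀ = time to reach (1−1/e)A₀ and
  up to 5 jittered restarts; a dense-τ-grid oracle in the test suite
  verifies the optimum is never missed. R² is computed over the fitted
  (post-exposure) samples.
* **Baseline**: the mean of the ≥ 3 pre-exposure samples is subtracted;
  negative values after subtraction are retained (noise is symmetric).
* **Degenerate traces**: an identically-zero post-exposure trace returns a
  converged fit with A = 0 and τ flagged unidentifiable; negative-trending
  traces are flagged non-converged rather than forced into the model.

AUC is the trapezoidal integral of the baseline-subtracted trace (additive
over subintervals; endpoints interpolated). Group fold changes compare
baseline-subtracted means at an evaluation time via nearest-sample lookup
(tolerance one sampling interval). Spheroid swelling is quantified as the
percent change of the 2-D projected area at 10 min post-exposure relative
to the pre-exposure mean.

**A known estimator property**: when τ is comparable to the post-exposure
window (130 s vs 170 s), per-point noise makes the fitted τ right-skewed,
so the *mean* fitted τ over 20 replicates carries an upward bias of several
percent and noticeable seed-to-seed spread. This is intrinsic to
least-squares estimation in this low-information regime, not a fit defect
(the grid oracle confirms the optima); consumers comparing mean τ between
groups are unaffected because the bias is shared.

## Morphometrics (`morphometrics`)

The pipeline starts from per-cell measurement tables (segmentation is out
of scope). Form factor is 4π·area/perimeter², in (0, 1], 1 for a circle,
and scale-invariant. Monolayer statistics treat the *ROI mean* as the unit
of analysis (18 ROIs per line). Tissue-microarray (TMA) statistics average
per (tissue class, array) and then take weighted means across the 9 arrays
with cores-per-array weights — the weighted one-way ANOVA on these
per-array means with those weights reproduces the printed denominator
degrees of freedom (27 rows − 3 classes = 24). The spheroid "mean radius"
is defined as √(area/π) of the 2-D projection, the only measurement
available. The H-score is the standard weighted sum
0·%neg + 1·%weak + 2·%moderate + 3·%strong ∈ [0, 300].

## AFM stiffness (`mechanics`)

Approach curves from a sphere-tipped cantilever (R_tip = 1 µm, spring
constant k = 0.04 N/m) are reduced to force F = k·deflection and
indentation δ = (z − z_contact) − deflection. The Hertz model for a sphere
on an elastic half-space, F = (4/3)·E/(1−ν²)·√R_tip·δ^{3/2}, is fitted
with ν = 0.5 (incompressible soft tissue — the standard AFM convention when
ν is not otherwise known). Because F is linear in E given the contact
point, the fit is a grid search over candidate contact points with a
closed-form least-squares E at each; the pair with the smallest residual
wins. The fit range is capped at δ ≤ R_tip (the sphere form assumes
δ ≪ R_tip), and a +50-nm contact mis-specification changes noiseless E by a
bounded, regression-tested amount (< 15% at these settings). Neither the
indentation range nor the contact algorithm is prescribed by the source
description; both are configurable here.

A 5 × 5 force map is reduced to one representative modulus per spheroid by
the **median** over converged fits (the statistics description specifies
the median; an alternative figure caption says "averaged" — the median is
the default, configurable by using mean aggregation externally).
Post-exposure stiffness normalized to the pre-exposure baseline is fitted
with the decay-to-plateau model y(t) = p + (1−p)·e^{−t/τ_m}, y(0) = 1.
Solving y(4 min) = 0.50 and y(10 min) = 0.41 — the two reported RT4 losses —
gives p ≈ 0.404, τ_m ≈ 2.19 min; these are the RT4 generator defaults, with
the baseline modulus back-computed from the reported 10-min value
(401.8 Pa). SV-HUC-1 defaults come from its reported 26%/29% losses and
1218.5 Pa. Repeated-measures two-way ANOVA of the stiffness time courses is
a non-goal.

## Statistics (`stats`)

* **Welch's one-way ANOVA** (heteroscedasticity-robust): W with numerator
  df k−1 and Welch–Satterthwaite denominator df; verified against an
  independent implementation (pingouin) and against the identity
  W = t²_Welch for k = 2.
* **Dunnett's T3**: per-pair Welch t with per-pair Welch–Satterthwaite df,
  referred to the studentized maximum modulus (SMM) distribution with
  m = number of comparisons. The SMM tail probability is computed by
  adaptive quadrature of ∫ [2Φ(qs) − 1]^m f_{χ_ν/√ν}(s) ds and
  cross-checked against Monte-Carlo simulation to two decimals. The test is
  named but not algorithmically specified in the source; this is the
  standard T3 construction.
* **Weighted one-way ANOVA** with Tukey-adjusted pairwise comparisons of
  weighted marginal means: WLS F test (df = rows − k, matching the printed
  TMA result) with pairwise SE from the WLS MSE and studentized-range
  adjustment. With equal weights it reduces exactly to ordinary ANOVA;
  duplicating an observation equals doubling its weight up to the row-count
  df (the SS ratio F/df_den is invariant, which is the form the test suite
  asserts).
* **Pearson/linear regression**: r, r², two-sided p with df = n−2, OLS
  slope/intercept. Significance stars at 0.05/0.01/0.001/0.0001.

Repeated-measures designs, sphericity corrections and non-parametric tests
are non-goals.

## Synthetic data (`synthetic`)

The generators define the study conditions and are exact inverses of the
analysis models at zero noise (round-trip recovery is tested to numerical
precision). Distributional choice: sizes, time constants and plateaus are
positive right-skewed biological quantities and are drawn lognormal,
parameterized by arithmetic mean and CV; trace noise is additive Gaussian.
Only means ± SEM are reported by the experiments, so the families are a
documented modelling choice.

Key defaults (entries not reported anywhere are flagged `paper=False` in
the tables and were chosen once as field-realistic values):

* **Monolayer uptake** (11.5 kV/cm): τ = 130/84/86 s for T24 and
  115/75/75 s for UM-UC-3 at 0/2/5 mM Ca²⁺ (reported); normal lines
  SV-HUC-1 and HBLAK get interpolated τ around 60–75 s with the reported
  non-significant Ca²⁺ trend. End-of-acquisition uptake anchors SV-HUC-1 at
  100 a.u. per condition and encodes the reported fold differences (e.g.
  T24 = 6.1× SV-HUC-1 at 5 mM). Lower field levels scale uptake by 0.6
  (10 kV/cm) and 0.33 (8 kV/cm) with τ unchanged (field strength was
  reported not to alter τ). Replicate CV 15%, per-point noise 5% of the
  plateau, baseline 50 a.u.
* **Spheroids**: acquisition every 10 s; exposure is placed 30 s after
  acquisition start (the exact exposure time within the spheroid recordings
  is not stated; 30 s preserves ≥ 3 pre-exposure baseline frames at the
  10-s sampling) with a 10-min post-exposure window. Swelling traces follow
  a₀(1 + g(1 − e^{−t/τ_s})) with τ_s = 3 min (not reported; chosen to place
  most of the rise in the first minutes, as observed) and g calibrated per
  group so the 10-min percent change hits the targets 12% (SV-HUC-1), 42%
  (RT4), 14–21% (patient-derived organoids).
* **Size–uptake correlation**: per-spheroid mean cell area is drawn per
  group; final fluorescence is α + β·area + ε with σ_ε solved from the
  target population correlation r = 0.36 at the five-group mixture variance
  (n = 45). The mean *sample* r over 100 generations lands within 0.05 of
  the target (verified by simulation in the acceptance suite).
* **TMA morphometry**: class mean areas 111.8 µm² (primary tumor and nodal
  metastasis) vs 90.7 µm² (normal urothelium); 47/66/56 cores split
  deterministically across 9 arrays so the totals are exact; 50 cells per
  core, within-core CV 30%. Monolayer lines use 720 vs 400 µm² (the 1.8×
  reported ratio; absolute monolayer areas are not reported).
* **Force maps**: 5 × 5 Hertzian curves per timepoint at {0, 1, 4, 7, 10}
  min with multiplicative map noise (CV 10%), spheroid-level baseline CV
  15%, 1-nm deflection noise and randomized contact points; `noiseless=True`
  switches every noise source off for deterministic pipeline checks.

What the generators deliberately do **not** emulate: spatial structure
(images, cell packing), photobleaching, focus drift, Ca²⁺
reaction–diffusion, viscoelastic (non-Hertzian) response, and
between-biological-replicate batch effects. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
structure, not robustness to those real-data artifacts.

## Problem sizes and numerics

Default problem sizes are the experimental ones (n = 18–20 monolayer
replicates, n = 9–11 spheroids, 45 spheroids for the correlation, 25-curve
force maps); the seed-averaged correlation check uses 100 generations of
n = 45. Tolerances: τ and uptake recoveries are asserted at the reported
precision (±10%), swelling at ±3 percentage points, the noiseless
mechanics chain at ±1 percentage point, field-model identities at 1e-9
relative, and noiseless fit recoveries at 1e-6 relative. Ties and
degenerate inputs (zero-variance groups, zero-amplitude traces, all-failed
force maps) are handled explicitly as documented above rather than left to
solver behavior.

## Reproducibility

All generators consume a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical CSV output.
`electroperm report` writes a manifest (tool version, config, config hash)
alongside its outputs, and `scripts/acceptance.py --seed N --out f.json`
recomputes the headline quantities end to end.
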