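# Methods

This note records the models, conventions and design choices behind
`glucotriad`, in the spirit of a statistical software methods appendix.

## Traces, units and missing data

The canonical internal unit is mg/dL; the conversion factor to mmol/L is
fixed at 18.016 (glucose molar-mass convention).  Indices whose literature
definition is on the mmol/L scale (CONGA, LI, J-index, MODD, MAGE, MAG)
convert internally, so a panel mixes units deliberately — each index is
reported in the unit its literature uses.

CGM readers never impute silently: non-positive readings are dropped into a
QC report, subjects with non-monotone time axes are rejected with a reason.
Resampling interpolates linearly only across gaps ≤ `max_gap` (default 30
min, an artifact policy — field practice varies and no single convention is
standard); longer gaps split the trace and the longest contiguous block is
analyzed.  Day-based indices (MODD, ADRR) use consecutive 1440-min blocks
from the first reading, which makes synthetic traces deterministic; with a
calendar start time the same blocks align to it.

## The CGM index panel

Fifteen values per subject.  Conventions that the literature leaves open
were fixed as follows:

- **ACF**: biased-denominator estimator on the full contiguous series (not
  per-day averaged).  **AC_Mean/AC_Var** are the mean and unbiased (n−1)
  variance of r_1..r_K with K = 30 at 5-min sampling and K = 10 at 15-min
  sampling; both windows cover 150 minutes, so the two samplings measure the
  same physiological memory span.  AC metrics are exactly invariant under
  affine maps of glucose, which the suite checks to 1e-10.
- **CONGA** lag defaults to 1 h; Std of the lagged differences, unbiased.
- **LI** is computed on a 60-min resampled grid: mean of (ΔG_mmol)²/Δt_h.
- **J-index**: 0.324 (mean + Std)², mmol/L.
- **HBGI/LBGI**: f(g) = 1.509((ln g)^1.084 − 5.381) on mg/dL; risk
  10 f² split by sign; **ADRR** is the mean over complete days of
  (max low-risk + max high-risk).  A day counts as complete with ≥ 20 h of
  coverage (artifact threshold); one complete day suffices.
- **GRADE**: per-reading 425(log₁₀(log₁₀ g_mmol) + 0.16)², capped at 50,
  summarized by the mean (the original publication used the median; the mean
  follows the dominant software convention).
- **M-value**: ideal glucose 120 mg/dL, cubic log-deviation score plus the
  W/20 range correction.
- **MAGE** finds interior alternating local extrema by three-point
  comparison with plateau merging, iteratively deletes the smallest adjacent
  excursion below 1 Std of the whole trace, and averages the remaining
  amplitudes direction-agnostically.  Counting both directions (rather than
  Service's single direction) makes the statistic deterministic and
  symmetric.  Endpoints are not extrema: including them would dilute the
  amplitude of a clean oscillation (a sinusoid of swing 40 mg/dL must score
  40).  A trace with no qualifying excursion reports 0 with a flag, not an
  error.
- **TIR** bounds are inclusive at 70 and 180 mg/dL.

Every index is checked against a naive loop-based re-implementation on
random traces to 1e-8 relative.

## OGTT indices

Insulinogenic index, Matsuda composite and oral disposition index use
glucose in mg/dL and insulin in μU/mL.  The composite-index means are the
unweighted five measured samples (standard Matsuda convention).  The oral DI
multiplies the composite index by the trapezoid AUC ratio of insulin to
glucose over minutes {0, 30, 60, 120}; the 90-min samples are excluded by
definition.  The 3-point OGTT curve (0/30/120 min) is linearly interpolated
onto a 1-min grid (121 points); its AC_Var uses lags 1–20, i.e. the first
20 minutes of displacement on a 2-h curve.  The curve mean is grid-step
stable to 1e-9; the Std to about 1e-3 relative.

## The delay-integral simulator

State (G, I) with glucose cleared insulin-independently (k_glu, 1/min) and
insulin-dependently (k_sen, per insulin-unit·min), produced endogenously
(k_pro, mg/dL/min) and perturbed by an external appearance rate f(t);
insulin secretion responds to the k_tim-minute moving average of glucose
(gain k_sec) and clears at k_cle.  Insulin units are arbitrary: only the
products k_sen·I and k_sec·G are physically constrained.

Numerics: classical fixed-step RK4 (default step 0.1 min over 240 min) with
the distributed delay evaluated by trapezoid over the stored history, the
current stage value appended as the final node.  Pre-history is
G(s ≤ 0) = G(0).  The end stage of each RK4 step evaluates f at the left
limit of the interval's right endpoint so that the half-open square bolus
(default 5 mg/dL/min on t ∈ [30, 40)) is integrated without smearing; with
this convention step-halving moves G by < 1e-6 relative.  Steps larger than
k_tim/4 are rejected as under-resolving the delay.  The closed-form rest
point (I* = (k_sec/k_cle)G*, G* the positive root of
k_sen(k_sec/k_cle)G² + k_glu G − k_pro = 0) is reproduced by the integrator
to 1e-6 and is the default initial condition.

Default parameters (k_glu 0.01, k_sen 1e-4, k_pro 1.0, k_sec 0.02, k_cle
0.1, k_tim 30) give a rest glucose of ~85 mg/dL and a realistic ~130 mg/dL
bolus peak; they and the sweep ranges in `DEFAULT_SWEEP_RANGES` are package
choices labelled NGT-plausible, not fitted values.  `component_sweep`
searches the cartesian grid (3 values per parameter over six parameters,
including the bolus rate) for pairs of runs in which exactly one of
(mean, Std, AC_Var) differs by ≥ 20 % while the other two agree within 5 %
(relative differences symmetrized by the pair mean).  The bolus rate is in
the sweep because it scales the excursion — hence Std — while k_pro can
compensate the mean.

## Synthetic cohorts

The generator emulates the study conditions the analysis stages assume: 8
NGT, 16 IGT and 29 T2DM subjects (counts configurable), three consecutive
days of 5-min CGM, an OGTT per subject, and a continuous %NC-like outcome.
Traces come from an AR(1)-plus-meals process
G_t = μ + X_t + meals, X_t = φX_{t−1} + η_t, with three Gaussian meal bumps
per day (~07:30/12:30/19:00, ±40-min jitter, 45-min width, 30 % amplitude
jitter) and a 40 mg/dL floor; per-class parameter distributions
(`CLASS_PARAMS`) grade μ, σ, φ and meal amplitude upward from NGT to T2DM.
A mechanistic variant driven by the simulator exists; recovery studies
default to the AR(1) model because its autocorrelation is analytically
known and it is fast.

Diagnostic markers (FBG, HbA1c, PG120) are drawn inside the class-defining
ranges (T2DM: HbA1c ≥ 6.5 %, FPG ≥ 126 mg/dL or PG120 ≥ 200 mg/dL; IGT:
6.0–6.4 %, 110–125, 140–199; NGT below all), positioned within the range by
the subject's baseline glucose — so the markers carry mean-component
information only.  OGTT insulin curves fall from NGT to T2DM in early-phase
secretion (insulinogenic index ranges per class).

The outcome is %NC = β₀ + β_m z(mean) + β_v z(Std) + β_a z(AC_Var) + ε,
ε ~ N(0, σ_nc), truncated to [0, 100]; defaults β₀ = 18, β_m = 4,
β_v = 3, β_a = 3, σ_nc = 5 give %NC in the realistic 5–35 % band with all
three components genuinely informative.  The z-scores are of the *empirical*
trace components, so regression on the measured indices is an exact recovery
problem.  Generation metadata (betas, per-subject components, class labels)
is returned for recovery tests.

What the generator does **not** emulate: sensor noise spectra and dropout,
physiological meal-response asymmetry, circadian baseline drift, and any
real covariance between lipids/blood-pressure covariates and glucose
dynamics.  Passing recovery tests therefore show that the pipelines are
correct and well-calibrated under the stated generative structure, not that
the clinical effect sizes are reproduced.

## Regression and selection stages

- z-scoring uses the unbiased Std; constant columns are an error naming the
  column.
- OLS reports t-based 95 % CIs and a Gaussian-ML AIC with all constants and
  parameter count p + 1 (σ not counted) — a fixed internal convention for
  model comparison; a numerically perfect fit floors the AIC and sets a
  flag rather than reporting −∞.
- VIF pruning drops the single highest-VIF variable per round until all are
  below 10, ties to first in input order; the removal trail is returned.
- The Spearman network computes all pairwise correlations (average ranks for
  ties), percentile bootstrap 95 % CIs over subjects (default 10000
  resamples), and Benjamini–Hochberg Q-values jointly across all pairs with
  edges flagged at Q < 0.05.  On independent noise the flagged fraction
  averages below 5 %, which the suite checks.
- LASSO uses the (1/(2n))‖y − β₀ − Xβ‖² + λ‖β‖₁ objective with the intercept
  unpenalized, a 200-point log grid on [1e-3, 1e2] by default, exact-argmin
  leave-one-out CV, and a full-data refit at the optimum; solutions are
  verified against the KKT subgradient conditions in tests.
- PLS picks its component count (1..5 by default) by LOO MSE;
  VIP_j = √(p Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a), so Σ VIP² = p.
- The power calculation is the two-sided Fisher-z approximation
  n = ⌈((z_{1−α/2} + z_power)/atanh r)²⌉ + 3.

## Factor analysis

Extraction is maximum likelihood (needed for a likelihood-based BIC:
−2 logL + [pk + p − k(k−1)/2] ln n over k = 1..min(Ledermann bound, 8)).
Velicer's MAP uses squared partial correlations (the original form); a
minimum at zero components removed means "no common factor".  Rotation is
Kaiser-normalized varimax; factors are sign-oriented by their largest
loading and ordered by explained variance; rotation preserves communalities
to 1e-8.  Factor scores use the regression (Thurstone) estimator
F = Z R⁻¹ Λ.  Interpretation sets collect variables with |loading| ≥ 0.30.
Heywood cases are flagged with a warning, not fatal.

KMO compares squared correlations to squared anti-image partials; Bartlett's
sphericity is −(n−1−(2p+5)/6) ln det R on p(p−1)/2 df.  Cronbach's α comes
with a Feldt F-based 95 % CI and corrected item–total correlations (item
excluded from the total; negatively keyed items sign-flipped first — the
corrected form is adopted because it is the stricter reading).  Variable
clustering negates a caller-supplied inversion list (indices whose healthy
direction is high, e.g. insulin-sensitivity measures and AC_Mean), then
applies Ward/Euclidean linkage with the variables as points and subjects as
coordinates, choosing k in 2..6 by maximum mean silhouette.

## Problem sizes in the shipped checks

The end-to-end suite and `scripts/acceptance.py` use seeded synthetic
problems sized for a desk machine: n = 200 cohorts × 100 seeds for the
regression comparison, n = 100 cohorts × 100 seeds with a 15-variable panel
for LASSO/PLS selection, n = 300 index tables for factor recovery, 50
simulator traces for the 5-vs-15-min AC_Var agreement, and a 3⁶-point
parameter grid for the component sweep.  These sizes are the package's
standard demonstration scale; all rates are recomputed at run time.

## Known limitations

- EasyGV-lineage indices have minor formula variants across software
  (GRADE mean vs median, M-value reference, LI pair spacing); the
  conventions above are fixed and documented but not the only ones in use.
- The ML factor fit can fail to converge for over-parameterized k; such k
  are skipped in the BIC scan rather than guessed.
- The simulator's NGT parameter ranges are plausibility choices, not
  estimates; simulator outputs support qualitative separability claims only.
- LASSO selection among strongly collinear near-duplicates is inherently
  unstable; driver-selection checks therefore use panels where each
  component has a unique carrier, mirroring what the statistic can promise.
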