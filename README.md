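# glucotriad

Glucose dynamics measured by continuous glucose monitoring (CGM) carry three
statistically separable components — the **mean** level, the **variance**
(glycemic variability), and the **autocorrelation** (how strongly glucose
remembers its recent past). `glucotriad` is a Python library for clinical and
biostatistical researchers who want to measure these components, simulate
them mechanistically, and relate them to a continuous vascular outcome such
as the necrotic-core fraction of coronary plaque (%NC) on the 0–100 % scale.

It provides:

- **CGM indices** — the 14 classic and autocorrelation-based indices plus
  time in range: CGM_Mean, CGM_Std, CONGA, LI, J-index, HBGI, GRADE, MODD,
  MAGE, ADRR, M-value, MAG, AC_Mean, AC_Var, TIR.  AC_Mean and AC_Var are
  the mean and variance of the autocorrelation function
  r_k = Σ_t (G_t − Ḡ)(G_{t+k} − Ḡ) / Σ_t (G_t − Ḡ)² over lags k = 1..30 at
  5-min sampling (1..10 at 15-min; both span 150 min).
- **OGTT indices** — insulinogenic index (ΔIRI₃₀/ΔPG₃₀), Matsuda composite
  index 10000/√(FPG·FIRI·Ḡ·Ī), oral disposition index, and
  mean/Std/AC_Var of the 3-point post-load glucose curve.
- **A delay-integral glucose–insulin simulator**
  dG/dt = −k_glu G − k_sen I G + k_pro + f(t),
  dI/dt = (k_sec/k_tim)∫_{t−k_tim}^t G ds − k_cle I,
  integrated by fixed-step RK4, demonstrating that mean, Std and AC_Var are
  independently adjustable.
- **A synthetic cohort generator** (8 NGT / 16 IGT / 29 T2DM by default,
  3 days of 5-min CGM each) whose %NC outcome is linear in the z-scored
  trace components, so every downstream stage is a recovery problem with a
  known truth.
- **Statistical pipelines** — z-scoring, OLS with AIC/VIF, iterative VIF
  pruning, bootstrap Spearman networks with Benjamini–Hochberg correction,
  LASSO with leave-one-out cross-validation, PLS with VIP scores, the
  Fisher-z power calculation, and an exploratory-factor-analysis stage
  (BIC/MAP factor counts, varimax ML factors, KMO/Bartlett, Cronbach's α,
  factor-score associations, Ward/silhouette variable clustering).

## Worked example

```python
from glucotriad import fit_ols, generate_cohort, zscore

traces, table, truth = generate_cohort()   # 53 subjects, seeded
df = table.to_frame()
three = fit_ols(zscore(df[["CGM_Mean", "CGM_Std", "AC_Var"]]), df["NC"])
markers = fit_ols(zscore(df[["FBG", "HbA1c", "PG120"]]), df["NC"])
print(round(three.r2, 3), round(markers.r2, 3))
```

prints `0.576 0.371`: on the default synthetic cohort the three-component
model explains substantially more of the %NC variance than the
conventional-marker model, because FBG/HbA1c/PG120 track only the mean
component while the outcome also loads on variance and autocorrelation.
The same script is expanded in `examples/cohort_regression_pipeline.py`;
each capability has a short narrative script under `examples/`, and a thin
CLI (`glucotriad indices|ogtt|simulate|cohort|pipeline|factor`) wraps the
library for shell use.

## Layout

```
src/glucotriad/   trace.py (I/O, units, resampling)   indices.py (CGM panel)
                  ogtt.py   sim.py (delay-integral model)   cohort.py
                  assoc.py (OLS/VIF/LASSO/PLS/network)   factors.py (EFA)
examples/         one narrative script per capability
docs/methods.md   models, conventions, parameter choices, limitations
tests/            pytest suite incl. end-to-end acceptance checks
```
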