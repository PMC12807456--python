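"""Regression and feature-selection pipeline on a synthetic cohort.

Generates the default 53-subject cohort (8 NGT / 16 IGT / 29 T2DM, 3 days
of 5-min CGM each, %NC outcome driven by the mean, Std and AC_Var of each
trace), then compares the three-component regression against the
conventional-marker model and runs LASSO + PLS-VIP feature selection.
"""

import numpy as np

from glucotriad import (fit_ols, generate_cohort, lasso_loocv, pls_vip,
                        power_sample_size, zscore)

print(f"planning: detecting r = 0.4 at alpha 0.05, power 0.8 needs "
      f"n = {power_sample_size(0.4)} subjects")

traces, table, truth = generate_cohort()
df = table.to_frame()
print(f"generated {len(df)} subjects; %NC range "
      f"{df.NC.min():.1f}-{df.NC.max():.1f} %\n")

three = fit_ols(zscore(df[["CGM_Mean", "CGM_Std", "AC_Var"]]), df["NC"])
markers = fit_ols(zscore(df[["FBG", "HbA1c", "PG120"]]), df["NC"])
print(f"three-component model: R2 = {three.r2:.3f}, AIC = {three.aic:.1f}, "
      f"VIFs = {np.round(three.vif.to_numpy(), 2)}")
print(f"FBG/HbA1c/PG120 model: R2 = {markers.r2:.3f}, AIC = {markers.aic:.1f}")
print("the mean-only markers recover part of the signal; the variance and")
print("autocorrelation terms carry the rest.\n")

predictors = ["BMI", "FBG", "HbA1c", "PG120", "II", "Composite", "OralDI",
              "CGM_Mean", "CGM_Std", "CONGA", "LI", "JINDEX", "HBGI",
              "GRADE", "MODD", "MAGE", "ADRR", "MVALUE", "MAG",
              "AC_Mean", "AC_Var"]
X = zscore(df[predictors])
lasso = lasso_loocv(X, df["NC"])
print(f"LASSO (LOO-CV): optimal lambda = {lasso.optimal_lambda:.3f}; "
      f"nonzero: {lasso.nonzero}")
pls = pls_vip(X, df["NC"])
vip_hits = pls.vip[pls.vip > 1].sort_values(ascending=False)
print(f"PLS ({pls.n_components} components), VIP > 1:")
for name, v in vip_hits.items():
    print(f"  {name:10s} VIP = {v:.2f}")
print("indices loading on all three components dominate both selections.")
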