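"""Simulate the delay-integral glucose-insulin model.

Starts the model at its closed-form rest point, applies the standard
external glucose appearance (5 mg/dL/min for 10 min at t=30), and prints
the 240-min response summary.  A second run with higher endogenous
production shows the mean component moving while Std and AC_Var barely
change - the separability that makes the three components independently
informative.
"""

from dataclasses import replace

import numpy as np

from glucotriad import SimParams, simulate, steady_state

params = SimParams()  # k_glu=0.01, k_sen=1e-4, k_pro=1.0, k_sec=0.02, ...
g_star, i_star = steady_state(params)
print(f"rest point: G* = {g_star:.2f} mg/dL, I* = {i_star:.2f} insulin units")

res = simulate(params)
peak_t = res.t[np.argmax(res.G)]
print(f"bolus response: peak G = {res.G.max():.1f} mg/dL at t = {peak_t:.0f} "
      f"min, back to {res.G[-1]:.1f} mg/dL by t = 240 min")
print("summary (G sampled every 5 min, AC lags 1-30):")
for k, v in res.summary.items():
    print(f"  {k:6s} = {v:.4f}")

res_hi = simulate(replace(params, k_pro=1.3))
print("\nwith endogenous production k_pro raised 1.0 -> 1.3 mg/dL/min:")
for k in ("mean", "std", "ac_var"):
    a, b = res.summary[k], res_hi.summary[k]
    print(f"  {k:6s}: {a:8.4f} -> {b:8.4f}  ({100 * (b - a) / a:+.1f} %)")
print("the mean shifts strongly while Std and AC_Var stay close: the three")
print("components of glucose dynamics are separately adjustable.")
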