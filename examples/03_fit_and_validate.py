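"""Calibrate the model on synthetic observations and validate with Af/Bf.

Generates a noisy study-like dataset (3 seasonal experiments, constant
storage at 0/5/10/20 degC, measurement noise sd 0.03 %), fits all six
constants plus the per-experiment initial acidities with the two-stage
optimiser, and scores the fitted model against the observations with the
accuracy (Af) and bias (Bf) factors.
"""

import numpy as np

import kimchikinetics as kk
from kimchikinetics.synthetic import SyntheticDesign

truth = kk.reference_parameters()
design = SyntheticDesign(include_fluctuating=False, seed=42)
obs = kk.generate_observations(truth, design)

fit = kk.fit_parameters(obs, seed=42)
fit = kk.confidence_intervals(fit, obs)

print(f"{'constant':>16} {'true':>10} {'fitted':>10} {'95% CI':>24}")
for name in ("a0", "a1", "a2", "q0", "nmax_intercept", "nmax_slope"):
    true = getattr(truth, name)
    est = getattr(fit.params, name)
    lo, hi = fit.ci_low[name], fit.ci_high[name]
    print(f"{name:>16} {true:10.3g} {est:10.3g}   [{lo:10.3g}, {hi:10.3g}]")
print(f"residual sum of squares: {fit.rss:.4f} on {fit.diagnostics['n_obs']} points")
print()

# validate per condition: Af/Bf of the fitted model against the noisy data
rec = obs.constant_temperature_records()
report = kk.ValidationReport()
for (exp, cond), grp in rec.groupby(["experiment", "condition"]):
    T = float(cond)
    t_obs = grp["time_d"].to_numpy()
    pred = kk.closed_form_constant_temperature(fit.params, fit.n0[exp], T, t_obs)
    af, bf = kk.accuracy_bias_factors(pred, grp["acidity_pct"].to_numpy())
    report.add(exp, cond, af, bf, len(grp))
print(report.rows.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("Af and Bf near 1 mean the fitted curves track every condition with")
print("little spread and no systematic bias.")
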