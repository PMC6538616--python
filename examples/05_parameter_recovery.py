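"""Simulation-based calibration: do the 90% credible intervals cover the
generating coefficients at (roughly) their nominal rate?

Runs a handful of generate-and-refit replicates and reports per-coefficient
coverage, bias and RMSE.  Increase ``n_replicates`` for a sharper estimate.
"""

from pikemodel import ModelSpec, preset
from pikemodel.pipeline import run_parameter_recovery

report = run_parameter_recovery(
    preset("full_scale"), ModelSpec(),
    dict(n_chains=3, n_iterations=4000, n_burnin=2000, thin=2),
    n_replicates=5, seed=42)

print(report.round(3).to_string(index=False))
print(f"\nmean 90%-CI coverage across coefficients: "
      f"{report.attrs['mean_coverage']:.2f} (nominal 0.90)")
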