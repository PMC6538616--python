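"""Counterfactual conservation targets: re-predict poaching rates with each
covariate set to its most elephant-friendly observed value.

The table compares the pooled median poaching rate under each scenario with
the no-intervention baseline; scenarios whose covariate carries a strong
coefficient and a large gap to its best observed value drop the most.
"""

from pikemodel import (McmcSettings, ModelSpec, fit, generate_dataset,
                       preset, run_all_interventions)

truth = generate_dataset(preset("full_scale"), seed=5)
samples = fit(truth.data, ModelSpec(),
              McmcSettings(seed=1, n_chains=3, n_iterations=6000,
                           n_burnin=3000, thin=3))

table = run_all_interventions(samples, truth.data, m_n=0.03)
table = table.sort_values("pooled_median")
print("pooled annual poaching rate by scenario (m_n = 0.03)")
print(f"{'scenario':<12} {'median':>8} {'90% CI':>18}  provenance")
for _, r in table.iterrows():
    print(f"{r['scenario']:<12} {r['pooled_median']:>8.3f} "
          f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}]  {r['provenance']}")
print("\nprecipitation is held at its mean everywhere (it proxies natural "
      "mortality),\nand random intercepts keep their posterior draws: only "
      "the targeted covariate changes.")
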