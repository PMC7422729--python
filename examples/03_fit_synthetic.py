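"""Generate a small timed test and fit it by MH-within-Gibbs.

Simulates 300 examinees on 15 items with time weight 1, fits the matched
model, and prints item-parameter recovery and chain diagnostics.
"""

import numpy as np

from g3plt import (SimulationDesign, generate_item_parameters,
                   generate_abilities, generate_structured_times,
                   generate_responses, run_mcmc, ChainConfig, psrf)

design = SimulationDesign(N=300, J=15, W=1.0)
items = generate_item_parameters(15, 1, design)
theta = generate_abilities(300, 2)
t_star = generate_structured_times(items, theta, 3, design)
y = generate_responses(theta, items, t_star, design.W, 4)

draws = run_mcmc(y, t_star + design.W,
                 chains=ChainConfig(iterations=10_000, burn_in=5_000,
                                    n_chains=2, seed=5))

print("block acceptance rates:",
      {k: round(v, 2) for k, v in draws.acceptance.items()})
for name, truth in (("a", items.a), ("b", items.b), ("c", items.c)):
    eap = draws.eap(name)
    r = np.corrcoef(truth, eap)[0, 1]
    rmse = np.sqrt(np.mean((eap - truth) ** 2))
    rhat = psrf(draws.split_by_chain(name)).max()
    print(f"{name}: corr(truth, EAP) = {r:.2f}   RMSE = {rmse:.3f}   "
          f"max PSRF = {rhat:.3f}")
print("theta: corr(truth, EAP) =",
      round(float(np.corrcoef(theta, draws.eap('theta'))[0, 1]), 2))
print("\nPSRF near 1 means the two chains agree; the guessing block mixes")
print("slowest because its proposal is a narrow +-0.01 random walk, so its")
print("PSRF can sit slightly above the others on a toy this small.")
print("Correlations show how well each class is recovered at this size.")
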