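"""Generate a synthetic illness-death cohort and query the exact truth oracle.

Simulates the base scenario (discrete treatment times with a small mass at
baseline) and prints, for each delay strategy, the true marginal probability
of recovery by the 1.5-unit horizon computed by Gauss-Hermite quadrature over
the confounder distribution, next to the raw observed event composition.
"""

import numpy as np

from msdelay import Strategy, scenario_config, simulate_dataset, true_recovery_prob

cfg = scenario_config("scenario1", n=2500)
ds = simulate_dataset(cfg, seed=7)

counts = {
    "treated first": int((ds.delta_w == 1).sum()),
    "recovered untreated": int((ds.delta_w == 2).sum()),
    "censored before either": int((ds.delta_w == 0).sum()),
}
print(f"simulated {ds.n} subjects:", counts)

print("\ntrue P(recovery by 1.5) under each delay strategy:")
for strat in [Strategy(0.0), Strategy(0.25), Strategy(0.5), Strategy(0.75),
              Strategy(1.0), Strategy.never()]:
    p = true_recovery_prob(cfg, strat, 1.5)
    print(f"  treat at {strat.label():>5}: {p:.4f}")
print("\nTreating earlier raises the recovery probability here because the "
      "post-treatment hazard (0.8) exceeds the untreated hazard (0.4) and "
      "decays with delay.")
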