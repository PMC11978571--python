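"""G-computation recovery curves with bootstrap confidence bands.

Fits the two Cox transition models (untreated recovery on the study clock;
post-treatment recovery on the reset clock with delay as a covariate) to a
simulated cohort, standardizes over the empirical confounder distribution,
and prints the estimated marginal recovery probability at the horizon with a
95% percentile bootstrap interval, next to the exact truth.
"""

import numpy as np

from msdelay import (Strategy, bootstrap_ci, estimate_all, scenario_config,
                     simulate_dataset, true_recovery_prob)

cfg = scenario_config("scenario1", n=2500)
ds = simulate_dataset(cfg, seed=42)
strategies = [Strategy(0.0), Strategy(0.5), Strategy.never()]

curves = estimate_all(ds, strategies, variant="continuous", times=[1.5])
bands = bootstrap_ci(ds, strategies, [1.5], B=200, seed=1)

print("marginal P(recovery by 1.5), multistate-continuous g-computation:")
print(f"{'strategy':>9} {'estimate':>9} {'95% CI':>17} {'truth':>7}")
for c, b in zip(curves, bands):
    truth = true_recovery_prob(cfg, c.strategy, 1.5)
    print(f"{c.strategy.label():>9} {c.prob[0]:9.3f} "
          f"[{b.lower[0]:.3f}, {b.upper[0]:.3f}] {truth:7.3f}")
print("\nEach estimate averages subject-level plug-in recovery probabilities "
      "over all baseline covariate rows; the interval is a subject-level "
      "pairs bootstrap.")
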