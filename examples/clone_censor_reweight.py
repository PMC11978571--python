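"""Clone-censor-reweight comparator with weight diagnostics.

Clones every subject into each compatible delay strategy, censors clones at
deviation, weights by inverse adherence probabilities from a time-to-treatment
Cox model, and estimates per-strategy recovery curves by weighted Kaplan-Meier
and by a weighted Cox outcome model.  A positivity diagnostic shows why the
discrete treatment grid makes every studied strategy estimable.
"""

from msdelay import (Strategy, check_positivity, run_ccr, scenario_config,
                     simulate_dataset, true_recovery_prob)

cfg = scenario_config("scenario1", n=2500)
ds = simulate_dataset(cfg, seed=42)
strategies = [Strategy(0.0), Strategy(0.25), Strategy(0.5), Strategy.never()]

pos = check_positivity(ds, strategies)
print("positivity diagnostic (subjects at risk / initiating per strategy):")
print(pos[pos["bin"] == "all"].to_string(index=False))

km, diag = run_ccr(ds, strategies, variant="km", times=[1.5])
cox, _ = run_ccr(ds, strategies, variant="cox", times=[1.5])
print(f"\nweight diagnostics: max finite weight "
      f"{diag['max_finite_weight']:.1f}, non-finite {diag['n_nonfinite_weights']}, "
      f"trimmed={diag['trimmed']}")

print(f"\n{'strategy':>9} {'weighted KM':>12} {'weighted Cox':>13} {'truth':>7}")
for ckm, ccox in zip(km, cox):
    truth = true_recovery_prob(cfg, ckm.strategy, 1.5)
    print(f"{ckm.strategy.label():>9} {ckm.prob[0]:12.3f} {ccox.prob[0]:13.3f} "
          f"{truth:7.3f}")
print("\nBoth variants should track the truth here: the weight model is "
      "correctly specified in this scenario.")
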