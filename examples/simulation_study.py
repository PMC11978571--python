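"""A scaled-down replicated study comparing the four estimators.

Runs 25 replications of the base scenario and of the misspecified-outcome
scenario (delay-shaped Weibull post-treatment hazard), applying all four
methods, and prints bias/RMSE at the horizon against the quadrature truth.
The full 200-replication version of this table is what scripts/acceptance.py
recomputes.
"""

from msdelay import run_ademp, scenario_config

perf, results, diag = run_ademp(
    [scenario_config("scenario1"), scenario_config("scenario3")],
    methods=("ms_cont", "ms_cat", "ccr_cont", "ccr_cat"),
    reps=25, base_seed=1, progress=True,
)

table = perf.table.copy()
for col in ("truth", "bias", "rmse", "mc_se"):
    table[col] = table[col].round(3)
print(table.to_string(index=False))
print("\ndiagnostics:", diag)
print(
    "\nReading the table: in scenario1 all methods are near-unbiased, with the"
    "\nmultistate-continuous model most precise; in scenario3 the two"
    "\ncontinuous-delay variants acquire bias at late delays because the true"
    "\npost-treatment hazard violates proportionality in the delay."
)
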