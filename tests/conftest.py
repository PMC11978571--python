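"""Shared fixtures: small datasets, rigged models, and session-scoped studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from msdelay.evaluate import run_ademp, run_replication
from msdelay.msdata import IllnessDeathDataset, Strategy
from msdelay.simulate import scenario_config, simulate_dataset


STRATEGIES = [Strategy(0.0), Strategy(0.25), Strategy(0.5), Strategy(0.75),
              Strategy(1.0), Strategy.never()]
STRATEGY_LABELS = ["0", "0.25", "0.5", "0.75", "1", "never"]


@pytest.fixture(scope="session")
def scenario1_dataset():
    return simulate_dataset(scenario_config("scenario1"), seed=11)


@pytest.fixture(scope="session")
def scenario1_large():
    """One large scenario-1 draw for parameter-recovery checks."""
    return simulate_dataset(scenario_config("scenario1", n=50000), seed=5)


@pytest.fixture
def tiny_dataset():
    """Five hand-written subjects covering all first-event types."""
    frame = pd.DataFrame({
        "id": ["a", "b", "c", "d", "e"],
        "x": [0.0, 1.0, -1.0, 0.5, -0.5],
        "w": [0.5, 0.25, 0.3, 0.4, 0.0],
        "delta_w": [2, 1, 1, 0, 1],
        "r": [0.5, 1.0, 0.9, 0.4, 0.8],
        "delta_r": [1, 1, 0, 0, 1],
    })
    return IllnessDeathDataset(frame=frame, covariate_names=["x"], horizon=1.5)


# ---------------------------------------------------------------------------
# session-scoped replicated studies reused by the acceptance tests
# (replication counts are the package's working problem sizes; see the
# methods note for the Monte-Carlo error they imply)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def scenario1_study():
    perf, results, diag = run_ademp(
        [scenario_config("scenario1")], methods=("ms_cont", "ms_cat"),
        reps=200, base_seed=1)
    return perf, diag


@pytest.fixture(scope="session")
def scenario3_study():
    perf, results, diag = run_ademp(
        [scenario_config("scenario3")],
        methods=("ms_cont", "ms_cat", "ccr_cont", "ccr_cat"),
        reps=150, base_seed=1)
    return perf, diag


@pytest.fixture(scope="session")
def scenario4_study():
    perf, results, diag = run_ademp(
        [scenario_config("scenario4")],
        methods=("ms_cont", "ms_cat", "ccr_cont", "ccr_cat"),
        reps=150, base_seed=1)
    return perf, diag


@pytest.fixture(scope="session")
def scenario2_weight_diag():
    """Non-finite-weight flags for 200 scenario-2 clone-censor replications."""
    cfg = scenario_config("scenario2")
    flags = []
    max_w = []
    for r in range(200):
        rr = run_replication(cfg, methods=("ccr_cat",), seed=1 + r)[0]
        flags.append(bool(rr.flags.get("any_nonfinite_weights")))
        max_w.append(rr.flags.get("max_finite_weight"))
    return flags, max_w
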