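"""G-computation of marginal recovery curves under treatment-delay strategies.

The estimator plugs fitted transition models into the identification formula:
for a strategy "treat at ``tg`` if not yet recovered" and horizon ``l``,

* ``l <= tg`` (and the never strategy):
  ``p_i(l) = 1 - exp(-Lam13(l) * exp(b13' x_i))``
* ``l > tg``:
  ``p_i(l) = 1 - exp(-Lam13(tg) * exp(b13' x_i)
  - Lam23_0(l - tg) * exp(b23' x_i + gamma * tau(tg)))``

with ``Lam`` the step (Breslow) cumulative baseline hazards, ``tau`` the stored
delay transform, and the marginal estimate the average of ``p_i`` over the
empirical covariate distribution of the sample.  In the delay-stratified
(categorical) variant the 2->3 term uses the stratum's own baseline and no
delay coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxph import EstimationError
from .msdata import IllnessDeathDataset, Strategy
from .transitions import (
    TransitionModel,
    build_transition_frames,
    delay_stratum,
    fit_cox,
)

__all__ = [
    "RecoveryCurve",
    "gcomp_curve",
    "gcomp_categorical_curve",
    "fit_multistate_models",
    "estimate_all",
    "bootstrap_ci",
    "BootstrapBand",
]


@dataclass
class RecoveryCurve:
    """Estimated marginal recovery probability as a step function of horizon."""

    times: np.ndarray
    prob: np.ndarray
    strategy: Strategy
    method: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.prob = np.clip(np.asarray(self.prob, dtype=float), 0.0, 1.0)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("curve times must be nondecreasing")
        if np.any(np.diff(self.prob) < -1e-9):
            raise ValueError("recovery curve must be nondecreasing")

    def at(self, ell) -> np.ndarray:
        """Right-continuous step lookup (0 before the first grid time)."""
        ell = np.asarray(ell, dtype=float)
        idx = np.searchsorted(self.times, ell, side="right") - 1
        return np.where(idx >= 0, self.prob[np.clip(idx, 0, len(self.prob) - 1)], 0.0)


def _conditional_probs(model13, model23, strategy, X, times,
                       categorical: bool, stratum_scheme: str,
                       survival_form: str) -> np.ndarray:
    """(n_subjects, n_times) conditional recovery probabilities."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    times = np.asarray(times, dtype=float)
    tg = strategy.tg
    base13 = model13.baseline()
    lp13 = model13.linear_predictor(X)

    t13 = np.minimum(times, tg) if not strategy.is_never else times
    if survival_form == "product-limit":
        logS13 = _pl_log_survival(base13, lp13, t13)
    else:
        logS13 = -np.outer(np.exp(lp13), base13.at(t13))

    if strategy.is_never:
        return 1.0 - np.exp(logS13)

    if categorical:
        label = delay_stratum(np.array([tg]), stratum_scheme)[0]
        if label not in model23.fit.baselines or model23.fit.baselines[label].times.size == 0:
            raise EstimationError(
                f"no events in delay stratum {label!r} for strategy tg={tg:g} "
                "(empirical positivity failure)"
            )
        base23 = model23.baseline(label)
        lp23 = model23.linear_predictor(X)
    else:
        base23 = model23.baseline()
        tau = float(model23.transform_delay(tg))
        Xd = np.column_stack([X, np.full(X.shape[0], tau)])
        lp23 = model23.linear_predictor(Xd)

    dt = np.clip(times - tg, 0.0, None)
    if survival_form == "product-limit":
        logS23 = _pl_log_survival(base23, lp23, dt)
    else:
        logS23 = -np.outer(np.exp(lp23), base23.at(dt))
    after = times > tg
    log_surv = np.where(after[None, :], logS13 + logS23, logS13)
    return 1.0 - np.exp(log_surv)


def _pl_log_survival(base, lp, times) -> np.ndarray:
    """log of the product-limit survival Prod_{tau<=t} (1 - dLam * exp(lp))."""
    if base.times.size == 0:
        return np.zeros((len(lp), len(times)))
    factors = 1.0 - np.outer(np.exp(lp), base.jumps)  # (n, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(factors > 0, np.log(np.clip(factors, 1e-300, None)), -np.inf)
    cum = np.cumsum(logf, axis=1)
    idx = np.searchsorted(base.times, np.asarray(times, dtype=float), side="right") - 1
    out = np.zeros((len(lp), len(times)))
    pos = idx >= 0
    out[:, pos] = cum[:, idx[pos]]
    return out


def gcomp_curve(
    model13: TransitionModel,
    model23: TransitionModel,
    strategy: Strategy,
    covariate_rows,
    times,
    method: str = "ms_cont",
    survival_form: str = "exp",
    horizon: float | None = None,
) -> RecoveryCurve:
    """Continuous-delay g-computation curve (delay enters the 2->3 model linearly
    through the stored transform)."""
    if horizon is not None and not strategy.is_never and strategy.tg > horizon:
        raise ValueError(f"strategy delay {strategy.tg:g} exceeds the horizon {horizon:g}")
    probs = _conditional_probs(model13, model23, strategy, covariate_rows,
                               times, categorical=False, stratum_scheme="exact",
                               survival_form=survival_form)
    return RecoveryCurve(times=np.asarray(times, float), prob=probs.mean(axis=0),
                         strategy=strategy, method=method)


def gcomp_categorical_curve(
    model13: TransitionModel,
    model23_strat: TransitionModel,
    strategy: Strategy,
    covariate_rows,
    times,
    stratum_scheme: str = "exact",
    method: str = "ms_cat",
    survival_form: str = "exp",
) -> RecoveryCurve:
    """Delay-stratified g-computation curve (stratum baseline, no delay coefficient)."""
    probs = _conditional_probs(model13, model23_strat, strategy, covariate_rows,
                               times, categorical=True, stratum_scheme=stratum_scheme,
                               survival_form=survival_form)
    return RecoveryCurve(times=np.asarray(times, float), prob=probs.mean(axis=0),
                         strategy=strategy, method=method)


def fit_multistate_models(
    dataset: IllnessDeathDataset,
    variant: str = "continuous",
    ties: str = "efron",
    delay_transform: str = "identity",
    stratum_scheme: str = "exact",
) -> tuple[TransitionModel, TransitionModel]:
    """Fit the 1->3 and 2->3 transition models used by the g-computation curves.

    With ``stratum_scheme='intervals'`` (continuous treatment times), subjects
    treated after the horizon are censored at treatment time before fitting the
    2->3 model, so no baseline is built from post-horizon initiators.
    """
    if variant not in ("continuous", "categorical"):
        raise ValueError("variant must be 'continuous' or 'categorical'")
    frames = build_transition_frames(
        dataset,
        delay_transform=delay_transform,
        stratum_scheme=stratum_scheme if variant == "categorical" else None,
        censor_post_horizon_treatment=(variant == "categorical" and stratum_scheme == "intervals"),
    )
    covs = frames.covariate_names
    model13 = fit_cox(frames.frame13, covs, ties=ties, clock="forward")
    if variant == "continuous":
        model23 = fit_cox(frames.frame23, [*covs, "delay_tr"], ties=ties,
                          clock="reset", delay_transform=delay_transform)
    else:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # event-free strata surface later
            model23 = fit_cox(frames.frame23, covs, strata="stratum", ties=ties,
                              clock="reset")
    return model13, model23


def default_grid(model13: TransitionModel, model23: TransitionModel,
                 strategy: Strategy, horizon: float) -> np.ndarray:
    """Evaluation grid: 0, the horizon, the 1->3 jump times and the delay-shifted
    2->3 jump times (restricted to [0, horizon])."""
    pts = [np.array([0.0, horizon]), model13.baseline().times]
    if not strategy.is_never:
        for b in model23.fit.baselines.values():
            pts.append(strategy.tg + b.times)
        pts.append(np.array([strategy.tg]))
    grid = np.unique(np.concatenate(pts))
    return grid[(grid >= 0) & (grid <= horizon)]


def estimate_all(
    dataset: IllnessDeathDataset,
    strategies,
    variant: str = "continuous",
    times=None,
    ties: str = "efron",
    delay_transform: str = "identity",
    stratum_scheme: str = "exact",
    survival_form: str = "exp",
) -> list[RecoveryCurve]:
    """Fit both transition models once and evaluate every strategy."""
    model13, model23 = fit_multistate_models(
        dataset, variant=variant, ties=ties, delay_transform=delay_transform,
        stratum_scheme=stratum_scheme,
    )
    out = []
    for strat in strategies:
        grid = np.asarray(times, float) if times is not None else default_grid(
            model13, model23, strat, dataset.horizon)
        if variant == "continuous":
            out.append(gcomp_curve(model13, model23, strat, dataset.x, grid,
                                   survival_form=survival_form, horizon=dataset.horizon))
        else:
            out.append(gcomp_categorical_curve(model13, model23, strat, dataset.x,
                                               grid, stratum_scheme=stratum_scheme,
                                               survival_form=survival_form))
    return out


@dataclass
class BootstrapBand:
    """Pointwise percentile confidence band for one strategy's recovery curve."""

    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    strategy: Strategy
    level: float
    n_failures: int = 0


def bootstrap_ci(
    dataset: IllnessDeathDataset,
    strategies,
    times,
    B: int = 500,
    seed: int = 0,
    level: float = 0.95,
    variant: str = "continuous",
    ties: str = "efron",
    delay_transform: str = "identity",
    stratum_scheme: str = "exact",
) -> list[BootstrapBand]:
    """Nonparametric pairs bootstrap (subject-level resampling), percentile bands.

    A replicate whose transition fits fail to converge is redrawn; more than 10%
    failed replicates raises an estimation error.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    est = np.empty((B, len(list(strategies)), len(times)))
    strategies = list(strategies)
    failures = 0
    b = 0
    while b < B:
        idx = rng.integers(0, dataset.n, size=dataset.n)
        boot = IllnessDeathDataset(
            frame=dataset.frame.iloc[idx].reset_index(drop=True),
            covariate_names=dataset.covariate_names,
            horizon=dataset.horizon,
        )
        try:
            curves = estimate_all(boot, strategies, variant=variant, times=times,
                                  ties=ties, delay_transform=delay_transform,
                                  stratum_scheme=stratum_scheme)
        except EstimationError:
            failures += 1
            if failures > max(1, 0.1 * B):
                raise EstimationError(
                    f"more than 10% of bootstrap replicates failed ({failures} failures)"
                )
            continue
        for j, c in enumerate(curves):
            est[b, j] = c.prob
        b += 1
    alpha = (1.0 - level) / 2.0
    out = []
    for j, strat in enumerate(strategies):
        lo = np.quantile(est[:, j, :], alpha, axis=0)
        hi = np.quantile(est[:, j, :], 1.0 - alpha, axis=0)
        out.append(BootstrapBand(times=times, lower=lo, upper=hi,
                                 strategy=strat, level=level, n_failures=failures))
    return out
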