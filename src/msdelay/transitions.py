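"""Counting-process construction and transition-hazard models.

Converts an illness-death dataset into risk-set frames for the three
transitions and fits proportional-hazards transition models with step
(Breslow-type) cumulative baseline hazards:

* ``1->2`` (treatment initiation) and ``1->3`` (untreated recovery) form a
  competing-risks decomposition on the study clock: every subject contributes
  the interval (0, w] with the corresponding cause indicator.
* ``2->3`` (post-treatment recovery) uses a clock reset at treatment
  initiation: treated subjects contribute (0, r - w] on the time-since-treatment
  clock, with the delay ``t = w`` carried either as a covariate (continuous
  variant) or as a stratum label (categorical variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxph import CoxFit, EstimationError, StepCumHaz, fit_coxph
from .msdata import IllnessDeathDataset, Strategy

__all__ = [
    "TransitionModel",
    "TransitionFrames",
    "build_transition_frames",
    "delay_stratum",
    "INTERVAL_EDGES",
    "fit_cox",
    "breslow_cumhaz",
    "predict_cumhaz",
    "check_positivity",
]

#: Delay-category boundaries used when treatment times are continuous:
#: [0, 0.125], (0.125, 0.375], ..., (0.875, 1.125], (1.125, horizon].
INTERVAL_EDGES = (0.125, 0.375, 0.625, 0.875, 1.125)

_DELAY_TRANSFORMS = {
    "identity": lambda t: t,
    "log": lambda t: np.log(t),
    "log1p": lambda t: np.log1p(t),
}


@dataclass
class TransitionModel:
    """A fitted proportional-hazards transition model.

    Wraps the coefficient vector and per-stratum step cumulative baseline
    hazards; records the clock convention and, for the 2->3 transition, how the
    treatment delay enters (transformed covariate or stratum).
    """

    fit: CoxFit
    covariate_names: list[str]
    clock: str = "forward"
    delay_transform: str | None = None
    stratified: bool = False

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.fit.beta, index=self.fit.names)

    def baseline(self, stratum=None) -> StepCumHaz:
        return self.fit.baseline(stratum)

    @property
    def strata(self) -> list:
        return list(self.fit.baselines.keys())

    def transform_delay(self, t):
        if self.delay_transform is None:
            raise ValueError("model has no delay covariate")
        return _DELAY_TRANSFORMS[self.delay_transform](np.asarray(t, dtype=float))

    def linear_predictor(self, X) -> np.ndarray:
        return self.fit.linear_predictor(X)

    # -- plain-text serialization (coefficients + baseline step times/values) --
    def to_dict(self) -> dict:
        return {
            "coefficients": {n: float(b) for n, b in zip(self.fit.names, self.fit.beta)},
            "se": [float(s) for s in self.fit.se],
            "baselines": [
                {"stratum": None if k is None else (float(k) if np.isscalar(k) else str(k)),
                 "times": [float(t) for t in b.times],
                 "jumps": [float(j) for j in b.jumps]}
                for k, b in self.fit.baselines.items()
            ],
            "clock": self.clock,
            "delay_transform": self.delay_transform,
            "stratified": self.stratified,
            "ties": self.fit.ties,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        names = list(d["coefficients"])
        beta = np.array([d["coefficients"][n] for n in names], dtype=float)
        se = np.asarray(d.get("se", np.zeros_like(beta)), dtype=float)
        baselines = {
            b["stratum"]: StepCumHaz(times=np.asarray(b["times"], float),
                                     jumps=np.asarray(b["jumps"], float))
            for b in d["baselines"]
        }
        fit = CoxFit(beta=beta, cov=np.diag(se ** 2), names=names, loglik=float("nan"),
                     n_events=0, baselines=baselines, ties=d.get("ties", "efron"),
                     n_iter=0)
        return cls(fit=fit, covariate_names=names, clock=d.get("clock", "forward"),
                   delay_transform=d.get("delay_transform"),
                   stratified=bool(d.get("stratified", False)))


@dataclass
class TransitionFrames:
    """Risk-set frames for the three transitions (column layout shared:
    ``id, entry, exit, event, <covariates...>`` plus ``delay``/``delay_tr``/
    ``stratum`` on the 2->3 frame)."""

    frame12: pd.DataFrame
    frame13: pd.DataFrame
    frame23: pd.DataFrame
    covariate_names: list[str]


def delay_stratum(t, scheme: str = "exact", horizon: float = 1.5):
    """Map treatment delays to stratum labels.

    ``scheme='exact'`` uses the delay value itself (discrete treatment grids);
    ``scheme='intervals'`` uses the printed categorization for continuous
    treatment times, labelling each bin by its target delay
    (0, 0.25, 0.5, 0.75, 1, then the tail bin above 1.125).
    """
    t = np.asarray(t, dtype=float)
    if scheme == "exact":
        return t.copy()
    if scheme != "intervals":
        raise ValueError("scheme must be 'exact' or 'intervals'")
    edges = np.asarray(INTERVAL_EDGES)
    # bin 0 is [0, 0.125]; later bins are (edge_{k-1}, edge_k]; tail (1.125, horizon]
    idx = np.searchsorted(edges, t, side="left")
    targets = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.25])
    return targets[np.clip(idx, 0, len(targets) - 1)]


def build_transition_frames(
    dataset: IllnessDeathDataset,
    delay_transform: str = "identity",
    stratum_scheme: str | None = None,
    censor_post_horizon_treatment: bool = False,
) -> TransitionFrames:
    """Decompose a dataset into the three transition risk-set frames.

    ``censor_post_horizon_treatment`` drops treated subjects with ``w`` beyond
    the dataset horizon from the 2->3 frame (they are treated as censored at
    treatment time), as done by the delay-stratified variant with continuous
    treatment times.
    """
    if delay_transform not in _DELAY_TRANSFORMS:
        raise ValueError(f"unknown delay transform {delay_transform!r}")
    f = dataset.frame
    covs = dataset.covariate_names
    base = {
        "id": f["id"].to_numpy(),
        "entry": np.zeros(dataset.n),
        "exit": dataset.w,
    }
    x = dataset.x
    frame12 = pd.DataFrame({**base, "event": (dataset.delta_w == 1).astype(int)})
    frame13 = pd.DataFrame({**base, "event": (dataset.delta_w == 2).astype(int)})
    for j, c in enumerate(covs):
        frame12[c] = x[:, j]
        frame13[c] = x[:, j]

    treated = dataset.delta_w == 1
    if censor_post_horizon_treatment:
        treated = treated & (dataset.w <= dataset.horizon)
    t = dataset.w[treated]
    frame23 = pd.DataFrame({
        "id": f["id"].to_numpy()[treated],
        "entry": np.zeros(int(treated.sum())),
        "exit": dataset.r[treated] - dataset.w[treated],
        "event": dataset.delta_r[treated].astype(int),
    })
    for j, c in enumerate(covs):
        frame23[c] = x[treated, j]
    frame23["delay"] = t
    frame23["delay_tr"] = _DELAY_TRANSFORMS[delay_transform](t)
    if stratum_scheme is not None:
        frame23["stratum"] = delay_stratum(t, stratum_scheme, dataset.horizon)
    return TransitionFrames(frame12=frame12, frame13=frame13, frame23=frame23,
                            covariate_names=list(covs))


def fit_cox(
    frame: pd.DataFrame,
    covariate_names,
    strata: str | None = None,
    ties: str = "efron",
    clock: str = "forward",
    delay_transform: str | None = None,
    weights: str | None = None,
) -> TransitionModel:
    """Fit a proportional-hazards model to one transition frame.

    ``strata``/``weights`` name columns of the frame.  Raises
    :class:`~msdelay.coxph.EstimationError` when the fit cannot converge or the
    design is degenerate; strata without events get a baseline identically 0
    and are flagged on the returned fit.
    """
    covariate_names = list(covariate_names)
    X = frame[covariate_names].to_numpy(dtype=float) if covariate_names else None
    fit = fit_coxph(
        exit=frame["exit"].to_numpy(dtype=float),
        event=frame["event"].to_numpy(),
        X=X,
        entry=frame["entry"].to_numpy(dtype=float) if "entry" in frame else None,
        weights=frame[weights].to_numpy(dtype=float) if weights else None,
        strata=frame[strata].to_numpy() if strata else None,
        names=covariate_names,
        ties=ties,
    )
    return TransitionModel(
        fit=fit,
        covariate_names=covariate_names,
        clock=clock,
        delay_transform=delay_transform,
        stratified=strata is not None,
    )


def breslow_cumhaz(frame: pd.DataFrame, coefficients, covariate_names=(),
                   strata: str | None = None, ties: str = "breslow"):
    """Step cumulative baseline hazard(s) at fixed coefficients.

    At each distinct event time the jump is (weighted events) / (sum of
    ``exp(linear predictor)`` over the risk set); reduces to Nelson-Aalen when
    all linear predictors are zero.  Returns a dict keyed by stratum label
    (key ``None`` when unstratified).
    """
    from .coxph import _stratum_quantities

    covariate_names = list(covariate_names)
    beta = np.asarray(coefficients, dtype=float)
    exit = frame["exit"].to_numpy(dtype=float)
    n = len(exit)
    event = frame["event"].to_numpy().astype(int)
    entry = frame["entry"].to_numpy(dtype=float) if "entry" in frame else np.zeros(n)
    X = frame[covariate_names].to_numpy(dtype=float) if covariate_names else np.empty((n, 0))
    w = np.ones(n)
    if strata is None:
        groups = {None: np.arange(n)}
    else:
        svals = frame[strata].to_numpy()
        groups = {k: np.flatnonzero(svals == k) for k in np.unique(svals)}
    out = {}
    for key, idx in groups.items():
        *_, (tau, jumps) = _stratum_quantities(exit[idx], entry[idx], event[idx],
                                               X[idx], w[idx], beta, ties)
        out[key] = StepCumHaz(times=tau, jumps=jumps)
    return out


def predict_cumhaz(model: TransitionModel, x, t0: float, t1: float,
                   stratum=None) -> float:
    """Covariate-specific cumulative-hazard increment over (t0, t1].

    Beyond the last observed event time the baseline extrapolates flat (the
    Breslow-estimator convention) and a warning is issued.
    """
    if t0 > t1:
        raise ValueError("t0 must not exceed t1")
    base = model.baseline(stratum)
    if t1 > base.last_time and base.times.size:
        warnings.warn(
            f"extrapolating baseline cumulative hazard flat beyond last event "
            f"time {base.last_time:g}", RuntimeWarning, stacklevel=2,
        )
    lp = float(model.linear_predictor(np.atleast_2d(x))[0])
    return float(base.increment(t0, t1)) * np.exp(lp)


def check_positivity(
    dataset: IllnessDeathDataset,
    strategies,
    covariate_bins: int = 4,
) -> pd.DataFrame:
    """Empirical positivity diagnostic for a set of delay strategies.

    For each finite-delay strategy, counts subjects still at risk at the target
    delay and subjects initiating treatment inside the strategy window, overall
    and within quantile bins of the first covariate; flags empty cells.  The
    never strategy reports subjects at risk at the horizon.
    """
    w, dw = dataset.w, dataset.delta_w
    x0 = dataset.x[:, 0] if dataset.x.shape[1] else np.zeros(dataset.n)
    qs = np.quantile(x0, np.linspace(0, 1, covariate_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    bin_idx = np.clip(np.searchsorted(qs, x0, side="right") - 1, 0, covariate_bins - 1)

    rows = []
    for strat in strategies:
        if strat.is_never:
            at_risk = w >= dataset.horizon
            rows.append({
                "strategy": strat.label(), "bin": "all",
                "at_risk": int(at_risk.sum()), "initiators": np.nan, "flag": "",
            })
            continue
        a, b = strat.window
        at_risk = w >= a
        init = (dw == 1) & (w >= a) & ((w <= b) if a == b else (w < b))
        rows.append({
            "strategy": strat.label(), "bin": "all",
            "at_risk": int(at_risk.sum()), "initiators": int(init.sum()),
            "flag": "" if init.any() else "no initiators",
        })
        for k in range(covariate_bins):
            m = bin_idx == k
            rows.append({
                "strategy": strat.label(), "bin": f"q{k + 1}",
                "at_risk": int((at_risk & m).sum()),
                "initiators": int((init & m).sum()),
                "flag": "" if (init & m).any() else "no initiators",
            })
    return pd.DataFrame(rows)
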