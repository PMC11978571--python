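"""Clone-censor-reweight estimation of recovery under delay strategies.

The comparator to g-computation: each subject is cloned into every treatment
strategy compatible with their data at time zero, clones are artificially
censored when they deviate from their assigned strategy, and the selection
induced by that censoring is corrected with inverse-probability-of-adherence
weights derived from a time-to-treatment Cox model.  Outcomes are then
estimated per strategy arm by a weighted Kaplan-Meier (categorical variant) or
by a single weighted Cox model on the stacked clones with the baseline hazard
stratified by treatment status and the assigned delay entering linearly in the
treated stratum (continuous variant).

Weight convention: a clone's weight at time ``s`` is the inverse of its
estimated probability of still being adherent at ``s`` given its covariates —
the probability of remaining untreated through every decision time before the
strategy window, times (once the clone initiates) the probability of initiating
inside the window.  Weights are time-varying until the end of the strategy
window (the clone's initiation, for point strategies) and frozen thereafter.
When non-finite weights occur, all weights above the configured percentile of
the finite weights are trimmed to that percentile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxph import CoxFit, EstimationError, StepCumHaz, fit_coxph
from .gcomp import RecoveryCurve
from .msdata import IllnessDeathDataset, Strategy

__all__ = [
    "TreatmentModel",
    "CloneArm",
    "WeightedClones",
    "fit_treatment_model",
    "make_clones",
    "censor_clones",
    "compute_weights",
    "weighted_km",
    "ccr_cox_curve",
    "run_ccr",
]


# ---------------------------------------------------------------------------
# treatment (weight) model
# ---------------------------------------------------------------------------

@dataclass
class TreatmentModel:
    """Time-to-treatment model supplying adherence probabilities for weights.

    ``variant='cox'`` (default) is a single proportional-hazards model for the
    time of treatment initiation on the study clock, fitted on all subjects with
    recovery and censoring treated as censoring; a point mass of initiation at
    time 0 appears as a Breslow jump at 0, so one common coefficient governs
    every decision time.  ``variant='logistic'`` instead models the time-0 mass
    with a separate logistic regression and fits the Cox model to the
    strictly-positive initiation times.
    """

    cox: CoxFit
    covariate_names: list[str]
    variant: str = "cox"
    mass0_coef: np.ndarray | None = None   # logistic intercept+slopes, or None

    @property
    def baseline(self) -> StepCumHaz:
        return self.cox.baseline()

    def risk_mult(self, X) -> np.ndarray:
        """exp(linear predictor) of the Cox component."""
        return np.exp(self.cox.linear_predictor(X))

    def log1m_mass0(self, X) -> np.ndarray:
        """log P(not initiating at time 0 | x) for the logistic component (else 0)."""
        if self.variant != "logistic":
            return np.zeros(np.atleast_2d(X).shape[0])
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = self.mass0_coef[0] + X @ self.mass0_coef[1:]
        return -np.logaddexp(0.0, eta)  # log(1 - sigmoid(eta))

    def mass0_prob(self, X) -> np.ndarray:
        """P(initiating at time 0 | x)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.variant == "logistic":
            eta = self.mass0_coef[0] + X @ self.mass0_coef[1:]
            return 1.0 / (1.0 + np.exp(-eta))
        j0 = self.baseline.jump_at(0.0)
        return 1.0 - np.exp(-j0 * self.risk_mult(X))


def fit_treatment_model(
    dataset: IllnessDeathDataset,
    variant: str = "cox",
    ties: str = "efron",
) -> TreatmentModel:
    """Fit the time-to-treatment model used for inverse-probability weights."""
    if (dataset.delta_w == 1).sum() == 0:
        raise EstimationError("no treatment initiations in the data")
    X = dataset.x
    if variant == "cox":
        fit = fit_coxph(exit=dataset.w, event=(dataset.delta_w == 1).astype(int),
                        X=X, names=dataset.covariate_names, ties=ties)
        return TreatmentModel(cox=fit, covariate_names=dataset.covariate_names)
    if variant != "logistic":
        raise ValueError("variant must be 'cox' or 'logistic'")
    import statsmodels.api as sm

    treated0 = ((dataset.delta_w == 1) & (dataset.w == 0)).astype(float)
    design = sm.add_constant(X)
    res = sm.GLM(treated0, design, family=sm.families.Binomial()).fit()
    post = dataset.w > 0
    fit = fit_coxph(exit=dataset.w[post], event=((dataset.delta_w == 1) & post)[post].astype(int),
                    X=X[post], names=dataset.covariate_names, ties=ties)
    return TreatmentModel(cox=fit, covariate_names=dataset.covariate_names,
                          variant="logistic", mass0_coef=np.asarray(res.params, dtype=float))


# ---------------------------------------------------------------------------
# cloning and artificial censoring
# ---------------------------------------------------------------------------

@dataclass
class CloneArm:
    """All clones assigned to one strategy.

    ``exit``/``event`` describe follow-up *after* artificial censoring;
    ``treated`` marks clones that initiated inside the strategy window, with
    ``t_init`` their initiation time on the study clock.
    """

    strategy: Strategy
    subj_idx: np.ndarray
    X: np.ndarray
    exit: np.ndarray
    event: np.ndarray
    treated: np.ndarray
    t_init: np.ndarray
    artificial: np.ndarray          # True where censoring is strategy-induced
    censored_applied: bool = False

    @property
    def n(self) -> int:
        return len(self.subj_idx)


def make_clones(dataset: IllnessDeathDataset, strategies,
                grace_halfwidth: float = 0.0) -> list[CloneArm]:
    """Create one clone per subject per strategy compatible at time zero.

    Subjects treated at exactly 0 are compatible only with strategies whose
    window contains 0; subjects untreated at 0 are compatible with every other
    strategy (including never).  Follow-up is copied unmodified; apply
    :func:`censor_clones` to impose the deviation censoring.
    """
    strategies = [s if s.grace_halfwidth or s.is_never else
                  Strategy(s.tg, grace_halfwidth) for s in strategies]
    w, dw = dataset.w, dataset.delta_w
    treated_at_0 = (dw == 1) & (w == 0)
    arms = []
    for strat in strategies:
        a, b = strat.window
        if strat.is_never:
            compat = ~treated_at_0
        elif a == 0 and b == 0:          # point strategy at baseline
            compat = treated_at_0
        elif a == 0:                     # grace window containing 0
            compat = np.ones(dataset.n, dtype=bool)
        else:
            compat = ~treated_at_0
        idx = np.flatnonzero(compat)
        arms.append(CloneArm(
            strategy=strat,
            subj_idx=idx,
            X=dataset.x[idx],
            exit=dataset.r[idx].copy(),
            event=dataset.delta_r[idx].astype(int),
            treated=np.zeros(len(idx), dtype=bool),
            t_init=np.full(len(idx), np.nan),
            artificial=np.zeros(len(idx), dtype=bool),
        ))
    return arms


def censor_clones(arm: CloneArm, dataset: IllnessDeathDataset) -> CloneArm:
    """Apply artificial censoring at deviation from the assigned strategy.

    A clone is censored at the first of: treatment initiation before the
    strategy window; failure to initiate by the window's end while still at
    risk; (never strategy) treatment initiation at any time.  Window convention
    is ``[a, b)`` — initiating exactly at the window's end is a deviation.
    """
    idx = arm.subj_idx
    w, dw = dataset.w[idx], dataset.delta_w[idx]
    r, dr = dataset.r[idx], dataset.delta_r[idx]
    a, b = arm.strategy.window
    exit = np.empty(arm.n)
    event = np.zeros(arm.n, dtype=int)
    treated = np.zeros(arm.n, dtype=bool)
    t_init = np.full(arm.n, np.nan)
    artificial = np.zeros(arm.n, dtype=bool)

    is_treat = dw == 1
    if arm.strategy.is_never:
        exit[:] = np.where(is_treat, w, r)
        event[:] = np.where(is_treat, 0, dr)
        artificial[:] = is_treat
    else:
        deadline = b if b > a else a     # point strategies: deadline = tg
        in_win = is_treat & (w >= a) & ((w < b) if b > a else (w == a))
        early = is_treat & (w < a)
        late = is_treat & ~in_win & ~early
        # treated inside window: adherent, keep post-treatment follow-up
        exit[in_win] = r[in_win]
        event[in_win] = dr[in_win]
        treated[in_win] = True
        t_init[in_win] = w[in_win]
        # treated before window: deviation at initiation
        exit[early] = w[early]
        artificial[early] = True
        # treated after the window: untreated and at risk at the deadline
        exit[late] = deadline
        artificial[late] = True
        # recovery / censoring without treatment
        other = ~is_treat
        reached = other & (w > deadline)
        exit[other] = np.where(w[other] > deadline, deadline, r[other])
        event[other] = np.where(w[other] > deadline, 0, (dw[other] == 2) * dr[other])
        artificial[reached] = True
    return CloneArm(strategy=arm.strategy, subj_idx=idx, X=arm.X, exit=exit,
                    event=event, treated=treated, t_init=t_init,
                    artificial=artificial, censored_applied=True)


# ---------------------------------------------------------------------------
# inverse-probability-of-adherence weights
# ---------------------------------------------------------------------------

@dataclass
class WeightedClones:
    """Censored clone arms with their adherence-weight machinery.

    ``hazard_form`` controls how the fitted cumulative treatment hazard is
    turned into probabilities: ``'exp'`` uses proper survival probabilities
    ``exp(-Lam * exp(bx))`` and initiation probabilities
    ``1 - exp(-dLam * exp(bx))``; ``'discrete'`` uses the product-limit form
    with discrete hazards ``dLam * exp(bx)``, which can produce non-finite
    weights when a discrete hazard reaches 1.
    """

    arms: list[CloneArm]
    tm: TreatmentModel
    horizon: float
    hazard_form: str = "exp"
    trim_pct: float = 97.5
    cap: float = math.inf
    diagnostics: dict = field(default_factory=dict)
    _mults: list[np.ndarray] = field(default_factory=list)
    _log_pre_a: list[np.ndarray] = field(default_factory=list)
    _frozen_raw: list[np.ndarray] = field(default_factory=list)
    _cumlog: list[np.ndarray] = field(default_factory=list)

    def _discrete_cumlog(self, k: int) -> np.ndarray:
        """(n_clones, n_jumps+1) cumulative log product-limit factors, cached."""
        if len(self._cumlog) <= k or self._cumlog[k] is None:
            while len(self._cumlog) <= k:
                self._cumlog.append(None)
            e = self._mults[k]
            logf = _log1m_discrete(np.outer(e, self.tm.baseline.jumps))
            self._cumlog[k] = np.concatenate(
                [np.zeros((len(e), 1)), np.cumsum(logf, axis=1)], axis=1)
        return self._cumlog[k]

    def _log_untreated(self, k: int, s_vals: np.ndarray, left: bool = False) -> np.ndarray:
        """(n_clones, n_s) log P(untreated through s | x) for arm k.

        ``left=True`` means "through every decision time strictly before s".
        """
        e = self._mults[k]
        base = self.tm.baseline
        extra = self.tm.log1m_mass0(self.arms[k].X)
        s_vals = np.asarray(s_vals, dtype=float)
        include_mass = (s_vals > 0) if left else (s_vals >= 0)
        if self.hazard_form == "exp":
            lam = base.at_left(s_vals) if left else base.at(s_vals)
            out = -np.outer(e, lam)
        else:
            side = "left" if left else "right"
            idx = np.searchsorted(base.times, s_vals, side=side)
            out = self._discrete_cumlog(k)[:, idx]
        return out + np.where(include_mass, 1.0, 0.0)[None, :] * extra[:, None]

    def _log_window(self, k: int) -> np.ndarray:
        """log P(initiating inside the strategy window | untreated at its start)."""
        arm = self.arms[k]
        a, b = arm.strategy.window
        e = self._mults[k]
        base = self.tm.baseline
        if self.tm.variant == "logistic" and a == 0:
            p0 = self.tm.mass0_prob(arm.X)
            if b == 0:
                return np.log(np.clip(p0, 0.0, None))
            # initiate at 0 or in (0, b)
            surv_post = np.exp(self._posthaz_logsurv_left(e, b))
            p = 1.0 - (1.0 - p0) * surv_post
            return np.log(np.clip(p, 0.0, None))
        if b == a:  # point strategy: discrete hazard at tg
            j = base.jump_at(a)
            h = (1.0 - np.exp(-j * e)) if self.hazard_form == "exp" else j * e
            with np.errstate(divide="ignore"):
                return np.log(np.clip(h, 0.0, None))
        if self.hazard_form == "exp":
            inc = float(base.at_left(b) - base.at_left(a))
            p = 1.0 - np.exp(-inc * e)
        else:
            m = (base.times >= a) & (base.times < b)
            logf = _log1m_discrete(np.outer(e, base.jumps[m]))
            p = 1.0 - np.exp(logf.sum(axis=1))
        with np.errstate(divide="ignore"):
            return np.log(np.clip(p, 0.0, None))

    def _posthaz_logsurv_left(self, e: np.ndarray, b: float) -> np.ndarray:
        base = self.tm.baseline
        if self.hazard_form == "exp":
            return -e * float(base.at_left(b))
        m = base.times < b
        return _log1m_discrete(np.outer(e, base.jumps[m])).sum(axis=1)

    # -- public evaluation ----------------------------------------------------
    def weights_at(self, k: int, taus, _uncapped: bool = False) -> np.ndarray:
        """(n_clones, n_taus) adherence weights for arm k at study times taus."""
        arm = self.arms[k]
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        a, _ = arm.strategy.window
        if arm.strategy.is_never:
            s_eff = np.minimum(taus, self.horizon)
            logp = self._log_untreated(k, s_eff)
        else:
            logp = self._log_untreated(k, np.minimum(taus, a), left=True)
            before_a = taus < a
            if before_a.any():
                logp_open = self._log_untreated(k, taus)
                logp[:, before_a] = logp_open[:, before_a]
        with np.errstate(over="ignore"):
            w = np.exp(-logp)
        if arm.treated.any():
            frozen = self._frozen_raw[k]
            mask = arm.treated[:, None] & (taus[None, :] >= arm.t_init[:, None])
            w = np.where(mask, frozen[:, None], w)
        return w if _uncapped else np.minimum(w, self.cap)

    def _log_untreated_elem(self, k: int, s: np.ndarray, left: np.ndarray) -> np.ndarray:
        """Per-clone log P(untreated through own time s_i); ``left`` flags strict."""
        e = self._mults[k]
        base = self.tm.baseline
        extra = self.tm.log1m_mass0(self.arms[k].X)
        include_mass = np.where(left, s > 0, s >= 0)
        if self.hazard_form == "exp":
            lam = np.where(left, base.at_left(s), base.at(s))
            out = -e * lam
        else:
            idx = np.where(left,
                           np.searchsorted(base.times, s, side="left"),
                           np.searchsorted(base.times, s, side="right"))
            out = self._discrete_cumlog(k)[np.arange(len(e)), idx]
        return out + np.where(include_mass, extra, 0.0)

    def end_weights(self, k: int, raw: bool = False) -> np.ndarray:
        """Each clone's weight at the end of its own follow-up.

        ``raw=True`` returns untrimmed values (used for the trimming percentile
        and the non-finite-weight diagnostics).
        """
        arm = self.arms[k]
        if arm.strategy.is_never:
            s = np.minimum(arm.exit, self.horizon)
            logp = self._log_untreated_elem(k, s, np.zeros(arm.n, dtype=bool))
        else:
            a, _ = arm.strategy.window
            s = np.minimum(arm.exit, a)
            logp = self._log_untreated_elem(k, s, arm.exit >= a)
        with np.errstate(over="ignore"):
            out = np.exp(-logp)
        if arm.treated.any():
            out[arm.treated] = self._frozen_raw[k][arm.treated]
        return out if raw else np.minimum(out, self.cap)


def _weighted_counts(ws: "WeightedClones", k: int, ev_times: np.ndarray,
                     end: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted risk-set sizes and event counts at ``ev_times`` for arm k.

    Accumulates in event-time chunks to keep the (clones x times) weight
    matrices small at large n.
    """
    K = len(ev_times)
    n_w = np.zeros(K)
    d_w = np.zeros(K)
    step = max(1, int(4_000_000 // max(ws.arms[k].n, 1)))
    for lo in range(0, K, step):
        sl = slice(lo, min(lo + step, K))
        W = ws.weights_at(k, ev_times[sl])
        at_risk = end[:, None] >= ev_times[None, sl]
        n_w[sl] = np.sum(W * at_risk, axis=0)
        d_w[sl] = np.sum(W * ((event == 1)[:, None] &
                              (end[:, None] == ev_times[None, sl])), axis=0)
    return n_w, d_w


def _log1m_discrete(h: np.ndarray) -> np.ndarray:
    """log(1 - h) with -inf for h >= 1 (improper discrete hazards)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(h < 1.0, np.log1p(-np.clip(h, None, 1.0 - 1e-300)), -np.inf)


def compute_weights(
    arms: list[CloneArm],
    tm: TreatmentModel,
    horizon: float = 1.5,
    trim_pct: float = 97.5,
    hazard_form: str = "exp",
    always_trim: bool = False,
) -> WeightedClones:
    """Attach inverse-probability-of-adherence weights to censored clone arms.

    Trimming engages when any weight is non-finite (or ``always_trim``): all
    weights above the ``trim_pct`` percentile of the finite weights are set to
    that percentile.  Diagnostics report the count of non-finite weights and
    the largest finite weight.
    """
    if hazard_form not in ("exp", "discrete"):
        raise ValueError("hazard_form must be 'exp' or 'discrete'")
    for arm in arms:
        if not arm.censored_applied:
            raise ValueError("clones must be artificially censored before weighting")
    ws = WeightedClones(arms=arms, tm=tm, horizon=horizon,
                        hazard_form=hazard_form, trim_pct=trim_pct)
    for k, arm in enumerate(arms):
        e = tm.risk_mult(arm.X)
        ws._mults.append(e)
        lw = ws._log_window(k)
        a, _ = arm.strategy.window
        pre = (ws._log_untreated(k, np.array([a]), left=True)[:, 0]
               if not arm.strategy.is_never else np.zeros(arm.n))
        ws._log_pre_a.append(pre)
        with np.errstate(over="ignore"):
            frozen = np.exp(-(pre + lw))
        frozen[~arm.treated] = np.nan
        ws._frozen_raw.append(frozen)

    all_end = np.concatenate([ws.end_weights(k, raw=True) for k in range(len(arms))])
    finite = np.isfinite(all_end)
    n_nonfinite = int((~finite).sum())
    max_finite = float(all_end[finite].max()) if finite.any() else math.nan
    if (n_nonfinite > 0 or always_trim) and finite.any():
        ws.cap = float(np.percentile(all_end[finite], trim_pct))
    ws.diagnostics = {
        "n_nonfinite_weights": n_nonfinite,
        "any_nonfinite": n_nonfinite > 0,
        "max_finite_weight": max_finite,
        "trimmed": math.isfinite(ws.cap),
        "cap": ws.cap,
    }
    return ws


# ---------------------------------------------------------------------------
# outcome estimation
# ---------------------------------------------------------------------------

def weighted_km(ws: WeightedClones, k: int, times) -> RecoveryCurve:
    """Weighted Kaplan-Meier recovery curve for one strategy arm.

    Product-limit estimator with time-varying-weighted risk sets and event
    counts; returns 1 - S as the recovery curve.  If the weighted risk set
    empties before the horizon the curve stays flat and the arm is flagged in
    the weight diagnostics.
    """
    arm = ws.arms[k]
    times = np.asarray(times, dtype=float)
    ev_times = np.unique(arm.exit[arm.event == 1])
    ev_times = ev_times[ev_times <= times.max()]       # later events never enter the curve
    if ev_times.size == 0:
        return RecoveryCurve(times=times, prob=np.zeros_like(times),
                             strategy=arm.strategy, method="ccr_cat")
    n_w, d_w = _weighted_counts(ws, k, ev_times, arm.exit, arm.event)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_w > 0, d_w / n_w, 0.0)
    if np.any(n_w <= 0):
        ws.diagnostics.setdefault("empty_risk_set_arms", []).append(arm.strategy.label())
    surv = np.cumprod(1.0 - np.clip(frac, 0.0, 1.0))
    idx = np.searchsorted(ev_times, times, side="right") - 1
    prob = np.where(idx >= 0, 1.0 - surv[np.clip(idx, 0, len(surv) - 1)], 0.0)
    return RecoveryCurve(times=times, prob=prob, strategy=arm.strategy, method="ccr_cat")


def _untreated_na(ws: WeightedClones, t_max: float) -> StepCumHaz:
    """Pooled weighted Nelson-Aalen hazard of untreated recovery on the stacked clones."""
    per_arm = []
    for arm in ws.arms:
        u_end = np.where(arm.treated, arm.t_init, arm.exit)
        u_event = np.where(arm.treated, 0, arm.event)
        per_arm.append((u_end, u_event))
    all_ev = np.concatenate([e[ev == 1] for e, ev in per_arm])
    ev_times = np.unique(all_ev[all_ev <= t_max])
    if ev_times.size == 0:
        return StepCumHaz(times=np.empty(0), jumps=np.empty(0))
    n_w = np.zeros(len(ev_times))
    d_w = np.zeros(len(ev_times))
    for k, (u_end, u_event) in enumerate(per_arm):
        nk, dk = _weighted_counts(ws, k, ev_times, u_end, u_event)
        n_w += nk
        d_w += dk
    with np.errstate(divide="ignore", invalid="ignore"):
        jumps = np.where(n_w > 0, d_w / n_w, 0.0)
    return StepCumHaz(times=ev_times, jumps=jumps)


def ccr_cox_curve(ws: WeightedClones, times) -> list[RecoveryCurve]:
    """Weighted-Cox (continuous) clone-censor-reweight recovery curves.

    One proportional-hazards outcome model on the stacked clones: the baseline
    is stratified by treatment status; in the treated stratum the clock resets
    at initiation and the assigned strategy delay (the window's target value)
    enters linearly.  Curves follow the g-formula structure
    ``1 - exp(-Lam_untreated(min(l, tg)) - 1{l > tg} e^{g*tg} Lam_treated(l - tg))``.
    """
    times = np.asarray(times, dtype=float)
    lam1 = _untreated_na(ws, float(times.max()))

    rows_dur, rows_event, rows_delay, rows_w = [], [], [], []
    for k, arm in enumerate(ws.arms):
        if arm.strategy.is_never or not arm.treated.any():
            continue
        tr = arm.treated
        rows_dur.append(arm.exit[tr] - arm.t_init[tr])
        rows_event.append(arm.event[tr])
        rows_delay.append(np.full(int(tr.sum()), arm.strategy.tg))
        rows_w.append(np.minimum(ws._frozen_raw[k][tr], ws.cap))
    gamma = 0.0
    lam2 = StepCumHaz(times=np.empty(0), jumps=np.empty(0))
    if rows_dur:
        dur = np.concatenate(rows_dur)
        evs = np.concatenate(rows_event)
        dly = np.concatenate(rows_delay)
        wts = np.concatenate(rows_w)
        ok = np.isfinite(wts)
        if len(np.unique(dly[ok])) > 1:
            fit = fit_coxph(exit=dur[ok], event=evs[ok], X=dly[ok, None],
                            weights=wts[ok], names=["delay"])
            gamma = float(fit.beta[0])
            lam2 = fit.baseline()
        else:
            fit = fit_coxph(exit=dur[ok], event=evs[ok], weights=wts[ok])
            lam2 = fit.baseline()

    out = []
    for arm in ws.arms:
        strat = arm.strategy
        if strat.is_never:
            chaz = lam1.at(times)
        else:
            tg = strat.tg
            chaz = lam1.at(np.minimum(times, tg)) + np.where(
                times > tg, np.exp(gamma * tg) * lam2.at(np.clip(times - tg, 0, None)), 0.0)
        out.append(RecoveryCurve(times=times, prob=1.0 - np.exp(-chaz),
                                 strategy=strat, method="ccr_cont"))
    return out


def run_ccr(
    dataset: IllnessDeathDataset,
    strategies,
    variant: str = "km",
    times=None,
    grace_halfwidth: float = 0.0,
    trim_pct: float = 97.5,
    hazard_form: str = "exp",
    tm_variant: str = "cox",
    always_trim: bool = False,
) -> tuple[list[RecoveryCurve], dict]:
    """Full clone-censor-reweight pipeline; returns curves and weight diagnostics."""
    if variant not in ("km", "cox"):
        raise ValueError("variant must be 'km' or 'cox'")
    times = np.asarray(times, float) if times is not None else np.linspace(
        0.0, dataset.horizon, 151)
    tm = fit_treatment_model(dataset, variant=tm_variant)
    arms = [censor_clones(arm, dataset)
            for arm in make_clones(dataset, strategies, grace_halfwidth)]
    ws = compute_weights(arms, tm, horizon=dataset.horizon, trim_pct=trim_pct,
                         hazard_form=hazard_form, always_trim=always_trim)
    if variant == "km":
        curves = [weighted_km(ws, k, times) for k in range(len(arms))]
    else:
        curves = ccr_cox_curve(ws, times)
    return curves, ws.diagnostics
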