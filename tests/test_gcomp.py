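import math

import numpy as np
import pytest

from msdelay.coxph import CoxFit, EstimationError, StepCumHaz
from msdelay.gcomp import (
    bootstrap_ci,
    estimate_all,
    fit_multistate_models,
    gcomp_categorical_curve,
    gcomp_curve,
)
from msdelay.msdata import Strategy
from msdelay.simulate import (
    conditional_recovery_prob,
    scenario_config,
    simulate_dataset,
    true_recovery_prob,
)
from msdelay.transitions import TransitionModel, build_transition_frames, fit_cox

from conftest import STRATEGIES


def _exact_model(beta, names, times, cumvals, stratum=None):
    """TransitionModel with hand-set coefficients and an exact step baseline."""
    jumps = np.diff(np.concatenate([[0.0], cumvals]))
    base = StepCumHaz(times=np.asarray(times, float), jumps=jumps)
    fit = CoxFit(beta=np.asarray(beta, float), cov=np.eye(len(beta)) if beta else np.zeros((0, 0)),
                 names=list(names), loglik=0.0, n_events=1,
                 baselines={stratum: base}, ties="efron", n_iter=0)
    return fit


def true_scenario1_models():
    """Transition models carrying the exact scenario-1 parameters.

    Baselines are step functions that agree with the true cumulative hazards
    0.4*s and 0.8*s exactly on the evaluation times used below.
    """
    grid = np.round(np.linspace(0.05, 2.0, 40), 10)
    fit13 = _exact_model([-0.25], ["x"], grid, 0.4 * grid)
    m13 = TransitionModel(fit=fit13, covariate_names=["x"], clock="forward")
    fit23 = _exact_model([-0.15, -0.25], ["x", "delay_tr"], grid, 0.8 * grid)
    m23 = TransitionModel(fit=fit23, covariate_names=["x"], clock="reset",
                          delay_transform="identity")
    return m13, m23


class TestClosedForm:
    def test_single_subject_matches_hand_formula(self):
        """tg=0.5, l=1.5, x=0 with the true parameters: 1-exp(-0.2-0.8 e^{-0.125})."""
        m13, m23 = true_scenario1_models()
        curve = gcomp_curve(m13, m23, Strategy(0.5), np.array([[0.0]]), [1.5])
        expect = 1 - math.exp(-0.2 - 0.8 * math.exp(-0.125))
        assert curve.prob[0] == pytest.approx(expect, abs=1e-12)
        # and agrees with the truth oracle's conditional value
        cfg = scenario_config("scenario1")
        assert curve.prob[0] == pytest.approx(
            conditional_recovery_prob(cfg, 0.0, 0.5, 1.5), abs=1e-12)

    def test_curve_zero_at_zero_and_never_ignores_post_treatment_model(self):
        m13, m23 = true_scenario1_models()
        x = np.array([[0.3], [-0.7]])
        times = [0.0, 0.5, 1.5]
        never = gcomp_curve(m13, m23, Strategy.never(), x, times)
        assert never.prob[0] == 0.0
        # perturb the 2->3 model: the never curve must not move
        m23b = TransitionModel(fit=_exact_model([9.0, 9.0], ["x", "delay_tr"],
                                                [1.0], [5.0]),
                               covariate_names=["x"], clock="reset",
                               delay_transform="identity")
        never_b = gcomp_curve(m13, m23b, Strategy.never(), x, times)
        assert np.allclose(never.prob, never_b.prob)

    def test_branch_agreement_before_delay(self):
        """Curves for tg=0.25 and tg=0.5 coincide on [0, 0.25]."""
        m13, m23 = true_scenario1_models()
        x = np.array([[0.0], [1.0]])
        times = [0.05, 0.15, 0.25]
        c1 = gcomp_curve(m13, m23, Strategy(0.25), x, times)
        c2 = gcomp_curve(m13, m23, Strategy(0.5), x, times)
        assert np.allclose(c1.prob, c2.prob, atol=1e-14)

    def test_continuity_at_delay(self):
        """The two branches share Lam13(tg), so the curve cannot jump at tg."""
        m13, m23 = true_scenario1_models()
        x = np.array([[0.2]])
        at = gcomp_curve(m13, m23, Strategy(0.5), x, [0.5]).prob[0]
        just_after = gcomp_curve(m13, m23, Strategy(0.5), x, [0.5 + 1e-9]).prob[0]
        assert just_after == pytest.approx(at, abs=1e-9)

    def test_delay_beyond_horizon_rejected(self):
        m13, m23 = true_scenario1_models()
        with pytest.raises(ValueError, match="horizon"):
            gcomp_curve(m13, m23, Strategy(2.0), np.array([[0.0]]), [1.5], horizon=1.5)


class TestFittedCurves:
    def test_curves_monotone_and_bounded(self, scenario1_dataset):
        times = np.linspace(0, 1.5, 40)
        for variant in ("continuous", "categorical"):
            for c in estimate_all(scenario1_dataset, STRATEGIES, variant=variant,
                                  times=times):
                assert np.all(c.prob >= 0) and np.all(c.prob <= 1)
                assert np.all(np.diff(c.prob) >= -1e-12)

    def test_order_invariance(self, scenario1_dataset):
        times = [0.75, 1.5]
        a = estimate_all(scenario1_dataset, STRATEGIES, times=times)
        shuffled = type(scenario1_dataset)(
            frame=scenario1_dataset.frame.sample(frac=1, random_state=0),
            covariate_names=["x"])
        b = estimate_all(shuffled, STRATEGIES, times=times)
        for ca, cb in zip(a, b):
            assert np.allclose(ca.prob, cb.prob, atol=1e-12)

    def test_categorical_uses_requested_stratum(self, scenario1_dataset):
        m13, m23 = fit_multistate_models(scenario1_dataset, variant="categorical")
        assert 0.5 in m23.strata
        c = gcomp_categorical_curve(m13, m23, Strategy(0.5),
                                    scenario1_dataset.x, [1.5])
        assert 0 < c.prob[0] < 1
        with pytest.raises(EstimationError, match="0.37"):
            gcomp_categorical_curve(m13, m23, Strategy(0.37),
                                    scenario1_dataset.x, [1.5])

    def test_one_stratum_degenerate_equals_continuous_with_zero_gamma(self):
        """With a single delay value, stratification and a gamma=0 linear model
        describe the same fit."""
        cfg = scenario_config("scenario1", treatment_times=(0.5,),
                              treat_mass0_rate=1e-9)
        ds = simulate_dataset(cfg, 3)
        m13, m23s = fit_multistate_models(ds, variant="categorical")
        frames = build_transition_frames(ds, delay_transform="identity")
        m23c = fit_cox(frames.frame23, ["x"], clock="reset")
        # same events, same covariate: identical coefficient and baseline
        assert m23s.coefficients["x"] == pytest.approx(m23c.coefficients["x"], abs=1e-10)
        cat = gcomp_categorical_curve(m13, m23s, Strategy(0.5), ds.x, [1.5])
        base = m23c.baseline()
        man = TransitionModel(fit=CoxFit(
            beta=np.array([m23c.coefficients["x"], 0.0]), cov=np.eye(2),
            names=["x", "delay_tr"], loglik=0.0, n_events=1,
            baselines={None: base}, ties="efron", n_iter=0),
            covariate_names=["x"], clock="reset", delay_transform="identity")
        cont = gcomp_curve(m13, man, Strategy(0.5), ds.x, [1.5])
        assert cat.prob[0] == pytest.approx(cont.prob[0], abs=1e-12)

    def test_large_sample_consistency_all_strategies(self):
        """Estimated curve at the horizon within 0.01 of the quadrature truth."""
        cfg = scenario_config("scenario1", n=100_000)
        ds = simulate_dataset(cfg, 23)
        curves = estimate_all(ds, STRATEGIES, variant="continuous", times=[1.5])
        for c in curves:
            truth = true_recovery_prob(cfg, c.strategy, 1.5)
            assert c.prob[0] == pytest.approx(truth, abs=0.01), c.strategy.label()

    def test_product_limit_reduction_to_kaplan_meier(self, scenario1_dataset):
        """No covariates + never strategy: the product-limit curve equals the
        complement of the Kaplan-Meier that censors treatment, and the default
        exponential form agrees within the exp(-Lam) vs product-limit bound."""
        from lifelines import KaplanMeierFitter

        ds = scenario1_dataset
        frames = build_transition_frames(ds)
        m13 = fit_cox(frames.frame13, [])
        m23 = fit_cox(frames.frame23, [], clock="reset")
        times = np.linspace(0.1, 1.5, 15)
        pl = gcomp_curve(m13, m23, Strategy.never(), np.zeros((1, 0)), times,
                         survival_form="product-limit")
        km = KaplanMeierFitter().fit(ds.w, ds.delta_w == 2)
        ref = 1.0 - km.survival_function_at_times(times).to_numpy()
        assert np.allclose(pl.prob, ref, atol=1e-10)
        ex = gcomp_curve(m13, m23, Strategy.never(), np.zeros((1, 0)), times)
        base = m13.baseline()
        bound = float(np.max(base.jumps) * base.at(1.5))  # second-order discrepancy
        assert np.all(np.abs(ex.prob - pl.prob) <= bound + 1e-12)


class TestBootstrap:
    def test_single_replicate_band_collapses(self, scenario1_dataset):
        bands = bootstrap_ci(scenario1_dataset, [Strategy(0.5)], [0.75, 1.5],
                             B=1, seed=9)
        assert np.allclose(bands[0].lower, bands[0].upper)

    def test_bands_ordered_and_reproducible(self, scenario1_dataset):
        a = bootstrap_ci(scenario1_dataset, [Strategy(0.5), Strategy.never()],
                         [0.75, 1.5], B=20, seed=9)
        b = bootstrap_ci(scenario1_dataset, [Strategy(0.5), Strategy.never()],
                         [0.75, 1.5], B=20, seed=9)
        for ba, bb in zip(a, b):
            assert np.all(ba.lower <= ba.upper + 1e-15)
            assert np.allclose(ba.lower, bb.lower) and np.allclose(ba.upper, bb.upper)

    def test_nominal_coverage_scaled_study(self):
        """Percentile intervals cover the truth at roughly the nominal rate.

        Scaled-down design (20 outer replications, B=60, n=800) keeps the
        binomial check meaningful without a large compute bill.
        """
        cfg = scenario_config("scenario1", n=800)
        truth = true_recovery_prob(cfg, Strategy.never(), 1.5)
        hits = 0
        outer = 20
        for r in range(outer):
            ds = simulate_dataset(cfg, 300 + r)
            band = bootstrap_ci(ds, [Strategy.never()], [1.5], B=60, seed=r)[0]
            hits += bool(band.lower[0] <= truth <= band.upper[0])
        # 95% nominal: P(hits >= 15) ~ 1 under correct coverage
        assert hits >= 15
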