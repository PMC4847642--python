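"""Likelihood contributions for all four model variants."""

import numpy as np
import pytest
from scipy.optimize import minimize

from polyhazard.data import SurvivalData
from polyhazard.hazards import HazardComponent, PolyhazardModel
from polyhazard.likelihoods import (
    PiecewiseBaseline,
    arm_hazard,
    joint_loglik,
    piecewise_loglik,
    pop_cause_loglik,
    study_loglik,
    weibull_ph_loglik,
)


def _ds(time, event, cause=None, group="study"):
    return SurvivalData.from_arrays(time, event, cause=cause, group=group)


EMPTY = SurvivalData.from_arrays([], [], group="study")


class TestPopCauseLoglik:
    def test_empty_dataset_is_zero(self):
        assert pop_cause_loglik(EMPTY, 1, HazardComponent("weibull", 1, 0.5)) == 0.0

    def test_single_event(self):
        ds = _ds([1.0], [1], cause=[1], group="population")
        ll = pop_cause_loglik(ds, 1, HazardComponent("weibull", 1.0, 0.5))
        assert ll == pytest.approx(np.log(0.5) - 0.5, rel=1e-12)

    def test_all_censored(self):
        ds = _ds([2.0] * 10, [0] * 10, cause=[None] * 10, group="population")
        ll = pop_cause_loglik(ds, 1, HazardComponent("weibull", 1.0, 0.1))
        assert ll == pytest.approx(-2.0, rel=1e-12)

    def test_other_cause_death_counts_as_censored(self):
        """A cause-2 death contributes only the survivor term to cause 1."""
        comp = HazardComponent("weibull", 1.3, 0.2)
        died_other = _ds([3.0], [1], cause=[2], group="population")
        censored = _ds([3.0], [0], cause=[None], group="population")
        assert pop_cause_loglik(died_other, 1, comp) == pytest.approx(
            pop_cause_loglik(censored, 1, comp)
        )

    def test_requires_cause_labels(self):
        ds = _ds([1.0], [1])
        with pytest.raises(ValueError, match="cause-labelled"):
            pop_cause_loglik(ds, 1, HazardComponent("weibull", 1, 0.5))


class TestStudyLoglik:
    def test_censored_record(self):
        model = PolyhazardModel.two_component_weibull(
            (1.0, 1.0), (0.1, 0.2), beta=0.0
        )
        ds = _ds([5.0], [0])
        assert study_loglik(ds, model, "study") == pytest.approx(-1.5, rel=1e-12)

    def test_zero_beta_matches_population_group(self):
        model = PolyhazardModel.two_component_weibull(
            (1.5, 2.0), (0.001, 0.002), beta=0.0
        )
        ds = _ds([1.0, 4.0, 9.0], [1, 0, 1])
        assert study_loglik(ds, model, "study") == pytest.approx(
            study_loglik(ds, model, "population")
        )

    def test_single_component_equals_cause_specific(self):
        comp = HazardComponent("weibull", 1.4, 0.05)
        model = PolyhazardModel([comp])
        times, events = [1.0, 2.5, 7.0], [1, 1, 0]
        unlabelled = _ds(times, events)
        labelled = _ds(times, events, cause=[1, 1, None], group="population")
        assert study_loglik(unlabelled, model, "population") == pytest.approx(
            pop_cause_loglik(labelled, 1, comp), rel=1e-12
        )


class TestJointLoglik:
    @pytest.fixture
    def model(self):
        return PolyhazardModel.two_component_weibull(
            (1.5, 2.0), (0.0015, 0.0022), beta=1.2
        )

    @pytest.fixture
    def pop(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.5, 30, 40)
        return _ds(t, [1] * 40, cause=rng.integers(1, 3, 40), group="population")

    @pytest.fixture
    def study(self):
        return _ds([1.0, 2.0, 8.0, 9.5], [1, 0, 1, 0])

    def test_reduces_to_study_term_without_population(self, model, study):
        assert joint_loglik(None, study, model) == pytest.approx(
            study_loglik(study, model, "study")
        )

    def test_additivity(self, model, pop, study):
        total = joint_loglik(pop, study, model)
        parts = (
            study_loglik(study, model, "study")
            + pop_cause_loglik(pop, 1, model.components[0])
            + pop_cause_loglik(pop, 2, model.components[1])
        )
        assert total == pytest.approx(parts, rel=1e-14)

    def test_beta_perturbation_changes_only_study_term(self, pop, study):
        m1 = PolyhazardModel.two_component_weibull(
            (1.5, 2.0), (0.0015, 0.0022), beta=0.7
        )
        m2 = PolyhazardModel.two_component_weibull(
            (1.5, 2.0), (0.0015, 0.0022), beta=1.9
        )
        for k, comp1 in enumerate(m1.components, start=1):
            assert pop_cause_loglik(pop, k, comp1) == pop_cause_loglik(
                pop, k, m2.components[k - 1]
            )
        assert joint_loglik(pop, study, m1) - joint_loglik(
            pop, study, m2
        ) == pytest.approx(
            study_loglik(study, m1, "study") - study_loglik(study, m2, "study")
        )

    def test_excess_cause_labels_raise(self, model, study):
        bad = _ds([1.0], [1], cause=[3], group="population")
        with pytest.raises(ValueError, match="exceed"):
            joint_loglik(bad, study, model)


class TestArmHazard:
    def test_three_arm_values(self):
        model = PolyhazardModel.two_component_weibull((1.0, 1.0), (0.1, 0.2))
        got = arm_hazard(model, "treated", 4.0, beta=1.0, gamma=0.5)
        assert got == pytest.approx(np.exp(1.5) * 0.1 + 0.2, rel=1e-12)
        assert arm_hazard(model, "population", 4.0, beta=1.0, gamma=0.5) == (
            pytest.approx(0.3)
        )

    def test_zero_gamma_equals_study(self):
        model = PolyhazardModel.two_component_weibull((1.3, 1.8), (0.01, 0.02))
        t = np.linspace(0.1, 30, 7)
        np.testing.assert_allclose(
            arm_hazard(model, "treated", t, beta=0.9, gamma=0.0),
            arm_hazard(model, "study", t, beta=0.9),
        )

    def test_component1_hazard_ratio_constant_in_time(self):
        comp1 = HazardComponent("weibull", 1.7, 0.002)
        beta, gamma = 0.8, 0.4
        t = np.array([1.0, 5.0, 25.0])
        ratio = (np.exp(beta + gamma) * comp1.hazard(t)) / (
            np.exp(beta) * comp1.hazard(t)
        )
        np.testing.assert_allclose(ratio, np.exp(gamma))

    def test_unknown_arm(self):
        model = PolyhazardModel.two_component_weibull((1.0, 1.0), (0.1, 0.2))
        with pytest.raises(KeyError):
            arm_hazard(model, "placebo", 1.0, beta=0.1)


class TestWeibullPH:
    def test_single_population_death(self):
        pop = _ds([1.0], [1], group="population")
        ll = weibull_ph_loglik(pop, EMPTY, shape=1.0, rate=0.3, log_hr=0.0)
        assert ll == pytest.approx(np.log(0.3) - 0.3, rel=1e-12)

    def test_beta_zero_pools_groups(self):
        pop = _ds([2.0, 3.0], [1, 0], group="population")
        study = _ds([1.5, 4.0], [1, 1])
        pooled = _ds([2.0, 3.0, 1.5, 4.0], [1, 0, 1, 1], group="population")
        assert weibull_ph_loglik(pop, study, 1.4, 0.05, 0.0) == pytest.approx(
            weibull_ph_loglik(pooled, EMPTY, 1.4, 0.05, 0.0)
        )

    def test_consistent_with_polyweibull_when_effect_hits_both_components(self):
        """Splitting one Weibull rate into two equal-shape components and
        scaling both by exp(beta) reproduces the all-cause likelihood."""
        shape, beta = 1.6, 0.9
        l1, l2 = 0.004, 0.006
        pop = _ds(
            [2.0, 5.0, 9.0], [1, 1, 0], cause=[1, 2, None], group="population"
        )
        study = _ds([1.0, 3.5], [1, 0])
        from polyhazard.hazards import GroupEffects

        model = PolyhazardModel(
            [
                HazardComponent("weibull", shape, l1),
                HazardComponent("weibull", shape, l2),
            ],
            [GroupEffects("study", {0: beta, 1: beta})],
        )
        # study terms only: the all-cause model has no cause structure
        got = study_loglik(study, model, "study")
        want_comp = HazardComponent("weibull", shape, (l1 + l2) * np.exp(beta))
        want = -np.sum(want_comp.cumulative_hazard(study.time)) + np.sum(
            want_comp.log_hazard(study.time[study.event == 1])
        )
        assert got == pytest.approx(float(want), rel=1e-12)


class TestPiecewise:
    def test_two_interval_censored_record(self):
        base = PiecewiseBaseline(np.array([1.0]), np.array([0.1, 0.2]))
        ds = _ds([3.0], [0])
        assert piecewise_loglik(None, ds, base, log_hr=0.0) == pytest.approx(-0.5)

    def test_single_interval_is_exponential_model(self):
        base = PiecewiseBaseline.from_death_times([100.0], hazards=[0.25, 0.25])
        ds = _ds([2.0, 5.0], [1, 0])
        expect = np.log(0.25) - 0.25 * 2.0 - 0.25 * 5.0
        assert piecewise_loglik(None, ds, base, 0.0) == pytest.approx(expect)

    def test_beta_scales_study_only(self):
        base = PiecewiseBaseline(np.array([1.0, 2.0]), np.array([0.1, 0.2, 0.3]))
        pop = _ds([1.5], [0], group="population")
        study = _ds([1.5], [0])
        beta = 0.7
        got = piecewise_loglik(pop, study, base, beta)
        H = 0.1 * 1.0 + 0.2 * 0.5
        assert got == pytest.approx(-H - np.exp(beta) * H)

    def test_death_at_change_point_uses_terminating_interval(self):
        base = PiecewiseBaseline(np.array([1.0, 2.0]), np.array([0.1, 0.2, 0.3]))
        assert base.hazard(1.0) == 0.1
        assert base.hazard(1.5) == 0.2
        assert base.hazard(99.0) == 0.3

    def test_mean_survival_matches_quadrature(self):
        base = PiecewiseBaseline(
            np.array([1.0, 3.0, 6.0]), np.array([0.05, 0.1, 0.2, 0.4])
        )
        from scipy.integrate import quad

        for lhr in (0.0, 0.8):
            ref = quad(
                lambda t: np.exp(-np.exp(lhr) * base.cumulative_hazard(t)),
                0,
                400,
                limit=1000,
            )[0]
            assert base.mean_survival(lhr) == pytest.approx(ref, rel=1e-6)

    def test_duplicate_death_times_deduplicated(self):
        base = PiecewiseBaseline.from_death_times([2.0, 2.0, 5.0])
        np.testing.assert_array_equal(base.change_points, [2.0, 5.0])

    def test_validation(self):
        with pytest.raises(ValueError):
            PiecewiseBaseline(np.array([2.0, 1.0]), np.array([0.1, 0.1, 0.1]))
        with pytest.raises(ValueError):
            PiecewiseBaseline(np.array([1.0]), np.array([0.1]))


@pytest.mark.parametrize("variant", ["poly", "weibull-ph", "piecewise"])
def test_fully_censored_data_gives_minus_total_cumulative_hazard(variant):
    """With no events, every variant's log-likelihood is minus the sum of
    (group-scaled) cumulative hazards."""
    t_pop = np.array([2.0, 6.0])
    t_stud = np.array([1.0, 3.0])
    pop = _ds(t_pop, [0, 0], cause=[None, None], group="population")
    study = _ds(t_stud, [0, 0])
    beta = 0.6
    if variant == "poly":
        model = PolyhazardModel.two_component_weibull(
            (1.5, 2.0), (0.001, 0.002), beta=beta
        )
        got = joint_loglik(pop, study, model)
        expect = -(
            np.sum(0.001 * t_pop**1.5 + 0.002 * t_pop**2.0)
            + np.sum(np.exp(beta) * 0.001 * t_stud**1.5 + 0.002 * t_stud**2.0)
        )
    elif variant == "weibull-ph":
        got = weibull_ph_loglik(pop, study, 1.5, 0.01, beta)
        expect = -(
            np.sum(0.01 * t_pop**1.5) + np.exp(beta) * np.sum(0.01 * t_stud**1.5)
        )
    else:
        base = PiecewiseBaseline(np.array([4.0]), np.array([0.1, 0.3]))
        got = piecewise_loglik(pop, study, base, beta)
        H = base.cumulative_hazard(np.concatenate([t_pop, t_stud]))
        expect = -(H[0] + H[1]) - np.exp(beta) * (H[2] + H[3])
    assert got == pytest.approx(float(expect), rel=1e-12)


def test_mle_on_large_single_cause_sample_recovers_parameters(rng):
    """Maximising the cause-specific likelihood on simulated Weibull data
    recovers (shape, rate) within 3 standard errors."""
    a_true, l_true, n = 1.7, 0.0037, 20000
    t = (rng.exponential(size=n) / l_true) ** (1.0 / a_true)
    ds = SurvivalData.from_arrays(t, np.ones(n, int), cause=np.ones(n, int),
                                  group="population")

    def nll(x):
        return -pop_cause_loglik(ds, 1, HazardComponent("weibull", np.exp(x[0]),
                                                        np.exp(x[1])))

    res = minimize(nll, [0.0, -5.0], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-8})
    # observed information by central finite differences
    h = 1e-4
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            for si, sj, w in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
                x = res.x.copy()
                x[i] += si * h
                x[j] += sj * h
                H[i, j] += w * nll(x)
            H[i, j] /= 4 * h * h
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    assert abs(res.x[0] - np.log(a_true)) < 3 * se[0]
    assert abs(res.x[1] - np.log(l_true)) < 3 * se[1]
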