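"""Posterior sampling, summaries and deviance for the fitted estimators."""

import warnings

import numpy as np
import pandas as pd
import pytest

from polyhazard.data import SurvivalData
from polyhazard.estimators import (
    PiecewiseExtrapolator,
    PolyhazardExtrapolator,
    PosteriorSamples,
    WeibullPHExtrapolator,
    fit_mcmc,
    make_estimator,
    posterior_mean_deviance,
    summarize,
)
from polyhazard.likelihoods import (
    PiecewiseBaseline,
    piecewise_loglik,
    pop_cause_loglik,
    study_loglik,
    weibull_ph_loglik,
)
from polyhazard.hazards import GroupEffects, HazardComponent, PolyhazardModel

FAST = dict(n_steps=400, n_burn=150, thin=4)


def _fit_quiet(est, data):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return est.fit(data)


def _toy_samples(draws: np.ndarray, derived=None):
    n = len(draws)
    return PosteriorSamples(
        draws=pd.DataFrame({"x": draws}),
        derived=pd.DataFrame(derived if derived is not None else {}, index=range(n)),
        chain_shape=(1, n),
        diagnostics={},
        seed=0,
    )


class TestSummarize:
    def test_normal_draws_quantiles(self, rng):
        s = _toy_samples(rng.standard_normal(200000))
        tab = summarize(s)
        assert tab.loc["x", "2.5%"] == pytest.approx(-1.96, abs=0.03)
        assert tab.loc["x", "97.5%"] == pytest.approx(1.96, abs=0.03)
        assert list(tab.columns) == ["mean", "sd", "2.5%", "97.5%"]

    def test_constant_quantity_has_zero_sd_point_interval(self):
        s = _toy_samples(np.full(500, 3.25))
        tab = summarize(s)
        assert tab.loc["x", "sd"] == 0.0
        assert tab.loc["x", "2.5%"] == tab.loc["x", "97.5%"] == 3.25

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="at least 100"):
            summarize(_toy_samples(np.arange(50.0)))


class TestDeviance:
    def test_single_draw_equals_minus_two_loglik(self, m2_pair):
        pop, study = m2_pair
        est = _fit_quiet(WeibullPHExtrapolator(random_state=3, **FAST),
                         pop.concat(study))
        row = est.posterior_.draws.iloc[0]
        ll = weibull_ph_loglik(pop, study, row["alpha"], row["lambda"], row["beta"])
        assert est.posterior_.derived["deviance_total"].iloc[0] == pytest.approx(
            -2.0 * ll, rel=1e-9
        )
        one = PosteriorSamples(
            draws=est.posterior_.draws.iloc[:1],
            derived=est.posterior_.derived.iloc[:1],
            chain_shape=(1, 1),
            diagnostics={},
            seed=0,
        )
        assert posterior_mean_deviance(one, "total") == pytest.approx(-2 * ll, rel=1e-9)

    def test_polyhazard_components_match_likelihood_functions(self, pw_treatment_fit,
                                                              m2_pair):
        pop, study = m2_pair
        post = pw_treatment_fit.posterior_
        i = 7
        row = post.draws.iloc[i]
        model = PolyhazardModel(
            [
                HazardComponent("weibull", row["alpha1"], row["lambda1"]),
                HazardComponent("weibull", row["alpha2"], row["lambda2"]),
            ],
            [GroupEffects("study", {0: row["beta"]})],
        )
        assert post.derived["deviance_study"].iloc[i] == pytest.approx(
            -2 * study_loglik(study, model, "study"), rel=1e-9
        )
        assert post.derived["deviance_pop_cause1"].iloc[i] == pytest.approx(
            -2 * pop_cause_loglik(pop, 1, model.components[0]), rel=1e-9
        )
        assert post.derived["deviance_pop_cause2"].iloc[i] == pytest.approx(
            -2 * pop_cause_loglik(pop, 2, model.components[1]), rel=1e-9
        )

    def test_absent_term_contributes_zero(self, pw_treatment_fit):
        assert posterior_mean_deviance(pw_treatment_fit.posterior_, "arm") == 0.0

    def test_correct_family_has_lower_mean_deviance(self, m2_pair):
        """Poly-Weibull and poly-Gompertz have identical structure, so
        their posterior mean deviances are directly comparable; on
        Weibull-generated data (full-lifetime population records) the
        Weibull family must fit better.  Ordering check only."""
        pop, study = m2_pair
        data = pop.concat(study)
        pw = _fit_quiet(PolyhazardExtrapolator(random_state=4, **FAST), data)
        pg = _fit_quiet(
            PolyhazardExtrapolator(family="gompertz", random_state=4, **FAST), data
        )
        d_pw = posterior_mean_deviance(pw.posterior_, "total")
        d_pg = posterior_mean_deviance(pg.posterior_, "total")
        assert d_pw < d_pg


class TestFitBehaviour:
    def test_fixed_seed_reproducible(self, m2_pair):
        pop, study = m2_pair
        data = pop.concat(study)
        a = _fit_quiet(WeibullPHExtrapolator(random_state=9, **FAST), data)
        b = _fit_quiet(WeibullPHExtrapolator(random_state=9, **FAST), data)
        pd.testing.assert_frame_equal(a.posterior_.draws, b.posterior_.draws)
        pd.testing.assert_frame_equal(a.posterior_.derived, b.posterior_.derived)

    def test_polyhazard_requires_population_records(self):
        study = SurvivalData.from_arrays([1.0, 2.0], [1, 0], group="study")
        with pytest.raises(ValueError, match="population"):
            PolyhazardExtrapolator(**FAST).fit(study)

    def test_second_arm_data_require_gamma_prior(self):
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0],
                "event": [1, 0, 1],
                "group": ["study", "study", "treated"],
            }
        )
        with pytest.raises(ValueError, match="gamma prior"):
            WeibullPHExtrapolator(**FAST).fit(df)

    def test_burn_in_validation(self):
        with pytest.raises(ValueError, match="n_burn"):
            WeibullPHExtrapolator(n_steps=100, n_burn=100).fit(
                pd.DataFrame({"time": [1.0], "event": [1], "group": ["study"]})
            )

    def test_ordering_constraint_holds_in_every_draw(self, pw_treatment_fit):
        d = pw_treatment_fit.posterior_.draws
        sigma1 = d["lambda1"] ** (-1 / d["alpha1"])
        sigma2 = d["lambda2"] ** (-1 / d["alpha2"])
        assert (sigma1 > sigma2).all()
        assert (d[["lambda1", "lambda2"]] > 0).all().all()

    def test_treated_arm_quantities_present_and_ordered(self, pw_treatment_fit):
        est = pw_treatment_fit
        # gamma prior mean is positive (treated arm at higher hazard), so
        # treated-arm mean survival is below the study arm's
        assert est.mean_survival("treated") < est.mean_survival("study")
        assert est.life_years_gained_ == pytest.approx(
            est.mean_survival("study") - est.mean_survival("treated"), rel=1e-9
        )
        assert est.life_years_gained_ > 0

    def test_sklearn_params_roundtrip(self):
        est = PolyhazardExtrapolator(n_steps=500, random_state=3)
        params = est.get_params()
        assert params["n_steps"] == 500
        clone = PolyhazardExtrapolator(**params)
        assert clone.get_params() == params

    def test_fit_mcmc_wrapper(self, m2_pair):
        pop, study = m2_pair
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_mcmc(pop, study, "weibull-ph", mcmc_config=dict(
                random_state=2, **FAST))
        assert {"alpha", "lambda", "beta"} <= set(post.draws.columns)
        assert post.n_draws >= 100

    def test_make_estimator_rejects_unknown(self):
        with pytest.raises(ValueError):
            make_estimator("cox")


class TestPiecewiseEstimator:
    @pytest.fixture(scope="class")
    def cox_fit(self, m2_pair):
        pop, study = m2_pair
        est = PiecewiseExtrapolator(random_state=6, n_steps=400, n_burn=150)
        return _fit_quiet(est, pop.concat(study))

    def test_mean_survival_plausible(self, cox_fit):
        ms = cox_fit.mean_survival("study")
        assert 5.0 < ms < 40.0
        lo, hi = cox_fit.credible_interval("mean_survival_study")
        assert lo < ms < hi

    def test_survival_function_monotone_from_one(self, cox_fit):
        t = np.linspace(0, 50, 40)
        s = cox_fit.predict_survival_function(t, arm="study")
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((0 <= s) & (s <= 1))

    def test_deviance_matches_piecewise_loglik(self, cox_fit, m2_pair):
        pop, study = m2_pair
        i = 3
        base = PiecewiseBaseline(cox_fit.change_points_, cox_fit.baseline_draws_[i])
        beta = cox_fit.posterior_.draws["beta"].iloc[i]
        want = -2 * piecewise_loglik(pop, study, base, beta)
        got = (
            cox_fit.posterior_.derived["deviance_pop"].iloc[i]
            + cox_fit.posterior_.derived["deviance_study"].iloc[i]
        )
        assert got == pytest.approx(want, rel=1e-9)

    def test_mean_survival_draws_match_baseline_closed_form(self, cox_fit):
        i = 11
        base = PiecewiseBaseline(cox_fit.change_points_, cox_fit.baseline_draws_[i])
        beta = cox_fit.posterior_.draws["beta"].iloc[i]
        assert cox_fit.posterior_.derived["mean_survival_study"].iloc[
            i
        ] == pytest.approx(base.mean_survival(beta), rel=1e-9)

    def test_reproducible(self, m2_pair, cox_fit):
        pop, study = m2_pair
        again = _fit_quiet(
            PiecewiseExtrapolator(random_state=6, n_steps=400, n_burn=150),
            pop.concat(study),
        )
        pd.testing.assert_frame_equal(again.posterior_.draws, cox_fit.posterior_.draws)


def test_equal_shape_data_polyweibull_agrees_with_allcause_weibull():
    """When the generating shapes are equal, the polyhazard model
    collapses to an all-cause Weibull, so the two estimators' posterior
    means of study mean survival should agree closely on large data.

    The residual difference is dominated by the two variants' different
    priors (order 0.1 years here), so the bound is a small fraction of
    the posterior sd rather than pure Monte-Carlo error.
    """
    from dataclasses import replace

    from polyhazard.simulation import generate_scenario_data, get_scenario

    spec = replace(get_scenario("model1_b15"), name="big", n_pop=5000, n_study=2500)
    pop, study = generate_scenario_data(spec, seed=3)
    data = pop.concat(study)
    pw = _fit_quiet(PolyhazardExtrapolator(random_state=2), data)
    w = _fit_quiet(WeibullPHExtrapolator(random_state=2), data)
    m_pw, m_w = pw.mean_survival("study"), w.mean_survival("study")
    sd = pw.posterior_.derived["mean_survival_study"].std()
    assert abs(m_pw - m_w) < max(0.5 * sd, 0.25)
    lo, hi = pw.credible_interval("mean_survival_study")
    assert lo < m_w < hi
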