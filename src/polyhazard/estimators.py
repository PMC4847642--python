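"""Bayesian survival-extrapolation estimators.

Three scikit-learn-style estimators fit the joint population + study
survival model by MCMC and expose posterior summaries of lifetime mean
survival and life years gained:

- :class:`PolyhazardExtrapolator` -- the cause-specific polyhazard model
  (Weibull or Gompertz components) with proportional cause-of-interest
  hazards between groups;
- :class:`WeibullPHExtrapolator` -- the all-cause Weibull
  proportional-hazards comparator (ignores cause labels);
- :class:`PiecewiseExtrapolator` -- the semi-parametric "Cox-like"
  comparator with a piecewise-constant baseline hazard and change points
  at every observed death time.

Each ``fit`` takes a single dataset (DataFrame or
:class:`~polyhazard.data.SurvivalData`) whose ``group`` column
distinguishes the general-population records (cause-labelled for the
polyhazard variants), the study cohort, and optionally a second
treatment arm.  When a treatment-effect prior is supplied without
second-arm individual data, the treated arm's survival is derived purely
from the prior on its log hazard ratio gamma (the posterior of gamma
then equals its prior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import _samplers as smp
from .data import SurvivalData
from .hazards import GOMPERTZ, WEIBULL
from .priors import PriorSpec, default_priors, gamma_prior_from_hazard_ratio

__all__ = [
    "PosteriorSamples",
    "summarize",
    "posterior_mean_deviance",
    "PolyhazardExtrapolator",
    "WeibullPHExtrapolator",
    "PiecewiseExtrapolator",
    "fit_mcmc",
    "make_estimator",
]


@dataclass
class PosteriorSamples:
    """Retained posterior draws plus derived quantities and diagnostics.

    ``draws`` holds natural-scale model parameters, one row per retained
    draw; ``derived`` aligned per-draw summaries (mean survival by arm,
    life years gained, deviance contributions); ``chain_shape`` the
    (chains, draws-per-chain) layout of the rows, used for effective
    sample size computations.
    """

    draws: pd.DataFrame
    derived: pd.DataFrame
    chain_shape: Tuple[int, int]
    diagnostics: Dict
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def column(self, name: str) -> np.ndarray:
        if name in self.draws.columns:
            return self.draws[name].to_numpy()
        return self.derived[name].to_numpy()

    def to_chain(self, name: str) -> np.ndarray:
        return self.column(name).reshape(self.chain_shape)

    def ess(self, name: str) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(az.ess(az.convert_to_dataset(self.to_chain(name)))["x"])

    def mcse(self, name: str) -> float:
        """Monte-Carlo standard error of the posterior mean."""
        x = self.column(name)
        return float(x.std(ddof=1) / np.sqrt(max(self.ess(name), 1.0)))

    def summary(self) -> pd.DataFrame:
        return summarize(self)


def summarize(samples: PosteriorSamples, min_draws: int = 100) -> pd.DataFrame:
    """Posterior mean, sd and equal-tailed 95% interval per quantity.

    Column order is fixed (mean, sd, 2.5%, 97.5%); rows are the
    parameters followed by the derived quantities.
    """
    if samples.n_draws < min_draws:
        raise ValueError(
            f"need at least {min_draws} retained draws, have {samples.n_draws}"
        )
    tab = pd.concat([samples.draws, samples.derived], axis=1)
    out = pd.DataFrame(
        {
            "mean": tab.mean(),
            "sd": tab.std(ddof=1),
            "2.5%": tab.quantile(0.025),
            "97.5%": tab.quantile(0.975),
        }
    )
    return out


def posterior_mean_deviance(samples: PosteriorSamples, which: str = "study") -> float:
    """Posterior mean deviance D-bar = E[-2 log L] for one likelihood term.

    ``which`` selects the data source: ``study``, ``pop_cause1``,
    ``pop_cause2`` (polyhazard variants), ``pop`` (all-cause variants) or
    ``total``.  A term with no data contributes 0.
    """
    col = f"deviance_{which}"
    if col not in samples.derived.columns:
        return 0.0
    return float(samples.derived[col].mean())


def _coerce(data) -> SurvivalData:
    if isinstance(data, SurvivalData):
        return data
    return SurvivalData(pd.DataFrame(data))


def _split_groups(data: SurvivalData, population, study, treated):
    present = set(data.group_labels())
    pop = data.subset(population) if population in present else None
    if study not in present:
        raise ValueError(f"no records with study group label {study!r}")
    stud = data.subset(study)
    arm = data.subset(treated) if treated and treated in present else None
    return pop, stud, arm


class _BaseExtrapolator(BaseEstimator):
    """Shared plumbing: group splitting, priors, derived quantities."""

    _variant: str = ""

    def _resolve_priors(self) -> PriorSpec:
        if self.priors is not None:
            priors = self.priors
        else:
            priors = default_priors(self._variant)
        if self.treatment_hazard_ratio is not None and priors.gamma is None:
            priors = priors.with_gamma(
                gamma_prior_from_hazard_ratio(
                    self.treatment_hazard_ratio,
                    self.treatment_ci,
                    self.treatment_sd,
                )
            )
        return priors

    def _seed_pair(self):
        ss = np.random.SeedSequence(self.random_state)
        a, b = ss.generate_state(2)
        return int(a % (2**31)), int(b % (2**31))

    def _finish(self, samples: PosteriorSamples):
        self.posterior_ = samples
        self.converged_ = bool(samples.diagnostics.get("converged", True))
        if not self.converged_:
            warnings.warn(
                "MCMC convergence diagnostics failed (max R-hat "
                f"{samples.diagnostics.get('max_rhat'):.3f}); treat results "
                "with caution",
                stacklevel=3,
            )
        self.mean_survival_ = {
            c.replace("mean_survival_", ""): float(samples.derived[c].mean())
            for c in samples.derived.columns
            if c.startswith("mean_survival_")
        }
        if "life_years_gained" in samples.derived.columns:
            self.life_years_gained_ = float(
                samples.derived["life_years_gained"].mean()
            )
        return self

    # -- public posterior accessors -----------------------------------
    def mean_survival(self, arm: Optional[str] = None) -> float:
        """Posterior mean of lifetime mean survival for one arm (years)."""
        check_is_fitted(self, "posterior_")
        arm = arm or self.study_group
        return self.mean_survival_[arm]

    def credible_interval(self, name: str, level: float = 0.95):
        check_is_fitted(self, "posterior_")
        x = self.posterior_.column(name)
        a = (1.0 - level) / 2.0
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))

    def summary(self) -> pd.DataFrame:
        check_is_fitted(self, "posterior_")
        return self.posterior_.summary()


def _rhat_ess(chain: np.ndarray, names) -> Tuple[dict, dict]:
    """R-hat and ESS per parameter from a (draw, chain, dim) array."""
    data = {n: np.moveaxis(chain[:, :, i], 0, 1) for i, n in enumerate(names)}
    ds = az.convert_to_dataset(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = {n: float(az.rhat(ds)[n].values) for n in names}
        ess = {n: float(az.ess(ds)[n].values) for n in names}
    return rhat, ess


class _ParametricExtrapolator(_BaseExtrapolator):
    def fit(self, data, y=None):
        if self.n_burn >= self.n_steps:
            raise ValueError("n_burn must be smaller than n_steps")
        data = _coerce(data)
        pop, study, arm = _split_groups(
            data, self.population_group, self.study_group, self.treatment_group
        )
        priors = self._resolve_priors()
        logpost = smp.ParametricJointLogPost(self._variant, priors, pop, study, arm)
        seed_init, seed_run = self._seed_pair()
        rng = np.random.default_rng(seed_init)
        center, spread = self._initial_guess(logpost, pop, study, priors)
        p0 = smp.initial_walkers(logpost, center, spread, self.n_walkers, rng)
        chain = smp.run_ensemble(logpost, p0, self.n_steps, seed_run)
        post = chain[self.n_burn :]
        rhat, ess = _rhat_ess(post, logpost.param_names)
        max_rhat = max(rhat.values())
        # rows ordered walker-major so each walker is a contiguous "chain"
        flat = np.concatenate(
            [post[:: self.thin, w, :] for w in range(self.n_walkers)], axis=0
        )
        params = logpost.natural_params(flat)
        draws = pd.DataFrame(params)
        derived = self._derived(logpost, flat, params)
        n_per = post[:: self.thin].shape[0]
        samples = PosteriorSamples(
            draws=draws,
            derived=derived,
            chain_shape=(self.n_walkers, n_per),
            diagnostics={
                "rhat": rhat,
                "ess": ess,
                "max_rhat": max_rhat,
                "converged": max_rhat < self.rhat_threshold,
                "n_chains": self.n_walkers,
                "sampler": "emcee-ensemble",
            },
            seed=self.random_state,
        )
        self.priors_ = priors
        self.param_names_ = logpost.param_names
        self._logpost = logpost
        return self._finish(samples)

    def _derived(self, logpost, flat, params) -> pd.DataFrame:
        out = {}
        arms = self._arm_log_hrs(params)
        for label, lhr in arms.items():
            out[f"mean_survival_{label}"] = self._mean_survival_draws(params, lhr)
        labels = list(arms)
        if len(labels) == 3:
            # life years gained: study arm minus the (worse) treated arm
            out["life_years_gained"] = (
                out[f"mean_survival_{labels[1]}"] - out[f"mean_survival_{labels[2]}"]
            )
        comps = logpost.loglik_components(flat)
        total = np.zeros(flat.shape[0])
        for name, ll in comps.items():
            key = "arm" if name == "arm" else name
            out[f"deviance_{key}"] = -2.0 * ll
            total += -2.0 * ll
        out["deviance_total"] = total
        return pd.DataFrame(out)

    def _arm_log_hrs(self, params) -> Dict[str, np.ndarray]:
        beta = params["beta"]
        arms = {self.population_group: np.zeros_like(beta), self.study_group: beta}
        if "gamma" in params:
            label = self.treatment_group or "treated"
            arms[label] = beta + params["gamma"]
        return arms

    def predict_survival_function(self, times, arm: Optional[str] = None):
        """Posterior-mean survivor function evaluated at ``times``."""
        check_is_fitted(self, "posterior_")
        arm = arm or self.study_group
        params = {k: v.to_numpy() for k, v in self.posterior_.draws.items()}
        lhr = self._arm_log_hrs(params)[arm]
        t = np.asarray(times, dtype=float)
        cum = np.zeros((len(lhr), len(t)))
        if self._variant == "poly-weibull":
            it = ((params["alpha1"], params["lambda1"] * np.exp(lhr)),
                  (params["alpha2"], params["lambda2"]))
            for a, l in it:
                with np.errstate(divide="ignore"):
                    cum += l[:, None] * np.exp(a[:, None] * np.log(t)[None, :])
        elif self._variant == "poly-gompertz":
            it = ((params["alpha1"], params["lambda1"] * np.exp(lhr)),
                  (params["alpha2"], params["lambda2"]))
            for a, l in it:
                cum += l[:, None] * smp._gomp_cumhaz_factor(a[:, None], t)
        else:
            a, l = params["alpha"], params["lambda"] * np.exp(lhr)
            with np.errstate(divide="ignore"):
                cum += l[:, None] * np.exp(a[:, None] * np.log(t)[None, :])
        return np.exp(-np.nan_to_num(cum, nan=0.0)).mean(axis=0)


class PolyhazardExtrapolator(_ParametricExtrapolator):
    """Two-component polyhazard joint model with cause-specific effects.

    Requires cause-labelled population records and unlabelled study
    records in the fitted dataset.  The study group's hazard for the
    cause of interest (cause 1) is ``exp(beta)`` times the population's;
    other-cause hazards are identical.  With a treatment-effect prior, a
    treated arm with additional log hazard ratio gamma on cause 1 is
    propagated to the derived quantities.

    Parameters largely mirror the sampler: ``n_walkers`` ensemble
    walkers, ``n_steps`` iterations, first ``n_burn`` discarded, then
    thinned by ``thin``.
    """

    def __init__(
        self,
        family: str = WEIBULL,
        priors: Optional[PriorSpec] = None,
        treatment_hazard_ratio: Optional[float] = None,
        treatment_ci: Optional[Tuple[float, float]] = None,
        treatment_sd: Optional[float] = None,
        n_walkers: int = 32,
        n_steps: int = 1700,
        n_burn: int = 700,
        thin: int = 8,
        rhat_threshold: float = 1.05,
        population_group: str = "population",
        study_group: str = "study",
        treatment_group: Optional[str] = "treated",
        random_state: int = 0,
    ):
        self.family = family
        self.priors = priors
        self.treatment_hazard_ratio = treatment_hazard_ratio
        self.treatment_ci = treatment_ci
        self.treatment_sd = treatment_sd
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.thin = thin
        self.rhat_threshold = rhat_threshold
        self.population_group = population_group
        self.study_group = study_group
        self.treatment_group = treatment_group
        self.random_state = random_state

    @property
    def _variant(self):
        return "poly-weibull" if self.family == WEIBULL else "poly-gompertz"

    def _initial_guess(self, logpost, pop, study, priors):
        t_pop, t_stud = pop.time, study.time
        cause = pop.cause
        d = pop.event == 1
        sigmas = []
        a0 = 1.3
        for k in (1, 2):
            dk = int((d & (np.nan_to_num(cause, nan=-1) == k)).sum())
            lam = (dk + 0.5) / np.sum(t_pop**a0)
            sigmas.append(float(np.clip(lam ** (-1.0 / a0), 2.0, 95.0)))
        if priors.ordered_scales and sigmas[0] <= sigmas[1]:
            sigmas[1] = 0.85 * sigmas[0]
        rate_p = (d.sum() + 0.5) / t_pop.sum()
        rate_s = ((study.event == 1).sum() + 0.5) / t_stud.sum()
        beta0 = float(np.clip(np.log(rate_s / rate_p), -3.0, 3.0))
        if self.family == WEIBULL:
            center = [np.log(a0), np.log(a0), sigmas[0], sigmas[1], beta0]
            spread = [0.2, 0.2, 2.0, 2.0, 0.3]
        else:
            lam0 = max(rate_p, 1e-4)
            s0 = float(np.clip(1.0 / lam0, 2.0, 95.0))
            center = [0.05, 0.05, s0, 0.85 * s0, beta0]
            spread = [0.02, 0.02, 2.0, 2.0, 0.3]
        if logpost.with_gamma:
            center.append(priors.gamma.mean)
            spread.append(priors.gamma.sd)
        return np.array(center), np.array(spread)

    def _mean_survival_draws(self, params, lhr):
        alphas = np.column_stack([params["alpha1"], params["alpha2"]])
        lams = np.column_stack(
            [params["lambda1"] * np.exp(lhr), params["lambda2"]]
        )
        return smp.mean_survival_poly_batch(self._variant, alphas, lams)


class WeibullPHExtrapolator(_ParametricExtrapolator):
    """All-cause Weibull model with proportional hazards between groups.

    The misspecified comparator: cause labels are ignored, the study
    group's all-cause hazard is ``exp(beta)`` times the population's
    (common shape), and an optional treated arm scales it by
    ``exp(beta+gamma)``.
    """

    _variant = "weibull-ph"

    def __init__(
        self,
        priors: Optional[PriorSpec] = None,
        treatment_hazard_ratio: Optional[float] = None,
        treatment_ci: Optional[Tuple[float, float]] = None,
        treatment_sd: Optional[float] = None,
        n_walkers: int = 24,
        n_steps: int = 1300,
        n_burn: int = 500,
        thin: int = 6,
        rhat_threshold: float = 1.05,
        population_group: str = "population",
        study_group: str = "study",
        treatment_group: Optional[str] = "treated",
        random_state: int = 0,
    ):
        self.priors = priors
        self.treatment_hazard_ratio = treatment_hazard_ratio
        self.treatment_ci = treatment_ci
        self.treatment_sd = treatment_sd
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.thin = thin
        self.rhat_threshold = rhat_threshold
        self.population_group = population_group
        self.study_group = study_group
        self.treatment_group = treatment_group
        self.random_state = random_state

    def _initial_guess(self, logpost, pop, study, priors):
        a0 = 1.3
        t_all = study.time if pop is None else np.concatenate([pop.time, study.time])
        d_all = (
            study.event.sum()
            if pop is None
            else pop.event.sum() + study.event.sum()
        )
        lam = (d_all + 0.5) / np.sum(t_all**a0)
        sigma = float(np.clip(lam ** (-1.0 / a0), 2.0, 95.0))
        if pop is not None:
            rate_p = (pop.event.sum() + 0.5) / pop.time.sum()
            rate_s = ((study.event == 1).sum() + 0.5) / study.time.sum()
            beta0 = float(np.clip(np.log(rate_s / rate_p), -3.0, 3.0))
        else:
            beta0 = 0.0
        center = [np.log(a0), sigma, beta0]
        spread = [0.2, 2.0, 0.3]
        if logpost.with_gamma:
            center.append(priors.gamma.mean)
            spread.append(priors.gamma.sd)
        return np.array(center), np.array(spread)

    def _mean_survival_draws(self, params, lhr):
        return smp.mean_survival_weibull_batch(
            params["alpha"], params["lambda"] * np.exp(lhr)
        )


class PiecewiseExtrapolator(_BaseExtrapolator):
    """Semi-parametric proportional-hazards model ("Cox-like").

    The shared baseline hazard is piecewise constant with change points
    at every observed death time (ties deduplicated); the study group
    scales it by ``exp(beta)``.  Interval hazards carry independent
    Gamma(c*mu_j, c) priors; by default ``mu_j`` is a smoothed
    Nelson-Aalen hazard estimate from the population records, and it can
    be overridden with an array or a callable evaluated at interval
    midpoints (e.g. the true hazard in simulation studies).  Sampling is
    Gibbs: interval hazards are conjugate Gamma updates and beta (and
    gamma) use slice sampling.  Mean survival extrapolates the final
    interval's hazard beyond the last death time.
    """

    _variant = "cox-like"

    def __init__(
        self,
        priors: Optional[PriorSpec] = None,
        baseline_means=None,
        treatment_hazard_ratio: Optional[float] = None,
        treatment_ci: Optional[Tuple[float, float]] = None,
        treatment_sd: Optional[float] = None,
        n_chains: int = 4,
        n_steps: int = 750,
        n_burn: int = 250,
        rhat_threshold: float = 1.05,
        population_group: str = "population",
        study_group: str = "study",
        treatment_group: Optional[str] = "treated",
        random_state: int = 0,
    ):
        self.priors = priors
        self.baseline_means = baseline_means
        self.treatment_hazard_ratio = treatment_hazard_ratio
        self.treatment_ci = treatment_ci
        self.treatment_sd = treatment_sd
        self.n_chains = n_chains
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.rhat_threshold = rhat_threshold
        self.population_group = population_group
        self.study_group = study_group
        self.treatment_group = treatment_group
        self.random_state = random_state

    def fit(self, data, y=None):
        if self.n_burn >= self.n_steps:
            raise ValueError("n_burn must be smaller than n_steps")
        data = _coerce(data)
        pop, study, arm = _split_groups(
            data, self.population_group, self.study_group, self.treatment_group
        )
        priors = self._resolve_priors()
        if arm is not None and priors.gamma is None:
            raise ValueError("second-arm data require a treatment (gamma) prior")

        death_times = [study.time[study.event == 1]]
        if pop is not None:
            death_times.append(pop.time[pop.event == 1])
        if arm is not None:
            death_times.append(arm.time[arm.event == 1])
        cp = np.unique(np.concatenate(death_times))
        if len(cp) == 0:
            raise ValueError("no observed deaths; cannot place change points")
        edges = np.concatenate(([0.0], cp))
        n_int = len(cp) + 1

        def interval_stats(ds):
            if ds is None:
                return np.zeros(n_int), np.zeros(n_int)
            t, d = ds.time, ds.event == 1
            j = np.searchsorted(cp, t, side="left")
            deaths = np.bincount(j[d], minlength=n_int).astype(float)
            # exposure of each record in interval (e_{j-1}, e_j]
            right = np.concatenate((cp, [np.inf]))
            expo = np.clip(
                t[:, None] - edges[None, :], 0.0, (right - edges)[None, :]
            ).sum(axis=0)
            return deaths, expo

        d_pop, e_pop = interval_stats(pop)
        d_stud, e_stud = interval_stats(study)
        d_arm, e_arm = interval_stats(arm)

        mu = self._resolve_baseline_means(cp, edges, d_pop, e_pop, d_stud, e_stud)
        c = priors.baseline_concentration
        beta_prior, gamma_prior = priors.beta, priors.gamma
        with_gamma = gamma_prior is not None
        have_arm = arm is not None

        seed_root = np.random.SeedSequence(self.random_state)
        chains_beta, chains_gamma, chains_h = [], [], []
        keep = self.n_steps - self.n_burn
        for chain_seed in seed_root.spawn(self.n_chains):
            rng = np.random.default_rng(chain_seed)
            beta = 0.0
            gamma = gamma_prior.mean if with_gamma else 0.0
            bs, gs, hs = [], [], []
            for it in range(self.n_steps):
                w_arm = np.exp(beta + gamma) if have_arm else 0.0
                expo = e_pop + np.exp(beta) * e_stud + w_arm * e_arm
                h = rng.gamma(c * mu + d_pop + d_stud + d_arm, 1.0 / (c + expo))
                a_s = float(h @ e_stud)
                a_a = float(h @ e_arm) if have_arm else 0.0
                d_s, d_a = float(d_stud.sum()), float(d_arm.sum())

                def lp_beta(b):
                    val = d_s * b - np.exp(b) * a_s + beta_prior.logpdf(b)
                    if have_arm:
                        val += d_a * b - np.exp(b + gamma) * a_a
                    return val

                beta = smp.slice_sample(lp_beta, beta, rng, width=0.5)
                if with_gamma:
                    if have_arm:
                        gamma = smp.slice_sample(
                            lambda g: d_a * g
                            - np.exp(beta + g) * a_a
                            + gamma_prior.logpdf(g),
                            gamma,
                            rng,
                            width=0.5,
                        )
                    else:
                        gamma = float(rng.normal(gamma_prior.mean, gamma_prior.sd))
                if it >= self.n_burn:
                    bs.append(beta)
                    gs.append(gamma)
                    hs.append(h)
            chains_beta.append(bs)
            chains_gamma.append(gs)
            chains_h.append(np.asarray(hs))

        beta_arr = np.asarray(chains_beta)  # (chains, keep)
        gamma_arr = np.asarray(chains_gamma)
        h_arr = np.concatenate(chains_h, axis=0)  # (chains*keep, n_int)
        names = ["beta"] + (["gamma"] if with_gamma else [])
        chain_stack = np.stack(
            [beta_arr] + ([gamma_arr] if with_gamma else []), axis=-1
        )  # (chains, keep, d)
        rhat, ess = _rhat_ess(np.moveaxis(chain_stack, 0, 1), names)
        max_rhat = max(rhat.values())

        draws = {"beta": beta_arr.reshape(-1)}
        if with_gamma:
            draws["gamma"] = gamma_arr.reshape(-1)
        draws = pd.DataFrame(draws)

        derived = self._derived_piecewise(
            edges, cp, h_arr, draws, d_pop, e_pop, d_stud, e_stud, d_arm, e_arm,
            have_arm, with_gamma,
        )
        samples = PosteriorSamples(
            draws=draws,
            derived=derived,
            chain_shape=(self.n_chains, keep),
            diagnostics={
                "rhat": rhat,
                "ess": ess,
                "max_rhat": max_rhat,
                "converged": max_rhat < self.rhat_threshold,
                "n_chains": self.n_chains,
                "sampler": "gibbs+slice",
            },
            seed=self.random_state,
        )
        self.priors_ = priors
        self.change_points_ = cp
        self.baseline_draws_ = h_arr
        self.baseline_prior_means_ = mu
        self.param_names_ = names
        return self._finish(samples)

    def _resolve_baseline_means(self, cp, edges, d_pop, e_pop, d_stud, e_stud):
        n_int = len(cp) + 1
        spec = self.baseline_means
        if spec is None and self.priors is not None:
            if self.priors.baseline_means is not None:
                spec = np.asarray(self.priors.baseline_means, dtype=float)
        if spec is None:
            # smoothed Nelson-Aalen increments from whichever records exist
            d = d_pop if d_pop.sum() > 0 else d_stud
            e = e_pop if d_pop.sum() > 0 else e_stud
            with np.errstate(divide="ignore", invalid="ignore"):
                raw = np.where(e > 0, d / np.maximum(e, 1e-12), np.nan)
            overall = d.sum() / max(e.sum(), 1e-12)
            raw = np.where(np.isfinite(raw) & (raw > 0), raw, overall)
            win = min(11, n_int)
            mu = (
                pd.Series(raw)
                .rolling(win, center=True, min_periods=1)
                .mean()
                .to_numpy()
            )
            return np.maximum(mu, 1e-6)
        if callable(spec):
            widths = np.diff(edges)
            mids = edges + 0.5 * np.append(widths, np.median(widths) if len(widths) else 1.0)
            return np.maximum(np.asarray(spec(mids), dtype=float), 1e-12)
        spec = np.asarray(spec, dtype=float)
        if len(spec) != n_int:
            raise ValueError(
                f"baseline_means has {len(spec)} entries; need {n_int}"
            )
        return spec

    def _derived_piecewise(
        self, edges, cp, h, draws, d_pop, e_pop, d_stud, e_stud, d_arm, e_arm,
        have_arm, with_gamma,
    ) -> pd.DataFrame:
        widths = np.diff(edges)  # closed intervals only
        beta = draws["beta"].to_numpy()
        out = {}
        arms = {self.population_group: np.zeros_like(beta), self.study_group: beta}
        if with_gamma:
            arms[self.treatment_group or "treated"] = beta + draws["gamma"].to_numpy()
        for label, lhr in arms.items():
            out[f"mean_survival_{label}"] = _piecewise_mean_batch(h, widths, lhr)
        labels = list(arms)
        if len(labels) == 3:
            out["life_years_gained"] = (
                out[f"mean_survival_{labels[1]}"] - out[f"mean_survival_{labels[2]}"]
            )
        logh = np.log(h)
        out["deviance_pop"] = -2.0 * (logh @ d_pop - h @ e_pop)
        out["deviance_study"] = -2.0 * (
            logh @ d_stud + d_stud.sum() * beta - np.exp(beta) * (h @ e_stud)
        )
        total = out["deviance_pop"] + out["deviance_study"]
        if have_arm:
            lhr = beta + draws["gamma"].to_numpy()
            out["deviance_arm"] = -2.0 * (
                logh @ d_arm + d_arm.sum() * lhr - np.exp(lhr) * (h @ e_arm)
            )
            total = total + out["deviance_arm"]
        out["deviance_total"] = total
        return pd.DataFrame(out)

    def predict_survival_function(self, times, arm: Optional[str] = None):
        check_is_fitted(self, "posterior_")
        arm = arm or self.study_group
        beta = self.posterior_.draws["beta"].to_numpy()
        if arm == self.population_group:
            lhr = np.zeros_like(beta)
        elif arm == self.study_group:
            lhr = beta
        else:
            lhr = beta + self.posterior_.draws["gamma"].to_numpy()
        t = np.asarray(times, dtype=float)
        edges = np.concatenate(([0.0], self.change_points_))
        h = self.baseline_draws_
        j = np.searchsorted(self.change_points_, t, side="left")
        widths = np.diff(edges)
        cum_at_edges = np.concatenate(
            [np.zeros((h.shape[0], 1)), np.cumsum(h[:, :-1] * widths, axis=1)], axis=1
        )
        H = cum_at_edges[:, j] + h[:, j] * (t - edges[j])[None, :]
        return np.exp(-np.exp(lhr)[:, None] * H).mean(axis=0)


def _piecewise_mean_batch(h: np.ndarray, widths: np.ndarray, lhr: np.ndarray):
    """Mean survival per draw for the piecewise model (exact closed form)."""
    w = np.exp(lhr)[:, None]
    rates = w * h[:, :-1] * widths  # cumulative-hazard increments, closed intervals
    cum = np.concatenate([np.zeros((h.shape[0], 1)), np.cumsum(rates, axis=1)], axis=1)
    s_left = np.exp(-cum[:, :-1])
    seg = s_left * -np.expm1(-rates) / (w * h[:, :-1])
    tail = np.exp(-cum[:, -1]) / (w[:, 0] * h[:, -1])
    return seg.sum(axis=1) + tail


_CLASSES = {
    "poly-weibull": lambda **kw: PolyhazardExtrapolator(family=WEIBULL, **kw),
    "poly-gompertz": lambda **kw: PolyhazardExtrapolator(family=GOMPERTZ, **kw),
    "weibull-ph": WeibullPHExtrapolator,
    "cox-like": PiecewiseExtrapolator,
}


def make_estimator(variant: str, **kwargs):
    """Instantiate the estimator for a model variant name."""
    try:
        factory = _CLASSES[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(_CLASSES)}"
        ) from None
    return factory(**kwargs)


def fit_mcmc(
    pop_data: Optional[SurvivalData],
    study_data: SurvivalData,
    model_variant: str,
    priors: Optional[PriorSpec] = None,
    mcmc_config: Optional[dict] = None,
    second_arm_data: Optional[SurvivalData] = None,
) -> PosteriorSamples:
    """Functional front end: fit a variant by MCMC, return posterior samples.

    ``mcmc_config`` keys are passed to the estimator constructor (e.g.
    ``n_steps``, ``n_burn``, ``random_state``).
    """
    est = make_estimator(model_variant, priors=priors, **(mcmc_config or {}))
    frames = []
    for ds, label in (
        (pop_data, est.population_group),
        (study_data, est.study_group),
        (second_arm_data, est.treatment_group),
    ):
        if ds is None:
            continue
        f = ds.frame.copy()
        f["group"] = label
        frames.append(f)
    est.fit(SurvivalData(pd.concat(frames, ignore_index=True), validate=False))
    return est.posterior_
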