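"""Internal MCMC machinery: vectorized log-posteriors, the ensemble-sampler
driver for the parametric variants, and a univariate slice sampler used by
the Gibbs scheme of the piecewise model."""

from __future__ import annotations

from typing import Dict, Optional

import emcee
import numpy as np

from .data import SurvivalData
from .priors import PriorSpec

# Gauss-Legendre panels for batched mean-survival integrals over [0, 200]
# years.  64 nodes per panel is far beyond the accuracy needed for smooth
# parametric survivor functions (checked against adaptive quadrature).
_PANELS = ((0.0, 10.0), (10.0, 40.0), (40.0, 100.0), (100.0, 200.0))


def _gl_nodes():
    xs, ws = np.polynomial.legendre.leggauss(64)
    nodes, weights = [], []
    for a, b in _PANELS:
        nodes.append(0.5 * (b - a) * xs + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * ws)
    return np.concatenate(nodes), np.concatenate(weights)


_GL_T, _GL_W = _gl_nodes()
_GL_LOGT = np.log(_GL_T)


def _gomp_cumhaz_factor(a, t):
    """expm1(a*t)/a elementwise with the exponential limit at a -> 0.

    ``a`` has shape (..., 1) and ``t`` shape (n,)."""
    at = a * t
    small = np.abs(a) < 1e-10
    safe_a = np.where(small, 1.0, a)
    return np.where(small, t * (1.0 + 0.5 * at), np.expm1(at) / safe_a)


class _DataSummary:
    """Precomputed arrays for fast vectorized likelihood evaluation."""

    def __init__(self, ds: Optional[SurvivalData], n_causes: int = 2):
        if ds is None or len(ds) == 0:
            self.n = 0
            return
        self.n = len(ds)
        self.t = ds.time
        self.logt = np.log(self.t)
        d = ds.event == 1
        self.deaths = d
        self.t_death = self.t[d]
        self.logt_death = self.logt[d]
        self.n_deaths = int(d.sum())
        cause = ds.cause
        self.cause_deaths = []
        for k in range(1, n_causes + 1):
            if cause is None:
                self.cause_deaths.append(None)
            else:
                mk = d & (np.nan_to_num(cause, nan=-1) == k)
                self.cause_deaths.append(
                    {
                        "d": int(mk.sum()),
                        "sum_logt": float(self.logt[mk].sum()),
                        "sum_t": float(self.t[mk].sum()),
                    }
                )


class ParametricJointLogPost:
    """Vectorized log-posterior of the joint model, over walker batches.

    Parameter layout (columns of X):

    - ``poly-weibull``: log a_1, log a_2, sigma_1, sigma_2, beta[, gamma]
    - ``poly-gompertz``: a_1, a_2, s_1, s_2, beta[, gamma]  (s = 1/lam)
    - ``weibull-ph``: log a, sigma, beta[, gamma]

    sigma is the Weibull scale (lam = sigma**-a); beta the study log
    hazard ratio (cause-specific for polyhazard variants, all-cause for
    weibull-ph); gamma, present only when a treatment prior is set, the
    additional treated-arm log hazard ratio.
    """

    def __init__(
        self,
        variant: str,
        priors: PriorSpec,
        pop: Optional[SurvivalData],
        study: SurvivalData,
        arm: Optional[SurvivalData] = None,
    ):
        self.variant = variant
        self.priors = priors
        self.with_gamma = priors.gamma is not None
        if arm is not None and len(arm) and not self.with_gamma:
            raise ValueError("second-arm data require a gamma prior")
        self.pop = _DataSummary(pop)
        self.study = _DataSummary(study)
        self.arm = _DataSummary(arm)
        if variant in ("poly-weibull", "poly-gompertz"):
            if self.pop.n == 0:
                raise ValueError("polyhazard variants require population data")
            base = (
                ["log_alpha1", "log_alpha2", "sigma1", "sigma2"]
                if variant == "poly-weibull"
                else ["alpha1", "alpha2", "scale1", "scale2"]
            )
        elif variant == "weibull-ph":
            base = ["log_alpha", "sigma"]
        else:
            raise ValueError(f"unsupported parametric variant {variant!r}")
        self.param_names = base + ["beta"] + (["gamma"] if self.with_gamma else [])
        self.ndim = len(self.param_names)

    # -- priors --------------------------------------------------------
    def log_prior(self, X: np.ndarray) -> np.ndarray:
        p = self.priors
        lp = np.zeros(X.shape[0])
        if self.variant == "poly-weibull":
            la1, la2, s1, s2 = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
            lp += p.log_shape.logpdf(la1) + p.log_shape.logpdf(la2)
            ok = (s1 > 0) & (s1 < p.scale_upper) & (s2 > 0) & (s2 < p.scale_upper)
            if p.ordered_scales:
                ok &= s1 > s2  # lam_1 < lam_2 on the scale axis
            lp = np.where(ok, lp, -np.inf)
            ib = 4
        elif self.variant == "poly-gompertz":
            a1, a2, s1, s2 = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
            lp += p.gompertz_shape.logpdf(a1) + p.gompertz_shape.logpdf(a2)
            ok = (s1 > 0) & (s1 < p.scale_upper) & (s2 > 0) & (s2 < p.scale_upper)
            if p.ordered_scales:
                ok &= s1 > s2
            lp = np.where(ok, lp, -np.inf)
            ib = 4
        else:
            la, s = X[:, 0], X[:, 1]
            lp += p.log_shape.logpdf(la)
            lp = np.where((s > 0) & (s < p.scale_upper), lp, -np.inf)
            ib = 2
        lp = lp + p.beta.logpdf(X[:, ib])
        if self.with_gamma:
            lp = lp + p.gamma.logpdf(X[:, ib + 1])
        return lp

    # -- natural parameters --------------------------------------------
    def natural_params(self, X: np.ndarray) -> Dict[str, np.ndarray]:
        if self.variant == "poly-weibull":
            a1, a2 = np.exp(X[:, 0]), np.exp(X[:, 1])
            l1, l2 = X[:, 2] ** -a1, X[:, 3] ** -a2
            out = {"alpha1": a1, "alpha2": a2, "lambda1": l1, "lambda2": l2}
            ib = 4
        elif self.variant == "poly-gompertz":
            out = {
                "alpha1": X[:, 0],
                "alpha2": X[:, 1],
                "lambda1": 1.0 / X[:, 2],
                "lambda2": 1.0 / X[:, 3],
            }
            ib = 4
        else:
            a = np.exp(X[:, 0])
            out = {"alpha": a, "lambda": X[:, 1] ** -a}
            ib = 2
        out["beta"] = X[:, ib]
        if self.with_gamma:
            out["gamma"] = X[:, ib + 1]
        return out

    # -- likelihood ----------------------------------------------------
    def loglik_components(self, X: np.ndarray) -> Dict[str, np.ndarray]:
        """Per-draw log-likelihood, split by data source."""
        p = self.natural_params(X)
        if self.variant == "weibull-ph":
            return self._loglik_allcause(p)
        return self._loglik_polyhazard(p)

    def _weib_cumsum(self, a, logt):
        # sum_i t_i**a for each row of a:(W,) -> (W,)
        return np.exp(a[:, None] * logt[None, :]).sum(axis=1)

    def _loglik_polyhazard(self, p) -> Dict[str, np.ndarray]:
        weib = self.variant == "poly-weibull"
        a1, a2, l1, l2 = p["alpha1"], p["alpha2"], p["lambda1"], p["lambda2"]
        beta = p["beta"]
        out = {}
        # population cause-specific terms
        for k, (a, l) in enumerate(((a1, l1), (a2, l2)), start=1):
            cd = self.pop.cause_deaths[k - 1]
            if cd is None:
                raise ValueError("population data must be cause-labelled")
            if weib:
                cum = l * self._weib_cumsum(a, self.pop.logt)
                ev = cd["d"] * (np.log(l) + np.log(a)) + (a - 1.0) * cd["sum_logt"]
            else:
                cum = l * _gomp_cumhaz_factor(a[:, None], self.pop.t).sum(axis=1)
                ev = cd["d"] * np.log(l) + a * cd["sum_t"]
            out[f"pop_cause{k}"] = ev - cum
        # study (and optional second-arm) polyhazard terms
        for name, summ, lhr in (
            ("study", self.study, beta),
            ("arm", self.arm, beta + p["gamma"] if self.with_gamma else None),
        ):
            if summ.n == 0:
                continue
            if weib:
                cum = np.exp(lhr) * l1 * self._weib_cumsum(a1, summ.logt) + (
                    l2 * self._weib_cumsum(a2, summ.logt)
                )
                u1 = (
                    lhr[:, None]
                    + np.log(l1 * a1)[:, None]
                    + (a1 - 1.0)[:, None] * summ.logt_death[None, :]
                )
                u2 = (
                    np.log(l2 * a2)[:, None]
                    + (a2 - 1.0)[:, None] * summ.logt_death[None, :]
                )
            else:
                cum = np.exp(lhr) * l1 * _gomp_cumhaz_factor(
                    a1[:, None], summ.t
                ).sum(axis=1) + l2 * _gomp_cumhaz_factor(a2[:, None], summ.t).sum(
                    axis=1
                )
                u1 = (
                    lhr[:, None]
                    + np.log(l1)[:, None]
                    + a1[:, None] * summ.t_death[None, :]
                )
                u2 = np.log(l2)[:, None] + a2[:, None] * summ.t_death[None, :]
            ev = np.logaddexp(u1, u2).sum(axis=1) if summ.n_deaths else 0.0
            out[name] = ev - cum
        return out

    def _loglik_allcause(self, p) -> Dict[str, np.ndarray]:
        a, l, beta = p["alpha"], p["lambda"], p["beta"]
        out = {}
        for name, summ, lhr in (
            ("pop", self.pop, np.zeros_like(beta)),
            ("study", self.study, beta),
            ("arm", self.arm, beta + p["gamma"] if self.with_gamma else None),
        ):
            if summ.n == 0:
                continue
            cum = np.exp(lhr) * l * self._weib_cumsum(a, summ.logt)
            ev = summ.n_deaths * (lhr + np.log(l) + np.log(a)) + (
                a - 1.0
            ) * summ.logt_death.sum()
            out[name] = ev - cum
        return out

    def loglik(self, X: np.ndarray) -> np.ndarray:
        comps = self.loglik_components(X)
        return sum(comps.values())

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        lp = self.log_prior(X)
        ok = np.isfinite(lp)
        out = np.full(X.shape[0], -np.inf)
        if ok.any():
            out[ok] = lp[ok] + self.loglik(X[ok])
        return out


def initial_walkers(
    logpost,
    center: np.ndarray,
    spread: np.ndarray,
    n_walkers: int,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Draw walkers around ``center``, resampling any that land outside
    the posterior's support."""
    p0 = center + spread * rng.standard_normal((n_walkers, len(center)))
    for _ in range(max_tries):
        bad = ~np.isfinite(logpost(p0))
        if not bad.any():
            return p0
        p0[bad] = center + spread * rng.standard_normal((int(bad.sum()), len(center)))
    raise RuntimeError("could not initialize walkers inside the posterior support")


def run_ensemble(
    logpost,
    p0: np.ndarray,
    n_steps: int,
    seed: int,
) -> np.ndarray:
    """Run the affine-invariant ensemble sampler; returns the raw chain
    with shape (n_steps, n_walkers, ndim)."""
    n_walkers, ndim = p0.shape
    sampler = emcee.EnsembleSampler(n_walkers, ndim, logpost, vectorize=True)
    sampler.random_state = np.random.RandomState(seed % (2**32)).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    return sampler.get_chain()


def slice_sample(logpdf, x0: float, rng: np.random.Generator, width: float = 1.0,
                 max_steps: int = 50) -> float:
    """One update of a univariate slice sampler (stepping out + shrinkage)."""
    f0 = logpdf(x0)
    logy = f0 + np.log(rng.uniform())
    u = rng.uniform()
    lo, hi = x0 - width * u, x0 + width * (1.0 - u)
    for _ in range(max_steps):
        if logpdf(lo) < logy:
            break
        lo -= width
    for _ in range(max_steps):
        if logpdf(hi) < logy:
            break
        hi += width
    while True:
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


# -- batched mean-survival integrals ---------------------------------------


def mean_survival_weibull_batch(alpha: np.ndarray, lam_eff: np.ndarray) -> np.ndarray:
    """Mean survival for single-Weibull draws (closed form)."""
    from scipy.special import gammaln

    return np.exp(
        -np.log(lam_eff) / alpha + gammaln(1.0 + 1.0 / alpha)
    )


def mean_survival_poly_batch(
    variant: str,
    alphas: np.ndarray,  # (W, K)
    lams_eff: np.ndarray,  # (W, K) effect-scaled rates
) -> np.ndarray:
    """Mean survival per draw by Gauss-Legendre panels on [0, 200] years."""
    if variant == "poly-weibull":
        cum = np.zeros((alphas.shape[0], len(_GL_T)))
        for k in range(alphas.shape[1]):
            cum += lams_eff[:, k : k + 1] * np.exp(
                alphas[:, k : k + 1] * _GL_LOGT[None, :]
            )
    elif variant == "poly-gompertz":
        cum = np.zeros((alphas.shape[0], len(_GL_T)))
        for k in range(alphas.shape[1]):
            cum += lams_eff[:, k : k + 1] * _gomp_cumhaz_factor(
                alphas[:, k : k + 1], _GL_T
            )
    else:
        raise ValueError(variant)
    return np.exp(-cum) @ _GL_W
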