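"""Prior construction for the Bayesian survival-extrapolation models.

The weakly informative defaults express beliefs on interpretable scales,
for patients entering a study at around age 60:

- Weibull scale ``sigma_k = lam_k**(-1/a_k)`` ~ Uniform(0, 100) years:
  since a single-component mean survival is ``sigma * Gamma(1 + 1/a)``,
  this bounds prior mean survival at roughly 60-100 years, i.e. nobody
  survives much past age 160.
- log Weibull shape ~ Normal(0.5, 0.78^2): the sd is derived so that the
  hazard ratio over a doubling of time since entry, ``2**(a-1)``, has a
  95% prior interval of about (0.64, 100) with prior mean 1.5.
- Study:population log hazard ratio ``beta`` ~ Normal(0, 2.5^2): hazard
  ratio 95% interval about (1/150, 150).
- Treatment log hazard ratio ``gamma``: built from a published
  meta-analysis hazard ratio with 95% CI.
- Piecewise-baseline interval hazards ~ Gamma(c*mu_j, c) with
  concentration c = 200 and mean vector mu (the true hazard in
  simulations; a smoothed Nelson-Aalen estimate otherwise).
- Gompertz log-hazard slopes ``a_k`` ~ Normal, calibrated so the hazard
  ratio over a doubling of time (10 -> 20 years) has the same 95% prior
  interval as under the Weibull shape prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

__all__ = [
    "NormalPrior",
    "PriorSpec",
    "log_shape_prior_sd",
    "gamma_prior_from_hazard_ratio",
    "gompertz_shape_prior",
    "default_priors",
    "VARIANTS",
]

VARIANTS = ("poly-weibull", "poly-gompertz", "weibull-ph", "cox-like")

_Z975 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    sd: float

    def __post_init__(self):
        if not (self.sd > 0 and np.isfinite(self.sd)):
            raise ValueError(f"prior sd must be positive, got {self.sd}")

    def logpdf(self, x):
        return norm.logpdf(x, self.mean, self.sd)

    def rvs(self, size, rng):
        return rng.normal(self.mean, self.sd, size=size)


def log_shape_prior_sd(horizon: float = 100.0, prior_mean: float = 0.5) -> float:
    """Standard deviation of the Normal prior on log Weibull shape.

    Chosen so the upper 97.5% limit of the shape corresponds to a hazard
    ratio of ``horizon`` for a doubling of time since entry:
    ``(log(log(horizon)/log(2) + 1) - prior_mean) / z_0.975``.
    Evaluates to 0.78 for the default horizon of 100.
    """
    return float((np.log(np.log(horizon) / np.log(2.0) + 1.0) - prior_mean) / _Z975)


def gamma_prior_from_hazard_ratio(
    hazard_ratio: float,
    ci: Optional[Tuple[float, float]] = None,
    sd: Optional[float] = None,
) -> NormalPrior:
    """Normal prior on the treatment log hazard ratio gamma.

    ``gamma`` is oriented as (untreated : treated), so a protective
    published hazard ratio (treated : untreated) below 1 gives a positive
    prior mean ``-log(hazard_ratio)``.  The sd defaults to
    ``(log hi - log lo) / (2 * 1.96)`` from the 95% CI, or can be given
    directly (useful when reproducing a published sd that a symmetric-CI
    formula does not exactly recover).
    """
    if not (hazard_ratio > 0):
        raise ValueError("hazard ratio must be positive")
    mean = -np.log(hazard_ratio)
    if sd is None:
        if ci is None:
            raise ValueError("supply either a 95% CI or an sd for the gamma prior")
        lo, hi = ci
        if not (0 < lo < hazard_ratio < hi):
            raise ValueError(
                f"CI ({lo}, {hi}) must bracket the hazard ratio {hazard_ratio}"
            )
        sd = (np.log(hi) - np.log(lo)) / (2.0 * _Z975)
    if not (sd > 0):
        raise ValueError("gamma prior sd must be positive")
    return NormalPrior(float(mean), float(sd))


def gompertz_shape_prior(
    reference_time: float = 10.0,
    weibull_log_shape: Optional[NormalPrior] = None,
) -> NormalPrior:
    """Normal prior on the Gompertz slope a (per year).

    Calibrated so ``exp(a * t_ref)`` -- the hazard ratio over the time
    doubling t_ref -> 2*t_ref -- has the same 95% interval as the
    Weibull doubling-time hazard ratio ``2**(a_w - 1)`` under the
    Weibull log-shape prior.
    """
    wp = weibull_log_shape or NormalPrior(0.5, log_shape_prior_sd())
    aw_lo, aw_hi = (np.exp(wp.mean - _Z975 * wp.sd), np.exp(wp.mean + _Z975 * wp.sd))
    log_hr_lo, log_hr_hi = ((aw_lo - 1) * np.log(2), (aw_hi - 1) * np.log(2))
    a_lo, a_hi = log_hr_lo / reference_time, log_hr_hi / reference_time
    return NormalPrior((a_lo + a_hi) / 2.0, (a_hi - a_lo) / (2.0 * _Z975))


@dataclass(frozen=True)
class PriorSpec:
    """Full prior configuration for one model variant."""

    scale_upper: float = 100.0  # Uniform(0, scale_upper) on the Weibull scale, years
    log_shape: NormalPrior = field(
        default_factory=lambda: NormalPrior(0.5, log_shape_prior_sd())
    )
    beta: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 2.5))
    gamma: Optional[NormalPrior] = None
    gompertz_shape: NormalPrior = field(default_factory=gompertz_shape_prior)
    baseline_concentration: float = 200.0  # c in Gamma(c*mu_j, c)
    baseline_means: Optional[np.ndarray] = None  # mu_j per interval, or None
    ordered_scales: bool = True  # lam_1 < lam_2, i.e. sigma_1 > sigma_2

    def __post_init__(self):
        if not (self.scale_upper > 0):
            raise ValueError("scale_upper must be positive")
        if not (self.baseline_concentration > 0):
            raise ValueError("baseline concentration must be positive")
        if self.baseline_means is not None and np.any(
            np.asarray(self.baseline_means) <= 0
        ):
            raise ValueError("baseline prior means must be positive")

    def with_gamma(self, gamma: NormalPrior) -> "PriorSpec":
        return replace(self, gamma=gamma)


def default_priors(
    model_variant: str,
    treatment_hazard_ratio: Optional[float] = None,
    treatment_ci: Optional[Tuple[float, float]] = None,
    treatment_sd: Optional[float] = None,
) -> PriorSpec:
    """The standard priors for a model variant.

    If a meta-analysis treatment hazard ratio (with 95% CI, or a direct
    sd) is supplied, a gamma prior is attached with mean ``-log(HR)``.
    """
    if model_variant not in VARIANTS:
        raise ValueError(f"unknown variant {model_variant!r}; choose from {VARIANTS}")
    spec = PriorSpec()
    if model_variant in ("weibull-ph", "cox-like"):
        spec = replace(spec, ordered_scales=False)
    if treatment_hazard_ratio is not None:
        spec = spec.with_gamma(
            gamma_prior_from_hazard_ratio(
                treatment_hazard_ratio, treatment_ci, treatment_sd
            )
        )
    return spec
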