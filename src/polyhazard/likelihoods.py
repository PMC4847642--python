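"""Log-likelihood contributions for the joint survival models.

Four model variants share these building blocks:

- population cause-specific likelihood: independent parametric models per
  recorded cause, each individual contributing an event term for their
  recorded cause and a censored term (at the same time) for every other
  cause (independent competing risks);
- study polyhazard likelihood: causes unobserved, so death times follow
  the polyhazard distribution whose hazard is the sum of effect-scaled
  component hazards;
- joint likelihood: the product (sum of logs) of the above, with
  component parameters shared;
- misspecified comparators: an all-cause proportional-hazards Weibull and
  a semi-parametric model with a piecewise-constant baseline hazard
  ("Cox-like"), both ignoring cause labels.

All functions accumulate in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import SurvivalData
from .hazards import GroupEffects, HazardComponent, PolyhazardModel, WEIBULL

__all__ = [
    "pop_cause_loglik",
    "study_loglik",
    "joint_loglik",
    "arm_hazard",
    "weibull_ph_loglik",
    "PiecewiseBaseline",
    "piecewise_loglik",
]


def pop_cause_loglik(
    dataset: SurvivalData, cause: int, component: HazardComponent
) -> float:
    """Cause-specific log-likelihood of cause-labelled population data.

    ``sum_i [d_ik * log h_k(t_i) - H_k(t_i)]`` where ``d_ik = 1`` iff
    record i died of cause ``cause`` (1-based).  Deaths from other causes
    contribute as censored for this cause at their death time.
    """
    if len(dataset) == 0:
        return 0.0
    if not dataset.cause_labelled:
        raise ValueError("population dataset must be cause-labelled")
    t = dataset.time
    d = (dataset.event == 1) & (np.nan_to_num(dataset.cause, nan=-1) == cause)
    ll = -np.sum(component.cumulative_hazard(t))
    if d.any():
        ll += np.sum(component.log_hazard(t[d]))
    return float(ll)


def study_loglik(
    dataset: SurvivalData, model: PolyhazardModel, group: str = "study"
) -> float:
    """Polyhazard log-likelihood of data without cause labels.

    ``sum_j [d_j * log h(t_j) + log S(t_j)]`` with the group's
    effect-scaled overall hazard and survivor.
    """
    if len(dataset) == 0:
        return 0.0
    t = dataset.time
    d = dataset.event == 1
    ll = -np.sum(model.cumulative_hazard(t, group))
    if d.any():
        ll += np.sum(np.log(model.hazard(t[d], group)))
    return float(ll)


def joint_loglik(
    pop_data: Optional[SurvivalData],
    study_data: SurvivalData,
    model: PolyhazardModel,
    study_group: str = "study",
    second_arm_data: Optional[SurvivalData] = None,
    second_arm_group: str = "treated",
) -> float:
    """Joint log-likelihood with component parameters shared across terms.

    Population data (cause-labelled) contribute one cause-specific term
    per component; study data contribute the polyhazard term; an optional
    second treatment arm contributes a polyhazard term under its own
    group effects.
    """
    ll = study_loglik(study_data, model, study_group)
    if pop_data is not None and len(pop_data) > 0:
        causes = pop_data.cause
        observed = set(int(c) for c in causes[~np.isnan(causes)])
        if observed - set(range(1, model.n_components + 1)):
            raise ValueError(
                f"cause labels {sorted(observed)} exceed the model's "
                f"{model.n_components} components"
            )
        for k, comp in enumerate(model.components, start=1):
            ll += pop_cause_loglik(pop_data, k, comp)
    if second_arm_data is not None and len(second_arm_data) > 0:
        ll += study_loglik(second_arm_data, model, second_arm_group)
    return float(ll)


def arm_hazard(
    model: PolyhazardModel,
    arm: str,
    t,
    beta: Optional[float] = None,
    gamma: Optional[float] = None,
):
    """Overall hazard of one treatment arm under the three-arm convention.

    ``population``: h1 + h2; ``study``: e^beta h1 + h2;
    ``treated``: e^(gamma+beta) h1 + h2.  If ``beta``/``gamma`` are given
    they override any group effects stored in the model.
    """
    if beta is not None:
        effects = {
            "population": {},
            "study": {0: beta},
            "treated": {0: beta + (gamma if gamma is not None else 0.0)},
        }
        if arm not in effects:
            raise KeyError(f"unknown arm {arm!r}")
        model = PolyhazardModel(
            model.components,
            [GroupEffects(a, e) for a, e in effects.items() if a != "population"],
        )
    return model.hazard(t, arm)


def weibull_ph_loglik(
    pop_data: Optional[SurvivalData],
    study_data: SurvivalData,
    shape: float,
    rate: float,
    log_hr: float,
    second_arm_data: Optional[SurvivalData] = None,
    gamma: float = 0.0,
) -> float:
    """All-cause Weibull proportional-hazards log-likelihood.

    Ignores cause labels: population terms use rate ``lam``, study terms
    ``e^beta * lam``, and an optional second arm ``e^(beta+gamma) * lam``,
    all with common shape.
    """
    ll = 0.0
    for ds, lhr in (
        (pop_data, 0.0),
        (study_data, log_hr),
        (second_arm_data, log_hr + gamma),
    ):
        if ds is None or len(ds) == 0:
            continue
        comp = HazardComponent(WEIBULL, shape, rate * np.exp(lhr))
        t = ds.time
        d = ds.event == 1
        ll += -np.sum(comp.cumulative_hazard(t))
        if d.any():
            ll += np.sum(comp.log_hazard(t[d]))
    return float(ll)


@dataclass(frozen=True)
class PiecewiseBaseline:
    """Piecewise-constant baseline hazard with change points at death times.

    ``change_points`` are the strictly increasing interior breakpoints
    (deduplicated observed death times); ``hazards`` has one value per
    interval, ``len(change_points) + 1`` in total, the last applying to
    the open-ended interval beyond the last change point (its hazard
    extrapolates indefinitely).  The hazard on interval j applies to
    times in ``(c_{j-1}, c_j]`` so that a death at a change point uses
    the hazard of the interval it terminates.
    """

    change_points: np.ndarray
    hazards: np.ndarray

    def __post_init__(self):
        cp = np.asarray(self.change_points, dtype=float)
        hz = np.asarray(self.hazards, dtype=float)
        if np.any(cp <= 0) or np.any(np.diff(cp) <= 0):
            raise ValueError("change points must be strictly increasing and positive")
        if len(hz) != len(cp) + 1:
            raise ValueError("need one hazard per interval (len(change_points)+1)")
        if np.any(hz <= 0):
            raise ValueError("interval hazards must be positive")
        object.__setattr__(self, "change_points", cp)
        object.__setattr__(self, "hazards", hz)

    @classmethod
    def from_death_times(cls, times, hazards=None) -> "PiecewiseBaseline":
        """Build from observed death times (ties deduplicated)."""
        cp = np.unique(np.asarray(times, dtype=float))
        if hazards is None:
            hazards = np.full(len(cp) + 1, 0.1)
        return cls(cp, hazards)

    def _interval_index(self, t):
        # t in (c_{j-1}, c_j] -> j ; t > c_last -> last interval
        return np.searchsorted(self.change_points, np.asarray(t, float), side="left")

    def hazard(self, t):
        return self.hazards[self._interval_index(t)]

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        widths = np.diff(np.concatenate(([0.0], self.change_points)))
        cum = np.concatenate(([0.0], np.cumsum(self.hazards[:-1] * widths)))
        j = self._interval_index(t)
        left = np.concatenate(([0.0], self.change_points))[j]
        return cum[j] + self.hazards[j] * (t - left)

    def mean_survival(self, log_hr: float = 0.0) -> float:
        """Exact area under exp(-e^log_hr * H0(t)), extrapolating the
        final interval's hazard to infinity."""
        w = np.exp(log_hr)
        edges = np.concatenate(([0.0], self.change_points))
        widths = np.diff(edges)
        total = 0.0
        s_left = 1.0
        for h, dt in zip(self.hazards[:-1], widths):
            rate = w * h
            total += s_left * -np.expm1(-rate * dt) / rate
            s_left *= np.exp(-rate * dt)
        total += s_left / (w * self.hazards[-1])
        return float(total)


def piecewise_loglik(
    pop_data: Optional[SurvivalData],
    study_data: SurvivalData,
    baseline: PiecewiseBaseline,
    log_hr: float,
    second_arm_data: Optional[SurvivalData] = None,
    gamma: float = 0.0,
) -> float:
    """Semi-parametric proportional-hazards log-likelihood.

    Population records use the step baseline hazard; study records scale
    it by ``e^log_hr`` (second arm by ``e^(log_hr+gamma)``).  Times beyond
    the last change point use the final interval's hazard.
    """
    ll = 0.0
    for ds, lhr in (
        (pop_data, 0.0),
        (study_data, log_hr),
        (second_arm_data, log_hr + gamma),
    ):
        if ds is None or len(ds) == 0:
            continue
        t = ds.time
        d = ds.event == 1
        ll += -np.exp(lhr) * np.sum(baseline.cumulative_hazard(t))
        if d.any():
            ll += np.sum(lhr + np.log(baseline.hazard(t[d])))
    return float(ll)
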