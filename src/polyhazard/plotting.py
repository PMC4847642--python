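"""Plots of fitted survivor and log-hazard curves by treatment arm."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["plot_survival_curves", "plot_log_hazards"]


def plot_survival_curves(
    estimator,
    arms: Optional[Sequence[str]] = None,
    max_time: float = 50.0,
    ax=None,
):
    """Posterior-mean survivor curves for one fitted estimator."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = np.linspace(0.0, max_time, 200)
    for arm in arms or estimator.mean_survival_:
        ax.plot(t, estimator.predict_survival_function(t, arm=arm), label=arm)
    ax.set_xlabel("years since entry")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_log_hazards(
    estimator,
    arms: Optional[Sequence[str]] = None,
    max_time: float = 50.0,
    ax=None,
):
    """Posterior-mean log overall hazard by arm (finite-difference of the
    posterior-mean cumulative hazard)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = np.linspace(0.05, max_time, 400)
    for arm in arms or estimator.mean_survival_:
        s = estimator.predict_survival_function(t, arm=arm)
        h = -np.gradient(np.log(np.maximum(s, 1e-300)), t)
        ax.plot(t, np.log(np.maximum(h, 1e-300)), label=arm)
    ax.set_xlabel("years since entry")
    ax.set_ylabel("log hazard")
    ax.legend()
    return ax
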