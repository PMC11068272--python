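"""Posterior trajectory summaries on a time grid.

A skyline envelope is drawn by evaluating each posterior sample's Ne(t) on
a common grid and taking per-time quantiles — quantiles of the function
values, not of the parameters.  Quantiles use linear interpolation of the
order statistics (type 7, the numpy default), and the "exponential" grid
is equally spaced in log(1 + t) so it can include the present (t = 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demography import DemographicTrajectory

__all__ = ["exponential_grid", "ne_matrix", "summarize_trace", "plot_summary"]

SUMMARY_COLUMNS = ("time", "ne_median", "ne_lower_2.5", "ne_upper_97.5")


def exponential_grid(t_max: float, n_points: int = 500) -> np.ndarray:
    """n_points grid times with log(1 + t) equally spaced between 0 and
    log(1 + t_max): g_i = exp(log(1 + t_max)·i/(n−1)) − 1."""
    if t_max <= 0 or n_points < 2:
        raise ValueError("need t_max > 0 and n_points >= 2")
    return np.expm1(np.log1p(t_max) * np.arange(n_points) / (n_points - 1))


def ne_matrix(trace, grid) -> np.ndarray:
    """Ne evaluated for every trace sample at every grid time
    (shape n_samples × n_grid)."""
    grid = np.asarray(grid, float)
    mode = getattr(trace, "mode", "constant")
    rows = [
        DemographicTrajectory(x, rho, mode=mode).ne_at(grid)
        for x, rho in trace.trajectories()
    ]
    if not rows:
        raise ValueError("empty trace")
    return np.asarray(rows)


def summarize_trace(trace, grid) -> pd.DataFrame:
    """Per-grid-time posterior median and central 95% credible interval of
    Ne.  Returns a frame with columns time, ne_median, ne_lower_2.5,
    ne_upper_97.5."""
    grid = np.asarray(grid, float)
    mat = ne_matrix(trace, grid)
    lo, med, hi = np.quantile(mat, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "time": grid,
            "ne_median": med,
            "ne_lower_2.5": lo,
            "ne_upper_97.5": hi,
        }
    )


def plot_summary(summary: pd.DataFrame, ax=None, log_time: bool = False, log_ne: bool = True):
    """Median trajectory with shaded 95% credible band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(
        summary["time"], summary["ne_lower_2.5"], summary["ne_upper_97.5"], alpha=0.3
    )
    ax.plot(summary["time"], summary["ne_median"], lw=2)
    if log_time:
        ax.set_xscale("log")
    if log_ne:
        ax.set_yscale("log")
    ax.set_xlabel("time before present")
    ax.set_ylabel("effective population size")
    ax.invert_xaxis()
    return ax
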