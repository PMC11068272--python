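"""Model / Results interface for Bayesian skyline inference.

``CoalescentSkylineModel`` binds data (one genealogy, a multi-locus set,
or a posterior sample of genealogies) to one of the nine trajectory prior
models; ``fit()`` runs the replicate MCMC and returns a
``SkylineResults`` carrying the trace, trajectory credible envelopes,
convergence diagnostics and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import mcmc as _mcmc
from . import summary as _summary
from .genealogy import read_genealogies, read_genealogy, read_tip_ages
from .priors import MODEL_NAMES, PriorSpec

__all__ = ["CoalescentSkylineModel", "SkylineResults"]


class CoalescentSkylineModel:
    """A coalescent skyline plot model bound to genealogy data.

    Parameters
    ----------
    data
        A ``Genealogy``, a list of genealogies (multi-locus; requires a
        model with change-points independent of coalescent events), a
        ``GenealogySample`` for sequential inference, or None for
        prior-only runs.
    prior
        One of {constant, skyline, bsp, ebsp, skyride, skygrid, gmrf,
        hsmrf, skyfish}.
    mode
        Per-interval demographic function: "constant" or "linear".
    t_max
        Horizon for the specified-change-point models and skyfish;
        defaults to 1.25 × the oldest coalescent event in the data.
    n_intervals
        Interval count for the equal-grid models (default 50).
    hyper
        Hyperparameter overrides for the model's defaults.
    """

    def __init__(
        self,
        data,
        prior: str = "constant",
        mode: str = "constant",
        t_max: float | None = None,
        n_intervals: int | None = None,
        hyper: dict | None = None,
    ):
        if prior not in MODEL_NAMES:
            raise ValueError(f"unknown prior model {prior!r}")
        self.data = data
        self.spec = PriorSpec(prior, dict(hyper or {}))
        self.mode = mode
        self.t_max = t_max
        self.n_intervals = n_intervals

    @classmethod
    def from_files(
        cls,
        newick_path,
        ages_path,
        multi_tree: bool = False,
        **kwargs,
    ) -> "CoalescentSkylineModel":
        """Build from a Newick file (single- or multi-tree, one per line)
        and a two-column tip-age TSV."""
        newick = Path(newick_path).read_text()
        ages = read_tip_ages(Path(ages_path).read_text())
        if multi_tree:
            data = read_genealogies(newick, ages)
            if len(data) == 1:
                data = data[0]
        else:
            data = read_genealogy(newick, ages)
        return cls(data, **kwargs)

    def fit(
        self,
        iterations: int = 100_000,
        thinning: int = 10,
        burn_in_fraction: float = 0.1,
        n_replicates: int = 2,
        seed: int | None = None,
        settings: _mcmc.MCMCSettings | None = None,
        likelihood_off: bool = False,
    ) -> "SkylineResults":
        """Run the replicate MCMC and return the results object."""
        settings = settings or _mcmc.MCMCSettings(
            iterations=iterations,
            thinning=thinning,
            burn_in_fraction=burn_in_fraction,
            n_replicates=n_replicates,
            seed=seed,
        )
        trace = _mcmc.run_mcmc(
            self.spec,
            self.data,
            settings,
            mode=self.mode,
            t_max=self.t_max,
            n_intervals=self.n_intervals,
            likelihood_off=likelihood_off,
        )
        return SkylineResults(model=self, trace=trace)

    def log_marginal_likelihood(
        self,
        n_stones: int = 128,
        iterations_per_stone: int = 5000,
        seed: int | None = None,
        **kwargs,
    ) -> float:
        """Stepping-stone log marginal likelihood of this model."""
        return _mcmc.stepping_stone(
            self.spec,
            self.data,
            n_stones,
            iterations_per_stone,
            seed=seed,
            mode=self.mode,
            t_max=self.t_max,
            n_intervals=self.n_intervals,
            **kwargs,
        )


@dataclass
class SkylineResults:
    """Posterior results of a fitted coalescent skyline plot model."""

    model: CoalescentSkylineModel
    trace: _mcmc.MCMCTrace

    @property
    def n_samples(self) -> int:
        return len(self.trace.df)

    def _default_grid(self, n_points: int = 500) -> np.ndarray:
        t_max = self.model.t_max
        if t_max is None:
            trees = _mcmc._data_trees(self.model.data)
            if trees:
                t_max = 1.25 * max(g.tmrca for g in trees)
            else:
                t_max = max(max(float(x.max()), 1.0) for x, _ in self.trace.trajectories())
        return _summary.exponential_grid(t_max, n_points)

    def trajectory_summary(self, grid=None, n_points: int = 500) -> pd.DataFrame:
        """Median and 95% credible interval of Ne on a time grid
        (exponentially spaced by default)."""
        if grid is None:
            grid = self._default_grid(n_points)
        return _summary.summarize_trace(self.trace, grid)

    def convergence(self, grid=None, threshold: float = 0.05, n_points: int = 25):
        """Replicate-agreement diagnostic: per-grid-time KS distance
        between the two replicates' log-Ne samples."""
        reps = _mcmc.split_replicates(self.trace)
        if len(reps) < 2:
            raise ValueError("convergence checking needs at least two replicates")
        if grid is None:
            grid = self._default_grid(n_points)
        return _mcmc.check_convergence(reps[0], reps[1], grid, threshold=threshold)

    def plot(self, grid=None, **kwargs):
        return _summary.plot_summary(self.trajectory_summary(grid), **kwargs)

    def save_trace(self, path) -> None:
        self.trace.to_tsv(path)

    def summary(self, grid=None) -> str:
        """Printable overview: run settings, acceptance rates, and the Ne
        envelope at a handful of grid times."""
        s = self.trace.settings
        lines = [
            "Coalescent skyline plot model results",
            "=" * 53,
            f"prior model:        {self.trace.model}",
            f"interval function:  {self.trace.mode}",
            f"retained samples:   {self.n_samples}",
        ]
        if s is not None:
            lines.append(
                f"iterations:         {s.iterations} x {s.n_replicates} replicates, "
                f"thinning {s.thinning}, burn-in {s.burn_in_fraction:.0%}"
            )
        if "kappa" in self.trace.df.columns:
            kappa = self.trace.df["kappa"]
            lines.append(
                f"change-points:      mean {kappa.mean():.2f} "
                f"(95% CI {kappa.quantile(0.025):.0f}-{kappa.quantile(0.975):.0f})"
            )
        summ = self.trajectory_summary(grid, n_points=6 if grid is None else None)
        lines.append("-" * 53)
        lines.append(f"{'time':>12}  {'Ne median':>12}  {'2.5%':>11}  {'97.5%':>11}")
        for _, row in summ.iterrows():
            lines.append(
                f"{row['time']:>12.4g}  {row['ne_median']:>12.5g}  "
                f"{row['ne_lower_2.5']:>11.5g}  {row['ne_upper_97.5']:>11.5g}"
            )
        lines.append("=" * 53)
        return "\n".join(lines)
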