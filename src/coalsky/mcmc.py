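"""Metropolis–Hastings and reversible-jump MCMC over skyline model states,
replicate management, convergence checking, and stepping-stone marginal
likelihoods.

One sweep updates every free positive parameter with a multiplier
(scale) move, slides each skyfish change-point (reflected at [0, tMAX]),
and makes one dimension-changing move for the trans-dimensional models
(skyfish birth/death, ebsp activation toggle).  Proposal windows are
auto-tuned toward 44% acceptance during burn-in only and frozen afterward
so the post-burn-in chain satisfies detailed balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import ks_2samp

from . import summary as _summary
from .demography import ChangePointScheme, equal_grid, events_grouping
from .density import CoalescentLikelihood
from .genealogy import Genealogy
from .priors import (
    PriorSpec,
    _lpdf_lognormal,
    make_prior_model,
)

__all__ = [
    "MCMCSettings",
    "MCMCTrace",
    "GenealogySample",
    "raw_sample_count",
    "retained_sample_count",
    "scale_move",
    "slide_reflect",
    "rj_birth_death_move",
    "ebsp_toggle_move",
    "run_mcmc",
    "check_convergence",
    "stepping_stone",
    "bayes_factor",
]


@dataclass
class MCMCSettings:
    """Run-length and proposal configuration.

    The defaults reproduce the standard analysis settings: 100,000
    iterations, sampling every 10th, 10% burn-in, two replicate runs —
    18,000 retained samples in total.
    """

    iterations: int = 100_000
    thinning: int = 10
    burn_in_fraction: float = 0.1
    n_replicates: int = 2
    seed: int | None = None
    tune: bool = True
    tuning_target: float = 0.44
    initial_tuning: float = 2.0
    rj_sd: float = 1.0
    slide_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.thinning < 1:
            raise ValueError("iterations > 0 and thinning >= 1 required")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")


def raw_sample_count(iterations: int, thinning: int) -> int:
    """Samples recorded per replicate before burn-in removal."""
    return iterations // thinning

def retained_sample_count(
    iterations: int, thinning: int, burn_in_fraction: float, n_replicates: int
) -> int:
    """Pooled sample count after per-replicate burn-in removal."""
    per = iterations // thinning
    return n_replicates * (per - int(burn_in_fraction * per))


@dataclass
class GenealogySample:
    """A posterior sample of genealogies for sequential inference, with the
    coalescent log-density each sample had under the first analysis."""

    genealogies: list
    reference_log_densities: np.ndarray

    def __post_init__(self) -> None:
        self.genealogies = list(self.genealogies)
        self.reference_log_densities = np.asarray(self.reference_log_densities, float)
        if len(self.genealogies) == 0:
            raise ValueError("empty genealogy sample")
        if len(self.genealogies) != len(self.reference_log_densities):
            raise ValueError("one reference log-density per genealogy")


@dataclass
class MCMCTrace:
    """Retained posterior samples, one row per sample.

    The ``x`` and ``rho`` columns hold comma-joined change-point times and
    per-interval population sizes so that variable-dimension (skyfish)
    states fit the same tabular format.
    """

    df: pd.DataFrame
    model: str
    mode: str = "constant"
    acceptance: dict = field(default_factory=dict)
    settings: MCMCSettings | None = None

    def trajectories(self):
        for xs, rs in zip(self.df["x"], self.df["rho"]):
            yield _parse_floats(xs), _parse_floats(rs)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, model: str = "", mode: str = "constant") -> "MCMCTrace":
        return cls(df=pd.read_csv(path, sep="\t"), model=model, mode=mode)


def _join_floats(a) -> str:
    return ",".join(f"{v:.10g}" for v in np.atleast_1d(a))


def _parse_floats(s) -> np.ndarray:
    return np.fromstring(str(s), sep=",")


# -- elementary moves --------------------------------------------------------


def scale_move(value: float, tuning: float, rng: np.random.Generator):
    """Multiplier proposal for a positive parameter:
    value · exp(tuning·(u−1/2)); log Hastings ratio log(proposal/value)."""
    factor = tuning * (rng.random() - 0.5)
    # log(proposal/value) equals the exponent even when the product
    # under/overflows double range
    return value * math.exp(factor), factor


def slide_reflect(value: float, width: float, lo: float, hi: float, rng: np.random.Generator) -> float:
    """Symmetric sliding proposal reflected at the interval bounds."""
    prop = value + width * (rng.random() - 0.5)
    span = hi - lo
    prop = (prop - lo) % (2.0 * span)
    if prop > span:
        prop = 2.0 * span - prop
    return lo + prop


def _safe_log(x: float) -> float:
    return math.log(x) if x > 0.0 else -math.inf


def rj_birth_death_move(
    state: dict,
    t_max: float,
    tuning: float,
    rng: np.random.Generator,
    p_birth: float = 0.5,
):
    """Skyfish reversible-jump birth/death move.

    Birth: a new change-point ξ* ~ Uniform(0, tMAX) splits its containing
    interval; the new interval's log-size is drawn from a Normal centered
    on the current log population size at ξ* with sd ``tuning``.  Death:
    a uniformly chosen change-point and its size are removed.  Returns
    (proposal_state, log q(reverse)/q(forward)), or None when a death is
    proposed at κ = 0 (auto-rejected).  The identity dimension map has
    unit Jacobian; the prior ratio enters through the full prior density
    difference computed by the caller.
    """
    kappa = int(state["kappa"])
    xi, rho = state["xi"], state["rho"]
    if rng.random() < p_birth:
        xi_new = rng.uniform(0.0, t_max)
        j = int(np.searchsorted(xi, xi_new))
        center = math.log(rho[j])
        rho_new = math.exp(rng.normal(center, tuning))
        new = dict(state)
        new["kappa"] = kappa + 1
        new["xi"] = np.insert(xi, j, xi_new)
        new["rho"] = np.insert(rho, j + 1, rho_new)
        log_q_fwd = (
            _safe_log(p_birth)
            - math.log(t_max)
            + _lpdf_lognormal(rho_new, center, tuning)
        )
        log_q_rev = _safe_log(1.0 - p_birth) - math.log(kappa + 1)
        return new, log_q_rev - log_q_fwd
    if kappa == 0:
        return None
    j = int(rng.integers(kappa))
    removed = rho[j + 1]
    new = dict(state)
    new["kappa"] = kappa - 1
    new["xi"] = np.delete(xi, j)
    new["rho"] = np.delete(rho, j + 1)
    log_q_fwd = _safe_log(1.0 - p_birth) - math.log(kappa)
    log_q_rev = (
        _safe_log(p_birth)
        - math.log(t_max)
        + _lpdf_lognormal(removed, math.log(rho[j]), tuning)
    )
    return new, log_q_rev - log_q_fwd


def ebsp_toggle_move(
    state: dict,
    mean: float,
    rng: np.random.Generator,
    index: int | None = None,
):
    """Toggle one EBSP candidate change-point between "tied to the previous
    interval" and "free, exponentially distributed".

    Activation draws the new size from its Exponential(mean) prior, so the
    proposal density cancels the prior term; the α_eq prior odds enter via
    the full prior difference computed by the caller.  Returns
    (proposal_state, log q(reverse)/q(forward)).
    """
    active = state["active"]
    if len(active) == 0:
        return None
    if index is None:
        index = int(rng.integers(len(active)))
    new = dict(state)
    new["active"] = active.copy()
    new["values"] = state["values"].copy()
    if active[index]:
        new["active"][index] = False
        old_value = state["values"][index + 1]
        log_q_fwd = 0.0
        log_q_rev = math.log(1.0 / mean) - old_value / mean
    else:
        new["active"][index] = True
        v = rng.exponential(scale=mean)
        new["values"][index + 1] = v
        log_q_fwd = math.log(1.0 / mean) - v / mean
        log_q_rev = 0.0
    return new, log_q_rev - log_q_fwd


# -- target assembly ---------------------------------------------------------


def _default_layout(spec: PriorSpec, data, t_max, n_intervals):
    """Per-model change-point layout: fixed x vector (or None for skyfish)
    plus the interval count."""
    model = spec.model
    trees = _data_trees(data)
    if t_max is None and trees:
        t_max = 1.25 * max(g.tmrca for g in trees)

    if model == "skyfish":
        if t_max is None:
            raise ValueError("skyfish needs t_max (no data to derive it from)")
        return None, None, t_max

    if model == "constant":
        return np.array([0.0]), 1, t_max

    if model in ("skyline", "bsp", "ebsp", "skyride"):
        if not trees:
            if n_intervals is None:
                raise ValueError(f"{model} without data needs n_intervals")
            return None, n_intervals, t_max
        if len(trees) > 1:
            raise ValueError(
                f"{model} uses coalescent-event change-points, which are "
                "locus-specific; multi-locus data needs a specified-method model"
            )
        g = trees[0]
        n_ev = g.n_tips - 1
        if model in ("skyline", "bsp"):
            counts = events_grouping(n_ev, 5)
        else:
            counts = np.ones(n_ev, dtype=int)
        scheme = ChangePointScheme("events", events_per_interval=counts)
        x = scheme.resolve(g)
        return x, len(x), t_max

    # skygrid / gmrf / hsmrf: equal grid of specified change-points
    if n_intervals is None:
        n_intervals = 50
    if t_max is None:
        raise ValueError(f"{model} needs t_max for its equal interval grid")
    return equal_grid(t_max, n_intervals), n_intervals, t_max


def _data_trees(data):
    if data is None:
        return []
    if isinstance(data, Genealogy):
        return [data]
    if isinstance(data, GenealogySample):
        return data.genealogies
    return list(data)


def _make_loglik(data, pm, x_fixed, mode):
    """Build a state -> log-likelihood closure for the data variant."""
    model = pm.spec.model

    def state_xr(state):
        if model == "skyfish":
            return pm.changepoints(state), state["rho"]
        return x_fixed, pm.rho_vector(state)

    if data is None:
        return lambda state: 0.0

    if isinstance(data, GenealogySample):
        evals = [CoalescentLikelihood([g], mode) for g in data.genealogies]
        refs = data.reference_log_densities
        logm = math.log(len(evals))

        def seq_ll(state):
            x, rho = state_xr(state)
            ll = np.array([ev.loglik(x, rho) for ev in evals])
            return float(logsumexp(ll - refs) - logm)

        return seq_ll

    trees = [data] if isinstance(data, Genealogy) else list(data)
    clike = CoalescentLikelihood(trees, mode)
    if mode == "constant" and x_fixed is not None and model != "skyfish":
        A, c = clike.cache(x_fixed)

        def cached_ll(state):
            return CoalescentLikelihood.loglik_cached(A, c, pm.rho_vector(state))

        return cached_ll

    def generic_ll(state):
        x, rho = state_xr(state)
        return clike.loglik(x, rho)

    return generic_ll


class _Sampler:
    """One MH/RJ chain over a model state, with burn-in auto-tuning."""

    def __init__(self, pm, loglik_fn, settings: MCMCSettings, rng, power: float = 1.0):
        self.pm = pm
        self.loglik_fn = loglik_fn
        self.settings = settings
        self.rng = rng
        self.power = power
        self.tunings: dict[str, float] = {}
        self.acc: dict[str, list[int]] = {}
        self.rates: dict[str, tuple[int, int]] = {}

    # tuning bookkeeping -----------------------------------------------------

    def _tuning(self, key):
        return self.tunings.setdefault(key, self.settings.initial_tuning)

    def _record(self, key, accepted, adapting):
        tries, accs = self.rates.get(key, (0, 0))
        self.rates[key] = (tries + 1, accs + int(accepted))
        if not adapting or not self.settings.tune or key not in self.tunings:
            return
        batch = self.acc.setdefault(key, [0, 0])
        batch[0] += 1
        batch[1] += int(accepted)
        if batch[0] >= 50:
            rate = batch[1] / batch[0]
            t = self.tunings[key] * math.exp(rate - self.settings.tuning_target)
            self.tunings[key] = min(max(t, 1e-3), 50.0)
            self.acc[key] = [0, 0]

    # state initialisation ---------------------------------------------------

    def init_state(self):
        for _ in range(1000):
            state = self.pm.sample_prior(self.rng)
            lp = self.pm.log_prior(state)
            if not np.isfinite(lp):
                continue
            ll = self.loglik_fn(state)
            if np.isfinite(ll) or (self.power == 0.0 and ll == -np.inf):
                self.state, self.lp, self.ll = state, lp, ll
                return
        raise RuntimeError("no finite-probability initial state in 1,000 prior draws")

    # move machinery ---------------------------------------------------------

    def _try(self, new_state, log_hastings, key, adapting):
        new_lp = self.pm.log_prior(new_state)
        if np.isfinite(new_lp):
            new_ll = self.loglik_fn(new_state)
            # at power 0 the likelihood drops out entirely (0·(-inf) traps)
            delta_ll = 0.0 if self.power == 0.0 else self.power * (new_ll - self.ll)
            log_alpha = delta_ll + new_lp - self.lp + log_hastings
            accepted = math.log(self.rng.random()) < log_alpha
        else:
            accepted = False
        if accepted:
            self.state, self.lp, self.ll = new_state, new_lp, new_ll
        self._record(key, accepted, adapting)

    def sweep(self, adapting: bool):
        pm, state, rng = self.pm, self.state, self.rng
        model = pm.spec.model

        for key, idx in pm.scale_components(state):
            tkey = f"scale:{key}"
            cur = state[key] if idx is None else state[key][idx]
            prop, lh = scale_move(float(cur), self._tuning(tkey), rng)
            new = dict(state)
            if idx is None:
                new[key] = prop
            else:
                arr = state[key].copy()
                arr[idx] = prop
                new[key] = arr
            self._try(new, lh, tkey, adapting)
            state = self.state

        if model == "skyfish":
            width = self.settings.slide_fraction * pm.t_max
            for i in range(int(state["kappa"])):
                xi = state["xi"]
                prop = slide_reflect(float(xi[i]), width, 0.0, pm.t_max, rng)
                new_xi = xi.copy()
                new_xi[i] = prop
                if np.any(np.diff(new_xi) < 0):
                    self._record("slide:xi", False, adapting)
                    continue
                new = dict(state)
                new["xi"] = new_xi
                self._try(new, 0.0, "slide:xi", adapting)
                state = self.state
            res = rj_birth_death_move(state, pm.t_max, self.settings.rj_sd, rng)
            if res is None:
                self._record("rj:birth_death", False, adapting)
            else:
                self._try(res[0], res[1], "rj:birth_death", adapting)
        elif model == "ebsp":
            res = ebsp_toggle_move(self.state, self.state["mean"], rng)
            if res is not None:
                self._try(res[0], res[1], "rj:toggle", adapting)

    def acceptance_rates(self):
        return {k: (a / t if t else 0.0) for k, (t, a) in self.rates.items()}


def _state_row(pm, state, x_fixed):
    model = pm.spec.model
    row = {}
    if model == "skyfish":
        row["kappa"] = int(state["kappa"])
        row["sigma"] = state["sigma"]
        x = pm.changepoints(state)
        rho = state["rho"]
    else:
        x = x_fixed
        rho = pm.rho_vector(state)
        for key in ("tau", "gamma", "mean"):
            if key in state:
                row[key] = state[key]
        if "sigma" in state and isinstance(state["sigma"], np.ndarray):
            row["sigma_local"] = _join_floats(state["sigma"])
        if "active" in state:
            row["n_active"] = int(state["active"].sum())
    row["x"] = _join_floats(x) if x is not None else ""
    row["rho"] = _join_floats(rho)
    return row


def run_mcmc(
    prior_spec: PriorSpec,
    data,
    settings: MCMCSettings | None = None,
    *,
    mode: str = "constant",
    t_max: float | None = None,
    n_intervals: int | None = None,
    likelihood_off: bool = False,
) -> MCMCTrace:
    """Run replicate MH/RJ-MCMC chains targeting posterior ∝ likelihoodᵖᵒʷ × prior.

    ``data`` is a single Genealogy, a list of genealogies (multi-locus,
    specified change-points only), a GenealogySample (sequential
    inference), or None for a prior-only run (as is ``likelihood_off``).
    Seeded runs are reproducible; per-move acceptance rates are attached
    to the returned trace.
    """
    settings = settings or MCMCSettings()
    if likelihood_off:
        data = None
    x_fixed, L, t_max = _default_layout(prior_spec, data, t_max, n_intervals)
    pm = make_prior_model(prior_spec, L if L is not None else 1, t_max)
    loglik_fn = _make_loglik(data, pm, x_fixed, mode)

    per_rep = raw_sample_count(settings.iterations, settings.thinning)
    drop = int(settings.burn_in_fraction * per_rep)
    burn_iters = int(settings.burn_in_fraction * settings.iterations)

    seed_seq = np.random.SeedSequence(settings.seed)
    rows = []
    acceptance = {}
    for rep, child in enumerate(seed_seq.spawn(settings.n_replicates), start=1):
        rng = np.random.default_rng(child)
        sampler = _Sampler(pm, loglik_fn, settings, rng)
        sampler.init_state()
        rep_rows = []
        for it in range(1, settings.iterations + 1):
            sampler.sweep(adapting=it <= burn_iters)
            if it % settings.thinning == 0:
                row = {
                    "iteration": it,
                    "replicate": rep,
                    "log_posterior": sampler.lp + sampler.ll,
                    "log_likelihood": sampler.ll,
                    "log_prior": sampler.lp,
                }
                row.update(_state_row(pm, sampler.state, x_fixed))
                rep_rows.append(row)
        rows.extend(rep_rows[drop:])
        acceptance[f"replicate_{rep}"] = sampler.acceptance_rates()

    trace = MCMCTrace(
        df=pd.DataFrame(rows),
        model=prior_spec.model,
        mode=mode,
        acceptance=acceptance,
        settings=settings,
    )
    expected = retained_sample_count(
        settings.iterations, settings.thinning, settings.burn_in_fraction, settings.n_replicates
    )
    assert len(trace.df) == expected
    return trace


# -- convergence -------------------------------------------------------------


def check_convergence(
    trace_rep1,
    trace_rep2,
    grid,
    threshold: float = 0.05,
    min_samples: int = 100,
):
    """Kolmogorov–Smirnov distance between two replicates' samples of
    log Ne at each grid time; fails if any grid point exceeds the
    threshold.  Returns (per-grid statistic array, passed flag)."""
    m1 = _summary.ne_matrix(trace_rep1, grid)
    m2 = _summary.ne_matrix(trace_rep2, grid)
    if m1.shape[0] < min_samples or m2.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples per replicate")
    stats = np.array(
        [ks_2samp(np.log(m1[:, j]), np.log(m2[:, j])).statistic for j in range(len(grid))]
    )
    return stats, bool(np.all(stats <= threshold))


def split_replicates(trace: MCMCTrace):
    """The per-replicate sub-traces of a pooled trace."""
    return [
        MCMCTrace(df=g.reset_index(drop=True), model=trace.model, mode=trace.mode)
        for _, g in trace.df.groupby("replicate")
    ]


# -- marginal likelihood -----------------------------------------------------


def _require_proper(spec: PriorSpec):
    for key, val in spec.resolved_hyper().items():
        if isinstance(val, (int, float)) and not math.isfinite(val):
            raise ValueError(
                f"improper prior: hyperparameter {key} of {spec.model} is not finite; "
                "marginal likelihoods need proper priors"
            )


def stepping_stone(
    prior_spec: PriorSpec,
    data,
    n_stones: int = 128,
    iterations_per_stone: int = 5000,
    *,
    seed: int | None = None,
    mode: str = "constant",
    t_max: float | None = None,
    n_intervals: int | None = None,
    spacing_exponent: float = 1.0 / 0.3,
    stone_burn_in: float = 0.25,
    settings: MCMCSettings | None = None,
) -> float:
    """Stepping-stone estimate of the log marginal likelihood.

    Powers β_i = (i/(n_stones−1))^spacing_exponent — the quantiles of a
    Beta(0.3, 1) ladder, the customary default — run from the prior (β=0)
    to the posterior (β=1).  Each stone's chain is warm-started from the
    previous stone; the log-ML is assembled from the stone-wise importance
    ratios log E_βk[ L^(β_{k+1}−β_k) ].
    """
    _require_proper(prior_spec)
    settings = settings or MCMCSettings(seed=seed)
    x_fixed, L, t_max = _default_layout(prior_spec, data, t_max, n_intervals)
    pm = make_prior_model(prior_spec, L if L is not None else 1, t_max)
    loglik_fn = _make_loglik(data, pm, x_fixed, mode)

    betas = (np.arange(n_stones) / (n_stones - 1)) ** spacing_exponent
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sampler = _Sampler(pm, loglik_fn, settings, rng, power=0.0)
    sampler.init_state()

    drop = int(stone_burn_in * iterations_per_stone)
    log_ml = 0.0
    for k in range(n_stones - 1):
        sampler.power = betas[k]
        # a warm start stuck in an underflowed-likelihood region has zero
        # mass once the power is positive; re-draw from the prior
        if betas[k] > 0.0 and not np.isfinite(sampler.ll):
            sampler.init_state()
        lls = np.empty(iterations_per_stone - drop)
        for it in range(iterations_per_stone):
            sampler.sweep(adapting=it < drop)
            if it >= drop:
                lls[it - drop] = sampler.ll
        contrib = logsumexp((betas[k + 1] - betas[k]) * lls) - math.log(len(lls))
        if not np.isfinite(contrib):
            raise RuntimeError(f"non-finite stepping-stone contribution at stone {k}")
        log_ml += contrib
    return float(log_ml)


def bayes_factor(log_ml_a: float, log_ml_b: float) -> float:
    """log Bayes factor of model a over model b."""
    if not (math.isfinite(log_ml_a) and math.isfinite(log_ml_b)):
        raise ValueError("marginal likelihoods must be finite")
    return log_ml_a - log_ml_b
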