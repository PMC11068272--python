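"""The heterochronous coalescent probability density of a genealogy.

Backward in time, k active lineages coalesce at instantaneous rate

    c(t) = k(t) (k(t) - 1) / (2 Ne(t)),

where sampling events increment k and coalescent events decrement it.  The
log-density of the coalescent times given a piecewise trajectory is the sum
over consecutive timeline events of the no-event log-probability
-∫ c(t) dt plus, at each coalescent event u_j, the log point-mass factor
log[ 2/(k(k-1)) · c(u_j) ] = -log Ne(u_j).

For piecewise constant or linear Ne the per-segment integrals are analytic,
so the density is exact: no quadrature is used outside the test oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .demography import ChangePointScheme, DemographicTrajectory
from .genealogy import COALESCENT, SAMPLING, Genealogy

__all__ = [
    "coalescent_rate",
    "integrated_rate",
    "log_density",
    "multilocus_log_density",
    "sequential_log_likelihood",
    "CoalescentLikelihood",
]


def coalescent_rate(k: int, ne: float) -> float:
    """Pairwise coalescent rate k(k-1)/(2 Ne); zero when fewer than two
    lineages are active."""
    if ne <= 0:
        raise ValueError("effective population size must be positive")
    if k < 2:
        return 0.0
    return k * (k - 1) / (2.0 * ne)


def integrated_rate(segment, k: int, trajectory: DemographicTrajectory) -> float:
    """Cumulative coalescent hazard ∫_a^b c(t) dt over a segment that lies
    within a single trajectory interval.

    Constant mode: k(k-1)(b-a) / (2 ρ_i).  Linear mode with slope α_i ≠ 0:
    k(k-1)/(2 α_i) · ln(Ne(b)/Ne(a)); a zero slope falls back to the
    constant formula.  Segments straddling a change-point are rejected —
    the caller must split them first.
    """
    a, b = float(segment[0]), float(segment[1])
    if b < a:
        raise ValueError("segment must have a <= b")
    x = trajectory.change_points
    i = int(np.searchsorted(x, a, side="right") - 1)
    nxt = x[i + 1] if i + 1 < len(x) else np.inf
    if b > nxt:
        raise ValueError("segment straddles a change-point; split it first")
    if k < 2 or a == b:
        return 0.0
    kk2 = k * (k - 1) / 2.0
    if trajectory.mode == "linear":
        alpha = trajectory.slopes[i]
        ne_a = trajectory.ne_at(a)
        if alpha != 0.0:
            # log1p form of (1/α)·ln(Ne(b)/Ne(a)) stays accurate as α → 0
            r = alpha * (b - a) / ne_a
            return kk2 * (b - a) / ne_a * (math.log1p(r) / r)
        ne = ne_a
    else:
        ne = trajectory.pop_sizes[i]
    return kk2 * (b - a) / ne


@dataclass
class _TreeEvents:
    """Precomputed per-genealogy event structure (sampling + coalescent)."""

    u: np.ndarray        # merged sorted event times
    delta: np.ndarray    # +1 sampling, -1 coalescent
    coal_times: np.ndarray

    @classmethod
    def from_genealogy(cls, g: Genealogy) -> "_TreeEvents":
        s = np.sort(g.sampling_ages)
        t = g.coalescent_times
        times = np.concatenate([s, t])
        types = np.concatenate([np.full(len(s), SAMPLING), np.full(len(t), COALESCENT)])
        order = np.lexsort((types, times))
        times, types = times[order], types[order]
        delta = np.where(types == SAMPLING, 1, -1)
        k = np.cumsum(delta)
        # a coalescent event needs >= 2 lineages just before it
        if np.any((types == COALESCENT) & (k < 1)):
            raise ValueError("fewer than two lineages at a coalescent event")
        return cls(u=times, delta=delta, coal_times=t)


def _segment_structure(ev: _TreeEvents, x: np.ndarray):
    """Segment boundaries, per-segment k-choose-2 and interval index for a
    given change-point vector x (x[0] = 0)."""
    xi = x[1:]
    b = np.concatenate([ev.u, xi])
    tb = np.concatenate([np.zeros(len(ev.u)), np.ones(len(xi))])
    order = np.lexsort((tb, b))  # change-points sort after events at ties
    b = b[order]
    delta = np.concatenate([ev.delta, np.zeros(len(xi), dtype=int)])[order]
    k = np.cumsum(delta)
    b_start, b_end = b[:-1], b[1:]
    kseg = k[:-1]
    kk2 = kseg * (kseg - 1) / 2.0
    iv = np.searchsorted(x, b_start, side="right") - 1
    civ = np.searchsorted(x, ev.coal_times, side="right") - 1
    return b_start, b_end, kk2, iv, civ


def _tree_log_density(ev: _TreeEvents, x, rho, mode: str) -> float:
    x = np.asarray(x, float)
    rho = np.asarray(rho, float)
    b0, b1, kk2, iv, civ = _segment_structure(ev, x)
    if mode == "linear":
        alpha = np.zeros(len(rho))
        if len(rho) > 1:
            alpha[:-1] = np.diff(rho) / np.diff(x)
        a = alpha[iv]
        ne0 = rho[iv] + (b0 - x[iv]) * a
        r = a * (b1 - b0) / ne0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r == 0.0, 1.0, np.log1p(r) / np.where(r == 0.0, 1.0, r))
        haz = kk2 * (b1 - b0) / ne0 * ratio
        point_ne = rho[civ] + (ev.coal_times - x[civ]) * alpha[civ]
    else:
        with np.errstate(over="ignore", divide="ignore"):
            haz = kk2 * (b1 - b0) / rho[iv]
        point_ne = rho[civ]
    with np.errstate(divide="ignore", over="ignore"):
        return float(-haz.sum() - np.log(point_ne).sum())


class CoalescentLikelihood:
    """Fast repeated evaluation of the coalescent log-density for one or
    several genealogies under a shared trajectory.

    The per-genealogy event structure is computed once.  In constant mode
    with fixed change-points, :meth:`cache` collapses the timeline into two
    length-L vectors (A, c) so that the log-density is
    -Σ A_i/ρ_i - Σ c_i ln ρ_i — an O(L) evaluation per MCMC proposal.
    """

    def __init__(self, genealogies, mode: str = "constant"):
        if isinstance(genealogies, Genealogy):
            genealogies = [genealogies]
        self.genealogies = list(genealogies)
        self.mode = mode
        self._events = [_TreeEvents.from_genealogy(g) for g in self.genealogies]

    def loglik(self, x, rho) -> float:
        return sum(_tree_log_density(ev, x, rho, self.mode) for ev in self._events)

    def cache(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Constant-mode sufficient statistics (A, c) for fixed x."""
        if self.mode != "constant":
            raise ValueError("the compressed cache applies to constant mode only")
        x = np.asarray(x, float)
        L = len(x)
        A = np.zeros(L)
        c = np.zeros(L)
        for ev in self._events:
            b0, b1, kk2, iv, civ = _segment_structure(ev, x)
            A += np.bincount(iv, weights=kk2 * (b1 - b0), minlength=L)
            c += np.bincount(civ, minlength=L)
        return A, c

    @staticmethod
    def loglik_cached(A: np.ndarray, c: np.ndarray, rho: np.ndarray) -> float:
        with np.errstate(over="ignore", divide="ignore"):
            return float(-(A / rho).sum() - (c * np.log(rho)).sum())


def _resolve(genealogy, trajectory, scheme):
    if scheme is not None and scheme.method == "events":
        x = scheme.resolve(genealogy)
        if len(x) != trajectory.n_intervals:
            raise ValueError(
                "trajectory has a population size per interval; events scheme "
                f"yields {len(x)} intervals but trajectory has {trajectory.n_intervals}"
            )
        return x
    return trajectory.change_points


def log_density(
    genealogy: Genealogy,
    trajectory: DemographicTrajectory,
    scheme: ChangePointScheme | None = None,
) -> float:
    """Coalescent log-density of one genealogy under a trajectory.

    With an events-method scheme, change-points are first derived from the
    genealogy's own coalescent times (the trajectory's sizes are reused,
    one per interval); otherwise the trajectory's change-points are used
    as given.
    """
    x = _resolve(genealogy, trajectory, scheme)
    ev = _TreeEvents.from_genealogy(genealogy)
    return _tree_log_density(ev, x, trajectory.pop_sizes, trajectory.mode)


def multilocus_log_density(
    genealogies,
    trajectory: DemographicTrajectory,
    scheme: ChangePointScheme | None = None,
) -> float:
    """Sum of per-locus log-densities under one shared trajectory.

    Only change-points independent of coalescent events are meaningful
    across loci, so an events-method scheme is rejected.
    """
    if scheme is not None and scheme.method == "events":
        raise ValueError(
            "coalescent-event change-points are locus-specific; multi-locus "
            "densities need the specified method"
        )
    return sum(log_density(g, trajectory) for g in genealogies)


def sequential_log_likelihood(
    genealogy_samples,
    reference_log_densities,
    trajectory: DemographicTrajectory,
) -> float:
    """Pseudo-likelihood for sequential inference from a posterior sample of
    genealogies: the log of the importance-weighted average

        (1/M) Σ_j exp[ log p(g_j | trajectory) - log p_ref(g_j) ],

    where p_ref is the coalescent density each sampled genealogy had under
    the demographic model of the first analysis.  Computed stably with a
    max-shift (logsumexp).
    """
    refs = np.asarray(reference_log_densities, float)
    trees = list(genealogy_samples)
    if len(trees) == 0:
        raise ValueError("empty genealogy sample")
    if len(trees) != len(refs):
        raise ValueError("one reference log-density per sampled genealogy")
    ll = np.array([log_density(g, trajectory) for g in trees])
    return float(logsumexp(ll - refs) - np.log(len(trees)))
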