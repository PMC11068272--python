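"""Piecewise demographic trajectories Ne(t) and interval change-point schemes.

A trajectory divides backward time into L intervals by change-points
x_1 = 0 < x_2 < ... < x_L, with one population size ρ_i per interval.
Within an interval Ne is either constant (ρ_i) or changes linearly,
reaching ρ_{i+1} at the next change-point; past the last change-point Ne
stays at ρ_L in both modes.  Intervals are left-closed / right-open,
[x_i, x_{i+1}), so Ne(0) = ρ_1 is always defined and a time equal to a
change-point belongs to the older interval.

Change-points come from one of two schemes: tied to coalescent events of a
genealogy ("events" method — the classic skyline construction) or placed
independently of the genealogy ("specified" method, e.g. an equal grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemographicTrajectory",
    "ChangePointScheme",
    "ne_at",
    "slope",
    "changepoints_from_events",
    "equal_grid",
    "events_grouping",
    "read_trajectory_tsv",
    "format_trajectory_tsv",
]


@dataclass
class DemographicTrajectory:
    """Piecewise constant or piecewise linear Ne(t).

    Parameters
    ----------
    change_points : array of L sorted times, first entry 0.
    pop_sizes : array of L positive sizes, one per interval.
    mode : "constant" or "linear".
    """

    change_points: np.ndarray
    pop_sizes: np.ndarray
    mode: str = "constant"

    def __post_init__(self) -> None:
        self.change_points = np.atleast_1d(np.asarray(self.change_points, float))
        self.pop_sizes = np.atleast_1d(np.asarray(self.pop_sizes, float))
        x, rho = self.change_points, self.pop_sizes
        if len(x) != len(rho):
            raise ValueError("change_points and pop_sizes must have equal length")
        if x[0] != 0.0:
            raise ValueError("the first change-point must be 0 (the present)")
        if np.any(np.diff(x) <= 0):
            raise ValueError("change_points must be strictly increasing")
        if np.any(rho <= 0):
            raise ValueError("population sizes must be positive")
        if self.mode not in ("constant", "linear"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_intervals(self) -> int:
        return len(self.pop_sizes)

    @property
    def slopes(self) -> np.ndarray:
        """Per-interval slopes α_i = (ρ_{i+1} − ρ_i)/(x_{i+1} − x_i).

        Length L: the final interval is constant in both modes, so its
        slope is 0.  In constant mode all slopes are 0.
        """
        L = self.n_intervals
        alpha = np.zeros(L)
        if self.mode == "linear" and L > 1:
            alpha[:-1] = np.diff(self.pop_sizes) / np.diff(self.change_points)
        return alpha

    def ne_at(self, t) -> np.ndarray | float:
        """Evaluate Ne(t); vectorized over t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        idx = np.searchsorted(self.change_points, t, side="right") - 1
        ne = self.pop_sizes[idx]
        if self.mode == "linear":
            ne = ne + (t - self.change_points[idx]) * self.slopes[idx]
        return float(ne) if ne.ndim == 0 else ne


def ne_at(trajectory: DemographicTrajectory, t):
    return trajectory.ne_at(t)


def slope(trajectory: DemographicTrajectory, i: int) -> float:
    """Slope α_i of interval i (1-based, 1 ≤ i < L), linear mode only."""
    if trajectory.mode != "linear":
        raise ValueError("slopes are defined for linear mode only")
    if not 1 <= i < trajectory.n_intervals:
        raise ValueError(f"slope index {i} out of range")
    return float(trajectory.slopes[i - 1])


@dataclass
class ChangePointScheme:
    """How interval change-points are placed.

    method="events": change-points co-occur with coalescent events, with
    ``events_per_interval`` coalescent events in each interval (counts sum
    to n−1).  method="specified": explicit ``times``, independent of the
    genealogy.
    """

    method: str
    events_per_interval: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method == "events":
            if self.events_per_interval is None:
                raise ValueError("events method needs events_per_interval")
            self.events_per_interval = np.asarray(self.events_per_interval, int)
            if np.any(self.events_per_interval < 1):
                raise ValueError("each interval needs at least one coalescent event")
        elif self.method == "specified":
            if self.times is None:
                raise ValueError("specified method needs times")
            self.times = np.asarray(self.times, float)
            if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be sorted, nonnegative, distinct")
            if self.times[0] != 0.0:
                raise ValueError("the first change-point must be 0")
        else:
            raise ValueError(f"unknown change-point method {self.method!r}")

    def resolve(self, genealogy=None) -> np.ndarray:
        """The concrete change-point times, deriving them from the
        genealogy's coalescent events for the events method."""
        if self.method == "specified":
            return self.times
        if genealogy is None:
            raise ValueError("events method needs a genealogy")
        return changepoints_from_events(genealogy, self.events_per_interval)

    @property
    def n_intervals(self) -> int:
        if self.method == "events":
            return len(self.events_per_interval)
        return len(self.times)


def events_grouping(n_events: int, per_group: int) -> np.ndarray:
    """Split n−1 coalescent events into ⌈n_events/per_group⌉ groups of
    ``per_group``, the final group taking the remainder.

    This is the fixed grouping used by the classic skyline constructions
    (e.g. 35 events in groups of 5 → 7 intervals).
    """
    if per_group < 1 or n_events < 1:
        raise ValueError("need positive counts")
    n_groups = -(-n_events // per_group)
    counts = np.full(n_groups, per_group)
    counts[-1] = n_events - per_group * (n_groups - 1)
    return counts


def changepoints_from_events(genealogy, events_per_interval) -> np.ndarray:
    """Change-point times for the events method: the first interval starts
    at 0 and change-point i sits at the coalescent time ending group i."""
    counts = np.asarray(events_per_interval, int)
    coal = genealogy.coalescent_times
    if counts.sum() != len(coal):
        raise ValueError(
            f"events_per_interval sums to {counts.sum()}, need {len(coal)}"
        )
    ends = np.cumsum(counts)[:-1] - 1
    return np.concatenate([[0.0], coal[ends]])


def equal_grid(t_max: float, L: int) -> np.ndarray:
    """L equally sized intervals on [0, t_max): change-points at
    i·t_max/L for i = 0..L−1."""
    if t_max <= 0 or L < 1:
        raise ValueError("need t_max > 0 and L >= 1")
    return t_max / L * np.arange(L)


# -- trajectory TSV ----------------------------------------------------------


def read_trajectory_tsv(text: str, mode: str = "constant") -> DemographicTrajectory:
    """Two-column TSV (change_point_time, pop_size), one row per interval."""
    x, rho = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("change_point"):
            continue
        a, b = line.split("\t")
        x.append(float(a))
        rho.append(float(b))
    return DemographicTrajectory(np.array(x), np.array(rho), mode=mode)


def format_trajectory_tsv(trajectory: DemographicTrajectory) -> str:
    lines = ["change_point_time\tpop_size"]
    for x, rho in zip(trajectory.change_points, trajectory.pop_sizes):
        lines.append(f"{float(x)!r}\t{float(rho)!r}")
    return "\n".join(lines) + "\n"
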