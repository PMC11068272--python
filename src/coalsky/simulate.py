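"""Simulation of heterochronous coalescent genealogies under piecewise
trajectories, sequence evolution on genealogies, and study-shaped fixtures.

Genealogies are drawn by exact inversion of the integrated coalescent
hazard: backward in time, a unit-exponential deviate is converted into a
waiting time segment by segment, with the accumulation restarted at every
sampling event and trajectory change-point (valid by memorylessness of the
exponential).  Constant segments invert to w = 2ρE/(k(k−1)); linear
segments to w = Ne(a)(exp(2αE/(k(k−1))) − 1)/α.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .demography import DemographicTrajectory, format_trajectory_tsv
from .genealogy import Genealogy, format_tip_ages, write_genealogy

__all__ = [
    "simulate_genealogy",
    "simulate_alignment",
    "write_fasta",
    "make_fixture",
    "FIXTURE_SCENARIOS",
    "CONSTANT_TRUTH",
    "BSP_LIKE_TRUTH",
]

# Truth trajectories for the simulation-study scenarios: a constant history
# and a variable one with a population-size peak near the present, in
# calendar years, sized for a mitochondrial-scale dataset.
CONSTANT_TRUTH = DemographicTrajectory([0.0], [5.0e4])
BSP_LIKE_TRUTH = DemographicTrajectory(
    [0.0, 5.0e3, 2.0e4, 5.0e4, 2.5e5],
    [2.0e4, 1.0e5, 3.0e4, 3.0e4, 6.0e4],
)

#: fixture defaults: ~16 kb mitochondrial-like locus with a clock chosen to
#: give about 2% expected pairwise diversity under the constant truth.
FIXTURE_SEQ_LENGTH = 16_000
FIXTURE_MUTATION_RATE = 2.0e-7


def simulate_genealogy(
    sampling_ages,
    trajectory: DemographicTrajectory,
    rng: np.random.Generator,
    labels=None,
) -> Genealogy:
    """Draw one coalescent genealogy for tips at the given ages under the
    trajectory; the coalescing pair at each event is chosen uniformly."""
    ages = np.asarray(sampling_ages, float)
    n = len(ages)
    if n < 2:
        raise ValueError("need at least two samples")
    if np.any(ages < 0):
        raise ValueError("sampling ages must be nonnegative")
    if labels is None:
        labels = [f"t{i+1}" for i in range(n)]

    order = np.argsort(ages, kind="stable")
    pending = list(order)  # tip node ids, youngest first
    x = trajectory.change_points
    rho = trajectory.pop_sizes
    alpha = trajectory.slopes
    L = len(x)

    parent = np.full(2 * n - 1, -1, dtype=int)
    node_times = np.empty(2 * n - 1)
    node_times[:n] = ages
    next_node = n

    active: list[int] = []
    T = ages[pending[0]]
    while pending and ages[pending[0]] <= T:
        active.append(pending.pop(0))

    while len(active) + len(pending) > 1:
        k = len(active)
        next_s = ages[pending[0]] if pending else math.inf
        if k < 2:
            T = next_s
            while pending and ages[pending[0]] <= T:
                active.append(pending.pop(0))
            continue
        i = int(np.searchsorted(x, T, side="right") - 1)
        seg_end = min(next_s, x[i + 1] if i + 1 < L else math.inf)
        kk2 = k * (k - 1) / 2.0
        E = rng.exponential()
        a_i = alpha[i]
        ne_T = rho[i] + (T - x[i]) * a_i
        if a_i == 0.0:
            w = E * ne_T / kk2
        else:
            w = ne_T * math.expm1(a_i * E / kk2) / a_i
        t_cand = T + w
        if t_cand < seg_end:
            j1 = int(rng.integers(k))
            j2 = int(rng.integers(k - 1))
            if j2 >= j1:
                j2 += 1
            c1, c2 = active[j1], active[j2]
            node_times[next_node] = t_cand
            parent[c1] = next_node
            parent[c2] = next_node
            active = [v for v in active if v not in (c1, c2)]
            active.append(next_node)
            next_node += 1
            T = t_cand
        else:
            T = seg_end
            while pending and ages[pending[0]] <= T:
                active.append(pending.pop(0))

    return Genealogy(tip_labels=list(labels), parent=parent, node_times=node_times)


_BASES = np.array(list("ACGT"))


def simulate_alignment(
    genealogy: Genealogy,
    mutation_rate: float,
    seq_length: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve sequences site-independently down the genealogy under the
    Jukes–Cantor model at the given per-site, per-time-unit rate."""
    if mutation_rate < 0 or seq_length < 1:
        raise ValueError("need mutation_rate >= 0 and seq_length >= 1")
    n = genealogy.n_tips
    kids = genealogy.children()
    times = genealogy.node_times
    seqs: dict[int, np.ndarray] = {
        genealogy.root: rng.integers(0, 4, size=seq_length)
    }
    # root-to-tips, oldest first
    for node in sorted(range(2 * n - 1), key=lambda i: -times[i]):
        if node not in seqs:
            continue
        src = seqs.pop(node) if node >= n else seqs[node]
        for child in kids[node]:
            t = times[node] - times[child]
            p_change = 0.75 * -math.expm1(-4.0 * mutation_rate * t / 3.0)
            seq = src.copy()
            hit = rng.random(seq_length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
            seqs[child] = seq
    return {
        lab: "".join(_BASES[seqs[i]])
        for i, lab in enumerate(genealogy.tip_labels)
    }


def write_fasta(alignment: dict[str, str]) -> str:
    return "".join(f">{lab}\n{seq}\n" for lab, seq in alignment.items())


FIXTURE_SCENARIOS = (
    "isochronous36",
    "heterochronous173",
    "constant_truth",
    "bsp_like_truth",
)


def _scenario_config(scenario: str):
    if scenario == "isochronous36":
        return np.zeros(36), CONSTANT_TRUTH, 1
    if scenario == "heterochronous173":
        ages = np.zeros(173)
        return ages, CONSTANT_TRUTH, 1  # 137 ancient ages drawn at run time
    if scenario == "constant_truth":
        return np.zeros(36), CONSTANT_TRUTH, 10
    if scenario == "bsp_like_truth":
        return np.zeros(36), BSP_LIKE_TRUTH, 10
    raise ValueError(f"unknown scenario {scenario!r}")


def make_fixture(
    scenario: str,
    rng: np.random.Generator,
    out_dir: str | Path | None = None,
    seq_length: int = FIXTURE_SEQ_LENGTH,
    mutation_rate: float = FIXTURE_MUTATION_RATE,
) -> dict:
    """Generate genealogies, alignments and truth files for one of the
    study-shaped scenarios.

    ``heterochronous173`` draws its 137 ancient tip ages uniformly on
    (0, 50,000); the replicated scenarios share one truth trajectory
    across all 10 replicates.  When ``out_dir`` is given, writes a
    multi-tree Newick file, a tip-age TSV per replicate, FASTA alignments
    and the true trajectory TSV.
    """
    ages, truth, n_reps = _scenario_config(scenario)
    if scenario == "heterochronous173":
        ages = ages.copy()
        ages[36:] = rng.uniform(0.0, 5.0e4, size=137)

    genealogies = [simulate_genealogy(ages, truth, rng) for _ in range(n_reps)]
    alignments = [
        simulate_alignment(g, mutation_rate, seq_length, rng) for g in genealogies
    ]
    result = {
        "scenario": scenario,
        "genealogies": genealogies,
        "alignments": alignments,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        newicks = []
        for i, (g, aln) in enumerate(zip(genealogies, alignments), start=1):
            newick, age_table = write_genealogy(g)
            newicks.append(newick)
            (out / f"{scenario}_rep{i}_ages.tsv").write_text(age_table)
            (out / f"{scenario}_rep{i}.fasta").write_text(write_fasta(aln))
        (out / f"{scenario}.trees").write_text("\n".join(newicks) + "\n")
        (out / f"{scenario}_truth.tsv").write_text(format_trajectory_tsv(truth))
    return result
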