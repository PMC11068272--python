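"""Dated genealogies and coalescent event timelines.

Time runs backward from the present: an age of 0 means "now" and ages
increase into the past, so the root carries the largest time.  Tips may be
sampled at different past times (heterochronous sampling); a genealogy in
which every tip has age 0 is isochronous.  All times are in the genealogy's
own units (generations or calendar years) — nothing here rescales them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Genealogy",
    "EventTimeline",
    "SAMPLING",
    "COALESCENT",
    "CHANGEPOINT",
    "read_genealogy",
    "read_genealogies",
    "write_genealogy",
    "read_tip_ages",
    "format_tip_ages",
    "build_timeline",
]

# Event type codes.  The ordering of the codes is the tie-break order for
# simultaneous events: sampling < coalescent < change-point, so that a
# coalescent event occurring exactly at a sampling time still sees the newly
# added lineage, and a change-point never splits a tie ahead of the event
# that defines it.
SAMPLING = 0
COALESCENT = 1
CHANGEPOINT = 2

_REL_TOL = 1e-6


class GenealogyError(ValueError):
    """Raised for malformed genealogies or inconsistent input files."""


@dataclass
class Genealogy:
    """A rooted binary tree with dated tips and internal nodes.

    Nodes are indexed 0..2n-2: tips are 0..n-1 (aligned with
    ``tip_labels``), internal nodes follow.  ``parent[i]`` is the index of
    node i's parent (-1 for the root).  ``node_times[i]`` is the age
    (time before present) of node i; for a tip this is its sampling age,
    for an internal node the time of the coalescent event it represents.
    """

    tip_labels: list[str]
    parent: np.ndarray
    node_times: np.ndarray

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.node_times = np.asarray(self.node_times, dtype=float)
        self.validate()

    # -- basic accessors ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def sampling_ages(self) -> np.ndarray:
        """Tip ages, aligned with ``tip_labels``."""
        return self.node_times[: self.n_tips]

    @property
    def coalescent_times(self) -> np.ndarray:
        """The n-1 internal node times, sorted ascending (youngest first).

        With the backward-time indexing convention the m-th coalescent
        time t_m is the time of the (n-m)-th event, so t_1 — the root —
        is the last entry of this array.
        """
        return np.sort(self.node_times[self.n_tips:])

    @property
    def tmrca(self) -> float:
        return float(self.node_times.max())

    @property
    def is_isochronous(self) -> bool:
        return bool(np.all(self.sampling_ages == 0.0))

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise GenealogyError("a genealogy needs at least two tips")
        if len(self.parent) != 2 * n - 1 or len(self.node_times) != 2 * n - 1:
            raise GenealogyError(
                f"expected {2 * n - 1} nodes for {n} tips, got {len(self.parent)}"
            )
        if np.any(self.node_times < 0):
            raise GenealogyError("node times must be nonnegative")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise GenealogyError("tree must have exactly one root")
        kids = self.children()
        for i in range(n):
            if kids[i]:
                raise GenealogyError(f"tip node {i} has children")
        for i in range(n, 2 * n - 1):
            if len(kids[i]) != 2:
                raise GenealogyError(f"internal node {i} is not binary")
            for c in kids[i]:
                if not self.node_times[i] > self.node_times[c]:
                    raise GenealogyError(
                        f"node {i} (t={self.node_times[i]}) is not strictly older "
                        f"than child {c} (t={self.node_times[c]})"
                    )


@dataclass
class EventTimeline:
    """Merged, time-ordered sampling / coalescent / change-point events.

    ``k_after[j]`` is the number of active (extant ancestral) lineages
    immediately after event j, looking backward in time: sampling events
    increment k, coalescent events decrement it, change-points leave it
    unchanged.
    """

    times: np.ndarray
    types: np.ndarray
    k_after: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.types = np.asarray(self.types, dtype=int)
        self.k_after = np.asarray(self.k_after, dtype=int)

    @property
    def r(self) -> int:
        """Total number of events."""
        return len(self.times)

    def validate(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise GenealogyError("timeline times must be sorted")
        if np.any(self.k_after < 0):
            raise GenealogyError("negative lineage count")
        n_coal = int(np.sum(self.types == COALESCENT))
        if n_coal and self.k_after[np.flatnonzero(self.types == COALESCENT)[-1]] != 1:
            raise GenealogyError("final coalescent event must leave one lineage")


def build_timeline(genealogy: Genealogy, change_points=()) -> EventTimeline:
    """Merge sampling times, coalescent times and change-points into one
    ordered event list with the active-lineage count after each event.

    Ties are broken sampling < coalescent < change-point, then input order
    (numpy stable mergesort on the type key).
    """
    cps = np.asarray(sorted(change_points), dtype=float)
    if cps.size and cps[0] < 0:
        raise GenealogyError("change-points must be nonnegative")
    s = np.sort(genealogy.sampling_ages)
    t = genealogy.coalescent_times
    times = np.concatenate([s, t, cps])
    types = np.concatenate(
        [
            np.full(len(s), SAMPLING),
            np.full(len(t), COALESCENT),
            np.full(len(cps), CHANGEPOINT),
        ]
    )
    order = np.lexsort((types, times))
    times, types = times[order], types[order]
    delta = np.where(types == SAMPLING, 1, np.where(types == COALESCENT, -1, 0))
    k_after = np.cumsum(delta)
    tl = EventTimeline(times=times, types=types, k_after=k_after)
    tl.validate()
    return tl


# -- file I/O ----------------------------------------------------------------


def read_tip_ages(text: str) -> dict[str, float]:
    """Parse a two-column (label, age) TSV into a dict."""
    ages: dict[str, float] = {}
    for line_no, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise GenealogyError(f"tip-age table line {line_no}: expected 2 columns")
        label, age = parts[0], float(parts[1])
        if age < 0:
            raise GenealogyError(f"tip {label!r} has negative age {age}")
        ages[label] = age
    return ages


def format_tip_ages(genealogy: Genealogy) -> str:
    lines = [
        f"{lab}\t{float(age)!r}"
        for lab, age in zip(genealogy.tip_labels, genealogy.sampling_ages)
    ]
    return "\n".join(lines) + "\n"


def _from_dendropy(tree: dendropy.Tree, tip_ages: dict[str, float]) -> Genealogy:
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    for lab in labels:
        if lab not in tip_ages:
            raise GenealogyError(f"tip {lab!r} missing from the tip-age table")
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    for nd in internal:
        if len(nd.child_nodes()) != 2:
            raise GenealogyError("tree is not strictly binary")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise GenealogyError("every edge needs a branch length")
            if nd.edge.length < 0:
                raise GenealogyError(f"negative branch length {nd.edge.length}")

    # Depth from root via branch lengths; tip ages are authoritative, the
    # branch lengths are only validated against them.
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[nd] = depth[nd.parent_node] + nd.edge.length
    root_age = tip_ages[labels[0]] + depth[leaves[0]]
    scale = max(1.0, abs(root_age))
    for lf, lab in zip(leaves, labels):
        implied = root_age - depth[lf]
        if abs(implied - tip_ages[lab]) > _REL_TOL * scale:
            raise GenealogyError(
                f"tip {lab!r}: stated age {tip_ages[lab]} inconsistent with branch "
                f"lengths (implied {implied})"
            )

    n = len(leaves)
    index = {lf: i for i, lf in enumerate(leaves)}
    for j, nd in enumerate(internal):
        index[nd] = n + j
    parent = np.full(2 * n - 1, -1, dtype=int)
    times = np.empty(2 * n - 1)
    for nd, i in index.items():
        if nd.parent_node is not None:
            parent[i] = index[nd.parent_node]
        if nd.is_leaf():
            times[i] = tip_ages[nd.taxon.label]
        else:
            times[i] = root_age - depth[nd]
    return Genealogy(tip_labels=labels, parent=parent, node_times=times)


def read_genealogy(newick_text: str, tip_ages: dict[str, float] | str) -> Genealogy:
    """Read a rooted binary Newick tree plus a tip-age table.

    ``tip_ages`` may be a mapping or the raw TSV text.  Node times are
    reconstructed so that each tip sits at its stated age; branch lengths
    inconsistent with the ages beyond 1e-6 relative tolerance are rejected.
    """
    if isinstance(tip_ages, str):
        tip_ages = read_tip_ages(tip_ages)
    tree = dendropy.Tree.get(
        data=newick_text, schema="newick", preserve_underscores=True
    )
    return _from_dendropy(tree, tip_ages)


def read_genealogies(newick_text: str, tip_ages: dict[str, float] | str) -> list[Genealogy]:
    """Read a multi-tree Newick file (one tree per line), shared age table."""
    if isinstance(tip_ages, str):
        tip_ages = read_tip_ages(tip_ages)
    trees = dendropy.TreeList.get(
        data=newick_text, schema="newick", preserve_underscores=True
    )
    return [_from_dendropy(t, tip_ages) for t in trees]


def write_genealogy(genealogy: Genealogy) -> tuple[str, str]:
    """Serialize to (newick_text, tip_age_table_text).

    Branch lengths are written with full float precision so that
    ``read_genealogy(*write_genealogy(g))`` reproduces every node time
    to well within 1e-9.
    """
    kids = genealogy.children()
    times = genealogy.node_times

    def render(i: int) -> str:
        if i < genealogy.n_tips:
            return genealogy.tip_labels[i]
        a, b = kids[i]
        la = float(times[i] - times[a])
        lb = float(times[i] - times[b])
        return f"({render(a)}:{la!r},{render(b)}:{lb!r})"

    newick = render(genealogy.root) + ";"
    return newick, format_tip_ages(genealogy)
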