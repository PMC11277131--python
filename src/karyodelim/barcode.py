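"""COI barcode analysis: p-distances, haplogroup clustering, neighbor joining,
and diagnostic fixed substitutions.

The mitochondrial barcode carries two signals used in delimitation: overall
divergence (uncorrected p-distance, computed with pairwise deletion of gaps
and ambiguous bases) and diagnostic fixed substitutions — alignment columns
at which two groups show disjoint nucleotide state sets, such as a T/A
difference fixed between two species.  Haplogroups are formed by
single-linkage clustering of the distance matrix at a threshold ``theta``
(default 2%, a conventional barcode-gap value), serving as a distance-based
stand-in for clusters read off a phylogenetic tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import Alignment, UNAMBIGUOUS

__all__ = [
    "DEFAULT_THETA",
    "DistanceMatrix",
    "HaplogroupAssignment",
    "DiagnosticSite",
    "p_distance",
    "distance_matrix",
    "cluster_haplogroups",
    "neighbor_joining",
    "diagnostic_sites",
    "min_between_group_distance",
]

#: Default haplogroup clustering threshold (proportion): 2% divergence.
DEFAULT_THETA = 0.02


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix; undefined pairs (zero comparable sites)
    are stored as NaN."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class HaplogroupAssignment:
    """Sample -> mitochondrial haplogroup mapping at a given threshold."""

    assignments: dict[str, str]
    threshold_used: float

    def __getitem__(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, hg in self.assignments.items():
            out.setdefault(hg, []).append(sid)
        return out


@dataclass(frozen=True)
class DiagnosticSite:
    """Alignment column (1-based) at which two groups have disjoint states."""

    position: int
    state_a: frozenset[str]
    state_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.state_a & self.state_b:
            raise ValueError("diagnostic states must be disjoint")


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected distance: mismatches / comparable sites.

    Comparable sites have an unambiguous A/C/G/T in both sequences (pairwise
    deletion of gaps, N and IUPAC ambiguity codes).  Returns NaN when no site
    is comparable — an undefined distance, deliberately distinct from 0.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    comparable = 0
    mismatches = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        return math.nan
    return mismatches / comparable


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All pairwise p-distances of an alignment (symmetric, zero diagonal)."""
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    # vectorized over columns: code A/C/G/T as 0..3, everything else missing
    lut = np.full(256, -1, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        lut[ord(base)] = i
    codes = np.vstack([
        lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        for s in aln.sequences
    ])
    valid = codes >= 0
    n = len(aln)
    values = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        comparable = both.sum(axis=1)
        mismatch = ((codes[i] != codes[i + 1:]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comparable > 0, mismatch / np.maximum(comparable, 1),
                         np.nan)
        values[i, i + 1:] = d
        values[i + 1:, i] = d
    return DistanceMatrix(list(aln.ids), values)


def cluster_haplogroups(dm: DistanceMatrix,
                        theta: float = DEFAULT_THETA) -> HaplogroupAssignment:
    """Single-linkage clusters at distance threshold ``theta``.

    Samples joined by any chain of pairwise distances <= theta share a
    haplogroup.  Group ids ("H1", "H2", ...) are assigned by order of each
    group's first member in the matrix, so the partition is invariant to
    input order up to this deterministic relabelling.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    if dm.has_undefined:
        raise ValueError("distance matrix has undefined entries")
    adjacency = csr_matrix(dm.values <= theta)
    _, labels = connected_components(adjacency, directed=False)
    relabel: dict[int, str] = {}
    assignments: dict[str, str] = {}
    for sid, lab in zip(dm.ids, labels):
        if lab not in relabel:
            relabel[lab] = f"H{len(relabel) + 1}"
        assignments[sid] = relabel[lab]
    return HaplogroupAssignment(assignments, theta)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a p-distance matrix.

    Standard saitou-nei agglomeration on the Q criterion; ties on Q are
    broken by joining the pair whose (sorted) representative leaf labels are
    lexicographically smallest, making the output deterministic.  Negative
    branch lengths are clamped to 0 with the deficit moved to the sister
    branch.  The tree is unrooted (trifurcating root node).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa; "
                         "smaller inputs have a trivial topology")
    if dm.has_undefined:
        raise ValueError("distance matrix has undefined entries")

    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for label in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    # representative label per active node: smallest leaf label underneath
    reps = list(dm.ids)
    d = dm.values.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # tie-break: lexicographically smallest (sorted) label pair
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((reps[active[a]], reps[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best  # type: ignore[misc]
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the rest
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        k = d.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [k]

    # closed-form three-point attachment for the final trifurcation
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = dendropy.Node()
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.edge.length = max(ln, 0.0)
        root.add_child(node)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def diagnostic_sites(aln: Alignment, group_a: set[str], group_b: set[str],
                     strict: bool = False) -> list[DiagnosticSite]:
    """Columns where two groups show disjoint unambiguous nucleotide states.

    A column is eligible when each group contributes at least one unambiguous
    A/C/G/T observation; N, gaps and ambiguity codes are ignored by default.
    With ``strict=True`` any non-ACGT character in either group disqualifies
    the column.  Positions are reported 1-based, ascending.
    """
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    overlap = group_a & group_b
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    seqs_a = [aln.sequence(i) for i in sorted(group_a)]
    seqs_b = [aln.sequence(i) for i in sorted(group_b)]
    sites: list[DiagnosticSite] = []
    for col in range(aln.length):
        col_a = [s[col] for s in seqs_a]
        col_b = [s[col] for s in seqs_b]
        states_a = frozenset(c for c in col_a if c in UNAMBIGUOUS)
        states_b = frozenset(c for c in col_b if c in UNAMBIGUOUS)
        if not states_a or not states_b:
            continue
        if strict and (len(states_a) < len(col_a) or len(states_b) < len(col_b)):
            continue
        if not (states_a & states_b):
            sites.append(DiagnosticSite(col + 1, states_a, states_b))
    return sites


def min_between_group_distance(dm: DistanceMatrix, group_a: set[str],
                               group_b: set[str]) -> float:
    """Minimum pairwise p-distance between members of two groups."""
    ia = [dm.ids.index(s) for s in sorted(group_a)]
    ib = [dm.ids.index(s) for s in sorted(group_b)]
    block = dm.values[np.ix_(ia, ib)]
    if np.isnan(block).all():
        return math.nan
    return float(np.nanmin(block))
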