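"""Karyotype group summaries and fixed-difference comparisons.

Chromosome number in these butterflies evolves by fusions/fissions and is the
primary species-level character.  A putative taxon is summarized by its range
of haploid counts (exact counts kept apart from approximate "ca" counts), its
modal count, and its marker-bivalent structure signature.  Two groups are then
compared under a fixed-difference rule: a shared structure with a count gap of
at least ``delta`` (the species-level gap, default 3) is treated as a fixed
chromosomal difference, the kind expected to disrupt meiosis in hybrids.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io import KaryotypeObservation, StructureSignature

__all__ = [
    "DEFAULT_DELTA",
    "GroupSummary",
    "KaryoRelation",
    "KaryoComparison",
    "summarize_group",
    "compare_groups",
    "karyotype_classes",
]

#: Default species-level count gap: gaps of 1-2 between same-structure groups
#: are treated as intraspecific (subspecies-grade), gaps of 3 or more as fixed.
DEFAULT_DELTA = 3


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    n_samples: int
    exact_min: int | None
    exact_max: int | None
    approx_min: int | None
    approx_max: int | None
    modal_count: int
    structure: StructureSignature
    any_multivalents: bool

    @property
    def count_range(self) -> tuple[int, int]:
        """Best available (min, max): exact counts preferred, else approximate."""
        if self.exact_min is not None:
            return self.exact_min, self.exact_max  # type: ignore[return-value]
        if self.approx_min is not None:
            return self.approx_min, self.approx_max  # type: ignore[return-value]
        raise ValueError(f"group {self.group_id} has no counts")

    @property
    def approximate_only(self) -> bool:
        return self.exact_min is None


class KaryoRelation(str, Enum):
    INDISTINGUISHABLE = "indistinguishable"
    MINOR_COUNT_DIFFERENCE = "minor_count_difference"
    FIXED_COUNT_DIFFERENCE = "fixed_count_difference"
    STRUCTURE_DIFFERENCE = "structure_difference"


@dataclass(frozen=True)
class KaryoComparison:
    """Outcome of comparing two karyotype group summaries.

    ``count_gap`` is the distance between the nearest endpoints of the two
    count ranges (0 when they overlap).  ``low_confidence`` marks comparisons
    where at least one side had only approximate ("ca") counts.
    """

    relation: KaryoRelation
    count_gap: int
    structures_equal: bool
    low_confidence: bool = False


def summarize_group(observations: Sequence[KaryotypeObservation],
                    group_id: str) -> GroupSummary:
    """Summarize the karyotype observations of one putative taxon.

    The exact range covers non-approximate counts only, the approximate range
    the "ca" counts; the modal count is taken over all observations by numeric
    value, ties broken toward the smaller value.
    """
    if not observations:
        raise ValueError("cannot summarize an empty observation list")
    exact = sorted(o.n_count for o in observations if not o.approximate)
    approx = sorted(o.n_count for o in observations if o.approximate)
    counts = Counter(o.n_count for o in observations)
    top = max(counts.values())
    modal = min(v for v, c in counts.items() if c == top)
    structures = Counter(o.structure for o in observations)
    top_s = max(structures.values())
    structure = min((s for s, c in structures.items() if c == top_s),
                    key=lambda s: (s.n_large, s.n_medium))
    return GroupSummary(
        group_id=group_id,
        n_samples=len(observations),
        exact_min=exact[0] if exact else None,
        exact_max=exact[-1] if exact else None,
        approx_min=approx[0] if approx else None,
        approx_max=approx[-1] if approx else None,
        modal_count=modal,
        structure=structure,
        any_multivalents=any(o.multivalents_observed for o in observations),
    )


def _range_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    if lo <= hi:  # ranges overlap
        return 0
    return lo - hi


def compare_groups(a: GroupSummary, b: GroupSummary,
                   delta: int = DEFAULT_DELTA) -> KaryoComparison:
    """Classify the karyotype relation between two groups.

    A structure mismatch dominates; otherwise the gap between count ranges
    decides: 0 → indistinguishable, 1..delta-1 → minor (subspecies-grade)
    difference, >= delta → fixed (species-grade) difference.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    gap = _range_gap(a.count_range, b.count_range)
    structures_equal = a.structure == b.structure
    if not structures_equal:
        relation = KaryoRelation.STRUCTURE_DIFFERENCE
    elif gap == 0:
        relation = KaryoRelation.INDISTINGUISHABLE
    elif gap >= delta:
        relation = KaryoRelation.FIXED_COUNT_DIFFERENCE
    else:
        relation = KaryoRelation.MINOR_COUNT_DIFFERENCE
    return KaryoComparison(
        relation=relation,
        count_gap=gap,
        structures_equal=structures_equal,
        low_confidence=a.approximate_only or b.approximate_only,
    )


def karyotype_classes(observations: Iterable[KaryotypeObservation],
                      delta: int = DEFAULT_DELTA) -> Mapping[str, str]:
    """Partition samples into karyotype classes by chaining similar karyotypes.

    Two observations are linked when they share the structure signature and
    their haploid counts differ by less than ``delta``; classes are the
    connected components of that relation.  Chaining lets a class absorb the
    intraspecific count variability seen in real taxa (e.g. a 77-79 or 29-34
    range) while keeping same-structure groups separated by a fixed gap apart.
    Class ids ("K1", "K2", ...) are assigned by order of first member.
    """
    obs = list(observations)
    parent = list(range(len(obs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # link within structure groups via sorted counts: chaining makes linking
    # consecutive counts sufficient for full transitive closure
    by_structure: dict[StructureSignature, list[int]] = {}
    for i, o in enumerate(obs):
        by_structure.setdefault(o.structure, []).append(i)
    for idxs in by_structure.values():
        idxs_sorted = sorted(idxs, key=lambda i: obs[i].n_count)
        for i, j in zip(idxs_sorted, idxs_sorted[1:]):
            if obs[j].n_count - obs[i].n_count < delta:
                union(i, j)

    labels: dict[str, str] = {}
    root_to_class: dict[int, str] = {}
    for i, o in enumerate(obs):
        r = find(i)
        if r not in root_to_class:
            root_to_class[r] = f"K{len(root_to_class) + 1}"
        labels[o.sample_id] = root_to_class[r]
    return labels
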