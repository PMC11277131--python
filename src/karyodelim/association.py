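"""Sympatry detection and the within-locality marker-association test.

Karyotype (nuclear) and mitochondrial barcode are unlinked genome
compartments.  Within one interbreeding population they should combine at
random (linkage equilibrium); two reproductively isolated species coexisting
at a site instead show stable species-specific combinations — an apparent
linkage disequilibrium between unlinked markers.  This module formalizes that
criterion as a permutation test of a karyotype-class x haplogroup contingency
table using the G statistic, with exact enumeration of label permutations on
small tables, plus a screen for chromosomal heterozygotes (multivalents),
whose absence corroborates the lack of hybridization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from sympy.utilities.iterables import multiset_permutations

from .io import KaryotypeObservation, Locality, SampleRecord

__all__ = [
    "EXACT_ENUMERATION_LIMIT",
    "SympatryMap",
    "AssociationResult",
    "detect_sympatry",
    "association_test",
    "g_statistic",
    "heterozygote_screen",
    "haversine_km",
]

#: Exact enumeration replaces permutation sampling when the number of
#: distinct label arrangements is at most this.
EXACT_ENUMERATION_LIMIT = 10_000

_EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points in kilometres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class SympatryMap:
    """Which groups co-occur where.

    ``sites`` maps a (possibly merged) site id to the set of group ids found
    there; a pair of groups is sympatric iff some site contains both.
    """

    sites: dict[str, set[str]]

    def is_sympatric(self, group_a: str, group_b: str) -> bool:
        return any(group_a in g and group_b in g for g in self.sites.values())

    def shared_sites(self, group_a: str, group_b: str) -> list[str]:
        return sorted(s for s, g in self.sites.items()
                      if group_a in g and group_b in g)

    def cooccurrence(self) -> dict[tuple[str, str], bool]:
        groups = sorted({g for s in self.sites.values() for g in s})
        return {(a, b): self.is_sympatric(a, b)
                for i, a in enumerate(groups) for b in groups[i + 1:]}


def _species_level_label(taxon_label: str) -> str:
    """Genus + species epithet prefix of a trinomial label."""
    parts = taxon_label.split()
    return " ".join(parts[:2]) if len(parts) >= 2 else taxon_label


def detect_sympatry(records: Sequence[SampleRecord],
                    localities: Sequence[Locality] | None = None,
                    radius_km: float = 0.0,
                    groups: Mapping[str, str] | None = None) -> SympatryMap:
    """Compute group co-occurrence across collecting sites.

    Localities whose great-circle distance is at most ``radius_km`` are merged
    into one site (single-linkage) before co-occurrence is computed; with the
    default radius 0 this is a pure group-by on locality_id.  ``groups`` maps
    sample_id to a group id; by default the species-level prefix of the
    record's taxon_label is used.
    """
    if radius_km < 0:
        raise ValueError("radius_km must be >= 0")
    loc_index = {l.locality_id: l for l in (localities or [])}
    for rec in records:
        if rec.locality_id and localities is not None and rec.locality_id not in loc_index:
            raise ValueError(
                f"sample {rec.sample_id!r} has unknown locality_id {rec.locality_id!r}")

    # merge localities within radius via single linkage
    merged: dict[str, str] = {}
    if radius_km > 0 and localities:
        locs = list(localities)
        parent = list(range(len(locs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(locs)):
            for j in range(i + 1, len(locs)):
                dij = haversine_km(locs[i].latitude, locs[i].longitude,
                                   locs[j].latitude, locs[j].longitude)
                if dij <= radius_km:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        comp: dict[int, list[str]] = {}
        for i, loc in enumerate(locs):
            comp.setdefault(find(i), []).append(loc.locality_id)
        for members in comp.values():
            site_id = "+".join(sorted(members))
            for lid in members:
                merged[lid] = site_id

    sites: dict[str, set[str]] = {}
    for rec in records:
        site = merged.get(rec.locality_id, rec.locality_id)
        gid = (groups[rec.sample_id] if groups is not None
               else _species_level_label(rec.taxon_label))
        sites.setdefault(site, set()).add(gid)
    return SympatryMap(sites)


@dataclass(frozen=True)
class AssociationResult:
    locality_id: str
    table: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    statistic: float
    p_value: float
    n_permutations: int
    exact: bool
    one_to_one: bool
    degenerate: bool = False


def g_statistic(table: np.ndarray) -> float:
    """Likelihood-ratio (G) statistic of independence for a contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def _is_one_to_one(table: np.ndarray) -> bool:
    nz = table > 0
    return bool((nz.sum(axis=1) == 1).all() and (nz.sum(axis=0) == 1).all())


def _g_from_label_arrays(rows: np.ndarray, cols: np.ndarray,
                         n_rows: int, n_cols: int) -> np.ndarray:
    """Vectorized G for one row-label vector against many column-label rows.

    ``cols`` has shape (m, n).  Expected counts depend only on the margins,
    which are permutation-invariant, so only the O*log(O) term varies.
    """
    m, n = cols.shape
    flat = rows[None, :] * n_cols + cols
    counts = np.zeros((m, n_rows * n_cols), dtype=np.int64)
    row_idx = np.repeat(np.arange(m), n)
    np.add.at(counts, (row_idx, flat.ravel()), 1)
    row_marg = np.bincount(rows, minlength=n_rows).astype(float)
    col_marg = np.bincount(cols[0], minlength=n_cols).astype(float)
    expected = np.outer(row_marg, col_marg).ravel() / n
    with np.errstate(divide="ignore", invalid="ignore"):
        log_e = np.where(expected > 0, np.log(expected), 0.0)
        c = counts.astype(float)
        o_log_o = np.where(c > 0, c * np.log(c), 0.0)
    return 2.0 * (o_log_o - c * log_e).sum(axis=1)


def _n_distinct_permutations(cols: np.ndarray, n_cols: int) -> float:
    counts = np.bincount(cols, minlength=n_cols)
    return float(np.exp(gammaln(len(cols) + 1) - gammaln(counts + 1).sum()))


def association_test(samples: Sequence[tuple[str, str]],
                     n_permutations: int = 9999,
                     seed: int = 0,
                     locality_id: str = "") -> AssociationResult:
    """Permutation test of karyotype-class x haplogroup association.

    ``samples`` is a list of (karyotype class, haplogroup) pairs for the
    individuals of one site.  The null distribution is built by permuting the
    haplogroup labels; when the number of distinct permutations is at most
    EXACT_ENUMERATION_LIMIT the full set is enumerated (p = b/m over all
    arrangements), otherwise ``n_permutations`` are sampled and the add-one
    estimator p = (b+1)/(m+1) is used.  ``one_to_one`` reports whether the
    observed table maps each karyotype class to exactly one haplogroup and
    vice versa — the "stable species-specific combinations" pattern.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    row_labels = tuple(sorted({k for k, _ in samples}))
    col_labels = tuple(sorted({h for _, h in samples}))
    r_idx = {k: i for i, k in enumerate(row_labels)}
    c_idx = {h: i for i, h in enumerate(col_labels)}
    rows = np.array([r_idx[k] for k, _ in samples])
    cols = np.array([c_idx[h] for _, h in samples])
    n_rows, n_cols = len(row_labels), len(col_labels)
    table = np.zeros((n_rows, n_cols), dtype=np.int64)
    np.add.at(table, (rows, cols), 1)

    if n_rows == 1 and n_cols == 1:
        warnings.warn("degenerate table: a single karyotype class and a "
                      "single haplogroup; no association is testable")
        return AssociationResult(locality_id, table, row_labels, col_labels,
                                 0.0, 1.0, 0, True, True, degenerate=True)

    observed = g_statistic(table)
    if n_rows == 1 or n_cols == 1:
        # margins fully determine the table; G is identically 0
        return AssociationResult(locality_id, table, row_labels, col_labels,
                                 observed, 1.0, 0, True, _is_one_to_one(table))

    n_distinct = _n_distinct_permutations(cols, n_cols)
    tol = 1e-9
    if n_distinct <= EXACT_ENUMERATION_LIMIT * (1 + 1e-9):
        perms = np.array(list(multiset_permutations(cols.tolist())))
        stats = _g_from_label_arrays(rows, perms, n_rows, n_cols)
        b = int((stats >= observed - tol).sum())
        p = b / len(perms)
        return AssociationResult(locality_id, table, row_labels, col_labels,
                                 observed, p, len(perms), True,
                                 _is_one_to_one(table))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(cols, (n_permutations, 1)), axis=1)
    stats = _g_from_label_arrays(rows, perms, n_rows, n_cols)
    b = int((stats >= observed - tol).sum())
    p = (b + 1) / (n_permutations + 1)
    return AssociationResult(locality_id, table, row_labels, col_labels,
                             observed, p, n_permutations, False,
                             _is_one_to_one(table))


def heterozygote_screen(observations: Iterable[KaryotypeObservation]) -> bool:
    """True iff any observation shows multivalents (chromosomal heterozygotes).

    Multivalents at meiotic metaphase I are the expected signature of hybrids
    between chromosomally divergent forms; their absence across a sympatric
    sample supports reproductive isolation.
    """
    obs = list(observations)
    if not obs:
        warnings.warn("heterozygote screen on an empty observation list")
        return False
    return any(o.multivalents_observed for o in obs)
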