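"""Rule engine turning karyotype, barcode, sympatry and heterozygote evidence
into pairwise taxonomic verdicts, plus the end-to-end pipeline.

The decision framework distinguishes two regimes.  In sympatry, reproductive
isolation is directly testable: stable one-to-one combinations of karyotype
class and mitochondrial haplogroup (significant association, no chromosomal
heterozygotes) demonstrate separate gene pools; random combinations or
heterozygotes indicate one polymorphic species.  In allopatry, isolation must
be inferred: fixed karyotype differences (structure mismatch or a count gap of
at least delta) indicate distinct species even when barcodes are shared — the
shared-barcode case is flagged as likely mitochondrial introgression; groups
with equal-grade karyotypes but differentiated barcodes are phylogeographic
sublineages (subspecies); groups differing in nothing are synonyms.

Rules fire in a fixed, total order (R1..R6); exactly one rule fires per pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from . import association as assoc_mod
from . import barcode as barcode_mod
from . import karyotype as karyo_mod
from .io import (Alignment, KaryotypeObservation, Locality, SampleRecord,
                 read_alignment, read_karyotype_table, read_locality_table)
from .karyotype import (GroupSummary, KaryoComparison, KaryoRelation,
                        compare_groups, karyotype_classes, summarize_group)

__all__ = [
    "Decision",
    "Evidence",
    "Verdict",
    "RunConfig",
    "PipelineResult",
    "decide",
    "barcode_differentiation",
    "run_pipeline",
]


class Decision(str, Enum):
    DISTINCT_SPECIES = "distinct_species"
    CONSPECIFIC_SUBSPECIES = "conspecific_subspecies"
    SYNONYM = "synonym"
    SINGLE_POLYMORPHIC_SPECIES = "single_polymorphic_species"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Evidence:
    """Everything the rule engine consults for one pair of groups.

    ``association_p`` and ``one_to_one`` are None for allopatric pairs (the
    association test needs co-occurring samples).  ``barcode_differentiated``
    may be None when one side lacks sequences (karyotype-only group).
    """

    sympatric: bool
    karyo_relation: KaryoComparison
    barcode_differentiated: bool | None
    n_diagnostic_sites: int
    association_p: float | None = None
    one_to_one: bool | None = None
    heterozygotes: bool = False


@dataclass(frozen=True)
class Verdict:
    group_a: str
    group_b: str
    decision: Decision
    rule_fired: str
    evidence: Evidence
    introgression_flag: bool = False
    karyotype_only: bool = False
    low_confidence: bool = False


_FIXED_GRADE = {KaryoRelation.STRUCTURE_DIFFERENCE,
                KaryoRelation.FIXED_COUNT_DIFFERENCE}
_CONSPECIFIC_GRADE = {KaryoRelation.INDISTINGUISHABLE,
                      KaryoRelation.MINOR_COUNT_DIFFERENCE}


def decide(evidence: Evidence, alpha: float = 0.05,
           group_a: str = "A", group_b: str = "B") -> Verdict:
    """Apply the decision rules to one pair of groups.

    Pure function of the evidence; the first matching rule fires:

    R1  sympatric, stable one-to-one combinations (p < alpha and one-to-one),
        no heterozygotes                      -> distinct_species
    R2  sympatric, heterozygotes present or association not significant
                                              -> single_polymorphic_species
    R3  allopatric, fixed karyotype difference -> distinct_species
        (introgression flagged when barcodes are NOT differentiated)
    R4  allopatric, conspecific-grade karyotype, barcodes differentiated
                                              -> conspecific_subspecies
    R5  allopatric, indistinguishable karyotype, barcodes not differentiated
                                              -> synonym
    R6  otherwise                             -> unresolved
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ev = evidence
    low_conf = ev.karyo_relation.low_confidence
    karyotype_only = ev.barcode_differentiated is None

    if ev.sympatric:
        if ev.association_p is None:
            raise ValueError("sympatric pair with no association test result")
        significant = ev.association_p < alpha
        if significant and bool(ev.one_to_one) and not ev.heterozygotes:
            return Verdict(group_a, group_b, Decision.DISTINCT_SPECIES, "R1",
                           ev, low_confidence=low_conf,
                           karyotype_only=karyotype_only)
        if ev.heterozygotes or not significant:
            return Verdict(group_a, group_b,
                           Decision.SINGLE_POLYMORPHIC_SPECIES, "R2", ev,
                           low_confidence=low_conf,
                           karyotype_only=karyotype_only)
        return Verdict(group_a, group_b, Decision.UNRESOLVED, "R6", ev,
                       low_confidence=low_conf, karyotype_only=karyotype_only)

    relation = ev.karyo_relation.relation
    if relation in _FIXED_GRADE:
        introgression = ev.barcode_differentiated is False
        return Verdict(group_a, group_b, Decision.DISTINCT_SPECIES, "R3", ev,
                       introgression_flag=introgression,
                       low_confidence=low_conf, karyotype_only=karyotype_only)
    if relation in _CONSPECIFIC_GRADE and ev.barcode_differentiated:
        return Verdict(group_a, group_b, Decision.CONSPECIFIC_SUBSPECIES,
                       "R4", ev, low_confidence=low_conf)
    if (relation is KaryoRelation.INDISTINGUISHABLE
            and ev.barcode_differentiated is False):
        return Verdict(group_a, group_b, Decision.SYNONYM, "R5", ev,
                       low_confidence=low_conf)
    return Verdict(group_a, group_b, Decision.UNRESOLVED, "R6", ev,
                   low_confidence=low_conf, karyotype_only=karyotype_only)


def barcode_differentiation(aln: Alignment, group_a: set[str],
                            group_b: set[str],
                            dm: barcode_mod.DistanceMatrix,
                            theta: float = barcode_mod.DEFAULT_THETA,
                            ) -> tuple[bool, int]:
    """Are two groups differentiated by their barcodes?

    True when at least one diagnostic fixed site separates them OR the
    minimum between-group p-distance exceeds ``theta`` (the haplogroup
    threshold) — the distance criterion stands in for sublineage monophyly.
    Returns (differentiated, number of diagnostic sites).
    """
    sites = barcode_mod.diagnostic_sites(aln, group_a, group_b)
    if sites:
        return True, len(sites)
    min_d = barcode_mod.min_between_group_distance(dm, group_a, group_b)
    return bool(min_d > theta), 0


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters; every report echoes these for reproducibility."""

    theta: float = barcode_mod.DEFAULT_THETA   # haplogroup threshold
    delta: int = karyo_mod.DEFAULT_DELTA       # species-level count gap
    alpha: float = 0.05                        # association significance
    n_permutations: int = 9999
    radius_km: float = 0.0
    seed: int = 0

    def as_dict(self) -> dict[str, float | int]:
        return {"theta": self.theta, "delta": self.delta, "alpha": self.alpha,
                "n_permutations": self.n_permutations,
                "radius_km": self.radius_km, "seed": self.seed}


@dataclass
class PipelineResult:
    config: RunConfig
    records: list[SampleRecord]
    observations: dict[str, KaryotypeObservation]
    group_of: dict[str, str]                  # sample_id -> final group id
    group_members: dict[str, list[str]]
    summaries: dict[str, GroupSummary]
    sympatry: assoc_mod.SympatryMap
    association_results: list[assoc_mod.AssociationResult]
    verdicts: list[Verdict]
    tree: dendropy.Tree | None
    haplogroups: barcode_mod.HaplogroupAssignment | None

    def verdict_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            ev = v.evidence
            rows.append({
                "group_a": v.group_a,
                "group_b": v.group_b,
                "decision": v.decision.value,
                "rule_fired": v.rule_fired,
                "sympatric": ev.sympatric,
                "karyo_relation": ev.karyo_relation.relation.value,
                "count_gap": ev.karyo_relation.count_gap,
                "structures_equal": ev.karyo_relation.structures_equal,
                "barcode_differentiated": ev.barcode_differentiated,
                "n_diagnostic_sites": ev.n_diagnostic_sites,
                "association_p": ev.association_p,
                "one_to_one": ev.one_to_one,
                "heterozygotes": ev.heterozygotes,
                "introgression_flag": v.introgression_flag,
                "karyotype_only": v.karyotype_only,
                "low_confidence": v.low_confidence,
            })
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.summaries):
            s = self.summaries[gid]
            rows.append({
                "group_id": gid, "n_samples": s.n_samples,
                "exact_min": s.exact_min, "exact_max": s.exact_max,
                "approx_min": s.approx_min, "approx_max": s.approx_max,
                "modal_count": s.modal_count, "structure": str(s.structure),
                "any_multivalents": s.any_multivalents,
            })
        return pd.DataFrame(rows)


def _assign_groups(records: Sequence[SampleRecord],
                   observations: Mapping[str, KaryotypeObservation],
                   haplogroups: barcode_mod.HaplogroupAssignment | None,
                   delta: int) -> dict[str, str]:
    """Final group labels: one group per observed (karyotype class, haplogroup)
    combination.

    Karyotype classes chain same-structure samples with count gaps below
    delta.  Samples with a karyotype but no sequence join the combination
    group of their class when the class carries a single haplogroup among
    sequenced samples, preferring a group seen at the same locality; otherwise
    they form a karyotype-only group.  Sequence-only samples join the unique
    class of their haplogroup when one exists.
    """
    kclass = karyotype_classes(
        [observations[r.sample_id] for r in records
         if r.sample_id in observations], delta)
    hg = haplogroups.assignments if haplogroups is not None else {}

    pair_of: dict[str, tuple[str | None, str | None]] = {}
    for rec in records:
        sid = rec.sample_id
        pair_of[sid] = (kclass.get(sid), hg.get(sid))

    # karyotype class -> haplogroups seen among fully-typed samples (and the
    # localities where each combination occurs)
    combos: dict[str, dict[str, set[str]]] = {}
    hap_to_classes: dict[str, set[str]] = {}
    for rec in records:
        k, h = pair_of[rec.sample_id]
        if k is not None and h is not None:
            combos.setdefault(k, {}).setdefault(h, set()).add(rec.locality_id)
            hap_to_classes.setdefault(h, set()).add(k)

    group_of: dict[str, str] = {}
    for rec in records:
        sid = rec.sample_id
        k, h = pair_of[sid]
        if k is not None and h is None:
            seen = combos.get(k, {})
            if len(seen) == 1:
                h = next(iter(seen))
            else:
                at_loc = [hh for hh, locs in seen.items()
                          if rec.locality_id in locs]
                h = at_loc[0] if len(at_loc) == 1 else None
        elif k is None and h is not None:
            classes = hap_to_classes.get(h, set())
            if len(classes) == 1:
                k = next(iter(classes))
        group_of[sid] = f"{k or '?'}|{h or '?'}"
    return group_of


def run_pipeline(karyotype_path: str | Path,
                 fasta_path: str | Path | None,
                 locality_path: str | Path | None,
                 config: RunConfig = RunConfig()) -> PipelineResult:
    """Run the full delimitation pipeline on file inputs.

    Samples may carry a karyotype, a sequence, or both, but at least one
    sample must have both so karyotype classes and haplogroups can be tied
    together.  Groups are the observed (karyotype class, haplogroup)
    combinations; every group pair is adjudicated by ``decide``.
    """
    rows = read_karyotype_table(karyotype_path)
    records = [rec for rec, _ in rows]
    observations = {rec.sample_id: obs for rec, obs in rows}
    localities = (read_locality_table(locality_path)
                  if locality_path is not None else None)

    aln = dm = haplogroups = tree = None
    if fasta_path is not None:
        aln = read_alignment(fasta_path)
        known = {r.sample_id for r in records}
        for sid in aln.ids:
            if sid not in known:
                records.append(SampleRecord(sid))
        joint = known & set(aln.ids)
        if not joint:
            raise ValueError("no sample has both a karyotype and a sequence; "
                             "the pipeline needs joint samples")
        dm = barcode_mod.distance_matrix(aln)
        haplogroups = barcode_mod.cluster_haplogroups(dm, config.theta)
        if len(aln) >= 3:
            tree = barcode_mod.neighbor_joining(dm)

    group_of = _assign_groups(records, observations, haplogroups, config.delta)
    group_members: dict[str, list[str]] = {}
    for rec in records:
        group_members.setdefault(group_of[rec.sample_id], []).append(rec.sample_id)

    summaries = {}
    for gid, members in group_members.items():
        obs = [observations[s] for s in members if s in observations]
        if obs:
            summaries[gid] = summarize_group(obs, gid)

    sympatry = assoc_mod.detect_sympatry(
        [r for r in records if r.locality_id], localities,
        config.radius_km, groups=group_of)

    association_results: list[assoc_mod.AssociationResult] = []
    verdicts: list[Verdict] = []
    gids = sorted(group_members)
    for i, ga in enumerate(gids):
        for gb in gids[i + 1:]:
            if ga not in summaries or gb not in summaries:
                continue  # no karyotype data on one side: nothing to compare
            comparison = compare_groups(summaries[ga], summaries[gb],
                                        config.delta)
            seq_a = {s for s in group_members[ga] if aln and s in aln.ids}
            seq_b = {s for s in group_members[gb] if aln and s in aln.ids}
            if seq_a and seq_b:
                differentiated, n_sites = barcode_differentiation(
                    aln, seq_a, seq_b, dm, config.theta)
            else:
                differentiated, n_sites = None, 0

            sympatric = sympatry.is_sympatric(ga, gb)
            p_value = one_to_one = None
            heterozygotes = False
            if sympatric:
                shared = set(sympatry.shared_sites(ga, gb))
                site_of: dict[str, str] = {}
                for rec in records:
                    for s in shared:
                        if rec.locality_id and rec.locality_id in s.split("+"):
                            site_of[rec.sample_id] = s
                pair_samples = [
                    (group_of[rec.sample_id], haplogroups[rec.sample_id]
                     if haplogroups and rec.sample_id in haplogroups.assignments
                     else "?")
                    for rec in records
                    if rec.sample_id in site_of
                    and group_of[rec.sample_id] in (ga, gb)
                ]
                labelled = [(k, h) for k, h in pair_samples if h != "?"]
                if len(labelled) >= 2:
                    res = assoc_mod.association_test(
                        labelled, config.n_permutations, config.seed,
                        locality_id=",".join(sorted(shared)))
                    association_results.append(res)
                    p_value, one_to_one = res.p_value, res.one_to_one
                heterozygotes = assoc_mod.heterozygote_screen(
                    [observations[rec.sample_id] for rec in records
                     if rec.sample_id in site_of
                     and group_of[rec.sample_id] in (ga, gb)
                     and rec.sample_id in observations])
                if p_value is None:
                    # co-occurring but untestable (no sequenced samples on a
                    # side); fall back to the allopatric-style comparison
                    sympatric = False

            evidence = Evidence(
                sympatric=sympatric,
                karyo_relation=comparison,
                barcode_differentiated=differentiated,
                n_diagnostic_sites=n_sites,
                association_p=p_value,
                one_to_one=one_to_one,
                heterozygotes=heterozygotes,
            )
            verdicts.append(decide(evidence, config.alpha, ga, gb))

    return PipelineResult(
        config=config, records=records, observations=observations,
        group_of=group_of, group_members=group_members, summaries=summaries,
        sympatry=sympatry, association_results=association_results,
        verdicts=verdicts, tree=tree, haplogroups=haplogroups,
    )
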