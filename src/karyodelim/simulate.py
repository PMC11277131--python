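"""Synthetic cryptic-species-complex datasets with known truth.

The generator emulates the statistical structure of a karyotype + barcode
delimitation study: K species, each with a species-specific haploid-count
range (uniform integer noise around a base count — the data report ranges,
not a fission/fusion process model), a marker-bivalent structure signature,
and a barcode consensus carrying species-diagnostic fixed sites; individual
barcodes add independent per-site mutations.  Optional mitochondrial
introgression replaces a recipient species' consensus with the donor's before
within-species mutation (complete haplotype capture), reproducing the
barcode-identity-despite-karyotype-divergence pattern seen between real
chromosomally divergent species pairs.  Localities define sympatric and
allopatric layouts.  Output files are byte-identical for identical seeds.

Fixed sites are implemented as ``n_fixed_diffs`` shared diagnostic columns at
which every species carries a distinct nucleotide, so every species pair
differs at exactly ``n_fixed_diffs`` positions and the minimum between-species
p-distance under zero within-species mutation is exactly
``n_fixed_diffs / seq_length``.  With four nucleotides this caps the number of
species at 4 when ``n_fixed_diffs`` > 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .io import (Alignment, KaryotypeObservation, Locality, SampleRecord,
                 StructureSignature, write_alignment, write_karyotype_table,
                 write_locality_table)
from .karyotype import DEFAULT_DELTA
from .barcode import DEFAULT_THETA

__all__ = [
    "SpeciesSpec",
    "LocalitySpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "write_dataset",
    "reference_karyotype_fixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SpeciesSpec:
    """Generating parameters for one species."""

    species_id: str
    base_n: int                      # haploid chromosome number (center)
    count_spread: int = 0            # counts drawn uniformly in base_n +/- spread
    structure: StructureSignature = StructureSignature(1, 1)
    n_samples: int = 8

    def count_range(self) -> tuple[int, int]:
        return self.base_n - self.count_spread, self.base_n + self.count_spread


@dataclass(frozen=True)
class LocalitySpec:
    locality_id: str
    name: str
    latitude: float
    longitude: float
    species: tuple[str, ...]         # species collected at this site


def _default_species() -> tuple[SpeciesSpec, ...]:
    # Three-species cryptic complex: a high-count
    # species (n=90, one large + one medium marker bivalent), a mid-count
    # sister with intraspecific variability (n=77-79, same structure), and a
    # species distinguished by structure alone (n=79, a single large bivalent).
    return (
        SpeciesSpec("sp1", base_n=90, count_spread=0,
                    structure=StructureSignature(1, 1), n_samples=8),
        SpeciesSpec("sp2", base_n=78, count_spread=1,
                    structure=StructureSignature(1, 1), n_samples=8),
        SpeciesSpec("sp3", base_n=79, count_spread=0,
                    structure=StructureSignature(1, 0), n_samples=8),
    )


def _default_localities() -> tuple[LocalitySpec, ...]:
    # One site where two species fly together plus an allopatric site for the
    # third, mirroring a sympatric mountain locality and a distant range.
    return (
        LocalitySpec("siteA", "sympatric highland site", 39.67, 45.29,
                     ("sp2", "sp3")),
        LocalitySpec("siteB", "allopatric eastern site", 39.20, 71.20,
                     ("sp1",)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    species: tuple[SpeciesSpec, ...] = field(default_factory=_default_species)
    localities: tuple[LocalitySpec, ...] = field(default_factory=_default_localities)
    seq_length: int = 658
    n_fixed_diffs: int = 20   # ~3% of 658 bp: congener-level COI divergence
    within_species_mutation_rate: float = 0.002
    introgression_pairs: tuple[tuple[str, str], ...] = ()   # (donor, recipient)
    approx_fraction: float = 0.3     # fraction of counts emitted as "ca"
    seed: int = 0
    # analysis parameters assumed when deriving expected decisions
    delta: int = DEFAULT_DELTA
    theta: float = DEFAULT_THETA

    def validate(self) -> None:
        if not self.species:
            raise ValueError("need at least one species")
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")
        for s in self.species:
            if s.n_samples < 1:
                raise ValueError(f"species {s.species_id} has n_samples=0")
            if s.base_n - s.count_spread < 1:
                raise ValueError(f"species {s.species_id} count range below 1")
        if self.n_fixed_diffs > self.seq_length:
            raise ValueError("seq_length too short to host all fixed differences")
        if self.n_fixed_diffs > 0 and len(self.species) > len(_BASES):
            raise ValueError("at most 4 species supported with shared "
                             "diagnostic columns (one base per species)")
        if not 0.0 <= self.within_species_mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if not 0.0 <= self.approx_fraction <= 1.0:
            raise ValueError("approx_fraction must be in [0, 1]")
        known = set(ids)
        for donor, recipient in self.introgression_pairs:
            if donor not in known or recipient not in known:
                raise ValueError(f"introgression pair ({donor}, {recipient}) "
                                 "names unknown species")
        for loc in self.localities:
            for sp in loc.species:
                if sp not in known:
                    raise ValueError(f"locality {loc.locality_id} lists "
                                     f"unknown species {sp!r}")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    records: list[SampleRecord]
    observations: list[KaryotypeObservation]
    alignment: Alignment
    localities: list[Locality]
    truth: dict


def _expected_decision(a: SpeciesSpec, b: SpeciesSpec,
                       config: SimulationConfig,
                       sympatric: bool, introgressed: bool) -> dict:
    """Decision the pipeline should reach for a pair, given the generator's
    own parameters (all simulated species are distinct by construction; the
    expectation reflects what the evidence can support)."""
    barcode_diff = config.n_fixed_diffs > 0 and not introgressed
    if sympatric:
        return {"decision": "distinct_species", "introgression": False}
    if a.structure != b.structure:
        return {"decision": "distinct_species",
                "introgression": introgressed and not barcode_diff}
    lo_a, hi_a = a.count_range()
    lo_b, hi_b = b.count_range()
    gap = max(0, max(lo_a, lo_b) - min(hi_a, hi_b))
    if gap >= config.delta:
        return {"decision": "distinct_species",
                "introgression": not barcode_diff}
    if barcode_diff:
        return {"decision": "conspecific_subspecies", "introgression": False}
    if gap == 0:
        return {"decision": "synonym", "introgression": False}
    return {"decision": "unresolved", "introgression": False}


def simulate(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate one dataset (records, karyotypes, alignment, localities) with
    a truth record mapping samples to species and species pairs to the
    decision the pipeline is expected to reach."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    # ancestral sequence and shared diagnostic columns
    ancestral = rng.integers(0, 4, size=config.seq_length)
    diag_positions = np.sort(rng.choice(config.seq_length,
                                        size=config.n_fixed_diffs,
                                        replace=False))
    base_order = rng.permutation(4)
    consensus: dict[str, np.ndarray] = {}
    for k, spec in enumerate(config.species):
        seq = ancestral.copy()
        seq[diag_positions] = base_order[k]
        consensus[spec.species_id] = seq
    for donor, recipient in config.introgression_pairs:
        consensus[recipient] = consensus[donor].copy()

    # localities hosting each species; samples spread evenly across them
    sites_of: dict[str, list[LocalitySpec]] = {s.species_id: []
                                               for s in config.species}
    for loc in config.localities:
        for sp in loc.species:
            sites_of[sp].append(loc)

    records: list[SampleRecord] = []
    observations: list[KaryotypeObservation] = []
    ids: list[str] = []
    seqs: list[str] = []
    sample_truth: dict[str, str] = {}
    for spec in config.species:
        lo, hi = spec.count_range()
        hosts = sites_of[spec.species_id] or [None]
        for k in range(spec.n_samples):
            sid = f"{spec.species_id}_{k + 1:02d}"
            loc = hosts[k % len(hosts)]
            count = int(rng.integers(lo, hi + 1))
            approx = bool(rng.random() < config.approx_fraction)
            records.append(SampleRecord(
                sid, taxon_label=spec.species_id,
                locality_id=loc.locality_id if loc else "",
                reference="simulated"))
            observations.append(KaryotypeObservation(
                sid, count, approx, spec.structure, False))
            seq = consensus[spec.species_id].copy()
            hit = rng.random(config.seq_length) < config.within_species_mutation_rate
            if hit.any():
                # mutate to a uniformly chosen different base
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 4
            ids.append(sid)
            seqs.append("".join(_BASES[b] for b in seq))
            sample_truth[sid] = spec.species_id

    introgressed_pairs = {frozenset(p) for p in config.introgression_pairs}
    pair_truth = []
    for i, a in enumerate(config.species):
        for b in config.species[i + 1:]:
            sympatric = any(a.species_id in loc.species and
                            b.species_id in loc.species
                            for loc in config.localities)
            expected = _expected_decision(
                a, b, config, sympatric,
                frozenset((a.species_id, b.species_id)) in introgressed_pairs)
            pair_truth.append({"a": a.species_id, "b": b.species_id,
                               "sympatric": sympatric, **expected})

    truth = {
        "samples": sample_truth,
        "pairs": pair_truth,
        "config": {
            "seed": config.seed,
            "n_species": len(config.species),
            "seq_length": config.seq_length,
            "n_fixed_diffs": config.n_fixed_diffs,
            "within_species_mutation_rate": config.within_species_mutation_rate,
            "approx_fraction": config.approx_fraction,
            "delta": config.delta,
            "theta": config.theta,
        },
    }
    localities = [Locality(l.locality_id, l.name, l.latitude, l.longitude)
                  for l in config.localities]
    return SimulatedDataset(config, records, observations,
                            Alignment(ids, seqs), localities, truth)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four simulator outputs (karyotype TSV, FASTA, locality TSV,
    truth JSON); deterministic content for a given config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "karyotypes": outdir / "karyotypes.tsv",
        "alignment": outdir / "barcodes.fasta",
        "localities": outdir / "localities.tsv",
        "truth": outdir / "truth.json",
    }
    write_karyotype_table(zip(dataset.records, dataset.observations),
                          paths["karyotypes"])
    write_alignment(dataset.alignment, paths["alignment"])
    write_locality_table(dataset.localities, paths["localities"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def reference_karyotype_fixture() -> tuple[Path, Path]:
    """Paths to the packaged reference karyotype table (62 karyotyped voucher
    specimens of a Transcaucasian blue-butterfly complex) and its locality
    gazetteer."""
    data = resources.files("karyodelim") / "data"
    return (Path(str(data / "reference_karyotypes.tsv")),
            Path(str(data / "reference_localities.tsv")))
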