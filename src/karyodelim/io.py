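"""Readers and writers for the pipeline's external artifacts.

The pipeline consumes three plain-text inputs — an aligned nucleotide FASTA
(the 658 bp COI barcode region), a karyotype observation table (TSV), and a
locality table (TSV) — and emits newick trees and TSV reports.  This module
defines the corresponding in-memory types and enforces their invariants at
the boundary, so the analysis modules never see malformed data.

Conventions
-----------
* Alignment positions are 1-based everywhere a position is reported, matching
  how diagnostic sites are cited in the cytogenetic literature.
* Haploid chromosome counts transcribed with a "ca" prefix (approximate
  counts, read off imperfect metaphase plates) keep the integer value plus an
  ``approximate`` flag; the flag survives a write/read round trip.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SampleRecord",
    "KaryotypeObservation",
    "StructureSignature",
    "Alignment",
    "Locality",
    "read_karyotype_table",
    "write_karyotype_table",
    "read_locality_table",
    "write_locality_table",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
]

UNAMBIGUOUS = frozenset("ACGT")

_STRUCTURE_RE = re.compile(r"^\s*(\d+)\s*L\s*\+\s*(\d+)\s*M\s*$", re.IGNORECASE)
_COUNT_RE = re.compile(r"^\s*(?:n\s*=\s*)?(ca\s*)?(\d+)\s*$", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class StructureSignature:
    """Marker-bivalent composition of a karyotype.

    Chromosome sets in this group of butterflies are described by the number
    of conspicuous "large" and "medium-sized" marker bivalents visible at the
    first meiotic metaphase; relative bivalent sizes are deliberately not
    modelled numerically.  Serialized losslessly as ``"<n_large>L+<n_medium>M"``.
    """

    n_large: int
    n_medium: int

    def __post_init__(self) -> None:
        if self.n_large < 0 or self.n_medium < 0:
            raise ValueError("marker bivalent counts must be non-negative")

    def __str__(self) -> str:
        return f"{self.n_large}L+{self.n_medium}M"

    @classmethod
    def parse(cls, text: str) -> "StructureSignature":
        m = _STRUCTURE_RE.match(text)
        if m is None:
            raise ValueError(f"cannot parse structure signature {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class SampleRecord:
    """Identity and provenance of one voucher specimen."""

    sample_id: str
    taxon_label: str = ""
    locality_id: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass(frozen=True)
class KaryotypeObservation:
    """One sample's haploid chromosome count and karyotype structure.

    ``n_count`` is the haploid number n (bivalents at meiotic metaphase I).
    ``approximate`` marks counts transcribed with a "ca" prefix.
    ``multivalents_observed`` flags tri-/multivalent associations, the
    cytological signature of a hybrid heterozygous for fusions/fissions.
    """

    sample_id: str
    n_count: int
    approximate: bool = False
    structure: StructureSignature = StructureSignature(0, 0)
    multivalents_observed: bool = False

    def __post_init__(self) -> None:
        if self.n_count < 1:
            raise ValueError(f"n_count must be >= 1, got {self.n_count}")


@dataclass(frozen=True)
class Locality:
    """Named collecting site with decimal-degree coordinates."""

    locality_id: str
    name: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class Alignment:
    """Equal-length nucleotide alignment with ordered, unique ids.

    Sequences are stored uppercase over A/C/G/T/N/- plus IUPAC ambiguity
    codes; U is normalized to T on construction.
    """

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in number")
        if not self.ids:
            raise ValueError("alignment is empty")
        seen = set()
        for sid in self.ids:
            if sid in seen:
                raise ValueError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
        self.sequences = [s.upper().replace("U", "T") for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            ragged = [i for i, s in zip(self.ids, self.sequences)
                      if len(s) != len(self.sequences[0])]
            raise ValueError(f"ragged alignment; offending ids: {ragged}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, sample_id: str) -> str:
        try:
            return self.sequences[self.ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"no sequence for id {sample_id!r}") from None

    def subset(self, ids: Sequence[str]) -> "Alignment":
        return Alignment(list(ids), [self.sequence(i) for i in ids])


def _parse_count(raw: str, row: int) -> tuple[int, bool]:
    """Parse a chromosome-count cell; accepts "90", "ca90", "ca 90", "n = 90"."""
    m = _COUNT_RE.match(raw)
    if m is None:
        raise ValueError(f"non-integer chromosome count {raw!r} in row {row}")
    return int(m.group(2)), m.group(1) is not None


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(raw: str, column: str, row: int) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {raw!r} in column {column}, row {row}")


REQUIRED_KARYOTYPE_COLUMNS = ("sample_id", "taxon_label", "n_count", "locality_id")


def read_karyotype_table(path: str | Path) -> list[tuple[SampleRecord, KaryotypeObservation]]:
    """Read a karyotype observation TSV.

    Expected columns: sample_id, taxon_label, n_count, locality_id, and
    optionally approximate, structure, reference, multivalents_observed.
    The count column accepts the "ca" prefix dialects; the prefix sets the
    approximate flag (OR-ed with the explicit column when present).
    Rows are returned in file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in REQUIRED_KARYOTYPE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    out: list[tuple[SampleRecord, KaryotypeObservation]] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = row._asdict()
        sid = d["sample_id"].strip()
        if sid in seen:
            raise ValueError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        count, ca = _parse_count(d["n_count"], idx)
        approx = ca or (_parse_bool(d.get("approximate", ""), "approximate", idx)
                        if "approximate" in d else False)
        structure = (StructureSignature.parse(d["structure"])
                     if d.get("structure", "").strip() else StructureSignature(0, 0))
        multi = (_parse_bool(d["multivalents_observed"], "multivalents_observed", idx)
                 if "multivalents_observed" in d else False)
        record = SampleRecord(sid, d["taxon_label"].strip(), d["locality_id"].strip(),
                              d.get("reference", "").strip())
        obs = KaryotypeObservation(sid, count, approx, structure, multi)
        out.append((record, obs))
    return out


def write_karyotype_table(rows: Iterable[tuple[SampleRecord, KaryotypeObservation]],
                          path: str | Path) -> None:
    df = pd.DataFrame(
        [{
            "sample_id": rec.sample_id,
            "taxon_label": rec.taxon_label,
            "n_count": obs.n_count,
            "approximate": str(obs.approximate).lower(),
            "structure": str(obs.structure),
            "locality_id": rec.locality_id,
            "reference": rec.reference,
            "multivalents_observed": str(obs.multivalents_observed).lower(),
        } for rec, obs in rows]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_locality_table(path: str | Path) -> list[Locality]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in ("locality_id", "name", "lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    out = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.locality_id in seen:
            raise ValueError(f"duplicate locality_id {row.locality_id!r}")
        seen.add(row.locality_id)
        # locale-independent: "." is the only accepted decimal separator
        out.append(Locality(row.locality_id, row.name,
                            float(row.lat), float(row.lon)))
    return out


def write_locality_table(localities: Iterable[Locality], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"locality_id": l.locality_id, "name": l.name,
          "lat": repr(l.latitude), "lon": repr(l.longitude)} for l in localities]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA (wrapped lines allowed) into an Alignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize a tree with branch lengths to newick.

    Leaf labels must be present and unique so the file re-reads to an
    identical topology.
    """
    labels = [leaf.taxon.label if leaf.taxon else None
              for leaf in tree.leaf_node_iter()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise ValueError("tree has unnamed leaves")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf names: {dupes}")
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
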