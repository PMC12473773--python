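"""Sequence, alignment, annotation and tree file I/O.

Sample metadata rides in FASTA headers using a ``sample_id|species|tissue``
dialect; a ``_leaf`` suffix on the sample id marks leaf tissue when the third
field is absent (wood is the default material in the barcoding panels this
package targets). All coordinates are 0-based half-open internally.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .trees import Tree

Tissue = Literal["wood", "leaf", "unknown"]

#: IUPAC nucleotide codes plus gap, the only characters allowed in sequences.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

# A,C,G,T -> 0..3; everything else (ambiguity, gap) -> 4.
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


def normalize_sequence(seq: str, *, line: int | None = None) -> str:
    """Upper-case, U->T, and validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        where = f" at line {line}" if line is not None else ""
        raise FastaParseError(f"invalid sequence characters {sorted(bad)}{where}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    sample_id: str
    sequence: str
    species: str = ""
    tissue: Tissue = "unknown"

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("empty sample_id")
        if not self.sequence:
            raise ValueError(f"empty sequence for sample {self.sample_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_label(header: str) -> tuple[str, str, Tissue]:
    """Split ``id|species|tissue`` lazily; ``_leaf`` id suffix implies leaf tissue."""
    fields = header.strip().split("|")
    sample_id = fields[0].strip()
    species = fields[1].strip() if len(fields) > 1 else ""
    tissue: Tissue = "unknown"
    if len(fields) > 2:
        t = fields[2].strip().lower()
        if t in ("wood", "leaf"):
            tissue = t  # type: ignore[assignment]
    elif sample_id.endswith("_leaf"):
        tissue = "leaf"
    return sample_id, species, tissue


def format_label(record: SequenceRecord) -> str:
    return f"{record.sample_id}|{record.species}|{record.tissue}"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA, parsing headers through :func:`parse_label`.

    A hand-written reader so parse errors can name the line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"empty sequence for header at line {header_line}")
        sample_id, species, tissue = parse_label(header)
        if not sample_id:
            raise FastaParseError(f"empty sample id in header at line {header_line}")
        if sample_id in seen:
            raise FastaParseError(
                f"duplicate sample_id {sample_id!r} in header at line {header_line}"
            )
        seen.add(sample_id)
        records.append(SequenceRecord(sample_id, seq, species, tissue))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:]
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(f"sequence data before any header at line {lineno}")
                chunks.append(normalize_sequence(line, line=lineno))
        _flush()
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{format_label(rec)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


class LabelledAlignment:
    """Equal-length sequences with per-record species/tissue labels."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        length = len(records[0].sequence)
        for rec in records:
            if len(rec.sequence) != length:
                raise ValueError(
                    f"unequal sequence lengths: {rec.sample_id!r} has "
                    f"{len(rec.sequence)}, expected {length}"
                )
        ids = [r.sample_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in alignment")
        self.records = records
        self.length = length

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def partition(self) -> dict[str, str]:
        """Sample-id -> species map (the SpeciesPartition of downstream stages)."""
        return {r.sample_id: r.species for r in self.records}

    def to_codes(self) -> np.ndarray:
        """(n_records, length) uint8 matrix; A,C,G,T -> 0..3, other -> 4."""
        buf = np.frombuffer(
            "".join(r.sequence for r in self.records).encode("ascii"), dtype=np.uint8
        )
        return _CODE_TABLE[buf].reshape(self.n_records, self.length)

    def slice_columns(self, start: int, end: int) -> "LabelledAlignment":
        return LabelledAlignment(
            [
                SequenceRecord(r.sample_id, r.sequence[start:end], r.species, r.tissue)
                for r in self.records
            ]
        )

    @classmethod
    def read(cls, path: str | Path) -> "LabelledAlignment":
        return cls(read_fasta(path))

    def write(self, path: str | Path) -> None:
        write_fasta(self.records, path)


def concat_loci(
    aligns: Mapping[str, LabelledAlignment], order: Sequence[str]
) -> tuple[LabelledAlignment, list[str]]:
    """Per-sample concatenation of loci in the stated order.

    Returns the supermatrix and a per-column locus provenance list.
    """
    if not order:
        raise ValueError("empty locus order")
    first = aligns[order[0]]
    ref_ids = first.sample_ids
    ref_set = set(ref_ids)
    for name in order:
        ids = set(aligns[name].sample_ids)
        if ids != ref_set:
            missing = sorted((ref_set - ids) | (ids - ref_set))
            raise ValueError(f"locus {name!r} sample set mismatch; differing ids: {missing}")
    provenance: list[str] = []
    for name in order:
        provenance.extend([name] * aligns[name].length)
    by_id = {name: {r.sample_id: r for r in aligns[name].records} for name in order}
    records = []
    for rec in first.records:
        seq = "".join(by_id[name][rec.sample_id].sequence for name in order)
        records.append(SequenceRecord(rec.sample_id, seq, rec.species, rec.tissue))
    return LabelledAlignment(records), provenance


# --------------------------------------------------------------------- newick

def write_newick(tree: Tree, path: str | Path) -> None:
    if len(tree.leaves()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> Tree:
    with open(path) as fh:
        return Tree.from_newick(fh.read())


# -------------------------------------------------------------------- genbank

@dataclass(frozen=True)
class Feature:
    """One annotation entry in 0-based half-open coordinates."""

    gene: str
    start: int
    end: int
    strand: Literal["+", "-"]
    kind: Literal["CDS", "tRNA", "rRNA", "other"]

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


FeatureTable = list  # list[Feature]; kept loose for easy construction in callers

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank_features(path: str | Path) -> tuple[str, list[Feature]]:
    """Genome sequence plus gene/CDS/tRNA/rRNA features; join() locations split."""
    from Bio import SeqIO

    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:
        raise ValueError(f"cannot parse GenBank file {path} (truncated or missing ORIGIN?)") from exc
    try:
        sequence = normalize_sequence(str(record.seq))
    except Exception as exc:  # Biopython raises on undefined (ORIGIN-less) sequences
        raise ValueError(f"GenBank file {path} has no usable ORIGIN sequence") from exc
    if not sequence:
        raise ValueError(f"GenBank file {path} has no usable ORIGIN sequence")
    features: list[Feature] = []
    for feat in record.features:
        if feat.type == "source":
            continue
        kind = _KIND_MAP.get(feat.type, "other")
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or quals.get("locus_tag") or [feat.type])[0]
        for part in feat.location.parts:
            strand = "-" if part.strand == -1 else "+"
            features.append(Feature(name, int(part.start), int(part.end), strand, kind))
    features.sort(key=lambda f: (f.start, f.end, f.gene))
    return sequence, features
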