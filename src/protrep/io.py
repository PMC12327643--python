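"""Readers and writers for every external artifact the pipeline touches.

Sequences travel as FASTA; labels, domain intervals, embedding tables and
all result tables are TSV with a header line. Domain intervals use 0-based
half-open coordinates so interval length is simply ``end - start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import STANDARD_AA_SET

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class ValidationError(ValueError):
    """An input artifact violates a format or domain invariant."""


@dataclass
class ProteinRecord:
    """One protein: id, residue string, optional domain intervals and label.

    Domain intervals are 0-based half-open ``(start, end)`` pairs, sorted
    and pairwise non-overlapping, with ``0 <= start < end <= len(sequence)``.
    """

    id: str
    sequence: str
    domains: list[Interval] | None = None
    label: object | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record has an empty id")
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        if self.domains is not None:
            self.domains = validate_intervals(self.domains, len(self.sequence), self.id)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_standard(self) -> bool:
        return all(res in STANDARD_AA_SET for res in self.sequence)

    def domain_length(self) -> int:
        return sum(e - s for s, e in (self.domains or []))

    def nondomain_length(self) -> int:
        return self.length - self.domain_length()


def validate_intervals(intervals: list[Interval], length: int, rec_id: str) -> list[Interval]:
    """Sort and validate intervals against the record invariants."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    prev_end = -1
    for s, e in ivs:
        if not (0 <= s < e <= length):
            raise ValidationError(
                f"record {rec_id!r}: interval [{s},{e}) invalid for length {length}"
            )
        if s < prev_end:
            raise ValidationError(f"record {rec_id!r}: overlapping domain intervals")
        prev_end = e
    return ivs


@dataclass
class EmbeddingTable:
    """Pre-trained per-trigram embedding vectors of a fixed dimension."""

    dimension: int
    vectors: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValidationError("embedding dimension must be positive")
        for key, vec in self.vectors.items():
            if len(key) != 3:
                raise ValidationError(f"embedding key {key!r} is not a trigram")
            if vec.shape != (self.dimension,):
                raise ValidationError(
                    f"vector for {key!r} has length {vec.shape}, expected {self.dimension}"
                )

    def __contains__(self, trigram: str) -> bool:
        return trigram in self.vectors

    def __getitem__(self, trigram: str) -> np.ndarray:
        return self.vectors[trigram]

    def __len__(self) -> int:
        return len(self.vectors)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords.

    The header token before the first whitespace becomes the id; sequences
    are uppercased. Duplicate ids and empty sequences raise ValidationError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id = entry.id
        if rec_id in seen:
            raise ValidationError(f"duplicate FASTA id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = str(entry.seq)
        if not seq:
            raise ValidationError(f"record {rec_id!r} in {path} has an empty sequence")
        records.append(ProteinRecord(id=rec_id, sequence=seq))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(entries, str(Path(path)), "fasta")


def filter_standard(
    records: list[ProteinRecord],
) -> tuple[list[ProteinRecord], list[str]]:
    """Keep only proteins made of the 20 standard amino acids.

    Returns the kept records (order preserved) and the dropped ids.
    """
    kept, dropped = [], []
    for rec in records:
        (kept if rec.is_standard() else dropped).append(rec)
    dropped_ids = [rec.id for rec in dropped]
    if dropped_ids:
        logger.info("filter_standard dropped %d record(s): %s", len(dropped_ids), dropped_ids[:10])
    return kept, [rec.id for rec in dropped]


# ---------------------------------------------------------------------------
# Labels

def read_labels(path: str | Path) -> dict[str, object]:
    """Read a TSV of ``id<TAB>label``; labels parse as int, float or string."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"labels file {path} needs columns id, label")
    ids, labels = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise ValidationError(f"duplicate ids in labels file {path}: {dupes[:5]}")
    out: dict[str, object] = {}
    for rec_id, raw in zip(ids, labels):
        try:
            val: object = int(raw)
        except ValueError:
            try:
                val = float(raw)
            except ValueError:
                val = raw
        out[str(rec_id)] = val
    return out


def write_labels(labels: dict[str, object], path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(labels), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def attach_labels(records: list[ProteinRecord], labels: dict[str, object]) -> None:
    for rec in records:
        if rec.id in labels:
            rec.label = labels[rec.id]


# ---------------------------------------------------------------------------
# Domain annotations

def read_domain_annotations(path: str | Path) -> dict[str, list[Interval]]:
    """Read a TSV of ``id<TAB>start<TAB>end`` domain intervals per protein.

    Intervals are 0-based half-open; per id they must be non-empty,
    sorted after loading, and pairwise non-overlapping. Full validation
    against sequence length happens when joined to records.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if cols[:3] != ["id", "start", "end"]:
        raise ValidationError(f"annotation file {path} needs header columns id, start, end")
    out: dict[str, list[Interval]] = {}
    for rec_id, start, end in df.itertuples(index=False):
        try:
            s, e = int(start), int(end)
        except (TypeError, ValueError):
            raise ValidationError(f"malformed interval row for {rec_id!r} in {path}") from None
        if s >= e:
            raise ValidationError(f"record {rec_id!r}: interval [{s},{e}) is empty or inverted")
        out.setdefault(str(rec_id), []).append((s, e))
    for rec_id, ivs in out.items():
        ivs.sort()
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValidationError(f"record {rec_id!r}: overlapping domain intervals in {path}")
    return out


def write_domain_annotations(annotations: dict[str, list[Interval]], path: str | Path) -> None:
    rows = [
        {"id": rec_id, "start": s, "end": e}
        for rec_id, ivs in annotations.items()
        for s, e in ivs
    ]
    pd.DataFrame(rows, columns=["id", "start", "end"]).to_csv(path, sep="\t", index=False)


def attach_domains(records: list[ProteinRecord], annotations: dict[str, list[Interval]]) -> None:
    """Join annotations onto records, validating against sequence lengths."""
    for rec in records:
        if rec.id in annotations:
            rec.domains = validate_intervals(annotations[rec.id], rec.length, rec.id)


# ---------------------------------------------------------------------------
# Embedding tables and per-residue matrices

def read_embedding_table(path: str | Path) -> EmbeddingTable:
    """Read a whitespace/TSV table: first column trigram, rest a real vector.

    All rows must have the same width; duplicate trigram keys are an error.
    The dimension is the column count minus one.
    """
    vectors: dict[str, np.ndarray] = {}
    width: int | None = None
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            parts = line.split()
            if not parts:
                continue
            if width is None:
                width = len(parts)
                if width < 2:
                    raise ValidationError(f"{path}:{line_no}: need a key and at least one value")
            elif len(parts) != width:
                raise ValidationError(
                    f"{path}:{line_no}: ragged row (width {len(parts)}, expected {width})"
                )
            key = parts[0]
            if key in vectors:
                raise ValidationError(f"{path}:{line_no}: duplicate trigram key {key!r}")
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError:
                raise ValidationError(f"{path}:{line_no}: non-numeric embedding entry") from None
            vectors[key] = vec
    if width is None:
        raise ValidationError(f"embedding table {path} is empty")
    return EmbeddingTable(dimension=width - 1, vectors=vectors)


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        for key, vec in table.vectors.items():
            handle.write(key + "\t" + "\t".join(repr(float(x)) for x in vec) + "\n")


def read_residue_matrix(path: str | Path, expected_length: int | None = None) -> np.ndarray:
    """Read one protein's per-residue embedding matrix (rows = residues)."""
    mat = np.loadtxt(path, ndmin=2)
    if expected_length is not None and mat.shape[0] != expected_length:
        raise ValidationError(
            f"{path}: {mat.shape[0]} rows but sequence length is {expected_length}"
        )
    return mat


# ---------------------------------------------------------------------------
# Feature matrices (result tables)

def write_feature_matrix(
    ids: list[str], matrix: np.ndarray, feature_names: list[str], path: str | Path
) -> None:
    """Write per-protein feature vectors as TSV: id column + one column per feature."""
    df = pd.DataFrame(matrix, columns=feature_names)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a feature TSV back into (ids, matrix, feature_names)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "id":
        raise ValidationError(f"feature table {path} must start with an 'id' column")
    ids = df["id"].astype(str).tolist()
    names = list(df.columns[1:])
    return ids, df.iloc[:, 1:].to_numpy(dtype=float), names
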