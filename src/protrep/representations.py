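"""Protein representation builders.

Four families are compared throughout the package:

* **Hist-8000** — counts of each of the 20**3 = 8000 possible amino-acid
  trigrams taken from overlapping windows (a length-L sequence contributes
  L-2 windows, so every histogram sums to L-2).
* **Hist-reduced** (e.g. Hist-SDM12) — the same count histogram after the
  sequence is recoded into a reduced alphabet; G groups give G**3 bins.
* **SoT** (sum of learnt trigrams) — the sum over windows of pre-trained
  per-trigram embedding vectors, a ProtVec-style representation.
* **Mean-pooled per-residue embeddings** — the column-wise mean of an
  externally computed residue-by-dimension matrix (ProtT5-style).

Histograms are raw counts by default; pass ``normalize=True`` for L1
frequencies. Region-restricted histograms assign each trigram window to the
region (domain or non-domain) containing its centre residue, which makes
the domain and non-domain histograms an exact partition of the full one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabets import AlphabetGrouping, TrigramVocabulary, reduced_vocabulary
from .io import EmbeddingTable, ProteinRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Per-protein feature vectors with an ordered feature vocabulary.

    ``feature_names`` gives each column a portable name (trigram strings
    for histograms, ``e0..e{d-1}`` for embedding representations), so
    Hist-N column subsets remain interpretable.
    """

    ids: list[str]
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count does not match id count")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature-name count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: list[int] | np.ndarray) -> "FeatureMatrix":
        return subset_features(self, indices)


def extract_trigrams(sequence: str) -> list[str]:
    """All overlapping trigrams of a sequence; window i covers residues i..i+2."""
    if len(sequence) < 3:
        raise ValidationError(f"sequence of length {len(sequence)} has no trigrams (need >= 3)")
    return [sequence[i : i + 3] for i in range(len(sequence) - 2)]


def histogram(
    sequence: str, vocab: TrigramVocabulary, normalize: bool = False
) -> np.ndarray:
    """Count occurrences of each vocabulary trigram in the sequence.

    The result has length ``vocab.size`` and sums to ``len(sequence) - 2``
    (or 1.0 when ``normalize`` is set).
    """
    counts = np.zeros(vocab.size, dtype=float)
    for tri in extract_trigrams(sequence):
        counts[vocab.index(tri)] += 1
    if normalize:
        counts /= counts.sum()
    return counts


def reduce_sequence(sequence: str, grouping: AlphabetGrouping) -> str:
    """Recode each residue into its group symbol (same length)."""
    return grouping.apply(sequence)


def histogram_reduced(
    sequence: str, grouping: AlphabetGrouping, normalize: bool = False
) -> np.ndarray:
    """Reduced-alphabet trigram histogram: recode, then count over G**3 bins."""
    return histogram(reduce_sequence(sequence, grouping), reduced_vocabulary(grouping), normalize)


def sum_of_trigram_embeddings(
    sequence: str, table: EmbeddingTable, missing: str = "error"
) -> np.ndarray:
    """Sum the embedding vectors of all overlapping trigrams (SoT).

    ``missing`` controls trigrams absent from the table: ``"error"``
    (default) raises; ``"skip"`` treats them as zero vectors and logs the
    count, since silent zeros would bias the sum.
    """
    if missing not in ("error", "skip"):
        raise ValueError(f"unknown missing-trigram policy {missing!r}")
    total = np.zeros(table.dimension)
    skipped = 0
    for tri in extract_trigrams(sequence):
        if tri in table:
            total += table[tri]
        elif missing == "error":
            raise ValidationError(f"trigram {tri!r} missing from embedding table")
        else:
            skipped += 1
    if skipped:
        logger.warning("sum_of_trigram_embeddings skipped %d missing trigram(s)", skipped)
    return total


def mean_pool_residue_embeddings(matrix: np.ndarray) -> np.ndarray:
    """Column-wise mean of a per-residue embedding matrix (rows = residues)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValidationError("per-residue embedding matrix must have >= 1 row")
    return matrix.mean(axis=0)


def _domain_mask(record: ProteinRecord) -> np.ndarray:
    mask = np.zeros(record.length, dtype=bool)
    for s, e in record.domains or []:
        mask[s:e] = True
    return mask


def region_restricted_histogram(
    record: ProteinRecord,
    region: str,
    vocab: TrigramVocabulary,
    normalize: bool = False,
) -> np.ndarray:
    """Histogram over only the windows whose centre residue lies in ``region``.

    ``region`` is ``"domain"`` or ``"nondomain"``. Window i covers residues
    i..i+2 with centre i+1; under this rule the two region histograms sum
    entrywise to the full histogram. The record needs at least one domain
    interval and one non-domain residue.
    """
    if region not in ("domain", "nondomain"):
        raise ValueError(f"region must be 'domain' or 'nondomain', got {region!r}")
    if not record.domains:
        raise ValidationError(f"record {record.id!r} has no domain annotation")
    if record.nondomain_length() == 0:
        raise ValidationError(f"record {record.id!r} has no non-domain residues")
    mask = _domain_mask(record)
    want_domain = region == "domain"
    counts = np.zeros(vocab.size, dtype=float)
    for i, tri in enumerate(extract_trigrams(record.sequence)):
        if mask[i + 1] == want_domain:
            counts[vocab.index(tri)] += 1
    if normalize:
        total = counts.sum()
        if total == 0:
            raise ValidationError(
                f"record {record.id!r}: no {region} windows to normalise over"
            )
        counts /= total
    return counts


def subset_features(matrix: FeatureMatrix, indices: list[int] | np.ndarray) -> FeatureMatrix:
    """Restrict and reorder columns to ``indices`` (Hist-N construction)."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty feature-index list")
    if len(np.unique(indices)) != indices.size:
        raise ValueError("duplicate feature indices")
    if indices.min() < 0 or indices.max() >= matrix.n_features:
        raise ValueError("feature index out of range")
    return FeatureMatrix(
        ids=list(matrix.ids),
        values=matrix.values[:, indices],
        feature_names=[matrix.feature_names[i] for i in indices],
    )


def build_feature_matrix(
    records: list[ProteinRecord],
    method: str = "hist",
    vocab: TrigramVocabulary | None = None,
    grouping: AlphabetGrouping | None = None,
    table: EmbeddingTable | None = None,
    residue_matrices: dict[str, np.ndarray] | None = None,
    region: str = "full",
    normalize: bool = False,
    missing: str = "error",
) -> FeatureMatrix:
    """Featurize a list of records with one representation method.

    ``method``: ``"hist"`` (full-alphabet histogram, 8000-d with the
    standard vocabulary), ``"hist-reduced"`` (needs ``grouping``),
    ``"sot"`` (needs ``table``) or ``"meanpool"`` (needs
    ``residue_matrices`` keyed by record id). ``region`` restricts
    histogram methods to domain/non-domain windows.
    """
    from .alphabets import standard_vocabulary

    rows: list[np.ndarray] = []
    if method == "hist":
        vocab = vocab or standard_vocabulary()
        names = vocab.trigrams
        for rec in records:
            if region == "full":
                rows.append(histogram(rec.sequence, vocab, normalize))
            else:
                rows.append(region_restricted_histogram(rec, region, vocab, normalize))
    elif method == "hist-reduced":
        if grouping is None:
            raise ValueError("hist-reduced requires a grouping")
        vocab = reduced_vocabulary(grouping)
        names = vocab.trigrams
        for rec in records:
            if region == "full":
                rows.append(histogram_reduced(rec.sequence, grouping, normalize))
            else:
                reduced = ProteinRecord(
                    id=rec.id, sequence=grouping.apply(rec.sequence), domains=rec.domains
                )
                rows.append(region_restricted_histogram(reduced, region, vocab, normalize))
    elif method == "sot":
        if table is None:
            raise ValueError("sot requires an embedding table")
        if region != "full":
            raise ValueError("region restriction applies to histogram methods only")
        names = [f"e{i}" for i in range(table.dimension)]
        for rec in records:
            rows.append(sum_of_trigram_embeddings(rec.sequence, table, missing))
    elif method == "meanpool":
        if residue_matrices is None:
            raise ValueError("meanpool requires per-residue matrices")
        if region != "full":
            raise ValueError("region restriction applies to histogram methods only")
        dims = {m.shape[1] for m in residue_matrices.values()}
        if len(dims) != 1:
            raise ValidationError("per-residue matrices disagree on dimension")
        names = [f"e{i}" for i in range(dims.pop())]
        for rec in records:
            if rec.id not in residue_matrices:
                raise ValidationError(f"no per-residue matrix for record {rec.id!r}")
            mat = residue_matrices[rec.id]
            if mat.shape[0] != rec.length:
                raise ValidationError(
                    f"record {rec.id!r}: matrix rows {mat.shape[0]} != length {rec.length}"
                )
            rows.append(mean_pool_residue_embeddings(mat))
    else:
        raise ValueError(f"unknown representation method {method!r}")
    return FeatureMatrix(
        ids=[rec.id for rec in records], values=np.vstack(rows), feature_names=names
    )
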