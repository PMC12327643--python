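"""Alignment-vs-representation similarity concordance.

How well does a vector representation preserve sequence similarity? For
sampled sets of proteins we compute, over every unordered pair, the
Needleman-Wunsch global alignment score and the cosine similarity of the
two representation vectors, then the Spearman rank correlation between the
two pairwise score lists. Spearman makes the comparison invariant to the
(monotone) scale of either score, so the substitution matrix and gap
penalties mainly affect power, not validity.

The default scoring scheme is BLOSUM62 with affine gaps (open -10, extend
-0.5, Biopython convention: the first residue of a gap costs the open
score, each further residue the extend score). Toy match/mismatch/linear
schemes are first-class for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Global-alignment scoring: substitution scores plus gap penalties.

    ``substitution`` is either the name of a Biopython matrix (e.g.
    ``"BLOSUM62"``) or a symmetric ``(res_a, res_b) -> score`` mapping.
    ``mode="linear"`` charges ``gap_open`` per gap symbol;
    ``mode="affine"`` charges ``gap_open`` for the first symbol of each
    gap run and ``gap_extend`` for every further symbol.
    """

    substitution: object = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    mode: str = "affine"

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "affine"):
            raise ValueError(f"mode must be 'linear' or 'affine', got {self.mode!r}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if isinstance(self.substitution, dict):
            for (a, b), s in self.substitution.items():
                if self.substitution.get((b, a), s) != s:
                    raise ValueError(f"substitution map not symmetric at ({a},{b})")

    @classmethod
    def toy(cls, match: float = 1.0, mismatch: float = -1.0, gap: float = -1.0,
            alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> "ScoringScheme":
        """Match/mismatch substitution with a linear per-symbol gap penalty."""
        sub = {
            (a, b): (match if a == b else mismatch)
            for a in alphabet
            for b in alphabet
        }
        return cls(substitution=sub, gap_open=gap, gap_extend=gap, mode="linear")

    def _aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        if isinstance(self.substitution, str):
            aligner.substitution_matrix = substitution_matrices.load(self.substitution)
        else:
            alphabet = sorted({a for a, _ in self.substitution})
            mat = substitution_matrices.Array(alphabet="".join(alphabet), dims=2)
            for (a, b), s in self.substitution.items():
                mat[a, b] = s
            aligner.substitution_matrix = mat
        if self.mode == "linear":
            aligner.open_gap_score = self.gap_open
            aligner.extend_gap_score = self.gap_open
        else:
            aligner.open_gap_score = self.gap_open
            aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass
class SimilarityStudyResult:
    """Per-set Spearman rho between NW scores and representation cosines."""

    per_set_rho: list[float]
    set_size: int
    seed: int
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        rhos = np.asarray(self.per_set_rho, dtype=float)
        self.mean = float(rhos.mean())
        self.sd = float(rhos.std(ddof=1)) if len(rhos) > 1 else 0.0

    @property
    def n_sets(self) -> int:
        return len(self.per_set_rho)

    def summary(self) -> str:
        return (
            f"Similarity study: Spearman rho = {self.mean:.3f} +/- {self.sd:.3f} "
            f"over {self.n_sets} sets of {self.set_size} proteins (seed {self.seed})"
        )


def nw_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Optimal Needleman-Wunsch global alignment score of two sequences."""
    if not a or not b:
        raise ValueError("nw_score needs non-empty sequences")
    scheme = scheme or ScoringScheme()
    aligner = scheme._aligner()
    try:
        return float(aligner.score(a, b))
    except ValueError as exc:
        raise ValueError(f"alignment failed (residue outside substitution map?): {exc}") from exc


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); zero-norm vectors are an error, not 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties); NaN on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input: Spearman rho undefined, returning NaN")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def pairwise_concordance(
    records: list[ProteinRecord],
    vectors: np.ndarray,
    scheme: ScoringScheme | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """NW scores, cosine similarities and their Spearman rho over all pairs."""
    scheme = scheme or ScoringScheme()
    aligner = scheme._aligner()
    n = len(records)
    if vectors.shape[0] != n:
        raise ValueError("one representation vector per record is required")
    nw, cos = [], []
    for i in range(n):
        for j in range(i + 1, n):
            nw.append(float(aligner.score(records[i].sequence, records[j].sequence)))
            cos.append(cosine_similarity(vectors[i], vectors[j]))
    nw_arr, cos_arr = np.array(nw), np.array(cos)
    return nw_arr, cos_arr, spearman_rho(nw_arr, cos_arr)


def similarity_study(
    records: list[ProteinRecord],
    representation_fn: Callable[[ProteinRecord], np.ndarray],
    n_sets: int = 10,
    set_size: int = 1000,
    scheme: ScoringScheme | None = None,
    seed: int = 0,
) -> SimilarityStudyResult:
    """Spearman concordance over ``n_sets`` random samples of ``set_size`` proteins.

    Each set is sampled without replacement; for every unordered pair in a
    set the NW score and the representation cosine are computed, and the
    per-set rho correlates the two lists. ``set_size`` is lowered (with a
    warning) if fewer records are available.
    """
    if set_size > len(records):
        logger.warning(
            "set_size %d > %d available records; lowering", set_size, len(records)
        )
        set_size = len(records)
    if set_size < 3:
        raise ValueError("set_size must be at least 3")
    rng = np.random.default_rng(seed)
    rhos = []
    for _ in range(n_sets):
        idx = rng.choice(len(records), size=set_size, replace=False)
        sample = [records[i] for i in idx]
        vectors = []
        for rec in sample:
            try:
                vectors.append(np.asarray(representation_fn(rec), dtype=float))
            except Exception as exc:
                raise RuntimeError(f"representation failed for record {rec.id!r}") from exc
        _, _, rho = pairwise_concordance(sample, np.vstack(vectors), scheme)
        rhos.append(rho)
    return SimilarityStudyResult(per_set_rho=rhos, set_size=set_size, seed=seed)
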