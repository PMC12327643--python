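"""Bootstrapped Fisher-ratio feature selection and the random-feature null.

The selection procedure, run on trigram histogram features of a two-class
protein set, is:

(a) keep the 2000 features with the most occurrences summed over proteins;
(b) score the survivors with the two-class Fisher ratio
    ``(mu_pos - mu_neg)**2 / (var_pos + var_neg + eps)``;
(c) keep the top 200 by Fisher ratio;
(d) repeat (a)-(c) on 50 class-stratified bootstrap resamples, then rank
    each feature by how many of the 50 top-200 sets contain it.

The final Hist-N feature set is, by default, every feature appearing in at
least half of the bootstrap sets; the threshold is configurable. To certify
a selected set of size N, the random-feature null evaluates many uniformly
random N-feature subsets with the same cross-validated classifier and
places the selected set's score on that empirical distribution as a
percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

FISHER_EPS = 1e-12


@dataclass
class SelectionResult:
    """Outcome of the bootstrapped Fisher-ratio selection.

    ``frequency_ranking`` maps feature index -> number of bootstrap top-m
    sets containing it (0..B); ``final_indices`` is sorted by (frequency
    descending, feature order ascending).
    """

    occurrence_ranked_indices: np.ndarray
    per_bootstrap_sets: list[np.ndarray]
    frequency_ranking: dict[int, int]
    final_indices: np.ndarray
    n_selected: int
    seed: int
    min_frequency: int
    eps: float = FISHER_EPS

    def summary(self) -> str:
        freqs = [self.frequency_ranking[i] for i in self.final_indices]
        lines = [
            "Bootstrapped Fisher-ratio feature selection",
            f"  bootstrap sets:      {len(self.per_bootstrap_sets)}",
            f"  candidate pool:      {len(self.occurrence_ranked_indices)}",
            f"  consensus threshold: >= {self.min_frequency} sets",
            f"  features selected:   {self.n_selected}",
            f"  selection frequencies (top 10): {freqs[:10]}",
            f"  seed: {self.seed}",
        ]
        return "\n".join(lines)


@dataclass
class NullDistribution:
    """Random-feature null: CV scores of R random N-feature sets vs observed."""

    scores: np.ndarray
    observed: float
    n_features: int
    seed: int
    percentile: float = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.percentile = 100.0 * float(np.sum(self.scores < self.observed)) / len(self.scores)

    def summary(self) -> str:
        return (
            f"Random-feature null (R={len(self.scores)}, N={self.n_features}): "
            f"observed={self.observed:.4f}, null mean={self.scores.mean():.4f} "
            f"sd={self.scores.std(ddof=1):.4f}, percentile={self.percentile:.1f}"
        )


def occurrence_filter(values: np.ndarray, k: int = 2000) -> np.ndarray:
    """Indices of the k features with the largest total count over proteins.

    Ties break toward the earlier vocabulary index. The result is ordered
    by decreasing total (ties ascending by index).
    """
    values = np.asarray(values)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > values.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {values.shape[1]}")
    totals = values.sum(axis=0)
    order = np.argsort(-totals, kind="stable")  # stable => ties by index asc
    return order[:k]


def fisher_ratio(values: np.ndarray, labels: np.ndarray, eps: float = FISHER_EPS) -> np.ndarray:
    """Two-class Fisher discriminability score per feature.

    ``(mu_pos - mu_neg)**2 / (var_pos + var_neg + eps)`` with class-wise
    population (ddof=0) means and variances; ``eps`` stabilises constant
    features.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"fisher_ratio needs exactly 2 classes, got {len(classes)}")
    pos, neg = values[labels == classes[1]], values[labels == classes[0]]
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    var_p, var_n = pos.var(axis=0), neg.var(axis=0)
    return (mu_p - mu_n) ** 2 / (var_p + var_n + eps)


def select_top(scores: np.ndarray, candidates: np.ndarray, m: int = 200) -> np.ndarray:
    """The m highest-scoring candidate features; ties by vocabulary order.

    ``scores`` is aligned to ``candidates`` (score[i] belongs to feature
    candidates[i]). Returns original feature indices.
    """
    scores = np.asarray(scores, dtype=float)
    candidates = np.asarray(candidates)
    if m <= 0:
        raise ValueError("m must be positive")
    if m > len(candidates):
        raise ValueError(f"m={m} exceeds candidate count {len(candidates)}")
    # sort candidates by index first so the stable score sort breaks ties
    # toward the earlier vocabulary position
    by_index = np.argsort(candidates, kind="stable")
    order = np.argsort(-scores[by_index], kind="stable")
    return candidates[by_index][order][:m]


def _stratified_resample(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap row indices with replacement, per class at original sizes."""
    idx = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def bootstrap_selection(
    values: np.ndarray,
    labels: np.ndarray,
    B: int = 50,
    k: int = 2000,
    m: int = 200,
    min_frequency: int | None = None,
    seed: int = 0,
    eps: float = FISHER_EPS,
) -> SelectionResult:
    """Run the four-step selection on B stratified bootstrap resamples.

    ``min_frequency`` (default B//2) is the consensus threshold: a feature
    enters ``final_indices`` when it appears in at least that many of the B
    top-m sets. Resampling is class-stratified at the original class
    sizes, so a single-class resample cannot occur.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("bootstrap_selection needs binary labels with both classes present")
    k = min(k, values.shape[1])
    if min_frequency is None:
        min_frequency = B // 2
    rng = np.random.default_rng(seed)

    pool = occurrence_filter(values, k)
    sets: list[np.ndarray] = []
    counts: dict[int, int] = {}
    for _ in range(B):
        rows = _stratified_resample(labels, rng)
        vb, lb = values[rows], labels[rows]
        cand = occurrence_filter(vb, k)
        scores = fisher_ratio(vb[:, cand], lb, eps)
        chosen = select_top(scores, cand, m)
        sets.append(np.sort(chosen))
        for f in chosen:
            counts[int(f)] = counts.get(int(f), 0) + 1

    eligible = [f for f, c in counts.items() if c >= min_frequency]
    final = np.array(
        sorted(eligible, key=lambda f: (-counts[f], f)), dtype=int
    )
    return SelectionResult(
        occurrence_ranked_indices=pool,
        per_bootstrap_sets=sets,
        frequency_ranking=counts,
        final_indices=final,
        n_selected=len(final),
        seed=seed,
        min_frequency=min_frequency,
        eps=eps,
    )


def random_feature_null(
    values: np.ndarray,
    labels: np.ndarray,
    n_features: int,
    evaluator: Callable[[np.ndarray, np.ndarray], float],
    observed_indices: Sequence[int] | None = None,
    observed_score: float | None = None,
    R: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Empirical null of CV scores from R uniformly random N-feature subsets.

    ``evaluator(sub_matrix, labels)`` returns one scalar score (typically
    mean 10-fold logistic-regression AUC). The observed score comes either
    from ``observed_score`` directly or by evaluating
    ``observed_indices``. The percentile is the fraction of null scores
    strictly below the observed, times 100.
    """
    values = np.asarray(values, dtype=float)
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    if n_features > values.shape[1]:
        raise ValueError("n_features exceeds the feature count")
    if (observed_indices is None) == (observed_score is None):
        raise ValueError("provide exactly one of observed_indices / observed_score")
    if observed_score is None:
        observed_score = float(evaluator(values[:, np.asarray(observed_indices)], labels))
    rng = np.random.default_rng(seed)
    scores = np.empty(R)
    for r in range(R):
        draw = rng.choice(values.shape[1], size=n_features, replace=False)
        scores[r] = evaluator(values[:, draw], labels)
    return NullDistribution(
        scores=scores, observed=observed_score, n_features=n_features, seed=seed
    )
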