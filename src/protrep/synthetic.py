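"""Synthetic benchmark data with planted, fully known ground truth.

Three generators cover every input the pipeline needs:

* a two-class sequence set whose classes differ only in the insertion rate
  of a chosen set of "signal" trigrams, with one planted domain interval
  per protein and a controllable probability that signal lands inside it;
* toy trigram embedding tables (i.i.d. random, or signal-aligned so that a
  summed-embedding representation can separate the planted classes);
* mutation-ladder homolog families, in which copies of one parent sequence
  are degraded by point substitutions at increasing rates so that both
  alignment scores and representation similarities should decay.

Signal is planted by overwriting non-overlapping windows with signal
trigrams, so ground-truth occurrence positions are exact — which is what
the feature-selection recovery and region-enrichment tests score against.
All generators are pure functions of (config, seed); reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabets import STANDARD_AA
from .io import EmbeddingTable, Interval, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Parameters of the two-class planted-signal sequence generator.

    Insertion rates are expected signal insertions per 100 residues; each
    protein draws Poisson(rate * length / 100) insertions. ``domain_fraction``
    is the fraction of the sequence covered by the single planted domain
    interval (0 disables domain annotation) and ``signal_in_domain_prob``
    the probability that an insertion is placed wholly inside the domain.
    """

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (200, 400)
    background: np.ndarray | None = None
    signal_trigrams: tuple[str, ...] = ("WWW", "CHC", "MWM", "HCW", "WMH")
    insertion_rate_pos: float = 8.0
    insertion_rate_neg: float = 0.0
    domain_fraction: float = 0.5
    signal_in_domain_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background is None:
            self.background = np.full(20, 1 / 20)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 20 probabilities summing to 1")
        if self.insertion_rate_pos < 0 or self.insertion_rate_neg < 0:
            raise ValueError("insertion rates must be >= 0")
        if not 0 <= self.domain_fraction < 1:
            raise ValueError("domain_fraction must be in [0, 1)")
        if not 0 <= self.signal_in_domain_prob <= 1:
            raise ValueError("signal_in_domain_prob must be in [0, 1]")
        for tri in self.signal_trigrams:
            if len(tri) != 3 or any(c not in STANDARD_AA for c in tri):
                raise ValueError(f"signal trigram {tri!r} is not a standard trigram")


def _place_windows(
    length: int,
    domain: Interval | None,
    n_insert: int,
    in_domain_prob: float,
    rng: np.random.Generator,
) -> list[tuple[int, bool]] | None:
    """Pick non-overlapping window starts; returns None if placement fails."""
    occupied = np.zeros(length, dtype=bool)
    placements: list[tuple[int, bool]] = []
    for _ in range(n_insert):
        use_domain = domain is not None and rng.random() < in_domain_prob
        if domain is not None and use_domain:
            lo, hi = domain
        elif domain is not None:
            # non-domain side: windows fully outside the domain interval
            lo, hi = 0, length
        else:
            lo, hi = 0, length
        candidates = []
        for s in range(lo, hi - 2):
            if domain is not None:
                inside = domain[0] <= s and s + 3 <= domain[1]
                if use_domain != inside:
                    continue
            if not occupied[s : s + 3].any():
                candidates.append(s)
        if not candidates:
            return None
        start = int(rng.choice(candidates))
        occupied[start : start + 3] = True
        placements.append((start, use_domain))
    return placements


def _generate_protein(
    rec_id: str,
    label: int,
    rate: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    max_retries: int = 50,
) -> ProteinRecord:
    aa = np.array(list(STANDARD_AA))
    lo, hi = config.length_range
    for attempt in range(max_retries):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(aa, size=length, p=config.background)
        if config.domain_fraction > 0:
            dlen = max(3, int(round(config.domain_fraction * length)))
            offset = int(rng.integers(0, length - dlen + 1))
            domain: Interval | None = (offset, offset + dlen)
        else:
            domain = None
        n_insert = int(rng.poisson(rate * length / 100))
        placements = _place_windows(
            length, domain, n_insert, config.signal_in_domain_prob, rng
        )
        if placements is None:
            logger.info("placement failed for %s (attempt %d); resampling length", rec_id, attempt + 1)
            continue
        for start, _ in placements:
            tri = config.signal_trigrams[int(rng.integers(len(config.signal_trigrams)))]
            seq[start : start + 3] = list(tri)
        return ProteinRecord(
            id=rec_id,
            sequence="".join(seq),
            domains=[domain] if domain is not None else None,
            label=label,
        )
    raise RuntimeError(f"could not place {n_insert} signal windows for {rec_id}")


def generate_classification_dataset(
    config: GeneratorConfig,
) -> tuple[list[ProteinRecord], dict[str, list[Interval]], list[str]]:
    """Two-class planted-signal dataset.

    Returns (records with 0/1 labels, domain annotations keyed by id, and
    the ground-truth list of planted signal trigrams).
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    for i in range(config.n_pos):
        records.append(
            _generate_protein(f"pos{i:04d}", 1, config.insertion_rate_pos, config, rng)
        )
    for i in range(config.n_neg):
        records.append(
            _generate_protein(f"neg{i:04d}", 0, config.insertion_rate_neg, config, rng)
        )
    annotations = {rec.id: list(rec.domains) for rec in records if rec.domains}
    return records, annotations, list(config.signal_trigrams)


def generate_embedding_table(
    dimension: int = 100,
    structure: str = "random",
    signal_trigrams: tuple[str, ...] = (),
    noise: float = 0.1,
    seed: int = 0,
) -> EmbeddingTable:
    """Toy per-trigram embedding table over the full 8000-trigram vocabulary.

    ``structure="random"`` draws i.i.d. standard-normal vectors;
    ``"signal_aligned"`` places the given signal trigrams on a shared unit
    direction (scaled by 1) plus ``noise``-scaled Gaussian noise, so a
    summed-embedding representation can separate planted classes.
    """
    if structure not in ("random", "signal_aligned"):
        raise ValueError(f"unknown structure {structure!r}")
    if structure == "signal_aligned" and not signal_trigrams:
        raise ValueError("signal_aligned needs signal_trigrams")
    from .alphabets import standard_vocabulary

    rng = np.random.default_rng(seed)
    vocab = standard_vocabulary()
    vectors = {t: rng.standard_normal(dimension) for t in vocab.trigrams}
    if structure == "signal_aligned":
        direction = rng.standard_normal(dimension)
        direction /= np.linalg.norm(direction)
        for tri in signal_trigrams:
            vectors[tri] = direction + noise * rng.standard_normal(dimension)
    return EmbeddingTable(dimension=dimension, vectors=vectors)


def generate_homolog_ladder(
    parent_length: int = 150,
    mutation_rates: tuple[float, ...] = (0.05, 0.15, 0.3, 0.5),
    n_per_rate: int = 15,
    seed: int = 0,
) -> tuple[ProteinRecord, dict[float, list[ProteinRecord]]]:
    """Mutation-ladder homolog family from one random parent.

    Per rate r, each residue of the parent is independently substituted
    (uniformly over the other 19 letters) with probability r. Returns the
    parent and the copies grouped by rate.
    """
    if any(not 0 <= r <= 1 for r in mutation_rates):
        raise ValueError("mutation rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_AA))
    parent_seq = rng.choice(aa, size=parent_length)
    parent = ProteinRecord(id="parent", sequence="".join(parent_seq))
    ladder: dict[float, list[ProteinRecord]] = {}
    for rate in mutation_rates:
        group = []
        for i in range(n_per_rate):
            seq = parent_seq.copy()
            hits = np.flatnonzero(rng.random(parent_length) < rate)
            for pos in hits:
                others = aa[aa != seq[pos]]
                seq[pos] = others[int(rng.integers(len(others)))]
            group.append(
                ProteinRecord(id=f"rate{rate:g}_{i:03d}", sequence="".join(seq))
            )
        ladder[rate] = group
    return parent, ladder
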