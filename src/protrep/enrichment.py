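"""Domain vs non-domain enrichment of selected trigram features.

For each feature (trigram) and each annotated protein, occurrences are
assigned to the domain or non-domain region by the centre-residue rule and
divided by that protein's total region length (sum of domain interval
lengths, or its complement), giving a length-normalised coverage. Coverages
are summed over proteins, leaving two totals per feature; the feature is
called enriched in whichever region has the larger total (equal totals are
reported as ties rather than coerced).

Only proteins with at least one domain interval and at least one
non-domain residue can contribute; others are excluded upstream with a
logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabets import TrigramVocabulary
from .io import ProteinRecord
from .representations import extract_trigrams, _domain_mask

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """Length-normalised region coverage totals for one feature."""

    feature: int
    trigram: str
    domain_total: float
    nondomain_total: float

    @property
    def enriched_in(self) -> str:
        if self.domain_total > self.nondomain_total:
            return "domain"
        if self.nondomain_total > self.domain_total:
            return "nondomain"
        return "tie"


def eligible_records(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Records usable for region analysis: >=1 domain and >=1 non-domain residue."""
    kept, excluded = [], []
    for rec in records:
        if rec.domains and rec.domain_length() > 0 and rec.nondomain_length() > 0:
            kept.append(rec)
        else:
            excluded.append(rec.id)
    if excluded:
        logger.info(
            "region analysis excluded %d record(s) lacking a domain or non-domain region: %s",
            len(excluded), excluded[:10],
        )
    return kept


def _region_counts(record: ProteinRecord, trigram_to_col: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence counts of the tracked trigrams in each region of one protein."""
    mask = _domain_mask(record)
    dom = np.zeros(len(trigram_to_col))
    non = np.zeros(len(trigram_to_col))
    for i, tri in enumerate(extract_trigrams(record.sequence)):
        col = trigram_to_col.get(tri)
        if col is None:
            continue
        if mask[i + 1]:
            dom[col] += 1
        else:
            non[col] += 1
    return dom, non


def feature_region_coverage(
    feature: int, records: list[ProteinRecord], vocab: TrigramVocabulary
) -> tuple[float, float]:
    """Summed length-normalised (domain, non-domain) coverage of one feature."""
    table = enrichment_table([feature], records, vocab)
    return table[0].domain_total, table[0].nondomain_total


def enrichment_table(
    features: list[int] | np.ndarray,
    records: list[ProteinRecord],
    vocab: TrigramVocabulary,
) -> list[EnrichmentRecord]:
    """EnrichmentRecord per feature, computed over the eligible records.

    All records must already satisfy the eligibility precondition (use
    :func:`eligible_records` first); a record without both regions raises.
    """
    features = list(np.asarray(features, dtype=int))
    if not features:
        raise ValueError("empty feature list")
    trigrams = [vocab.trigrams[f] for f in features]
    trigram_to_col = {t: i for i, t in enumerate(trigrams)}
    dom_tot = np.zeros(len(features))
    non_tot = np.zeros(len(features))
    for rec in records:
        dlen, nlen = rec.domain_length(), rec.nondomain_length()
        if dlen == 0 or nlen == 0:
            raise ValueError(
                f"record {rec.id!r} lacks a domain or non-domain region; "
                "filter with eligible_records first"
            )
        dom, non = _region_counts(rec, trigram_to_col)
        dom_tot += dom / dlen
        non_tot += non / nlen
    return [
        EnrichmentRecord(
            feature=f, trigram=t, domain_total=float(d), nondomain_total=float(n)
        )
        for f, t, d, n in zip(features, trigrams, dom_tot, non_tot)
    ]


def summarize_enrichment(table: list[EnrichmentRecord]) -> dict[str, int]:
    """Partition counts: how many features are domain-/non-domain-enriched/tied."""
    counts = {"domain": 0, "nondomain": 0, "tie": 0}
    for rec in table:
        counts[rec.enriched_in] += 1
    if counts["tie"]:
        logger.info("%d feature(s) tied between regions", counts["tie"])
    return {
        "n_domain_enriched": counts["domain"],
        "n_nondomain_enriched": counts["nondomain"],
        "n_tied": counts["tie"],
    }
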