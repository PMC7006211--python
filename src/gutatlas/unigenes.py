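"""Unigene-set construction: isoform reduction, containment dedup, taxon filter.

The reduction mirrors a Trinity-based assembly workflow: keep the longest
protein per gene, drop proteins wholly contained in longer ones (exact
substring, identity 1.0), then discard genes with a significant
(e-value < 1e-5) best hit to an excluded taxon (bacteria, plants).  The
removed bacterial-like set is reported separately because it is analysed
(ANOVA along the gut) before being discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from gutatlas.io import parse_trinity_id

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_TAXA = frozenset({"bacteria", "plants"})


@dataclass(frozen=True)
class UnigeneRecord:
    """One protein-coding unigene (or isoform before reduction)."""

    gene_id: str
    isoform_id: str
    sequence: str
    taxon_hit: tuple[str, float] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def accession(self) -> str:
        return f"{self.gene_id}_{self.isoform_id}"


def records_from_fasta(
    seqs: Mapping[str, str],
) -> tuple[list[UnigeneRecord], list[str]]:
    """Parse accession->sequence into records; unparseable IDs are
    rejected and returned (and logged), not silently dropped."""
    records: list[UnigeneRecord] = []
    rejected: list[str] = []
    for acc, seq in seqs.items():
        try:
            gene, isoform = parse_trinity_id(acc)
        except ValueError:
            logger.warning("rejecting unparseable accession %r", acc)
            rejected.append(acc)
            continue
        records.append(UnigeneRecord(gene, isoform, seq))
    return records, rejected


def select_longest_isoform(records: Iterable[UnigeneRecord]) -> list[UnigeneRecord]:
    """Keep the longest protein of each gene.

    Ties on length are broken by the lexicographically smaller isoform
    id, so the result is deterministic and order-independent.
    """
    best: dict[str, UnigeneRecord] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if (
            cur is None
            or rec.length > cur.length
            or (rec.length == cur.length and rec.isoform_id < cur.isoform_id)
        ):
            best[rec.gene_id] = rec
    return sorted(best.values(), key=lambda r: r.gene_id)


def remove_contained(unigenes: Sequence[UnigeneRecord]) -> list[UnigeneRecord]:
    """Drop every sequence that is an exact substring of a longer (or
    identical, larger-ID) surviving sequence.

    Records are visited longest-first (ties by gene id), and a record
    survives only if it is not a substring of any already-surviving
    sequence; this makes the outcome independent of input order and
    keeps exactly one copy of identical sequences (smallest gene id).
    """
    ordered = sorted(unigenes, key=lambda r: (-r.length, r.gene_id))
    kept: list[UnigeneRecord] = []
    for rec in ordered:
        if any(rec.sequence in k.sequence for k in kept):
            continue
        kept.append(rec)
    return sorted(kept, key=lambda r: r.gene_id)


def filter_taxon(
    unigenes: Sequence[UnigeneRecord],
    taxon_annotation: pd.DataFrame,
    e_max: float = 1e-5,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TAXA,
) -> tuple[list[UnigeneRecord], list[UnigeneRecord]]:
    """Split unigenes into (kept, removed) by best-hit taxon.

    A gene is removed iff its best hit is in an excluded taxon group
    with e-value strictly below ``e_max``.  Annotation rows referencing
    unknown genes are ignored with a warning.
    """
    known = {r.gene_id for r in unigenes}
    flagged: set[str] = set()
    for row in taxon_annotation.itertuples(index=False):
        gene = str(row.gene_id)
        if gene not in known:
            logger.warning("taxon annotation for unknown gene %r ignored", gene)
            continue
        if str(row.taxon_group) in excluded and float(row.e_value) < e_max:
            flagged.add(gene)
    kept = [r for r in unigenes if r.gene_id not in flagged]
    removed = [r for r in unigenes if r.gene_id in flagged]
    return kept, removed


def build_unigene_set(
    seqs: Mapping[str, str],
    taxon_annotation: pd.DataFrame,
    e_max: float = 1e-5,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TAXA,
) -> dict[str, list]:
    """Full reduction pipeline in the fixed order: isoform selection ->
    containment dedup -> taxon filter.  Returns all intermediate sets so
    reports can account for every gene."""
    records, rejected = records_from_fasta(seqs)
    longest = select_longest_isoform(records)
    deduped = remove_contained(longest)
    kept, removed_taxon = filter_taxon(deduped, taxon_annotation, e_max, excluded)
    return {
        "rejected_accessions": rejected,
        "longest": longest,
        "deduped": deduped,
        "unigenes": kept,
        "removed_taxon": removed_taxon,
    }
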