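"""Local protein similarity search producing outfmt-6-style hit tables.

Smith-Waterman local alignment with BLOSUM62 and affine gaps in the
BLAST existence/extension convention (a gap of length L costs
open + extend * L = 11 + L).  Raw scores S are converted to bit scores
with fixed ungapped Karlin-Altschul constants,

    S' = (lambda * S - ln K) / ln 2,   lambda = 0.267, K = 0.041,

and e-values as E = m * n * 2^(-S') with m the query length and n the
search-space length: the total subject-database length in
:func:`similarity_search` (the BLAST convention), the single subject
length in :func:`align_pair`.  External BLAST/HMMer tabular output can
be used interchangeably with these tables downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from gutatlas.io import HitRecord

LAMBDA = 0.267
K_KA = 0.041
GAP_OPEN = 11  # gap existence cost
GAP_EXTEND = 1  # per-residue extension cost


@dataclass(frozen=True)
class SearchParams:
    evalue_max: float = 10.0
    gap_open: int = GAP_OPEN
    gap_extend: int = GAP_EXTEND


def _aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython's open_gap_score is the cost of the first gap residue
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def bit_score(raw_score: float) -> float:
    return (LAMBDA * raw_score - math.log(K_KA)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bit_score(raw_score))


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int, int, int]:
    """(identities, aln_len, mismatches, gap_opens, qs, qe, ss, se) for the
    best local alignment; coordinates 1-based inclusive."""
    q_blocks, s_blocks = alignment.aligned
    query, subject = alignment.sequences
    identities = 0
    block_len = 0
    for (qs, qe), (ss, _) in zip(q_blocks, s_blocks):
        block_len += qe - qs
        for off in range(qe - qs):
            if query[qs + off] == subject[ss + off]:
                identities += 1
    gap_cols = 0
    gap_opens = 0
    for i in range(1, len(q_blocks)):
        dq = q_blocks[i][0] - q_blocks[i - 1][1]
        ds = s_blocks[i][0] - s_blocks[i - 1][1]
        gap_cols += dq + ds
        gap_opens += (dq > 0) + (ds > 0)
    aln_len = block_len + gap_cols
    mismatches = block_len - identities
    return (
        identities,
        aln_len,
        mismatches,
        gap_opens,
        int(q_blocks[0][0]) + 1,
        int(q_blocks[-1][1]),
        int(s_blocks[0][0]) + 1,
        int(s_blocks[-1][1]),
    )


def align_pair(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    params: SearchParams = SearchParams(),
    search_space: int | None = None,
) -> HitRecord | None:
    """Best local alignment of one pair, or None if above the e-value cap.

    ``search_space`` overrides the database length used in the e-value
    (defaults to the subject length for a lone pair).
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = _aligner(params)
    raw = aligner.score(query, subject)
    if raw <= 0:
        return None
    E = evalue(raw, len(query), search_space or len(subject))
    if E > params.evalue_max:
        return None
    alignment = next(iter(aligner.align(query, subject)))
    ident, aln_len, mism, gapo, qs, qe, ss, se = _alignment_stats(alignment)
    return HitRecord(
        query=query_id,
        subject=subject_id,
        pident=100.0 * ident / aln_len,
        length=aln_len,
        mismatch=mism,
        gapopen=gapo,
        qstart=qs,
        qend=qe,
        sstart=ss,
        send=se,
        evalue=E,
        bitscore=bit_score(raw),
    )


def similarity_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    params: SearchParams = SearchParams(),
) -> list[HitRecord]:
    """All-vs-all local search; hits sorted by e-value then bit score.

    The raw alignment score is computed first for every pair and the
    full traceback only for pairs below the e-value cap, which keeps
    large searches fast.
    """
    if not queries or not subjects:
        raise ValueError("empty sequence set")
    aligner = _aligner(params)
    db_len = sum(len(s) for s in subjects.values())
    hits: list[HitRecord] = []
    for qid, q in queries.items():
        if not q:
            raise ValueError(f"empty sequence: {qid}")
        for sid, s in subjects.items():
            if not s:
                raise ValueError(f"empty sequence: {sid}")
            raw = aligner.score(q, s)
            if raw <= 0 or evalue(raw, len(q), db_len) > params.evalue_max:
                continue
            hit = align_pair(qid, q, sid, s, params, search_space=db_len)
            if hit is not None:
                hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.query, h.subject))
    return hits


def query_coverage(hit: HitRecord, query_length: int) -> float:
    """Aligned query span as a fraction of the query length."""
    return (hit.qend - hit.qstart + 1) / query_length
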