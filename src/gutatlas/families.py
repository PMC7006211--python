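"""Homology-based gene-family annotation: P450s and nutrient transporters.

Two bespoke pipelines drive family assignment from reference panels of
two species (human and fly for the transporter families; a curated
insect set for the P450s):

* P450-like families: a unigene is a candidate iff a panel query hits
  it (e <= 1e-3, query coverage > 40%), the reciprocal search of the
  unigene against the panel passes the same thresholds, its length
  lies in [150, 650], and it carries the P450 heme-ligand motif (or an
  externally supplied Pfam domain call).  Overlapping candidate
  fragments are joined at exact suffix/prefix overlaps.

* Transporter families: candidates pass a reciprocal family vote --
  (i) the top back-hit is in family F, (ii) at least 4 of the top 5
  back-hits are in F (all members suffice when F has fewer than 5),
  (iii) best identity to an F member is >= 20% -- and are then filtered
  for at least three predicted transmembrane segments and for length
  within [family min - sd, family max + sd].

Accepted candidates are fed back as queries and the search iterates to
a fixed point; earlier calls are never revoked.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from statistics import stdev
from typing import Iterable, Mapping, Sequence

import pandas as pd

from gutatlas.align import SearchParams, query_coverage, similarity_search
from gutatlas.hydropathy import count_tm
from gutatlas.io import MIDGUT_TISSUES, HitRecord

logger = logging.getLogger(__name__)

#: default P450 heme-ligand motif, F-x-x-G-x-[RH]-x-C-x-G
P450_MOTIF = r"F..G.[RH].C.G"


@dataclass(frozen=True)
class FamilyPanel:
    """Reference family with members pooled over two reference species."""

    name: str
    kind: str  # "p450" | "transporter"
    members: Mapping[str, str]  # accession -> sequence

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family panel {self.name!r} has no members")
        if self.kind not in ("p450", "transporter"):
            raise ValueError(f"unknown family kind {self.kind!r}")

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.members.values()]

    @property
    def min_length(self) -> int:
        return min(self.lengths)

    @property
    def max_length(self) -> int:
        return max(self.lengths)

    @property
    def length_sd(self) -> float:
        ls = self.lengths
        return stdev(ls) if len(ls) > 1 else 0.0


@dataclass(frozen=True)
class FamilyCall:
    gene_id: str
    family: str
    top_hit_family: str
    vote_count: int  # family hits among the top 5 back-hits
    best_identity: float
    tm_count: int | None
    length_ok: bool
    round_found: int


@dataclass(frozen=True)
class FamilyAnnotParams:
    evalue_max: float = 1e-3
    min_coverage: float = 0.40  # strict >
    min_identity: float = 20.0  # criterion iii, percent identity
    min_tm: int = 3
    tm_window: int = 19
    tm_threshold: float = 1.6
    p450_length: tuple[int, int] = (150, 650)
    motif: str = P450_MOTIF
    min_overlap: int = 20
    max_rounds: int = 5


# ---------------------------------------------------------------------------
# filters


def length_filter(candidate_length: int, panel: FamilyPanel) -> bool:
    """Keep iff within [min - sd, max + sd] of the panel lengths (inclusive)."""
    sd = panel.length_sd
    return panel.min_length - sd <= candidate_length <= panel.max_length + sd


def has_domain(
    sequence: str,
    motif: str = P450_MOTIF,
    gene_id: str | None = None,
    domain_table: Mapping[str, set[str]] | None = None,
    domain_accession: str = "PF00067",
) -> bool:
    """Domain check: an external per-gene domain table wins if provided,
    otherwise the motif pattern is searched in the sequence."""
    if domain_table is not None and gene_id is not None:
        return domain_accession in domain_table.get(gene_id, set())
    return re.search(motif, sequence) is not None


def _passes(hit: HitRecord, qlen: int, params: FamilyAnnotParams) -> bool:
    return hit.evalue <= params.evalue_max and query_coverage(hit, qlen) > params.min_coverage


# ---------------------------------------------------------------------------
# classification


def classify_family(
    candidate: str,
    reciprocal_hits: Sequence[HitRecord],
    panels: Mapping[str, FamilyPanel],
    min_identity: float = 20.0,
) -> FamilyCall | None:
    """Family vote over the candidate's back-hits (criteria i-iii).

    ``reciprocal_hits`` are the candidate's hits against the pooled
    panel members, already threshold-filtered; ties on e-value break by
    bit score then subject id.
    """
    if not reciprocal_hits:
        return None
    member_family = {
        acc: p.name for p in panels.values() for acc in p.members
    }
    hits = sorted(
        reciprocal_hits, key=lambda h: (h.evalue, -h.bitscore, h.subject)
    )
    top_family = member_family[hits[0].subject]
    top5 = hits[:5]
    fam = panels[top_family]
    in_family = [h for h in top5 if member_family[h.subject] == top_family]
    if len(fam.members) >= 5:
        vote_ok = len(in_family) >= 4
    else:
        seen = {h.subject for h in top5}
        vote_ok = set(fam.members) <= seen
    best_ident = max(
        (h.pident for h in hits if member_family[h.subject] == top_family),
        default=0.0,
    )
    if not vote_ok or best_ident < min_identity:
        return None
    return FamilyCall(
        gene_id=candidate,
        family=top_family,
        top_hit_family=top_family,
        vote_count=len(in_family),
        best_identity=best_ident,
        tm_count=None,
        length_ok=True,
        round_found=0,
    )


# ---------------------------------------------------------------------------
# fragment joining


def merge_fragments(
    candidates: Mapping[str, str], min_overlap: int = 20
) -> dict[str, str]:
    """Join candidate fragments that overlap exactly at their ends.

    Two fragments are joined when a suffix of one equals a prefix of
    the other over at least ``min_overlap`` residues at 100% identity;
    joining repeats to a fixed point and the result is independent of
    input order.  When one fragment end admits two incompatible joins,
    neither is applied and the conflict is logged.  Identical sequences
    collapse to a single record first.
    """
    # collapse exact duplicates (keep the smallest id)
    by_seq: dict[str, str] = {}
    for cid in sorted(candidates):
        seq = candidates[cid]
        if seq not in by_seq:
            by_seq[seq] = cid
    frags = {cid: seq for seq, cid in by_seq.items()}

    def best_overlap(a: str, b: str) -> int:
        limit = min(len(a), len(b))
        for o in range(limit, min_overlap - 1, -1):
            if a[-o:] == b[:o]:
                return o
        return 0

    while True:
        ids = sorted(frags)
        joins: list[tuple[str, str, int]] = []
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                o = best_overlap(frags[a], frags[b])
                if o:
                    joins.append((a, b, o))
        if not joins:
            return frags
        # an end (a-right or b-left) used by more than one join is in conflict
        right_use: dict[str, int] = {}
        left_use: dict[str, int] = {}
        for a, b, _ in joins:
            right_use[a] = right_use.get(a, 0) + 1
            left_use[b] = left_use.get(b, 0) + 1
        applied = False
        for a, b, o in joins:
            if right_use[a] > 1 or left_use[b] > 1:
                logger.warning("conflicting overlaps at %s/%s: join skipped", a, b)
                continue
            frags[f"{a}+{b}"] = frags[a] + frags[b][o:]
            del frags[a]
            if b in frags:
                del frags[b]
            applied = True
            break  # one join per pass keeps bookkeeping simple
        if not applied:
            return frags


# ---------------------------------------------------------------------------
# P450 candidate pipeline


def p450_candidates(
    forward_hits: Sequence[HitRecord],
    unigenes: Mapping[str, str],
    curated: Mapping[str, str],
    params: FamilyAnnotParams = FamilyAnnotParams(),
    domain_table: Mapping[str, set[str]] | None = None,
) -> list[str]:
    """Unigenes passing the four P450 criteria.

    ``forward_hits`` come from searching the curated P450 set against
    the unigenes.  Criteria: forward hit under thresholds, reciprocal
    hit under the same thresholds, length within ``params.p450_length``
    and presence of the P450 domain motif.
    """
    lo, hi = params.p450_length
    search = SearchParams(evalue_max=params.evalue_max)
    hit_unigenes = {
        h.subject
        for h in forward_hits
        if h.query in curated and _passes(h, len(curated[h.query]), params)
    }
    accepted: list[str] = []
    for uid in sorted(hit_unigenes):
        seq = unigenes[uid]
        if not lo <= len(seq) <= hi:
            continue
        if not has_domain(seq, params.motif, uid, domain_table):
            continue
        recip = similarity_search({uid: seq}, curated, search)
        if any(_passes(h, len(seq), params) for h in recip):
            accepted.append(uid)
    return accepted


# ---------------------------------------------------------------------------
# iterative annotation


def iterative_annotate(
    unigenes: Mapping[str, str],
    panels: Mapping[str, FamilyPanel],
    params: FamilyAnnotParams = FamilyAnnotParams(),
    domain_table: Mapping[str, set[str]] | None = None,
) -> list[FamilyCall]:
    """Iterative family annotation against reference panels.

    Round 1 searches the panel members against the unigene set;
    accepted candidates join the query set and rounds repeat until no
    new acceptance (or ``max_rounds``).  Calls from earlier rounds are
    never revoked.
    """
    search = SearchParams(evalue_max=params.evalue_max)
    pooled = {
        acc: seq for p in panels.values() for acc, seq in p.members.items()
    }
    calls: dict[str, FamilyCall] = {}
    queries: dict[str, str] = dict(pooled)

    for round_no in range(1, params.max_rounds + 1):
        forward = similarity_search(queries, unigenes, search)
        candidates = sorted(
            {
                h.subject
                for h in forward
                if h.subject not in calls
                and _passes(h, len(queries[h.query]), params)
            }
        )
        new_calls: dict[str, FamilyCall] = {}
        for uid in candidates:
            seq = unigenes[uid]
            recip = [
                h
                for h in similarity_search({uid: seq}, pooled, search)
                if _passes(h, len(seq), params)
            ]
            call = classify_family(uid, recip, panels, params.min_identity)
            if call is None:
                continue
            fam = panels[call.family]
            if fam.kind == "transporter":
                tm = count_tm(seq, params.tm_window, params.tm_threshold)
                ok_len = length_filter(len(seq), fam)
                if tm < params.min_tm or not ok_len:
                    continue
                call = FamilyCall(
                    gene_id=uid, family=call.family,
                    top_hit_family=call.top_hit_family,
                    vote_count=call.vote_count,
                    best_identity=call.best_identity,
                    tm_count=tm, length_ok=ok_len, round_found=round_no,
                )
            else:  # p450-like: length window + domain motif
                lo, hi = params.p450_length
                if not lo <= len(seq) <= hi:
                    continue
                if not has_domain(seq, params.motif, uid, domain_table):
                    continue
                call = FamilyCall(
                    gene_id=uid, family=call.family,
                    top_hit_family=call.top_hit_family,
                    vote_count=call.vote_count,
                    best_identity=call.best_identity,
                    tm_count=None, length_ok=True, round_found=round_no,
                )
            new_calls[uid] = call
        if not new_calls:
            break
        calls.update(new_calls)
        queries = {uid: unigenes[uid] for uid in new_calls}
    return [calls[g] for g in sorted(calls)]


def calls_to_frame(calls: Iterable[FamilyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "family": c.family,
                "top_hit_family": c.top_hit_family,
                "vote_count": c.vote_count,
                "best_identity": c.best_identity,
                "tm_count": c.tm_count,
                "length_ok": c.length_ok,
                "round_found": c.round_found,
            }
            for c in calls
        ]
    )


# ---------------------------------------------------------------------------
# expression summary


def summarize_family_expression(
    calls: Sequence[FamilyCall],
    mean_table: pd.DataFrame,
    thresholds: tuple[float, ...] = (5.0, 50.0),
    tissues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per family x tissue: mean member TPM and counts above thresholds.

    Genes with TPM <= 1 in all midgut compartments are excluded first;
    a family whose members are all filtered away keeps a zero row and
    is flagged.
    """
    tissues = list(tissues) if tissues is not None else list(mean_table.columns)
    expressed = mean_table[list(MIDGUT_TISSUES)].gt(1.0).any(axis=1)
    rows = []
    families = sorted({c.family for c in calls})
    for fam in families:
        members = [
            c.gene_id
            for c in calls
            if c.family == fam and c.gene_id in mean_table.index
            and expressed.get(c.gene_id, False)
        ]
        row: dict[str, object] = {"family": fam, "n_members": len(members)}
        row["all_filtered"] = len(members) == 0
        for t in tissues:
            vals = mean_table.loc[members, t] if members else pd.Series(dtype=float)
            row[f"avg_{t}"] = float(vals.mean()) if len(members) else 0.0
            for thr in thresholds:
                row[f"n_over_{thr:g}_{t}"] = int((vals > thr).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    if rows:
        out = out.set_index("family")
        for fam in out.index[out["all_filtered"]]:
            logger.warning("family %s: all members below 1 TPM everywhere", fam)
    return out
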