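"""Gene-group term enrichment: one-sided Fisher's exact test with BH FDR.

Each (gene group, term) pair yields a 2x2 contingency table over a gene
universe; over-representation is scored by the hypergeometric upper
tail, P(X >= k), and Benjamini-Hochberg adjustment is applied jointly
across every test in the run.  Terms annotating fewer than
``min_genes`` universe genes are excluded before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one (group, term) pair over a gene universe."""

    N: int  # universe size
    n: int  # group size
    K: int  # universe genes annotated with the term
    k: int  # group genes annotated with the term

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.n, self.K)
            and self.K <= self.N
            and self.n <= self.N
            and self.k >= self.n + self.K - self.N
        )
        if not ok:
            raise ValueError(f"inconsistent contingency counts: {self}")


@dataclass(frozen=True)
class EnrichmentRow:
    group: str
    term: str
    term_kind: str
    table: ContingencyTable
    p_raw: float
    fdr: float
    annotation: str = ""


def _term_sets(
    term_annotation: pd.DataFrame, universe: set[str]
) -> dict[tuple[str, str], set[str]]:
    """(term_id, term_kind) -> set of annotated universe genes.

    Rows referencing genes outside the universe are ignored; duplicated
    (gene, term) rows collapse by the set semantics.
    """
    sets: dict[tuple[str, str], set[str]] = {}
    for row in term_annotation.itertuples(index=False):
        gene = str(row.gene_id)
        if gene not in universe:
            continue
        sets.setdefault((str(row.term_id), str(row.term_kind)), set()).add(gene)
    return sets


def build_contingency(
    group: Iterable[str],
    term_genes: Iterable[str],
    universe: Iterable[str],
) -> ContingencyTable:
    """Exact set-intersection counts for one group and one term."""
    uni = set(universe)
    grp = set(group)
    if not grp <= uni:
        raise ValueError("group is not a subset of the universe")
    term = set(term_genes) & uni
    return ContingencyTable(N=len(uni), n=len(grp), K=len(term), k=len(grp & term))


def fisher_right_tail(table: ContingencyTable) -> float:
    """One-sided over-representation p-value, P(X >= k) for
    X ~ Hypergeometric(N, K, n).  Numerically stable down to ~1e-300."""
    return float(stats.hypergeom.sf(table.k - 1, table.N, table.K, table.n))


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_groups(
    groups: Mapping[str, Iterable[str]],
    term_annotation: pd.DataFrame,
    universe: Iterable[str],
    min_genes: int = 10,
    fdr_max: float = 0.001,
    min_genes_on: str = "K",
    annotations: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Test every (group, term) pair; return rows with fdr < fdr_max.

    ``min_genes`` bounds the term size in the universe (K) by default;
    set ``min_genes_on="k"`` to bound the overlap instead.  BH runs
    jointly across all surviving tests; results are sorted by
    (group, fdr).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not groups:
        raise ValueError("need at least one group")
    if min_genes_on not in ("K", "k"):
        raise ValueError("min_genes_on must be 'K' or 'k'")
    sets = _term_sets(term_annotation, uni)

    tests: list[tuple[str, str, str, ContingencyTable, float]] = []
    for gname, members in groups.items():
        grp = set(members)
        if not grp <= uni:
            raise ValueError(f"group {gname!r} is not a subset of the universe")
        for (term, kind), tgenes in sets.items():
            if min_genes_on == "K" and len(tgenes) < min_genes:
                continue
            table = ContingencyTable(
                N=len(uni), n=len(grp), K=len(tgenes), k=len(grp & tgenes)
            )
            if min_genes_on == "k" and table.k < min_genes:
                continue
            tests.append((gname, term, kind, table, fisher_right_tail(table)))

    if not tests:
        return []
    fdr = bh_adjust([t[4] for t in tests])
    ann = annotations or {}
    rows = [
        EnrichmentRow(
            group=g, term=term, term_kind=kind, table=tab,
            p_raw=p, fdr=float(q), annotation=ann.get(term, ""),
        )
        for (g, term, kind, tab, p), q in zip(tests, fdr)
        if q < fdr_max
    ]
    rows.sort(key=lambda r: (r.group, r.fdr, r.term))
    return rows


def n_tested(
    groups: Mapping[str, Iterable[str]],
    term_annotation: pd.DataFrame,
    universe: Iterable[str],
    min_genes: int = 10,
) -> int:
    """Number of (group, term) pairs that survive the K >= min_genes cut."""
    uni = set(universe)
    sets = _term_sets(term_annotation, uni)
    eligible = sum(1 for s in sets.values() if len(s) >= min_genes)
    return eligible * len(groups)


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Table-shaped output: group, term, fdr, counts, annotation."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "term_id": r.term,
                "term_kind": r.term_kind,
                "fdr": r.fdr,
                "p_raw": r.p_raw,
                "k_in_group": r.table.k,
                "K_in_universe": r.table.K,
                "group_size": r.table.n,
                "universe_size": r.table.N,
                "annotation": r.annotation,
            }
            for r in rows
        ]
    )
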