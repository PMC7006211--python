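"""Atlas quantities from replicate TPM matrices.

Per-tissue replicate means, presence calls (mean TPM strictly > 1),
compartment-overlap partitions over the four midgut sections, Top-N
most-highly-expressed gene groups, a PCA summary over samples, and
per-gene one-way ANOVA across gut regions on log2(TPM+1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from gutatlas.enrichment import bh_adjust
from gutatlas.io import MIDGUT_TISSUES, TISSUES


def split_column(col: str) -> tuple[str, str]:
    tissue, _, rep = col.rpartition("_")
    return tissue, rep


def tissue_columns(matrix: pd.DataFrame, tissue: str) -> list[str]:
    cols = [c for c in matrix.columns if split_column(c)[0] == tissue]
    if not cols:
        raise ValueError(f"no replicate columns for tissue {tissue!r}")
    return cols


def average_replicates(
    matrix: pd.DataFrame, tissues: Sequence[str] = TISSUES
) -> pd.DataFrame:
    """Arithmetic mean TPM per (gene, tissue) across replicates."""
    out = {t: matrix[tissue_columns(matrix, t)].mean(axis=1) for t in tissues}
    return pd.DataFrame(out, index=matrix.index)


def presence_calls(mean_table: pd.DataFrame, tpm_min: float = 1.0) -> pd.DataFrame:
    """Boolean gene x tissue table; present iff mean TPM strictly > tpm_min.

    Genes absent everywhere keep an all-False row.
    """
    return mean_table.gt(tpm_min)


def overlap_partition(
    presence: pd.DataFrame, tissues: Sequence[str] = MIDGUT_TISSUES
) -> dict[frozenset[str], int]:
    """Counts of every non-empty presence pattern over ``tissues``.

    The 2^k - 1 cells form a disjoint partition of the genes present in
    at least one of the named tissues (Venn-diagram cells).
    """
    missing = [t for t in tissues if t not in presence.columns]
    if missing:
        raise ValueError(f"unknown tissue name(s): {missing}")
    sub = presence[list(tissues)]
    counts: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for r in range(1, len(tissues) + 1)
        for combo in itertools.combinations(tissues, r)
    }
    for _, row in sub.iterrows():
        pattern = frozenset(t for t in tissues if row[t])
        if pattern:
            counts[pattern] += 1
    return counts


def top_n(mean_table: pd.DataFrame, tissue: str, n: int = 500) -> list[str]:
    """The n most highly expressed genes in one tissue.

    Ties spanning rank n are resolved toward lexicographically smaller
    gene ids, so the group is deterministic and nested in the group at
    n + 1.
    """
    if tissue not in mean_table.columns:
        raise ValueError(f"unknown tissue {tissue!r}")
    if n > len(mean_table):
        raise ValueError(f"n={n} exceeds gene count {len(mean_table)}")
    order = sorted(
        mean_table.index, key=lambda g: (-mean_table.at[g, tissue], g)
    )
    return order[:n]


@dataclass
class PCASummary:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    n_genes_used: int


def pca_summary(matrix: pd.DataFrame, n_components: int | None = None) -> PCASummary:
    """PCA over samples (tissue x replicate columns).

    Genes are the variables, centred and scaled to unit variance;
    zero-variance genes are dropped first.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCASummary(
        scores=pd.DataFrame(
            scores,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_genes_used=int(keep.sum()),
    )


def anova_gene(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects F and p from the between/within decomposition.

    Degenerate inputs (zero between- and within-group variance) report
    F = 0, p = 1; zero within-group variance with distinct means reports
    F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    if dfw < 1:
        raise ValueError("ANOVA needs >= 2 replicates overall per extra group")
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    return float(F), float(stats.f.sf(F, dfb, dfw))


def anova_by_region(
    matrix: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    tissues: Sequence[str] = MIDGUT_TISSUES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA across gut regions on log2(TPM + 1).

    Returns F, p, BH-adjusted p and a significance flag at ``alpha``
    for the tested subset.
    """
    genes = list(gene_subset) if gene_subset is not None else list(matrix.index)
    cols_by_tissue = {t: tissue_columns(matrix, t) for t in tissues}
    for t, cols in cols_by_tissue.items():
        if len(cols) < 2:
            raise ValueError(f"tissue {t} has < 2 replicates")
    log = np.log2(matrix.loc[genes] + 1.0)
    rows = []
    for g in genes:
        groups = [log.loc[g, cols_by_tissue[t]].to_numpy(dtype=float) for t in tissues]
        F, p = anova_gene(groups)
        rows.append((g, F, p))
    out = pd.DataFrame(rows, columns=["gene_id", "F", "p"]).set_index("gene_id")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    return out
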