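"""Fuzzy C-means clustering of standardized expression profiles.

Profiles are z-scored per gene across the midgut compartments (so only
the relative pattern matters), then clustered with the standard fuzzy
C-means alternating optimisation: memberships

    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)),

centroids c_j = sum_i u_ij^m x_i / sum_i u_ij^m, Euclidean distance,
objective J = sum_ij u_ij^m d_ij^2 non-increasing every iteration.  The
best of several seeded restarts is kept.  Genes whose maximum
membership exceeds a retention threshold alpha (> 0.5, so assignments
are unique) form the cluster gene groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from gutatlas.io import MIDGUT_TISSUES


@dataclass(frozen=True)
class ClusterParams:
    c: int = 8          # cluster count
    m: float = 1.25     # fuzzifier (> 1); small keeps memberships decisive
    tol: float = 1e-8   # convergence tolerance on the objective
    max_iter: int = 300
    restarts: int = 20
    alpha: float = 0.6  # membership retention threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ClusterResult:
    centroids: np.ndarray           # c x n_features
    membership: pd.DataFrame        # genes x c
    objective: float
    iterations: int
    objective_trace: list[float] = field(default_factory=list)


def standardize(
    mean_table: pd.DataFrame,
    tissues: Sequence[str] = MIDGUT_TISSUES,
    tpm_min: float = 1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-profiles across ``tissues``.

    Genes with zero variance across the selected tissues, or with mean
    TPM <= ``tpm_min`` in all of them, are excluded and returned
    separately.
    """
    sub = mean_table[list(tissues)]
    sd = sub.std(axis=1, ddof=1)
    expressed = sub.gt(tpm_min).any(axis=1)
    keep = (sd > 0) & expressed
    z = sub.loc[keep].sub(sub.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z, list(sub.index[~keep])


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix from squared distances (n x c); exact centroid
    hits (d=0) get membership split over the hit centroids."""
    # distances below this are exact centroid hits; also guards the
    # d^(-2/(m-1)) power against overflow
    zero = d2 <= 1e-60
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        power = 1.0 / (m - 1.0)
        inv = d2 ** -power  # (1/d^2)^{1/(m-1)}
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.nonzero(any_zero)[0]
        u[rows] = 0.0
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return u


def _objective(d2: np.ndarray, u: np.ndarray, m: float) -> float:
    return float(((u**m) * d2).sum())


def _sq_dist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ C.T
        + (C**2).sum(axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def _run_once(
    X: np.ndarray, params: ClusterParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n = X.shape[0]
    init_idx = rng.choice(n, size=params.c, replace=False)
    C = X[init_idx].copy()
    trace: list[float] = []
    u = _memberships(_sq_dist(X, C), params.m)
    for it in range(1, params.max_iter + 1):
        um = u**params.m
        C = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = _sq_dist(X, C)
        u = _memberships(d2, params.m)
        J = _objective(d2, u, params.m)
        trace.append(J)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < params.tol:
            return C, u, J, it, trace
    return C, u, trace[-1], params.max_iter, trace


def fuzzy_cmeans(z_matrix: pd.DataFrame, params: ClusterParams) -> ClusterResult:
    """Cluster z-profiles; return the best of ``params.restarts`` runs."""
    X = z_matrix.to_numpy(dtype=float)
    distinct = len(np.unique(X, axis=0))
    if params.c > distinct:
        raise ValueError(
            f"c={params.c} exceeds the {distinct} distinct profiles available"
        )
    rng = np.random.default_rng(params.seed)
    best: tuple | None = None
    for _ in range(params.restarts):
        C, u, J, it, trace = _run_once(X, params, rng)
        if best is None or J < best[2]:
            best = (C, u, J, it, trace)
    C, u, J, it, trace = best
    membership = pd.DataFrame(
        u, index=z_matrix.index, columns=[f"cluster_{j + 1}" for j in range(params.c)]
    )
    return ClusterResult(
        centroids=C, membership=membership, objective=J,
        iterations=it, objective_trace=trace,
    )


def assign_members(
    result: ClusterResult, alpha: float = 0.6
) -> tuple[dict[str, list[str]], list[str]]:
    """Genes with membership strictly above alpha, per cluster.

    With alpha > 0.5 assignments are unique.  Returns
    ({cluster: [genes]}, unassigned genes).
    """
    U = result.membership
    groups: dict[str, list[str]] = {c: [] for c in U.columns}
    unassigned: list[str] = []
    best_cluster = U.idxmax(axis=1)
    best_val = U.max(axis=1)
    for gene in U.index:
        if best_val[gene] > alpha:
            groups[best_cluster[gene]].append(gene)
        else:
            unassigned.append(gene)
    return groups, unassigned


def hard_labels(result: ClusterResult) -> pd.Series:
    """Argmax cluster label per gene (for planted-truth comparisons)."""
    return result.membership.idxmax(axis=1)
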