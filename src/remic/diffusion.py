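"""Laplacian heat-kernel diffusion of gene mutation scores.

The diffusion kernel of a weighted undirected graph with Laplacian
L = D - W (D the diagonal of weighted degrees) is

    K_beta = exp(-beta * L),    beta >= 0,

the matrix exponential of the negated, scaled Laplacian. K_0 = I (no
diffusion); as beta grows, scores spread along edges, and on a connected
graph every row of K_beta tends to the uniform distribution, so diffusion
equilibrates while conserving the total score: sum(S K_beta) = sum(S) at
every scale. K_beta is symmetric, entrywise nonnegative and row-stochastic.

``diffuse_scores`` computes S K_beta as the action of the matrix
exponential on a vector (``scipy.sparse.linalg.expm_multiply``) without
ever forming the dense g x g kernel; ``diffusion_kernel`` forms the dense
kernel and is intended for small graphs (tests, cluster-level analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from remic.network_io import GeneNetwork

DENSE_NODE_CAP = 2000

__all__ = [
    "LaplacianMatrix",
    "DiffusedScores",
    "laplacian",
    "diffusion_kernel",
    "diffuse_scores",
    "diffuse_vectors",
    "make_beta_grid",
    "DENSE_NODE_CAP",
]

LaplacianMatrix = sp.csr_matrix  # alias: symmetric PSD, rows sum to zero


@dataclass
class DiffusedScores:
    """Score vector S K_beta at one diffusion scale."""

    beta: float
    scores: np.ndarray
    gene_ids: list[str] | None = None


def laplacian(net: GeneNetwork) -> sp.csr_matrix:
    """Weighted graph Laplacian L = D - W aligned to the gene order.

    L_ij = -W_ij for i != j and L_ii = sum_l W_il; rows sum to zero and L
    is positive semi-definite.
    """
    W = net.weights
    if (W != W.T).nnz != 0:
        raise ValueError("weight matrix must be symmetric")
    deg = np.asarray(W.sum(axis=1)).ravel()
    return (sp.diags(deg) - W).tocsr()


def _check_beta(beta: float) -> float:
    beta = float(beta)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return beta


def diffusion_kernel(
    L: sp.spmatrix | np.ndarray, beta: float, node_cap: int = DENSE_NODE_CAP
) -> np.ndarray:
    """Dense diffusion kernel K_beta = exp(-beta L).

    Only for graphs small enough to hold a dense kernel; raises if the
    node count exceeds ``node_cap``.
    """
    beta = _check_beta(beta)
    n = L.shape[0]
    if n > node_cap:
        raise ValueError(
            f"dense kernel requested for {n} nodes (cap {node_cap}); "
            "use diffuse_scores for the matrix-free action"
        )
    Ld = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=float)
    return scipy.linalg.expm(-beta * Ld)


def diffuse_scores(
    L: sp.spmatrix, S, beta: float, gene_ids: list[str] | None = None
) -> DiffusedScores:
    """Diffused score vector S K_beta via the exponential action.

    Accepts a plain vector or a :class:`~remic.mutation_scoring.GeneScoreVector`.
    K_beta is symmetric, so the row vector product S K_beta equals
    exp(-beta L) applied to S as a column; memory stays linear in
    edges + nodes.
    """
    beta = _check_beta(beta)
    if hasattr(S, "scores"):
        gene_ids = gene_ids or list(S.gene_ids)
        S = S.scores
    s = np.asarray(S, dtype=float)
    if s.shape != (L.shape[0],):
        raise ValueError(f"score vector length {s.shape} does not match L {L.shape}")
    if beta == 0.0:
        return DiffusedScores(beta, s.copy(), gene_ids)
    out = expm_multiply((-beta) * L.tocsc(), s)
    return DiffusedScores(beta, out, gene_ids)


def diffuse_vectors(L: sp.spmatrix, V: np.ndarray, beta: float) -> np.ndarray:
    """Diffuse many score vectors at once.

    ``V`` has one score vector per column (g x m); returns the g x m array
    of diffused columns. Used to push permutation-null vectors through one
    exponential-action operator per scale.
    """
    beta = _check_beta(beta)
    V = np.asarray(V, dtype=float)
    if V.shape[0] != L.shape[0]:
        raise ValueError("vector dimension does not match Laplacian")
    if beta == 0.0:
        return V.copy()
    return expm_multiply((-beta) * L.tocsc(), V)


def make_beta_grid(
    beta_min: float = 0.0,
    beta_max: float = 0.03,
    n_scales: int = 16,
    spacing: str = "linear",
) -> np.ndarray:
    """Grid of diffusion scales covering [beta_min, beta_max].

    ``spacing`` is ``"linear"`` or ``"log"``; log spacing with
    beta_min == 0 prepends the zero scale to a geometric grid spanning two
    decades below beta_max. Both endpoints are always included and the
    grid is strictly increasing.
    """
    if not 0 <= beta_min < beta_max:
        raise ValueError("need 0 <= beta_min < beta_max")
    if n_scales < 2:
        raise ValueError("need at least 2 scales")
    if spacing == "linear":
        return np.linspace(beta_min, beta_max, n_scales)
    if spacing == "log":
        lo = beta_min if beta_min > 0 else beta_max / 100.0
        grid = np.geomspace(lo, beta_max, n_scales - 1 if beta_min == 0 else n_scales)
        if beta_min == 0:
            grid = np.concatenate([[0.0], grid])
        return grid
    raise ValueError(f"unknown spacing {spacing!r}")
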