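"""Permutation significance of diffused mutation scores.

The null model breaks the association between mutation scores and network
position while respecting each tumor's mutation load: every tumor's row
of M is permuted independently and the permuted rows are re-summed into a
random score vector, which is then diffused at the scale under test. A
gene's empirical p-value is the pseudocounted exceedance fraction
(b + 1) / (n + 1), where b counts null diffused scores >= the observed
diffused score over the n permutations actually run. To save work, a
gene's permutation loop is discontinued once b exceeds a small cap
(default 10) — such genes cannot reach small p-values anyway.

Two null engines are provided: ``per-tumor`` (default) draws a fresh
within-tumor permutation for every iteration; ``pooled`` precomputes a
pool of random score vectors (default 1e5) once and resamples whole
vectors from it. Multiple testing over genes x scales is handled with
Storey-Tibshirani q-values; genes with q <= alpha (default 0.001) at a
scale are the ReMIC genes of that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import UnivariateSpline

from remic.diffusion import diffuse_vectors, diffuse_scores
from remic.mutation_scoring import MutationMatrix, gene_scores

__all__ = [
    "NullPool",
    "PermutationConfig",
    "build_null_pool",
    "permutation_pvalues",
    "storey_qvalues",
    "significance_table",
    "call_remic",
]


@dataclass
class NullPool:
    """Precomputed randomized gene score vectors (pool_size x g)."""

    vectors: np.ndarray
    seed: int

    @property
    def pool_size(self) -> int:
        return self.vectors.shape[0]


@dataclass
class PermutationConfig:
    n_permutations: int = 10_000_000
    early_stop_exceedances: int = 10
    alpha: float = 0.001
    seed: int = 0
    null_mode: str = "per-tumor"  # or "pooled"
    batch_size: int = 512
    call_on: str = "q"  # call ReMIC on q <= alpha ("q") or raw p <= alpha ("p")

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.early_stop_exceedances < 1:
            raise ValueError("early_stop_exceedances must be >= 1")
        if self.null_mode not in {"per-tumor", "pooled"}:
            raise ValueError(f"unknown null_mode {self.null_mode!r}")
        if self.call_on not in {"q", "p"}:
            raise ValueError("call_on must be 'q' or 'p'")


def _permuted_rowsums(M: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """n random score vectors, each permuting every tumor row independently."""
    t, g = M.shape
    out = np.empty((n, g))
    # chunk the (n, t, g) permutation-key tensor to bound memory
    chunk = max(1, int(4e6) // max(1, t * g))
    row_idx = np.arange(t)[:, None]
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        keys = rng.random((hi - lo, t, g))
        cols = np.argsort(keys, axis=2)
        for k in range(lo, hi):
            out[k] = M[row_idx, cols[k - lo]].sum(axis=0)
    return out


def build_null_pool(M: MutationMatrix, pool_size: int = 100_000,
                    seed: int = 0) -> NullPool:
    """Precompute ``pool_size`` random score vectors by within-tumor permutation."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = np.random.default_rng(seed)
    return NullPool(_permuted_rowsums(M.values, rng, pool_size), seed)


def _null_batches(M: MutationMatrix, cfg: PermutationConfig,
                  pool: NullPool | None) -> Iterator[np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    remaining = cfg.n_permutations
    while remaining > 0:
        n = min(cfg.batch_size, remaining)
        if cfg.null_mode == "pooled":
            if pool is None:
                raise ValueError("pooled null mode requires a NullPool")
            idx = rng.integers(pool.pool_size, size=n)
            yield pool.vectors[idx]
        else:
            yield _permuted_rowsums(M.values, rng, n)
        remaining -= n


def permutation_pvalues(
    L: sp.spmatrix,
    M: MutationMatrix,
    beta: float,
    cfg: PermutationConfig,
    pool: NullPool | None = None,
    observed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene permutation p-values of diffused scores at one scale.

    Returns a DataFrame aligned to the gene order with columns
    ``score`` (raw S), ``diffused_score``, ``n_perm``, ``n_exceed`` and
    ``p``. Exceedance is >= (ties count against significance); a gene's
    loop stops once its exceedance count passes
    ``cfg.early_stop_exceedances``, and its p is reported from the counts
    at stop. Identical seeds give identical results.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    S = gene_scores(M)
    g = len(S.gene_ids)
    if L.shape[0] != g:
        raise ValueError("Laplacian does not match mutation matrix gene order")
    d_obs = (observed if observed is not None
             else diffuse_scores(L, S.scores, beta).scores)
    b = np.zeros(g, dtype=np.int64)
    n = np.zeros(g, dtype=np.int64)
    active = np.ones(g, dtype=bool)
    for batch in _null_batches(M, cfg, pool):
        diffused = diffuse_vectors(L, batch.T, beta)  # g x m
        exceed = (diffused >= d_obs[:, None]).sum(axis=1)
        b[active] += exceed[active]
        n[active] += batch.shape[0]
        active &= b <= cfg.early_stop_exceedances
        if not active.any():
            break
    p = (b + 1) / (n + 1)
    return pd.DataFrame(
        {
            "gene_id": S.gene_ids,
            "beta": beta,
            "score": S.scores,
            "diffused_score": d_obs,
            "n_perm": n,
            "n_exceed": b,
            "p": p,
        }
    )


def storey_qvalues(p_values: Sequence[float] | np.ndarray,
                   lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values for a vector of p-values.

    pi0, the fraction of true nulls, is estimated from the p-value
    distribution: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is
    evaluated on a lambda grid and extrapolated to lambda -> 1 with a
    cubic smoothing spline. For short vectors (< 100) the single-lambda
    estimate at lambda = 0.5 is used instead. q-values are then
    pi0 * m * p_(i) / i with step-up monotonicity enforced.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.0, 0.95, 0.05)
    if m < 100:
        pi0 = np.mean(p > 0.5) / 0.5
    else:
        pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        spline = UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spline(lambdas.max()))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def significance_table(
    L: sp.spmatrix,
    M: MutationMatrix,
    betas: Sequence[float],
    cfg: PermutationConfig,
    pool: NullPool | None = None,
) -> pd.DataFrame:
    """Full genes x scales significance table with pooled q-values.

    Runs the permutation test at every scale, pools the p-values over all
    (gene, beta) pairs for the Storey-Tibshirani FDR (so the correction
    accounts for the number of genes as well as the number of scales), and
    flags ReMIC calls at ``cfg.alpha``.
    """
    if cfg.null_mode == "pooled" and pool is None:
        pool = build_null_pool(M, seed=cfg.seed)
    parts = [permutation_pvalues(L, M, beta, cfg, pool=pool) for beta in betas]
    table = pd.concat(parts, ignore_index=True)
    table["q"] = storey_qvalues(table["p"].to_numpy())
    stat = table["q"] if cfg.call_on == "q" else table["p"]
    table["is_remic"] = stat <= cfg.alpha
    return table


def call_remic(table: pd.DataFrame, alpha: float | None = None,
               call_on: str | None = None) -> dict[float, set[str]]:
    """ReMIC gene set per scale, plus the union under the key ``"union"``.

    With ``alpha``/``call_on`` unset the precomputed ``is_remic`` flags are
    used; otherwise the call is re-thresholded on q (or raw p).
    """
    if table.empty:
        return {"union": set()}
    if alpha is None:
        flags = table["is_remic"]
    else:
        stat = table["p"] if call_on == "p" else table["q"]
        flags = stat <= alpha
    out: dict[float, set[str]] = {}
    for beta, sub in table[flags].groupby("beta"):
        out[float(beta)] = set(sub["gene_id"])
    for beta in table["beta"].unique():
        out.setdefault(float(beta), set())
    out["union"] = set().union(*out.values()) if out else set()
    return out
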