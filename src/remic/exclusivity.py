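"""Mutual exclusivity of cluster mutations across tumors.

Mutations in functionally linked genes tend not to co-occur in the same
tumor when the genes act in one pathway. To test a gene cluster for such
exclusivity, the mutation matrix M is binarized into a bipartite
gene-tumor graph (edge iff M_gt > 0) and randomized with the
degree-preserving switching permutation: two random edges (g1, t1) and
(g2, t2) exchange endpoints to (g1, t2), (g2, t1) unless a duplicate edge
would result, repeated for k x q attempted swaps (k = edge count,
q = 100). Every gene and tumor keeps its exact degree, so a cluster's
total mutation count is invariant under the null; the discriminating
statistic is the MEMo-style tumor coverage — the number of distinct
tumors carrying a mutation in at least one cluster gene, which is maximal
when mutations are perfectly exclusive. The right-tail empirical p-value
over randomizations (default 1e4) is pseudocounted as (x + 1) / (n + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from remic.mutation_scoring import MutationMatrix

__all__ = [
    "BipartiteMutationGraph",
    "ExclusivityResult",
    "binarize",
    "switching_permutation",
    "coverage_statistic",
    "exclusivity_pvalue",
]


@dataclass
class BipartiteMutationGraph:
    """Bipartite gene-tumor mutation graph in edge-array + adjacency form."""

    gene_ids: list[str]
    tumor_ids: list[str]
    edge_genes: np.ndarray  # edge -> gene index
    edge_tumors: np.ndarray  # edge -> tumor index
    adjacency: np.ndarray  # genes x tumors boolean

    @property
    def n_edges(self) -> int:
        return int(self.edge_genes.size)

    def gene_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def tumor_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)


def binarize(M: MutationMatrix) -> BipartiteMutationGraph:
    """Bipartite graph with an edge wherever a mutation score is positive."""
    adj = (M.values > 0).T.copy()  # genes x tumors
    g_idx, t_idx = np.nonzero(adj)
    return BipartiteMutationGraph(
        list(M.gene_ids), list(M.tumor_ids),
        g_idx.astype(np.int64), t_idx.astype(np.int64), adj,
    )


@njit(cache=False)
def _switch(edge_genes, edge_tumors, adj, n_iter, seed):  # pragma: no cover
    np.random.seed(seed)
    k = edge_genes.size
    for _ in range(n_iter):
        i = np.random.randint(k)
        j = np.random.randint(k)
        if i == j:
            continue
        g1, t1 = edge_genes[i], edge_tumors[i]
        g2, t2 = edge_genes[j], edge_tumors[j]
        if g1 == g2 or t1 == t2:
            continue
        if adj[g1, t2] or adj[g2, t1]:
            continue  # duplicate edge would result; rejection still consumes an iteration
        adj[g1, t1] = False
        adj[g2, t2] = False
        adj[g1, t2] = True
        adj[g2, t1] = True
        edge_tumors[i] = t2
        edge_tumors[j] = t1


def switching_permutation(
    graph: BipartiteMutationGraph, q_multiplier: int = 100, seed: int = 0
) -> BipartiteMutationGraph:
    """Degree-preserving randomization by k x q attempted edge swaps.

    Swap attempts that would create a duplicate gene-tumor edge are
    rejected but still count toward the k x q budget. Per-gene and
    per-tumor degrees are preserved exactly.
    """
    if q_multiplier < 1:
        raise ValueError("q_multiplier must be >= 1")
    genes = graph.edge_genes.copy()
    tumors = graph.edge_tumors.copy()
    adj = graph.adjacency.copy()
    if graph.n_edges > 1:
        _switch(genes, tumors, adj, graph.n_edges * q_multiplier,
                int(seed) % (2**31))
    return BipartiteMutationGraph(graph.gene_ids, graph.tumor_ids,
                                  genes, tumors, adj)


def coverage_statistic(graph: BipartiteMutationGraph,
                       cluster: Iterable[str]) -> int:
    """Distinct tumors with a mutation in at least one cluster gene."""
    cluster = set(cluster)
    if not cluster:
        raise ValueError("cluster must be nonempty")
    index = {g: i for i, g in enumerate(graph.gene_ids)}
    missing = cluster - index.keys()
    if missing:
        raise KeyError(f"cluster genes not in mutation matrix: {sorted(missing)[:5]}")
    rows = [index[g] for g in cluster]
    return int(graph.adjacency[rows].any(axis=0).sum())


@dataclass
class ExclusivityResult:
    cluster_genes: list[str]
    observed_coverage: int
    n_randomizations: int
    p_value: float
    is_exclusive: bool
    alpha: float = 0.05


def exclusivity_pvalue(
    M: MutationMatrix,
    cluster: Iterable[str],
    n_rand: int = 10_000,
    q_multiplier: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> ExclusivityResult:
    """Right-tail switching-permutation p-value of cluster tumor coverage.

    p = (#{randomizations with coverage >= observed} + 1) / (n_rand + 1);
    small p means the cluster's mutations are spread over more tumors than
    degree-matched chance allows, i.e. mutually exclusive. Degree
    preservation is audited on every randomization.
    """
    cluster = sorted(set(cluster))
    graph = binarize(M)
    observed = coverage_statistic(graph, cluster)
    gdeg = graph.gene_degrees()
    tdeg = graph.tumor_degrees()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_rand)
    exceed = 0
    for r in range(n_rand):
        rand = switching_permutation(graph, q_multiplier, seed=int(seeds[r]))
        if not (
            np.array_equal(rand.gene_degrees(), gdeg)
            and np.array_equal(rand.tumor_degrees(), tdeg)
        ):  # pragma: no cover - defensive audit
            raise AssertionError("switching permutation changed a degree")
        if coverage_statistic(rand, cluster) >= observed:
            exceed += 1
    p = (exceed + 1) / (n_rand + 1)
    return ExclusivityResult(cluster, observed, n_rand, p, p <= alpha, alpha)
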