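"""Girvan-Newman clustering of significant subnetworks.

The subnetwork induced by the ReMIC genes of one diffusion scale is cut
into densely connected clusters by iteratively removing the edge with the
highest betweenness (number of all-pairs shortest paths through the edge,
with fractional splitting among equal-length paths) and recomputing
betweenness after each removal. Every removal that splits a component
records a partition; the dendrogram is cut at the partition maximizing
the modularity

    Q = Tr(E) - ||E^2||,

where E is the symmetric cluster-level edge-fraction matrix: E_ii is the
fraction of edges inside cluster i, and an edge between clusters i and j
contributes half its mass to E_ij and half to E_ji, so total mass is 1.
Q = 0 for the trivial single-cluster partition, and Q near 1 indicates a
strong community division. Betweenness treats the graph as unweighted
(hop-count shortest paths); interaction weights remain metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from remic.network_io import GeneNetwork

__all__ = [
    "Dendrogram",
    "ClusterPartition",
    "induced_subnetwork",
    "edge_betweenness",
    "girvan_newman",
    "modularity",
    "best_partition",
]

Partition = list[frozenset]


@dataclass
class Dendrogram:
    """Sequence of partitions recorded while removing max-betweenness edges.

    ``levels[0]`` is the starting component partition of the whole
    subnetwork; each later level records the components right after a
    removal split one of them; the last level is all singletons.
    ``removals`` lists edges in removal order.
    """

    levels: list[Partition] = field(default_factory=list)
    removals: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ClusterPartition:
    """Gene -> cluster label assignment with its modularity Q."""

    labels: dict[str, int]
    modularity_q: float

    def clusters(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for g, c in self.labels.items():
            out.setdefault(c, set()).add(g)
        return [out[c] for c in sorted(out)]


def induced_subnetwork(net: GeneNetwork, genes: Iterable[str]) -> GeneNetwork:
    """Subgraph on ``genes`` with the original interaction weights."""
    return net.subnetwork(genes)


def edge_betweenness(net: GeneNetwork) -> dict[tuple[str, str], float]:
    """Unnormalized edge betweenness (unweighted shortest paths).

    Keys are canonical (sorted) node pairs; the value counts the shortest
    paths over all unordered node pairs that traverse the edge, split
    fractionally among equal-length alternatives.
    """
    G = net.to_networkx()
    raw = nx.edge_betweenness_centrality(G, normalized=False, weight=None)
    return {tuple(sorted(e)): v for e, v in raw.items()}


def _components(G: nx.Graph) -> Partition:
    return sorted(
        (frozenset(c) for c in nx.connected_components(G)),
        key=lambda c: sorted(c)[0],
    )


def girvan_newman(net: GeneNetwork) -> Dendrogram:
    """Full edge-removal dendrogram with betweenness recomputation.

    Repeatedly removes the edge of maximum betweenness (ties broken by the
    lexicographically smallest node pair, for determinism) and records the
    component partition whenever a removal disconnects a component.
    """
    G = net.to_networkx()
    dendro = Dendrogram()
    if net.n_genes == 0:
        return dendro
    dendro.levels.append(_components(G))
    n_comp = len(dendro.levels[0])
    while G.number_of_edges() > 0:
        bt = nx.edge_betweenness_centrality(G, normalized=False, weight=None)
        edge = min(
            bt, key=lambda e: (-bt[e], tuple(sorted(e)))
        )
        G.remove_edge(*edge)
        dendro.removals.append(tuple(sorted(edge)))
        comps = _components(G)
        if len(comps) > n_comp:
            n_comp = len(comps)
            dendro.levels.append(comps)
    return dendro


def modularity(partition: Sequence[Iterable[str]], net: GeneNetwork) -> float:
    """Q = Tr(E) - ||E^2|| for a partition of the network's genes.

    ``||E^2||`` is the sum of all entries of E squared (as a matrix). The
    partition must cover every gene exactly once. A network without edges
    has Q = 0 by convention.
    """
    clusters = [set(c) for c in partition]
    covered: set[str] = set()
    for c in clusters:
        if covered & c:
            raise ValueError("partition clusters overlap")
        covered |= c
    if covered != set(net.genes):
        raise ValueError("partition does not cover all network genes")
    m = net.n_edges
    if m == 0:
        return 0.0
    k = len(clusters)
    label = {g: i for i, c in enumerate(clusters) for g in c}
    E = np.zeros((k, k))
    for e in net.edges():
        i, j = label[e.node_a], label[e.node_b]
        if i == j:
            E[i, i] += 1.0 / m
        else:
            E[i, j] += 0.5 / m
            E[j, i] += 0.5 / m
    return float(np.trace(E) - (E @ E).sum())


def best_partition(dendrogram: Dendrogram, net: GeneNetwork) -> ClusterPartition:
    """Max-modularity cut of the dendrogram; ties go to fewer clusters.

    An empty network yields an empty partition with Q = 0. Isolated genes
    persist as singleton clusters at every level and are reported.
    """
    if not dendrogram.levels:
        return ClusterPartition({}, 0.0)
    best: Partition | None = None
    best_q = -np.inf
    for level in dendrogram.levels:
        q = modularity(level, net)
        if q > best_q + 1e-12 or (
            abs(q - best_q) <= 1e-12 and best is not None and len(level) < len(best)
        ):
            best, best_q = level, q
    assert best is not None
    ordered = sorted(best, key=lambda c: sorted(c)[0])
    labels = {g: i for i, c in enumerate(ordered) for g in c}
    return ClusterPartition(labels, float(best_q))
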