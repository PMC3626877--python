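"""Weighted gene interaction networks from STRING-dialect edge lists.

STRING distributes protein-protein links as a whitespace-separated table
(protein1, protein2, combined_score) with scores on a 0-1000 scale. This
module reads such files, applies a reliability threshold T_I, collapses
proteins to genes via a user-supplied mapping (weights of multiple
protein-level links between two genes are averaged), and exposes the
result as a :class:`GeneNetwork` -- an undirected weighted graph with a
fixed gene order shared by every score vector downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _csgraph_components

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedEdge",
    "GeneNetwork",
    "read_string_edges",
    "read_protein_gene_map",
    "collapse_to_genes",
    "connected_components",
    "write_network_tsv",
    "write_node_list",
]


@dataclass(frozen=True)
class WeightedEdge:
    """An undirected weighted link between two nodes (proteins or genes)."""

    node_a: str
    node_b: str
    weight: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"self-loop edge {self.node_a!r}")
        if self.weight < 0:
            raise ValueError(f"negative edge weight {self.weight!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Canonical (sorted) node pair identifying the undirected edge."""
        a, b = self.node_a, self.node_b
        return (a, b) if a <= b else (b, a)


class GeneNetwork:
    """Undirected weighted graph over genes with a fixed node order.

    Parameters
    ----------
    genes
        Gene identifiers; stored in sorted order, which defines the
        alignment of every weight matrix, Laplacian and score vector.
    weights
        Symmetric nonnegative matrix aligned to the (sorted) gene order,
        zero diagonal. Dense array or scipy sparse matrix.
    threshold_used
        The reliability threshold T_I applied at the protein level, kept
        for provenance.
    """

    def __init__(
        self,
        genes: Sequence[str],
        weights: np.ndarray | sp.spmatrix,
        threshold_used: float = 0.0,
    ) -> None:
        order = np.argsort(np.asarray(genes, dtype=object))
        self.genes: list[str] = [genes[i] for i in order]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        W = sp.csr_matrix(weights, dtype=float)
        if W.shape != (len(self.genes), len(self.genes)):
            raise ValueError("weight matrix shape does not match gene count")
        W = W[np.ix_(order, order)] if not _is_identity_order(order) else W
        if (W != W.T).nnz != 0:
            raise ValueError("weight matrix must be symmetric")
        if W.diagonal().any():
            raise ValueError("weight matrix must have zero diagonal")
        if W.count_nonzero() and W.data.min() < 0:
            raise ValueError("negative weights")
        W.eliminate_zeros()
        self.weights: sp.csr_matrix = W
        self.threshold_used = float(threshold_used)
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[WeightedEdge],
        genes: Sequence[str] | None = None,
        threshold_used: float = 0.0,
    ) -> "GeneNetwork":
        """Build a network from gene-level edges (plus optional isolated genes)."""
        edges = list(edges)
        node_set = set(genes or [])
        for e in edges:
            node_set.update((e.node_a, e.node_b))
        nodes = sorted(node_set)
        idx = {g: i for i, g in enumerate(nodes)}
        n = len(nodes)
        rows, cols, vals = [], [], []
        for e in edges:
            i, j = idx[e.node_a], idx[e.node_b]
            rows += [i, j]
            cols += [j, i]
            vals += [e.weight, e.weight]
        W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        return cls(nodes, W, threshold_used)

    # -- views ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return self.weights.count_nonzero() // 2

    def edges(self) -> Iterator[WeightedEdge]:
        """Iterate undirected edges once each (node_a < node_b)."""
        coo = sp.triu(self.weights, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield WeightedEdge(self.genes[i], self.genes[j], float(w))

    def degree_weights(self) -> np.ndarray:
        """Weighted degree (row sums of W) per gene."""
        return np.asarray(self.weights.sum(axis=1)).ravel()

    def subnetwork(self, genes: Iterable[str]) -> "GeneNetwork":
        """Induced subgraph on ``genes`` with original weights."""
        genes = sorted(set(genes))
        missing = [g for g in genes if g not in self.index]
        if missing:
            raise KeyError(f"genes not in network: {missing[:5]}")
        sel = np.array([self.index[g] for g in genes], dtype=int)
        W = self.weights[np.ix_(sel, sel)]
        return GeneNetwork(genes, W, self.threshold_used)

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.genes)
        G.add_weighted_edges_from(
            (e.node_a, e.node_b, e.weight) for e in self.edges()
        )
        return G

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneNetwork(n_genes={self.n_genes}, n_edges={self.n_edges}, "
            f"threshold_used={self.threshold_used})"
        )


def _is_identity_order(order: np.ndarray) -> bool:
    return bool(np.array_equal(order, np.arange(order.size)))


# ---------------------------------------------------------------------
# readers


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_string_edges(path: str | Path, score_threshold: float = 0.0) -> list[WeightedEdge]:
    """Read a STRING-dialect edge list, thresholding on the combined score.

    The file is whitespace- or tab-separated with at least three columns
    (node_a, node_b, score); a header row is auto-detected by a non-numeric
    third field. Edges with score below ``score_threshold`` are removed
    (weight equal to the threshold is kept), self-loops are dropped, and
    undirected duplicates (a,b)/(b,a) are merged keeping the first record.
    """
    if score_threshold < 0:
        raise ValueError("score_threshold must be >= 0")
    path = Path(path)
    kept: dict[tuple[str, str], WeightedEdge] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}"
                )
            if lineno == 1 and not _looks_numeric(fields[2]):
                continue  # header
            try:
                weight = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                ) from None
            a, b = fields[0], fields[1]
            if a == b:
                continue
            if weight < score_threshold:
                continue
            edge = WeightedEdge(a, b, weight)
            kept.setdefault(edge.key, edge)
    return list(kept.values())


def read_protein_gene_map(path: str | Path) -> dict[str, str]:
    """Read a protein_id -> gene_id mapping TSV (header optional).

    Many proteins may map to one gene; a protein mapping to two different
    genes is an error.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"protein_id", "protein"}:
                continue
            protein, gene = fields[0], fields[1]
            if protein in mapping and mapping[protein] != gene:
                raise ValueError(
                    f"{path}:{lineno}: protein {protein!r} maps to multiple genes"
                )
            mapping[protein] = gene
    return mapping


# ---------------------------------------------------------------------
# collapse and components


def collapse_to_genes(
    edges: Iterable[WeightedEdge],
    mapping: Mapping[str, str],
    threshold_used: float = 0.0,
) -> GeneNetwork:
    """Collapse protein-level edges into a gene-level network.

    The gene-to-gene weight is the arithmetic mean of all protein-level
    edge weights between the two genes' protein sets. Edges between
    proteins of the same gene are dropped (would be self-loops); proteins
    absent from the mapping are skipped with a logged warning.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    gene_nodes: set[str] = set()
    unmapped: set[str] = set()
    for e in edges:
        ga = mapping.get(e.node_a)
        gb = mapping.get(e.node_b)
        if ga is None:
            unmapped.add(e.node_a)
        if gb is None:
            unmapped.add(e.node_b)
        if ga is None or gb is None:
            continue
        gene_nodes.update((ga, gb))
        if ga == gb:
            continue
        key = (ga, gb) if ga <= gb else (gb, ga)
        sums[key] = sums.get(key, 0.0) + e.weight
        counts[key] = counts.get(key, 0) + 1
    if unmapped:
        logger.warning(
            "%d proteins without gene mapping skipped (e.g. %s)",
            len(unmapped),
            sorted(unmapped)[:3],
        )
    gene_edges = [
        WeightedEdge(a, b, sums[(a, b)] / counts[(a, b)]) for a, b in sums
    ]
    return GeneNetwork.from_edges(gene_edges, genes=sorted(gene_nodes),
                                  threshold_used=threshold_used)


def connected_components(net: GeneNetwork) -> np.ndarray:
    """Component label per gene, aligned to the network's gene order."""
    if net.n_genes == 0:
        return np.empty(0, dtype=int)
    _, labels = _csgraph_components(net.weights, directed=False)
    return labels


# ---------------------------------------------------------------------
# writers


def write_network_tsv(net: GeneNetwork, path: str | Path) -> None:
    """Write the gene-level edge list as TSV (gene_a, gene_b, weight)."""
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for e in net.edges():
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.weight:g}\n")


def write_node_list(net: GeneNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in net.genes:
            fh.write(g + "\n")
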