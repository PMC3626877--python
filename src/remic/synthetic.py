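"""Synthetic networks and insertional-mutation data with planted structure.

Generates the exact input dialects the pipeline consumes — STRING-style
edge lists, protein-gene maps, insertion tables, BED gene models and GMT
gene sets — from a planted-partition model: module genes are densely
interconnected with high-confidence weights, background edges are sparse,
and tumors mutate module genes according to an exclusivity mode
(``exclusive``: each affected tumor hits exactly one module gene,
round-robin; ``co-occurring``: affected tumors hit every module gene;
``random``: independent Bernoulli per gene). Mutations are emitted both
as matrix entries and as genomic insertions placed in (or, with placement
noise, near) synthetic gene models laid on one chromosome at 200 kb
spacing, so the 50 kb association cutoff isolates genes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from remic.mutation_scoring import (
    CUTOFF_DEFAULT,
    SIGMA_DEFAULT,
    GeneModel,
    GenomicInsertion,
    MutationMatrix,
    build_mutation_matrix,
)
from remic.network_io import GeneNetwork, WeightedEdge

__all__ = [
    "ModuleSpec",
    "SyntheticSpec",
    "module_genes",
    "simulate_network",
    "plant_mutations",
    "write_fixture",
]

GENE_SPACING = 200_000  # bp between synthetic gene starts
GENE_LENGTH = 20_000  # bp gene body
CHROM = "chrS"


@dataclass
class ModuleSpec:
    """One planted module: size, internal density, mutation behaviour."""

    n_genes: int
    p_in: float = 0.8
    mutation_rate: float = 0.8  # per-tumor probability the module is hit
    mode: str = "exclusive"  # exclusive | co-occurring | random

    def __post_init__(self) -> None:
        if not 0 <= self.p_in <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mode not in {"exclusive", "co-occurring", "random"}:
            raise ValueError(f"unknown exclusivity mode {self.mode!r}")


@dataclass
class SyntheticSpec:
    """Generator settings for one synthetic study."""

    n_genes: int = 100
    n_tumors: int = 200
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [ModuleSpec(n_genes=20)]
    )
    p_background: float = 0.03
    background_mutation_rate: float = 0.02
    placement_noise_bp: float = 0.0
    edge_weight_low: float = 600.0
    edge_weight_high: float = 1000.0
    threshold: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.n_genes for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not 0 <= self.p_background <= 1:
            raise ValueError("p_background must lie in [0, 1]")
        if not 0 <= self.background_mutation_rate <= 1:
            raise ValueError("background_mutation_rate must lie in [0, 1]")


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def module_genes(spec: SyntheticSpec) -> list[list[str]]:
    """Gene identifiers of each planted module (leading blocks of the gene list)."""
    names = _gene_names(spec.n_genes)
    out, offset = [], 0
    for m in spec.modules:
        out.append(names[offset : offset + m.n_genes])
        offset += m.n_genes
    return out


def simulate_network(spec: SyntheticSpec) -> GeneNetwork:
    """Planted-partition interaction network on the 0-1000 weight scale.

    Within-module gene pairs are connected with probability ``p_in``, all
    other pairs with ``p_background``; weights are uniform in
    [edge_weight_low, edge_weight_high], above the reliability threshold.
    """
    rng = np.random.default_rng(spec.seed)
    names = _gene_names(spec.n_genes)
    block = np.full(spec.n_genes, -1)
    offset = 0
    for mi, m in enumerate(spec.modules):
        block[offset : offset + m.n_genes] = mi
        offset += m.n_genes
    edges = []
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            same = block[i] >= 0 and block[i] == block[j]
            p = spec.modules[block[i]].p_in if same else spec.p_background
            if rng.random() < p:
                w = rng.uniform(spec.edge_weight_low, spec.edge_weight_high)
                edges.append(WeightedEdge(names[i], names[j], float(w)))
    return GeneNetwork.from_edges(edges, genes=names,
                                  threshold_used=spec.threshold)


def gene_models(spec: SyntheticSpec) -> list[GeneModel]:
    """Synthetic gene models on one chromosome, 200 kb apart."""
    return [
        GeneModel(name, CHROM, 100_000 + i * GENE_SPACING,
                  100_000 + i * GENE_SPACING + GENE_LENGTH)
        for i, name in enumerate(_gene_names(spec.n_genes))
    ]


def plant_mutations(
    spec: SyntheticSpec, network: GeneNetwork
) -> tuple[MutationMatrix, list[GenomicInsertion], list[GeneModel]]:
    """Mutation matrix plus the insertions and gene models that encode it.

    Each mutation event becomes one genomic insertion at a uniform
    position inside the target gene, jittered by Gaussian placement noise
    (which can push it into the flat-top Gaussian tails or past the
    cutoff). M is computed from the emitted insertions with the default
    scoring parameters, so matrix entries and insertion records always
    agree.
    """
    rng = np.random.default_rng(spec.seed + 1)
    names = _gene_names(spec.n_genes)
    models = gene_models(spec)
    model_by_gene = {m.gene_id: m for m in models}
    tumors = [f"T{t:04d}" for t in range(spec.n_tumors)]
    events: list[tuple[str, str]] = []  # (tumor, gene)
    mod_lists = module_genes(spec)
    in_module = {g for genes in mod_lists for g in genes}
    for mi, m in enumerate(spec.modules):
        genes = mod_lists[mi]
        rr = 0  # round-robin pointer for exclusive mode
        for t in tumors:
            if m.mode == "random":
                for g in genes:
                    if rng.random() < m.mutation_rate:
                        events.append((t, g))
            elif rng.random() < m.mutation_rate:
                if m.mode == "exclusive":
                    events.append((t, genes[rr % len(genes)]))
                    rr += 1
                else:  # co-occurring
                    events.extend((t, g) for g in genes)
    for t in tumors:
        for g in names:
            if g not in in_module and rng.random() < spec.background_mutation_rate:
                events.append((t, g))
    insertions = []
    for t, g in events:
        model = model_by_gene[g]
        pos = rng.integers(model.start, model.end)
        if spec.placement_noise_bp > 0:
            pos = int(round(pos + rng.normal(0.0, spec.placement_noise_bp)))
        insertions.append(GenomicInsertion(t, CHROM, max(0, pos)))
    M = build_mutation_matrix(insertions, models, network.genes,
                              SIGMA_DEFAULT, CUTOFF_DEFAULT)
    # carry every tumor, including unmutated ones, so permutations see the
    # full cohort
    full = np.zeros((spec.n_tumors, len(network.genes)))
    row = {t: i for i, t in enumerate(M.tumor_ids)}
    for i, t in enumerate(tumors):
        if t in row:
            full[i] = M.values[row[t]]
    return MutationMatrix(tumors, list(network.genes), full), insertions, models


# ---------------------------------------------------------------------
# fixture files


def write_fixture(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete input fixture in the dialects the pipeline reads.

    Produces a STRING-dialect edge TSV (protein ids are ``p.<gene>``), a
    protein-gene map, an insertion TSV, a BED file of gene models, and a
    GMT with one set per planted module plus a decoy set. Returns the
    paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = simulate_network(spec)
    M, insertions, models = plant_mutations(spec, net)
    paths = {
        "network": outdir / "network.tsv",
        "mapping": outdir / "protein_gene_map.tsv",
        "insertions": outdir / "insertions.tsv",
        "genes": outdir / "genes.bed",
        "gmt": outdir / "modules.gmt",
        "matrix": outdir / "mutation_matrix.tsv",
    }
    with paths["network"].open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for e in net.edges():
            fh.write(f"p.{e.node_a}\tp.{e.node_b}\t{e.weight:.0f}\n")
    with paths["mapping"].open("w") as fh:
        fh.write("protein_id\tgene_id\n")
        for g in net.genes:
            fh.write(f"p.{g}\t{g}\n")
    with paths["insertions"].open("w") as fh:
        fh.write("chrom\tposition\ttumor_id\n")
        for ins in insertions:
            fh.write(f"{ins.chrom}\t{ins.position}\t{ins.tumor_id}\n")
    with paths["genes"].open("w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t+\n")
    rng = np.random.default_rng(spec.seed + 2)
    with paths["gmt"].open("w") as fh:
        for mi, genes in enumerate(module_genes(spec)):
            fh.write("\t".join([f"module_{mi}", "planted module", *genes]) + "\n")
        decoy = rng.choice(net.genes, size=min(10, len(net.genes)), replace=False)
        fh.write("\t".join(["decoy", "random gene set", *sorted(decoy)]) + "\n")
    M.write_tsv(paths["matrix"])
    return paths
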