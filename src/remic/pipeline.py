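"""End-to-end analysis: score -> diffuse -> test -> cluster -> characterize.

``run_pipeline`` ties the stages together on files: read the interaction
network and insertion data, build the mutation matrix, diffuse the gene
score vector over a grid of scales, assess per-gene/per-scale
significance by permutation, call ReMIC genes, cluster each scale's
significant subnetwork with Girvan-Newman, and characterize clusters by
gene-set enrichment and mutual exclusivity. Every stage writes a plain
TSV so intermediate results are independently inspectable; a JSON
manifest records the configuration, seed and package version.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from remic import __version__
from remic.clustering import best_partition, girvan_newman, induced_subnetwork
from remic.diffusion import diffuse_scores, laplacian, make_beta_grid
from remic.enrichment import fisher_enrichment, read_gmt
from remic.exclusivity import exclusivity_pvalue
from remic.mutation_scoring import (
    CUTOFF_DEFAULT,
    SIGMA_DEFAULT,
    build_mutation_matrix,
    gene_scores,
    read_gene_models,
    read_insertions,
)
from remic.network_io import (
    collapse_to_genes,
    read_protein_gene_map,
    read_string_edges,
    write_network_tsv,
)
from remic.significance import PermutationConfig, call_remic, significance_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    network_path: str
    mapping_path: str
    insertions_path: str
    genes_path: str
    output_dir: str
    gmt_path: str | None = None
    sigma: float = SIGMA_DEFAULT
    cutoff: float = CUTOFF_DEFAULT
    score_threshold: float = 500.0  # T_I
    beta_min: float = 0.0
    beta_max: float = 0.03
    n_scales: int = 16
    beta_spacing: str = "linear"
    n_permutations: int = 10_000
    early_stop_exceedances: int = 10
    alpha: float = 0.001
    null_mode: str = "per-tumor"
    call_on: str = "q"
    min_cluster_size: int = 3
    exclusivity_n_rand: int = 10_000
    exclusivity_q_multiplier: int = 100
    exclusivity_alpha: float = 0.05
    seed: int = 0


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns a summary dict (also written as
    ``manifest.json``). Any stage failure aborts with the stage named in
    the exception; outputs of completed stages are retained."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "network"
    try:
        t0 = _stage(stage)
        edges = read_string_edges(cfg.network_path, cfg.score_threshold)
        mapping = read_protein_gene_map(cfg.mapping_path)
        net = collapse_to_genes(edges, mapping, threshold_used=cfg.score_threshold)
        write_network_tsv(net, out / "network.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "score"
        t0 = _stage(stage)
        insertions = read_insertions(cfg.insertions_path)
        models = read_gene_models(cfg.genes_path)
        M = build_mutation_matrix(insertions, models, net.genes,
                                  cfg.sigma, cfg.cutoff)
        S = gene_scores(M)
        M.write_tsv(out / "mutation_matrix.tsv")
        S.write_tsv(out / "gene_scores.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "diffuse"
        t0 = _stage(stage)
        L = laplacian(net)
        betas = make_beta_grid(cfg.beta_min, cfg.beta_max, cfg.n_scales,
                               cfg.beta_spacing)
        diffused_rows = []
        for beta in betas:
            d = diffuse_scores(L, S, beta)
            diffused_rows.append(pd.DataFrame({
                "gene_id": net.genes, "beta": beta,
                "raw_score": S.scores, "diffused_score": d.scores,
            }))
        pd.concat(diffused_rows, ignore_index=True).to_csv(
            out / "diffused_scores.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "significance"
        t0 = _stage(stage)
        perm_cfg = PermutationConfig(
            n_permutations=cfg.n_permutations,
            early_stop_exceedances=cfg.early_stop_exceedances,
            alpha=cfg.alpha, seed=cfg.seed, null_mode=cfg.null_mode,
            call_on=cfg.call_on,
        )
        table = significance_table(L, M, betas, perm_cfg)
        table.to_csv(out / "significance.tsv", sep="\t", index=False)
        remic_sets = call_remic(table)
        timings[stage] = time.perf_counter() - t0

        stage = "cluster"
        t0 = _stage(stage)
        cluster_rows, cluster_map = [], {}
        for beta in betas:
            genes = sorted(remic_sets.get(float(beta), set()))
            if not genes:
                continue
            sub = induced_subnetwork(net, genes)
            part = best_partition(girvan_newman(sub), sub)
            for g, c in sorted(part.labels.items()):
                cluster_rows.append((g, float(beta), c))
            for c, members in enumerate(part.clusters()):
                cluster_map[(float(beta), c)] = members
            cluster_rows_q = part.modularity_q
            logger.info("beta %.4g: %d ReMIC genes, Q=%.3f",
                        beta, len(genes), cluster_rows_q)
        pd.DataFrame(cluster_rows, columns=["gene_id", "beta", "cluster_id"]
                     ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "enrich"
        t0 = _stage(stage)
        enrich_rows = []
        if cfg.gmt_path:
            gene_sets = read_gmt(cfg.gmt_path)
            background = set(net.genes)
            for (beta, c), members in cluster_map.items():
                if len(members) < cfg.min_cluster_size:
                    continue
                res = fisher_enrichment(members, background, gene_sets)
                res.insert(0, "cluster_id", c)
                res.insert(0, "beta", beta)
                enrich_rows.append(res)
        (pd.concat(enrich_rows, ignore_index=True) if enrich_rows
         else pd.DataFrame(columns=["beta", "cluster_id", "set_name", "k", "n",
                                    "K", "N", "p", "q", "rank"])
         ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "exclusivity"
        t0 = _stage(stage)
        excl_rows = []
        rng = np.random.default_rng(cfg.seed)
        for (beta, c), members in sorted(cluster_map.items()):
            if len(members) < cfg.min_cluster_size:
                continue
            res = exclusivity_pvalue(
                M, members, n_rand=cfg.exclusivity_n_rand,
                q_multiplier=cfg.exclusivity_q_multiplier,
                seed=int(rng.integers(2**31)), alpha=cfg.exclusivity_alpha,
            )
            excl_rows.append((beta, c, len(res.cluster_genes),
                              res.observed_coverage, res.p_value,
                              res.is_exclusive))
        pd.DataFrame(excl_rows, columns=["beta", "cluster_id", "n_genes",
                                         "coverage", "p", "exclusive_flag"]
                     ).to_csv(out / "exclusivity.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "betas": [float(b) for b in betas],
        "n_genes": int(net.n_genes),
        "n_edges": int(net.n_edges),
        "n_tumors": int(M.n_tumors),
        "n_remic_union": len(remic_sets.get("union", set())),
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "finished_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
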