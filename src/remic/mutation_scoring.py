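"""Flat-top Gaussian scoring of insertional mutations against genes.

Retroviral insertional mutagenesis tags candidate cancer genes by
integration near them. Each insertion is associated to genes with a
weight that is 1 anywhere inside the gene body and decays as a Gaussian
(sigma = 25 kb by default) with distance outside it; insertions further
than 50 kb from the gene start or termination site contribute nothing.
Summing weights per (tumor, gene) yields the tumors x genes mutation
matrix M; column sums give the per-gene mutation score vector S.

Coordinates are 0-based, half-open [start, end): position p is inside the
gene iff start <= p < end; outside, the distance is measured to the
nearer of the start coordinate or the termination-site coordinate ``end``
(so p == end has distance 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIGMA_DEFAULT = 25_000.0  # bp, Gaussian tail width
CUTOFF_DEFAULT = 50_000.0  # bp, association cutoff

__all__ = [
    "GenomicInsertion",
    "GeneModel",
    "MutationMatrix",
    "GeneScoreVector",
    "flat_top_gaussian_weight",
    "score_insertion_against_gene",
    "build_mutation_matrix",
    "gene_scores",
    "read_insertions",
    "read_gene_models",
    "SIGMA_DEFAULT",
    "CUTOFF_DEFAULT",
]


@dataclass(frozen=True)
class GenomicInsertion:
    tumor_id: str
    chrom: str
    position: int  # 0-based

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass
class MutationMatrix:
    """Tumors x genes nonnegative score matrix M.

    The gene order is shared with the interaction network; ``values[i, j]``
    is the mutation score of gene j in tumor i.
    """

    tumor_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tumor_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.values < 0).any():
            raise ValueError("mutation scores must be nonnegative")

    @property
    def n_tumors(self) -> int:
        return len(self.tumor_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tumor_ids, columns=self.gene_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="tumor_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))


@dataclass
class GeneScoreVector:
    """Per-gene mutation scores S with S_j the column sum of M."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids),):
            raise ValueError("score vector shape does not match gene list")

    def write_tsv(self, path: str | Path) -> None:
        pd.Series(self.scores, index=self.gene_ids, name="score").to_csv(
            path, sep="\t", index_label="gene_id"
        )


# ---------------------------------------------------------------------
# scoring


def flat_top_gaussian_weight(
    distance_outside_gene: float | np.ndarray,
    sigma: float = SIGMA_DEFAULT,
    cutoff: float = CUTOFF_DEFAULT,
) -> float | np.ndarray:
    """Insertion-to-gene weight as a function of distance outside the gene.

    Returns 1 at distance 0 (inside the gene or at its boundary),
    ``exp(-d^2 / (2 sigma^2))`` for 0 < d <= cutoff, and 0 beyond the
    cutoff. Vectorized over ``distance_outside_gene``.
    """
    d = np.asarray(distance_outside_gene, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be >= 0")
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    w = np.where(d > cutoff, 0.0, w)
    if np.isscalar(distance_outside_gene) or d.ndim == 0:
        return float(w)
    return w


def _distance_to_gene(position: int, gene: GeneModel) -> int:
    if position < gene.start:
        return gene.start - position
    if position <= gene.end:  # inside [start, end) or at the termination site
        return 0
    return position - gene.end


def score_insertion_against_gene(
    ins: GenomicInsertion,
    gene: GeneModel,
    sigma: float = SIGMA_DEFAULT,
    cutoff: float = CUTOFF_DEFAULT,
) -> float:
    """Flat-top Gaussian weight of one insertion against one gene.

    Different chromosome gives 0; strand is ignored (the weighting is
    symmetric around gene start and termination site).
    """
    if ins.chrom != gene.chrom:
        return 0.0
    return float(
        flat_top_gaussian_weight(_distance_to_gene(ins.position, gene), sigma, cutoff)
    )


def build_mutation_matrix(
    insertions: Iterable[GenomicInsertion],
    genes: Iterable[GeneModel],
    network_genes: Sequence[str],
    sigma: float = SIGMA_DEFAULT,
    cutoff: float = CUTOFF_DEFAULT,
) -> MutationMatrix:
    """Build the tumors x genes mutation matrix M.

    ``M[i, j]`` sums the flat-top Gaussian weights of tumor i's insertions
    against gene j. Columns are restricted to (and ordered by)
    ``network_genes``; network genes without a gene model get an all-zero
    column and a logged warning. An insertion within the cutoff of several
    genes contributes to all of them.
    """
    network_genes = list(network_genes)
    gene_pos = {g: j for j, g in enumerate(network_genes)}
    models = [g for g in genes if g.gene_id in gene_pos]
    missing = set(network_genes) - {g.gene_id for g in models}
    if missing:
        logger.warning(
            "%d network genes without gene model get zero scores (e.g. %s)",
            len(missing),
            sorted(missing)[:3],
        )
    insertions = list(insertions)
    tumor_ids = sorted({ins.tumor_id for ins in insertions})
    tumor_pos = {t: i for i, t in enumerate(tumor_ids)}
    M = np.zeros((len(tumor_ids), len(network_genes)))
    # group insertions per chromosome, sorted by position, for window lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {ins.chrom for ins in insertions}:
        sub = [ins for ins in insertions if ins.chrom == chrom]
        pos = np.array([ins.position for ins in sub])
        order = np.argsort(pos, kind="stable")
        t_idx = np.array([tumor_pos[sub[k].tumor_id] for k in order])
        by_chrom[chrom] = (pos[order], t_idx)
    for gene in models:
        if gene.chrom not in by_chrom:
            continue
        pos, t_idx = by_chrom[gene.chrom]
        lo = np.searchsorted(pos, gene.start - cutoff, side="left")
        hi = np.searchsorted(pos, gene.end + cutoff, side="right")
        if lo == hi:
            continue
        p = pos[lo:hi]
        dist = np.where(
            p < gene.start, gene.start - p, np.where(p <= gene.end, 0, p - gene.end)
        )
        w = flat_top_gaussian_weight(dist, sigma, cutoff)
        np.add.at(M, (t_idx[lo:hi], gene_pos[gene.gene_id]), w)
    return MutationMatrix(tumor_ids, network_genes, M)


def gene_scores(M: MutationMatrix) -> GeneScoreVector:
    """Gene mutation score vector S: exact column sums of M."""
    return GeneScoreVector(list(M.gene_ids), M.values.sum(axis=0))


# ---------------------------------------------------------------------
# readers


def read_insertions(path: str | Path) -> list[GenomicInsertion]:
    """Read insertions from TSV (chrom, position, tumor_id; header optional)
    or 4-column BED (chrom, start, start+1, tumor_id) by ``.bed`` suffix."""
    path = Path(path)
    out: list[GenomicInsertion] = []
    is_bed = path.suffix.lower() == ".bed"
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if is_bed:
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED needs 4 columns")
                chrom, start, _end, tumor = fields[:4]
                out.append(GenomicInsertion(tumor, chrom, int(start)))
            else:
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                chrom, posn, tumor = fields[:3]
                if lineno == 1 and not posn.lstrip("-").isdigit():
                    continue  # header
                out.append(GenomicInsertion(tumor, chrom, int(posn)))
    return out


def _gff_attr(attrs: str, keys: tuple[str, ...]) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        elif " " in part:
            k, v = part.split(None, 1)
        else:
            continue
        if k in keys:
            return v.strip().strip('"')
    return None


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED (>= 4 columns) or GFF3 (type ``gene``).

    Format chosen by suffix: ``.gff``/``.gff3``/``.gtf`` parse gene-type
    records using the ID or gene_id attribute; everything else is treated
    as BED with the gene identifier in the name column.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3", ".gtf"}
    out: list[GeneModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if is_gff:
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF needs 9 columns")
                if fields[2] != "gene":
                    continue
                gene_id = _gff_attr(fields[8], ("ID", "gene_id"))
                if gene_id is None:
                    raise ValueError(f"{path}:{lineno}: gene record without ID")
                # GFF is 1-based inclusive; convert to 0-based half-open
                out.append(
                    GeneModel(gene_id, fields[0], int(fields[3]) - 1, int(fields[4]),
                              fields[6] if fields[6] in "+-" else ".")
                )
            else:
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
                strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
                out.append(
                    GeneModel(fields[3], fields[0], int(fields[1]), int(fields[2]),
                              strand)
                )
    return out
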