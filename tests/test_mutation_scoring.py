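import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remic.mutation_scoring import (
    GeneModel,
    GenomicInsertion,
    MutationMatrix,
    build_mutation_matrix,
    flat_top_gaussian_weight,
    gene_scores,
    read_gene_models,
    read_insertions,
    score_insertion_against_gene,
)

GENE = GeneModel("g", "chr1", 100_000, 120_000)


class TestFlatTopGaussian:
    @pytest.mark.parametrize(
        "distance,expected",
        [
            (0, 1.0),
            (25_000, math.exp(-0.5)),
            (50_000, math.exp(-2.0)),
            (50_001, 0.0),
            (60_000, 0.0),
        ],
    )
    def test_values(self, distance, expected):
        assert flat_top_gaussian_weight(distance) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            flat_top_gaussian_weight(-1)

    @given(st.integers(0, 49_000), st.integers(1, 1000))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_in_distance(self, d, step):
        assert flat_top_gaussian_weight(d + step) <= flat_top_gaussian_weight(d)

    def test_discontinuous_at_cutoff_continuous_at_gene_boundary(self):
        # value 1 holds right up to the boundary, then decays smoothly...
        assert flat_top_gaussian_weight(0) == 1.0
        assert flat_top_gaussian_weight(1) == pytest.approx(1.0, abs=1e-9)
        # ...but drops to exactly 0 past the cutoff
        eps_in = flat_top_gaussian_weight(50_000)
        assert eps_in > 0
        assert flat_top_gaussian_weight(50_000 + 1) == 0.0


class TestScoreAgainstGene:
    def test_inside_gene_weight_one(self):
        ins = GenomicInsertion("t", "chr1", 110_000)
        assert score_insertion_against_gene(ins, GENE) == 1.0

    def test_at_end_coordinate_counts_as_boundary(self):
        # half-open [start, end): position end is the termination site, distance 0
        ins = GenomicInsertion("t", "chr1", GENE.end)
        assert score_insertion_against_gene(ins, GENE) == 1.0

    def test_just_beyond_cutoff_upstream_is_zero(self):
        ins = GenomicInsertion("t", "chr1", GENE.start - 50_001)
        assert score_insertion_against_gene(ins, GENE) == 0.0

    def test_at_cutoff_still_associated(self):
        ins = GenomicInsertion("t", "chr1", GENE.start - 50_000)
        assert score_insertion_against_gene(ins, GENE) == pytest.approx(
            math.exp(-2.0)
        )

    def test_other_chromosome_is_zero(self):
        ins = GenomicInsertion("t", "chr2", 110_000)
        assert score_insertion_against_gene(ins, GENE) == 0.0


class TestBuildMatrix:
    def test_no_insertions_all_zero(self):
        M = build_mutation_matrix([], [GENE], ["g"])
        assert M.values.shape == (0, 1)

    def test_single_insertion_inside_gene(self):
        M = build_mutation_matrix(
            [GenomicInsertion("t1", "chr1", 110_000)], [GENE], ["g"]
        )
        assert M.values.tolist() == [[1.0]]

    def test_additivity_within_tumor_matches_per_insertion_oracle(self):
        inss = [
            GenomicInsertion("t1", "chr1", GENE.start - 10_000),
            GenomicInsertion("t1", "chr1", GENE.end + 20_000),
        ]
        M = build_mutation_matrix(inss, [GENE], ["g"])
        oracle = sum(score_insertion_against_gene(i, GENE) for i in inss)
        assert M.values[0, 0] == pytest.approx(oracle)
        assert 0 < M.values[0, 0] < 2

    def test_insertion_near_two_genes_contributes_to_both(self):
        g2 = GeneModel("h", "chr1", 130_000, 150_000)
        ins = GenomicInsertion("t1", "chr1", 125_000)  # between g and h
        M = build_mutation_matrix([ins], [GENE, g2], ["g", "h"])
        assert (M.values[0] > 0).all()

    def test_network_gene_without_model_gets_zero_column(self, caplog):
        with caplog.at_level("WARNING"):
            M = build_mutation_matrix(
                [GenomicInsertion("t1", "chr1", 110_000)], [GENE], ["g", "orphan"]
            )
        assert M.gene_ids == ["g", "orphan"]
        assert M.values[0, 1] == 0.0
        assert "without gene model" in caplog.text

    def test_linearity_doubling_insertions_doubles_matrix(self):
        inss = [
            GenomicInsertion("t1", "chr1", 110_000),
            GenomicInsertion("t2", "chr1", GENE.start - 5_000),
        ]
        M1 = build_mutation_matrix(inss, [GENE], ["g"])
        M2 = build_mutation_matrix(inss * 2, [GENE], ["g"])
        assert np.allclose(M2.values, 2 * M1.values)


class TestGeneScores:
    def test_column_sums_match_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.random((10, 5))
        M = MutationMatrix([f"t{i}" for i in range(10)],
                           [f"g{j}" for j in range(5)], vals)
        S = gene_scores(M)
        oracle = [sum(vals[i, j] for i in range(10)) for j in range(5)]
        assert np.allclose(S.scores, oracle)
        # conservation of total score
        assert S.scores.sum() == pytest.approx(vals.sum())

    def test_identity_matrix_gives_ones(self):
        M = MutationMatrix(["a", "b", "c"], ["x", "y", "z"], np.eye(3))
        assert gene_scores(M).scores.tolist() == [1.0, 1.0, 1.0]


class TestReaders:
    def test_insertions_tsv_with_header(self, tmp_path):
        p = tmp_path / "ins.tsv"
        p.write_text("chrom\tposition\ttumor_id\nchr1\t12345\tT1\nchr2\t99\tT2\n")
        out = read_insertions(p)
        assert out == [
            GenomicInsertion("T1", "chr1", 12345),
            GenomicInsertion("T2", "chr2", 99),
        ]

    def test_insertions_bed_name_field_is_tumor(self, tmp_path):
        p = tmp_path / "ins.bed"
        p.write_text("chr1\t500\t501\tT9\n")
        assert read_insertions(p) == [GenomicInsertion("T9", "chr1", 500)]

    def test_gene_models_bed_and_gff_agree(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tgeneA\t0\t+\n")
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
            "chr1\tsrc\texon\t101\t150\t.\t+\t.\tID=exon1\n"
        )
        assert read_gene_models(bed) == read_gene_models(gff)

    def test_matrix_tsv_roundtrip(self, tmp_path):
        M = MutationMatrix(["t1", "t2"], ["a", "b"], [[0.0, 1.5], [2.0, 0.25]])
        path = tmp_path / "m.tsv"
        M.write_tsv(path)
        M2 = MutationMatrix.read_tsv(path)
        assert M2.tumor_ids == M.tumor_ids and M2.gene_ids == M.gene_ids
        assert np.allclose(M2.values, M.values)
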