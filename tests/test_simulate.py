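import dataclasses

import numpy as np
import pandas as pd
import pytest

from hic3state._intervals import overlap_counts
from hic3state.simulate import (
    GroundTruth,
    SimulationConfig,
    depth_for_diagonal_mean,
    make_ground_truth,
    simulate_annotations,
    simulate_contact_matrix,
    simulate_expression,
    write_dataset,
)


class TestConfig:
    def test_resolution_divisibility(self):
        with pytest.raises(ValueError):
            SimulationConfig(fine_resolution=10_000, coarse_resolution=25_000)

    def test_boost_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(tad_boost=0.5)


class TestGroundTruth:
    def test_cancer_partition_refines_normal(self, tiny_cfg, tiny_truth):
        normal = tiny_truth.tads["normal"]
        cancer = tiny_truth.tads["cancerA"]
        assert len(cancer) == len(normal) + tiny_cfg.n_split_tads_per_chrom * tiny_cfg.n_chroms
        # split parents exist and are >= 2 cancer TADs each
        assert len(tiny_truth.split_parents) == tiny_cfg.n_split_tads_per_chrom * tiny_cfg.n_chroms

    def test_loop_class_conditions(self, tiny_truth):
        loops = tiny_truth.loops
        assert set(loops["class"]) <= {"common", "normal_specific", "cancer_specific"}
        normal_loops = tiny_truth.loops_of("normal")
        assert not (normal_loops["class"] == "cancer_specific").any()
        cancer_loops = tiny_truth.loops_of("cancerA")
        assert not (cancer_loops["class"] == "normal_specific").any()

    def test_loop_distance_range(self, tiny_cfg, tiny_truth):
        lo, hi = tiny_cfg.loop_distance_range
        assert tiny_truth.loops["distance"].between(lo, hi).all()

    def test_json_round_trip(self, tiny_truth, tmp_path):
        p = tmp_path / "truth.json"
        tiny_truth.to_json(p)
        back = GroundTruth.from_json(p)
        pd.testing.assert_frame_equal(back.loops, tiny_truth.loops)
        pd.testing.assert_frame_equal(back.genes, tiny_truth.genes)
        np.testing.assert_allclose(back.bias, tiny_truth.bias, rtol=1e-9)
        assert back.tf_bound_enhancer_bins == tiny_truth.tf_bound_enhancer_bins


class TestContactMatrix:
    def test_deterministic_under_seed(self, tiny_cfg, tiny_truth):
        a = simulate_contact_matrix(tiny_cfg, tiny_truth, "normal")
        b = simulate_contact_matrix(tiny_cfg, tiny_truth, "normal")
        assert np.array_equal(a.row, b.row)
        assert np.array_equal(a.count, b.count)

    def test_total_mass_near_depth(self, tiny_cfg, tiny_matrix):
        expected = tiny_cfg.depth * tiny_cfg.n_chroms
        assert abs(tiny_matrix.total() - expected) / expected < 0.05

    def test_pure_decay_mean_counts(self):
        cfg = SimulationConfig(
            n_chroms=1, chrom_length=3_000_000, tad_boost=1.0, loop_boost=1.0,
            bias_lognormal_sd=0.0, depth=600_000, n_tads_per_chrom=3,
            n_split_tads_per_chrom=1, n_common_loops_per_chrom=1,
            n_normal_loops_per_chrom=1, n_cancer_loops_per_chrom=1, seed=5,
        )
        truth = make_ground_truth(cfg)
        m = simulate_contact_matrix(cfg, truth, "normal")
        n = 300
        dense = m.dense_chrom("chr1")
        # expected counts follow C (d+1)^-alpha: check the ratio at two distances
        mean_d = {d: np.diagonal(dense, offset=d).mean() for d in (1, 9)}
        assert mean_d[1] / mean_d[9] == pytest.approx(10 / 2, rel=0.1)

    def test_planted_loop_enrichment_monte_carlo(self):
        """Across replicates the planted pair exceeds the same-distance mean
        in at least 95 of 100 runs."""
        base = SimulationConfig(
            n_chroms=1, chrom_length=2_000_000, n_tads_per_chrom=2,
            n_split_tads_per_chrom=1, n_common_loops_per_chrom=1,
            n_normal_loops_per_chrom=0, n_cancer_loops_per_chrom=0,
            depth=100_000, seed=3,
        )
        truth = make_ground_truth(base)
        loop = truth.loops_of("normal").iloc[0]
        d = int(loop["bin2"] - loop["bin1"])
        wins = 0
        for rep in range(100):
            cfg = dataclasses.replace(base, seed=1000 + rep)
            m = simulate_contact_matrix(cfg, make_ground_truth(base), "normal")
            diag = np.diagonal(m.dense_chrom("chr1"), offset=d)
            if diag[int(loop["bin1"])] > diag.mean():
                wins += 1
        assert wins >= 95

    def test_depth_for_diagonal_mean(self, tiny_cfg, tiny_truth):
        depth = depth_for_diagonal_mean(tiny_cfg, tiny_truth, "normal", 50.0)
        cfg = dataclasses.replace(tiny_cfg, depth=depth)
        m = simulate_contact_matrix(cfg, tiny_truth, "normal")
        coarse_factor = tiny_cfg.coarse_resolution // tiny_cfg.fine_resolution
        from hic3state.normalization import coarsen

        c = coarsen(m, coarse_factor)
        r, cc, v = c.chrom_entries("chr1")
        diag_mean = v[r == cc].sum() / c.bins.n_bins_chrom("chr1")
        assert diag_mean == pytest.approx(50.0, rel=0.15)

    def test_low_depth_warns(self, tiny_cfg, tiny_truth):
        cfg = dataclasses.replace(tiny_cfg, depth=50.0)
        with pytest.warns(UserWarning, match="depth too small"):
            simulate_contact_matrix(cfg, tiny_truth, "normal")


class TestAnnotations:
    def test_ndrs_nested_in_k27ac(self, tiny_annotations):
        for cond, ann in tiny_annotations.items():
            k27 = ann.peaks["H3K27ac"]
            inside = overlap_counts(ann.ndrs, k27)
            assert (inside >= 1).all()
            # strict nesting: each NDR is contained in a peak interval
            for _, ndr in ann.ndrs.iterrows():
                hit = k27[(k27["start"] <= ndr["start"]) & (k27["end"] >= ndr["end"])]
                assert len(hit) >= 1

    def test_normal_lacks_cancer_anchor_peaks(self, tiny_cfg, tiny_truth, tiny_annotations):
        res = tiny_cfg.fine_resolution
        cancer_enh = tiny_truth.loops[tiny_truth.loops["class"] == "cancer_specific"]
        anchors = pd.DataFrame(
            {
                "chrom": cancer_enh["chrom"],
                "start": cancer_enh["enhancer_bin"] * res,
                "end": (cancer_enh["enhancer_bin"] + 1) * res,
            }
        )
        normal_k27 = tiny_annotations["normal"].peaks["H3K27ac"]
        assert (overlap_counts(anchors, normal_k27) == 0).all()
        cancer_k27 = tiny_annotations["cancerA"].peaks["H3K27ac"]
        assert (overlap_counts(anchors, cancer_k27) >= 1).all()

    def test_tf_peaks_absent_in_normal(self, tiny_annotations):
        assert len(tiny_annotations["normal"].tf_peaks) == 0

    def test_deterministic(self, tiny_cfg, tiny_truth):
        a = simulate_annotations(tiny_cfg, tiny_truth, "cancerA")
        b = simulate_annotations(tiny_cfg, tiny_truth, "cancerA")
        pd.testing.assert_frame_equal(a.peaks["H3K27ac"], b.peaks["H3K27ac"])
        pd.testing.assert_frame_equal(a.ctcf_peaks, b.ctcf_peaks)


class TestExpression:
    def test_planted_effect_median_fold_change(self):
        cfg = SimulationConfig(seed=8)
        truth = make_ground_truth(cfg)
        expr = simulate_expression(cfg, truth)
        up = truth.genes[truth.genes["upregulated"]]["gene_id"]
        assert len(up) >= 10
        normal_cols = [c for c in expr.columns if c.startswith("normal_")]
        cancer_cols = [c for c in expr.columns if c.startswith("cancerA_")]
        fc = expr.loc[up, cancer_cols].mean(axis=1) / expr.loc[up, normal_cols].mean(axis=1)
        assert fc.median() > 2.0

    def test_expressed_genes_pass_threshold(self, tiny_cfg, tiny_truth, tiny_expression):
        from hic3state.expression import call_expressed

        normal_cols = [c for c in tiny_expression.columns if c.startswith("normal_")]
        called = call_expressed(tiny_expression[normal_cols])
        planted = tiny_truth.genes.set_index("gene_id")["expressed"]
        agreement = (called == planted.reindex(called.index)).mean()
        assert agreement > 0.95


def test_write_dataset_round_trip(tmp_path):
    cfg = SimulationConfig(
        n_chroms=1, chrom_length=2_000_000, n_tads_per_chrom=2,
        n_split_tads_per_chrom=1, n_common_loops_per_chrom=1,
        n_normal_loops_per_chrom=1, n_cancer_loops_per_chrom=1,
        depth=100_000, seed=4,
    )
    truth = write_dataset(cfg, tmp_path)
    from hic3state.genome_io import read_contact_matrix, read_gene_table

    m = read_contact_matrix(tmp_path / "normal" / "matrix.tsv", tmp_path / "normal" / "bins.bed")
    direct = simulate_contact_matrix(cfg, truth, "normal")
    assert m.total() == pytest.approx(direct.total())
    genes = read_gene_table(tmp_path / "genes.tsv")
    assert len(genes) == len(truth.genes)
    back = GroundTruth.from_json(tmp_path / "ground_truth.json")
    pd.testing.assert_frame_equal(back.loops, truth.loops)
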