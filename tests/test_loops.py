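import math

import numpy as np
import pandas as pd
import pytest

from hic3state import loops as lp
from hic3state.genome_io import BinTable, ContactMatrix
from hic3state.normalization import estimate_decay, ice_normalize


def peaks_df(rows):
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "name": f"p{k}", "score": sc}
         for k, (c, s, e, sc) in enumerate(rows)]
    )


def genes_df(rows):
    return pd.DataFrame(
        [{"gene_id": g, "chrom": c, "strand": "+", "tss": t, "length": 1000}
         for g, c, t in rows]
    )


def loop_row(chrom, b1, b2, res=10_000, **extra):
    row = {
        "chrom": chrom, "bin1": b1, "bin2": b2,
        "start1": b1 * res, "end1": (b1 + 1) * res,
        "start2": b2 * res, "end2": (b2 + 1) * res,
    }
    row.update(extra)
    return row


class TestBinomialTail:
    def test_exact_tail_vs_lgamma_sum(self):
        # P(X >= 10), X ~ Binomial(1000, 0.001), summed independently
        n, p, k = 1000, 0.001, 10
        logs = [
            math.lgamma(n + 1) - math.lgamma(j + 1) - math.lgamma(n - j + 1)
            + j * math.log(p) + (n - j) * math.log1p(-p)
            for j in range(k, 61)  # terms beyond are < 1e-30
        ]
        oracle = float(np.sum(np.exp(logs)))
        ours = float(lp.loop_binomial_p(k, n, p))
        assert ours == pytest.approx(oracle, rel=1e-9)

    def test_count_at_expectation_is_never_significant(self):
        p = float(lp.loop_binomial_p(100, 10_000, 0.01))
        assert 0.3 < p < 0.7


class TestCallLoops:
    def test_zero_total_rejected(self):
        bt = BinTable({"chr1": 200_000}, 10_000)
        m = ContactMatrix(bt)
        from hic3state.normalization import DecayProfile

        prof = DecayProfile(
            resolution=10_000, edges=np.array([5]), distances=np.array([5.0]),
            p_hat=np.array([0.0]), p_raw=np.array([0.0]),
            n_pairs=np.array([10.0]), count_sum=np.array([0.0]),
            n_total=0.0, min_dist_bins=5, max_dist_bins=10,
        )
        with pytest.raises(ValueError):
            lp.call_significant_loops(m, prof)

    def test_planted_pair_detected_without_bias(self, rng):
        n = 300
        bt = BinTable({"chr1": n * 10_000}, 10_000)
        i, j = np.triu_indices(n, k=1)
        d = j - i
        lam = 400.0 / d
        lam[(i == 40) & (j == 60)] *= 8
        m = ContactMatrix.from_entries(bt, i, j, rng.poisson(lam).astype(float))
        norm, _ = ice_normalize(m)
        decay = estimate_decay(norm, min_dist=50_000, max_dist=2_000_000)
        called = lp.call_significant_loops(norm, decay, min_dist=50_000, max_dist=2_000_000)
        assert {(40, 60)} == set(zip(called["bin1"], called["bin2"]))

    def test_loop_distance_range_enforced(self, tiny_cfg, tiny_matrix):
        norm, _ = ice_normalize(tiny_matrix)
        decay = estimate_decay(norm)
        called = lp.call_significant_loops(norm, decay)
        if len(called):
            assert called["distance"].between(50_000, 10_000_000).all()
            assert (called["q"] < 0.05).all()


class TestRegulatorySets:
    def build(self):
        genes = genes_df([("G1", "chr1", 50_000), ("G2", "chr1", 200_000)])
        expr = pd.DataFrame(
            {"r1": [2**1.4 - 1, 0.0], "r2": [2**1.5 - 1, 0.0], "r3": [2**1.7 - 1, 0.0]},
            index=["G1", "G2"],
        )
        k27 = peaks_df([
            ("chr1", 48_900, 49_400, 9.0),   # centered 1.35 kb from G1 TSS -> excluded
            ("chr1", 100_000, 100_500, 8.0),  # distal -> enhancer
        ])
        ctcf = peaks_df([
            ("chr1", 49_000, 49_500, 9.0),    # overlaps promoter -> excluded
            ("chr1", 100_100, 100_300, 8.0),  # overlaps enhancer -> excluded
            ("chr1", 150_000, 150_400, 7.0),  # clean -> insulator
        ])
        return lp.build_regulatory_sets(genes, expr, k27, ctcf)

    def test_sequential_construction(self):
        reg = self.build()
        # G1 mean log2(RPKM+1) = 1.533 > 1.5 -> promoter; G2 silent
        assert list(reg.promoters["name"]) == ["G1"]
        assert (reg.promoters["start"][0], reg.promoters["end"][0]) == (48_000, 52_000)
        assert list(reg.enhancers["start"]) == [100_000]
        assert list(reg.insulators["start"]) == [150_000]


class TestAnnotateAnchors:
    def reg(self):
        return lp.RegulatoryElementSet(
            promoters=peaks_df([("chr1", 12_000, 14_000, 0)]),
            enhancers=peaks_df([("chr1", 13_000, 13_500, 0), ("chr1", 95_000, 96_000, 0)]),
            insulators=peaks_df([("chr1", 205_000, 206_000, 0)]),
        )

    def test_priority_and_category(self):
        loops = pd.DataFrame([
            loop_row("chr1", 1, 9),    # anchor1 overlaps promoter+enhancer -> P; anchor2 E
            loop_row("chr1", 20, 40),  # I and O
        ])
        out, ranking = lp.annotate_anchors(loops, self.reg())
        assert list(out["anchor1_label"]) == ["P", "I"]
        assert list(out["anchor2_label"]) == ["E", "O"]
        assert list(out["category"]) == ["PE", "IO"]

    def test_ranking_sort(self):
        rows = [loop_row("chr1", 300 + k, 320 + k) for k in range(5)]  # OO x5
        rows += [loop_row("chr1", 1, 9)] * 2                            # PE x2
        rows += [loop_row("chr1", 9, 95 // 10)] * 0
        loops = pd.DataFrame(rows + [loop_row("chr1", 20, 40)] * 3)     # IO x3
        out, ranking = lp.annotate_anchors(loops, self.reg())
        assert list(ranking["category"]) == ["OO", "IO", "PE"]
        assert list(ranking["count"]) == [5, 3, 2]


class TestFateFractions:
    def test_partition_and_priority(self):
        reg = lp.RegulatoryElementSet(
            promoters=peaks_df([
                ("chr1", 12_000, 14_000, 0),    # loops to E and I -> loops_to_E
                ("chr1", 500_000, 502_000, 0),  # not looped
            ]),
            enhancers=peaks_df([("chr1", 95_000, 96_000, 0)]),
            insulators=peaks_df([("chr1", 205_000, 206_000, 0)]),
        )
        loops = pd.DataFrame([
            loop_row("chr1", 1, 9, anchor1_label="P", anchor2_label="E", category="PE"),
            loop_row("chr1", 1, 20, anchor1_label="P", anchor2_label="I", category="PI"),
        ])
        rep = lp.loop_fate_fractions(reg, loops)
        prom = rep[rep["element_class"] == "P"].iloc[0]
        assert prom["loops_to_E"] == pytest.approx(0.5)
        assert prom["not_looped"] == pytest.approx(0.5)
        fracs = rep[["loops_to_E", "loops_to_I", "loops_to_P", "loops_to_O", "not_looped"]]
        np.testing.assert_allclose(fracs.sum(axis=1), 1.0, atol=1e-9)


class TestShuffleNull:
    def loops(self, n=10):
        return pd.DataFrame([loop_row("chr1", 10 * k + 3, 10 * k + 8) for k in range(n)])

    def test_observed_exceeds_all_nulls(self):
        loops = self.loops()
        anchors = sorted(set(loops["start1"]) | set(loops["start2"]))
        reg = lp.RegulatoryElementSet(
            promoters=peaks_df([("chr1", a, a + 10_000, 0) for a in anchors]),
            enhancers=peaks_df([]).reindex(columns=["chrom", "start", "end", "name", "score"]),
            insulators=peaks_df([]).reindex(columns=["chrom", "start", "end", "name", "score"]),
        )
        rep = lp.shuffle_anchor_null(loops, reg, chrom_length=20_000_000, seed=4)
        row = rep[rep["element_type"] == "P"].iloc[0]
        assert row["observed_fraction"] == 1.0
        assert row["empirical_p"] == pytest.approx(1 / 101)

    def test_saturated_element_set_p_one(self):
        loops = self.loops()
        reg = lp.RegulatoryElementSet(
            promoters=peaks_df([("chr1", 0, 20_000_000, 0)]),
            enhancers=peaks_df([("chr1", 0, 20_000_000, 0)]),
            insulators=peaks_df([("chr1", 0, 20_000_000, 0)]),
        )
        rep = lp.shuffle_anchor_null(loops, reg, chrom_length=20_000_000, seed=4)
        np.testing.assert_allclose(rep["empirical_p"], 1.0)

    def test_deterministic_under_seed(self):
        loops = self.loops()
        reg = lp.RegulatoryElementSet(
            promoters=peaks_df([("chr1", 0, 1_000_000, 0)]),
            enhancers=peaks_df([("chr1", 3_000_000, 3_400_000, 0)]),
            insulators=peaks_df([("chr1", 9_000_000, 9_100_000, 0)]),
        )
        a = lp.shuffle_anchor_null(loops, reg, chrom_length=20_000_000, seed=12)
        b = lp.shuffle_anchor_null(loops, reg, chrom_length=20_000_000, seed=12)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_chromosome(self):
        reg = lp.RegulatoryElementSet(
            promoters=peaks_df([]), enhancers=peaks_df([]), insulators=peaks_df([])
        )
        with pytest.raises(ValueError, match="chr9"):
            lp.shuffle_anchor_null(self.loops(), reg, chrom_length=10**6, chrom="chr9")


class TestClassifyEpLoops:
    def lines(self):
        def df(pairs, cat="PE"):
            return pd.DataFrame(
                [loop_row("chr1", b1, b2, category=cat,
                          anchor1_label=cat[0], anchor2_label=cat[1])
                 for b1, b2 in pairs]
            )
        normal = df([(1, 9), (20, 40), (50, 70)])
        c1 = df([(1, 9), (20, 40), (100, 130)])
        c2 = df([(1, 9), (100, 130), (200, 230)])
        return {"normal": normal, "cancerA": c1, "cancerB": c2}

    def test_set_logic(self):
        classes = lp.classify_ep_loops(self.lines(), normal="normal", cancers=("cancerA", "cancerB"))
        common = set(zip(classes["common"]["bin1"], classes["common"]["bin2"]))
        cancer = set(zip(classes["cancer_specific"]["bin1"], classes["cancer_specific"]["bin2"]))
        nsp = set(zip(classes["normal_specific"]["bin1"], classes["normal_specific"]["bin2"]))
        assert common == {(1, 9)}
        assert cancer == {(100, 130)}
        assert nsp == {(50, 70)}  # (20,40) is in normal + one cancer: unlabeled

    def test_no_loop_in_two_classes(self):
        classes = lp.classify_ep_loops(self.lines(), normal="normal", cancers=("cancerA", "cancerB"))
        seen = []
        for df in classes.values():
            seen.extend(zip(df["chrom"], df["bin1"], df["bin2"]))
        assert len(seen) == len(set(seen))

    def test_unannotated_rejected(self):
        bad = {k: v.drop(columns="category") for k, v in self.lines().items()}
        with pytest.raises(ValueError, match="not annotated"):
            lp.classify_ep_loops(bad, normal="normal", cancers=("cancerA", "cancerB"))


class TestDifferentialLoopTest:
    def test_identical_proportions(self):
        res = lp.differential_loop_test([10], 1000, [10], 1000)
        assert res["p"][0] == pytest.approx(1.0)

    def test_enriched_pair_significant(self):
        res = lp.differential_loop_test([10], 1000, [1], 1000)
        assert res["p"][0] < 0.05
        assert res["odds_ratio"][0] > 1

    def test_zero_counts_p_one(self):
        res = lp.differential_loop_test([0], 100, [0], 100)
        assert res["p"][0] == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            lp.differential_loop_test([1], 0, [1], 100)


class TestTfBoundEnhancers:
    def setup_loops(self, n=10):
        loops = []
        for k in range(n):
            loops.append(
                loop_row("chr1", 100 + 10 * k, 105 + 10 * k,
                         anchor1_label="E", anchor2_label="P", category="PE")
            )
        enhancers = peaks_df(
            [("chr1", (100 + 10 * k) * 10_000 + 2000, (100 + 10 * k) * 10_000 + 2600, 5.0)
             for k in range(n)]
        )
        genes = genes_df(
            [(f"G{k}", "chr1", (105 + 10 * k) * 10_000 + 5000) for k in range(n)]
        )
        reg = lp.RegulatoryElementSet(
            promoters=peaks_df([]).reindex(columns=["chrom", "start", "end", "name", "score"]),
            enhancers=enhancers,
            insulators=peaks_df([]).reindex(columns=["chrom", "start", "end", "name", "score"]),
        )
        return pd.DataFrame(loops), reg, genes

    def test_no_tf_peaks(self):
        loops, reg, genes = self.setup_loops()
        frac, bound, targets = lp.tf_bound_looped_enhancers(
            loops, reg, peaks_df([]).reindex(columns=["chrom", "start", "end", "name", "score"]), genes=genes
        )
        assert frac == 0.0 and targets == []

    def test_giant_peak_covers_all(self):
        loops, reg, genes = self.setup_loops()
        tf = peaks_df([("chr1", 0, 10_000_000, 9.0)])
        frac, bound, targets = lp.tf_bound_looped_enhancers(loops, reg, tf, genes=genes)
        assert frac == 1.0
        assert len(targets) == 10

    def test_three_of_ten(self):
        loops, reg, genes = self.setup_loops()
        tf = peaks_df(
            [("chr1", reg.enhancers["start"][k], reg.enhancers["end"][k], 9.0) for k in range(3)]
        )
        frac, bound, targets = lp.tf_bound_looped_enhancers(loops, reg, tf, genes=genes)
        assert frac == pytest.approx(0.3)
        assert targets == ["G0", "G1", "G2"]
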