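import numpy as np
import pandas as pd
import pytest

from hic3state.tad_states import (
    classify_tad_states,
    count_enriched,
    detect_state_changes,
    gene_density_class,
    mean_signal_per_tad,
    random_tad_null,
    top_peaks,
)


def track(values, width=50, chrom="chr1"):
    starts = np.arange(len(values)) * width
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + width, "value": values}
    )


def tads(rows):
    return pd.DataFrame([{"chrom": "chr1", "start": s, "end": e} for s, e in rows])


class TestMeanSignal:
    def test_constant_track(self):
        out = mean_signal_per_tad(tads([(0, 100), (100, 300)]), track([2.0] * 6))
        np.testing.assert_allclose(out["mean_signal"], 2.0)

    def test_weighted_average(self):
        out = mean_signal_per_tad(tads([(0, 100)]), track([1.0, 3.0]))
        assert out["mean_signal"][0] == pytest.approx(2.0)

    def test_partial_overlap(self):
        out = mean_signal_per_tad(tads([(0, 75)]), track([1.0, 3.0]))
        assert out["mean_signal"][0] == pytest.approx((50 * 1 + 25 * 3) / 75)

    def test_no_coverage_flagged(self):
        out = mean_signal_per_tad(tads([(10_000, 20_000)]), track([1.0, 3.0]))
        assert out["mean_signal"][0] == 0.0
        assert bool(out["no_coverage"][0])


def peak(chrom, start, end, score, name="pk"):
    return {"chrom": chrom, "start": start, "end": end, "name": name, "score": score}


class TestClassify:
    def toy(self):
        """10 TADs; TADs 0-1 carry top peaks and high signal."""
        t = tads([(k * 1000, (k + 1) * 1000) for k in range(10)])
        peaks = pd.DataFrame(
            [peak("chr1", 100, 200, 9.0), peak("chr1", 1100, 1200, 8.0),
             peak("chr1", 5100, 5200, 0.1)]
            + [peak("chr1", 6100 + 500 * k, 6200 + 500 * k, 0.2) for k in range(5)]
        )  # 8 peaks total -> the 25% rule keeps the two high-score ones
        values = np.array([5.0, 5.0, 1, 1, 1, 5.0, 1, 1, 1, 1])
        return t, peaks, track(values, width=1000)

    def test_conjunction_required(self):
        t, peaks, sig = self.toy()
        ann = classify_tad_states(t, {"H3K36me3": peaks}, {"H3K36me3": sig}, top_n=2)
        flags = ann["H3K36me3_enriched"].to_numpy()
        assert flags[0] and flags[1]
        # TAD 5 has top-quantile signal but only a low-score peak outside top-N
        assert not flags[5]
        # no TAD without a peak is enriched regardless of signal
        assert not flags[2:5].any() and not flags[6:].any()
        assert list(ann["state"][:2]) == ["H3K36me3", "H3K36me3"]
        assert ann["state"][5] == "other"

    def test_invariant_enriched_implies_both(self):
        t, peaks, sig = self.toy()
        ann = classify_tad_states(t, {"H3K36me3": peaks}, {"H3K36me3": sig}, top_n=2)
        thresh = np.quantile(ann["H3K36me3_mean_signal"], 0.75)
        for _, row in ann.iterrows():
            if row["H3K36me3_enriched"]:
                assert row["H3K36me3_peaks"] >= 1
                assert row["H3K36me3_mean_signal"] >= thresh

    def test_monotone_signal_rescaling_invariance(self):
        t, peaks, sig = self.toy()
        a = classify_tad_states(t, {"H3K36me3": peaks}, {"H3K36me3": sig}, top_n=2)
        sig10 = sig.assign(value=sig["value"] * 10)
        b = classify_tad_states(t, {"H3K36me3": peaks}, {"H3K36me3": sig10}, top_n=2)
        assert list(a["H3K36me3_enriched"]) == list(b["H3K36me3_enriched"])

    def test_peak_order_invariance(self):
        t, peaks, sig = self.toy()
        a = classify_tad_states(t, {"H3K36me3": peaks}, {"H3K36me3": sig}, top_n=2)
        shuffled = peaks.iloc[::-1].reset_index(drop=True)
        b = classify_tad_states(t, {"H3K36me3": shuffled}, {"H3K36me3": sig}, top_n=2)
        assert list(a["H3K36me3_enriched"]) == list(b["H3K36me3_enriched"])

    def test_precedence_active_wins(self):
        t = tads([(0, 1000), (1000, 2000), (2000, 3000), (3000, 4000)])
        pk36 = pd.DataFrame([peak("chr1", 100, 200, 9.0)])
        pk27 = pd.DataFrame([peak("chr1", 150, 250, 9.0)])
        sig = track([5.0, 0.1, 0.1, 0.1], width=1000)
        ann = classify_tad_states(
            t, {"H3K36me3": pk36, "H3K27me3": pk27}, {"H3K36me3": sig, "H3K27me3": sig}
        )
        assert ann["H3K36me3_enriched"][0] and ann["H3K27me3_enriched"][0]
        assert ann["state"][0] == "H3K36me3"

    def test_top_peaks_quantile_cap(self):
        peaks = pd.DataFrame([peak("chr1", k * 10, k * 10 + 5, float(k)) for k in range(100)])
        kept = top_peaks(peaks, top_n=30_000)
        assert len(kept) == 25  # 25% rule binds
        assert kept["score"].min() == 75.0


class TestGeneDensity:
    @pytest.mark.parametrize("n_genes,expected", [(0, "desert"), (1, "poor"), (5, "poor"), (6, "enriched")])
    def test_boundaries(self, n_genes, expected):
        t = tads([(0, 100_000)])
        genes = pd.DataFrame(
            {"gene_id": [f"G{k}" for k in range(n_genes)], "chrom": "chr1",
             "tss": np.linspace(10, 90_000, max(n_genes, 1)).astype(int)[:n_genes]}
        )
        assert gene_density_class(t, genes)[0] == expected

    def test_tss_outside_not_counted(self):
        t = tads([(0, 50_000)])
        genes = pd.DataFrame({"gene_id": ["G1"], "chrom": ["chr1"], "tss": [60_000]})
        assert gene_density_class(t, genes)[0] == "desert"


class TestRandomTadNull:
    def setup(self):
        chrom_sizes = {"chr1": 5_000_000}
        peaks = pd.DataFrame([peak("chr1", k * 100_000, k * 100_000 + 500, 5.0) for k in range(40)])
        sig = track(np.full(100, 1.0), width=50_000)
        return chrom_sizes, peaks, sig

    def test_observed_exceeding_all_nulls(self):
        chrom_sizes, peaks, sig = self.setup()
        p, nulls = random_tad_null(chrom_sizes, 10**6, peaks, sig, seed=5)
        assert (nulls < 10**6).all()
        assert p == pytest.approx(1 / 101)

    def test_observed_zero_is_one(self):
        chrom_sizes, peaks, sig = self.setup()
        p, _ = random_tad_null(chrom_sizes, 0, peaks, sig, seed=5)
        assert p == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        chrom_sizes, peaks, sig = self.setup()
        p1, n1 = random_tad_null(chrom_sizes, 3, peaks, sig, seed=9)
        p2, n2 = random_tad_null(chrom_sizes, 3, peaks, sig, seed=9)
        assert p1 == p2 and np.array_equal(n1, n2)

    def test_genome_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            random_tad_null({"chr1": 100_000}, 1, pd.DataFrame(columns=["chrom", "start", "end", "name", "score"]), track([1.0]), seed=0)


class TestStateChanges:
    def annotated(self, states):
        t = tads([(k * 1000, (k + 1) * 1000) for k in range(len(states))])
        t = t.copy()
        t["state"] = states
        return t

    def test_identical_annotations_no_change(self):
        a = self.annotated(["H3K36me3"] * 5 + ["H3K27me3"] * 5)
        per_tad, summary, fisher = detect_state_changes(a[["chrom", "start", "end"]], a, a.copy())
        assert per_tad["changed"].sum() == 0
        assert (summary["fraction_changed"] == 0).all()
        assert (fisher["p"] == 1.0).all()

    def test_toy_fisher_table(self):
        # group A: 8/10 changed; group B: 2/10 changed -> Fisher p ~ 0.023
        normal = self.annotated(["H3K9me3"] * 10 + ["H3K27me3"] * 10)
        cancer_states = (
            ["other"] * 8 + ["H3K9me3"] * 2 + ["other"] * 2 + ["H3K27me3"] * 8
        )
        cancer = self.annotated(cancer_states)
        _, summary, fisher = detect_state_changes(
            normal[["chrom", "start", "end"]], normal, cancer
        )
        assert len(fisher) == 1
        assert fisher.iloc[0]["p"] == pytest.approx(0.023, abs=5e-4)

    def test_planted_flips_detected(self):
        """Ground-truth state flips in common TADs are all flagged, with
        direction recorded."""
        from hic3state.simulate import SimulationConfig, make_ground_truth

        truth = make_ground_truth(SimulationConfig(seed=2))
        normal = truth.tads["normal"]
        cancer = truth.tads["cancerA"]
        split = set(zip(truth.split_parents["chrom"], truth.split_parents["start"]))
        common = normal[
            ~normal.apply(lambda r: (r["chrom"], r["start"]) in split, axis=1)
        ][["chrom", "start", "end"]]
        ann_n = common.merge(normal, on=["chrom", "start", "end"])
        ann_c = common.merge(cancer, on=["chrom", "start", "end"])
        per_tad, _, _ = detect_state_changes(common, ann_n, ann_c)
        planted = (ann_n["state"] != ann_c["state"]).to_numpy()
        assert planted.sum() > 0  # the generator planted at least one flip
        assert np.array_equal(per_tad["changed"].to_numpy(), planted)
        flipped = per_tad[per_tad["changed"]]
        assert (flipped["state_normal"] == "H3K27me3").all()
        assert (flipped["state_cancer"] == "H3K36me3").all()


def test_count_enriched_matches_classify():
    t = tads([(k * 1000, (k + 1) * 1000) for k in range(8)])
    peaks = pd.DataFrame([peak("chr1", 100, 200, 9.0)])
    sig = track([5.0] + [0.5] * 7, width=1000)
    assert count_enriched(t, peaks, sig) == 1
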