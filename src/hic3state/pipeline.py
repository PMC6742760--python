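"""End-to-end orchestration: normalize -> TADs -> states -> loops -> anchors
-> specificity classes -> expression links, per cell line and across the
normal / cancer-1 / cancer-2 comparison.

The run is fully deterministic under (config, seed): every resampling stage
draws from a named substream of the root seed.  All tabular outputs are
written as TSV/BED/BEDPE with fixed float formatting; a run manifest logs
parameters, per-stage counts and wall times.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr_mod
from . import genome_io, loops as loops_mod, normalization, tad_states, tads as tads_mod
from .simulate import (
    GroundTruth,
    SimulationConfig,
    make_ground_truth,
    simulate_annotations,
    simulate_contact_matrix,
    simulate_expression,
)

_FLOAT_FMT = "%.6g"

MARKS = ("H3K36me3", "H3K27me3", "H3K9me3", "H3K27ac")


@dataclass
class RunConfig:
    """All analysis parameters (defaults are the study's stated values)."""

    fine_resolution: int = 10_000
    coarse_resolution: int = 40_000
    ice_tol: float = 1e-4
    ice_max_iter: int = 200
    low_coverage_filter: float = 0.02
    loop_q_cutoff: float = 0.05
    loop_min_dist: int = 50_000
    loop_max_dist: int = 10_000_000
    tad_window: int = 5
    tad_p_cutoff: float = 0.05
    match_tol_bp: int = 80_000
    match_min_overlap: float = 0.8
    top_n_state_peaks: int = 30_000
    state_quantile: float = 0.75
    enhancer_top_n: int = 25_000
    insulator_top_n: int = 50_000
    ndr_top_n: int = 50_000
    expressed_threshold: float = 1.5
    fc_cutoff: float = 2.0
    alpha: float = 0.05
    n_shuffles: int = 100
    random_tad_size_range: tuple[int, int] = (280_000, 440_000)
    scale_random_tad_sizes: bool = True
    seed: int = 0
    simulation: SimulationConfig | None = field(default=None)

    @classmethod
    def synthetic(cls, seed: int = 0, **kwargs) -> "RunConfig":
        sim = SimulationConfig(seed=seed)
        return cls(seed=seed, simulation=sim, **kwargs)


@dataclass
class CellLineData:
    """In-memory inputs of one cell line."""

    name: str
    matrix: genome_io.ContactMatrix           # fine-resolution raw counts
    peaks: dict[str, pd.DataFrame]
    signal_tracks: dict[str, pd.DataFrame]
    ctcf_peaks: pd.DataFrame
    ndrs: pd.DataFrame
    tf_peaks: pd.DataFrame


def _write(df: pd.DataFrame, path: Path, header: bool = True) -> None:
    df.to_csv(path, sep="\t", index=False, header=header, float_format=_FLOAT_FMT)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def synthetic_inputs(
    sim: SimulationConfig,
) -> tuple[dict[str, CellLineData], pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate per-line inputs, the gene table and expression in memory."""
    truth = make_ground_truth(sim)
    expr = simulate_expression(sim, truth)
    genes = truth.genes.drop(columns=["expressed", "upregulated"])
    lines = {}
    for cond in sim.conditions:
        ann = simulate_annotations(sim, truth, cond)
        lines[cond] = CellLineData(
            name=cond,
            matrix=simulate_contact_matrix(sim, truth, cond),
            peaks=ann.peaks,
            signal_tracks=ann.signal_tracks,
            ctcf_peaks=ann.ctcf_peaks,
            ndrs=ann.ndrs,
            tf_peaks=ann.tf_peaks,
        )
    return lines, genes, expr, truth


def run_pipeline(
    config: RunConfig,
    outdir,
    lines: dict[str, CellLineData] | None = None,
    genes: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
) -> dict:
    """Run the full study flow and write all result tables under ``outdir``.

    Without explicit inputs a synthetic dataset is generated from
    ``config.simulation``.  Returns a results dictionary (also serialized in
    the run manifest)."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _config_dict(config), "stages": {}, "outputs": []}

    if lines is None:
        if config.simulation is None:
            raise ValueError("no inputs given and no simulation configured")
        lines, genes, expression, truth = synthetic_inputs(config.simulation)
    if genes is None or expression is None:
        raise ValueError("gene table and expression are required")
    line_names = list(lines)
    if len(line_names) != 3:
        raise ValueError("the three-way comparison needs exactly 3 cell lines")
    normal_name, cancer1, cancer2 = line_names

    def log_stage(name: str, t_start: float, **counts) -> None:
        manifest["stages"][name] = {
            "seconds": round(time.time() - t_start, 3), **counts
        }

    # ---- per line: normalize, decay, loops, TADs -----------------------
    per_line: dict[str, dict] = {}
    expr_cols = {
        ln: [c for c in expression.columns if c.startswith(f"{ln}_")] for ln in line_names
    }
    for name, data in lines.items():
        t = time.time()
        fine_norm, bias = normalization.ice_normalize(
            data.matrix, max_iter=config.ice_max_iter, tol=config.ice_tol,
            low_coverage_filter=config.low_coverage_filter,
        )
        decay = normalization.estimate_decay(
            fine_norm, min_dist=config.loop_min_dist, max_dist=config.loop_max_dist
        )
        called = loops_mod.call_significant_loops(
            fine_norm, decay, q_cutoff=config.loop_q_cutoff,
            min_dist=config.loop_min_dist, max_dist=config.loop_max_dist,
        )
        factor = config.coarse_resolution // config.fine_resolution
        coarse_raw = normalization.coarsen(data.matrix, factor)
        coarse_norm, coarse_bias = normalization.ice_normalize(
            coarse_raw, max_iter=config.ice_max_iter, tol=config.ice_tol,
            low_coverage_filter=config.low_coverage_filter,
        )
        coarse_masked = {
            chrom: np.flatnonzero(
                ~np.isfinite(coarse_bias[slice(*coarse_norm.bins.bin_range(chrom))])
            )
            for chrom in coarse_norm.bins.chroms
        }
        tad_calls = tads_mod.call_tads(
            coarse_norm,
            tads_mod.TopDomParams(config.tad_window, config.tad_p_cutoff),
            cell_line=name,
        )
        reg = loops_mod.build_regulatory_sets(
            genes, expression[expr_cols[name]],
            data.peaks["H3K27ac"], data.ctcf_peaks,
            expressed_threshold=config.expressed_threshold,
            enhancer_top_n=config.enhancer_top_n,
            insulator_top_n=config.insulator_top_n,
        )
        annotated, ranking = loops_mod.annotate_anchors(called, reg)
        states = tad_states.classify_tad_states(
            tad_calls, {m: data.peaks[m] for m in MARKS},
            data.signal_tracks,
            top_n=config.top_n_state_peaks, quantile=config.state_quantile,
        )
        states["gene_density_class"] = tad_states.gene_density_class(tad_calls, genes)
        states["cell_line"] = name
        per_line[name] = {
            "bias": bias,
            "decay": decay,
            "matrix_norm": fine_norm,
            "matrix_raw": data.matrix,
            "loops": annotated,
            "ranking": ranking,
            "tads": tad_calls,
            "states": states,
            "reg": reg,
            "coarse_masked": coarse_masked,
        }
        _write(annotated, outdir / f"loops_{name}.tsv")
        genome_io.write_loops_bedpe(annotated, outdir / f"loops_{name}.bedpe")
        _write(tad_calls, outdir / f"tads_{name}.bed", header=False)
        _write(states, outdir / f"tad_states_{name}.tsv")
        _write(loops_mod.top_categories(ranking), outdir / f"loop_categories_{name}.tsv")
        _write(
            loops_mod.loop_fate_fractions(reg, annotated),
            outdir / f"loop_fates_{name}.tsv",
        )
        log_stage(
            f"line:{name}", t,
            n_loops=len(annotated), n_tads=len(tad_calls),
            n_masked_bins=int(np.isnan(bias).sum()),
        )

    # ---- three-way TAD comparison --------------------------------------
    t = time.time()
    classification = tads_mod.match_tads(
        per_line[normal_name]["tads"], per_line[cancer1]["tads"], per_line[cancer2]["tads"],
        tol_bp=config.match_tol_bp, min_overlap=config.match_min_overlap,
        line_names=(normal_name, cancer1, cancer2),
    )
    size_report = tads_mod.compare_tad_sizes(classification)
    splits = tads_mod.detect_split_tads(
        per_line[normal_name]["tads"], per_line[cancer1]["tads"],
        min_overlap=config.match_min_overlap,
    )
    _write(classification.labels, outdir / "tad_classification.tsv")
    _write(size_report, outdir / "tad_size_tests.tsv")
    _write(splits, outdir / "tad_splits.tsv")
    log_stage("tad_comparison", t, **{k: int(v) for k, v in classification.counts.items()})

    # ---- common-TAD state changes (normal vs each cancer line) ---------
    t = time.time()
    common_normal = classification.of_line(normal_name)
    common_normal = common_normal[common_normal["label"] == "common"][["chrom", "start", "end"]]
    de = expr_mod.differential_expression(
        expression, expr_cols[cancer1], expr_cols[normal_name],
        fc_cutoff=config.fc_cutoff, alpha=config.alpha,
    )
    de.insert(0, "gene_id", de.index)
    fold_changes = pd.Series(
        de["log2_fold_change"].to_numpy(), index=de["gene_id"].to_numpy()
    )
    state_change_results = {}
    for cancer in (cancer1, cancer2):
        ann_n = tad_states.classify_tad_states(
            common_normal, {m: lines[normal_name].peaks[m] for m in MARKS},
            lines[normal_name].signal_tracks,
            top_n=config.top_n_state_peaks, quantile=config.state_quantile,
        )
        ann_c = tad_states.classify_tad_states(
            common_normal, {m: lines[cancer].peaks[m] for m in MARKS},
            lines[cancer].signal_tracks,
            top_n=config.top_n_state_peaks, quantile=config.state_quantile,
        )
        changes, summary, fisher = tad_states.detect_state_changes(
            common_normal, ann_n, ann_c, genes=genes, fold_changes=fold_changes
        )
        _write(changes, outdir / f"state_changes_{cancer}.tsv")
        _write(summary, outdir / f"state_change_summary_{cancer}.tsv")
        _write(fisher, outdir / f"state_change_tests_{cancer}.tsv")
        state_change_results[cancer] = summary
    log_stage("state_changes", t, n_common_tads=len(common_normal))

    # ---- E-P loop specificity and differential tests --------------------
    t = time.time()
    loops_by_line = {n: per_line[n]["loops"] for n in line_names}
    ep_classes = loops_mod.classify_ep_loops(
        loops_by_line, normal=normal_name, cancers=(cancer1, cancer2)
    )
    for cls, df in ep_classes.items():
        _write(df, outdir / f"ep_loops_{cls}.tsv")

    # differential E-P loop test: union of E-P pairs, each cancer line vs normal
    ep_union = pd.concat(
        [df[df["category"] == "PE"] for df in loops_by_line.values()],
        ignore_index=True,
    )[loops_mod.LOOP_KEY].drop_duplicates().reset_index(drop=True)
    raw_counts = {}
    totals = {}
    for name in line_names:
        raw = per_line[name]["matrix_raw"]
        counts = np.zeros(len(ep_union), dtype=np.int64)
        total = 0
        min_bins = max(1, -(-config.loop_min_dist // config.fine_resolution))
        max_bins = config.loop_max_dist // config.fine_resolution
        lut: dict[tuple, int] = {}
        for chrom in raw.bins.chroms:
            r, c, v = raw.chrom_entries(chrom)
            d = c - r
            sel = (d >= min_bins) & (d <= max_bins)
            total += int(v[sel].sum())
            for rr, cc, vv in zip(r[sel], c[sel], v[sel]):
                lut[(chrom, int(rr), int(cc))] = int(vv)
        for i, key in enumerate(zip(ep_union["chrom"], ep_union["bin1"], ep_union["bin2"])):
            counts[i] = lut.get((key[0], int(key[1]), int(key[2])), 0)
        raw_counts[name] = counts
        totals[name] = total
    diff = ep_union.copy()
    for cancer in (cancer1, cancer2):
        res = loops_mod.differential_loop_test(
            raw_counts[cancer], totals[cancer],
            raw_counts[normal_name], totals[normal_name],
        )
        diff[f"count_{cancer}"] = raw_counts[cancer]
        diff[f"odds_ratio_{cancer}"] = res["odds_ratio"].to_numpy()
        diff[f"p_{cancer}"] = res["p"].to_numpy()
        diff[f"q_{cancer}"] = res["q"].to_numpy()
    diff[f"count_{normal_name}"] = raw_counts[normal_name]
    diff["significant"] = (
        (diff[f"q_{cancer1}"] < config.alpha) & (diff[f"q_{cancer2}"] < config.alpha)
    )
    _write(diff, outdir / "differential_ep_loops.tsv")
    log_stage(
        "ep_loops", t,
        **{f"n_{k}": len(v) for k, v in ep_classes.items()},
        n_differential=int(diff["significant"].sum()),
    )

    # ---- anchor shuffle null on chr1 ------------------------------------
    t = time.time()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    chrom_sizes = lines[normal_name].matrix.bins.chrom_sizes
    shuffle_reports = {}
    for name in line_names:
        try:
            rep = loops_mod.shuffle_anchor_null(
                per_line[name]["loops"], per_line[name]["reg"],
                chrom_length=chrom_sizes["chr1"], n=config.n_shuffles,
                chrom="chr1", anchor_size=config.fine_resolution, seed=rng,
            )
        except ValueError:
            continue
        rep.insert(0, "cell_line", name)
        shuffle_reports[name] = rep
    if shuffle_reports:
        _write(pd.concat(shuffle_reports.values(), ignore_index=True),
               outdir / "anchor_shuffle_null.tsv")
    log_stage("anchor_shuffle", t)

    # ---- random-TAD empirical null (H3K36me3) ---------------------------
    t = time.time()
    states_n = per_line[normal_name]["states"]
    observed = int(states_n["H3K36me3_enriched"].sum())
    size_range = config.random_tad_size_range
    if config.scale_random_tad_sizes and observed > 0:
        enriched = states_n[states_n["H3K36me3_enriched"]]
        mean_size = float((enriched["end"] - enriched["start"]).mean())
        size_range = (int(mean_size * 280 / 350), int(mean_size * 440 / 350))
    p_rand, null_counts = tad_states.random_tad_null(
        chrom_sizes, observed,
        lines[normal_name].peaks["H3K36me3"], lines[normal_name].signal_tracks["H3K36me3"],
        n_sets=config.n_shuffles, size_range=size_range,
        top_n=config.top_n_state_peaks, quantile=config.state_quantile,
        seed=np.random.default_rng(np.random.SeedSequence([config.seed, 103])),
    )
    pd.DataFrame(
        {
            "observed_enriched": [observed],
            "null_mean": [float(null_counts.mean())],
            "empirical_p": [p_rand],
            "size_range_lo": [size_range[0]],
            "size_range_hi": [size_range[1]],
        }
    ).pipe(_write, outdir / "random_tad_null.tsv")
    log_stage("random_tad_null", t, observed=observed)

    # ---- expression ------------------------------------------------------
    t = time.time()
    _write(de, outdir / "differential_expression.tsv")
    gene_sets: dict[str, set] = {}
    fine = config.fine_resolution
    for cls, df in ep_classes.items():
        ids = set()
        for _, r in df.iterrows():
            for a in (1, 2):
                if r[f"anchor{a}_label"] == "P":
                    astart, aend = int(r[f"start{a}"]), int(r[f"end{a}"])
                    sel = genes[
                        (genes["chrom"] == r["chrom"])
                        & (genes["tss"] + 2000 > astart)
                        & (genes["tss"] - 2000 < aend)
                    ]
                    ids.update(sel["gene_id"].astype(str))
        gene_sets[cls] = ids
    all_in_sets = set().union(*gene_sets.values()) if gene_sets else set()
    gene_sets["background"] = set(genes["gene_id"].astype(str)) - all_in_sets
    usable = {k: v for k, v in gene_sets.items() if len(v) >= 2}
    pairs = [
        (a, "background") for a in ("cancer_specific", "normal_specific", "common")
        if a in usable and "background" in usable
    ]
    if pairs:
        gs_report = expr_mod.compare_gene_set_table(fold_changes, usable, pairs)
        _write(gs_report, outdir / "ep_gene_set_tests.tsv")
    else:
        gs_report = pd.DataFrame()
    log_stage("expression", t, n_de_up=int(de["up"].sum()))

    # ---- TF-bound looped enhancers (cancer-specific, line cancer1) ------
    t = time.time()
    frac, bound_enh, target_genes = loops_mod.tf_bound_looped_enhancers(
        ep_classes["cancer_specific"], per_line[cancer1]["reg"],
        lines[cancer1].tf_peaks, genes=genes,
    )
    pd.DataFrame(
        {"bound_fraction": [frac], "n_bound": [len(bound_enh)],
         "target_genes": [";".join(target_genes)]}
    ).pipe(_write, outdir / "tf_bound_enhancers.tsv")
    log_stage("tf_enhancers", t, bound_fraction=frac)

    # ---- ground-truth comparison (synthetic runs) ------------------------
    results = {
        "n_tads": {n: len(per_line[n]["tads"]) for n in line_names},
        "tad_classes": {k: int(v) for k, v in classification.counts.items()},
        "n_loops": {n: len(per_line[n]["loops"]) for n in line_names},
        "ep_classes": {k: len(v) for k, v in ep_classes.items()},
        "tf_bound_fraction": frac,
    }
    if truth is not None:
        results["truth_comparison"] = _truth_comparison(
            config, per_line, ep_classes, truth, normal_name, (cancer1, cancer2)
        )
        with open(outdir / "truth_comparison.json", "w") as fh:
            json.dump(results["truth_comparison"], fh, indent=1)

    manifest["outputs"] = sorted(
        {p.name: _checksum(p) for p in outdir.iterdir() if p.suffix in (".tsv", ".bed", ".bedpe")}.items()
    )
    manifest["total_seconds"] = round(time.time() - t0, 3)
    manifest["results"] = {
        k: v for k, v in results.items() if k != "truth_comparison"
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["gene_set_report"] = gs_report
    results["state_change_summaries"] = state_change_results
    return results


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if config.simulation is not None:
        d["simulation"] = asdict(config.simulation)
    return d


def boundary_recovery(
    called: pd.DataFrame,
    truth_boundaries: pd.DataFrame,
    resolution: int,
    tol_bins: int = 1,
    masked_bins: dict[str, np.ndarray] | None = None,
) -> tuple[float, float]:
    """(fraction of planted boundaries recovered within +-tol bins,
    fraction of called boundaries not near any planted one).

    Domain edges abutting a masked (low-coverage) bin are coverage
    artifacts, not boundary claims, and are excluded from the spurious
    count when ``masked_bins`` (chromosome-local bin indices) is given."""
    recovered = 0
    called_pts: dict[str, np.ndarray] = {}
    for chrom, sub in called.groupby("chrom", sort=False):
        pts = np.asarray(sorted(set(sub["start"]) | set(sub["end"]))[1:-1], dtype=np.int64)
        if masked_bins is not None and chrom in masked_bins and len(pts):
            bad = np.zeros(len(pts), dtype=bool)
            mset = set(int(b) for b in masked_bins[chrom])
            for k, p in enumerate(pts):
                b = int(p) // resolution
                bad[k] = (b in mset) or (b - 1 in mset)
            pts = pts[~bad]
        called_pts[chrom] = pts
    truth_by_chrom = {}
    for chrom, sub in truth_boundaries.groupby("chrom", sort=False):
        tpos = np.sort(sub["pos"].to_numpy())
        if masked_bins is not None and chrom in masked_bins and len(tpos):
            mset = set(int(b) for b in masked_bins[chrom])
            observable = np.array(
                [
                    int(p) // resolution not in mset
                    and int(p) // resolution - 1 not in mset
                    for p in tpos
                ]
            )
            tpos = tpos[observable]
        truth_by_chrom[chrom] = tpos
    n_truth = sum(len(v) for v in truth_by_chrom.values())
    tol = tol_bins * resolution
    for chrom, tpos in truth_by_chrom.items():
        cpos = called_pts.get(chrom, np.empty(0, dtype=np.int64))
        for p in tpos:
            if cpos.size and np.abs(cpos - p).min() <= tol:
                recovered += 1
    n_called = sum(len(v) for v in called_pts.values())
    spurious = 0
    for chrom, cpos in called_pts.items():
        tpos = truth_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        for p in cpos:
            if not (tpos.size and np.abs(tpos - p).min() <= tol):
                spurious += 1
    return (
        recovered / n_truth if n_truth else float("nan"),
        spurious / n_called if n_called else 0.0,
    )


def _truth_comparison(
    config: RunConfig,
    per_line: dict[str, dict],
    ep_classes: dict[str, pd.DataFrame],
    truth: GroundTruth,
    normal_name: str,
    cancers: tuple[str, str],
) -> dict:
    out: dict = {}
    # TAD boundary recovery per line
    for name in per_line:
        cond = name if name in truth.tads else normal_name
        rec, spur = boundary_recovery(
            per_line[name]["tads"], truth.boundaries(cond), config.coarse_resolution,
            masked_bins=per_line[name]["coarse_masked"],
        )
        out[f"boundary_recovery_{name}"] = round(rec, 4)
        out[f"boundary_spurious_{name}"] = round(spur, 4)
    # planted-loop recovery per line and loop-call FDR
    for name in per_line:
        cond_loops = truth.loops_of(name if name in truth.tads else normal_name)
        planted = set(zip(cond_loops["chrom"], cond_loops["bin1"], cond_loops["bin2"]))
        called = set(
            zip(
                per_line[name]["loops"]["chrom"],
                per_line[name]["loops"]["bin1"],
                per_line[name]["loops"]["bin2"],
            )
        )
        hits = len(planted & called)
        out[f"loop_recovery_{name}"] = round(hits / len(planted), 4) if planted else None
        out[f"loop_fdr_{name}"] = (
            round(1 - len(planted & called) / len(called), 4) if called else 0.0
        )
    # cancer-specific E-P classification sensitivity
    cs_truth = truth.loops[truth.loops["class"] == "cancer_specific"]
    cs_keys = set(zip(cs_truth["chrom"], cs_truth["bin1"], cs_truth["bin2"]))
    found = set(
        zip(
            ep_classes["cancer_specific"]["chrom"],
            ep_classes["cancer_specific"]["bin1"],
            ep_classes["cancer_specific"]["bin2"],
        )
    )
    ns_found = set(
        zip(
            ep_classes["normal_specific"]["chrom"],
            ep_classes["normal_specific"]["bin1"],
            ep_classes["normal_specific"]["bin2"],
        )
    )
    out["ep_cancer_specific_sensitivity"] = (
        round(len(cs_keys & found) / len(cs_keys), 4) if cs_keys else None
    )
    out["ep_cancer_as_normal_mislabels"] = len(cs_keys & ns_found)
    return out
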