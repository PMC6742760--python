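"""Histone-mark TAD-state annotation, gene-density classes, random-TAD
empirical nulls and state-change detection.

A TAD counts as enriched for a mark when it intersects at least one top-N
peak of that mark (rank by score, top-N capped at 25% of the peak set) AND
its mean signal lies at or above the 75th percentile of per-TAD means for
that mark.  The state label applies the precedence H3K36me3 > H3K27me3 >
H3K9me3 when several marks are enriched; TADs with no enriched mark are
'other'.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from ._intervals import overlap_counts, points_in_intervals
from .stats import bh_adjust, empirical_p, fisher_test

STATE_PRECEDENCE = ("H3K36me3", "H3K27me3", "H3K9me3")


def mean_signal_per_tad(tads: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Length-weighted mean of a binned signal track over each TAD.

    ``track`` holds fixed-width bins (chrom, start, end, value).  Partial
    overlaps are weighted by covered bp; TADs with no coverage get mean 0
    and ``no_coverage=True``.
    """
    means = np.zeros(len(tads))
    flags = np.ones(len(tads), dtype=bool)
    for chrom, idx in tads.groupby("chrom", sort=False).indices.items():
        sub = track[track["chrom"] == chrom].sort_values("start")
        if sub.empty:
            continue
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=np.float64)
        cum = np.concatenate(([0.0], np.cumsum(vals * (ends - starts))))
        for k in idx:
            s = int(tads.iloc[k]["start"])
            e = int(tads.iloc[k]["end"])
            i0 = np.searchsorted(ends, s, side="right")
            i1 = np.searchsorted(starts, e, side="left")
            if i1 <= i0:
                continue
            total = cum[i1] - cum[i0]
            covered = float((np.minimum(ends[i0:i1], e) - np.maximum(starts[i0:i1], s)).sum())
            # correct the first/last partially covered bins
            total -= vals[i0] * max(0, s - starts[i0])
            total -= vals[i1 - 1] * max(0, ends[i1 - 1] - e)
            if covered > 0:
                means[k] = total / covered
                flags[k] = False
    out = tads[["chrom", "start", "end"]].copy().reset_index(drop=True)
    out["mean_signal"] = means
    out["no_coverage"] = flags
    return out


def top_peaks(peaks: pd.DataFrame, top_n: int = 30_000, fraction: float = 0.25) -> pd.DataFrame:
    """Rank peaks by score (desc, ties by coordinate) and keep
    min(top_n, ceil(fraction * total))."""
    if peaks.empty:
        return peaks
    k = min(top_n, math.ceil(fraction * len(peaks)))
    ordered = peaks.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.head(k).reset_index(drop=True)


def classify_tad_states(
    tads: pd.DataFrame,
    peak_sets: dict[str, pd.DataFrame],
    signal_tracks: dict[str, pd.DataFrame],
    top_n: int = 30_000,
    quantile: float = 0.75,
) -> pd.DataFrame:
    """Per-TAD mark enrichment flags and the precedence state label."""
    out = tads[["chrom", "start", "end"]].copy().reset_index(drop=True)
    marks = list(peak_sets)
    for mark in marks:
        import warnings as _warnings

        peaks = peak_sets[mark]
        if len(peaks) < top_n:
            _warnings.warn(f"{mark}: fewer peaks ({len(peaks)}) than top_n; using 25% rule")
        tops = top_peaks(peaks, top_n=top_n)
        out[f"{mark}_peaks"] = overlap_counts(out, tops)
        ms = mean_signal_per_tad(out, signal_tracks[mark])["mean_signal"]
        out[f"{mark}_mean_signal"] = ms.to_numpy()
        thresh = float(np.quantile(ms, quantile)) if len(ms) else np.inf
        out[f"{mark}_enriched"] = (out[f"{mark}_peaks"] >= 1) & (ms.to_numpy() >= thresh)
    state = np.full(len(out), "other", dtype=object)
    for mark in reversed([m for m in STATE_PRECEDENCE if m in marks]):
        state[out[f"{mark}_enriched"].to_numpy()] = mark
    out["state"] = state
    return out


def gene_density_class(tads: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """desert (0 genes), poor (1-5) or enriched (>5); a gene belongs to the
    TAD containing its TSS."""
    tads = tads.reset_index(drop=True)
    hit = points_in_intervals(
        genes["chrom"].to_numpy(), genes["tss"].to_numpy(), tads
    )
    counts = np.zeros(len(tads), dtype=np.int64)
    for h in hit:
        if h >= 0:
            counts[h] += 1
    labels = np.where(counts == 0, "desert", np.where(counts <= 5, "poor", "enriched"))
    return pd.Series(labels, index=tads.index, name="gene_density_class")


def random_tad_sets(
    chrom_sizes: dict[str, int],
    n_sets: int,
    size_range: tuple[int, int],
    rng: np.random.Generator,
) -> list[pd.DataFrame]:
    """Random non-overlapping TAD-like interval sets tiling each chromosome
    with sizes uniform in ``size_range``."""
    lo, hi = size_range
    if min(chrom_sizes.values()) < hi:
        raise ValueError("genome too small for the requested TAD size range")
    sets = []
    for _ in range(n_sets):
        rows = []
        for chrom, length in chrom_sizes.items():
            pos = 0
            while True:
                size = int(rng.integers(lo, hi + 1))
                if pos + size > length:
                    break
                rows.append({"chrom": chrom, "start": pos, "end": pos + size})
                pos += size
        sets.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return sets


def count_enriched(
    tads: pd.DataFrame,
    peaks: pd.DataFrame,
    track: pd.DataFrame,
    top_n: int = 30_000,
    quantile: float = 0.75,
) -> int:
    """Enriched-TAD count for a single mark under the standard rule."""
    ann = classify_tad_states(tads, {"mark": peaks}, {"mark": track}, top_n=top_n, quantile=quantile)
    return int(ann["mark_enriched"].sum())


def random_tad_null(
    chrom_sizes: dict[str, int],
    observed_count: int,
    peaks: pd.DataFrame,
    track: pd.DataFrame,
    n_sets: int = 100,
    size_range: tuple[int, int] = (280_000, 440_000),
    top_n: int = 30_000,
    quantile: float = 0.75,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Empirical p for the observed enriched-TAD count against random TAD
    sets; add-one convention (1 + #{null >= obs}) / (n_sets + 1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_counts = np.array(
        [
            count_enriched(s, peaks, track, top_n=top_n, quantile=quantile)
            for s in random_tad_sets(chrom_sizes, n_sets, size_range, rng)
        ]
    )
    return empirical_p(observed_count, null_counts), null_counts


def detect_state_changes(
    common_tads: pd.DataFrame,
    annotations_normal: pd.DataFrame,
    annotations_cancer: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    fold_changes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """State changes of common TADs between conditions.

    Returns (per-TAD change table, per-initial-state summary with fraction
    changed, pairwise Fisher report with BH-adjusted p)."""
    key = ["chrom", "start", "end"]
    merged = common_tads[key].merge(
        annotations_normal[key + ["state"]], on=key
    ).merge(
        annotations_cancer[key + ["state"]], on=key, suffixes=("_normal", "_cancer")
    )
    merged["changed"] = merged["state_normal"] != merged["state_cancer"]
    if genes is not None:
        tad_of = points_in_intervals(
            genes["chrom"].to_numpy(), genes["tss"].to_numpy(), merged
        )
        gene_lists = [[] for _ in range(len(merged))]
        for g, t in zip(genes["gene_id"], tad_of):
            if t >= 0:
                gene_lists[t].append(str(g))
        merged["genes"] = [";".join(gs) for gs in gene_lists]
        if fold_changes is not None:
            fc = fold_changes.to_dict()
            merged["median_gene_log2fc"] = [
                float(np.median([fc[g] for g in gs.split(";") if g in fc]))
                if any(g in fc for g in gs.split(";")) else np.nan
                for gs in merged["genes"]
            ]

    summary_rows = []
    for state, sub in merged.groupby("state_normal", sort=True):
        summary_rows.append(
            {
                "initial_state": state,
                "n": len(sub),
                "n_changed": int(sub["changed"].sum()),
                "fraction_changed": float(sub["changed"].mean()),
            }
        )
    summary = pd.DataFrame(
        summary_rows, columns=["initial_state", "n", "n_changed", "fraction_changed"]
    )

    fisher_rows = []
    for a, b in combinations(summary["initial_state"], 2):
        ra = summary[summary["initial_state"] == a].iloc[0]
        rb = summary[summary["initial_state"] == b].iloc[0]
        if ra["n"] == 0 or rb["n"] == 0:
            continue
        odds, p = fisher_test(
            [
                [int(ra["n_changed"]), int(ra["n"] - ra["n_changed"])],
                [int(rb["n_changed"]), int(rb["n"] - rb["n_changed"])],
            ]
        )
        fisher_rows.append(
            {"group_a": a, "group_b": b, "odds_ratio": odds, "p": p}
        )
    fisher = pd.DataFrame(fisher_rows, columns=["group_a", "group_b", "odds_ratio", "p"])
    if len(fisher):
        fisher["adj_p"] = bh_adjust(fisher["p"].to_numpy())
    else:
        fisher["adj_p"] = []
    return merged, summary, fisher
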