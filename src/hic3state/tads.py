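"""TAD calling on 40 kb matrices and cross-cell-line TAD comparison.

The caller follows the diamond-statistic scheme popularized by TopDom: a
per-bin boundary signal (mean of the w x w diamond spanning the putative
boundary), local-minimum candidate detection against a local linear trend,
and a one-sided rank-sum test of cross-boundary vs within-side contacts.

Cross-line comparison uses the study's matching rule: two TADs overlap when
both boundaries agree within ``tol_bp`` (80 kb, i.e. two 40 kb bins) or when
they reciprocally overlap at least ``min_overlap`` (80%) of both lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genome_io import ContactMatrix
from .stats import bh_adjust, rank_sum_test
from scipy import stats as sps

TAD_COLUMNS = ["chrom", "start", "end", "cell_line"]


@dataclass
class TopDomParams:
    window: int = 5          # w, in bins
    p_cutoff: float = 0.05   # boundary rank-sum cutoff

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2 bins")


def _bin_signal(a: np.ndarray, w: int) -> np.ndarray:
    """signal[i] = mean of the diamond between bins (i-w+1..i) and (i+1..i+w),
    truncated at the segment edges.  Defined for i = 0..n-2."""
    n = a.shape[0]
    s = np.empty(max(n - 1, 0))
    for i in range(n - 1):
        up = slice(max(0, i - w + 1), i + 1)
        down = slice(i + 1, min(n, i + w + 1))
        s[i] = a[up, down].mean()
    return s


def _candidate_minima(signal: np.ndarray, w: int) -> list[int]:
    """Local minima of the boundary signal, judged against a least-squares
    linear trend over +-w positions; ties are not candidates (the strict
    trend inequality rejects flat signal)."""
    cands = []
    n = len(signal)
    for i in range(n):
        lo, hi = max(0, i - w), min(n, i + w + 1)
        window = signal[lo:hi]
        if len(window) < 3 or signal[i] > window.min():
            continue
        xs = np.arange(lo, hi, dtype=np.float64)
        xc = xs - xs.mean()
        denom = (xc ** 2).sum()
        if denom == 0:
            continue
        slope = (xc * (window - window.mean())).sum() / denom
        trend_i = window.mean() + slope * (i - xs.mean())
        if signal[i] < trend_i:
            cands.append(i)
    return cands


def _observed_expected(a: np.ndarray) -> np.ndarray:
    """Divide every entry by the segment's mean count at its bin distance.
    The boundary rank-sum runs on these values: cross-boundary entries sit
    at larger distances than within-side ones, so on raw counts distance
    decay alone would make the one-sided test fire at every candidate."""
    n = a.shape[0]
    oe = np.zeros_like(a)
    for d in range(n):
        diag = np.diagonal(a, offset=d)
        mu = diag.mean()
        if mu > 0:
            idx = np.arange(n - d)
            oe[idx, idx + d] = diag / mu
            oe[idx + d, idx] = oe[idx, idx + d]
    return oe


def _boundary_p(a: np.ndarray, i: int, w: int) -> float:
    """One-sided rank-sum p for boundary after bin i: cross-boundary diamond
    entries vs pooled within-side upper-triangle entries (both on the
    observed/expected scale)."""
    n = a.shape[0]
    up = np.arange(max(0, i - w + 1), i + 1)
    down = np.arange(i + 1, min(n, i + w + 1))
    cross = a[np.ix_(up, down)].ravel()
    within_parts = []
    for side in (up, down):
        if len(side) >= 2:
            sub = a[np.ix_(side, side)]
            iu = np.triu_indices(len(side), k=1)
            within_parts.append(sub[iu])
    if not within_parts or len(cross) == 0:
        return 1.0
    within = np.concatenate(within_parts)
    if np.ptp(np.concatenate([cross, within])) == 0:
        return 1.0
    res = sps.mannwhitneyu(cross, within, alternative="less", method="asymptotic")
    return float(res.pvalue)


def call_tads(
    matrix: ContactMatrix,
    params: TopDomParams | None = None,
    cell_line: str | None = None,
) -> pd.DataFrame:
    """Call TADs per chromosome from a normalized coarse matrix.

    Masked (low-coverage) bins break the chromosome into segments that are
    processed independently; domains of fewer than 2 bins are dropped.
    """
    params = params or TopDomParams()
    w = params.window
    res = matrix.bins.resolution
    valid = matrix.valid_bins()
    rows = []
    for chrom in matrix.bins.chroms:
        lo, hi = matrix.bins.bin_range(chrom)
        if hi - lo < 2 * w:
            warnings.warn(f"chromosome {chrom} shorter than 2w bins; no TADs called")
            continue
        dense = matrix.dense_chrom(chrom)
        v = valid[lo:hi]
        # contiguous unmasked segments
        edges = np.flatnonzero(np.diff(np.concatenate(([0], v.view(np.int8), [0]))))
        for seg_start, seg_end in zip(edges[::2], edges[1::2]):
            n_seg = seg_end - seg_start
            if n_seg < 2:
                continue
            a = dense[seg_start:seg_end, seg_start:seg_end]
            signal = _bin_signal(a, w)
            oe = _observed_expected(a)
            bounds = [
                i for i in _candidate_minima(signal, w)
                if _boundary_p(oe, i, w) < params.p_cutoff
            ]
            cuts = [0] + [i + 1 for i in bounds] + [n_seg]
            for b0, b1 in zip(cuts[:-1], cuts[1:]):
                if b1 - b0 < 2:
                    continue
                rows.append(
                    {
                        "chrom": chrom,
                        "start": (seg_start + b0) * res,
                        "end": min((seg_start + b1) * res, matrix.bins.chrom_sizes[chrom]),
                        "cell_line": cell_line,
                    }
                )
    return pd.DataFrame(rows, columns=TAD_COLUMNS)


def tad_boundaries(tads: pd.DataFrame) -> pd.DataFrame:
    """Internal boundaries (shared edges between consecutive TADs are listed
    once); start/end of isolated domains count as boundaries too."""
    pts = set()
    for _, t in tads.iterrows():
        pts.add((t["chrom"], int(t["start"])))
        pts.add((t["chrom"], int(t["end"])))
    return pd.DataFrame(sorted(pts), columns=["chrom", "pos"])


# ---------------------------------------------------------------------------
# Cross-line matching and classification
# ---------------------------------------------------------------------------

def _check_sorted_nonoverlapping(tads: pd.DataFrame, label: str) -> pd.DataFrame:
    tads = tads.sort_values(["chrom", "start"]).reset_index(drop=True)
    for chrom, sub in tads.groupby("chrom", sort=False):
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping TADs within cell line {label} on {chrom}")
    return tads


def tads_match(
    a_start: int, a_end: int, b_start: int, b_end: int,
    tol_bp: int = 80_000, min_overlap: float = 0.8,
) -> bool:
    """The pairwise overlap rule: boundary agreement within tol_bp on both
    ends, or reciprocal overlap >= min_overlap of both TADs."""
    if abs(a_start - b_start) <= tol_bp and abs(a_end - b_end) <= tol_bp:
        return True
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return False
    return (
        ov / (a_end - a_start) >= min_overlap
        and ov / (b_end - b_start) >= min_overlap
    )


def _best_matches(
    a: pd.DataFrame, b: pd.DataFrame, tol_bp: int, min_overlap: float
) -> np.ndarray:
    """For each TAD in a: index of its best matching TAD in b (largest
    reciprocal overlap; ties broken by coordinate order) or -1."""
    out = np.full(len(a), -1, dtype=np.int64)
    for chrom, sub_a in a.groupby("chrom", sort=False):
        sub_b = b[b["chrom"] == chrom]
        if sub_b.empty:
            continue
        bs = sub_b["start"].to_numpy()
        be = sub_b["end"].to_numpy()
        bidx = sub_b.index.to_numpy()
        for ia, ta in sub_a.iterrows():
            s, e = int(ta["start"]), int(ta["end"])
            near = (bs <= e + tol_bp) & (be >= s - tol_bp)
            best_score, best_j = -1.0, -1
            for j in np.flatnonzero(near):
                if tads_match(s, e, int(bs[j]), int(be[j]), tol_bp, min_overlap):
                    ov = max(0, min(e, be[j]) - max(s, bs[j]))
                    score = min(ov / (e - s), ov / (be[j] - bs[j])) if ov > 0 else 0.0
                    if score > best_score:
                        best_score, best_j = score, int(bidx[j])
            out[ia] = best_j
    return out


@dataclass
class TadClassification:
    """Per-TAD labels across the normal / cancer-1 / cancer-2 comparison."""

    labels: pd.DataFrame            # chrom,start,end,cell_line,label
    counts: dict[str, int] = field(default_factory=dict)

    def of_line(self, cell_line: str) -> pd.DataFrame:
        return self.labels[self.labels["cell_line"] == cell_line].reset_index(drop=True)


def match_tads(
    normal: pd.DataFrame,
    cancer1: pd.DataFrame,
    cancer2: pd.DataFrame,
    tol_bp: int = 80_000,
    min_overlap: float = 0.8,
    line_names: tuple[str, str, str] = ("normal", "cancer1", "cancer2"),
) -> TadClassification:
    """Three-way TAD classification.

    common: the TAD sits on a chain matched across all three lines;
    normal_specific: a normal TAD matched in neither cancer line;
    cancer_specific: a cancer TAD matched in the other cancer line but not
    in normal; everything else is 'other'.
    """
    n = _check_sorted_nonoverlapping(normal, line_names[0])
    c1 = _check_sorted_nonoverlapping(cancer1, line_names[1])
    c2 = _check_sorted_nonoverlapping(cancer2, line_names[2])

    n_c1 = _best_matches(n, c1, tol_bp, min_overlap)
    n_c2 = _best_matches(n, c2, tol_bp, min_overlap)
    c1_n = _best_matches(c1, n, tol_bp, min_overlap)
    c1_c2 = _best_matches(c1, c2, tol_bp, min_overlap)
    c2_n = _best_matches(c2, n, tol_bp, min_overlap)
    c2_c1 = _best_matches(c2, c1, tol_bp, min_overlap)

    def chain_ok(df_a, ia, df_b, ib) -> bool:
        ta, tb = df_a.loc[ia], df_b.loc[ib]
        return tads_match(
            int(ta["start"]), int(ta["end"]), int(tb["start"]), int(tb["end"]),
            tol_bp, min_overlap,
        ) and ta["chrom"] == tb["chrom"]

    rows = []
    for i in range(len(n)):
        if n_c1[i] >= 0 and n_c2[i] >= 0 and chain_ok(c1, n_c1[i], c2, n_c2[i]):
            label = "common"
        elif n_c1[i] < 0 and n_c2[i] < 0:
            label = "normal_specific"
        else:
            label = "other"
        rows.append((n.loc[i, "chrom"], n.loc[i, "start"], n.loc[i, "end"], line_names[0], label))
    for df, other_match, normal_match, other_df, name in (
        (c1, c1_c2, c1_n, c2, line_names[1]),
        (c2, c2_c1, c2_n, c1, line_names[2]),
    ):
        for i in range(len(df)):
            if normal_match[i] >= 0 and other_match[i] >= 0 and chain_ok(
                n, normal_match[i], other_df, other_match[i]
            ):
                label = "common"
            elif other_match[i] >= 0 and normal_match[i] < 0:
                label = "cancer_specific"
            else:
                label = "other"
            rows.append((df.loc[i, "chrom"], df.loc[i, "start"], df.loc[i, "end"], name, label))

    labels = pd.DataFrame(rows, columns=["chrom", "start", "end", "cell_line", "label"])
    counts = labels["label"].value_counts().to_dict()
    return TadClassification(labels=labels, counts=counts)


def compare_tad_sizes(classification: TadClassification) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests of TAD size among classes, with BH
    adjustment over the comparisons in the report."""
    df = classification.labels.copy()
    df["size"] = df["end"] - df["start"]
    groups = {
        g: df.loc[df["label"] == g, "size"].to_numpy()
        for g in ("common", "normal_specific", "cancer_specific")
    }
    rows = []
    for a, b in combinations(groups, 2):
        xa, xb = groups[a], groups[b]
        if len(xa) < 2 or len(xb) < 2:
            continue  # comparison skipped: group too small
        rows.append(
            {
                "group_a": a, "group_b": b,
                "n_a": len(xa), "n_b": len(xb),
                "median_a": float(np.median(xa)), "median_b": float(np.median(xb)),
                "p": rank_sum_test(xa, xb, "two-sided"),
            }
        )
    report = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "median_a", "median_b", "p"])
    if len(report):
        report["adj_p"] = bh_adjust(report["p"].to_numpy())
    else:
        report["adj_p"] = []
    return report


def detect_split_tads(
    normal_tads: pd.DataFrame,
    cancer_tads: pd.DataFrame,
    min_overlap: float = 0.8,
) -> pd.DataFrame:
    """A normal TAD is 'split' when >=2 cancer TADs each lie >= min_overlap
    of their own length inside it and jointly cover >= min_overlap of it."""
    rows = []
    for chrom, sub_n in normal_tads.groupby("chrom", sort=False):
        sub_c = cancer_tads[cancer_tads["chrom"] == chrom]
        cs = sub_c["start"].to_numpy()
        ce = sub_c["end"].to_numpy()
        for _, tn in sub_n.iterrows():
            s, e = int(tn["start"]), int(tn["end"])
            ov = np.minimum(e, ce) - np.maximum(s, cs)
            frac_child = np.where(ce > cs, ov / (ce - cs), 0.0)
            children = np.flatnonzero((ov > 0) & (frac_child >= min_overlap))
            if len(children) < 2:
                continue
            joint = ov[children].sum() / (e - s)
            if joint >= min_overlap:
                rows.append(
                    {
                        "chrom": chrom, "start": s, "end": e,
                        "n_children": len(children),
                        "children": ";".join(
                            f"{int(cs[j])}-{int(ce[j])}" for j in children
                        ),
                        "joint_coverage": float(joint),
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_children", "children", "joint_coverage"]
    )
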