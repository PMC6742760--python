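"""Overlap arithmetic on half-open genomic intervals stored in DataFrames.

All functions expect DataFrames with at least ``chrom``, ``start``, ``end``
columns (0-based, half-open).  Subjects may overlap each other; the counting
rule ``n_subjects - #(start >= q.end) - #(end <= q.start)`` is exact in that
case because the two excluded events are disjoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _per_chrom_arrays(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = (
            np.sort(sub["start"].to_numpy(dtype=np.int64)),
            np.sort(sub["end"].to_numpy(dtype=np.int64)),
        )
    return out


def overlap_counts(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Number of subject intervals overlapping (>=1 bp) each query interval."""
    counts = np.zeros(len(query), dtype=np.int64)
    if len(query) == 0 or len(subject) == 0:
        return counts
    subj = _per_chrom_arrays(subject)
    qs = query["start"].to_numpy(dtype=np.int64)
    qe = query["end"].to_numpy(dtype=np.int64)
    for chrom, idx in query.groupby("chrom", sort=False).indices.items():
        arrs = subj.get(str(chrom))
        if arrs is None:
            continue
        starts, ends = arrs
        n = len(starts)
        ge_end = n - np.searchsorted(starts, qe[idx], side="left")
        le_start = np.searchsorted(ends, qs[idx], side="right")
        counts[idx] = n - ge_end - le_start
    return counts


def has_overlap(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    return overlap_counts(query, subject) > 0


def points_in_intervals(
    chroms: np.ndarray, positions: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Index of the (non-overlapping, sorted-by-construction) interval that
    contains each point, or -1.  Interval order follows ``intervals``."""
    result = np.full(len(positions), -1, dtype=np.int64)
    if len(intervals) == 0:
        return result
    pos = np.asarray(positions, dtype=np.int64)
    chroms = np.asarray(chroms, dtype=object)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        orig = sub.index.to_numpy()
        sel = np.nonzero(chroms == chrom)[0]
        if sel.size == 0:
            continue
        k = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (k >= 0) & (pos[sel] < ends[np.clip(k, 0, len(ends) - 1)])
        result[sel[ok]] = orig[k[ok]]
    return result


def distance_to_nearest_point(
    query: pd.DataFrame, point_chroms: np.ndarray, point_pos: np.ndarray
) -> np.ndarray:
    """bp distance from each query interval to the nearest point (0 if the
    point falls inside the half-open interval); inf when the chromosome has
    no points."""
    dist = np.full(len(query), np.inf)
    pts: dict[str, np.ndarray] = {}
    point_chroms = np.asarray(point_chroms, dtype=object)
    point_pos = np.asarray(point_pos, dtype=np.int64)
    for chrom in pd.unique(point_chroms):
        pts[str(chrom)] = np.sort(point_pos[point_chroms == chrom])
    qs = query["start"].to_numpy(dtype=np.int64)
    qe = query["end"].to_numpy(dtype=np.int64)
    for chrom, idx in query.groupby("chrom", sort=False).indices.items():
        p = pts.get(str(chrom))
        if p is None or len(p) == 0:
            continue
        # nearest point to the interval [s, e): inside -> 0
        s, e = qs[idx], qe[idx]
        right = np.searchsorted(p, s, side="left")
        d = np.full(len(idx), np.inf)
        has_left = right > 0
        d[has_left] = s[has_left] - p[np.clip(right - 1, 0, len(p) - 1)][has_left]
        has_right = right < len(p)
        d_right = np.where(has_right, p[np.clip(right, 0, len(p) - 1)] - (e - 1), np.inf)
        d = np.minimum(d, d_right)
        d = np.maximum(d, 0)
        inside = overlap_counts(
            query.iloc[idx],
            pd.DataFrame({"chrom": chrom, "start": p, "end": p + 1}),
        )
        d[inside > 0] = 0
        dist[idx] = d
    return dist
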