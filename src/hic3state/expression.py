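"""RPKM normalization, expressed-gene calling, differential expression and
gene-set fold-change comparisons.

Fold changes are computed on condition means with a pseudocount of 1 RPKM,
keeping genes silent in one condition finite.  The differential test is a
Welch t test on log2(RPKM + 1) with BH adjustment (a documented stand-in
for a gene-specific model); expressed genes are those with mean
log2(RPKM + 1) above 1.5 across replicates.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, rank_sum_test


def rpkm(counts, gene_length_bp, total_mapped) -> np.ndarray:
    """Reads per kilobase of gene model per million mapped reads."""
    counts = np.asarray(counts, dtype=np.float64)
    gene_length_bp = np.asarray(gene_length_bp, dtype=np.float64)
    if np.any(gene_length_bp <= 0):
        raise ValueError("gene length must be > 0")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be > 0")
    return counts / (gene_length_bp / 1e3) / (total_mapped / 1e6)


def call_expressed(expression: pd.DataFrame, threshold: float = 1.5) -> pd.Series:
    """Expressed iff the mean over replicates of log2(RPKM + 1) exceeds the
    threshold (strict).  ``expression``: genes x replicate RPKM values,
    indexed by gene id."""
    mean_log = np.log2(expression + 1).mean(axis=1)
    return mean_log > threshold


def differential_expression(
    expression: pd.DataFrame,
    cancer_cols: list[str],
    normal_cols: list[str],
    fc_cutoff: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene fold change and Welch t test (log2 scale) between conditions.

    With fewer than 2 replicates on either side only the fold change is
    reported (p undefined, flagged)."""
    mc = expression[cancer_cols].mean(axis=1)
    mn = expression[normal_cols].mean(axis=1)
    fc = (mc + 1.0) / (mn + 1.0)
    out = pd.DataFrame(
        {
            "mean_rpkm_cancer": mc,
            "mean_rpkm_normal": mn,
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
        }
    )
    if len(cancer_cols) >= 2 and len(normal_cols) >= 2:
        lc = np.log2(expression[cancer_cols] + 1)
        ln = np.log2(expression[normal_cols] + 1)
        p = sps.ttest_ind(lc, ln, axis=1, equal_var=False).pvalue
        p = np.where(np.isnan(p), 1.0, p)
        out["p"] = p
        out["adj_p"] = bh_adjust(p)
        out["p_defined"] = True
    else:
        out["p"] = np.nan
        out["adj_p"] = np.nan
        out["p_defined"] = False
    out["up"] = (out["fold_change"] > fc_cutoff) & (out["adj_p"] < alpha)
    out["down"] = (out["fold_change"] < 1.0 / fc_cutoff) & (out["adj_p"] < alpha)
    return out


def compare_gene_sets(fold_changes: pd.Series, set_a, set_b) -> dict:
    """Two-sided rank-sum comparison of log2 fold-change distributions
    between two gene sets (not necessarily disjoint)."""
    xa = fold_changes.reindex(list(set_a)).dropna().to_numpy()
    xb = fold_changes.reindex(list(set_b)).dropna().to_numpy()
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each gene set needs >= 2 genes with fold changes")
    return {
        "n_a": len(xa),
        "n_b": len(xb),
        "median_a": float(np.median(xa)),
        "median_b": float(np.median(xb)),
        "p": rank_sum_test(xa, xb, "two-sided"),
    }


def compare_gene_set_table(
    fold_changes: pd.Series,
    sets: dict[str, set],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """All requested pairwise gene-set comparisons with BH adjustment across
    the report."""
    if pairs is None:
        pairs = list(combinations(sets, 2))
    rows = []
    for a, b in pairs:
        r = compare_gene_sets(fold_changes, sets[a], sets[b])
        r.update({"set_a": a, "set_b": b})
        rows.append(r)
    report = pd.DataFrame(
        rows, columns=["set_a", "set_b", "n_a", "n_b", "median_a", "median_b", "p"]
    )
    if len(report):
        report["adj_p"] = bh_adjust(report["p"].to_numpy())
    else:
        report["adj_p"] = []
    return report
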