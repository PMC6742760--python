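"""ICE matrix balancing, resolution coarsening and distance-decay estimation.

ICE (iterative correction) removes multiplicative per-bin bias by driving all
unmasked row marginals to a common value; the per-bin correction vector is
returned alongside the normalized matrix.  The decay profile is the
distance-stratified expected contact probability used as the null for loop
significance: for stratum d,

    p_hat_d = (sum of counts at d) / (N_total * M_d)

with M_d the number of unmasked locus pairs at that distance (zero-count
pairs included), followed by non-increasing isotonic smoothing across strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from .genome_io import BinTable, ContactMatrix


def ice_normalize(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-4,
    low_coverage_filter: float = 0.02,
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative proportional fitting of per-bin biases.

    The bias update is the square-root-damped symmetric scaling step
    ``b <- b * (m / mean(m))**0.5``; the undamped step oscillates between
    two fixed points on symmetric matrices and stalls far from the
    tolerance, while the damped step converges geometrically.

    Bins whose raw marginal falls below the ``low_coverage_filter`` quantile
    of positive marginals (or is zero) are masked: their bias is NaN and
    their entries are dropped from the normalized matrix.
    """
    A = matrix.to_symmetric_csr()
    marg0 = np.asarray(A.sum(axis=1)).ravel()
    positive = marg0[marg0 > 0]
    if positive.size == 0:
        raise ValueError("matrix has no contacts")
    thresh = np.quantile(positive, low_coverage_filter)
    masked = (marg0 <= 0) | (marg0 < thresh)
    keep = ~masked

    # zero out masked rows/cols once
    scale = keep.astype(np.float64)
    A = A.multiply(scale[:, None]).multiply(scale[None, :]).tocsr()

    n = matrix.bins.n_bins
    b = np.ones(n)
    dev = np.inf
    for _ in range(max_iter):
        invb = np.where(keep, 1.0 / b, 0.0)
        m = invb * (A @ invb)
        mean_m = m[keep].mean()
        if mean_m <= 0:
            raise ValueError("matrix has no contacts among unmasked bins")
        dev = float(np.abs(m[keep] / mean_m - 1.0).max())
        if dev < tol:
            break
        b = np.where(keep, b * np.sqrt(m / mean_m), 1.0)
    else:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations "
            f"(max relative marginal deviation {dev:.3g})"
        )
    b = b / b[keep].mean()
    bias = np.where(keep, b, np.nan)

    entry_keep = keep[matrix.row] & keep[matrix.col]
    row = matrix.row[entry_keep]
    col = matrix.col[entry_keep]
    norm = matrix.count[entry_keep] / (b[row] * b[col])
    out = ContactMatrix(matrix.bins, row, col, norm, bias=bias)
    return out, bias


def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum counts over factor x factor fine-bin blocks (raw counts; total
    mass conserved exactly).  The bias vector does not carry over."""
    if not float(factor).is_integer() or int(factor) < 2:
        raise ValueError("factor must be an integer >= 2")
    factor = int(factor)
    fine = matrix.bins
    coarse = BinTable(fine.chrom_sizes, fine.resolution * factor)
    fine_to_coarse = np.empty(fine.n_bins, dtype=np.int64)
    for chrom in fine.chroms:
        lo, hi = fine.bin_range(chrom)
        clo, _ = coarse.bin_range(chrom)
        fine_to_coarse[lo:hi] = clo + np.arange(hi - lo) // factor
    return ContactMatrix.from_entries(
        coarse, fine_to_coarse[matrix.row], fine_to_coarse[matrix.col], matrix.count
    )


@dataclass
class DecayProfile:
    """Distance-stratified expected contact probability for one matrix."""

    resolution: int
    edges: np.ndarray       # stratum lower edges in bin distance (sorted)
    distances: np.ndarray   # representative (mean possible) distance per stratum
    p_hat: np.ndarray       # smoothed expected probability per pair per stratum
    p_raw: np.ndarray       # pre-smoothing estimates
    n_pairs: np.ndarray     # M_d: unmasked pair count per stratum
    count_sum: np.ndarray   # observed count mass per stratum
    n_total: float
    min_dist_bins: int
    max_dist_bins: int

    @property
    def total_pairs(self) -> int:
        return int(self.n_pairs.sum())

    def stratum_of(self, d_bins: np.ndarray) -> np.ndarray:
        d = np.asarray(d_bins)
        if ((d < self.min_dist_bins) | (d > self.max_dist_bins)).any():
            raise ValueError("distance outside the profile range")
        return np.searchsorted(self.edges, d, side="right") - 1

    def p_for(self, d_bins: np.ndarray) -> np.ndarray:
        return self.p_hat[self.stratum_of(d_bins)]


def _stratum_edges(min_bins: int, max_bins: int, max_exact: int, log_step: float) -> np.ndarray:
    exact_hi = min(max_bins, max_exact)
    edges = list(range(min_bins, exact_hi + 1))
    d = float(exact_hi)
    while d * log_step <= max_bins:
        d *= log_step
        edges.append(int(round(d)))
    edges = sorted(set(edges))
    return np.asarray(edges, dtype=np.int64)


def estimate_decay(
    matrix: ContactMatrix,
    min_dist: int = 50_000,
    max_dist: int = 10_000_000,
    max_exact_bins: int = 1024,
    log_step: float = 1.08,
    smooth: bool = True,
) -> DecayProfile:
    """Estimate the distance-decay null from (normalized) intra-chromosomal
    counts in the [min_dist, max_dist] bp range.

    Strata are exact per-bin-distance up to ``max_exact_bins`` and log-spaced
    beyond; the estimate is made non-increasing by weighted isotonic
    regression (weights = pair counts), which also fills empty strata from
    their neighbors.
    """
    res = matrix.bins.resolution
    min_bins = max(1, -(-min_dist // res))
    max_bins = max_dist // res
    if max_bins < min_bins:
        raise ValueError("distance range spans no full bin distance")
    edges = _stratum_edges(min_bins, max_bins, max_exact_bins, log_step)
    n_strata = len(edges)
    upper = np.append(edges[1:], max_bins + 1)  # half-open stratum [edge, upper)

    count_sum = np.zeros(n_strata)
    n_pairs = np.zeros(n_strata)
    valid = matrix.valid_bins()
    for chrom in matrix.bins.chroms:
        lo, hi = matrix.bins.bin_range(chrom)
        r, c, v = matrix.chrom_entries(chrom)
        d = c - r
        sel = (d >= min_bins) & (d <= max_bins)
        if sel.any():
            s = np.searchsorted(edges, d[sel], side="right") - 1
            np.add.at(count_sum, s, v[sel])
        u = valid[lo:hi].astype(np.float64)
        # pairs at distance d among unmasked bins: sum_i u_i * u_{i+d}
        if u.sum() > 0:
            corr = np.correlate(u, u, mode="full")[len(u):]  # index d-1 -> distance d
            dmax = min(max_bins, len(u) - 1)
            if dmax >= min_bins:
                dd = np.arange(min_bins, dmax + 1)
                s = np.searchsorted(edges, dd, side="right") - 1
                np.add.at(n_pairs, s, np.rint(corr[dd - 1]))

    n_total = float(count_sum.sum())
    if n_total <= 0:
        raise ValueError("no contacts in the requested distance range")
    with np.errstate(divide="ignore", invalid="ignore"):
        p_raw = np.where(n_pairs > 0, count_sum / (n_total * n_pairs), 0.0)
    if smooth:
        w = np.maximum(n_pairs, 1e-12)
        p_hat = isotonic_regression(p_raw, weights=w, increasing=False).x
        p_hat = np.maximum(p_hat, 0.0)
    else:
        p_hat = p_raw.copy()
    distances = (edges + np.minimum(upper - 1, max_bins)) / 2.0
    return DecayProfile(
        resolution=res,
        edges=edges,
        distances=distances,
        p_hat=p_hat,
        p_raw=p_raw,
        n_pairs=n_pairs,
        count_sum=count_sum,
        n_total=n_total,
        min_dist_bins=min_bins,
        max_dist_bins=int(max_bins),
    )
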