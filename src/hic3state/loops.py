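"""Distance-stratified chromatin-loop significance at 10 kb and regulatory
anchor analysis.

Loop significance: every intra-chromosomal bin pair in the 50 kb-10 Mb range
is tested against the distance-decay null.  The test runs on the *raw*
count of the pair (Poisson by construction) against a two-factor expected
model

    mu_ij = beta_i * beta_j * lambda_d,    p = P(X >= k), X ~ Binomial(N_raw, mu_ij / N_raw)

where beta is the ICE bias divided by the *positional* factor obtained by
balancing the distance-decay kernel itself (the ICE bias of a bias-free
matrix is not 1: matrix balancing absorbs the finite-chromosome edge
profile, and using it directly as a per-pair factor mis-scales
expectations near the diagonal), and lambda_d is the per-stratum expected
raw count re-estimated with beta weights and isotonic (non-increasing)
smoothing.  On an unbiased infinite matrix this reduces to the plain
Binomial(N_total, p_hat_d) decay test.  p-values are BH-adjusted over
*all* in-range pairs (zero-count pairs included in the family size); pairs
with q below the cutoff are loops.

Anchors are full bins; each anchor is labeled by the sequential scheme
promoter > enhancer > insulator > other (first overlap wins), and the loop
category is the unordered label pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._intervals import distance_to_nearest_point, has_overlap, overlap_counts
from .genome_io import ContactMatrix
from .normalization import DecayProfile
from .stats import bh_adjust, empirical_p, fisher_exact_2x2

ANCHOR_LABELS = ("P", "E", "I", "O")
_LABEL_ORDER = {lab: i for i, lab in enumerate(ANCHOR_LABELS)}

LOOP_KEY = ["chrom", "bin1", "bin2"]


def _balance_kernel(g: np.ndarray, keep: np.ndarray, n_iter: int = 100,
                    tol: float = 1e-8) -> np.ndarray:
    """Positional factor of a chromosome: balance the Toeplitz kernel
    K_ij = g(|i-j|) restricted to unmasked bins.  Returns u (1 on masked
    bins) with mean 1 on unmasked bins."""
    from scipy.signal import fftconvolve

    n = len(keep)
    g2 = np.concatenate([g[::-1], g[1:]])  # symmetric kernel, length 2n-1

    def matvec(x: np.ndarray) -> np.ndarray:
        return fftconvolve(x, g2)[n - 1:2 * n - 1]

    u = np.ones(n)
    for _ in range(n_iter):
        invu = np.where(keep, 1.0 / u, 0.0)
        m = invu * matvec(invu)
        mean_m = m[keep].mean()
        if np.abs(m[keep] / mean_m - 1.0).max() < tol:
            break
        u = np.where(keep, u * np.sqrt(m / mean_m), 1.0)
    return u / u[keep].mean() if keep.any() else u


@dataclass
class _PairNull:
    """Per-pair expected raw counts: mu_ij = beta_i beta_j lambda_d."""

    beta: dict[str, np.ndarray]      # per chrom, 0 on masked bins
    lam: np.ndarray                  # per stratum expected raw count
    n_raw: int
    decay: DecayProfile


def loop_binomial_p(k, n_total: int, p_success) -> np.ndarray:
    """Binomial tail p = P(X >= k), X ~ Binomial(n_total, p_success): the
    significance measure of a single locus pair."""
    k = np.asarray(k)
    return sps.binom.sf(k - 1, n_total, np.clip(np.asarray(p_success), 0.0, 1.0))


def decoupled_bias(matrix: ContactMatrix, decay: DecayProfile) -> np.ndarray:
    """Per-bin experimental bias with the positional (finite-chromosome)
    factor divided out of the ICE bias; NaN on masked bins.  This is the
    quantity comparable with a planted multiplicative bias."""
    null = _fit_pair_null(matrix, decay)
    out = np.full(matrix.bins.n_bins, np.nan)
    for chrom in matrix.bins.chroms:
        lo, hi = matrix.bins.bin_range(chrom)
        bt = null.beta[chrom]
        keep = bt > 0
        vals = np.where(keep, bt, np.nan)
        if keep.any():
            vals = vals / bt[keep].mean()
        out[lo:hi] = vals
    return out


def _fit_pair_null(matrix: ContactMatrix, decay: DecayProfile) -> _PairNull:
    from scipy.optimize import isotonic_regression

    bins = matrix.bins
    beta: dict[str, np.ndarray] = {}
    n_strata = len(decay.edges)
    sum_raw = np.zeros(n_strata)
    sum_bb = np.zeros(n_strata)
    n_raw = 0.0
    for chrom in bins.chroms:
        lo, hi = bins.bin_range(chrom)
        n = hi - lo
        r, c, v = matrix.chrom_entries(chrom)
        d = c - r
        b = matrix.bias[lo:hi] if matrix.bias is not None else np.ones(n)
        keep = np.isfinite(b)
        bsafe = np.where(keep, b, 1.0)
        # mean normalized count per distance (the decay kernel, all distances)
        g = np.zeros(n)
        np.add.at(g, d, v)
        u_count = np.correlate(keep.astype(float), keep.astype(float), mode="full")[n - 1:]
        g = np.where(u_count > 0, g / np.maximum(u_count, 1), 0.0)
        u = _balance_kernel(g, keep)
        bt = np.where(keep, bsafe / u, 0.0)
        beta[chrom] = bt
        # stratum sums of raw counts and of beta_i * beta_j over ALL pairs
        sel = (d >= decay.min_dist_bins) & (d <= decay.max_dist_bins)
        raw = v[sel] * bsafe[r[sel]] * bsafe[c[sel]]
        s = np.searchsorted(decay.edges, d[sel], side="right") - 1
        np.add.at(sum_raw, s, raw)
        n_raw += raw.sum()
        corr = np.correlate(bt, bt, mode="full")[n:]
        dmax = min(decay.max_dist_bins, n - 1)
        if dmax >= decay.min_dist_bins:
            dd = np.arange(decay.min_dist_bins, dmax + 1)
            ss = np.searchsorted(decay.edges, dd, side="right") - 1
            np.add.at(sum_bb, ss, corr[dd - 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_raw = np.where(sum_bb > 0, sum_raw / sum_bb, 0.0)
    lam = isotonic_regression(
        lam_raw, weights=np.maximum(sum_bb, 1e-12), increasing=False
    ).x
    lam = np.maximum(lam, 0.0)
    return _PairNull(beta=beta, lam=lam, n_raw=int(round(n_raw)), decay=decay)


def _chrom_pvalues(
    matrix: ContactMatrix, null: _PairNull, chrom: str
) -> tuple[np.ndarray, ...]:
    """Raw counts and binomial tail p-values of the in-range entries of one
    chromosome."""
    bins = matrix.bins
    lo, _ = bins.bin_range(chrom)
    decay = null.decay
    r, c, v = matrix.chrom_entries(chrom)
    d = c - r
    sel = (d >= decay.min_dist_bins) & (d <= decay.max_dist_bins)
    r, c, v, d = r[sel], c[sel], v[sel], d[sel]
    if matrix.bias is not None:
        bb = matrix.bias[r + lo] * matrix.bias[c + lo]
    else:
        bb = np.ones(len(r))
    k = np.rint(v * bb).astype(np.int64)  # raw count (exact for iced input)
    bt = null.beta[chrom]
    strata = np.searchsorted(decay.edges, d, side="right") - 1 if len(d) else d
    mu = bt[r] * bt[c] * null.lam[strata] if len(d) else np.empty(0)
    p = loop_binomial_p(k, null.n_raw, mu / null.n_raw)
    return r, c, v, d, k, p


def call_significant_loops(
    matrix: ContactMatrix,
    decay: DecayProfile,
    q_cutoff: float = 0.05,
    min_dist: int = 50_000,
    max_dist: int = 10_000_000,
) -> pd.DataFrame:
    """Significant loops of an ICE-normalized matrix against its decay null.

    The matrix's bias vector (when present) enters the per-pair expected
    model; without one only the positional factor and decay remain.
    """
    if decay.n_total <= 0:
        raise ValueError("decay profile has zero total contact count")
    res = matrix.bins.resolution
    null = _fit_pair_null(matrix, decay)
    if null.n_raw <= 0:
        raise ValueError("no raw contacts in the loop distance range")
    rows = []
    for chrom in matrix.bins.chroms:
        r, c, v, d, k, p = _chrom_pvalues(matrix, null, chrom)
        nz = k > 0
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin1": r[nz],
                    "bin2": c[nz],
                    "distance": d[nz] * res,
                    "count": k[nz],
                    "count_norm": v[nz],
                    "p": p[nz],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "bin1", "bin2", "distance", "count", "count_norm", "p"]
    )
    table["q"] = (
        bh_adjust(table["p"].to_numpy(), m=decay.total_pairs) if len(table) else []
    )
    loops = table[table["q"] < q_cutoff].reset_index(drop=True)
    for a in (1, 2):
        loops[f"start{a}"] = loops[f"bin{a}"] * res
        loops[f"end{a}"] = loops[f"bin{a}"] * res + res
    return loops


def loop_pvalues(
    matrix: ContactMatrix, decay: DecayProfile
) -> tuple[np.ndarray, int]:
    """All in-range pair p-values (zero-count pairs contribute p = 1),
    for calibration checks.  Returns (p-values, family size)."""
    null = _fit_pair_null(matrix, decay)
    ps = []
    for chrom in matrix.bins.chroms:
        _, _, _, _, k, p = _chrom_pvalues(matrix, null, chrom)
        ps.append(p[k > 0])
    m = decay.total_pairs
    p = np.concatenate(ps) if ps else np.empty(0)
    if m > len(p):
        p = np.concatenate([p, np.ones(m - len(p))])
    return p, m


# ---------------------------------------------------------------------------
# Regulatory element sets
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryElementSet:
    """Sequentially constructed promoter / enhancer / insulator intervals."""

    promoters: pd.DataFrame
    enhancers: pd.DataFrame
    insulators: pd.DataFrame

    def of_label(self, label: str) -> pd.DataFrame:
        return {"P": self.promoters, "E": self.enhancers, "I": self.insulators}[label]


def build_regulatory_sets(
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    h3k27ac_peaks: pd.DataFrame,
    ctcf_peaks: pd.DataFrame,
    expressed_threshold: float = 1.5,
    promoter_flank: int = 2_000,
    enhancer_top_n: int = 25_000,
    insulator_top_n: int = 50_000,
    tss_exclusion: int = 2_000,
) -> RegulatoryElementSet:
    """Promoters: +-2 kb TSS windows of expressed genes (mean log2(RPKM+1)
    above threshold).  Enhancers: top-ranked H3K27ac peaks more than 2 kb
    from any annotated TSS.  Insulators: top-ranked CTCF peaks overlapping
    neither promoters nor enhancers."""
    from .expression import call_expressed

    expressed = call_expressed(expression, threshold=expressed_threshold)
    exp_genes = genes[genes["gene_id"].map(expressed).fillna(False).astype(bool)]
    promoters = pd.DataFrame(
        {
            "chrom": exp_genes["chrom"].to_numpy(),
            "start": np.maximum(exp_genes["tss"].to_numpy() - promoter_flank, 0),
            "end": exp_genes["tss"].to_numpy() + promoter_flank,
            "name": exp_genes["gene_id"].to_numpy(),
        }
    ).reset_index(drop=True)

    def _top(peaks: pd.DataFrame, n: int) -> pd.DataFrame:
        ordered = peaks.sort_values(
            ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
        )
        return ordered.head(n).reset_index(drop=True)

    cand_enh = _top(h3k27ac_peaks, enhancer_top_n)
    if len(cand_enh):
        dist = distance_to_nearest_point(
            cand_enh, genes["chrom"].to_numpy(), genes["tss"].to_numpy()
        )
        enhancers = cand_enh[dist > tss_exclusion].reset_index(drop=True)
    else:
        enhancers = cand_enh
    cand_ins = _top(ctcf_peaks, insulator_top_n)
    if len(cand_ins):
        bad = has_overlap(cand_ins, promoters) | has_overlap(cand_ins, enhancers)
        insulators = cand_ins[~bad].reset_index(drop=True)
    else:
        insulators = cand_ins
    return RegulatoryElementSet(promoters, enhancers, insulators)


# ---------------------------------------------------------------------------
# Anchor annotation
# ---------------------------------------------------------------------------

def _anchor_frame(loops: pd.DataFrame, which: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": loops["chrom"],
            "start": loops[f"start{which}"].astype(int),
            "end": loops[f"end{which}"].astype(int),
        }
    )


def _label_anchors(anchors: pd.DataFrame, reg: RegulatoryElementSet) -> np.ndarray:
    labels = np.full(len(anchors), "O", dtype=object)
    for lab in ("I", "E", "P"):  # later assignments win: P > E > I
        hit = has_overlap(anchors, reg.of_label(lab))
        labels[hit] = lab
    return labels


def annotate_anchors(
    loops: pd.DataFrame, reg: RegulatoryElementSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label both anchors (P > E > I > O), derive the unordered category and
    the category ranking table (count desc, ties lexicographic)."""
    out = loops.copy().reset_index(drop=True)
    if len(out) == 0:
        out["anchor1_label"] = pd.Series(dtype=object)
        out["anchor2_label"] = pd.Series(dtype=object)
        out["category"] = pd.Series(dtype=object)
        return out, pd.DataFrame(columns=["category", "count"])
    l1 = _label_anchors(_anchor_frame(out, 1), reg)
    l2 = _label_anchors(_anchor_frame(out, 2), reg)
    out["anchor1_label"] = l1
    out["anchor2_label"] = l2
    out["category"] = [
        "".join(sorted((a, b), key=_LABEL_ORDER.get)) for a, b in zip(l1, l2)
    ]
    ranking = (
        out["category"].value_counts().rename_axis("category").reset_index(name="count")
    )
    ranking = ranking.sort_values(
        ["count", "category"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out, ranking


def top_categories(ranking: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    return ranking.head(n).reset_index(drop=True)


def loop_fate_fractions(
    reg: RegulatoryElementSet, loops: pd.DataFrame
) -> pd.DataFrame:
    """For each element class, the fraction of elements that loop to an
    enhancer / insulator / promoter / other region, or are not looped.
    Multi-looped elements are assigned once by partner priority E > I > P > O."""
    anchors = []
    for which, partner in ((1, "anchor2_label"), (2, "anchor1_label")):
        a = _anchor_frame(loops, which)
        a["partner"] = loops[partner].to_numpy()
        anchors.append(a)
    anchor_df = pd.concat(anchors, ignore_index=True) if len(loops) else pd.DataFrame(
        columns=["chrom", "start", "end", "partner"]
    )
    rows = []
    for cls in ("P", "E", "I"):
        elements = reg.of_label(cls)
        if len(elements) == 0:
            continue  # skipped: empty element set
        assigned = np.full(len(elements), "not_looped", dtype=object)
        for partner in ("O", "P", "I", "E"):  # later (higher-priority) wins
            sub = anchor_df[anchor_df["partner"] == partner]
            if len(sub):
                hit = has_overlap(elements, sub)
                assigned[hit] = f"loops_to_{partner}"
        frac = pd.Series(assigned).value_counts(normalize=True)
        row = {"element_class": cls, "n": len(elements)}
        for bucket in ("loops_to_E", "loops_to_I", "loops_to_P", "loops_to_O", "not_looped"):
            row[bucket] = float(frac.get(bucket, 0.0))
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["element_class", "n", "loops_to_E", "loops_to_I", "loops_to_P",
                 "loops_to_O", "not_looped"],
    )


def shuffle_anchor_null(
    loops: pd.DataFrame,
    reg: RegulatoryElementSet,
    chrom_length: int,
    n: int = 100,
    chrom: str = "chr1",
    anchor_size: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Empirical significance of loop-anchor overlap with regulatory elements
    on one chromosome: each shuffle places the same number of non-overlapping
    artificial anchors uniformly on the anchor-size grid."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = loops[loops["chrom"] == chrom]
    if len(sub) == 0:
        raise ValueError(f"no loops on chromosome {chrom}")
    anchor_bins = np.unique(
        np.concatenate([sub["start1"].to_numpy(), sub["start2"].to_numpy()])
    )
    real = pd.DataFrame(
        {"chrom": chrom, "start": anchor_bins, "end": anchor_bins + anchor_size}
    )
    n_grid = chrom_length // anchor_size
    if n_grid < len(anchor_bins):
        raise ValueError("chromosome too short for the requested anchor count")
    rows = []
    null_fracs = {lab: np.empty(n) for lab in ("P", "E", "I")}
    for s in range(n):
        pos = rng.choice(n_grid, size=len(anchor_bins), replace=False) * anchor_size
        fake = pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + anchor_size})
        for lab in ("P", "E", "I"):
            null_fracs[lab][s] = has_overlap(fake, reg.of_label(lab)).mean()
    for lab in ("P", "E", "I"):
        obs = float(has_overlap(real, reg.of_label(lab)).mean())
        rows.append(
            {
                "element_type": lab,
                "observed_fraction": obs,
                "null_mean": float(null_fracs[lab].mean()),
                "empirical_p": empirical_p(obs, null_fracs[lab]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-cell-line loop classes
# ---------------------------------------------------------------------------

def _loop_keys(loops: pd.DataFrame) -> set[tuple]:
    return set(zip(loops["chrom"], loops["bin1"], loops["bin2"]))


def classify_ep_loops(
    loops_by_line: dict[str, pd.DataFrame],
    normal: str,
    cancers: tuple[str, str],
) -> dict[str, pd.DataFrame]:
    """Enhancer-promoter loop specificity classes across three lines.

    Presence means the anchor pair was called significant in that line
    (exact bin equality); the E-P category is required in the line(s)
    defining each class.  normal_specific: E-P in normal, absent from both
    cancers.  cancer_specific: E-P in both cancers, absent from normal.
    common: present and E-P in all three."""
    for name, df in loops_by_line.items():
        if "category" not in df.columns:
            raise ValueError(f"loops of line {name} are not annotated")
    called = {name: _loop_keys(df) for name, df in loops_by_line.items()}
    ep = {
        name: _loop_keys(df[df["category"] == "PE"])
        for name, df in loops_by_line.items()
    }
    c1, c2 = cancers

    def _subset(line: str, keys: set[tuple]) -> pd.DataFrame:
        df = loops_by_line[line]
        mask = [k in keys for k in zip(df["chrom"], df["bin1"], df["bin2"])]
        return df[mask].reset_index(drop=True)

    normal_keys = ep[normal] - called[c1] - called[c2]
    cancer_keys = (ep[c1] & ep[c2]) - called[normal]
    common_keys = ep[normal] & ep[c1] & ep[c2]
    return {
        "normal_specific": _subset(normal, normal_keys),
        "cancer_specific": _subset(c1, cancer_keys),
        "common": _subset(normal, common_keys),
    }


def differential_loop_test(
    counts_cancer, total_cancer: int, counts_normal, total_normal: int
) -> pd.DataFrame:
    """Fisher exact comparison of per-loop raw contact frequency between one
    cancer line and normal; totals are the in-range intra-chromosomal
    contact sums of each line.  Returns odds ratio, two-sided p and BH q."""
    if total_cancer <= 0 or total_normal <= 0:
        raise ValueError("contact totals must be positive")
    kc = np.atleast_1d(np.asarray(counts_cancer, dtype=np.int64))
    kn = np.atleast_1d(np.asarray(counts_normal, dtype=np.int64))
    p = fisher_exact_2x2(kc, total_cancer - kc, kn, total_normal - kn)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (kc * (total_normal - kn)) / ((total_cancer - kc) * kn)
    return pd.DataFrame(
        {"odds_ratio": odds, "p": p, "q": bh_adjust(p)}
    )


def tf_bound_looped_enhancers(
    ep_loops: pd.DataFrame,
    reg: RegulatoryElementSet,
    tf_peaks: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    ndrs: pd.DataFrame | None = None,
    promoter_flank: int = 2_000,
) -> tuple[float, pd.DataFrame, list[str]]:
    """Fraction of distinct looped enhancers bound by a TF, plus the genes
    whose promoters sit at the partner anchors of bound enhancers.

    With ``ndrs`` given, only enhancers containing a nucleosome-depleted
    region are considered (NDR-restricted mode)."""
    enhancers = reg.enhancers
    if ndrs is not None and len(enhancers):
        enhancers = enhancers[has_overlap(enhancers, ndrs)].reset_index(drop=True)
    e_anchors = []
    partner_of = []
    for which, other in ((1, 2), (2, 1)):
        sel = ep_loops[ep_loops[f"anchor{which}_label"] == "E"]
        if len(sel):
            a = _anchor_frame(sel, which)
            e_anchors.append(a)
            partner_of.append(_anchor_frame(sel, other))
    if not e_anchors or len(enhancers) == 0:
        return 0.0, enhancers.head(0), []
    e_anchor_df = pd.concat(e_anchors, ignore_index=True)
    partner_df = pd.concat(partner_of, ignore_index=True)
    looped = has_overlap(enhancers, e_anchor_df)
    looped_enh = enhancers[looped].reset_index(drop=True)
    if len(looped_enh) == 0:
        return 0.0, looped_enh, []
    bound = (
        has_overlap(looped_enh, tf_peaks) if len(tf_peaks) else
        np.zeros(len(looped_enh), dtype=bool)
    )
    fraction = float(bound.mean())
    bound_enh = looped_enh[bound].reset_index(drop=True)
    target_genes: list[str] = []
    if genes is not None and len(bound_enh):
        # partner anchors of loops whose E anchor overlaps a bound enhancer
        keep = has_overlap(e_anchor_df, bound_enh)
        partners = partner_df[keep]
        prom = pd.DataFrame(
            {
                "chrom": genes["chrom"].to_numpy(),
                "start": np.maximum(genes["tss"].to_numpy() - promoter_flank, 0),
                "end": genes["tss"].to_numpy() + promoter_flank,
            }
        )
        hit = has_overlap(prom, partners)
        target_genes = sorted(set(genes.loc[hit, "gene_id"].astype(str)))
    return fraction, bound_enh, target_genes
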