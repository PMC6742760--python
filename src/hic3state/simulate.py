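"""Synthetic multi-cell-line 3D-epigenome dataset with known ground truth.

The generator plants every structure the downstream analyses look for:

* distance-decaying intra-chromosomal contact counts with per-bin
  multiplicative (log-normal) bias, Poisson sampling, within-TAD enrichment
  and loop-anchor-pair enrichment -- expected count for a pair at bin
  distance d is ``C (d+1)^-alpha * tad_boost^[same TAD] * loop_boost^[loop
  pair] * b_i b_j`` with C set so the total mass per chromosome matches the
  configured depth;
* a normal TAD partition of which a subset of large TADs is split into two
  smaller cancer TADs (shared by both cancer lines), with histone-mark
  states per TAD and planted state flips in common TADs;
* loop anchor pairs in three specificity classes (common / normal-specific /
  cancer-specific), each with a designated promoter anchor (hosting an
  expressed gene TSS) and enhancer anchor (hosting a condition-specific
  H3K27ac peak, kept clear of any TSS);
* ChIP-seq-like peak sets and binned signal tracks per mark, CTCF peaks at
  TAD boundaries and loop anchors, NDRs nested in H3K27ac peaks, TF peaks
  bound to a fixed fraction of cancer-specific looped enhancers;
* replicate expression tables with planted fold-change effects on the genes
  whose promoters anchor cancer-specific loops.

Everything is deterministic under (seed, config); ground truth is carried in
a serializable record so downstream checks never re-derive it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import BinTable, ContactMatrix

# substream tags so every stage draws from an independent deterministic stream
_S_TRUTH, _S_BIAS, _S_MATRIX, _S_ANNOT, _S_EXPR = 11, 13, 17, 19, 23


@dataclass(frozen=True)
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    fine_resolution: int = 10_000
    coarse_resolution: int = 40_000
    decay_exponent: float = 1.0
    tad_boost: float = 2.0
    loop_boost: float = 5.0
    depth: float = 2_000_000.0          # contacts per chromosome
    bias_lognormal_sd: float = 0.3
    conditions: tuple[str, ...] = ("normal", "cancerA", "cancerB")
    n_tads_per_chrom: int = 25
    n_split_tads_per_chrom: int = 5
    n_common_loops_per_chrom: int = 6
    n_normal_loops_per_chrom: int = 5
    n_cancer_loops_per_chrom: int = 8
    loop_distance_range: tuple[int, int] = (50_000, 300_000)
    state_fractions: tuple[tuple[str, float], ...] = (
        ("H3K36me3", 0.18), ("H3K27me3", 0.18), ("H3K9me3", 0.14), ("other", 0.50),
    )
    state_flip_fraction: float = 0.25   # of common H3K27me3 TADs -> H3K36me3 in cancer
    n_replicates: int = 3
    noise_sd_log2: float = 0.25
    effect_size: float = 4.0            # RPKM multiplier for planted upregulation
    tf_bound_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coarse_resolution % self.fine_resolution != 0:
            raise ValueError("coarse resolution must be a multiple of fine resolution")
        if self.tad_boost < 1 or self.loop_boost < 1:
            raise ValueError("boosts must be >= 1 (1 disables the structure)")
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be > 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    def fine_bins(self) -> BinTable:
        return BinTable(self.chrom_sizes, self.fine_resolution)

    def rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *tags]))


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the way downstream checks
    need it."""

    tads: dict[str, pd.DataFrame]        # condition -> chrom,start,end,state
    split_parents: pd.DataFrame          # normal TADs split in cancer
    loops: pd.DataFrame                  # chrom,bin1,bin2,promoter_bin,enhancer_bin,class,gene_id
    genes: pd.DataFrame                  # gene_id,chrom,strand,tss,length,expressed,upregulated
    bias: np.ndarray                     # per fine bin, genome-wide
    tf_bound_enhancer_bins: list[tuple[str, int]] = field(default_factory=list)

    def loops_of(self, condition: str) -> pd.DataFrame:
        if condition == "normal":
            keep = self.loops["class"].isin(["common", "normal_specific"])
        else:
            keep = self.loops["class"].isin(["common", "cancer_specific"])
        return self.loops[keep].reset_index(drop=True)

    def boundaries(self, condition: str) -> pd.DataFrame:
        """Internal TAD boundary positions (bp) per chromosome."""
        rows = []
        for chrom, sub in self.tads[condition].groupby("chrom", sort=False):
            inner = sorted(set(sub["start"]) | set(sub["end"]))[1:-1]
            rows.extend({"chrom": chrom, "pos": int(p)} for p in inner)
        return pd.DataFrame(rows, columns=["chrom", "pos"])

    def to_json(self, path) -> None:
        payload = {
            "tads": {k: v.to_dict(orient="list") for k, v in self.tads.items()},
            "split_parents": self.split_parents.to_dict(orient="list"),
            "loops": self.loops.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
            "bias": [round(float(x), 10) for x in self.bias],
            "tf_bound_enhancer_bins": [[c, int(b)] for c, b in self.tf_bound_enhancer_bins],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            tads={k: pd.DataFrame(v) for k, v in payload["tads"].items()},
            split_parents=pd.DataFrame(payload["split_parents"]),
            loops=pd.DataFrame(payload["loops"]),
            genes=pd.DataFrame(payload["genes"]),
            bias=np.asarray(payload["bias"], dtype=np.float64),
            tf_bound_enhancer_bins=[(c, int(b)) for c, b in payload["tf_bound_enhancer_bins"]],
        )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _partition_chrom(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """TAD sizes in coarse bins: minimum 5 bins, remainder multinomial."""
    n_coarse = cfg.chrom_length // cfg.coarse_resolution
    k = cfg.n_tads_per_chrom
    min_size = 5
    extra = n_coarse - k * min_size
    if extra < 0:
        raise ValueError("chromosome too short for the requested TAD count")
    sizes = min_size + rng.multinomial(extra, np.full(k, 1.0 / k))
    return sizes


def make_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    rng = cfg.rng(_S_TRUTH)
    coarse = cfg.coarse_resolution
    fine = cfg.fine_resolution
    state_names = [s for s, _ in cfg.state_fractions]
    state_probs = np.array([p for _, p in cfg.state_fractions])
    state_probs = state_probs / state_probs.sum()

    normal_rows, cancer_rows, split_rows = [], [], []
    loop_rows = []
    used_bins: dict[str, set[int]] = {}

    for chrom in cfg.chrom_names:
        sizes = _partition_chrom(cfg, rng)
        starts = np.concatenate(([0], np.cumsum(sizes)[:-1])) * coarse
        ends = np.cumsum(sizes) * coarse
        ends[-1] = cfg.chrom_length
        states = rng.choice(state_names, size=len(sizes), p=state_probs)

        # split the largest TADs into two cancer TADs at the (coarse) middle
        order = np.argsort(-(ends - starts), kind="mergesort")
        split_idx = set(order[: cfg.n_split_tads_per_chrom].tolist())
        # planted state flips among non-split (common) H3K27me3 TADs
        common_k27 = [i for i in range(len(sizes)) if i not in split_idx and states[i] == "H3K27me3"]
        n_flip = int(np.floor(cfg.state_flip_fraction * len(common_k27)))
        flip_idx = set(
            rng.choice(common_k27, size=n_flip, replace=False).tolist()
        ) if n_flip else set()

        for i in range(len(sizes)):
            s, e, st = int(starts[i]), int(ends[i]), str(states[i])
            normal_rows.append({"chrom": chrom, "start": s, "end": e, "state": st})
            cancer_state = "H3K36me3" if i in flip_idx else st
            if i in split_idx:
                mid = s + ((e - s) // (2 * coarse)) * coarse
                cancer_rows.append({"chrom": chrom, "start": s, "end": mid, "state": cancer_state})
                cancer_rows.append({"chrom": chrom, "start": mid, "end": e, "state": cancer_state})
                split_rows.append({"chrom": chrom, "start": s, "end": e})
            else:
                cancer_rows.append({"chrom": chrom, "start": s, "end": e, "state": cancer_state})

        # ---- loops ----
        used: set[int] = set()
        used_bins[chrom] = used
        dmin = max(1, cfg.loop_distance_range[0] // fine)
        dmax = cfg.loop_distance_range[1] // fine

        def host_tads(cls: str) -> list[tuple[int, int]]:
            if cls == "cancer_specific":
                rows = [r for r in cancer_rows if r["chrom"] == chrom]
            elif cls == "common":
                rows = [
                    r for i, r in enumerate(
                        r2 for r2 in normal_rows if r2["chrom"] == chrom
                    ) if i not in split_idx
                ]
            else:
                rows = [r for r in normal_rows if r["chrom"] == chrom]
            return [(r["start"] // fine, r["end"] // fine) for r in rows]

        def place(cls: str, n_loops: int) -> None:
            hosts = host_tads(cls)
            attempts = 0
            placed = 0
            while placed < n_loops and attempts < 2000:
                attempts += 1
                lo, hi = hosts[int(rng.integers(len(hosts)))]
                span = hi - lo
                if span < dmin + 4:
                    continue
                d = int(rng.integers(dmin, min(dmax, span - 3) + 1))
                a = int(rng.integers(lo + 1, hi - d - 1))
                b = a + d
                if any(
                    u in used for u in (a - 1, a, a + 1, b - 1, b, b + 1)
                ):
                    continue
                promoter_first = bool(rng.integers(2))
                p_bin, e_bin = (a, b) if promoter_first else (b, a)
                used.update((a, b))
                loop_rows.append(
                    {
                        "chrom": chrom,
                        "bin1": min(a, b),
                        "bin2": max(a, b),
                        "promoter_bin": p_bin,
                        "enhancer_bin": e_bin,
                        "class": cls,
                    }
                )
                placed += 1
            if placed < n_loops:
                warnings.warn(f"placed only {placed}/{n_loops} {cls} loops on {chrom}")

        place("common", cfg.n_common_loops_per_chrom)
        place("normal_specific", cfg.n_normal_loops_per_chrom)
        place("cancer_specific", cfg.n_cancer_loops_per_chrom)

    tads_normal = pd.DataFrame(normal_rows)
    tads_cancer = pd.DataFrame(cancer_rows)
    loops = pd.DataFrame(loop_rows)
    loops["distance"] = (loops["bin2"] - loops["bin1"]) * fine

    # ---- genes ----
    gene_rows = []
    gid = 0

    def new_gene(chrom: str, tss: int, expressed: bool, upregulated: bool) -> str:
        nonlocal gid
        gid += 1
        name = f"G{gid:05d}"
        gene_rows.append(
            {
                "gene_id": name,
                "chrom": chrom,
                "strand": "+" if rng.integers(2) else "-",
                "tss": int(tss),
                "length": int(rng.integers(5_000, 50_000)),
                "expressed": bool(expressed),
                "upregulated": bool(upregulated),
            }
        )
        return name

    loops["gene_id"] = [
        new_gene(
            r["chrom"],
            r["promoter_bin"] * fine + fine // 2,
            expressed=True,
            upregulated=r["class"] == "cancer_specific",
        )
        for _, r in loops.iterrows()
    ]

    # background genes, density by TAD state; kept >= 1 bin away from anchors
    forbidden = {
        chrom: {b + off for b in bins for off in (-1, 0, 1)}
        for chrom, bins in used_bins.items()
    }
    for _, tad in tads_normal.iterrows():
        st = tad["state"]
        if st == "H3K36me3":
            n_genes = int(rng.integers(7, 11))
            p_expr = 0.75
        elif st == "other":
            n_genes = int(rng.integers(0, 6))
            p_expr = 0.4
        else:
            n_genes = int(rng.integers(0, 3))
            p_expr = 0.2
        lo_bin = tad["start"] // fine
        hi_bin = tad["end"] // fine
        free = [b for b in range(lo_bin, hi_bin) if b not in forbidden[tad["chrom"]]]
        for _ in range(n_genes):
            if not free:
                break
            b = free[int(rng.integers(len(free)))]
            tss = b * fine + int(rng.integers(2_500, fine - 2_500))
            new_gene(tad["chrom"], tss, expressed=rng.random() < p_expr, upregulated=False)
    genes = pd.DataFrame(gene_rows).sort_values(["chrom", "tss"]).reset_index(drop=True)

    # ---- per-bin bias (shared across conditions) ----
    brng = cfg.rng(_S_BIAS)
    n_bins = cfg.fine_bins().n_bins
    bias = np.exp(brng.normal(0.0, cfg.bias_lognormal_sd, size=n_bins))
    bias /= bias.mean()

    # ---- TF-bound cancer-specific looped enhancers ----
    cs = loops[loops["class"] == "cancer_specific"]
    n_bound = int(round(cfg.tf_bound_fraction * len(cs)))
    bound_rows = (
        rng.choice(len(cs), size=n_bound, replace=False) if n_bound else np.empty(0, int)
    )
    tf_bound = [
        (cs.iloc[int(i)]["chrom"], int(cs.iloc[int(i)]["enhancer_bin"])) for i in bound_rows
    ]

    return GroundTruth(
        tads={"normal": tads_normal, "cancerA": tads_cancer.copy(), "cancerB": tads_cancer.copy()},
        split_parents=pd.DataFrame(split_rows, columns=["chrom", "start", "end"]),
        loops=loops,
        genes=genes,
        bias=bias,
        tf_bound_enhancer_bins=tf_bound,
    )


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

def _tad_id_per_bin(tads: pd.DataFrame, chrom: str, n_bins: int, fine: int) -> np.ndarray:
    sub = tads[tads["chrom"] == chrom].sort_values("start")
    starts = sub["start"].to_numpy() // fine
    tid = np.searchsorted(starts, np.arange(n_bins), side="right") - 1
    return tid


def _structure_lambdas(
    cfg: SimulationConfig, truth: GroundTruth, condition: str, chrom: str
) -> list[np.ndarray]:
    """Per-distance expected-count structure (C = 1), index d = 0..n-1."""
    n = cfg.chrom_length // cfg.fine_resolution + (cfg.chrom_length % cfg.fine_resolution > 0)
    tid = _tad_id_per_bin(truth.tads[condition], chrom, n, cfg.fine_resolution)
    loops = truth.loops_of(condition)
    loops = loops[loops["chrom"] == chrom]
    loop_by_d: dict[int, list[int]] = {}
    for _, r in loops.iterrows():
        loop_by_d.setdefault(int(r["bin2"] - r["bin1"]), []).append(int(r["bin1"]))
    lams = []
    alpha = cfg.decay_exponent
    for d in range(n):
        base = (d + 1.0) ** (-alpha)
        lam = np.full(n - d, base)
        same = tid[: n - d] == tid[d:]
        lam[same] *= cfg.tad_boost
        for i in loop_by_d.get(d, []):
            lam[i] *= cfg.loop_boost
        lams.append(lam)
    return lams


def depth_for_diagonal_mean(
    cfg: SimulationConfig,
    truth: GroundTruth,
    condition: str,
    target_diag_mean: float,
    at_resolution: int | None = None,
) -> float:
    """Depth per chromosome that yields the requested mean diagonal count at
    ``at_resolution`` (default: the coarse resolution)."""
    res = at_resolution or cfg.coarse_resolution
    factor = res // cfg.fine_resolution
    total_struct = 0.0
    diag_struct = 0.0
    n_diag = 0
    for chrom in cfg.chrom_names:
        lams = _structure_lambdas(cfg, truth, condition, chrom)
        n = len(lams[0])
        total_struct += sum(l.sum() for l in lams)
        blocks = np.arange(n) // factor
        for d in range(min(factor, n)):
            same_block = blocks[: n - d] == blocks[d:]
            diag_struct += lams[d][same_block].sum()
        n_diag += n // factor
    # mean diag = C * diag_struct / n_diag with C = depth * n_chroms / total... C is per chrom
    # depth applies per chromosome: C_chrom = depth / (total_struct / n_chroms)
    per_chrom_struct = total_struct / cfg.n_chroms
    per_chrom_diag = diag_struct / cfg.n_chroms
    n_diag_per_chrom = n_diag / cfg.n_chroms
    c_needed = target_diag_mean * n_diag_per_chrom / per_chrom_diag
    return float(c_needed * per_chrom_struct)


def simulate_contact_matrix(
    cfg: SimulationConfig, truth: GroundTruth, condition: str
) -> ContactMatrix:
    """Poisson-sampled fine-resolution contact matrix for one condition."""
    bins = cfg.fine_bins()
    rng = cfg.rng(_S_MATRIX, cfg.conditions.index(condition))
    rows, cols, vals = [], [], []
    for chrom in cfg.chrom_names:
        lo, hi = bins.bin_range(chrom)
        b = truth.bias[lo:hi]
        lams = _structure_lambdas(cfg, truth, condition, chrom)
        n = len(lams[0])
        c_scale = cfg.depth / sum(l.sum() for l in lams)
        if c_scale * lams[0].mean() < 1:
            warnings.warn(
                f"depth too small: mean diagonal count < 1 on {chrom} ({condition})"
            )
        for d in range(n):
            mu = c_scale * lams[d] * b[: n - d] * b[d:]
            counts = rng.poisson(mu)
            nz = np.flatnonzero(counts)
            if nz.size:
                rows.append(nz + lo)
                cols.append(nz + d + lo)
                vals.append(counts[nz])
    if rows:
        return ContactMatrix.from_entries(
            bins, np.concatenate(rows), np.concatenate(cols),
            np.concatenate(vals).astype(np.float64),
        )
    return ContactMatrix(bins)


def simulate_null_matrix(
    cfg: SimulationConfig, seed_tag: int = 0
) -> ContactMatrix:
    """Structure-free matrix (pure distance decay + bias): the loop-caller
    calibration null."""
    bins = cfg.fine_bins()
    rng = cfg.rng(_S_MATRIX, 999, seed_tag)
    brng = cfg.rng(_S_BIAS)
    bias = np.exp(brng.normal(0.0, cfg.bias_lognormal_sd, size=bins.n_bins))
    bias /= bias.mean()
    rows, cols, vals = [], [], []
    alpha = cfg.decay_exponent
    for chrom in cfg.chrom_names:
        lo, hi = bins.bin_range(chrom)
        n = hi - lo
        b = bias[lo:hi]
        struct_total = sum((n - d) * (d + 1.0) ** (-alpha) for d in range(n))
        c_scale = cfg.depth / struct_total
        for d in range(n):
            mu = c_scale * (d + 1.0) ** (-alpha) * b[: n - d] * b[d:]
            counts = rng.poisson(mu)
            nz = np.flatnonzero(counts)
            if nz.size:
                rows.append(nz + lo)
                cols.append(nz + d + lo)
                vals.append(counts[nz])
    if rows:
        return ContactMatrix.from_entries(
            bins, np.concatenate(rows), np.concatenate(cols),
            np.concatenate(vals).astype(np.float64),
        )
    return ContactMatrix(bins)


# ---------------------------------------------------------------------------
# Annotations (peaks, tracks, NDRs, TF) and expression
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAnnotations:
    peaks: dict[str, pd.DataFrame]       # mark -> chrom,start,end,name,score
    signal_tracks: dict[str, pd.DataFrame]  # mark -> chrom,start,end,value
    ndrs: pd.DataFrame
    tf_peaks: pd.DataFrame
    ctcf_peaks: pd.DataFrame


_PEAK_COLS = ["chrom", "start", "end", "name", "score"]


def _peak_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_PEAK_COLS)
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def simulate_annotations(
    cfg: SimulationConfig, truth: GroundTruth, condition: str
) -> SimulatedAnnotations:
    rng = cfg.rng(_S_ANNOT, cfg.conditions.index(condition))
    fine = cfg.fine_resolution
    tads = truth.tads[condition]
    loops_here = truth.loops_of(condition)

    # bins (any condition) reserved for planted anchors: background peaks stay out
    anchor_exclusion: dict[str, set[int]] = {}
    for _, r in truth.loops.iterrows():
        s = anchor_exclusion.setdefault(r["chrom"], set())
        for b in (int(r["bin1"]), int(r["bin2"])):
            s.update((b - 1, b, b + 1))

    def sample_center(chrom: str, lo: int, hi: int, avoid_anchors: bool) -> int:
        excl = anchor_exclusion.get(chrom, set())
        for _ in range(50):
            c = int(rng.integers(lo, hi))
            if not avoid_anchors or (c // fine) not in excl:
                return c
        return int(rng.integers(lo, hi))

    mark_rows: dict[str, list[dict]] = {m: [] for m in ("H3K36me3", "H3K27me3", "H3K9me3", "H3K27ac")}
    pk = 0

    def add_peak(mark: str, chrom: str, center: int, width: int, score: float) -> dict:
        nonlocal pk
        pk += 1
        row = {
            "chrom": chrom,
            "start": max(0, center - width // 2),
            "end": center + width // 2,
            "name": f"{mark}_{pk}",
            "score": float(score),
        }
        mark_rows[mark].append(row)
        return row

    planted_k27ac: list[dict] = []
    for _, tad in tads.iterrows():
        chrom, s, e, st = tad["chrom"], int(tad["start"]), int(tad["end"]), tad["state"]
        for mark in ("H3K36me3", "H3K27me3", "H3K9me3"):
            if st == mark:
                for _ in range(15 if mark != "H3K36me3" else 20):
                    add_peak(mark, chrom, sample_center(chrom, s + 500, e - 500, True),
                             1_000, rng.uniform(5, 10))
            else:
                for _ in range(3):
                    add_peak(mark, chrom, sample_center(chrom, s + 500, e - 500, True),
                             600, rng.uniform(0.5, 2.0))
        if st == "H3K36me3":
            for _ in range(15):
                row = add_peak("H3K27ac", chrom, sample_center(chrom, s + 500, e - 500, True),
                               800, rng.uniform(4, 8))
                planted_k27ac.append(row)

    # enhancer-anchor H3K27ac peaks for loops present in this condition
    for _, r in loops_here.iterrows():
        center = int(r["enhancer_bin"]) * fine + fine // 2
        row = add_peak("H3K27ac", r["chrom"], center, 800, rng.uniform(8, 10))
        planted_k27ac.append(row)

    # NDRs nested inside every planted H3K27ac peak
    ndr_rows = []
    for i, row in enumerate(planted_k27ac):
        mid = (row["start"] + row["end"]) // 2
        ndr_rows.append(
            {"chrom": row["chrom"], "start": mid - 150, "end": mid + 150,
             "name": f"NDR_{i + 1}", "score": 1.0}
        )

    # CTCF: TAD boundaries + loop anchors + background
    ctcf_rows = []
    ck = 0

    def add_ctcf(chrom: str, center: int, score: float) -> None:
        nonlocal ck
        ck += 1
        ctcf_rows.append(
            {"chrom": chrom, "start": max(0, center - 300), "end": center + 300,
             "name": f"CTCF_{ck}", "score": float(score)}
        )

    for chrom, sub in tads.groupby("chrom", sort=False):
        for pos in sorted(set(sub["start"]) | set(sub["end"]))[1:-1]:
            add_ctcf(chrom, int(pos), rng.uniform(5, 10))
    for _, r in loops_here.iterrows():
        for b in (int(r["bin1"]), int(r["bin2"])):
            add_ctcf(r["chrom"], b * fine + fine // 2 + 2_500, rng.uniform(4, 8))
    for chrom in cfg.chrom_names:
        for _ in range(20):
            add_ctcf(chrom, sample_center(chrom, 1_000, cfg.chrom_length - 1_000, True),
                     rng.uniform(0.5, 3.0))

    # TF peaks: cancer conditions only, on the fixed bound-enhancer subset
    tf_rows = []
    if condition != "normal":
        for i, (chrom, b) in enumerate(truth.tf_bound_enhancer_bins):
            center = b * fine + fine // 2
            tf_rows.append(
                {"chrom": chrom, "start": center - 250, "end": center + 250,
                 "name": f"TF_{i + 1}", "score": float(rng.uniform(5, 10))}
            )
        for chrom in cfg.chrom_names:
            for j in range(10):
                c = sample_center(chrom, 1_000, cfg.chrom_length - 1_000, True)
                tf_rows.append(
                    {"chrom": chrom, "start": c - 200, "end": c + 200,
                     "name": f"TFbg_{chrom}_{j}", "score": float(rng.uniform(1, 3))}
                )

    # binned signal tracks: noise floor + elevation inside enriched TADs
    tracks: dict[str, pd.DataFrame] = {}
    bins = cfg.fine_bins()
    frame = bins.to_frame()
    for mark in ("H3K36me3", "H3K27me3", "H3K9me3", "H3K27ac"):
        value = np.abs(rng.normal(0.5, 0.15, size=bins.n_bins))
        source_state = "H3K36me3" if mark == "H3K27ac" else mark
        for _, tad in tads[tads["state"] == source_state].iterrows():
            lo = bins.bin_id(tad["chrom"], int(tad["start"]))
            hi = bins.bin_id(tad["chrom"], int(tad["end"]) - 1) + 1
            value[lo:hi] += rng.normal(3.0, 0.3, size=hi - lo)
        track = frame[["chrom", "start", "end"]].copy()
        track["value"] = np.round(value, 6)
        tracks[mark] = track

    return SimulatedAnnotations(
        peaks={m: _peak_frame(rows) for m, rows in mark_rows.items()},
        signal_tracks=tracks,
        ndrs=_peak_frame(ndr_rows),
        tf_peaks=_peak_frame(tf_rows),
        ctcf_peaks=_peak_frame(ctcf_rows),
    )


def simulate_expression(cfg: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """RPKM table: genes x (condition, replicate); planted upregulated genes
    carry the configured effect in every cancer condition."""
    rng = cfg.rng(_S_EXPR)
    genes = truth.genes
    base_log = np.where(
        genes["expressed"].to_numpy(),
        rng.uniform(2.2, 5.0, size=len(genes)),
        rng.uniform(0.0, 0.8, size=len(genes)),
    )
    base_rpkm = 2.0 ** base_log - 1.0
    data = {}
    for cond in cfg.conditions:
        effect = np.where(
            genes["upregulated"].to_numpy() & (cond != "normal"), cfg.effect_size, 1.0
        )
        for rep in range(cfg.n_replicates):
            noise = 2.0 ** rng.normal(0.0, cfg.noise_sd_log2, size=len(genes))
            data[f"{cond}_rep{rep + 1}"] = np.round(base_rpkm * effect * noise, 6)
    return pd.DataFrame(data, index=genes["gene_id"].to_numpy())


# ---------------------------------------------------------------------------
# Dataset on disk
# ---------------------------------------------------------------------------

def write_dataset(cfg: SimulationConfig, outdir) -> GroundTruth:
    """Generate the full dataset and write it in the pipeline's input
    formats (triplet matrices + bin BEDs, peak BEDs, signal TSVs, gene TSV
    with expression columns, ground-truth JSON)."""
    from .genome_io import write_contact_matrix, write_gene_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_ground_truth(cfg)
    expr = simulate_expression(cfg, truth)
    genes_out = truth.genes.drop(columns=["expressed", "upregulated"]).merge(
        expr, left_on="gene_id", right_index=True
    )
    write_gene_table(genes_out, outdir / "genes.tsv")
    truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1)
    for cond in cfg.conditions:
        cdir = outdir / cond
        cdir.mkdir(exist_ok=True)
        mat = simulate_contact_matrix(cfg, truth, cond)
        write_contact_matrix(mat, cdir / "matrix.tsv", cdir / "bins.bed")
        ann = simulate_annotations(cfg, truth, cond)
        for mark, peaks in ann.peaks.items():
            peaks.to_csv(cdir / f"{mark}_peaks.bed", sep="\t", header=False, index=False)
        for mark, track in ann.signal_tracks.items():
            track.to_csv(cdir / f"{mark}_signal.tsv", sep="\t", index=False)
        ann.ndrs.to_csv(cdir / "ndrs.bed", sep="\t", header=False, index=False)
        ann.tf_peaks.to_csv(cdir / "tf_peaks.bed", sep="\t", header=False, index=False)
        ann.ctcf_peaks.to_csv(cdir / "ctcf_peaks.bed", sep="\t", header=False, index=False)
    return truth


def config_with_diagonal_mean(
    cfg: SimulationConfig, target_diag_mean: float, condition: str = "normal"
) -> tuple[SimulationConfig, GroundTruth]:
    """Clone a config with depth chosen to hit a target mean diagonal count
    at the coarse resolution (ground truth is depth-independent)."""
    truth = make_ground_truth(cfg)
    depth = depth_for_diagonal_mean(cfg, truth, condition, target_diag_mean)
    return replace(cfg, depth=depth), truth
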