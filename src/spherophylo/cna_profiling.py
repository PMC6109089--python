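"""Variable-size bin copy-number profiling.

Implements the low-depth WGS copy-number workflow: the genome is divided
into a fixed number of variable-sized bins such that each bin contains an
(as nearly as possible) equal number of reference mappable positions, reads
are counted per bin, the count-vs-GC trend is removed by Lowess, and the
normalized depth is scaled by the median depth of the reference DNA to a
copy-number ratio (1.0 = diploid-neutral). Profiles are then clustered
hierarchically into genetic subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import skew, spearmanr
from sklearn.metrics import silhouette_score
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .synthetic_data import gc_content


@dataclass
class BinningConfig:
    n_bins: int = 15_000
    lowess_fraction: float = 0.3
    lowess_iterations: int = 1
    linkage: str = "ward"
    distance: str = "euclidean"
    max_clusters: int = 6
    skew_threshold: float = 1.0

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not 0 < self.lowess_fraction <= 1:
            raise ValueError("lowess_fraction must be in (0, 1]")


@dataclass
class CopyNumberProfile:
    sample_id: str
    ratio: np.ndarray          # per-bin copy-number ratio, 1.0 = neutral
    raw_counts: np.ndarray

    def __post_init__(self):
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts)
        if len(self.ratio) != len(self.raw_counts):
            raise ValueError("ratio and raw_counts must have equal length")
        if (self.ratio < 0).any():
            raise ValueError("copy-number ratios must be non-negative")


# ---------------------------------------------------------------------------
# Variable-size binning
# ---------------------------------------------------------------------------

def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``shares``."""
    raw = shares / shares.sum() * total
    quotas = np.floor(raw).astype(int)
    rem = total - quotas.sum()
    order = np.argsort(-(raw - quotas))
    quotas[order[:rem]] += 1
    return quotas


def build_variable_bins(reference_positions: dict, config: BinningConfig | None = None,
                        n_bins: int | None = None, gc=gc_content) -> pd.DataFrame:
    """Divide the genome into variable-sized bins of equal reference coverage.

    ``reference_positions`` maps chromosome -> sorted array of uniquely
    mappable read-start positions of the reference DNA. The total bin
    quota is apportioned to chromosomes by their share of positions
    (largest-remainder rule); within a chromosome, bins are chosen so each
    contains ``floor(N/k)`` or ``ceil(N/k)`` positions, with boundaries at
    the midpoint between adjacent positions of neighbouring bins. Bins are
    0-based half-open, contiguous over each chromosome's covered span.

    Returns a DataFrame with columns chrom, start, end, gc, n_ref.
    """
    if config is None:
        config = BinningConfig(n_bins=n_bins if n_bins is not None else 15_000)
    if n_bins is not None:
        config = BinningConfig(n_bins=n_bins, lowess_fraction=config.lowess_fraction)
    chroms = [c for c in reference_positions if len(reference_positions[c]) > 0]
    counts = np.array([len(reference_positions[c]) for c in chroms])
    total = int(counts.sum())
    if total < config.n_bins:
        raise ValueError(f"{total} reference positions cannot fill {config.n_bins} bins")

    quotas = _largest_remainder(counts.astype(float), config.n_bins)
    # every chromosome with positions gets at least one bin, and never more
    # bins than positions; steal from / give to the largest-count chromosomes
    for _ in range(2 * len(chroms)):
        under = np.where(quotas == 0)[0]
        over = np.where(quotas > counts)[0]
        if len(under) == 0 and len(over) == 0:
            break
        if len(under):
            donor = np.argmax(quotas - 1)   # chromosome that can spare a bin
            quotas[donor] -= 1
            quotas[under[0]] += 1
        if len(over):
            i = over[0]
            excess = quotas[i] - counts[i]
            quotas[i] -= excess
            taker = np.argmax(counts - quotas)
            quotas[taker] += excess

    rows = []
    for chrom, q in zip(chroms, quotas):
        pos = np.asarray(reference_positions[chrom])
        if not np.all(np.diff(pos) >= 0):
            pos = np.sort(pos)
        n = len(pos)
        # index boundaries giving per-bin counts of floor(n/q) or ceil(n/q);
        # tied coordinates cannot be split by an interval boundary, so each
        # interior boundary is pushed to the end of its run of equal values
        idx = ((np.arange(q + 1) * n) // q).astype(int)
        for k in range(1, q):
            while 0 < idx[k] < n and pos[idx[k] - 1] == pos[idx[k]]:
                idx[k] += 1
        idx = np.minimum.accumulate(idx[::-1])[::-1]   # keep non-decreasing
        if len(np.unique(idx)) != q + 1:
            raise ValueError(
                f"too many tied positions on {chrom} to form {q} non-empty bins")
        starts, ends = [], []
        for k in range(q):
            first, last = pos[idx[k]], pos[idx[k + 1] - 1]
            if k == 0:
                start = int(first)
            else:
                start = ends[-1]
            if k == q - 1:
                end = int(last) + 1
            else:
                nxt = pos[idx[k + 1]]
                end = int((last + nxt) // 2) + 1
            starts.append(start)
            ends.append(end)
            rows.append((chrom, start, end, idx[k + 1] - idx[k]))

    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_ref"])
    if gc is not None:
        mids = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
        bins["gc"] = np.concatenate([
            gc(chrom, mids[bins["chrom"] == chrom])
            for chrom in bins["chrom"].unique()
        ]) if len(bins) else np.array([])
    return bins


def count_reads_in_bins(read_positions: dict, bins: pd.DataFrame) -> np.ndarray:
    """Assign each read start to the bin containing it (half-open intervals).

    Reads outside the covered territory of their chromosome are dropped.
    """
    out = np.zeros(len(bins), dtype=np.int64)
    for chrom, sub in bins.groupby("chrom", sort=False):
        pos = np.asarray(read_positions.get(chrom, []), dtype=np.int64)
        if len(pos) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        np.add.at(out, sub.index.to_numpy()[j[ok]], 1)
    return out


# ---------------------------------------------------------------------------
# Lowess GC normalization and copy ratio
# ---------------------------------------------------------------------------

def lowess_gc_normalize(counts, gc_per_bin, lowess_fraction: float = 0.3,
                        iterations: int = 1) -> np.ndarray:
    """Remove the count-vs-GC trend by locally weighted regression.

    Counts are divided by the Lowess fit of count against GC, then rescaled
    so the genome-wide median of the output equals the median of the input.
    If all GC values are equal no trend is fittable and the input is
    returned unchanged (with a warning).
    """
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc_per_bin, dtype=float)
    if len(counts) != len(gc):
        raise ValueError("counts and gc must have equal length")
    if len(counts) < 10:
        raise ValueError("need at least 10 bins for a Lowess fit")
    if np.ptp(gc) == 0:
        warnings.warn("all GC values equal; no GC trend fittable", stacklevel=2)
        return counts.copy()
    fitted = sm_lowess(counts, gc, frac=lowess_fraction, it=iterations,
                       return_sorted=False)
    floor = max(1e-12, 1e-6 * np.median(np.abs(fitted)))
    fitted = np.maximum(fitted, floor)
    norm = counts / fitted
    med = np.median(norm)
    if med > 0:
        norm = norm * (np.median(counts) / med)
    return norm


def residual_gc_trend(depths, gc_per_bin) -> float:
    """Spearman correlation of normalized depth vs GC (QC statistic)."""
    rho = spearmanr(depths, gc_per_bin).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def estimate_copy_ratio(sample_id: str, sample_depths, reference_depths,
                        raw_counts=None) -> CopyNumberProfile:
    """Copy-number ratio: per-bin normalized depth over the median depth of
    the reference DNA. For the reference sample itself the median ratio is
    exactly 1.0."""
    sample_depths = np.asarray(sample_depths, dtype=float)
    reference_depths = np.asarray(reference_depths, dtype=float)
    if len(sample_depths) != len(reference_depths):
        raise ValueError("sample and reference must share the bin grid")
    med = np.median(reference_depths)
    if med == 0:
        raise ValueError("median reference depth is zero")
    ratio = sample_depths / med
    raw = sample_depths if raw_counts is None else raw_counts
    return CopyNumberProfile(sample_id=sample_id, ratio=ratio, raw_counts=raw)


# ---------------------------------------------------------------------------
# QC and clustering
# ---------------------------------------------------------------------------

def depth_distribution_qc(profile, skew_threshold: float = 1.0) -> dict:
    """Summary statistics of the normalized-depth distribution.

    Uneven whole-genome amplification shows up as heavy-tailed / skewed
    depth distributions; the sample is flagged when |skewness| exceeds the
    threshold. A constant profile has variance 0 and skewness defined as 0.
    """
    values = profile.ratio if isinstance(profile, CopyNumberProfile) else np.asarray(profile, float)
    if len(values) == 0:
        raise ValueError("profile is empty")
    var = float(np.var(values))
    sk = 0.0 if var == 0 else float(skew(values))
    return {"mean": float(np.mean(values)), "variance": var, "skewness": sk,
            "flagged_skewed": bool(abs(sk) > skew_threshold)}


def cluster_profiles(profiles: list, config: BinningConfig | None = None):
    """Hierarchically cluster copy-number profiles into genetic subgroups.

    Ward linkage on Euclidean distances between per-bin ratio vectors; the
    number of clusters is chosen by maximizing the mean silhouette over
    k in [2, min(max_clusters, n - 1)]. Returns ``(labels, k, linkage
    matrix, silhouette)`` with labels aligned to the input order.
    """
    if config is None:
        config = BinningConfig()
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = np.vstack([p.ratio for p in profiles])
    dists = pdist(X, metric=config.distance)
    if np.max(dists, initial=0.0) == 0:
        warnings.warn("all profiles identical; clustering is degenerate", stacklevel=2)
        labels = np.zeros(len(profiles), dtype=int)
        labels[-1] = 1
        Z = hierarchy.linkage(dists, method=config.linkage)
        return labels, 2, Z, 0.0
    Z = hierarchy.linkage(dists, method=config.linkage)
    best = None
    for k in range(2, min(config.max_clusters, len(profiles) - 1) + 1):
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels, metric=config.distance)
        if best is None or score > best[0]:
            best = (score, k, labels)
    if best is None:   # n == 2: silhouette undefined, fall back to 2 clusters
        labels = hierarchy.fcluster(Z, t=2, criterion="maxclust") - 1
        return labels, 2, Z, 0.0
    score, k, labels = best
    return labels, k, Z, float(score)
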