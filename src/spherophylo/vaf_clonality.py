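"""Variant-allele-frequency analysis: purity, subclonality, clonality index.

For a diploid heterozygous somatic variant carried by every tumor cell of
a sample with tumor purity ``p``, the expected VAF is ``p/2``. Hence:

* purity is estimated as ``min(1, 2 x median VAF)`` over the common
  (clonal) mutations of the sample; samples below a purity threshold are
  flagged and excluded from phylogenetics, mirroring the exclusion of
  normal-cell-rich spheroids;
* a one-sided Mann-Whitney U test of common-vs-group-private VAFs detects
  subclonal structure (private mutations carried by only part of the
  tumor cells sit at lower VAF);
* a likelihood-ratio clonality index scores whether two samples share a
  clonal origin: each shared rare mutation multiplies the odds by 1/p_i
  (p_i = background probability of mutation at locus i under independent
  origin), each discordant locus by a penalty < 1, and the ratio is mapped
  to [0, 1] via LR/(1+LR). Two samples with no shared mutations have
  index 0 by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .snv_consensus import CATEGORY_ASCITES, CATEGORY_COMMON, CATEGORY_PRIMARY, ConsensusTable


@dataclass
class PuritySummary:
    sample_id: str
    purity: float | None
    low_purity: bool
    n_loci: int
    comparison_p: float | None = None


@dataclass
class ClonalityResult:
    sample_a: str
    sample_b: str
    ci: float
    n_shared: int
    n_private_a: int
    n_private_b: int
    background_prob: float


# ---------------------------------------------------------------------------
# VAF records
# ---------------------------------------------------------------------------

def compute_vafs(table: ConsensusTable, pileups_by_sample: dict) -> pd.DataFrame:
    """Per-sample VAF at every final locus, labelled with its category.

    VAF = variant allele count / total pileup depth. Zero-depth records
    are dropped with a warning. Absent loci are reported at their measured
    (typically zero) allele fraction so distributions can be compared.
    """
    lookups = {s: {(r.chrom, r.pos): r for r in p.itertuples()}
               for s, p in pileups_by_sample.items()}
    rows = []
    for locus in table.presence.index:
        chrom, pos, alt = locus
        cat = table.category.loc[[locus]].iloc[0]
        for s in table.presence.columns:
            row = lookups.get(s, {}).get((chrom, pos))
            if row is None:
                continue
            depth = int(row.A + row.C + row.G + row.T)
            if depth == 0:
                warnings.warn(f"zero depth for {s} at {chrom}:{pos}; record dropped",
                              stacklevel=2)
                continue
            alt_depth = int(getattr(row, alt))
            present = bool(table.presence.loc[[locus], s].iloc[0])
            rows.append((chrom, pos, alt, s, alt_depth, depth,
                         alt_depth / depth, cat, present))
    return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "sample", "alt_depth",
                                       "total_depth", "vaf", "category", "present"])


def compare_common_vs_private(vafs: pd.DataFrame, sample_id: str, group: str,
                              alpha: float = 0.01) -> dict:
    """Test whether common-mutation VAFs exceed group-private VAFs.

    One-sided Mann-Whitney U (common > private) on the sample's present
    loci. A significantly higher common-VAF distribution indicates that the
    private mutations are subclonal within the sample. Requires at least 3
    present records in each category; otherwise the verdict is
    "not testable".
    """
    private_cat = CATEGORY_PRIMARY if group == "primary" else CATEGORY_ASCITES
    sub = vafs[(vafs["sample"] == sample_id) & vafs["present"]]
    common = sub.loc[sub["category"] == CATEGORY_COMMON, "vaf"].to_numpy()
    private = sub.loc[sub["category"] == private_cat, "vaf"].to_numpy()
    if len(common) < 3 or len(private) < 3:
        return {"sample_id": sample_id, "p_value": None, "verdict": "not testable",
                "n_common": len(common), "n_private": len(private)}
    p = float(mannwhitneyu(common, private, alternative="greater").pvalue)
    verdict = "subclonal structure" if p < alpha else "no subclonal structure detected"
    return {"sample_id": sample_id, "p_value": p, "verdict": verdict,
            "n_common": len(common), "n_private": len(private)}


def estimate_purity(vafs: pd.DataFrame, sample_id: str,
                    low_purity_threshold: float = 0.3) -> PuritySummary:
    """Tumor purity from the clonal (common) VAF distribution.

    purity = min(1, 2 x median VAF over present common loci). With fewer
    than 3 common loci the purity is undefined and the sample is flagged
    low-purity (it cannot be trusted in phylogenetics either way).
    """
    sub = vafs[(vafs["sample"] == sample_id) & vafs["present"]
               & (vafs["category"] == CATEGORY_COMMON)]
    if len(sub) < 3:
        return PuritySummary(sample_id=sample_id, purity=None, low_purity=True,
                             n_loci=len(sub))
    purity = float(min(1.0, 2.0 * np.median(sub["vaf"])))
    return PuritySummary(sample_id=sample_id, purity=purity,
                         low_purity=purity < low_purity_threshold, n_loci=len(sub))


# ---------------------------------------------------------------------------
# Clonality index
# ---------------------------------------------------------------------------

def clonality_index(loci_a, loci_b, background_probs=1e-4,
                    discordance_penalty: float = 0.5) -> ClonalityResult:
    """Likelihood-ratio clonality index for a pair of mutation profiles.

    ``background_probs`` is either a scalar (uniform background mutation
    probability per locus) or a mapping locus -> probability. The
    likelihood ratio of clonal vs independent origin is

        LR = prod_{shared i} (1 / p_i) * prod_{discordant j} nu,

    with nu the discordance penalty (< 1: each private mutation is less
    likely under a shared clonal origin). The reported index is
    CI = LR / (1 + LR) in [0, 1]; with no shared mutations CI = 0.
    """
    loci_a, loci_b = set(loci_a), set(loci_b)
    if not loci_a or not loci_b:
        raise ValueError("both samples need at least one somatic locus")
    if not 0 < discordance_penalty < 1:
        raise ValueError("discordance penalty must be in (0, 1)")

    def prob(locus):
        p = background_probs if np.isscalar(background_probs) else background_probs[locus]
        if not 0 < p < 1:
            raise ValueError(f"background probability must be in (0, 1), got {p}")
        return p

    shared = loci_a & loci_b
    private_a, private_b = loci_a - loci_b, loci_b - loci_a
    scalar_bg = float(background_probs) if np.isscalar(background_probs) else float("nan")
    if not shared:
        ci = 0.0
    else:
        log_lr = -sum(np.log(prob(l)) for l in shared)
        log_lr += (len(private_a) + len(private_b)) * np.log(discordance_penalty)
        # LR/(1+LR) computed stably in log space
        ci = float(1.0 / (1.0 + np.exp(-log_lr))) if abs(log_lr) < 700 else \
            (1.0 if log_lr > 0 else 0.0)
    return ClonalityResult(sample_a="A", sample_b="B", ci=ci, n_shared=len(shared),
                           n_private_a=len(private_a), n_private_b=len(private_b),
                           background_prob=scalar_bg)


def plot_vaf_histograms(vafs: pd.DataFrame, path, bins: int = 25) -> None:
    """One VAF histogram panel per sample, colored by mutation category
    (PNG/SVG chosen by file extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = sorted(vafs["sample"].unique())
    ncol = min(4, len(samples))
    nrow = (len(samples) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False, sharex=True)
    colors = {CATEGORY_COMMON: "#444444", CATEGORY_PRIMARY: "#c0392b",
              CATEGORY_ASCITES: "#2980b9"}
    edges = np.linspace(0, 1, bins + 1)
    for ax, s in zip(axes.flat, samples):
        sub = vafs[(vafs["sample"] == s) & vafs["present"]]
        for cat, color in colors.items():
            vals = sub.loc[sub["category"] == cat, "vaf"]
            if len(vals):
                ax.hist(vals, bins=edges, alpha=0.6, color=color, label=cat)
        ax.set_title(s, fontsize=9)
        ax.set_xlim(0, 1)
    for ax in axes.flat[len(samples):]:
        ax.set_visible(False)
    axes.flat[0].legend(fontsize=7)
    fig.supxlabel("variant allele frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def purity_table(vafs: pd.DataFrame, groups: dict,
                 low_purity_threshold: float = 0.3, alpha: float = 0.01) -> pd.DataFrame:
    """Per-sample purity and common-vs-private comparison, as one table."""
    rows = []
    for s in sorted(vafs["sample"].unique()):
        ps = estimate_purity(vafs, s, low_purity_threshold)
        cmp_res = compare_common_vs_private(vafs, s, groups.get(s, "primary"), alpha)
        rows.append((s, groups.get(s), ps.purity, ps.low_purity, ps.n_loci,
                     cmp_res["p_value"], cmp_res["verdict"]))
    return pd.DataFrame(rows, columns=["sample", "group", "purity", "low_purity",
                                       "n_common_loci", "common_vs_private_p", "verdict"])
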