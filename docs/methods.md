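# Methods

This note documents the models, parameter choices and numerical details
behind spherophylo, and what the synthetic-data experiments do and do not
demonstrate.

## Simulation model

**Clone tree.** The root represents the normal (germline) genotype. Each
tumor clone attaches to an earlier clone; a clone's genotype is the union
of all events on its root path. Two generators are provided:
`simulate_clone_tree` (random attachment, arbitrary shape — used by the
end-to-end pipeline) and `simulate_binary_clone_tree` (fully binary, with
samples intended at leaf clones — used by topology-recovery studies,
where a well-defined binary truth is needed for Robinson–Foulds
comparison). Every edge carries at least one event; the binary generator
can guarantee at least one SNV *and* one CNA per edge so that either data
type alone determines the topology.

**Events.** The model is diploid-baseline: somatic SNVs are heterozygous,
and each CNA changes total copy number by ±1 over one segment. This
matches the ratio-scale copy-number readout and the `VAF ≈ purity/2`
reasoning used throughout; higher amplifications and copy-neutral LOH are
out of scope. SNV positions are uniform over the genome; CNA lengths are
log-uniform between configurable fractions of their chromosome (defaults
5%–50%). Two refinements matter for recovery studies:

- *Disjoint CNAs* (default in the binary generator): a +1 event nested
  inside an inherited +1 region produces copy 4, which a trinary
  loss/neutral/gain coding cannot distinguish from copy 3 — the extra
  event is invisible by construction. Recovery studies therefore draw
  non-overlapping segments.
- *Resolution floor*: a CNA narrower than a bin cannot be observed at
  any purity or depth. The recovery study sets the minimum CNA length to
  three bin widths; this encodes observability, not a tuning of the
  inference.

**Genome.** A 24-chromosome synthetic genome of 30 Mb with human-like
decreasing chromosome sizes. All contracts are scale-free; the 3 Gb /
15,000-bin configuration is exercised where the bin-count contract itself
is under test. GC content is a deterministic smooth field (two sine
waves, chromosome-specific phase, range ≈ 0.30–0.62) standing in for
isochore-scale variation.

**Read counts.** Bin counts are Poisson with mean
`depth_per_bin · [p·c/2 + (1−p)] · bias(gc)`, where `p` is purity and `c`
the clone's copy number at the bin midpoint. The default GC bias is
monotone, ±60% across the GC range — strong enough that uncorrected
profiles fail a rank-correlation check, so the Lowess step is genuinely
load-bearing in the tests. Locus depths for the exome-like layer are
Poisson by default with an optional gamma-Poisson (negative-binomial)
dispersion, reflecting the modest overdispersion of real capture data
(the study's exomes averaged 134× ± 21×; 134 is the default depth).

**Error modes.** Three distinct mechanisms, each independently switchable:

| mode | scope | default | downstream filter that kills it |
|---|---|---|---|
| NGS false positives | private to one caller | `ngs_fp_rate` (per true locus) | ≥2-caller double-calling |
| WGA artifacts | private to one sample, seen by ≥2 of its callers at allele fraction `wga_vaf` = 0.3 | `wga_fp_rate` | ≥2-sample confident-site rule |
| false negatives / base errors | per caller / per read | `fn_rate`, `base_error_rate` = 10⁻³ | Fisher rescue recovers dropout |

No quantitative WGA error rate is published for this protocol; the rates
are free parameters and the tests exercise them at deliberately high
values (0.2–0.5) to make suppression measurable. All randomness derives
from one root seed through named substreams, so every sample and stage is
independently reproducible.

**What the simulator does not emulate.** Read-level artifacts (mapping
error, strand bias), indels and structural variants, subclonal mixtures
within one sample beyond normal-cell admixture, allele-specific copy
number, and correlated (locus-specific) WGA error hotspots. Passing tests
demonstrate that the filtering logic removes the error classes it was
designed for and that parameters are recovered under the stated model —
not that the pipeline is robust to artifact classes outside the model.

## Copy-number profiling

Variable-size bins hold equal numbers of reference mappable positions
(quota per chromosome by largest-remainder apportionment of its position
share; within a chromosome, `⌊N/k⌋`/`⌈N/k⌉` positions per bin, boundaries
at midpoints between adjacent positions, shifted off runs of tied
coordinates). Coordinates are 0-based half-open everywhere internally;
VCF's 1-based convention is applied only at the I/O boundary.

Lowess GC normalization uses span 0.3 with one robustifying iteration
(the method's originators name Lowess but no span; 0.3 is wide enough to
be stable at a few hundred bins and narrow enough to track the injected
bias). Output is rescaled to preserve the input median. The operation is
idempotent up to the smoother's own residual: exactly so on trends the
local-linear fit captures exactly (tested on a linear bias), and to
well under 1% on noisy data.

Copy ratio divides a sample's normalized depth by the *median* of the
reference profile — a single scale factor, as the variable bins already
flatten positional bias. This presumes sample and reference were
sequenced to comparable depth, which the simulator guarantees and real
designs approximate.

Clustering is Ward linkage on Euclidean distances between ratio vectors,
with `k` chosen by mean-silhouette maximization over `k ∈ [2, min(6,
n−1)]`. Identical profiles make the silhouette undefined; the
implementation then returns a flagged arbitrary 2-split with silhouette
0 rather than failing.

## SNV consensus

Locus identity is `(chrom, pos, alt)`. The chain is double-calling (≥2 of
exactly 3 callers) → germline subtraction (in the order the protocol
describes) → confident sites (≥2 samples) → per-sample Fisher rescue. The
rescue table is `[[alt, d−alt], [other_max, d−other_max]]` with
`other_max` the larger of the two non-reference, non-variant base counts,
tested one-sided ("greater") with the exact hypergeometric distribution;
the published description fixes neither the table layout nor sidedness,
and this conservative reading — *is the variant allele specifically
elevated above the background error floor at this site?* — is the
default (`fisher_alpha` = 10⁻³ as published). Samples where the variant
was double-called are present regardless of the test; the p-value is
still recorded. A consequence of the confident-site rule worth stating:
mutations genuinely private to a single sample are discarded by design —
the price of removing WGA artifacts. Cohorts with ≥2 samples per clone
(as in multi-region designs) lose nothing.

## Purity, subclonality, clonality index

For clonal heterozygous SNVs, `E[VAF] = p/2`, so purity is estimated as
`min(1, 2·median VAF)` over the sample's common-category mutations (≥3
required). The low-purity exclusion threshold is 0.3, chosen from the
clear bimodality between normal-cell-rich spheroids and the rest;
configurable. The common-vs-private comparison is a one-sided
Mann–Whitney U (no distributional assumptions, exact at small n); the
protocol reports only a p-value threshold without naming a test.

The clonality index is a Begg-style likelihood ratio mapped to [0, 1]:
shared mutations multiply the clonal-origin odds by `1/p_i` (a rare
shared somatic variant is strong evidence against independent origin),
discordant mutations by a penalty `ν = 0.5` (a private event is half as
likely under a shared origin as under independence). `CI = LR/(1+LR)`;
with no shared mutations `CI ≡ 0`. The source protocol cites prior work
without reproducing a formula, so this is an interpretation with the
stated structure, not a reimplementation; the background probability
defaults to a uniform 10⁻⁴ per locus and accepts per-locus values. Only a
single index is implemented (the cited work defines several).

## Segmentation and trees

Joint segmentation minimizes, per chromosome, the summed squared error of
all samples around shared segment means plus γ per breakpoint, by exact
dynamic programming (O(n²) per chromosome). Each sample is first
standardized by a robust noise SD (median absolute first difference /
(√2·0.6745)), putting γ on the noise scale — this is how the established
multi-sample piecewise-constant-fit tool applies its penalty, and it is
what lets the published γ = 50 transfer across depths and bin counts. A
noiseless profile (SD 0) falls back to SD 1.

Trinary coding works on the ploidy scale: `ploidy = 2 × ratio`. The
published thresholds (event beyond mean ± 0.7, neutral within ± 0.5,
missing in the band between) are meaningful only on that scale — a full
one-copy change in a pure sample moves the ratio by 0.5, which could
never cross 0.7 — so the conversion is applied before thresholding, with
the factor configurable. "Mean ploidy" is the segment-length-weighted
mean, the natural genome-wide average. The 0.5–0.7 ambiguity band is
implemented literally as missing data.

Parsimony uses unit-cost Sankoff scoring vectorized over characters
(binary SNV, trinary CNA); missing entries admit every state at no cost,
and duplicate character columns are collapsed with weights. Search is
exhaustive over all unrooted topologies through 8 leaves — (2n−5)!! ≤
10,395 — returning every co-optimal topology and a strict consensus when
there are several; beyond 8 leaves, NNI hill climbing from a
neighbour-joining start (Hamming distances, missing excluded pairwise)
with random restarts, which guarantees only a local optimum no worse
than the start tree. Trees are rooted on the edge to the all-neutral
normal outgroup, which is always included (the normal sample for CNA
matrices, an explicit all-zero row for SNV matrices). Tree comparison is
the standard unrooted Robinson–Foulds distance.

## Problem sizes and defaults

The end-to-end pipeline default is 6 clones, 60 SNVs, 10 CNAs, 400 bins
over a 30 Mb genome, 9 samples (4 primary, 4 ascites — one at purity
0.05 to reproduce the normal-cell-rich-spheroid exclusion — and 1
normal), 500 expected reads per bin and 134× locus depth. Recovery
studies use 20 replicates of a 6-leaf binary tree with one pure sample
per leaf. These sizes were chosen so a full run completes in seconds on
one core while every estimate stays comfortably inside its sampling
error; all are configurable.

## Known limitations

- The confident-site rule removes single-sample mutations; sensitivity
  to them is zero by design.
- Trinary CNA coding saturates at one event per region; nested and
  overlapping dosage changes are partially invisible, which is also why
  CNA trees are intrinsically less stable than SNV trees here.
- The purity estimator assumes clonal heterozygous variants in
  copy-neutral regions; variants inside CNAs bias it (no allele-specific
  correction is applied).
- The clonality index depends on the assumed background mutation
  probability; it is a comparative statistic, not a calibrated posterior.
- The NNI heuristic above 8 leaves is a local search; co-optimal-tree
  enumeration is exhaustive-mode only.
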