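# spherophylo

Clonal-evolution inference for multi-region tumor sequencing at desk
scale: copy-number profiling of low-depth whole-genome data by
variable-size binning, three-caller somatic SNV consensus with
Fisher-exact rescue, VAF-based tumor-purity and clonality analysis, and
maximum-parsimony phylogenies built from CNA and SNV event matrices.

## The problem

In epithelial ovarian cancer, tumor cells shed from the primary tumor
float in the peritoneal fluid (malignant ascites) as multicellular
spheroids. Sequencing spatially separated pieces of the primary tumor
together with individual spheroids makes it possible to ask whether the
ascites population is a recent emigrant from the dominant primary clone
or an independent lineage that diverged early — a question answered by
reconstructing the patient's clone phylogeny from somatic copy-number
alterations (CNAs) and single-nucleotide variants (SNVs).

Two practical obstacles shape the analysis. First, single spheroids
yield nanograms of DNA, so libraries come from whole-genome amplification
(WGA), which introduces sample-private artifact variants and uneven
coverage. Second, each sample is an unknown mixture of tumor and normal
cells (purity), which attenuates both copy-number ratios and variant
allele frequencies (VAFs). This package implements the full inference
chain and, because such patient data are not freely redistributable,
ships a synthetic clone-tree simulator that generates all inputs with
known ground truth, including both artifact modes.

## Methods at a glance

- **Copy number.** The genome is divided into `n` variable-sized bins
  (default 15,000) holding equal numbers of uniquely mappable reference
  positions. Per-bin read counts are GC-corrected by Lowess regression of
  count on GC fraction, and converted to copy-number ratio by dividing by
  the median depth of the reference (blood) DNA; for a sample of purity
  `p` and local copy number `c`, the expected ratio is `p·c/2 + (1−p)`.
  Profiles are clustered (Ward linkage, silhouette-selected `k`) into
  genetic subgroups.
- **SNV consensus.** Per sample, variants called by ≥2 of 3 callers are
  kept (suppressing caller-private NGS errors); germline variants seen in
  the matched normal are removed; loci double-called in ≥2 samples become
  *confident sites* (suppressing sample-private WGA artifacts). At every
  confident site, each sample is scored present if double-called there or
  if ≥1 caller reported it **and** the variant allele count beats the
  largest other non-reference base count in a one-sided Fisher's exact
  test at `p < 10⁻³` — the rescue step that recovers allele dropout.
  Final loci are categorized *common*, *primary-only*, or *ascites-only*.
- **Purity and clonality.** Purity is `min(1, 2·median VAF)` over a
  sample's clonal (common) mutations; samples under 0.3 are flagged and
  excluded from tree building. A one-sided Mann–Whitney U test of common
  vs group-private VAFs detects subclonal structure. A likelihood-ratio
  clonality index `CI = LR/(1+LR)` with
  `LR = Π_shared (1/p_i) · Π_discordant ν` scores whether two samples
  share a clonal origin (`p_i` = background mutation probability,
  `ν` < 1 a discordance penalty).
- **Phylogeny.** Copy-ratio profiles are segmented jointly (shared
  breakpoints; exact per-chromosome dynamic programming, per-breakpoint
  penalty γ = 50 on noise-standardized data). Segment ploidies are coded
  −1/0/+1 against each sample's length-weighted mean ploidy with an
  explicit missing band (event threshold ±0.7, neutral band ±0.5); SNVs
  are coded 0/1. Maximum-parsimony trees are found exhaustively up to 8
  leaves (Sankoff scoring, missing = fully ambiguous) and by NNI hill
  climbing from a neighbour-joining start above that, rooted at an
  all-neutral normal outgroup. Trees are compared by Robinson–Foulds
  distance.

## Worked example

Run the full pipeline on a synthetic cohort (6 clones, 4 primary + 4
ascites samples including one normal-cell-rich spheroid, plus a matched
normal):

```bash
spherophylo run --seed 3 --outdir results/run3
```

prints (abridged):

```json
{
  "stage_counts": {"double_called": 60, "after_germline_removal": 60,
                   "confident_sites": 29, "final_loci": 29},
  "category_counts": {"common": 7, "primary_only": 12, "ascites_only": 10},
  "category_percentages": {"common": 24.1, "primary_only": 41.4, "ascites_only": 34.5},
  "excluded_samples": ["A4"],
  "cna_tree": "((((P2,P3),(P1,P4)),(A3,(A1,A2))),normal);",
  "snv_tree": "((((P2,P3),(P1,P4)),(A3,(A1,A2))),normal);",
  "rf_cna_vs_snv": 0
}
```

Reading the output: of 60 simulated somatic SNVs, 29 survive the
confidence filter (mutations private to a single sample are
intentionally sacrificed to kill WGA artifacts) and split into common /
primary-only / ascites-only categories. Sample `A4` — the spheroid
simulated with 5% tumor cells — is flagged low-purity and excluded from
tree building, exactly as a normal-cell-rich spheroid must be. The CNA-
and SNV-based trees agree (Robinson–Foulds 0) and both place the primary
samples and the ascites spheroids on two lineages diverging from the
common ancestor. Per-sample purity estimates, clonality indices for all
sample pairs, copy-ratio profiles, consensus tables, VCFs and newick
trees are written to the output directory as plain text.

The same stages are available as library functions
(`spherophylo.build_variable_bins`, `build_consensus_table`,
`estimate_purity`, `clonality_index`, `search_max_parsimony`, ...) and as
`spherophylo cna / snv / vaf / phylo` subcommands operating on files.

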