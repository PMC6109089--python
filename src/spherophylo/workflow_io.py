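"""End-to-end pipeline driver, file formats, configuration and reporting.

File conventions: VCF 4.2 (1-based positions, GT:AD:DP genotype fields)
for call sets; BED-like TSV (0-based half-open) for bins and profiles;
TSV for pileups, purity and clonality tables; newick for trees. Internal
coordinates are 0-based half-open; conversion to VCF's 1-based happens at
the I/O boundary only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from . import cna_profiling as cna
from . import phylogenetics as phylo
from . import snv_consensus as snv
from . import vaf_clonality as vaf
from . import synthetic_data as sim
from .synthetic_data import CallSet, CloneTree, ErrorModel, SampleSpec

log = logging.getLogger("spherophylo")


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_vcf(callset: CallSet, path, genome: pd.DataFrame | None = None) -> None:
    """Write a call set as minimal VCF 4.2 with AD-style allele depths."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=spherophylo\n")
        fh.write(f"##caller={callset.caller_id}\n")
        if genome is not None:
            for r in genome.itertuples():
                fh.write(f"##contig=<ID={r.chrom},length={r.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{callset.sample_id}\n")
        calls = callset.calls.sort_values(["chrom", "pos"])
        for r in calls.itertuples():
            ref_d = int(r.total_depth) - int(r.alt_depth)
            fh.write(f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                     f"GT:AD:DP\t0/1:{ref_d},{int(r.alt_depth)}:{int(r.total_depth)}\n")


def read_vcf(path) -> CallSet:
    """Read a VCF 4.2 call set; multi-allelic records are split into
    biallelic calls sharing the record's depths."""
    path = str(path)
    vcf = VCF(path)
    caller = "unknown"
    for line in vcf.raw_header.splitlines():
        if line.startswith("##caller="):
            caller = line.split("=", 1)[1]
    sample = vcf.samples[0] if vcf.samples else "unknown"
    rows = []
    for i, v in enumerate(vcf):
        try:
            ad = v.format("AD")
            dp = int(v.format("DP")[0][0]) if v.format("DP") is not None else None
            for k, alt in enumerate(v.ALT):
                alt_d = int(ad[0][k + 1]) if ad is not None else 0
                total = dp if dp is not None else int(np.sum(ad[0]))
                rows.append((v.CHROM, v.POS, v.REF, alt, alt_d, total))
        except Exception as exc:     # pragma: no cover - malformed input path
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    calls = pd.DataFrame(rows, columns=list(CallSet.COLUMNS))
    return CallSet(caller_id=caller, sample_id=sample, calls=calls)


def write_bed_bins(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", index=False)


def read_bed_bins(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pileup_tsv(pileups: pd.DataFrame, path) -> None:
    pileups.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "ref", "A", "C", "G", "T"} - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV {path} lacks columns {sorted(missing)}")
    return df


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    Defaults mirror the study design at desk scale: a handful of primary
    tumor samples and ascites spheroids (one of them normal-cell-rich),
    one matched normal, low-depth WGS bins and WES-like allele depths.
    """
    seed: int = 0
    # simulation
    n_clones: int = 6
    n_snvs: int = 60
    n_cnas: int = 10
    n_primary: int = 4
    n_ascites: int = 4
    primary_purities: tuple = (0.75, 0.8, 0.7, 0.85)
    ascites_purities: tuple = (0.7, 0.75, 0.8, 0.1)    # last spheroid normal-rich
    genome_size: int = sim.DEFAULT_GENOME_SIZE
    n_chromosomes: int = sim.DEFAULT_N_CHROMOSOMES
    n_reference_positions: int = 200_000
    wgs_depth_per_bin: float = 500.0
    wes_depth: float = 134.0
    error: ErrorModel = field(default_factory=ErrorModel)
    gc_bias_strength: float = 0.6
    # analysis
    binning: cna.BinningConfig = field(default_factory=lambda: cna.BinningConfig(n_bins=400))
    consensus: snv.ConsensusConfig = field(default_factory=snv.ConsensusConfig)
    thresholds: phylo.ThresholdConfig = field(default_factory=phylo.ThresholdConfig)
    purity_threshold: float = 0.3
    subclonality_alpha: float = 0.01
    background_mutation_prob: float = 1e-4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "error":
                v = ErrorModel(**v)
            elif f.name == "binning":
                v = cna.BinningConfig(**v)
            elif f.name == "consensus":
                v = snv.ConsensusConfig(**v)
            elif f.name == "thresholds":
                v = phylo.ThresholdConfig(**v)
            elif isinstance(getattr(cls, f.name, None), tuple):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def default_gc_bias(strength: float):
    """Monotone GC efficiency curve: 1 at GC 0.46, +-strength across the
    observed GC range."""
    def bias(gc):
        return 1.0 + strength * (np.asarray(gc) - 0.46) / 0.16
    return bias


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

def design_samples(config: PipelineConfig, tree: CloneTree) -> list:
    """Assign samples to clones so the cohort mirrors the study: primary
    samples on one lineage and ascites spheroids on the other, diverging at
    the tree's first bifurcation (shared trunk events become the common
    mutations). Falls back to a first-half / second-half split when the
    clone tree is a pure chain. One matched normal is always appended."""
    children: dict = {n: [] for n in tree.nodes}
    for n in tree.nodes:
        if tree.parent[n] is not None:
            children[tree.parent[n]].append(n)

    def descendants(node):
        out = [node]
        for c in children[node]:
            out.extend(descendants(c))
        return out

    clones = [n for n in tree.nodes if n != tree.root]
    primary_clones = ascites_clones = None
    node = children[tree.root][0] if children[tree.root] else None
    while node is not None:
        kids = children[node]
        if len(kids) >= 2:
            primary_clones = descendants(kids[0])
            ascites_clones = [c for k in kids[1:] for c in descendants(k)]
            break
        node = kids[0] if kids else None
    if primary_clones is None:
        half = max(1, len(clones) // 2)
        primary_clones, ascites_clones = clones[:half], clones[half:] or clones[:1]
    specs = []
    for i in range(config.n_primary):
        specs.append(SampleSpec(f"P{i + 1}", "primary",
                                primary_clones[i % len(primary_clones)],
                                config.primary_purities[i % len(config.primary_purities)],
                                config.wes_depth))
    for i in range(config.n_ascites):
        specs.append(SampleSpec(f"A{i + 1}", "ascites",
                                ascites_clones[i % len(ascites_clones)],
                                config.ascites_purities[i % len(config.ascites_purities)],
                                config.wes_depth))
    specs.append(SampleSpec("NB", "normal", tree.root, 0.0, config.wes_depth))
    return specs


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    seed: int
    stage_counts: dict
    category_counts: dict
    category_percentages: dict
    cluster_labels: dict
    n_clusters: int
    purity: pd.DataFrame
    clonality: pd.DataFrame
    excluded_samples: list
    cna_tree: phylo.PhyloTree
    snv_tree: phylo.PhyloTree
    rf_cna_vs_snv: int

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "category_counts": self.category_counts,
            "category_percentages": self.category_percentages,
            "total_loci": int(sum(self.category_counts.values())),
            "n_clusters": self.n_clusters,
            "cluster_labels": self.cluster_labels,
            "excluded_samples": self.excluded_samples,
            "cna_tree": self.cna_tree.newick,
            "cna_parsimony_score": self.cna_tree.score,
            "snv_tree": self.snv_tree.newick,
            "snv_parsimony_score": self.snv_tree.score,
            "rf_cna_vs_snv": self.rf_cna_vs_snv,
        }


def report_percentages(counts: dict) -> dict:
    return snv.category_percentages(counts)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Execute simulate -> CNA -> SNV consensus -> VAF -> phylogeny.

    Deterministic given ``config.seed``. When ``outdir`` is given, every
    intermediate artifact is written there (plain text). Returns the
    assembled RunReport.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, **counts):
        log.info("stage=%s %s", name,
                 " ".join(f"{k}={v}" for k, v in counts.items()))

    # -- simulate ----------------------------------------------------------
    genome = sim.synthetic_genome(config.n_chromosomes, config.genome_size)
    tree = sim.simulate_clone_tree(config.n_clones, config.n_snvs, config.n_cnas,
                                   genome, seed=config.seed)
    specs = design_samples(config, tree)
    rng = sim.substream(config.seed, "reference_positions")
    ref_positions = _uniform_positions(genome, config.n_reference_positions, rng)
    bins = cna.build_variable_bins(ref_positions, config.binning)
    wgs_specs = [dataclasses.replace(s, mean_depth=config.wgs_depth_per_bin)
                 for s in specs]
    cohort = sim.simulate_cohort(tree, specs, config.error, bins,
                                 root_seed=config.seed,
                                 gc_bias=default_gc_bias(config.gc_bias_strength))
    for ws, s in zip(wgs_specs, cohort.specs):
        ws = dataclasses.replace(ws, seed=s.seed)
        cohort.counts[s.sample_id] = sim.simulate_binned_counts(
            ws, tree, bins, gc_bias=default_gc_bias(config.gc_bias_strength))
    stage("simulate", clones=config.n_clones, samples=len(specs),
          snvs=config.n_snvs, cnas=config.n_cnas, bins=len(bins))
    if out is not None:
        sim.write_truth_tsv(tree, out / "truth_events.tsv")
        write_newick(tree.to_newick(), out / "truth_tree.nwk")
        write_bed_bins(bins, out / "bins.bed.tsv")
        for s in cohort.specs:
            write_pileup_tsv(cohort.pileups[s.sample_id],
                             out / f"pileup_{s.sample_id}.tsv")
            for cs in cohort.callsets[s.sample_id]:
                write_vcf(cs, out / f"calls_{s.sample_id}_{cs.caller_id}.vcf", genome)

    # -- CNA profiling -----------------------------------------------------
    gc_col = bins["gc"].to_numpy()
    normalized = {
        s.sample_id: cna.lowess_gc_normalize(cohort.counts[s.sample_id], gc_col,
                                             config.binning.lowess_fraction,
                                             config.binning.lowess_iterations)
        for s in cohort.specs}
    reference_id = next(s.sample_id for s in cohort.specs if s.group == "normal")
    profiles = [cna.estimate_copy_ratio(sid, normalized[sid], normalized[reference_id],
                                        raw_counts=cohort.counts[sid])
                for sid in normalized]
    labels, k, _, silhouette = cna.cluster_profiles(profiles, config.binning)
    cluster_labels = {p.sample_id: int(l) for p, l in zip(profiles, labels)}
    stage("cna", profiles=len(profiles), clusters=k)
    if out is not None:
        prof_df = bins[["chrom", "start", "end", "gc"]].copy()
        for p in profiles:
            prof_df[p.sample_id] = p.ratio
        prof_df.to_csv(out / "copy_ratio_profiles.tsv", sep="\t", index=False)

    # -- SNV consensus -----------------------------------------------------
    tumor_ids = [s.sample_id for s in cohort.specs if s.group != "normal"]
    groups = {s.sample_id: s.group for s in cohort.specs}
    table = snv.build_consensus_table(
        {sid: cohort.callsets[sid] for sid in tumor_ids},
        {sid: cohort.pileups[sid] for sid in tumor_ids},
        cohort.normal_calls, groups, config.consensus)
    counts = {c: table.category_counts().get(c, 0)
              for c in (snv.CATEGORY_COMMON, snv.CATEGORY_PRIMARY, snv.CATEGORY_ASCITES)}
    pct = report_percentages(counts)
    stage("snv", **table.stage_counts)
    if out is not None:
        _write_consensus_tsv(table, out / "consensus_table.tsv")

    # -- VAF / purity / clonality -----------------------------------------
    vafs = vaf.compute_vafs(table, {sid: cohort.pileups[sid] for sid in tumor_ids})
    purity = vaf.purity_table(vafs, groups, config.purity_threshold,
                              config.subclonality_alpha)
    excluded = purity.loc[purity["low_purity"], "sample"].tolist()
    included = [sid for sid in tumor_ids if sid not in excluded]
    loci_by_sample = {
        sid: set(map(tuple, table.presence.index[table.presence[sid]]))
        for sid in tumor_ids}
    ci_rows = []
    for i, a in enumerate(tumor_ids):
        for b in tumor_ids[i + 1:]:
            if not loci_by_sample[a] or not loci_by_sample[b]:
                continue
            r = vaf.clonality_index(loci_by_sample[a], loci_by_sample[b],
                                    config.background_mutation_prob)
            ci_rows.append((a, b, r.ci, r.n_shared, r.n_private_a, r.n_private_b))
    clonality = pd.DataFrame(ci_rows, columns=["sample_a", "sample_b", "ci",
                                               "n_shared", "n_private_a", "n_private_b"])
    stage("vaf", records=len(vafs), excluded=len(excluded))
    if out is not None:
        vafs.to_csv(out / "vafs.tsv", sep="\t", index=False)
        purity.to_csv(out / "purity.tsv", sep="\t", index=False)
        clonality.to_csv(out / "clonality.tsv", sep="\t", index=False)
        vaf.plot_vaf_histograms(vafs, out / "vaf_histograms.png")

    # -- phylogenetics -----------------------------------------------------
    keep = included + [reference_id]
    ratio_df = pd.DataFrame({p.sample_id: p.ratio for p in profiles}).T
    seg = phylo.joint_segmentation(ratio_df.loc[keep], bins, config.thresholds.gamma)
    cna_matrix = phylo.trinary_matrix(seg, config.thresholds, add_root=False)
    cna_matrix.data = cna_matrix.data.rename(index={reference_id: "normal"})
    snv_matrix = phylo.binary_snv_matrix(table, included_samples=included)
    cna_tree = phylo.search_max_parsimony(cna_matrix, seed=config.seed)
    snv_tree = phylo.search_max_parsimony(snv_matrix, seed=config.seed)
    shared = set(cna_tree.leaves) & set(snv_tree.leaves)
    rf = phylo.compare_trees(_restrict(cna_tree.newick, shared),
                             _restrict(snv_tree.newick, shared))
    stage("phylo", cna_score=cna_tree.score, snv_score=snv_tree.score, rf=rf)
    if out is not None:
        write_newick(cna_tree.newick, out / "cna_tree.nwk")
        write_newick(snv_tree.newick, out / "snv_tree.nwk")

    report = RunReport(seed=config.seed, stage_counts=table.stage_counts,
                       category_counts=counts, category_percentages=pct,
                       cluster_labels=cluster_labels, n_clusters=k,
                       purity=purity, clonality=clonality,
                       excluded_samples=excluded, cna_tree=cna_tree,
                       snv_tree=snv_tree, rf_cna_vs_snv=rf)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report.summary(), indent=2))
    return report


# ---------------------------------------------------------------------------
# Simulation studies
# ---------------------------------------------------------------------------

def tree_recovery_replicate(seed: int, n_leaf_clones: int = 6, n_snvs: int = 60,
                            n_cnas: int = 12, n_bins: int = 300,
                            n_reference_positions: int = 200_000,
                            wgs_depth_per_bin: float = 500.0,
                            wes_depth: float = 134.0) -> dict:
    """One no-observation-noise topology-recovery replicate.

    Simulates a binary clone tree (one SNV and one disjoint CNA per edge),
    one pure (purity 1) sample per leaf clone plus a matched normal, runs
    the full CNA and SNV tree inference, and returns the Robinson-Foulds
    distance of each inferred tree to the true topology.
    """
    genome = sim.synthetic_genome()
    # events narrower than ~3 bins are below observation resolution and
    # unrecoverable by construction, so the study draws none
    min_cna_len = 3 * int(genome["length"].sum() // n_bins)
    tree, leaf_clones = sim.simulate_binary_clone_tree(
        n_leaf_clones, n_snvs, n_cnas, genome, seed=seed,
        cna_min_len=min_cna_len)
    specs = [SampleSpec(f"S{i + 1}", "primary" if i < n_leaf_clones // 2 else "ascites",
                        c, 1.0, wes_depth) for i, c in enumerate(leaf_clones)]
    specs.append(SampleSpec("NB", "normal", tree.root, 0.0, wes_depth))
    rng = sim.substream(seed, "recovery_reference")
    ref = _uniform_positions(genome, n_reference_positions, rng)
    bins = cna.build_variable_bins(ref, n_bins=n_bins)
    cohort = sim.simulate_cohort(tree, specs, ErrorModel(), bins, root_seed=seed)
    for s in cohort.specs:
        ws = dataclasses.replace(s, mean_depth=wgs_depth_per_bin)
        cohort.counts[s.sample_id] = sim.simulate_binned_counts(ws, tree, bins)

    tumor = [s.sample_id for s in cohort.specs if s.group != "normal"]
    groups = {s.sample_id: s.group for s in cohort.specs}
    table = snv.build_consensus_table(
        {s: cohort.callsets[s] for s in tumor},
        {s: cohort.pileups[s] for s in tumor}, cohort.normal_calls, groups)
    rename = {c: f"S{i + 1}" for i, c in enumerate(leaf_clones)}
    truth = sim.leaf_topology_newick(tree, rename=rename)
    snv_tree = phylo.search_max_parsimony(phylo.binary_snv_matrix(table), seed=seed)

    gc_col = bins["gc"].to_numpy()
    norm = {sid: cna.lowess_gc_normalize(cohort.counts[sid], gc_col)
            for sid in cohort.counts}
    profs = [cna.estimate_copy_ratio(sid, norm[sid], norm["NB"])
             for sid in tumor + ["NB"]]
    ratio = pd.DataFrame({p.sample_id: p.ratio for p in profs}).T
    seg = phylo.joint_segmentation(ratio, bins, phylo.ThresholdConfig().gamma)
    cm = phylo.trinary_matrix(seg, add_root=False)
    cm.data = cm.data.rename(index={"NB": "normal"})
    cna_tree = phylo.search_max_parsimony(cm, seed=seed)
    return {"rf_snv": phylo.compare_trees(snv_tree, truth),
            "rf_cna": phylo.compare_trees(cna_tree, truth),
            "truth_newick": truth, "table": table, "cohort": cohort}


def three_group_cluster_experiment(seed: int, n_bins: int = 300,
                                   n_reference_positions: int = 100_000) -> dict:
    """Three-group clustering study: primary-like samples on one tumor
    lineage, ascites-like on the other, and low-purity (normal-like)
    samples; returns the chosen k and the label partition."""
    genome = sim.synthetic_genome()
    rng = sim.substream(seed, "cluster_tree")
    cnas = sim._draw_cnas(rng, genome, 12, disjoint=True)
    snvs = sim._draw_snvs(rng, genome, 12)
    # balanced two-lineage tree: shared trunk, equal private loads
    tree = CloneTree(
        nodes=["normal", "trunk", "primary_clone", "ascites_clone"],
        parent={"normal": None, "trunk": "normal",
                "primary_clone": "trunk", "ascites_clone": "trunk"},
        root="normal",
        branch_events={"trunk": {"snvs": snvs[:4], "cnas": cnas[:4]},
                       "primary_clone": {"snvs": snvs[4:8], "cnas": cnas[4:8]},
                       "ascites_clone": {"snvs": snvs[8:], "cnas": cnas[8:]}},
        genome=genome)
    primary_clone, ascites_clone = "primary_clone", "ascites_clone"
    specs = ([SampleSpec(f"P{i + 1}", "primary", primary_clone, 0.8, 134.0)
              for i in range(4)]
             + [SampleSpec(f"A{i + 1}", "ascites", ascites_clone, 0.8, 134.0)
                for i in range(3)]
             + [SampleSpec("A4", "ascites", ascites_clone, 0.05, 134.0),
                SampleSpec("NB", "normal", tree.root, 0.0, 134.0)])
    rng = sim.substream(seed, "cluster_reference")
    ref = _uniform_positions(genome, n_reference_positions, rng)
    bins = cna.build_variable_bins(ref, n_bins=n_bins)
    counts = {s.sample_id: sim.simulate_binned_counts(
        dataclasses.replace(s, seed=int(sim.substream(seed, "c", s.sample_id)
                                        .integers(2**31 - 1)),
                            mean_depth=500.0), tree, bins)
        for s in specs}
    gc_col = bins["gc"].to_numpy()
    norm = {sid: cna.lowess_gc_normalize(counts[sid], gc_col) for sid in counts}
    profs = [cna.estimate_copy_ratio(sid, norm[sid], norm["NB"]) for sid in norm]
    labels, k, _, silhouette = cna.cluster_profiles(profs)
    by_label: dict = {}
    for p, l in zip(profs, labels):
        by_label.setdefault(int(l), set()).add(p.sample_id)
    return {"k": k, "partition": sorted(map(frozenset, by_label.values()), key=len),
            "silhouette": silhouette,
            "labels": {p.sample_id: int(l) for p, l in zip(profs, labels)}}


def purity_recovery_experiment(seed: int, purities=(0.8, 0.6, 0.4, 0.7, 0.5),
                               depth: float = 100.0, n_trunk_snvs: int = 40,
                               n_private_snvs: int = 15) -> pd.DataFrame:
    """Purity-estimation study: a two-lineage clone tree whose trunk
    carries >= 30 clonal SNVs, one sample per listed purity (split between
    the two lineages), full consensus + VAF chain, estimates vs truth."""
    genome = sim.synthetic_genome()
    rng = sim.substream(seed, "purity_tree")
    snvs = sim._draw_snvs(rng, genome, n_trunk_snvs + 2 * n_private_snvs)
    tree = CloneTree(
        nodes=["normal", "trunk", "primary_clone", "ascites_clone"],
        parent={"normal": None, "trunk": "normal",
                "primary_clone": "trunk", "ascites_clone": "trunk"},
        root="normal",
        branch_events={
            "trunk": {"snvs": snvs[:n_trunk_snvs], "cnas": []},
            "primary_clone": {"snvs": snvs[n_trunk_snvs:n_trunk_snvs + n_private_snvs],
                              "cnas": []},
            "ascites_clone": {"snvs": snvs[n_trunk_snvs + n_private_snvs:],
                              "cnas": []}},
        genome=genome)
    specs = []
    for i, p in enumerate(purities):
        group = "primary" if i < (len(purities) + 1) // 2 else "ascites"
        clone = "primary_clone" if group == "primary" else "ascites_clone"
        specs.append(SampleSpec(f"S{i + 1}", group, clone, p, depth))
    specs.append(SampleSpec("NB", "normal", tree.root, 0.0, depth))
    bins = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000], "gc": [0.4]})
    cohort = sim.simulate_cohort(tree, specs, ErrorModel(), bins, root_seed=seed)
    tumor = [s.sample_id for s in cohort.specs if s.group != "normal"]
    groups = {s.sample_id: s.group for s in cohort.specs}
    table = snv.build_consensus_table(
        {s: cohort.callsets[s] for s in tumor},
        {s: cohort.pileups[s] for s in tumor}, cohort.normal_calls, groups)
    vafs = vaf.compute_vafs(table, {s: cohort.pileups[s] for s in tumor})
    rows = []
    for s in cohort.specs:
        if s.group == "normal":
            continue
        est = vaf.estimate_purity(vafs, s.sample_id)
        rows.append((s.sample_id, s.purity, est.purity, est.n_loci))
    return pd.DataFrame(rows, columns=["sample", "true_purity",
                                       "estimated_purity", "n_loci"])


def _uniform_positions(genome: pd.DataFrame, n: int, rng) -> dict:
    lengths = genome["length"].to_numpy()
    p = lengths / lengths.sum()
    counts = rng.multinomial(n, p)
    return {r.chrom: np.sort(rng.integers(0, r.length, size=c))
            for r, c in zip(genome.itertuples(), counts)}


def _restrict(newick: str, leaves: set) -> str:
    import dendropy
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.retain_taxa_with_labels(list(leaves))
    return t.as_string(schema="newick").strip()


def _write_consensus_tsv(table: snv.ConsensusTable, path) -> None:
    df = pd.DataFrame({"chrom": [l[0] for l in table.presence.index],
                       "pos": [l[1] for l in table.presence.index],
                       "alt": [l[2] for l in table.presence.index]})
    for s in table.presence.columns:
        df[s] = np.where(table.presence[s].to_numpy(), "present", "absent")
    df["category"] = table.category.to_numpy()
    df.to_csv(path, sep="\t", index=False)
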