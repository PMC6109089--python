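"""Synthetic clone-tree data generator.

Simulates the ground truth and the sequencing-like observations of a
multi-region tumor / ascites-spheroid study: a rooted clone tree whose
branches carry somatic SNVs and copy-number events, samples that mix one
tumor clone with normal cells at a given purity, binned whole-genome read
counts with GC bias and Poisson noise, per-locus allele depths, and three
variant-caller outputs with two distinct false-positive modes —
caller-private random errors (NGS noise) and sample-private artifacts seen
by several callers of the same sample (whole-genome-amplification errors).

All randomness flows from one root seed through named substreams, so any
piece of the simulation can be regenerated independently and
deterministically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

#: Default scaled-down genome: 24 chromosomes, ~30 Mb total, human-like
#: decreasing chromosome sizes. Real genomes are two orders of magnitude
#: larger; every downstream contract is scale-free.
DEFAULT_GENOME_SIZE = 30_000_000
DEFAULT_N_CHROMOSOMES = 24


def synthetic_genome(n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
                     total_length: int = DEFAULT_GENOME_SIZE) -> pd.DataFrame:
    """Chromosome-length table with sizes decreasing roughly like the
    human karyotype (chr1 largest), summing to ``total_length``."""
    if n_chromosomes < 1 or total_length < n_chromosomes:
        raise ValueError("need at least one chromosome and one base per chromosome")
    weights = np.arange(n_chromosomes + 1, 1, -1, dtype=float)
    weights /= weights.sum()
    lengths = np.maximum(1, np.floor(weights * total_length).astype(np.int64))
    lengths[0] += total_length - lengths.sum()
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    return pd.DataFrame({"chrom": chroms, "length": lengths})


def gc_content(chrom: str, positions: np.ndarray) -> np.ndarray:
    """Deterministic smooth synthetic GC landscape in roughly [0.30, 0.62].

    A sum of two sine waves with a chromosome-specific phase; stands in for
    isochore-scale GC variation so that GC-bias injection and Lowess
    correction have a realistic covariate to act on.
    """
    phase = (zlib.crc32(chrom.encode()) % 1000) / 1000.0 * 2 * np.pi
    p = np.asarray(positions, dtype=float)
    gc = (0.46
          + 0.10 * np.sin(2 * np.pi * p / 3.1e6 + phase)
          + 0.05 * np.sin(2 * np.pi * p / 6.3e5 + 2.1 * phase))
    return np.clip(gc, 0.30, 0.62)


def substream(root_seed: int, *names: str) -> np.random.Generator:
    """Named reproducible substream of the root seed.

    Each name is hashed into the seed sequence's spawn key, so e.g.
    ``substream(seed, "counts", sample_id)`` is stable across runs and
    independent of other substreams.
    """
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=root_seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnvEvent:
    """A somatic heterozygous single-nucleotide variant on one branch."""
    snv_id: str
    chrom: str
    pos: int          # 1-based, as in VCF
    ref: str
    alt: str

    @property
    def locus(self) -> tuple:
        return (self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class CnaEvent:
    """A somatic copy-number event changing total copy number by +-1."""
    cna_id: str
    chrom: str
    start: int        # 0-based half-open
    end: int
    direction: int    # +1 gain, -1 loss


@dataclass
class CloneTree:
    """Rooted clone tree with branch-assigned somatic events.

    The root is the normal (germline) genotype; each non-root node is a
    tumor clone whose genotype is the union of the events on its root path.
    """
    nodes: list
    parent: dict                 # node -> parent node (root maps to None)
    root: str
    branch_events: dict          # child node -> {"snvs": [...], "cnas": [...]}
    genome: pd.DataFrame

    def edges(self):
        return [(self.parent[n], n) for n in self.nodes if self.parent[n] is not None]

    def root_path(self, node: str) -> list:
        path = []
        while node is not None and self.parent.get(node) is not None:
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    def clone_snvs(self, node: str) -> list:
        out = []
        for child in self.root_path(node):
            out.extend(self.branch_events[child]["snvs"])
        return out

    def clone_cnas(self, node: str) -> list:
        out = []
        for child in self.root_path(node):
            out.extend(self.branch_events[child]["cnas"])
        return out

    def all_snvs(self) -> list:
        return [s for ev in self.branch_events.values() for s in ev["snvs"]]

    def all_cnas(self) -> list:
        return [c for ev in self.branch_events.values() for c in ev["cnas"]]

    def copy_number(self, node: str, chrom: str, pos: int) -> int:
        """Total copy number of the clone at a genomic position (diploid = 2,
        clamped at zero)."""
        c = 2
        for ev in self.clone_cnas(node):
            if ev.chrom == chrom and ev.start <= pos < ev.end:
                c += ev.direction
        return max(c, 0)

    def copy_number_per_bin(self, node: str, bins: pd.DataFrame) -> np.ndarray:
        """Copy number of each bin, evaluated at the bin midpoint."""
        c = np.full(len(bins), 2.0)
        mid = ((bins["start"].to_numpy() + bins["end"].to_numpy()) // 2)
        chroms = bins["chrom"].to_numpy()
        for ev in self.clone_cnas(node):
            hit = (chroms == ev.chrom) & (mid >= ev.start) & (mid < ev.end)
            c[hit] += ev.direction
        return np.maximum(c, 0.0)

    def to_newick(self) -> str:
        children: dict = {n: [] for n in self.nodes}
        for n in self.nodes:
            p = self.parent[n]
            if p is not None:
                children[p].append(n)

        def fmt(n):
            if not children[n]:
                return n
            return "(" + ",".join(fmt(c) for c in children[n]) + ")" + n

        return fmt(self.root) + ";"


@dataclass(frozen=True)
class SampleSpec:
    """One sequenced sample: a tumor clone diluted with normal cells."""
    sample_id: str
    group: str                   # "primary" | "ascites" | "normal"
    clone_id: str
    purity: float
    mean_depth: float
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        if self.group == "normal" and self.purity != 0.0:
            raise ValueError("the normal sample must have purity 0")
        if self.group not in ("primary", "ascites", "normal"):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class ErrorModel:
    """Observation-error model for pileups and caller outputs.

    ``ngs_fp_rate`` — expected caller-private false calls per true somatic
    locus, drawn independently per caller (sequencing/calling noise).
    ``wga_fp_rate`` — expected sample-private artifact loci per true locus;
    each artifact is reported by >=2 callers of that sample, mimicking
    amplification errors that look allele-like within one sample.
    ``fn_rate`` — per-caller probability of missing a true variant.
    ``base_error_rate`` — per-read probability of a miscalled base in the
    pileup. ``wga_vaf`` is the allele fraction at which an amplification
    artifact presents.
    """
    ngs_fp_rate: float = 0.0
    wga_fp_rate: float = 0.0
    fn_rate: float = 0.0
    base_error_rate: float = 0.001
    wga_vaf: float = 0.3
    depth_dispersion: float | None = None   # None -> Poisson depths

    def __post_init__(self):
        for name in ("ngs_fp_rate", "wga_fp_rate", "fn_rate", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass
class CallSet:
    """Variant calls of one caller on one sample (VCF-like records)."""
    caller_id: str
    sample_id: str
    calls: pd.DataFrame   # chrom, pos, ref, alt, alt_depth, total_depth

    COLUMNS = ("chrom", "pos", "ref", "alt", "alt_depth", "total_depth")

    def loci(self) -> set:
        return set(zip(self.calls["chrom"], self.calls["pos"], self.calls["alt"]))


# ---------------------------------------------------------------------------
# Clone-tree simulation
# ---------------------------------------------------------------------------

def simulate_clone_tree(n_clones: int, n_snvs: int, n_cnas: int,
                        genome: pd.DataFrame | None = None, seed: int = 0,
                        cna_min_frac: float = 0.05,
                        cna_max_frac: float = 0.5) -> CloneTree:
    """Simulate a rooted clone tree with branch-assigned somatic events.

    The root is the normal genotype; ``clone_1`` is the ancestral tumor
    clone and each later clone attaches to a uniformly chosen earlier
    clone, so the tumor is monophyletic. Every edge receives at least one
    event; the remaining events are spread uniformly over edges. SNV
    positions are uniform over the genome; CNA segment lengths are
    log-uniform between the configured fractions of their chromosome.
    """
    if n_clones < 2:
        raise ValueError("need at least 2 clones")
    if genome is None:
        genome = synthetic_genome()
    if len(genome) == 0:
        raise ValueError("genome must be non-empty")
    n_edges = n_clones
    if n_snvs + n_cnas < n_edges:
        raise ValueError(
            f"{n_snvs + n_cnas} events cannot cover {n_edges} edges with one event each")

    rng = substream(seed, "clone_tree")
    clones = [f"clone_{i + 1}" for i in range(n_clones)]
    parent = {"normal": None, clones[0]: "normal"}
    for i in range(1, n_clones):
        parent[clones[i]] = clones[int(rng.integers(0, i))]

    snvs = _draw_snvs(rng, genome, n_snvs)
    cnas = _draw_cnas(rng, genome, n_cnas, cna_min_frac, cna_max_frac)
    branch_events = _distribute_events(rng, clones, snvs, cnas)
    return CloneTree(nodes=["normal"] + clones, parent=parent, root="normal",
                     branch_events=branch_events, genome=genome)


def _draw_snvs(rng, genome, n_snvs, prefix="snv"):
    lengths = genome["length"].to_numpy()
    chrom_p = lengths / lengths.sum()
    names = genome["chrom"].to_list()
    snvs, seen = [], set()
    while len(snvs) < n_snvs:
        ci = int(rng.choice(len(names), p=chrom_p))
        pos = int(rng.integers(1, lengths[ci] + 1))
        if (names[ci], pos) in seen:
            continue
        seen.add((names[ci], pos))
        ref = BASES[int(rng.integers(4))]
        alt = rng.choice([b for b in BASES if b != ref])
        snvs.append(SnvEvent(f"{prefix}_{len(snvs) + 1}", names[ci], pos, ref, str(alt)))
    return snvs


def _draw_cnas(rng, genome, n_cnas, min_frac=0.05, max_frac=0.5, disjoint=False,
               min_len: int | None = None):
    """Random CNA segments, length log-uniform between the configured
    fractions of the chromosome. ``min_len`` imposes an absolute floor
    (events below the binning resolution are unobservable, so resolution-
    aware studies set it to a few bin widths). With ``disjoint`` segments
    never overlap each other (nested +-1 events saturate a trinary
    loss/neutral/gain coding)."""
    lengths = genome["length"].to_numpy()
    chrom_p = lengths / lengths.sum()
    names = genome["chrom"].to_list()
    cnas = []
    attempts = 0
    while len(cnas) < n_cnas:
        attempts += 1
        if attempts > 1000 * n_cnas:
            raise ValueError("cannot place disjoint CNA segments; genome too small")
        ci = int(rng.choice(len(names), p=chrom_p))
        clen = int(lengths[ci])
        lo = max(1, int(min_frac * clen), int(min_len or 1))
        hi = max(2, int(max_frac * clen))
        if lo >= clen or lo >= hi:
            continue        # chromosome too small for the requested floor
        seg_len = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        start = int(rng.integers(0, max(1, clen - seg_len)))
        end = start + seg_len
        if disjoint and any(c.chrom == names[ci] and c.start < end and start < c.end
                            for c in cnas):
            continue
        direction = int(rng.choice([-1, 1]))
        cnas.append(CnaEvent(f"cna_{len(cnas) + 1}", names[ci], start, end, direction))
    return cnas


def _distribute_events(rng, edges, snvs, cnas, per_edge_per_kind=False):
    """Spread events over edges: one per edge first (one per kind per edge
    when requested), the remainder uniformly."""
    branch_events = {c: {"snvs": [], "cnas": []} for c in edges}
    n = len(edges)

    def place(events, guaranteed):
        order = rng.permutation(len(events))
        targets = list(guaranteed) + [edges[int(rng.integers(n))]
                                      for _ in range(len(events) - len(guaranteed))]
        for idx, edge in zip(order, targets):
            ev = events[idx]
            kind = "snvs" if isinstance(ev, SnvEvent) else "cnas"
            branch_events[edge][kind].append(ev)

    if per_edge_per_kind:
        place(list(snvs), edges)
        place(list(cnas), edges)
    else:
        events = list(snvs) + list(cnas)
        order = rng.permutation(len(events))
        targets = list(edges) + [edges[int(rng.integers(n))]
                                 for _ in range(len(events) - n)]
        for idx, edge in zip(order, targets):
            ev = events[idx]
            kind = "snvs" if isinstance(ev, SnvEvent) else "cnas"
            branch_events[edge][kind].append(ev)
    return branch_events


def simulate_binary_clone_tree(n_leaf_clones: int, n_snvs: int, n_cnas: int,
                               genome: pd.DataFrame | None = None, seed: int = 0,
                               events_per_edge_per_kind: bool = True,
                               disjoint_cnas: bool = True,
                               cna_min_len: int | None = None):
    """Simulate a clone tree with a fully binary topology.

    The normal root has a single ancestral-clone child; random leaf clones
    are repeatedly split in two until ``n_leaf_clones`` leaves exist, so
    only the leaf clones represent extant sampled populations (internal
    clones are unsampled ancestors). With ``events_per_edge_per_kind``
    every edge carries at least one SNV and one CNA, making the topology
    recoverable from either data type alone.

    Returns ``(tree, leaf_clone_ids)``.
    """
    if n_leaf_clones < 2:
        raise ValueError("need at least 2 leaf clones")
    if genome is None:
        genome = synthetic_genome()
    rng = substream(seed, "binary_clone_tree")
    parent = {"normal": None, "clone_1": "normal"}
    leaves = ["clone_1"]
    counter = 1
    while len(leaves) < n_leaf_clones:
        target = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            counter += 1
            child = f"clone_{counter}"
            parent[child] = target
            leaves.append(child)
    clones = [c for c in parent if c != "normal"]
    n_edges = len(clones)
    if events_per_edge_per_kind and (n_snvs < n_edges or n_cnas < n_edges):
        raise ValueError(f"need >= {n_edges} SNVs and CNAs to cover every edge")
    if n_snvs + n_cnas < n_edges:
        raise ValueError("not enough events to give every edge one")
    snvs = _draw_snvs(rng, genome, n_snvs)
    cnas = _draw_cnas(rng, genome, n_cnas, disjoint=disjoint_cnas,
                      min_len=cna_min_len)
    branch_events = _distribute_events(rng, clones, snvs, cnas,
                                       per_edge_per_kind=events_per_edge_per_kind)
    tree = CloneTree(nodes=["normal"] + clones, parent=parent, root="normal",
                     branch_events=branch_events, genome=genome)
    return tree, sorted(leaves, key=lambda c: int(c.split("_")[1]))


def leaf_topology_newick(tree: CloneTree, rename: dict | None = None) -> str:
    """Newick over the tree's leaf clones plus the normal root as outgroup,
    with internal clone labels suppressed (for topology comparison)."""
    children: dict = {n: [] for n in tree.nodes}
    for n in tree.nodes:
        if tree.parent[n] is not None:
            children[tree.parent[n]].append(n)
    rename = rename or {}

    def fmt(n):
        if not children[n]:
            return rename.get(n, n)
        parts = [fmt(c) for c in children[n]]
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    (anc,) = children[tree.root]
    return f"({fmt(anc)},{rename.get(tree.root, tree.root)});"


# ---------------------------------------------------------------------------
# Binned read counts (low-depth WGS emulation)
# ---------------------------------------------------------------------------

def simulate_binned_counts(spec: SampleSpec, tree: CloneTree, bins: pd.DataFrame,
                           gc_bias=None, seed: int | None = None) -> np.ndarray:
    """Poisson per-bin read counts for one sample.

    Expected count of bin b is
    ``mean_depth * [purity * copy_b / 2 + (1 - purity)] * gc_bias(gc_b)``,
    i.e. a tumor/normal mixture on the diploid-relative scale modulated by
    a GC-dependent efficiency. ``mean_depth`` is interpreted as the
    expected reads per copy-neutral bin at purity 0 and flat GC bias.
    """
    if len(bins) == 0:
        raise ValueError("bins must be non-empty")
    rng = substream(spec.seed if seed is None else seed, "binned_counts", spec.sample_id)
    copy = (tree.copy_number_per_bin(spec.clone_id, bins)
            if spec.purity > 0 else np.full(len(bins), 2.0))
    mix = spec.purity * copy / 2.0 + (1.0 - spec.purity)
    eff = np.ones(len(bins)) if gc_bias is None else np.asarray(gc_bias(bins["gc"].to_numpy()))
    lam = spec.mean_depth * mix * eff
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Pileups and caller outputs (WES emulation)
# ---------------------------------------------------------------------------

def _draw_depths(rng, n, mean_depth, dispersion):
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mean_depth, size=n)
    # gamma-Poisson mixture: variance = mean + mean^2 / dispersion
    lam = rng.gamma(shape=dispersion, scale=mean_depth / dispersion, size=n)
    return rng.poisson(lam)


def _other_bases(rng, ref, k=1):
    choices = [b for b in BASES if b != ref]
    return [choices[int(i)] for i in rng.integers(0, 3, size=k)]


def simulate_pileups_and_callsets(spec: SampleSpec, tree: CloneTree,
                                  error: ErrorModel, seed: int | None = None):
    """Per-locus allele counts and three caller call sets for one sample.

    The pileup covers every somatic locus on the tree (so downstream
    rescue can query any sample at any candidate site) plus this sample's
    false-positive loci. True somatic loci of the sample's clone receive
    alt counts ~ Binomial(depth, purity/2) (diploid heterozygous);
    remaining reads carry uniform base errors. Caller-private NGS false
    positives appear in exactly one caller with marginal pileup support;
    sample-private WGA artifacts appear in >=2 callers of this sample at
    allele fraction ``error.wga_vaf``, at loci outside every clone's truth.

    Returns ``(pileups, callsets, flags)`` where ``flags`` maps each
    called locus to its origin: "true", "ngs_fp" or "wga_fp".
    """
    rng = substream(spec.seed if seed is None else seed, "pileup", spec.sample_id)
    truth = tree.clone_snvs(spec.clone_id) if spec.purity > 0 else []
    truth_loci = {s.locus for s in truth}
    panel = {s.locus: s.ref for s in tree.all_snvs()}
    tree_loci = set(panel)

    n_true = len(truth)
    flags: dict = {}

    # --- sample-private WGA artifacts -------------------------------------
    wga_events = []
    if error.wga_fp_rate > 0 and n_true > 0:
        n_wga = rng.binomial(n_true, error.wga_fp_rate)
        lengths = tree.genome["length"].to_numpy()
        chrom_p = lengths / lengths.sum()
        names = tree.genome["chrom"].to_list()
        while len(wga_events) < n_wga:
            ci = int(rng.choice(len(names), p=chrom_p))
            pos = int(rng.integers(1, lengths[ci] + 1))
            ref = BASES[int(rng.integers(4))]
            alt = _other_bases(rng, ref)[0]
            if (names[ci], pos, alt) in tree_loci:
                continue
            wga_events.append(SnvEvent(f"wga_{len(wga_events)}", names[ci], pos, ref, alt))
        panel.update({e.locus: e.ref for e in wga_events})
    wga_loci = {e.locus for e in wga_events}

    # --- per-caller NGS false positives -----------------------------------
    ngs_by_caller = {c: [] for c in ("caller_1", "caller_2", "caller_3")}
    if error.ngs_fp_rate > 0 and n_true > 0:
        lengths = tree.genome["length"].to_numpy()
        chrom_p = lengths / lengths.sum()
        names = tree.genome["chrom"].to_list()
        used = set(panel)
        for caller in ngs_by_caller:
            n_fp = rng.binomial(n_true, error.ngs_fp_rate)
            while len(ngs_by_caller[caller]) < n_fp:
                ci = int(rng.choice(len(names), p=chrom_p))
                pos = int(rng.integers(1, lengths[ci] + 1))
                ref = BASES[int(rng.integers(4))]
                alt = _other_bases(rng, ref)[0]
                if (names[ci], pos, alt) in used:
                    continue
                used.add((names[ci], pos, alt))
                ev = SnvEvent(f"ngs_{caller}_{len(ngs_by_caller[caller])}",
                              names[ci], pos, ref, alt)
                ngs_by_caller[caller].append(ev)
                panel[ev.locus] = ev.ref

    # --- pileup -----------------------------------------------------------
    loci = sorted(panel, key=lambda l: (l[0], l[1], l[2]))
    depth = _draw_depths(rng, len(loci), spec.mean_depth, error.depth_dispersion)
    counts = {b: np.zeros(len(loci), dtype=np.int64) for b in BASES}
    alt_of = {}
    for i, locus in enumerate(loci):
        chrom, pos, alt = locus
        ref = panel[locus]
        d = int(depth[i])
        if d == 0:
            continue
        if locus in truth_loci:
            alt_reads = rng.binomial(d, spec.purity / 2.0)
        elif locus in wga_loci:
            alt_reads = rng.binomial(d, error.wga_vaf)
        else:
            alt_reads = 0
        alt_reads = min(alt_reads, d)
        rest = d - alt_reads
        n_err = rng.binomial(rest, error.base_error_rate) if rest else 0
        err_bases = _other_bases(rng, ref, n_err) if n_err else []
        counts[ref][i] = rest - n_err
        counts[alt][i] += alt_reads
        for b in err_bases:
            counts[b][i] += 1
        alt_of[locus] = (ref, alt)

    pileups = pd.DataFrame({
        "chrom": [l[0] for l in loci], "pos": [l[1] for l in loci],
        "ref": [panel[l] for l in loci],
        "A": counts["A"], "C": counts["C"], "G": counts["G"], "T": counts["T"],
    })
    pil_index = {(r.chrom, r.pos): i for i, r in enumerate(pileups.itertuples())}

    def _pileup_alt_depth(locus):
        i = pil_index[(locus[0], locus[1])]
        return int(pileups.iloc[i][locus[2]]), int(
            pileups.iloc[i][["A", "C", "G", "T"]].sum())

    # ensure every NGS FP has at least one supporting read in its pileup
    for caller, events in ngs_by_caller.items():
        for ev in events:
            i = pil_index[(ev.chrom, ev.pos)]
            if pileups.at[i, ev.alt] == 0 and pileups.at[i, ev.ref] > 0:
                pileups.at[i, ev.ref] -= 1
                pileups.at[i, ev.alt] += 1

    # --- caller outputs ---------------------------------------------------
    callsets = []
    caller_ids = ("caller_1", "caller_2", "caller_3")
    n_wga_callers = {e.locus: 2 + int(rng.random() < 0.5) for e in wga_events}
    wga_caller_sets = {loc: set(rng.choice(3, size=k, replace=False))
                       for loc, k in n_wga_callers.items()}
    for ci, caller in enumerate(caller_ids):
        rows = []
        for ev in truth:
            ad, dp = _pileup_alt_depth(ev.locus)
            if ad == 0:
                continue                        # allele dropout: nothing to call
            if error.fn_rate > 0 and rng.random() < error.fn_rate:
                continue
            rows.append((ev.chrom, ev.pos, ev.ref, ev.alt, ad, dp))
            flags[ev.locus] = "true"
        for ev in ngs_by_caller[caller]:
            ad, dp = _pileup_alt_depth(ev.locus)
            rows.append((ev.chrom, ev.pos, ev.ref, ev.alt, max(ad, 1), dp))
            flags[ev.locus] = "ngs_fp"
        for ev in wga_events:
            if ci in wga_caller_sets[ev.locus]:
                ad, dp = _pileup_alt_depth(ev.locus)
                rows.append((ev.chrom, ev.pos, ev.ref, ev.alt, ad, dp))
                flags[ev.locus] = "wga_fp"
        calls = pd.DataFrame(rows, columns=list(CallSet.COLUMNS)).sort_values(
            ["chrom", "pos"]).reset_index(drop=True)
        callsets.append(CallSet(caller_id=caller, sample_id=spec.sample_id, calls=calls))

    return pileups, callsets, flags


# ---------------------------------------------------------------------------
# Cohort convenience
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Everything one simulated study produces, with ground truth attached."""
    tree: CloneTree
    specs: list
    bins: pd.DataFrame
    counts: dict          # sample_id -> per-bin counts
    pileups: dict         # sample_id -> pileup DataFrame
    callsets: dict        # sample_id -> [CallSet x3]
    flags: dict           # sample_id -> locus -> origin
    normal_calls: CallSet = None

    def truth_loci(self, sample_id: str) -> set:
        spec = next(s for s in self.specs if s.sample_id == sample_id)
        if spec.purity == 0:
            return set()
        return {s.locus for s in self.tree.clone_snvs(spec.clone_id)}


def simulate_cohort(tree: CloneTree, specs: list, error: ErrorModel,
                    bins: pd.DataFrame, root_seed: int = 0,
                    gc_bias=None) -> Cohort:
    """Run the full per-sample simulation for a list of sample specs.

    The normal sample's caller output (germline calls) is represented as an
    empty somatic call set: germline variants shared by all samples cancel
    in the subtraction, so only the somatic layer is simulated.
    """
    counts, pileups, callsets, flags = {}, {}, {}, {}
    for i, spec in enumerate(specs):
        s = substream(root_seed, "sample", spec.sample_id)
        sample_seed = int(s.integers(0, 2**31 - 1))
        spec = SampleSpec(spec.sample_id, spec.group, spec.clone_id,
                          spec.purity, spec.mean_depth, seed=sample_seed)
        specs[i] = spec
        counts[spec.sample_id] = simulate_binned_counts(spec, tree, bins, gc_bias=gc_bias)
        p, cs, fl = simulate_pileups_and_callsets(spec, tree, error)
        pileups[spec.sample_id], callsets[spec.sample_id], flags[spec.sample_id] = p, cs, fl
    normal = CallSet("germline", "normal",
                     pd.DataFrame(columns=list(CallSet.COLUMNS)))
    return Cohort(tree=tree, specs=specs, bins=bins, counts=counts,
                  pileups=pileups, callsets=callsets, flags=flags,
                  normal_calls=normal)


def write_truth_tsv(tree: CloneTree, path) -> None:
    """Write per-edge ground-truth events as TSV."""
    rows = []
    for child, ev in tree.branch_events.items():
        for s in ev["snvs"]:
            rows.append((tree.parent[child], child, "snv", s.snv_id,
                         s.chrom, s.pos - 1, s.pos, f"{s.ref}>{s.alt}"))
        for c in ev["cnas"]:
            rows.append((tree.parent[child], child, "cna", c.cna_id,
                         c.chrom, c.start, c.end,
                         "gain" if c.direction > 0 else "loss"))
    pd.DataFrame(rows, columns=["parent", "child", "kind", "event_id",
                                "chrom", "start", "end", "detail"]).to_csv(
        path, sep="\t", index=False)
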