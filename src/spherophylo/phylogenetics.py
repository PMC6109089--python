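"""Joint segmentation, event matrices, and maximum-parsimony phylogenies.

Copy-number profiles of all samples are segmented jointly (shared
breakpoints, exact per-chromosome dynamic programming on a penalized
least-squares objective), thresholded into a trinary event matrix
(loss / neutral / gain, with an explicit missing band between the neutral
and event thresholds), and combined with the binary SNV presence matrix.
Trees are found by maximum parsimony: exhaustive search over all unrooted
topologies up to 8 leaves (guaranteed optimum, all co-optimal topologies
kept), nearest-neighbour-interchange hill climbing from a neighbour-joining
start above that. Missing values are treated as fully ambiguous states in
the Sankoff/Fitch small-parsimony pass. Trees are rooted at an explicit
all-neutral / all-zero outgroup representing the normal genotype.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .snv_consensus import ConsensusTable

INF = np.inf


@dataclass
class ThresholdConfig:
    """Event-calling thresholds on the ploidy scale (diploid = 2).

    A segment is gain/loss when its ploidy deviates from the sample's
    length-weighted mean ploidy by more than ``event_delta``; neutral when
    within ``neutral_delta``; otherwise (the ambiguous band between the
    two) it is a missing value. ``gamma`` is the per-breakpoint penalty of
    the joint segmentation. ``ploidy_scale`` converts copy-number ratios
    (diploid = 1) to ploidy.
    """
    event_delta: float = 0.7
    neutral_delta: float = 0.5
    gamma: float = 50.0
    ploidy_scale: float = 2.0

    def __post_init__(self):
        if not self.neutral_delta < self.event_delta:
            raise ValueError("neutral_delta must be smaller than event_delta")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class SegmentedProfile:
    segments: pd.DataFrame   # chrom, start_bin, end_bin, start, end, length
    means: pd.DataFrame      # samples x segments mean copy ratio

    @property
    def n_breakpoints(self) -> int:
        return sum(len(g) - 1 for _, g in self.segments.groupby("chrom", sort=False))


@dataclass
class EventMatrix:
    """Samples x characters matrix; CNA values in {-1, 0, +1, NaN=missing},
    SNV values in {0, 1}."""
    data: pd.DataFrame
    kind: str                 # "cna" | "snv"
    char_meta: pd.DataFrame = None

    @property
    def states(self):
        return (-1.0, 0.0, 1.0) if self.kind == "cna" else (0.0, 1.0)


@dataclass
class PhyloTree:
    newick: str               # rooted at the outgroup
    score: int
    leaves: list
    co_optimal: list = field(default_factory=list)   # newicks, exhaustive mode only
    consensus: str | None = None                     # strict consensus if several


# ---------------------------------------------------------------------------
# Joint segmentation
# ---------------------------------------------------------------------------

def _segment_chromosome(X: np.ndarray, gamma: float):
    """Exact DP for shared-breakpoint piecewise-constant fit of one
    chromosome. X is samples x bins. Returns breakpoint bin indices
    (segment start indices, excluding 0)."""
    S, n = X.shape
    if n == 1:
        return []
    C = np.concatenate([np.zeros((S, 1)), np.cumsum(X, axis=1)], axis=1)
    C2 = np.concatenate([np.zeros((S, 1)), np.cumsum(X ** 2, axis=1)], axis=1)
    D = np.full(n + 1, INF)
    D[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        i = np.arange(j)
        lens = (j - i).astype(float)
        d1 = C[:, j:j + 1] - C[:, :j]
        d2 = C2[:, j:j + 1] - C2[:, :j]
        cost = d2.sum(axis=0) - (d1 ** 2).sum(axis=0) / lens
        total = D[:j] + cost + np.where(i > 0, gamma, 0.0)
        k = int(np.argmin(total))
        D[j], back[j] = total[k], k
    bps, j = [], n
    while j > 0:
        if back[j] > 0:
            bps.append(int(back[j]))
        j = back[j]
    return sorted(bps)


def _noise_sd(row: np.ndarray) -> float:
    """Per-sample noise SD from median absolute first differences
    (robust to true copy-number steps)."""
    d = np.abs(np.diff(row))
    if len(d) == 0:
        return 0.0
    mad = np.median(d)
    return float(mad / (np.sqrt(2) * 0.6745))


def joint_segmentation(ratios: pd.DataFrame, bins: pd.DataFrame,
                       gamma: float = 50.0) -> SegmentedProfile:
    """Multi-sample segmentation with breakpoints shared across samples.

    Each sample is standardized by a robust estimate of its per-bin noise
    SD (median absolute first difference), then the exact per-chromosome
    dynamic program minimizes the summed squared error of the standardized
    data plus ``gamma`` per breakpoint. Standardizing puts ``gamma`` on
    the noise scale of the data, matching how the published multi-sample
    piecewise-constant-fit penalty behaves, so the default 50 transfers
    across depths and bin counts. ``ratios`` is a samples x bins DataFrame
    aligned with ``bins``; reported segment means are on the original
    ratio scale.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if ratios.shape[1] != len(bins):
        raise ValueError("ratio matrix and bin table must align")
    R = ratios.to_numpy(dtype=float)
    sds = np.array([_noise_sd(row) for row in R])
    sds[sds == 0] = 1.0     # noiseless profile: any real step is significant
    seg_rows, mean_cols = [], []
    for chrom, sub in bins.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        X = ratios.iloc[:, idx].to_numpy(dtype=float)
        bps = _segment_chromosome(X / sds[:, None], gamma)
        bounds = [0] + bps + [len(idx)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            start = int(sub.iloc[a]["start"])
            end = int(sub.iloc[b - 1]["end"])
            seg_rows.append((chrom, int(idx[a]), int(idx[b - 1]) + 1,
                             start, end, end - start))
            mean_cols.append(X[:, a:b].mean(axis=1))
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start_bin", "end_bin",
                                               "start", "end", "length"])
    means = pd.DataFrame(np.column_stack(mean_cols), index=ratios.index)
    return SegmentedProfile(segments=segments, means=means)


# ---------------------------------------------------------------------------
# Event matrices
# ---------------------------------------------------------------------------

def trinary_matrix(segmented: SegmentedProfile,
                   thresholds: ThresholdConfig | None = None,
                   add_root: bool = True, root_name: str = "normal") -> EventMatrix:
    """Trinary CNA event matrix from a segmented profile.

    Segment ratios are converted to ploidy (``ploidy_scale`` x ratio); per
    sample, the mean ploidy is the segment-length-weighted mean. Each cell
    is +1 (gain) above mean + event_delta, -1 (loss) below
    mean - event_delta, 0 (neutral) within +-neutral_delta of the mean,
    and missing in the ambiguous band in between.
    """
    if thresholds is None:
        thresholds = ThresholdConfig()
    ploidy = thresholds.ploidy_scale * segmented.means.to_numpy(dtype=float)
    w = segmented.segments["length"].to_numpy(dtype=float)
    mean_ploidy = (ploidy * w).sum(axis=1) / w.sum()
    dev = ploidy - mean_ploidy[:, None]
    out = np.full(dev.shape, np.nan)
    out[np.abs(dev) <= thresholds.neutral_delta] = 0.0
    out[dev > thresholds.event_delta] = 1.0
    out[dev < -thresholds.event_delta] = -1.0
    df = pd.DataFrame(out, index=segmented.means.index,
                      columns=[f"seg_{i}" for i in range(dev.shape[1])])
    if add_root:
        df.loc[root_name] = 0.0
    return EventMatrix(data=df, kind="cna", char_meta=segmented.segments)


def binary_snv_matrix(table: ConsensusTable, included_samples: list | None = None,
                      add_root: bool = True, root_name: str = "normal") -> EventMatrix:
    """Binary SNV matrix: 1 mutated, 0 not mutated, plus an all-zero root."""
    presence = table.presence
    if included_samples is not None:
        presence = presence[list(included_samples)]
    df = presence.T.astype(float)
    df.columns = [f"{c}:{p}:{a}" for (c, p, a) in presence.index]
    meta = pd.DataFrame([(c, p, a) for (c, p, a) in presence.index],
                        columns=["chrom", "pos", "alt"])
    if add_root:
        df.loc[root_name] = 0.0
    informative = (df.nunique(axis=0) > 1).sum()
    if informative == 0:
        raise ValueError("event matrix has no informative characters")
    return EventMatrix(data=df, kind="snv", char_meta=meta)


# ---------------------------------------------------------------------------
# Topologies (nested-tuple unrooted trees)
# ---------------------------------------------------------------------------

def _insertions(sub, leaf):
    """All ways to insert ``leaf`` into an edge of ``sub``, including the
    edge above ``sub`` itself."""
    out = [(sub, leaf)]
    if isinstance(sub, tuple):
        for i in range(len(sub)):
            for s in _insertions(sub[i], leaf):
                out.append(sub[:i] + (s,) + sub[i + 1:])
    return out


def enumerate_topologies(leaves: list):
    """All unrooted binary topologies over the leaves ((2n-5)!! of them),
    as nested tuples with a top-level trifurcation."""
    leaves = list(leaves)
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves")
    tops = [tuple(leaves[:3])]
    for leaf in leaves[3:]:
        nxt = []
        for top in tops:
            for i in range(3):
                for s in _insertions(top[i], leaf):
                    nxt.append(top[:i] + (s,) + top[i + 1:])
        tops = nxt
    return tops


def _leaf_costs(matrix: EventMatrix):
    """Per-leaf Sankoff cost arrays (n_states x n_chars), with duplicate
    character columns collapsed into weights."""
    states = matrix.states
    vals = matrix.data.to_numpy(dtype=float)
    cols, weights = np.unique(
        np.nan_to_num(vals, nan=9.0).T, axis=0, return_counts=True)
    cols = cols.T    # rows x unique chars
    costs = {}
    for r, leaf in enumerate(matrix.data.index):
        c = np.zeros((len(states), cols.shape[1]))
        for si, s in enumerate(states):
            mismatch = (cols[r] != s) & (cols[r] != 9.0)
            c[si, mismatch] = INF
        costs[leaf] = c
    return costs, weights.astype(float)


def _subtree_cost(node, leaf_costs):
    if isinstance(node, str):
        return leaf_costs[node]
    total = None
    for child in node:
        c = _subtree_cost(child, leaf_costs)
        contrib = np.minimum(c, c.min(axis=0)[None, :] + 1.0)
        total = contrib if total is None else total + contrib
    return total


def _score_topology(top, leaf_costs, weights) -> float:
    root = _subtree_cost(top, leaf_costs)
    return float((root.min(axis=0) * weights).sum())


def parsimony_score(tree, matrix: EventMatrix) -> int:
    """Small-parsimony (unit-cost Sankoff) score of a topology.

    ``tree`` may be a nested-tuple topology, a newick string, or a
    PhyloTree. Missing matrix values contribute the full state set at the
    leaf and never increase the score.
    """
    top = _as_nested(tree, set(matrix.data.index))
    leaves = set(_leaves_of(top))
    if leaves != set(matrix.data.index):
        raise ValueError("tree leaves do not match matrix rows")
    costs, weights = _leaf_costs(matrix)
    return int(round(_score_topology(top, costs, weights)))


def _leaves_of(node):
    if isinstance(node, str):
        return [node]
    out = []
    for child in node:
        out.extend(_leaves_of(child))
    return out


# ---------------------------------------------------------------------------
# Newick / adjacency conversions
# ---------------------------------------------------------------------------

def _nested_to_newick_rooted(top, outgroup: str | None) -> str:
    """Write the unrooted nested topology as newick, rooted on the edge to
    the outgroup leaf when given."""
    adj, leaves = _nested_to_adj(top)
    if outgroup is None or outgroup not in leaves:
        outgroup = sorted(leaves)[0]
    og = leaves[outgroup]
    (nbr,) = adj[og]

    def sub(node, parent):
        kids = [k for k in adj[node] if k != parent]
        if not kids:
            return _name_of(node, leaves)
        return "(" + ",".join(sub(k, node) for k in kids) + ")"

    return f"({sub(nbr, og)},{outgroup});"


def _name_of(node, leaves):
    for name, nid in leaves.items():
        if nid == node:
            return name
    raise KeyError(node)


def _nested_to_adj(top):
    """Adjacency dict over integer node ids; returns (adj, leaf name->id)."""
    adj: dict = {}
    leaves: dict = {}
    counter = [0]

    def new_node():
        nid = counter[0]
        counter[0] += 1
        adj[nid] = set()
        return nid

    def build(node):
        nid = new_node()
        if isinstance(node, str):
            leaves[node] = nid
            return nid
        for child in node:
            cid = build(child)
            adj[nid].add(cid)
            adj[cid].add(nid)
        return nid

    root = new_node()
    for child in top:
        cid = build(child)
        adj[root].add(cid)
        adj[cid].add(root)
    return adj, leaves


def _adj_to_nested(adj, leaves):
    """Nested-tuple topology from an adjacency dict (all internal nodes of
    degree 3)."""
    id_to_name = {v: k for k, v in leaves.items()}
    internal = [n for n in adj if n not in id_to_name]
    if not internal:   # 2 or fewer leaves; not a valid unrooted topology
        raise ValueError("tree too small")
    root = internal[0]

    def build(node, parent):
        if node in id_to_name:
            return id_to_name[node]
        kids = [k for k in adj[node] if k != parent]
        return tuple(build(k, node) for k in kids)

    kids = list(adj[root])
    return tuple(build(k, root) for k in kids)


def _as_nested(tree, leaf_names: set):
    if isinstance(tree, PhyloTree):
        tree = tree.newick
    if isinstance(tree, tuple):
        return tree
    if isinstance(tree, str):
        dt = dendropy.Tree.get(data=tree, schema="newick")
        adj, leaves = _dendropy_to_adj(dt)
        return _adj_to_nested(adj, leaves)
    raise TypeError(f"cannot interpret tree of type {type(tree)}")


def _dendropy_to_adj(dt: dendropy.Tree):
    """Unrooted adjacency from a dendropy tree; degree-2 nodes (rooting
    artifacts) are suppressed."""
    adj: dict = {}
    leaves: dict = {}
    ids: dict = {}

    def nid(node):
        if node not in ids:
            ids[node] = len(ids)
            adj[ids[node]] = set()
        return ids[node]

    for edge in dt.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        a, b = nid(edge.tail_node), nid(edge.head_node)
        adj[a].add(b)
        adj[b].add(a)
    for node in dt.leaf_node_iter():
        leaves[node.taxon.label] = ids[node]
    # suppress degree-2 internal nodes
    changed = True
    leaf_ids = set(leaves.values())
    while changed:
        changed = False
        for n in list(adj):
            if n not in leaf_ids and len(adj[n]) == 2:
                a, b = adj[n]
                adj[a].discard(n)
                adj[b].discard(n)
                adj[a].add(b)
                adj[b].add(a)
                del adj[n]
                changed = True
    return adj, leaves


# ---------------------------------------------------------------------------
# Tree search
# ---------------------------------------------------------------------------

def _nj_start(matrix: EventMatrix):
    """Neighbour-joining start topology from pairwise Hamming distances
    (missing values excluded pairwise)."""
    vals = matrix.data.to_numpy(dtype=float)
    names = list(matrix.data.index)
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            d = float(np.mean(vals[i][ok] != vals[j][ok])) if ok.any() else 0.0
            D[i, j] = D[j, i] = d
    buf = io.StringIO()
    buf.write("," + ",".join(names) + "\n")
    for i, nm in enumerate(names):
        buf.write(nm + "," + ",".join(f"{x:.6f}" for x in D[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    nj = pdm.nj_tree()
    adj, leaves = _dendropy_to_adj(nj)
    return _adj_to_nested(adj, leaves)


def _nni_neighbors(top):
    """All topologies one nearest-neighbour interchange away."""
    adj, leaves = _nested_to_adj(top)
    leaf_ids = set(leaves.values())
    out = []
    seen_edges = set()
    for u in adj:
        if u in leaf_ids:
            continue
        for v in adj[u]:
            if v in leaf_ids or (v, u) in seen_edges:
                continue
            seen_edges.add((u, v))
            a, b = [x for x in adj[u] if x != v]
            c, d = [x for x in adj[v] if x != u]
            for x, y in ((a, c), (a, d)):
                adj2 = {k: set(s) for k, s in adj.items()}
                adj2[u].discard(x); adj2[x].discard(u)
                adj2[v].discard(y); adj2[y].discard(v)
                adj2[u].add(y); adj2[y].add(u)
                adj2[v].add(x); adj2[x].add(v)
                out.append(_adj_to_nested(adj2, leaves))
    return out


def _random_topology(leaves, rng):
    order = list(leaves)
    rng.shuffle(order)
    top = tuple(order[:3])
    for leaf in order[3:]:
        cands = []
        for i in range(3):
            for s in _insertions(top[i], leaf):
                cands.append(top[:i] + (s,) + top[i + 1:])
        top = cands[int(rng.integers(len(cands)))]
    return top


def search_max_parsimony(matrix: EventMatrix, max_exhaustive: int = 8,
                         n_restarts: int = 3, seed: int = 0,
                         root_name: str = "normal") -> PhyloTree:
    """Maximum-parsimony tree for an event matrix.

    Up to ``max_exhaustive`` leaves: exhaustive search over all unrooted
    topologies (guaranteed optimum); every co-optimal topology is kept and
    a strict consensus reported when there are several. Above that:
    NNI hill climbing from a neighbour-joining start plus random restarts.
    The returned newick is rooted at the outgroup (``root_name``) when it
    is among the rows.
    """
    names = list(matrix.data.index)
    if len(names) < 3:
        raise ValueError("need at least 3 rows to build a tree")
    costs, weights = _leaf_costs(matrix)
    outgroup = root_name if root_name in names else None

    if len(names) <= max_exhaustive:
        best_score, best_tops = INF, []
        for top in enumerate_topologies(names):
            s = _score_topology(top, costs, weights)
            if s < best_score - 1e-9:
                best_score, best_tops = s, [top]
            elif abs(s - best_score) <= 1e-9:
                best_tops.append(top)
        newicks = [_nested_to_newick_rooted(t, outgroup) for t in best_tops]
        consensus = _strict_consensus(newicks) if len(newicks) > 1 else None
        return PhyloTree(newick=newicks[0], score=int(round(best_score)),
                         leaves=names, co_optimal=newicks, consensus=consensus)

    rng = np.random.default_rng(seed)
    starts = [_nj_start(matrix)] + [_random_topology(names, rng)
                                    for _ in range(n_restarts)]
    best_top, best_score = None, INF
    for top in starts:
        score = _score_topology(top, costs, weights)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(top):
                s = _score_topology(nb, costs, weights)
                if s < score - 1e-9:
                    top, score, improved = nb, s, True
                    break
        if score < best_score:
            best_top, best_score = top, score
    newick = _nested_to_newick_rooted(best_top, outgroup)
    return PhyloTree(newick=newick, score=int(round(best_score)),
                     leaves=names, co_optimal=[newick])


def _strict_consensus(newicks: list) -> str:
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(
        [dendropy.Tree.get(data=nw, schema="newick", taxon_namespace=tns)
         for nw in newicks], taxon_namespace=tns)
    cons = trees.consensus(min_freq=1.0)
    return cons.as_string(schema="newick").strip()


def compare_trees(t1, t2) -> int:
    """Unrooted Robinson-Foulds distance between two trees (newick strings,
    PhyloTrees, or nested topologies); 0 iff the split sets are identical."""
    def to_newick(t):
        if isinstance(t, PhyloTree):
            return t.newick
        if isinstance(t, tuple):
            return _nested_to_newick_rooted(t, None)
        return t

    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=to_newick(t1), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=to_newick(t2), schema="newick", taxon_namespace=tns)
    if {l.taxon.label for l in d1.leaf_node_iter()} != \
            {l.taxon.label for l in d2.leaf_node_iter()}:
        raise ValueError("trees have different leaf sets")
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(d1, d2))
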