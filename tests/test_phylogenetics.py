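"""Segmentation DP, event-matrix thresholds, parsimony and tree distance."""

import itertools

import numpy as np
import pandas as pd
import pytest

import spherophylo as sp
from spherophylo.phylogenetics import (EventMatrix, ThresholdConfig,
                                       _leaf_costs, _nj_start, _score_topology,
                                       enumerate_topologies, joint_segmentation,
                                       parsimony_score, search_max_parsimony,
                                       trinary_matrix)


def _bins(n, chrom="chr1", size=1000):
    return pd.DataFrame({"chrom": chrom, "start": np.arange(n) * size,
                         "end": (np.arange(n) + 1) * size})


def _exhaustive_segmentation_cost(X, gamma):
    """Minimum of the penalized SSE over all breakpoint subsets, by
    explicit enumeration (the independent oracle for the DP)."""
    S, n = X.shape
    best = np.inf
    best_bps = None
    for r in range(n):
        for bps in itertools.combinations(range(1, n), r):
            bounds = [0, *bps, n]
            cost = gamma * r
            for a, b in zip(bounds[:-1], bounds[1:]):
                seg = X[:, a:b]
                cost += ((seg - seg.mean(axis=1, keepdims=True)) ** 2).sum()
            if cost < best - 1e-12:
                best, best_bps = cost, list(bps)
    return best, best_bps


class TestJointSegmentation:
    def test_flat_profiles_no_breakpoints(self):
        rng = np.random.default_rng(0)
        ratios = pd.DataFrame(rng.normal(1.0, 0.05, (3, 50)))
        seg = joint_segmentation(ratios, _bins(50), gamma=50.0)
        assert seg.n_breakpoints == 0

    def test_shared_step_found_exactly(self):
        rng = np.random.default_rng(1)
        X = np.ones((3, 30)) + rng.normal(0, 0.03, (3, 30))
        X[:, 15:] += 1.0
        seg = joint_segmentation(pd.DataFrame(X), _bins(30), gamma=20.0)
        assert seg.n_breakpoints == 1
        assert seg.segments.iloc[1]["start_bin"] == 15

    def test_huge_gamma_suppresses_all_breakpoints(self):
        rng = np.random.default_rng(2)
        X = np.ones((2, 40)) + rng.normal(0, 0.05, (2, 40))
        X[:, 20:] += 1.0
        seg = joint_segmentation(pd.DataFrame(X), _bins(40), gamma=1e9)
        assert seg.n_breakpoints == 0

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_dp_matches_exhaustive_search(self, seed):
        """The DP optimum equals brute-force minimization over every
        breakpoint subset (3 samples, 12 bins)."""
        rng = np.random.default_rng(seed)
        n = 12
        X = rng.normal(1.0, 0.2, (3, n))
        X[:, rng.integers(2, 10):] += rng.uniform(0.5, 1.5)
        gamma = 1.0
        # oracle works on the standardized matrix, replicating the
        # objective but not the optimizer
        sds = np.array([np.median(np.abs(np.diff(r))) / (np.sqrt(2) * 0.6745)
                        for r in X])
        sds[sds == 0] = 1.0
        Xstd = X / sds[:, None]
        best_cost, best_bps = _exhaustive_segmentation_cost(Xstd, gamma)
        seg = joint_segmentation(pd.DataFrame(X), _bins(n), gamma=gamma)
        dp_bps = sorted(seg.segments["start_bin"].tolist()[1:])
        dp_cost = gamma * len(dp_bps)
        for a, b in zip([0, *dp_bps], [*dp_bps, n]):
            s = Xstd[:, a:b]
            dp_cost += ((s - s.mean(axis=1, keepdims=True)) ** 2).sum()
        assert np.isclose(dp_cost, best_cost)

    def test_single_bin_chromosome(self):
        ratios = pd.DataFrame(np.ones((2, 1)))
        seg = joint_segmentation(ratios, _bins(1), gamma=50.0)
        assert len(seg.segments) == 1 and seg.n_breakpoints == 0


class TestTrinaryMatrix:
    def _segmented(self, values, lengths=None):
        values = np.asarray(values, dtype=float)
        n = values.shape[1]
        lengths = lengths if lengths is not None else np.full(n, 1000)
        segments = pd.DataFrame({
            "chrom": "chr1", "start_bin": range(n), "end_bin": range(1, n + 1),
            "start": np.cumsum([0, *lengths[:-1]]), "end": np.cumsum(lengths),
            "length": lengths})
        means = pd.DataFrame(values, index=[f"S{i}" for i in range(len(values))])
        return sp.SegmentedProfile(segments=segments, means=means)

    def test_threshold_bands(self):
        """On the ploidy scale: 0 at the mean, missing in the 0.5-0.7 band,
        gain/loss beyond 0.7."""
        thr = ThresholdConfig(ploidy_scale=1.0)   # feed ploidy directly
        seg = self._segmented([[2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0]])
        m = trinary_matrix(seg, thr, add_root=False).data.to_numpy()[0]
        assert (m == 0).all()
        vals = np.full(40, 2.0)
        vals[0], vals[1], vals[2], vals[3] = 2.6, 2.8, 1.2, 1.4
        seg = self._segmented([vals])
        row = trinary_matrix(seg, thr, add_root=False).data.iloc[0]
        m = vals.mean()
        assert m == 2.0
        assert np.isnan(row.iloc[0])                       # +0.6: ambiguous band
        assert row.iloc[1] == 1.0 and row.iloc[2] == -1.0  # beyond +-0.7
        assert np.isnan(row.iloc[3])                       # -0.6: ambiguous band

    def test_randomized_cells_match_per_cell_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(1.0, 3.0, (4, 30))
        lengths = rng.integers(500, 5000, 30)
        thr = ThresholdConfig(ploidy_scale=1.0)
        out = trinary_matrix(self._segmented(vals, lengths), thr,
                             add_root=False).data.to_numpy()
        for i in range(4):
            mean = np.average(vals[i], weights=lengths)
            for j in range(30):
                v = vals[i, j]
                if v > mean + 0.7:
                    assert out[i, j] == 1.0
                elif v < mean - 0.7:
                    assert out[i, j] == -1.0
                elif abs(v - mean) <= 0.5:
                    assert out[i, j] == 0.0
                else:
                    assert np.isnan(out[i, j])

    def test_ratio_scale_conversion(self):
        """Default config doubles copy-number ratios, so a one-copy loss in
        a pure sample (ratio 0.5) crosses the 0.7 event threshold."""
        vals = np.full(40, 1.0)
        vals[0] = 0.5
        row = trinary_matrix(self._segmented([vals]), ThresholdConfig(),
                             add_root=False).data.iloc[0]
        assert row.iloc[0] == -1.0


class TestBinarySnvMatrix:
    def test_matches_truth_and_partition(self, nonoise_consensus):
        table, cohort, _ = nonoise_consensus
        m = sp.binary_snv_matrix(table)
        assert set(m.data.index) == {s.sample_id for s in cohort.specs
                                     if s.group != "normal"} | {"normal"}
        assert (m.data.loc["normal"] == 0).all()
        n_common = (table.category == "common").sum()
        n_p = (table.category == "primary_only").sum()
        n_a = (table.category == "ascites_only").sum()
        assert n_common + n_p + n_a == m.data.shape[1]   # category partition
        for s in m.data.index:
            if s == "normal":
                continue
            truth = cohort.truth_loci(s)
            called = {tuple(loc) for loc, v in zip(table.presence.index,
                                                   m.data.loc[s]) if v == 1.0}
            assert called == truth & set(table.presence.index)

    def test_rejects_uninformative_matrix(self):
        idx = pd.Index([("chr1", 1, "T")], tupleize_cols=False)
        presence = pd.DataFrame({"A": [True], "B": [True]}, index=idx)
        table = sp.ConsensusTable(presence=presence, evidence=pd.DataFrame(),
                                  category=pd.Series(["common"], index=idx),
                                  stage_counts={})
        with pytest.raises(ValueError):
            sp.binary_snv_matrix(table, add_root=False)


def _matrix(rows: dict, kind="snv"):
    return EventMatrix(data=pd.DataFrame(rows).T.astype(float), kind=kind)


def _brute_force_sankoff(top, matrix):
    """Enumerate all internal state assignments (the independent oracle)."""
    states = matrix.states
    leaves = list(matrix.data.index)

    def edges_and_nodes(node, acc_edges, acc_internal):
        if isinstance(node, str):
            return node
        ids = []
        for child in node:
            ids.append(edges_and_nodes(child, acc_edges, acc_internal))
        me = f"__int{len(acc_internal)}"
        acc_internal.append(me)
        for c in ids:
            acc_edges.append((me, c))
        return me

    total = 0
    for char in matrix.data.columns:
        obs = matrix.data[char]
        best = np.inf
        acc_edges, acc_internal = [], []
        edges_and_nodes(top, acc_edges, acc_internal)
        for assign in itertools.product(states, repeat=len(acc_internal)):
            amap = dict(zip(acc_internal, assign))
            cost = 0
            for a, b in acc_edges:
                sa = amap[a]
                if b in amap:
                    sb = amap[b]
                    cost += sa != sb
                else:
                    v = obs[b]
                    if not np.isnan(v):
                        cost += sa != v
            best = min(best, cost)
        total += best
    return int(total)


class TestParsimony:
    def test_identical_rows_score_zero(self):
        m = _matrix({"A": [0, 1, 1], "B": [0, 1, 1], "C": [0, 1, 1],
                     "D": [0, 1, 1]})
        for top in enumerate_topologies(["A", "B", "C", "D"]):
            assert parsimony_score(top, m) == 0

    def test_four_taxon_example_matches_enumeration(self):
        m = _matrix({"A": [0, 0], "B": [0, 1], "C": [1, 1], "D": [1, 0]})
        top = ("A", "B", ("C", "D"))   # the unrooted topology ((A,B),(C,D))
        score = parsimony_score(top, m)
        assert score == _brute_force_sankoff(top, m)
        assert score == 3

    @pytest.mark.parametrize("kind", ["snv", "cna"])
    def test_random_matrices_match_enumeration(self, kind):
        rng = np.random.default_rng(7)
        names = list("ABCDE")
        vals = rng.choice([-1, 0, 1] if kind == "cna" else [0, 1],
                          size=(5, 6)).astype(float)
        vals[rng.random((5, 6)) < 0.15] = np.nan   # sprinkle missing entries
        m = EventMatrix(data=pd.DataFrame(vals, index=names), kind=kind)
        for top in enumerate_topologies(names)[::5]:
            assert parsimony_score(top, m) == _brute_force_sankoff(top, m)

    def test_all_missing_character_contributes_nothing(self):
        m = _matrix({"A": [0, np.nan], "B": [1, np.nan], "C": [1, np.nan]})
        m2 = _matrix({"A": [0], "B": [1], "C": [1]})
        top = ("A", "B", "C")
        assert parsimony_score(top, m) == parsimony_score(top, m2)

    def test_leaf_mismatch_rejected(self):
        m = _matrix({"A": [0], "B": [1], "C": [1]})
        with pytest.raises(ValueError):
            parsimony_score(("A", "B", "D"), m)


class TestSearch:
    def test_recovers_known_six_leaf_topology(self, genome):
        tree, leaves = sp.simulate_binary_clone_tree(6, 40, 12, genome, seed=8)
        rows = {}
        all_snvs = [s.locus for s in tree.all_snvs()]
        for c in leaves:
            g = {s.locus for s in tree.clone_snvs(c)}
            rows[c] = [1.0 if l in g else 0.0 for l in all_snvs]
        rows["normal"] = [0.0] * len(all_snvs)
        m = EventMatrix(data=pd.DataFrame(rows).T, kind="snv")
        found = search_max_parsimony(m)
        assert sp.compare_trees(found, sp.leaf_topology_newick(tree)) == 0
        # optimality: score <= every enumerated topology's score
        for top in enumerate_topologies(list(m.data.index))[::50]:
            assert found.score <= parsimony_score(top, m)

    def test_star_matrix_scores_zero(self):
        m = _matrix({n: [1, 0, 1] for n in "ABCD"})
        found = search_max_parsimony(m)
        assert found.score == 0

    def test_heuristic_not_worse_than_nj_start(self):
        rng = np.random.default_rng(9)
        names = [f"S{i}" for i in range(10)]
        vals = rng.choice([0, 1], size=(10, 40)).astype(float)
        m = EventMatrix(data=pd.DataFrame(vals, index=names), kind="snv")
        found = search_max_parsimony(m, max_exhaustive=8, seed=0)
        costs, weights = _leaf_costs(m)
        nj_score = _score_topology(_nj_start(m), costs, weights)
        assert found.score <= nj_score

    def test_too_few_rows_rejected(self):
        m = _matrix({"A": [0], "B": [1]})
        with pytest.raises(ValueError):
            search_max_parsimony(m)


def _splits(top):
    """Non-trivial splits of a nested unrooted topology (oracle helper)."""
    leaves = set()

    def collect(node):
        if isinstance(node, str):
            leaves.add(node)
            return [node]
        out = []
        for c in node:
            out.extend(collect(c))
        return out

    collect(top)
    splits = set()

    def walk(node):
        if isinstance(node, str):
            return {node}
        below = set()
        for c in node:
            sub = walk(c)
            if 1 < len(sub) < len(leaves) - 1:
                splits.add(frozenset(sub) if min(sub) in sub else frozenset(sub))
            below |= sub
        return below

    walk(top)
    canon = {frozenset(s) if sorted(leaves)[0] not in s
             else frozenset(leaves - s) for s in splits}
    return canon


class TestCompareTrees:
    def test_identical_trees_distance_zero(self):
        t = "((A,B),(C,D));"
        assert sp.compare_trees(t, t) == 0

    def test_single_nni_distance_two(self):
        assert sp.compare_trees("((A,B),(C,D));", "((A,C),(B,D));") == 2

    def test_caterpillar_vs_balanced_matches_split_oracle(self):
        cat = ("A", "B", ("C", ("D", ("E", "F"))))
        bal = (("A", "B"), ("C", "D"), ("E", "F"))
        expected = len(_splits(cat) ^ _splits(bal))
        assert sp.compare_trees(cat, bal) == expected

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sp.compare_trees("((A,B),(C,D));", "((A,B),(C,E));")
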