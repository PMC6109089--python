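"""Three-caller consensus chain: double-calling, germline removal,
confident sites, Fisher rescue, categories and error suppression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import spherophylo as sp
from spherophylo.snv_consensus import (CATEGORY_ASCITES, CATEGORY_COMMON,
                                       CATEGORY_PRIMARY, ConsensusConfig,
                                       categorize, fisher_rescue)


def _callset(caller, sample, loci):
    rows = [(c, p, "A", alt, 10, 30) for (c, p, alt) in loci]
    return sp.CallSet(caller, sample, pd.DataFrame(
        rows, columns=list(sp.CallSet.COLUMNS)))


def _locus(i):
    return ("chr1", 100 + i, "T")


class TestDoubleCalled:
    def test_two_caller_locus_included_single_excluded(self):
        cs = [_callset("c1", "S", [_locus(1), _locus(2)]),
              _callset("c2", "S", [_locus(1)]),
              _callset("c3", "S", [_locus(3)])]
        out = sp.intra_sample_double_called(cs)
        assert _locus(1) in out
        assert _locus(2) not in out and _locus(3) not in out

    def test_duplicate_caller_rejected(self):
        cs = [_callset("c1", "S", []), _callset("c1", "S", []),
              _callset("c3", "S", [])]
        with pytest.raises(ValueError):
            sp.intra_sample_double_called(cs)

    def test_random_injection_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(0)
        loci = [_locus(i) for i in range(100)]
        sets = [set(l for l in loci if rng.random() < 0.5) for _ in range(3)]
        cs = [_callset(f"c{i}", "S", s) for i, s in enumerate(sets)]
        expected = {l for l in loci
                    if sum(l in s for s in sets) >= 2}   # brute-force tally
        assert sp.intra_sample_double_called(cs) == expected

    def test_adding_calls_never_shrinks(self):
        rng = np.random.default_rng(1)
        loci = [_locus(i) for i in range(60)]
        sets = [set(l for l in loci if rng.random() < 0.4) for _ in range(3)]
        base = sp.intra_sample_double_called(
            [_callset(f"c{i}", "S", s) for i, s in enumerate(sets)])
        sets[0] |= {l for l in loci if rng.random() < 0.3}
        grown = sp.intra_sample_double_called(
            [_callset(f"c{i}", "S", s) for i, s in enumerate(sets)])
        assert base <= grown


class TestGermlineAndConfident:
    def test_remove_germline(self):
        loci = {_locus(i) for i in range(10)}
        empty = _callset("n", "NB", [])
        assert sp.remove_germline(loci, empty) == loci
        allg = _callset("n", "NB", list(loci))
        assert sp.remove_germline(loci, allg) == set()
        half = _callset("n", "NB", [_locus(i) for i in range(5)])
        assert sp.remove_germline(loci, half) == {_locus(i) for i in range(5, 10)}

    def test_confident_requires_two_samples(self):
        dc = {"A": {_locus(1), _locus(2)}, "B": {_locus(1)}, "C": set()}
        assert sp.confident_sites(dc) == {_locus(1)}
        with pytest.raises(ValueError):
            sp.confident_sites({"A": {_locus(1)}})


class TestFisherRescue:
    def _row(self, ref_n, alt_n, other_n=0):
        return {"A": ref_n, "C": other_n, "G": 0, "T": alt_n}

    def test_strong_variant_rescued_by_single_caller(self):
        present, p = fisher_rescue(("chr1", 100, "T"), "A",
                                   self._row(88, 12), True)
        assert present and p < 1e-3

    def test_gate_condition_no_caller_no_rescue(self):
        present, p = fisher_rescue(("chr1", 100, "T"), "A",
                                   self._row(88, 12), False)
        assert not present and p < 1e-3

    def test_symmetric_table_not_significant(self):
        present, p = fisher_rescue(("chr1", 100, "T"), "A",
                                   self._row(96, 2, other_n=2), True)
        assert not present and p > 0.5

    def test_alt_equals_ref_rejected(self):
        with pytest.raises(ValueError):
            fisher_rescue(("chr1", 100, "A"), "A", self._row(50, 0), True)

    def test_matches_hypergeometric_oracle(self):
        """One-sided p equals tail of the hypergeometric distribution with
        the table's margins, computed independently."""
        for depth in (11, 40):
            for alt in range(0, depth + 1, 2):
                for other in range(0, depth - alt + 1, 2):
                    row = {"A": depth - alt - other, "C": other, "G": 0, "T": alt}
                    _, p = fisher_rescue(("chr1", 1, "T"), "A", row, True)
                    K = alt + other
                    expected = hypergeom.sf(alt - 1, 2 * depth, K, depth)
                    assert np.isclose(p, expected, rtol=1e-9)

    def test_raising_alpha_never_removes_presence(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            alt = int(rng.integers(0, 20))
            other = int(rng.integers(0, 5))
            row = {"A": 100 - alt - other, "C": other, "G": 0, "T": alt}
            lo, _ = fisher_rescue(("chr1", 1, "T"), "A", row, True,
                                  ConsensusConfig(fisher_alpha=1e-4))
            hi, _ = fisher_rescue(("chr1", 1, "T"), "A", row, True,
                                  ConsensusConfig(fisher_alpha=1e-2))
            assert (not lo) or hi


class TestFullChain:
    def test_no_noise_equals_simulator_truth(self, genome):
        """With two samples per clone and zero error rates the final table
        equals the simulator truth exactly (recall 1, no false entries).
        Two samples per clone mirror the study's multi-region sampling and
        keep clone-private mutations above the two-sample confidence rule."""
        tree, leaves = sp.simulate_binary_clone_tree(3, 30, 5, genome, seed=23)
        specs = []
        for i, c in enumerate(leaves):
            group = "primary" if i < 2 else "ascites"
            specs.append(sp.SampleSpec(f"S{i}a", group, c, 0.9, 134.0))
            specs.append(sp.SampleSpec(f"S{i}b", group, c, 0.9, 134.0))
        specs.append(sp.SampleSpec("NB", "normal", tree.root, 0.0, 134.0))
        bins = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [1000], "gc": 0.4})
        err = sp.ErrorModel(base_error_rate=0.0)
        cohort = sp.simulate_cohort(tree, specs, err, bins, root_seed=23)
        tumor = [s.sample_id for s in cohort.specs if s.group != "normal"]
        table = sp.build_consensus_table(
            {s: cohort.callsets[s] for s in tumor},
            {s: cohort.pileups[s] for s in tumor},
            cohort.normal_calls, {s.sample_id: s.group for s in cohort.specs})
        all_truth = set().union(*(cohort.truth_loci(s) for s in tumor))
        assert set(table.presence.index) == all_truth
        for s in tumor:
            called = set(table.presence.index[table.presence[s]])
            assert called == cohort.truth_loci(s)   # perfect recall and specificity

    def test_present_loci_subset_of_caller_calls(self, nonoise_consensus):
        table, cohort, _ = nonoise_consensus
        union = set()
        for s in cohort.specs:
            if s.group != "normal":
                for cs in cohort.callsets[s.sample_id]:
                    union |= cs.loci()
        assert set(table.presence.index) <= union

    def test_rescue_never_adds_loci_and_counts_nonincreasing(self, nonoise_consensus):
        table, _, _ = nonoise_consensus
        sc = table.stage_counts
        assert sc["double_called"] >= sc["after_germline_removal"] >= \
            sc["confident_sites"] == sc["final_loci"]

    def test_ngs_fp_suppression(self, genome):
        """Caller-private false positives vanish at the double-call stage
        when no two callers hit the same locus."""
        tree, leaves = sp.simulate_binary_clone_tree(3, 30, 5, genome, seed=21)
        err = sp.ErrorModel(ngs_fp_rate=0.2)
        specs = [sp.SampleSpec(f"S{i}", "primary" if i < 2 else "ascites",
                               c, 0.9, 134.0) for i, c in enumerate(leaves)]
        specs.append(sp.SampleSpec("NB", "normal", tree.root, 0.0, 134.0))
        bins = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [1000], "gc": 0.4})
        cohort = sp.simulate_cohort(tree, specs, err, bins, root_seed=21)
        tumor = [s.sample_id for s in cohort.specs if s.group != "normal"]
        fp_loci = {l for s in tumor for l, o in cohort.flags[s].items() if o != "true"}
        table = sp.build_consensus_table(
            {s: cohort.callsets[s] for s in tumor},
            {s: cohort.pileups[s] for s in tumor},
            cohort.normal_calls, {s.sample_id: s.group for s in cohort.specs})
        assert fp_loci
        assert set(table.presence.index) & fp_loci == set()

    def test_wga_fp_suppression(self, genome):
        """Sample-private WGA artifacts survive double-calling but die at
        the confident-sites filter when no locus recurs across samples."""
        tree, leaves = sp.simulate_binary_clone_tree(3, 30, 5, genome, seed=22)
        err = sp.ErrorModel(wga_fp_rate=0.2)
        specs = [sp.SampleSpec(f"S{i}", "primary" if i < 2 else "ascites",
                               c, 0.9, 134.0) for i, c in enumerate(leaves)]
        specs.append(sp.SampleSpec("NB", "normal", tree.root, 0.0, 134.0))
        bins = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [1000], "gc": 0.4})
        cohort = sp.simulate_cohort(tree, specs, err, bins, root_seed=22)
        tumor = [s.sample_id for s in cohort.specs if s.group != "normal"]
        wga = {l for s in tumor for l, o in cohort.flags[s].items() if o == "wga_fp"}
        per_sample = [{l for l, o in cohort.flags[s].items() if o == "wga_fp"}
                      for s in tumor]
        collisions = set()
        for a, b in itertools.combinations(per_sample, 2):
            collisions |= a & b
        table = sp.build_consensus_table(
            {s: cohort.callsets[s] for s in tumor},
            {s: cohort.pileups[s] for s in tumor},
            cohort.normal_calls, {s.sample_id: s.group for s in cohort.specs})
        assert wga
        surviving = set(table.presence.index) & wga
        assert surviving <= collisions

    def test_requires_three_callers_and_two_samples(self):
        one = {"S": [_callset("c1", "S", [])]}
        with pytest.raises(ValueError):
            sp.build_consensus_table(one, {}, _callset("n", "NB", []), {})


class TestCategories:
    def test_categorize_patterns(self):
        idx = pd.Index([_locus(1), _locus(2), _locus(3)], tupleize_cols=False)
        presence = pd.DataFrame(
            {"P1": [True, True, False], "A1": [True, False, True]}, index=idx)
        cats = categorize(presence, {"P1": "primary", "A1": "ascites"})
        assert cats.tolist() == [CATEGORY_COMMON, CATEGORY_PRIMARY, CATEGORY_ASCITES]

    def test_published_count_arithmetic(self):
        """66 common / 61 primary-only / 44 ascites-only mutations give
        38.6% / 35.7% / 25.7% of a 171-SNV total."""
        counts = {CATEGORY_COMMON: 66, CATEGORY_PRIMARY: 61, CATEGORY_ASCITES: 44}
        pct = sp.category_percentages(counts)
        assert sum(counts.values()) == 171
        assert pct[CATEGORY_COMMON] == 38.6
        assert pct[CATEGORY_PRIMARY] == 35.7
        assert pct[CATEGORY_ASCITES] == 25.7
        assert abs(sum(pct.values()) - 100.0) < 0.2
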