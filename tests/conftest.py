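import dataclasses

import numpy as np
import pytest

import spherophylo as sp


@pytest.fixture(scope="session")
def genome():
    return sp.synthetic_genome()


@pytest.fixture(scope="session")
def nonoise_cohort(genome):
    """Binary 6-leaf clone tree, one pure sample per leaf clone plus a
    matched normal, all observation-error rates zero."""
    tree, leaves = sp.simulate_binary_clone_tree(6, 60, 12, genome, seed=11)
    specs = [sp.SampleSpec(f"S{i + 1}", "primary" if i < 3 else "ascites",
                           c, 1.0, 134.0) for i, c in enumerate(leaves)]
    specs.append(sp.SampleSpec("NB", "normal", tree.root, 0.0, 134.0))
    rng = sp.substream(11, "refpos")
    lengths = genome["length"].to_numpy()
    counts = rng.multinomial(120_000, lengths / lengths.sum())
    ref = {r.chrom: np.sort(rng.integers(0, r.length, size=c))
           for r, c in zip(genome.itertuples(), counts)}
    bins = sp.build_variable_bins(ref, n_bins=300)
    cohort = sp.simulate_cohort(tree, specs, sp.ErrorModel(), bins, root_seed=11)
    for s in cohort.specs:
        ws = dataclasses.replace(s, mean_depth=500.0)
        cohort.counts[s.sample_id] = sp.simulate_binned_counts(ws, tree, bins)
    return cohort, leaves


@pytest.fixture(scope="session")
def nonoise_consensus(nonoise_cohort):
    cohort, leaves = nonoise_cohort
    tumor = [s.sample_id for s in cohort.specs if s.group != "normal"]
    groups = {s.sample_id: s.group for s in cohort.specs}
    table = sp.build_consensus_table(
        {s: cohort.callsets[s] for s in tumor},
        {s: cohort.pileups[s] for s in tumor},
        cohort.normal_calls, groups)
    return table, cohort, leaves
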