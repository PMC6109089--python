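"""Three-caller somatic SNV consensus with Fisher-exact rescue.

The filtering chain, per the study design this package reproduces:

1. *Intra-sample double-calling* — within each sample, keep variants
   reported by at least two of the three callers (suppresses caller-private
   sequencing/calling noise).
2. *Germline removal* — drop variants present in the matched-normal call
   set.
3. *Confident sites* — keep loci double-called in at least two distinct
   samples (suppresses sample-private whole-genome-amplification
   artifacts).
4. *Fisher rescue* — at every confident site, a sample is scored present
   if it was double-called there, or if at least one caller reported the
   variant and the variant's allele count is significantly larger than the
   largest other non-reference base count (one-sided Fisher's exact test,
   p < 1e-3 by default). This recovers allele-dropout samples without
   re-admitting noise.

Finally each locus is categorized by its presence pattern across sample
groups: common (>=1 primary and >=1 ascites sample), primary-only, or
ascites-only.

A locus is identified by (chrom, pos, alt): the same position with a
different alternate allele is a different variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import fisher_exact

from .synthetic_data import BASES, CallSet

Locus = tuple  # (chrom, pos, alt)

CATEGORY_COMMON = "common"
CATEGORY_PRIMARY = "primary_only"
CATEGORY_ASCITES = "ascites_only"


@dataclass
class ConsensusConfig:
    min_callers: int = 2
    min_samples: int = 2
    fisher_alpha: float = 1e-3

    def __post_init__(self):
        if self.min_callers not in (2, 3):
            raise ValueError("min_callers must be 2 or 3")
        if not 0 < self.fisher_alpha < 1:
            raise ValueError("fisher_alpha must be in (0, 1)")


@dataclass
class ConsensusTable:
    """Final per-locus, per-sample somatic variant status."""
    presence: pd.DataFrame       # bool, index = loci, columns = samples
    evidence: pd.DataFrame       # long form: locus, sample, n_callers, fisher_p
    category: pd.Series          # index = loci
    stage_counts: dict           # audit trail: filter stage -> locus count

    @property
    def loci(self) -> list:
        return list(self.presence.index)

    def category_counts(self) -> dict:
        return self.category.value_counts().to_dict()


# ---------------------------------------------------------------------------
# Filter stages
# ---------------------------------------------------------------------------

def intra_sample_double_called(callsets: list, config: ConsensusConfig | None = None) -> set:
    """Loci called by at least ``min_callers`` of a sample's three callers."""
    if config is None:
        config = ConsensusConfig()
    if len(callsets) != 3:
        raise ValueError("expected exactly 3 call sets for the sample")
    ids = [c.caller_id for c in callsets]
    if len(set(ids)) != 3:
        raise ValueError(f"duplicate caller ids: {ids}")
    tally: dict = {}
    for cs in callsets:
        for locus in cs.loci():
            tally[locus] = tally.get(locus, 0) + 1
    return {locus for locus, n in tally.items() if n >= config.min_callers}


def remove_germline(loci: set, normal_callset: CallSet) -> set:
    """Drop loci present in the matched-normal call set."""
    if normal_callset is None:
        raise ValueError("a matched-normal call set is required")
    return set(loci) - normal_callset.loci()


def confident_sites(double_called_by_sample: dict, config: ConsensusConfig | None = None) -> set:
    """Loci double-called in at least ``min_samples`` distinct samples."""
    if config is None:
        config = ConsensusConfig()
    if len(double_called_by_sample) < 2:
        raise ValueError("need at least 2 samples")
    tally: dict = {}
    for loci in double_called_by_sample.values():
        for locus in loci:
            tally[locus] = tally.get(locus, 0) + 1
    return {locus for locus, n in tally.items() if n >= config.min_samples}


def fisher_rescue(locus: Locus, ref: str, pileup_row, any_caller_called: bool,
                  config: ConsensusConfig | None = None):
    """Rescue decision for one sample at one confident site.

    The 2x2 table compares the variant allele count against the largest of
    the two other non-reference base counts at the same depth:
    ``[[alt, depth-alt], [other_max, depth-other_max]]``, tested one-sided
    (variant fraction greater) with the exact hypergeometric distribution.
    Present iff at least one caller reported the variant *and* p < alpha.

    Returns ``(present, p_value)``.
    """
    if config is None:
        config = ConsensusConfig()
    chrom, pos, alt = locus
    if alt == ref:
        raise ValueError(f"alt allele equals ref at {chrom}:{pos}")
    counts = {b: int(pileup_row[b]) for b in BASES}
    depth = sum(counts.values())
    if depth <= 0:
        raise ValueError(f"pileup depth is zero at {chrom}:{pos}")
    alt_count = counts[alt]
    other_max = max(counts[b] for b in BASES if b not in (ref, alt))
    table = [[alt_count, depth - alt_count], [other_max, depth - other_max]]
    p = float(fisher_exact(table, alternative="greater").pvalue)
    return (bool(any_caller_called) and p < config.fisher_alpha), p


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def _pileup_lookup(pileups: pd.DataFrame) -> dict:
    return {(r.chrom, r.pos): r for r in pileups.itertuples()}


def categorize(presence: pd.DataFrame, groups: dict) -> pd.Series:
    """Assign common / primary_only / ascites_only per locus from the
    per-sample presence matrix and the sample group labels."""
    primary = [s for s in presence.columns if groups.get(s) == "primary"]
    ascites = [s for s in presence.columns if groups.get(s) == "ascites"]
    cats = []
    for locus in presence.index:
        in_primary = bool(presence.loc[[locus], primary].to_numpy().any())
        in_ascites = bool(presence.loc[[locus], ascites].to_numpy().any())
        if in_primary and in_ascites:
            cats.append(CATEGORY_COMMON)
        elif in_primary:
            cats.append(CATEGORY_PRIMARY)
        else:
            cats.append(CATEGORY_ASCITES)
    return pd.Series(cats, index=presence.index, name="category")


def build_consensus_table(callsets_by_sample: dict, pileups_by_sample: dict,
                          normal_callset: CallSet, groups: dict,
                          config: ConsensusConfig | None = None) -> ConsensusTable:
    """Run the full consensus chain over all tumor samples.

    ``callsets_by_sample`` maps sample id -> list of exactly three
    CallSets; ``pileups_by_sample`` maps sample id -> pileup DataFrame
    (chrom, pos, ref, A, C, G, T); ``groups`` maps sample id -> "primary"
    or "ascites". Returns the final ConsensusTable with per-stage locus
    counts for auditing.
    """
    if config is None:
        config = ConsensusConfig()
    samples = list(callsets_by_sample)
    if len(samples) < 2:
        raise ValueError("need at least 2 tumor samples")
    for s in samples:
        if len(callsets_by_sample[s]) != 3:
            raise ValueError(f"sample {s} must have exactly 3 call sets")

    double_called = {s: intra_sample_double_called(callsets_by_sample[s], config)
                     for s in samples}
    n_double = len(set().union(*double_called.values()))
    somatic = {s: remove_germline(double_called[s], normal_callset) for s in samples}
    n_somatic = len(set().union(*somatic.values()))
    confident = confident_sites(somatic, config)

    # alt-allele lookup per locus for rescue; ref taken from the pileup
    caller_loci = {s: [cs.loci() for cs in callsets_by_sample[s]] for s in samples}
    any_called = {s: set().union(*caller_loci[s]) for s in samples}
    lookups = {s: _pileup_lookup(pileups_by_sample[s]) for s in samples}

    loci = sorted(confident)
    presence = pd.DataFrame(False, index=pd.Index(loci, tupleize_cols=False),
                            columns=samples)
    evid_rows = []
    for locus in loci:
        chrom, pos, alt = locus
        for s in samples:
            n_callers = sum(locus in loci_set for loci_set in caller_loci[s])
            row = lookups[s].get((chrom, pos))
            if locus in somatic[s]:
                present, p = True, None
                if row is not None:
                    _, p = fisher_rescue(locus, row.ref, row._asdict(), True, config)
            elif row is None:
                warnings.warn(f"no pileup for {s} at {chrom}:{pos}; status set absent",
                              stacklevel=2)
                present, p = False, None
            else:
                present, p = fisher_rescue(locus, row.ref, row._asdict(),
                                           locus in any_called[s], config)
            presence.loc[[locus], s] = present
            evid_rows.append((chrom, pos, alt, s, n_callers, p, present))

    evidence = pd.DataFrame(evid_rows, columns=["chrom", "pos", "alt", "sample",
                                                "n_callers", "fisher_p", "present"])
    category = categorize(presence, groups)
    stage_counts = {
        "double_called": n_double,
        "after_germline_removal": n_somatic,
        "confident_sites": len(confident),
        "final_loci": len(loci),
    }
    return ConsensusTable(presence=presence, evidence=evidence,
                          category=category, stage_counts=stage_counts)


def category_percentages(counts: dict) -> dict:
    """Percentages of each mutation category, to one decimal place."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}
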