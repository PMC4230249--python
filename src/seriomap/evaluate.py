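"""Recovery metrics comparing an inferred map against simulator truth.

Used by the simulation analyses and tests: how well LOD grouping recovers
chromosomes, how concordant within-group marker orders are with true
positions, and how closely summed map length matches the truth expressed on
the estimator's (Kosambi) scale.
"""

from __future__ import annotations

from typing import Sequence

from scipy.stats import kendalltau

from .linkage import OrderedGroup
from .simulate import SimTruth


def grouping_accuracy(groups: Sequence[OrderedGroup], truth: SimTruth) -> float:
    """Fraction of markers placed in the group matched to their true
    chromosome.

    Groups are matched one-to-one to chromosomes greedily by descending
    marker overlap (the standard clustering-accuracy matching), so a
    spuriously merged group can represent only one of its chromosomes and
    the other's markers count as misassigned.
    """
    overlaps = []
    for g in groups:
        by_chrom: dict[str, int] = {}
        for m in g.ordered_markers:
            c = truth.chromosome_of[m]
            by_chrom[c] = by_chrom.get(c, 0) + 1
        for c, n in by_chrom.items():
            overlaps.append((n, g.group_id, c))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g: set[str] = set()
    used_c: set[str] = set()
    correct = 0
    for n, gid, c in overlaps:
        if gid in used_g or c in used_c:
            continue
        used_g.add(gid)
        used_c.add(c)
        correct += n
    total = sum(len(g.ordered_markers) for g in groups)
    return correct / total


def order_concordance(group: OrderedGroup, truth: SimTruth) -> float:
    """|Kendall tau| between the recovered order and true positions, over the
    group's markers on its majority chromosome (merged-in strays excluded)."""
    chroms = [truth.chromosome_of[m] for m in group.ordered_markers]
    majority = max(set(chroms), key=chroms.count)
    ranks, true_pos = [], []
    for i, m in enumerate(group.ordered_markers):
        if truth.chromosome_of[m] == majority:
            ranks.append(i)
            true_pos.append(truth.true_positions[m][1])
    if len(ranks) < 3:
        return 1.0
    tau = kendalltau(ranks, true_pos).statistic
    return abs(float(tau))


def map_length_recovery(
    groups: Sequence[OrderedGroup], truth: SimTruth
) -> tuple[float, float]:
    """(estimated total map length, true total on the Kosambi scale).

    The simulator is interference-free, so per-chromosome truth is the sum
    of adjacent Haldane intervals converted through the Kosambi function —
    the scale the estimator reports on.
    """
    est = sum(g.length_cM for g in groups)
    chroms = {truth.chromosome_of[m] for m in truth.marker_order}
    true_len = sum(truth.true_length_cM(c, scale="kosambi") for c in chroms)
    return est, true_len
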