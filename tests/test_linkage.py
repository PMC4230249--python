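import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seriomap.genotypes import BackcrossVector, to_backcross
from seriomap.linkage import (
    LinkageGroup,
    TwoPointResult,
    _exhaustive_order,
    _greedy_2opt,
    _order_objective,
    all_two_point,
    build_map,
    count_double_recombinants,
    group_at_lod,
    haldane_cm,
    haldane_theta,
    kosambi_cm,
    kosambi_theta,
    lod_score,
    order_group,
    pairwise_counts,
    strip_double_recombinants,
    two_point,
    vectors_to_matrix,
)
from seriomap.simulate import SimMapConfig, simulate_cross


def vec(marker_id, codes, parent="dam"):
    table = {"A": "A", "H": "H", ".": None}
    return BackcrossVector(marker_id, parent, tuple(table[c] for c in codes))


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

class TestMapFunctions:
    def test_kosambi_zero(self):
        assert kosambi_cm(0.0) == 0.0

    def test_kosambi_closed_form(self):
        # d = 25 ln(1.5) for theta = 0.1
        assert kosambi_cm(0.1) == pytest.approx(25 * math.log(1.5))
        assert kosambi_cm(0.1) == pytest.approx(10.1366, abs=1e-4)

    @pytest.mark.parametrize("theta", np.arange(0.01, 0.46, 0.04).tolist())
    def test_kosambi_inverse_identity(self, theta):
        assert kosambi_theta(kosambi_cm(theta)) == pytest.approx(theta)

    def test_kosambi_domain(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)

    @pytest.mark.parametrize("theta", [0.05, 0.2, 0.4])
    def test_haldane_inverse_identity(self, theta):
        assert haldane_theta(haldane_cm(theta)) == pytest.approx(theta)

    def test_kosambi_shorter_than_haldane(self):
        # interference allowance compresses distances at equal theta
        for theta in (0.1, 0.2, 0.3):
            assert kosambi_cm(theta) < haldane_cm(theta)


# ---------------------------------------------------------------------------
# two-point statistics
# ---------------------------------------------------------------------------

class TestTwoPoint:
    def test_zero_recombinant_limit(self):
        a = vec("a", "AH" * 45)
        res = two_point(a, vec("b", "AH" * 45))
        assert res.theta_hat == 0.0
        assert res.n_informative == 90
        assert res.lod == pytest.approx(90 * math.log10(2))
        assert res.lod == pytest.approx(27.0927, abs=1e-4)

    def test_independence(self):
        a = vec("a", "A" * 90)
        b = vec("b", "A" * 45 + "H" * 45)
        res = two_point(a, b)
        assert res.theta_hat == 0.5
        assert res.lod == 0.0

    def test_r9_n90_closed_form(self):
        # LOD = 9 log10(.1) + 81 log10(.9) + 90 log10 2 = 14.38634...
        a = vec("a", "A" * 90)
        b = vec("b", "H" * 9 + "A" * 81)
        res = two_point(a, b)
        assert res.theta_hat == pytest.approx(0.1)
        assert res.lod == pytest.approx(14.3863, abs=1e-4)

    def test_phase_folding(self):
        # 81 mismatches out of 90 folds to r = 9
        a = vec("a", "A" * 90)
        b = vec("b", "A" * 9 + "H" * 81)
        res = two_point(a, b)
        assert res.n_recombinant == 9
        assert res.theta_hat == pytest.approx(0.1)

    def test_symmetry(self):
        a = vec("a", "AAHH" * 10 + "AH")
        b = vec("b", "AHAH" * 10 + "HA")
        r1, r2 = two_point(a, b), two_point(b, a)
        assert (r1.n_informative, r1.n_recombinant, r1.lod) == (
            r2.n_informative, r2.n_recombinant, r2.lod)

    def test_missing_excluded(self):
        a = vec("a", "AAH.")
        b = vec("b", "AH.H")
        res = two_point(a, b)
        assert res.n_informative == 2
        assert res.n_recombinant == 1

    def test_no_joint_information_raises(self):
        with pytest.raises(ValueError):
            two_point(vec("a", "A."), vec("b", ".H"))

    def test_lod_maximized_at_theta_hat(self):
        # grid-scan oracle: the reported LOD dominates the likelihood-ratio
        # statistic at every other theta on a fine grid
        def lod_at(theta, r, n):
            return (r * math.log10(theta) + (n - r) * math.log10(1 - theta)
                    + n * math.log10(2))

        for r, n in [(3, 40), (9, 90), (20, 88), (44, 90)]:
            best = lod_score(r, n)
            for theta in np.linspace(1e-4, 0.4999, 400):
                assert lod_at(theta, r, n) <= best + 1e-9

    def test_matrix_engine_matches_scalar(self, study_scale_cross):
        _, _, _, vectors = study_scale_cross
        sub = vectors[:25]
        mat = vectors_to_matrix(sub)
        n, r = pairwise_counts(mat)
        for i, j in [(0, 1), (3, 17), (5, 24), (10, 11)]:
            res = two_point(sub[i], sub[j])
            assert res.n_informative == n[i, j]
            assert res.n_recombinant == r[i, j]


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def tp(a, b, lod):
    return TwoPointResult(a, b, 90, 0, 0.0, lod)


class TestGrouping:
    def test_all_unlinked_gives_singletons(self):
        res = [tp("A", "B", 0.0), tp("B", "C", 0.0), tp("A", "C", 0.0)]
        groups = group_at_lod(res, 4.0)
        assert sorted(len(g.marker_ids) for g in groups) == [1, 1, 1]

    def test_transitive_closure(self):
        res = [tp("A", "B", 5.0), tp("B", "C", 5.0), tp("A", "C", 1.0)]
        (g,) = group_at_lod(res, 4.0)
        assert g.marker_ids == {"A", "B", "C"}

    def test_partition_and_monotone_refinement(self, study_scale_cross):
        _, _, _, vectors = study_scale_cross
        sub = vectors[:120]
        results = all_two_point(sub)
        low = group_at_lod(results, 3.0, markers=[v.marker_id for v in sub])
        high = group_at_lod(results, 6.0, markers=[v.marker_id for v in sub])
        for groups in (low, high):
            all_markers = [m for g in groups for m in g.marker_ids]
            assert len(all_markers) == len(sub)
            assert len(set(all_markers)) == len(sub)
        # raising the threshold only refines: every high group sits inside
        # exactly one low group
        lookup = {m: g.group_id for g in low for m in g.marker_ids}
        for g in high:
            assert len({lookup[m] for m in g.marker_ids}) == 1


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

class TestOrdering:
    def test_two_marker_group(self):
        a = vec("a", "AH" * 20)
        b = vec("b", "AH" * 19 + "HA")  # r = 2/40
        og = order_group(LinkageGroup("g", frozenset(["a", "b"])), {"a": a, "b": b})
        assert og.ordered_markers == ["a", "b"]
        assert og.positions_cM[0] == 0.0
        assert og.positions_cM[1] == pytest.approx(kosambi_cm(2 / 40))

    def test_heuristic_matches_exhaustive_on_six_markers(self):
        cfg = SimMapConfig(
            n_chromosomes=1, markers_per_chromosome=6, n_progeny=40,
            chromosome_lengths_cM=[50.0], error_rate=0.02, seed=13,
        )
        _, markers, _ = simulate_cross(cfg)
        vectors = [to_backcross(m, "dam") for m in markers]
        mat = vectors_to_matrix(vectors)
        _, r = pairwise_counts(mat)
        assert _order_objective(_greedy_2opt(r), r) == _order_objective(
            _exhaustive_order(r), r)

    def test_recovered_order_concordant_with_truth(self):
        cfg = SimMapConfig(
            n_chromosomes=1, markers_per_chromosome=20, n_progeny=90,
            chromosome_lengths_cM=[50.0], seed=5,
        )
        _, markers, truth = simulate_cross(cfg)
        vectors = {m.marker_id: to_backcross(m, "dam") for m in markers}
        og = order_group(
            LinkageGroup("g", frozenset(vectors)), vectors)
        true_pos = [truth.true_positions[m][1] for m in og.ordered_markers]
        from scipy.stats import kendalltau
        assert abs(kendalltau(range(20), true_pos).statistic) >= 0.9

    def test_orientation_deterministic(self):
        a, b, c = vec("a", "AH" * 20), vec("b", "AH" * 19 + "AA"), vec("c", "AH" * 18 + "AAHH")
        og = order_group(
            LinkageGroup("g", frozenset(["a", "b", "c"])), {"a": a, "b": b, "c": c})
        assert og.ordered_markers[0] < og.ordered_markers[-1]

    def test_positions_start_at_zero_and_non_decreasing(self, study_scale_cross):
        _, _, _, vectors = study_scale_cross
        groups = build_map(vectors[:60], lod_threshold=4.0)
        for g in groups:
            assert g.positions_cM[0] == 0.0
            assert all(x <= y for x, y in itertools.pairwise(g.positions_cM))
            assert len(g.positions_cM) == len(g.ordered_markers) == len(g.framework_flags)

    def test_cosegregating_markers_share_position_and_one_framework_flag(self):
        a = vec("a", "AH" * 20)
        b = vec("b", "AH" * 20)  # identical: theta 0
        c = vec("c", "AH" * 18 + "HAHA")
        og = order_group(
            LinkageGroup("g", frozenset(["a", "b", "c"])), {"a": a, "b": b, "c": c})
        pos = dict(zip(og.ordered_markers, og.positions_cM))
        assert pos["a"] == pos["b"]
        flags = dict(zip(og.ordered_markers, og.framework_flags))
        assert flags["a"] != flags["b"]  # one representative per position
        assert og.n_framework == 2


# ---------------------------------------------------------------------------
# double recombinants
# ---------------------------------------------------------------------------

class TestDoubleRecombinants:
    def _trio(self):
        # progeny 2 carries a single middle flip
        va = vec("a", "AAHH")
        vb = vec("b", "AHHH")
        vc = vec("c", "AAHH")
        og_vectors = {"a": va, "b": vb, "c": vc}
        return og_vectors

    def test_manual_count(self):
        vectors = self._trio()
        og = order_group(LinkageGroup("g", frozenset("abc")), vectors)
        # count on the fixed true order regardless of inferred one
        og.ordered_markers = ["a", "b", "c"]
        assert count_double_recombinants(og, vectors) == 1

    def test_reversal_invariance(self):
        vectors = self._trio()
        og = order_group(LinkageGroup("g", frozenset("abc")), vectors)
        og.ordered_markers = ["a", "b", "c"]
        fwd = count_double_recombinants(og, vectors)
        og.ordered_markers = ["c", "b", "a"]
        assert count_double_recombinants(og, vectors) == fwd

    def test_fewer_than_three_markers_is_zero(self):
        vectors = self._trio()
        og = order_group(LinkageGroup("g", frozenset("ab")), vectors)
        assert count_double_recombinants(og, vectors) == 0

    def test_near_zero_on_clean_dense_simulation(self):
        cfg = SimMapConfig(
            n_chromosomes=1, markers_per_chromosome=12, n_progeny=90,
            chromosome_lengths_cM=[40.0], seed=2,
        )
        _, markers, _ = simulate_cross(cfg)
        vectors = {m.marker_id: to_backcross(m, "dam") for m in markers}
        og = order_group(LinkageGroup("g", frozenset(vectors)), vectors)
        # no genotyping error and <5 cM spacing: genuine double crossovers rare
        assert og.double_recombinant_count <= 3

    def test_strip_blanks_the_flip(self):
        vectors = self._trio()
        corrected = strip_double_recombinants(["a", "b", "c"], vectors)
        assert corrected["b"].transmissions == ("A", None, "H", "H")
        assert corrected["a"].transmissions == vectors["a"].transmissions
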