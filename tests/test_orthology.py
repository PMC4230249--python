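import itertools

import numpy as np
import pytest

from seriomap.orthology import (
    BlastHit,
    E_VALUE_FLOOR,
    OxfordGrid,
    assign_all,
    assign_orthology,
    build_oxford_grid,
    cell_class,
    dedupe_top_hits,
    grid_relationships,
    read_blast_tabular,
    write_blast_tabular,
)
from seriomap.simulate import generate_blast_hits
import pandas as pd


def hit(q="q1", subj="chrI", e=1e-20, bits=200.0, qs=1, qe=100, chrom=""):
    return BlastHit(q, subj, 95.0, e, bits, qs, qe, subject_chromosome=chrom)


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

class TestTabularIO:
    def test_single_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\tchrI\t95.00\t100\t3\t1\t5\t104\t900\t999\t1e-30\t180.5\n")
        (h,) = read_blast_tabular(p)
        assert h.query_id == "q1"
        assert (h.query_start, h.query_end) == (5, 104)
        assert h.e_value == 1e-30
        assert not h.reversed_coords

    def test_reversed_coordinates_normalized(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\tchrI\t95.00\t100\t3\t1\t104\t5\t900\t999\t1e-30\t180.5\n")
        (h,) = read_blast_tabular(p)
        assert (h.query_start, h.query_end) == (5, 104)
        assert h.reversed_coords

    def test_malformed_lines_skipped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "q1\tchrI\t95.00\t100\t3\t1\t5\t104\t900\t999\t1e-30\t180.5\n"
            "truncated\tline\n"
            "q2\tchrI\tNOTANUMBER\t100\t3\t1\t5\t104\t900\t999\t1e-30\t180.5\n"
        )
        hits = read_blast_tabular(p)
        assert len(hits) == 1

    def test_synthetic_file_round_trips(self, tmp_path):
        hits, _, _ = generate_blast_hits(
            {f"Squ{i}": f"chr{i}" for i in range(1, 25)},
            markers_per_lg=21, reject_fraction=0.2, seed=12,
        )
        assert len(hits) >= 500
        p = tmp_path / "hits.tsv"
        write_blast_tabular(p, hits)
        back = read_blast_tabular(p)
        assert len(back) == len(hits)
        for a, b in zip(hits, back):
            assert a.query_id == b.query_id
            assert a.subject_id == b.subject_id
            assert (a.query_start, a.query_end) == (b.query_start, b.query_end)
            assert b.e_value == pytest.approx(a.e_value, rel=0.01)


# ---------------------------------------------------------------------------
# dedup
# ---------------------------------------------------------------------------

class TestDedup:
    def test_single_hit_kept(self):
        h = hit()
        assert dedupe_top_hits([h]) == [h]

    def test_overlapping_keeps_most_significant(self):
        strong = hit(e=1e-20, qs=1, qe=100)
        weak = hit(e=1e-15, qs=50, qe=150, subj="chrII")
        assert dedupe_top_hits([weak, strong]) == [strong]

    def test_disjoint_intervals_all_kept(self):
        a = hit(e=1e-20, qs=1, qe=100)
        b = hit(e=1e-15, qs=200, qe=300, subj="chrII")
        assert set(dedupe_top_hits([a, b])) == {a, b}

    def test_tie_broken_by_bit_score(self):
        lo = hit(e=1e-20, bits=150.0)
        hi = hit(e=1e-20, bits=250.0, subj="chrII")
        assert dedupe_top_hits([lo, hi]) == [hi]

    def test_never_increases_count(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            hits = [
                hit(e=10.0 ** -rng.integers(5, 40),
                    qs=int(rng.integers(1, 400)),
                    qe=int(rng.integers(1, 400)) + 420,
                    subj=f"chr{rng.integers(1, 5)}")
                for _ in range(rng.integers(1, 8))
            ]
            kept = dedupe_top_hits(hits)
            assert 1 <= len(kept) <= len(hits)


# ---------------------------------------------------------------------------
# orthology rule
# ---------------------------------------------------------------------------

def brute_force_rule(hits, ratio_threshold=1e-3):
    """Independent literal evaluation of the acceptance rule."""
    if not hits:
        return (False, "no_hit")
    ranked = sorted(hits, key=lambda h: (max(h.e_value, E_VALUE_FLOOR), -h.bit_score,
                                         h.subject_id))
    top = ranked[0]
    for k in (1, 2):
        if k >= len(ranked):
            break
        other = ranked[k]
        overlap = min(top.query_end, other.query_end) >= max(
            top.query_start, other.query_start)
        ratio = max(top.e_value, E_VALUE_FLOOR) / max(other.e_value, E_VALUE_FLOOR)
        if overlap and ratio > ratio_threshold:
            return (False, "unclear_ratio")
    return (True, "none")


class TestAssignOrthology:
    def test_clear_top_hit_accepted(self):
        a = assign_orthology(
            [hit(e=1e-30), hit(e=1e-10, subj="chrII", qs=10, qe=90)])
        assert a.accepted
        assert a.subject_chromosome == "chrI"

    def test_close_overlapping_second_hit_rejects(self):
        a = assign_orthology(
            [hit(e=1e-12), hit(e=1e-10, subj="chrII", qs=10, qe=90)])
        assert not a.accepted
        assert a.reject_reason == "unclear_ratio"

    def test_non_overlapping_second_hit_ignored(self):
        a = assign_orthology(
            [hit(e=1e-12, qs=1, qe=100), hit(e=1e-10, subj="chrII", qs=300, qe=400)])
        assert a.accepted

    def test_third_hit_can_reject(self):
        a = assign_orthology([
            hit(e=1e-30),
            hit(e=1e-25, subj="chrII", qs=300, qe=400),  # rank 2, disjoint
            hit(e=1e-28, subj="chrIII", qs=10, qe=90),   # rank... recheck below
        ])
        # ranks by e-value: 1e-30, 1e-28 (overlapping, ratio 1e-2 > 1e-3) -> reject
        assert not a.accepted

    def test_fourth_hit_never_consulted(self):
        # ranks 2 and 3 are disjoint (cannot reject); rank 4 overlaps with a
        # close ratio and would reject if it were examined — it must not be
        a = assign_orthology([
            hit(e=1e-30),
            hit(e=3e-30, subj="chrII", qs=300, qe=400),
            hit(e=5e-30, subj="chrIII", qs=500, qe=600),
            hit(e=8e-30, subj="chrIV", qs=10, qe=90),
        ])
        assert a.accepted

    def test_no_hits(self):
        a = assign_orthology([])
        assert not a.accepted
        assert a.reject_reason == "no_hit"

    def test_zero_e_value_floored(self):
        a = assign_orthology([hit(e=0.0), hit(e=1e-170, subj="chrII", qs=10, qe=90)])
        # floor 1e-180 / 1e-170 = 1e-10 <= 1e-3 -> accepted
        assert a.accepted

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(1000):
            k = int(rng.integers(0, 4))
            hits = []
            for i in range(k):
                qs = int(rng.integers(1, 300))
                hits.append(
                    hit(e=10.0 ** -float(rng.uniform(1, 60)),
                        subj=f"chr{i}", qs=qs, qe=qs + int(rng.integers(10, 200)),
                        bits=float(rng.uniform(50, 300)))
                )
            got = assign_orthology(hits)
            want_accept, want_reason = brute_force_rule(hits)
            assert got.accepted == want_accept
            assert got.reject_reason == want_reason
            agree += 1
        assert agree == 1000


# ---------------------------------------------------------------------------
# Oxford grid
# ---------------------------------------------------------------------------

class TestOxfordGrid:
    def test_zero_accepted_empty_grid(self):
        grid = build_oxford_grid([])
        assert grid.total == 0
        assert grid_relationships(grid) == {
            "one_to_one": [], "lg_one_to_two": [], "chrom_one_to_two": []}

    def test_permutation_grid_is_one_to_one(self):
        # planted 1-to-1 relation between 24 groups and 24 chromosomes
        relation = {f"Squ{i}": f"chr{(i % 24) + 1}" for i in range(1, 25)}
        hits, truth, marker_to_lg = generate_blast_hits(
            relation, markers_per_lg=8, seed=2)
        assignments = assign_all(hits, marker_to_lg)
        assert all(a.accepted for a in assignments)
        grid = build_oxford_grid(assignments)
        assert grid.total == 24 * 8
        rel = grid_relationships(grid)
        assert len(rel["one_to_one"]) == 24
        assert rel["lg_one_to_two"] == []
        # every row has exactly one non-zero cell, equal to 8
        assert (grid.counts.max(axis=1) == 8).all()
        assert ((grid.counts > 0).sum(axis=1) == 1).all()

    def test_engineered_rejections_excluded_from_grid(self):
        relation = {f"Squ{i}": f"chr{i}" for i in range(1, 13)}
        hits, truth, marker_to_lg = generate_blast_hits(
            relation, markers_per_lg=10, reject_fraction=0.25,
            benign_decoy_fraction=0.25, seed=6)
        assignments = assign_all(hits, marker_to_lg)
        by_query = {a.query_id: a for a in assignments}
        for t in truth:
            assert by_query[t.query_id].accepted == t.intended_accept
        grid = build_oxford_grid(assignments)
        assert grid.total == sum(t.intended_accept for t in truth)

    def test_fusion_detected_as_one_to_two(self):
        relation: dict = {f"Squ{i}": f"chr{i}" for i in range(1, 9)}
        relation["Squ9"] = ("chr9", "chr10")  # synthetic fusion group
        hits, _, marker_to_lg = generate_blast_hits(
            relation, markers_per_lg=14, seed=10)
        grid = build_oxford_grid(assign_all(hits, marker_to_lg))
        rel = grid_relationships(grid)
        assert rel["lg_one_to_two"] == ["Squ9"]
        assert len(rel["one_to_one"]) == 8

    @pytest.mark.parametrize(
        "count, expected",
        [(11, "red"), (10, "yellow"), (8, "yellow"), (7, "blue"), (6, "blue"),
         (5, "none"), (0, "none")],
    )
    def test_highlight_thresholds_strict(self, count, expected):
        assert cell_class(count) == expected

    def test_count_conservation_and_highlight_consistency(self):
        relation = {f"Squ{i}": f"chr{i}" for i in range(1, 25)}
        hits, truth, marker_to_lg = generate_blast_hits(
            relation, markers_per_lg=12, reject_fraction=0.3, seed=9)
        assignments = assign_all(hits, marker_to_lg)
        grid = build_oxford_grid(assignments)
        assert grid.total == sum(a.accepted for a in assignments)
        classes = grid.highlight()
        for lg in grid.counts.index:
            for ch in grid.counts.columns:
                assert classes.loc[lg, ch] == cell_class(grid.counts.loc[lg, ch])

    def test_natural_row_ordering(self):
        from seriomap.orthology import OrthologAssignment
        assignments = [
            OrthologAssignment("m1", "Squ2", "chrI", True),
            OrthologAssignment("m2", "Squ10", "chrI", True),
            OrthologAssignment("m3", "Squ1", "chrI", True),
        ]
        grid = build_oxford_grid(assignments)
        assert list(grid.counts.index) == ["Squ1", "Squ2", "Squ10"]
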