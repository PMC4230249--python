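"""Two-point linkage analysis and map assembly for one parent's meioses.

Markers in backcross coding are compared pairwise: the recombination
fraction is estimated from mismatching transmission codes, folded to
``min(r, n-r)/n`` because linkage phase is unknown in an outbred family,
and scored with the standard backcross two-point LOD

    LOD = r log10(theta) + (n - r) log10(1 - theta) + n log10(2).

Markers are sorted into linkage groups as connected components of the
"LOD >= threshold" graph (single-linkage closure, threshold 4.0 by
default), ordered within groups by minimizing the total count of
recombination events over adjacent intervals (exhaustive for small groups,
greedy seeding plus 2-opt otherwise), and placed on a Kosambi scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .genotypes import BackcrossVector

logger = logging.getLogger(__name__)

LOG10_2 = math.log10(2.0)

#: recombination fractions at/above this are capped before Kosambi conversion
THETA_MAX = 0.49


@dataclass(frozen=True)
class TwoPointResult:
    marker_a: str
    marker_b: str
    n_informative: int
    n_recombinant: int  # folded: min(r, n - r)
    theta_hat: float
    lod: float


@dataclass(frozen=True)
class LinkageGroup:
    group_id: str
    marker_ids: frozenset[str]


@dataclass
class OrderedGroup:
    group_id: str
    ordered_markers: list[str]
    positions_cM: list[float]
    framework_flags: list[bool]
    double_recombinant_count: int = 0

    @property
    def length_cM(self) -> float:
        return self.positions_cM[-1] if self.positions_cM else 0.0

    @property
    def n_framework(self) -> int:
        return sum(self.framework_flags)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_cm(theta: float) -> float:
    """Kosambi map distance d = 25 ln[(1+2t)/(1-2t)] in cM, for 0 <= t < 0.5."""
    if not 0.0 <= theta < 0.5:
        raise ValueError(f"theta {theta} outside [0, 0.5)")
    return 25.0 * math.log((1 + 2 * theta) / (1 - 2 * theta))


def kosambi_theta(d_cm: float) -> float:
    """Inverse Kosambi: recombination fraction at map distance d cM."""
    if d_cm < 0:
        raise ValueError("negative map distance")
    return 0.5 * math.tanh(d_cm / 50.0)


def haldane_theta(d_cm: float) -> float:
    """Haldane (no-interference) recombination fraction at d cM."""
    if d_cm < 0:
        raise ValueError("negative map distance")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def haldane_cm(theta: float) -> float:
    if not 0.0 <= theta < 0.5:
        raise ValueError(f"theta {theta} outside [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * theta)


def lod_score(r: int, n: int) -> float:
    """Backcross two-point LOD at the folded MLE theta = min(r, n-r)/n."""
    if n <= 0:
        raise ValueError("no informative meioses")
    r = min(r, n - r)
    if r == 0:
        return n * LOG10_2
    theta = r / n
    if theta >= 0.5:
        return 0.0
    return r * math.log10(theta) + (n - r) * math.log10(1 - theta) + n * LOG10_2


# ---------------------------------------------------------------------------
# two-point engine
# ---------------------------------------------------------------------------

def two_point(a: BackcrossVector, b: BackcrossVector) -> TwoPointResult:
    """Two-point linkage statistics for one marker pair (phase-folded)."""
    if a.parent != b.parent:
        raise ValueError("vectors are from different parents")
    if a.n_progeny != b.n_progeny:
        raise ValueError("vectors are from different families")
    n = 0
    mism = 0
    for x, y in zip(a.transmissions, b.transmissions):
        if x is None or y is None:
            continue
        n += 1
        mism += x != y
    if n == 0:
        raise ValueError(f"no jointly informative progeny for {a.marker_id}/{b.marker_id}")
    r = min(mism, n - mism)
    return TwoPointResult(a.marker_id, b.marker_id, n, r, r / n, lod_score(r, n))


def vectors_to_matrix(vectors: Sequence[BackcrossVector]) -> np.ndarray:
    """Stack vectors into an int8 matrix (markers x progeny): 0=A, 1=H, -1=missing."""
    code = {"A": 0, "H": 1, None: -1}
    return np.array(
        [[code[t] for t in v.transmissions] for v in vectors], dtype=np.int8
    )


def pairwise_counts(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (n_informative, folded recombinant count) via matrix products."""
    present = (matrix >= 0).astype(np.int32)
    is_h = (matrix == 1).astype(np.int32)
    is_a = present - is_h
    n = present @ present.T
    mism = is_h @ is_a.T + is_a @ is_h.T
    r = np.minimum(mism, n - mism)
    return n, r


def pairwise_lod(n: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized LOD over count matrices (0 where n == 0 or theta = 0.5)."""
    n_f = n.astype(float)
    r_f = r.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(n_f > 0, r_f / n_f, 0.5)
        lod = np.where(
            theta <= 0,
            n_f * LOG10_2,
            r_f * np.log10(np.where(theta > 0, theta, 1.0))
            + (n_f - r_f) * np.log10(1.0 - np.where(theta < 0.5, theta, 0.0))
            + n_f * LOG10_2,
        )
    lod = np.where((theta >= 0.5) | (n_f == 0), 0.0, lod)
    np.fill_diagonal(lod, 0.0)
    return lod


def all_two_point(vectors: Sequence[BackcrossVector]) -> list[TwoPointResult]:
    """TwoPointResult for every unordered marker pair (vectorized internally)."""
    mat = vectors_to_matrix(vectors)
    n, r = pairwise_counts(mat)
    lod = pairwise_lod(n, r)
    ids = [v.marker_id for v in vectors]
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if n[i, j] == 0:
                continue
            out.append(
                TwoPointResult(
                    ids[i], ids[j], int(n[i, j]), int(r[i, j]),
                    r[i, j] / n[i, j], float(lod[i, j]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_at_lod(
    results: Iterable[TwoPointResult],
    threshold: float = 4.0,
    markers: Optional[Iterable[str]] = None,
) -> list[LinkageGroup]:
    """Partition markers into connected components of the LOD >= threshold graph.

    Pairs absent from ``results`` are treated as below threshold.  Singleton
    groups are kept.  Group ids are assigned by decreasing size then by the
    smallest contained marker id, for determinism.
    """
    g = nx.Graph()
    if markers is not None:
        g.add_nodes_from(markers)
    for res in results:
        g.add_node(res.marker_a)
        g.add_node(res.marker_b)
        if res.lod >= threshold:
            g.add_edge(res.marker_a, res.marker_b)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return [
        LinkageGroup(f"LG{i + 1}", frozenset(c)) for i, c in enumerate(comps)
    ]


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def _order_objective(order: Sequence[int], r: np.ndarray) -> tuple[int, int]:
    """(adjacent recombination count, gap-2 recombination count).

    The primary objective is the total count of recombination events over
    adjacent intervals.  Orders of co-segregating or very tight markers are
    frequently tied on it; the secondary count over next-adjacent pairs
    breaks those ties using flanking information without ever trading away
    the primary optimum (comparison is lexicographic).
    """
    primary = sum(r[order[i], order[i + 1]] for i in range(len(order) - 1))
    secondary = sum(r[order[i], order[i + 2]] for i in range(len(order) - 2))
    return int(primary), int(secondary)


def _local_search(
    order: list[int], r: np.ndarray
) -> tuple[list[int], tuple[int, int]]:
    """Refine an order to a joint local optimum of 2-opt segment reversals
    and or-opt relocation of short segments (length 1-3)."""
    k = len(order)
    best = order
    best_obj = _order_objective(best, r)
    improved = True
    while improved:
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                cand = best[:i] + best[i:j + 1][::-1] + best[j + 1:]
                obj = _order_objective(cand, r)
                if obj < best_obj:
                    best, best_obj = cand, obj
                    improved = True
        for seg in (1, 2, 3):
            for i in range(k - seg + 1):
                piece = best[i:i + seg]
                rest = best[:i] + best[i + seg:]
                for j in range(len(rest) + 1):
                    if j == i:
                        continue
                    for p in (piece, piece[::-1]) if seg > 1 else (piece,):
                        cand = rest[:j] + p + rest[j:]
                        obj = _order_objective(cand, r)
                        if obj < best_obj:
                            best, best_obj = cand, obj
                            improved = True
    return best, best_obj


def _double_bridge_cuts(k: int) -> list[tuple[int, int, int]]:
    """Deterministic double-bridge cut triples: exhaustive for small orders,
    an evenly spread subset for long ones."""
    triples = [
        (a, b, c)
        for a in range(1, k - 2)
        for b in range(a + 1, k - 1)
        for c in range(b + 1, k)
    ]
    if len(triples) <= 60:
        return triples
    step = len(triples) / 24
    return [triples[int(i * step)] for i in range(24)]


def _greedy_2opt(r: np.ndarray) -> list[int]:
    """Nearest-neighbour construction refined by local search (2-opt +
    or-opt) with deterministic double-bridge restarts.

    Every start is refined for small groups; for larger groups only the
    most promising greedy chains are, keeping the ordering cost manageable
    at study scale.
    """
    k = r.shape[0]
    starts: list[list[int]] = []
    seen: set[tuple[int, ...]] = set()
    for start in range(k):
        left = set(range(k)) - {start}
        order = [start]
        while left:
            cur = order[-1]
            nxt = min(left, key=lambda j: (r[cur, j], j))
            order.append(nxt)
            left.remove(nxt)
        key = tuple(order if order[0] < order[-1] else order[::-1])
        if key not in seen:
            seen.add(key)
            starts.append(order)
    if k > 10:
        starts.sort(key=lambda o: _order_objective(o, r))
        starts = starts[:3]
    best: Optional[list[int]] = None
    best_obj: Optional[tuple[int, int]] = None
    for order in starts:
        cand, obj = _local_search(order, r)
        if best_obj is None or obj < best_obj:
            best, best_obj = cand, obj
    assert best is not None and best_obj is not None
    # iterated local search: double-bridge kicks escape 2-opt/or-opt local
    # optima; worthwhile only on small groups where exhaustive-level quality
    # is expected (large groups gain nothing measurable from kicks)
    if k <= 16:
        improved = True
        while improved:
            improved = False
            for a, b, c in _double_bridge_cuts(k):
                kicked = best[:a] + best[b:c] + best[a:b] + best[c:]
                cand, obj = _local_search(kicked, r)
                if obj < best_obj:
                    best, best_obj = cand, obj
                    improved = True
    return best


def _exhaustive_order(r: np.ndarray) -> list[int]:
    k = r.shape[0]
    rl = r.tolist()  # python-int lookups are much faster inside the loop
    best = list(range(k))
    best_p, best_s = _order_objective(best, r)
    for perm in itertools.permutations(range(k)):
        if perm[0] > perm[-1]:  # each order equals its reverse
            continue
        p = 0
        for i in range(k - 1):
            p += rl[perm[i]][perm[i + 1]]
            if p > best_p:
                break
        if p > best_p:
            continue
        s = sum(rl[perm[i]][perm[i + 2]] for i in range(k - 2))
        if p < best_p or (p == best_p and s < best_s):
            best, best_p, best_s = list(perm), p, s
    return best


EXHAUSTIVE_MAX = 8


def order_group(
    group: LinkageGroup,
    vectors: Mapping[str, BackcrossVector],
    theta_max: float = THETA_MAX,
) -> OrderedGroup:
    """Order a linkage group and assign Kosambi positions.

    The order minimizes the total recombination-event count over adjacent
    intervals (the double-recombinant-checking objective): exhaustive search
    up to ``EXHAUSTIVE_MAX`` markers, greedy nearest-neighbour seeding with
    2-opt refinement above.  Orientation is normalized so the
    lexicographically smaller terminal marker comes first.  Adjacent
    distances are Kosambi-transformed two-point theta estimates; markers
    with no informative pairing are placed at the ``theta_max`` cap with a
    warning.  Co-segregating markers (theta = 0) share a position; the first
    marker at each distinct position is flagged as a framework marker.
    """
    ids = sorted(group.marker_ids)
    if not ids:
        raise ValueError("empty linkage group")
    vecs = [vectors[m] for m in ids]
    mat = vectors_to_matrix(vecs)
    n, r = pairwise_counts(mat)

    if len(ids) == 1:
        return OrderedGroup(group.group_id, ids, [0.0], [True], 0)

    # penalize pairs with no joint information so they sit at the periphery
    no_info = (n == 0) & ~np.eye(len(ids), dtype=bool)
    if no_info.any():
        logger.warning(
            "group %s: %d marker pair(s) share no informative progeny",
            group.group_id, int(no_info.sum()) // 2,
        )
    r_obj = np.where(no_info, n.max() + 1, r)

    if len(ids) <= EXHAUSTIVE_MAX:
        order = _exhaustive_order(r_obj)
    else:
        order = _greedy_2opt(r_obj)
    if ids[order[0]] > ids[order[-1]]:
        order = order[::-1]

    ordered = [ids[i] for i in order]
    positions = [0.0]
    for a, b in itertools.pairwise(order):
        if n[a, b] == 0:
            theta = theta_max
        else:
            theta = min(r[a, b] / n[a, b], theta_max)
        positions.append(positions[-1] + kosambi_cm(theta))
    framework = [True] + [positions[i] > positions[i - 1] for i in range(1, len(positions))]
    og = OrderedGroup(group.group_id, ordered, positions, framework, 0)
    og.double_recombinant_count = count_double_recombinants(og, vectors)
    return og


def count_double_recombinants(
    og: OrderedGroup, vectors: Mapping[str, BackcrossVector]
) -> int:
    """Count (progeny, consecutive-informative-marker-triple) events where the
    middle transmission code differs from both flanks — the classic signature
    of a genotyping error at dense spacing."""
    markers = og.ordered_markers
    if len(markers) < 3:
        return 0
    vecs = [vectors[m] for m in markers]
    n_prog = vecs[0].n_progeny
    count = 0
    for p in range(n_prog):
        codes = [v.transmissions[p] for v in vecs if v.transmissions[p] is not None]
        for a, b, c in zip(codes, codes[1:], codes[2:]):
            if b != a and b != c:
                count += 1
    return count


# ---------------------------------------------------------------------------
# pipeline convenience + IO
# ---------------------------------------------------------------------------

def strip_double_recombinants(
    ordered_markers: Sequence[str], vectors: Mapping[str, BackcrossVector]
) -> dict[str, BackcrossVector]:
    """Blank single-locus double-recombinant calls (error correction).

    A transmission code that differs from both flanking informative codes in
    map order implies two crossovers within a short interval — at dense
    spacing almost always a genotyping error, which otherwise inflates every
    adjacent recombination fraction and hence the map length.  Such middle
    calls are set to missing; flanking (terminal) markers cannot be checked
    and are left as observed.  Returns corrected copies of the group's
    vectors; markers outside ``ordered_markers`` are not touched.
    """
    vecs = [vectors[m] for m in ordered_markers]
    if len(vecs) < 3:
        return {m: vectors[m] for m in ordered_markers}
    n_prog = vecs[0].n_progeny
    codes = [list(v.transmissions) for v in vecs]
    for p in range(n_prog):
        informative = [i for i in range(len(vecs)) if codes[i][p] is not None]
        for a, b, c in zip(informative, informative[1:], informative[2:]):
            if codes[b][p] != codes[a][p] and codes[b][p] != codes[c][p]:
                codes[b][p] = None
    return {
        m: BackcrossVector(m, vectors[m].parent, tuple(codes[i]))
        for i, m in enumerate(ordered_markers)
    }


def build_map(
    vectors: Sequence[BackcrossVector],
    lod_threshold: float = 4.0,
    correct_errors: bool = True,
) -> list[OrderedGroup]:
    """Group at a LOD threshold and order every group.

    With ``correct_errors`` (default) each group is ordered, single-locus
    double recombinants are blanked, and the group is re-ordered and
    re-measured on the corrected data — the double-recombination check
    applied as an error filter.
    """
    results = all_two_point(vectors)
    groups = group_at_lod(results, lod_threshold, markers=[v.marker_id for v in vectors])
    by_id = {v.marker_id: v for v in vectors}
    out = []
    for g in groups:
        og = order_group(g, by_id)
        if correct_errors and len(og.ordered_markers) >= 3:
            corrected = strip_double_recombinants(og.ordered_markers, by_id)
            og = order_group(g, corrected)
        out.append(og)
    return out


def write_map(path, groups: Iterable[OrderedGroup]) -> None:
    """TSV: group <TAB> marker <TAB> position_cM <TAB> framework."""
    with open(path, "w") as fh:
        fh.write("group\tmarker\tposition_cM\tframework\n")
        for g in groups:
            for m, pos, fw in zip(g.ordered_markers, g.positions_cM, g.framework_flags):
                fh.write(f"{g.group_id}\t{m}\t{pos:.3f}\t{int(fw)}\n")


def write_two_point(path, results: Iterable[TwoPointResult]) -> None:
    with open(path, "w") as fh:
        fh.write("marker_a\tmarker_b\tn\tr\ttheta\tlod\n")
        for t in results:
            fh.write(
                f"{t.marker_a}\t{t.marker_b}\t{t.n_informative}\t"
                f"{t.n_recombinant}\t{t.theta_hat:.5f}\t{t.lod:.3f}\n"
            )
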