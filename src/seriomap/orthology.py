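"""BLAST-tabular post-processing and Oxford-grid synteny analysis.

Mapped-marker flanking sequences are searched against a model-fish genome
(BLASTn, tabular output).  Per query we (1) collapse overlapping hits to
the most significant one, (2) apply an orthology acceptance rule on the
top three hits — if a lower-ranked hit overlaps the top hit's query
interval and the e-value quotient e1/ek exceeds 1e-3 the pair is deemed
unclear and rejected — and (3) cross-tabulate accepted assignments into an
Oxford grid (linkage groups x subject chromosomes), highlighting cells
with more than 10/7/5 shared markers and classifying one-to-one and
one-to-two chromosome relationships.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: substitute for an e-value printed as 0 before forming ratios
E_VALUE_FLOOR = 1e-180


@dataclass(frozen=True)
class BlastHit:
    """One line of 12-column BLAST tabular output (coordinates normalized
    so query start <= end; ``reversed_coords`` records the original strand
    orientation)."""

    query_id: str
    subject_id: str
    percent_identity: float
    e_value: float
    bit_score: float
    query_start: int
    query_end: int
    subject_chromosome: str = ""
    reversed_coords: bool = False

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("coordinates not normalized")
        if not self.subject_chromosome:
            object.__setattr__(self, "subject_chromosome", self.subject_id)

    @property
    def e_value_safe(self) -> float:
        if self.e_value <= 0:
            logger.warning("zero e-value for %s replaced by %g", self.query_id, E_VALUE_FLOOR)
            return E_VALUE_FLOOR
        return self.e_value


@dataclass(frozen=True)
class OrthologAssignment:
    query_id: str
    linkage_group: str
    subject_chromosome: str
    accepted: bool
    reject_reason: str = "none"  # none | unclear_ratio | no_hit

    def __post_init__(self) -> None:
        if self.accepted != (self.reject_reason == "none"):
            raise ValueError("accepted flag inconsistent with reject_reason")


@dataclass
class OxfordGrid:
    counts: pd.DataFrame  # rows = linkage groups, cols = subject chromosomes

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    def highlight(self) -> pd.DataFrame:
        """Per-cell class: red (>10), yellow (>7), blue (>5), none."""
        return self.counts.map(cell_class)


def cell_class(count: int) -> str:
    if count > 10:
        return "red"
    if count > 7:
        return "yellow"
    if count > 5:
        return "blue"
    return "none"


def _overlaps(a: BlastHit, b: BlastHit) -> bool:
    """>= 1 shared base on query coordinates."""
    return a.query_start <= b.query_end and b.query_start <= a.query_end


def _rank_key(h: BlastHit) -> tuple[float, float, str]:
    return (h.e_value_safe, -h.bit_score, h.subject_id)


# ---------------------------------------------------------------------------
# IO: standard 12-column tabular (qseqid sseqid pident length mismatch
# gapopen qstart qend sstart send evalue bitscore)
# ---------------------------------------------------------------------------

def read_blast_tabular(
    path, subject_to_chromosome: Optional[Callable[[str], str]] = None
) -> list[BlastHit]:
    """Parse tabular hits; malformed lines are counted, logged and skipped.
    Reversed query coordinates are normalized with the orientation flag kept."""
    hits: list[BlastHit] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                n_bad += 1
                continue
            try:
                qstart, qend = int(parts[6]), int(parts[7])
                rev = qstart > qend
                if rev:
                    qstart, qend = qend, qstart
                subj = parts[1]
                hits.append(
                    BlastHit(
                        query_id=parts[0],
                        subject_id=subj,
                        percent_identity=float(parts[2]),
                        e_value=float(parts[10]),
                        bit_score=float(parts[11]),
                        query_start=qstart,
                        query_end=qend,
                        subject_chromosome=(
                            subject_to_chromosome(subj) if subject_to_chromosome else ""
                        ),
                        reversed_coords=rev,
                    )
                )
            except ValueError:
                n_bad += 1
    if n_bad:
        logger.warning("skipped %d malformed BLAST line(s)", n_bad)
    if not hits:
        logger.warning("no hits parsed from %s", path)
    return hits


def write_blast_tabular(path, hits: Iterable[BlastHit]) -> None:
    """Writer for the same dialect (length/mismatch/gapopen/subject coords
    emitted as placeholders derived from the query span)."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = (h.query_end, h.query_start) if h.reversed_coords else (
                h.query_start, h.query_end)
            span = h.query_end - h.query_start + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t{span}\t0\t0\t"
                f"{qs}\t{qe}\t1\t{span}\t{h.e_value:.2e}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# filtering and acceptance
# ---------------------------------------------------------------------------

def dedupe_top_hits(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Within one query, keep only the most significant hit of each cluster
    of mutually overlapping query intervals; non-overlapping hits survive."""
    if not hits:
        return []
    if len({h.query_id for h in hits}) != 1:
        raise ValueError("dedupe_top_hits expects hits from a single query")
    by_start = sorted(hits, key=lambda h: (h.query_start, h.query_end))
    clusters: list[list[BlastHit]] = []
    cur = [by_start[0]]
    cur_end = by_start[0].query_end
    for h in by_start[1:]:
        if h.query_start <= cur_end:  # >= 1 shared base
            cur.append(h)
            cur_end = max(cur_end, h.query_end)
        else:
            clusters.append(cur)
            cur = [h]
            cur_end = h.query_end
    clusters.append(cur)
    kept = [min(c, key=_rank_key) for c in clusters]
    kept.sort(key=_rank_key)
    return kept


def assign_orthology(
    hits: Sequence[BlastHit],
    ratio_threshold: float = 1e-3,
    linkage_group: str = "",
) -> OrthologAssignment:
    """Accept or reject a query's top hit as an orthologous pair.

    Hits are ranked by e-value (ties by bit score).  Only ranks 1-3 are
    examined: if hit 2 or 3 overlaps hit 1 on the query and e1/ek exceeds
    the ratio threshold, the pair is 'unclear' and rejected; otherwise the
    top hit's subject chromosome is accepted.  No hits -> no_hit.
    """
    query_id = hits[0].query_id if hits else ""
    if not hits:
        return OrthologAssignment(query_id, linkage_group, "", False, "no_hit")
    ranked = sorted(hits, key=_rank_key)
    top = ranked[0]
    e1 = top.e_value_safe
    for other in ranked[1:3]:
        if _overlaps(top, other) and e1 / other.e_value_safe > ratio_threshold:
            return OrthologAssignment(
                top.query_id, linkage_group, top.subject_chromosome, False,
                "unclear_ratio",
            )
    return OrthologAssignment(
        top.query_id, linkage_group, top.subject_chromosome, True, "none"
    )


def assign_all(
    hits: Iterable[BlastHit],
    marker_to_lg: Mapping[str, str],
    ratio_threshold: float = 1e-3,
    dedupe: bool = False,
) -> list[OrthologAssignment]:
    """Group hits by query and apply the acceptance rule, attaching each
    query's linkage group.

    ``dedupe`` collapses overlapping hits to the most significant first;
    that belongs to the general homology survey, not the orthology call —
    the ratio rule needs the overlapping lower ranks as rejectors — so it
    is off by default here."""
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = []
    for query in sorted(by_query):
        qhits = by_query[query]
        if dedupe:
            qhits = dedupe_top_hits(qhits)
        out.append(
            assign_orthology(qhits, ratio_threshold, marker_to_lg.get(query, ""))
        )
    return out


# ---------------------------------------------------------------------------
# Oxford grid
# ---------------------------------------------------------------------------

def _natural_key(label: str) -> tuple:
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in re.findall(r"\d+|\D+", label)
    )


def build_oxford_grid(
    assignments: Sequence[OrthologAssignment],
    marker_to_lg: Optional[Mapping[str, str]] = None,
) -> OxfordGrid:
    """Count accepted assignments per (linkage group, subject chromosome).

    Linkage groups come from each assignment or from ``marker_to_lg``;
    markers without a group are skipped with a warning.  Rows and columns
    are naturally sorted (Squ1, Squ2, ..., Squ24')."""
    pairs = []
    n_unmapped = 0
    for a in assignments:
        if not a.accepted:
            continue
        lg = a.linkage_group or (marker_to_lg or {}).get(a.query_id, "")
        if not lg:
            n_unmapped += 1
            continue
        pairs.append((lg, a.subject_chromosome))
    if n_unmapped:
        logger.warning("%d accepted marker(s) missing a linkage group", n_unmapped)
    if not pairs:
        return OxfordGrid(pd.DataFrame(dtype=int))
    df = pd.DataFrame(pairs, columns=["lg", "chrom"])
    counts = df.groupby(["lg", "chrom"]).size().unstack(fill_value=0)
    counts = counts.reindex(
        index=sorted(counts.index, key=_natural_key),
        columns=sorted(counts.columns, key=_natural_key),
    )
    return OxfordGrid(counts.astype(int))


def grid_relationships(grid: OxfordGrid, min_count: int = 6) -> dict[str, list]:
    """Classify chromosome correspondences from grid cells holding at least
    ``min_count`` markers (default 6, i.e. the 'more than five' highlight).

    one_to_one: (lg, chrom) pairs that are each other's only partner.
    lg_one_to_two / chrom_one_to_two: rows (columns) with exactly two
    partner columns (rows) — candidate fusion/fission events."""
    if grid.counts.empty:
        return {"one_to_one": [], "lg_one_to_two": [], "chrom_one_to_two": []}
    strong = grid.counts >= min_count
    lg_partners = {lg: set(strong.columns[strong.loc[lg]]) for lg in strong.index}
    chrom_partners = {
        ch: set(strong.index[strong[ch]]) for ch in strong.columns
    }
    one_to_one = [
        (lg, next(iter(cols)))
        for lg, cols in lg_partners.items()
        if len(cols) == 1 and chrom_partners[next(iter(cols))] == {lg}
    ]
    return {
        "one_to_one": sorted(one_to_one, key=lambda p: _natural_key(p[0])),
        "lg_one_to_two": sorted(
            lg for lg, cols in lg_partners.items() if len(cols) == 2
        ),
        "chrom_one_to_two": sorted(
            ch for ch, rows in chrom_partners.items() if len(rows) == 2
        ),
    }


def write_grid(path, grid: OxfordGrid) -> None:
    grid.counts.to_csv(path, sep="\t", index_label="lg")


def write_grid_classes(path, grid: OxfordGrid) -> None:
    grid.highlight().to_csv(path, sep="\t", index_label="lg")
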