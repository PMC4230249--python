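"""Genome-length and coverage estimators, map summaries, library arithmetic.

Two method-of-moments corrections turn an observed linkage map into a
genome-length estimate:

* **L1** — add twice the average framework-marker interval ``d`` to every
  linkage group (accounts for chromosome ends beyond the terminal markers);
* **L2** — inflate each group's length by ``(m + 1)/(m - 1)`` where ``m`` is
  its framework-marker count.

Expected map coverage is ``c = 1 - exp(-2 d n / L)`` with ``n`` the total
framework-marker count.  Note: although coverage is often quoted "per
marker", only the framework-based d and n reproduce published per-sex map
summaries, so framework counts are used throughout (they are the markers
with unique map positions; co-segregating markers add no interval
information).

Also here: BAC-library bookkeeping (insert totals, fold coverage) and the
flow-cytometry C-value to base-pair conversion (1 pg = 978 Mbp).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

#: Dolezel conversion: base pairs per picogram of diploid-corrected DNA
BP_PER_PG = 0.978e9


@dataclass(frozen=True)
class MapSummaryRow:
    """One linkage group's summary: marker counts and observed length."""

    group_id: str
    n_markers: int
    n_framework: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.n_framework > self.n_markers:
            raise ValueError(f"{self.group_id}: framework count exceeds marker count")
        if self.length_cM < 0:
            raise ValueError(f"{self.group_id}: negative length")


@dataclass(frozen=True)
class GenomeLengthEstimate:
    d_avg_interval_cM: float
    per_group_L1: dict[str, float]
    per_group_L2: dict[str, float]
    total_L1: float
    total_L2: float
    coverage_c_L1: float
    coverage_c_L2: float


@dataclass(frozen=True)
class LibraryStats:
    total_clones: int
    insert_rate: float
    clones_with_insert: int
    mean_insert_bp: float
    total_insert_bp: float
    genome_size_bp: float
    fold_coverage: float

    @property
    def fold_coverage_rounded(self) -> int:
        return round(self.fold_coverage)


def average_framework_interval(rows: Sequence[MapSummaryRow]) -> float:
    """Average interval d = total map length / number of framework intervals.

    A group with m framework markers contributes m - 1 intervals, so the
    denominator is (total framework markers) - (number of groups).
    """
    total_len = sum(r.length_cM for r in rows)
    intervals = sum(max(r.n_framework, 1) - 1 for r in rows)
    if intervals < 1:
        raise ValueError("no framework intervals")
    return total_len / intervals


def genome_length_L1(
    rows: Sequence[MapSummaryRow], d: Optional[float] = None
) -> tuple[dict[str, float], float]:
    """Per-group and total L1: observed length + 2 d per group."""
    if d is None:
        d = average_framework_interval(rows)
    per_group = {r.group_id: r.length_cM + 2 * d for r in rows}
    return per_group, sum(per_group.values())


def genome_length_L2(rows: Sequence[MapSummaryRow]) -> tuple[dict[str, float], float]:
    """Per-group and total L2: length x (m+1)/(m-1); groups with m <= 1
    contribute their observed length unchanged."""
    per_group = {}
    for r in rows:
        if r.n_framework >= 2:
            m = r.n_framework
            per_group[r.group_id] = r.length_cM * (m + 1) / (m - 1)
        else:
            per_group[r.group_id] = r.length_cM
    return per_group, sum(per_group.values())


def coverage_c(d: float, n_framework_total: int, genome_length_cM: float) -> float:
    """Expected map coverage c = 1 - exp(-2 d n / L), in [0, 1]."""
    if d <= 0 or genome_length_cM <= 0 or n_framework_total < 1:
        raise ValueError("d, L must be positive and n >= 1")
    return 1.0 - math.exp(-2.0 * d * n_framework_total / genome_length_cM)


def estimate_genome_length(rows: Sequence[MapSummaryRow]) -> GenomeLengthEstimate:
    """Full L1/L2/coverage bundle for one sex's map."""
    d = average_framework_interval(rows)
    per1, tot1 = genome_length_L1(rows, d)
    per2, tot2 = genome_length_L2(rows)
    n_fw = sum(r.n_framework for r in rows)
    return GenomeLengthEstimate(
        d_avg_interval_cM=d,
        per_group_L1=per1,
        per_group_L2=per2,
        total_L1=tot1,
        total_L2=tot2,
        coverage_c_L1=coverage_c(d, n_fw, tot1),
        coverage_c_L2=coverage_c(d, n_fw, tot2),
    )


def build_map_summary(
    rows_female: Sequence[MapSummaryRow],
    rows_male: Sequence[MapSummaryRow] = (),
) -> dict[str, pd.DataFrame]:
    """Per-sex summary tables: one row per group plus Average/Total rows,
    with L1/L2 columns and a coverage row, all computed at full precision
    and rounded to 2 decimals on output."""
    out: dict[str, pd.DataFrame] = {}
    for sex, rows in (("female", rows_female), ("male", rows_male)):
        if not rows:
            continue
        est = estimate_genome_length(rows)
        df = pd.DataFrame(
            {
                "group": [r.group_id for r in rows],
                "n_markers": [r.n_markers for r in rows],
                "n_framework": [r.n_framework for r in rows],
                "length_cM": [r.length_cM for r in rows],
                "L1_cM": [est.per_group_L1[r.group_id] for r in rows],
                "L2_cM": [est.per_group_L2[r.group_id] for r in rows],
            }
        )
        summary = pd.DataFrame(
            {
                "group": ["Average", "Total"],
                "n_markers": [df.n_markers.mean(), df.n_markers.sum()],
                "n_framework": [df.n_framework.mean(), df.n_framework.sum()],
                "length_cM": [df.length_cM.mean(), df.length_cM.sum()],
                "L1_cM": [df.L1_cM.mean(), est.total_L1],
                "L2_cM": [df.L2_cM.mean(), est.total_L2],
            }
        )
        df = pd.concat([df, summary], ignore_index=True)
        df.attrs["d_avg_interval_cM"] = est.d_avg_interval_cM
        df.attrs["coverage_c_L1_pct"] = 100.0 * est.coverage_c_L1
        df.attrs["coverage_c_L2_pct"] = 100.0 * est.coverage_c_L2
        for col in ("length_cM", "L1_cM", "L2_cM"):
            df[col] = df[col].round(2)
        out[sex] = df
    return out


def summary_rows_from_map(groups) -> list[MapSummaryRow]:
    """MapSummaryRow per OrderedGroup produced by the linkage module."""
    return [
        MapSummaryRow(g.group_id, len(g.ordered_markers), g.n_framework, g.length_cM)
        for g in groups
    ]


def genome_size_from_cvalue(c_value_pg: float) -> float:
    """Haploid genome size in bp from a C-value in pg (978 Mbp/pg)."""
    if c_value_pg <= 0:
        raise ValueError("C-value must be positive")
    return c_value_pg * BP_PER_PG


def library_stats(
    total_clones: int,
    insert_rate: float,
    mean_insert_bp: float,
    genome_size_bp: float,
) -> LibraryStats:
    """BAC-library coverage arithmetic from clone counts and insert sizing."""
    if not 0.0 <= insert_rate <= 1.0:
        raise ValueError("insert rate outside [0, 1]")
    if total_clones <= 0 or mean_insert_bp <= 0 or genome_size_bp <= 0:
        raise ValueError("counts and sizes must be positive")
    with_insert = round(total_clones * insert_rate)
    total_insert = with_insert * mean_insert_bp
    return LibraryStats(
        total_clones=total_clones,
        insert_rate=insert_rate,
        clones_with_insert=with_insert,
        mean_insert_bp=mean_insert_bp,
        total_insert_bp=total_insert,
        genome_size_bp=genome_size_bp,
        fold_coverage=total_insert / genome_size_bp,
    )


def bes_survey_stats(
    total_bp: int, n_reads: int, genome_size_bp: float
) -> tuple[float, float]:
    """(average read length in bp, percent of the genome represented)."""
    if n_reads < 1 or total_bp < 0 or genome_size_bp <= 0:
        raise ValueError("invalid survey inputs")
    return total_bp / n_reads, 100.0 * total_bp / genome_size_bp


# ---------------------------------------------------------------------------
# summary-table TSV round trip
# ---------------------------------------------------------------------------

def write_summary_rows(path, rows: Iterable[MapSummaryRow]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["group", "n_markers", "n_framework", "length_cM"])
        for r in rows:
            w.writerow([r.group_id, r.n_markers, r.n_framework, f"{r.length_cM:.2f}"])


def read_summary_rows(path) -> list[MapSummaryRow]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            MapSummaryRow(
                row["group"], int(row["n_markers"]), int(row["n_framework"]),
                float(row["length_cM"]),
            )
            for row in reader
        ]
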