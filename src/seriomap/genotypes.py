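"""Genotype data model for an outbred F1 (pseudo-testcross) mapping family.

A single full-sib family (dam x sire, default 90 progeny) is genotyped at
codominant SSR markers.  Because grandparental genotypes are unknown, each
parent's heterozygous markers are recoded into a *backcross format*: per
progeny we record which of the two parental alleles was transmitted, giving
a two-symbol vector per marker per parent that downstream two-point linkage
analysis consumes.  Transmission ratios are checked against the Mendelian
1:1 expectation with a 1-d.f. chi-square test.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from scipy import stats

logger = logging.getLogger(__name__)

#: tokens normalized to a missing genotype call at load time
MISSING_TOKENS = {"", "na", "n/a", "-", "--", ".", "./.", "?"}

Call = Optional[tuple[str, str]]


class Informativeness(str, Enum):
    """Which parent(s) a marker can be mapped through."""

    both = "both"
    female_only = "female_only"
    male_only = "male_only"
    uninformative = "uninformative"


class Parent(str, Enum):
    dam = "dam"
    sire = "sire"


@dataclass(frozen=True)
class CrossFamily:
    """Identifiers for one two-parent mapping family."""

    dam_id: str
    sire_id: str
    progeny_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.dam_id == self.sire_id:
            raise ValueError("dam and sire ids must be distinct")
        if not self.progeny_ids:
            raise ValueError("progeny list is empty")
        if len(set(self.progeny_ids)) != len(self.progeny_ids):
            raise ValueError("progeny ids are not unique")

    @property
    def n_progeny(self) -> int:
        return len(self.progeny_ids)


@dataclass
class MarkerGenotypes:
    """One marker's allele calls across both parents and all progeny.

    ``progeny_calls[i]`` is an unordered allele pair (stored sorted) or
    ``None`` if the call is missing/unparseable.
    """

    marker_id: str
    dam_alleles: Optional[tuple[str, str]]
    sire_alleles: Optional[tuple[str, str]]
    progeny_calls: tuple[Call, ...]

    @property
    def n_missing(self) -> int:
        return sum(c is None for c in self.progeny_calls)

    def mendelian_consistent(self) -> bool:
        """True if every non-missing progeny call can be explained by one
        dam allele plus one sire allele."""
        if self.dam_alleles is None or self.sire_alleles is None:
            return True
        return all(
            c is None or _decompositions(self.dam_alleles, self.sire_alleles, c)
            for c in self.progeny_calls
        )


@dataclass
class BackcrossVector:
    """Per-progeny transmission codes for one marker and one parent.

    Codes: ``"A"`` = the lexicographically first allele of the tracked
    parent was inherited, ``"H"`` = the second, ``None`` = missing or
    ambiguous (transmission undecidable without phase).
    """

    marker_id: str
    parent: Parent
    transmissions: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        bad = {t for t in self.transmissions if t not in ("A", "H", None)}
        if bad:
            raise ValueError(f"invalid transmission codes {bad!r}")

    @property
    def n_progeny(self) -> int:
        return len(self.transmissions)

    def counts(self) -> tuple[int, int, int]:
        """(n_A, n_H, n_missing)."""
        n_a = sum(t == "A" for t in self.transmissions)
        n_h = sum(t == "H" for t in self.transmissions)
        return n_a, n_h, len(self.transmissions) - n_a - n_h


@dataclass(frozen=True)
class SegregationTestResult:
    counts: tuple[int, int]
    chi2: float
    p_value: float
    distorted: bool


def _normalize_call(cell: str) -> Call:
    """Parse a 'x/y' genotype cell; unknown dialects become missing."""
    token = cell.strip()
    if token.lower() in MISSING_TOKENS:
        return None
    parts = token.split("/")
    if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
        return None
    a, b = parts[0].strip(), parts[1].strip()
    if a.lower() in MISSING_TOKENS or b.lower() in MISSING_TOKENS:
        return None
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def _decompositions(
    dam: tuple[str, str], sire: tuple[str, str], call: tuple[str, str]
) -> set[tuple[str, str]]:
    """All (dam-transmitted, sire-transmitted) pairs explaining a call."""
    x, y = call
    out = set()
    for d, s in ((x, y), (y, x)):
        if d in dam and s in sire:
            out.add((d, s))
    return out


def classify_informativeness(m: MarkerGenotypes) -> Informativeness:
    """Informativeness class from parental heterozygosity.

    A marker maps through a parent only if that parent is heterozygous.
    Missing parental genotypes make the marker uninformative (warned).
    """
    if m.dam_alleles is None or m.sire_alleles is None:
        logger.warning("marker %s: missing parental genotype", m.marker_id)
        return Informativeness.uninformative
    dam_het = m.dam_alleles[0] != m.dam_alleles[1]
    sire_het = m.sire_alleles[0] != m.sire_alleles[1]
    if dam_het and sire_het:
        return Informativeness.both
    if dam_het:
        return Informativeness.female_only
    if sire_het:
        return Informativeness.male_only
    return Informativeness.uninformative


def to_backcross(m: MarkerGenotypes, parent: Parent | str) -> BackcrossVector:
    """Recode a marker into backcross format for one parent.

    The tracked parent must be heterozygous.  A progeny call is coded by
    which tracked-parent allele it received; calls where the transmitted
    allele cannot be deduced (both decompositions valid with different
    tracked alleles, e.g. a/b x a/b progeny a/b) or that are Mendelian-
    inconsistent are coded missing.
    """
    parent = Parent(parent)
    info = classify_informativeness(m)
    ok = {
        Parent.dam: (Informativeness.both, Informativeness.female_only),
        Parent.sire: (Informativeness.both, Informativeness.male_only),
    }
    if info not in ok[parent]:
        raise ValueError(
            f"marker {m.marker_id} is not informative for parent {parent.value}"
        )
    assert m.dam_alleles is not None and m.sire_alleles is not None
    tracked = m.dam_alleles if parent is Parent.dam else m.sire_alleles
    first = min(tracked)  # code "A" by lexicographic convention (phase unknown)
    codes: list[Optional[str]] = []
    n_inconsistent = 0
    for call in m.progeny_calls:
        if call is None:
            codes.append(None)
            continue
        decomps = _decompositions(m.dam_alleles, m.sire_alleles, call)
        transmitted = {d if parent is Parent.dam else s for d, s in decomps}
        if len(transmitted) != 1:
            if not decomps:
                n_inconsistent += 1
            codes.append(None)
            continue
        codes.append("A" if transmitted.pop() == first else "H")
    if n_inconsistent:
        logger.warning(
            "marker %s: %d Mendelian-inconsistent call(s) set to missing",
            m.marker_id,
            n_inconsistent,
        )
    return BackcrossVector(m.marker_id, parent, tuple(codes))


def segregation_test(v: BackcrossVector, alpha: float = 0.05) -> SegregationTestResult:
    """Chi-square goodness-of-fit of transmissions against 1:1 (1 d.f.).

    chi2 = (n_A - n_H)^2 / (n_A + n_H); no continuity correction.  Missing
    calls are excluded.  ``distorted`` flags p < alpha.
    """
    n_a, n_h, _ = v.counts()
    n = n_a + n_h
    if n == 0:
        raise ValueError(f"marker {v.marker_id}: no informative progeny")
    chi2 = (n_a - n_h) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTestResult((n_a, n_h), float(chi2), p, p < alpha)


# ---------------------------------------------------------------------------
# Genotype TSV dialect: header "marker <TAB> dam-id <TAB> sire-id <TAB> progeny..."
# ---------------------------------------------------------------------------

def load_genotypes(path, family: CrossFamily) -> list[MarkerGenotypes]:
    """Read a genotype TSV for one family.

    The header must contain both parent ids; progeny columns are taken in
    ``family.progeny_ids`` order.  Unparseable cells become missing (counted
    to the log); duplicate marker ids are a hard error.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if len(header) < 2:
            raise ValueError("genotype file has no individual columns")
        col = {name: i for i, name in enumerate(header)}
        for pid in (family.dam_id, family.sire_id):
            if pid not in col:
                raise ValueError(f"parent column {pid!r} missing from header")
        missing_prog = [p for p in family.progeny_ids if p not in col]
        if missing_prog:
            raise ValueError(f"progeny columns missing: {missing_prog[:5]}")
        markers: list[MarkerGenotypes] = []
        seen: set[str] = set()
        n_unparseable = 0
        for row in reader:
            if not row or not row[0].strip():
                continue
            marker_id = row[0].strip()
            if marker_id in seen:
                raise ValueError(f"duplicate marker id {marker_id!r}")
            seen.add(marker_id)

            def cell(name: str) -> Call:
                i = col[name]
                return _normalize_call(row[i]) if i < len(row) else None

            calls = tuple(cell(p) for p in family.progeny_ids)
            n_unparseable += sum(
                1
                for p in family.progeny_ids
                if col[p] < len(row)
                and row[col[p]].strip()
                and row[col[p]].strip().lower() not in MISSING_TOKENS
                and _normalize_call(row[col[p]]) is None
            )
            markers.append(
                MarkerGenotypes(marker_id, cell(family.dam_id), cell(family.sire_id), calls)
            )
    if n_unparseable:
        logger.warning("%d unparseable genotype cell(s) set to missing", n_unparseable)
    logger.info("loaded %d markers for %d progeny", len(markers), family.n_progeny)
    return markers


def write_genotypes(path, family: CrossFamily, markers: Iterable[MarkerGenotypes]) -> None:
    """Write the same TSV dialect ``load_genotypes`` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["marker", family.dam_id, family.sire_id, *family.progeny_ids])
        for m in markers:
            def fmt(c: Call) -> str:
                return "NA" if c is None else f"{c[0]}/{c[1]}"
            writer.writerow([m.marker_id, fmt(m.dam_alleles), fmt(m.sire_alleles),
                             *(fmt(c) for c in m.progeny_calls)])
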