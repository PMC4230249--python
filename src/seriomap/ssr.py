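"""SSR (microsatellite) mining from masked BAC-end sequences.

Reads arrive vector/quality-masked (masked bases as ``N`` or lowercase).
Reads with more than 100 unmasked bases are "qualified" and surveyed for
GC content and perfect tandem repeats of 1-10 bp units.  Arrays with at
least ``min_copies`` full copies (default 7, i.e. "over six repeats")
count as real SSRs; masked bases break arrays.  Repeat units are named
canonically — the lexicographically smallest rotation over both strands —
so CA, TG and GT all report as the AC family.  Marker selection picks the
longest motif per read, preferring the SP6-end read of each clone and
falling back to the T7 end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

UNMASKED = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

UNIT_CLASS = {
    1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta",
    6: "hexa", 7: "hepta", 8: "octa", 9: "nona", 10: "deca",
}


@dataclass(frozen=True)
class SequenceRead:
    """One masked end-read of a BAC clone."""

    read_id: str
    clone_id: str
    end: str  # "SP6" | "T7"
    sequence: str

    def __post_init__(self) -> None:
        if self.end not in ("SP6", "T7"):
            raise ValueError(f"unknown read end {self.end!r}")

    @property
    def effective_length(self) -> int:
        """Number of unmasked (uppercase ACGT) bases."""
        return sum(c in UNMASKED for c in self.sequence)


@dataclass(frozen=True)
class SSRMotif:
    """A perfect tandem repeat array on a read (0-based half-open span)."""

    read_id: str
    unit: str          # canonical repeat unit
    copies: int
    start: int
    end: int

    @property
    def unit_class(self) -> str:
        return UNIT_CLASS[len(self.unit)]

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_unit(unit: str) -> str:
    """Smallest unit among rotations of both strands (AC family <- CA/TG/GT)."""
    rc = reverse_complement(unit)
    k = len(unit)
    return min(
        min(unit[i:] + unit[:i] for i in range(k)),
        min(rc[i:] + rc[:i] for i in range(k)),
    )


def unit_family_label(unit: str) -> str:
    """Both-strand display label, e.g. AC -> 'AC/GT', A -> 'A/T'."""
    u = canonical_unit(unit)
    rc = reverse_complement(u)
    partner = min(rc[i:] + rc[:i] for i in range(len(rc)))
    return f"{u}/{partner}"


def _is_primitive(unit: str) -> bool:
    """True unless the unit is itself a repeat of a shorter unit."""
    k = len(unit)
    for p in range(1, k):
        if k % p == 0 and unit == unit[:p] * (k // p):
            return False
    return True


# ---------------------------------------------------------------------------
# qualification and composition
# ---------------------------------------------------------------------------

def qualify_reads(
    reads: Sequence[SequenceRead], min_len: int = 101
) -> list[SequenceRead]:
    """Keep reads with unmasked length >= min_len (default: 'more than 100 bp')."""
    if not reads:
        logger.warning("qualify_reads: empty input")
        return []
    kept = [r for r in reads if r.effective_length >= min_len]
    logger.info("qualified %d/%d reads", len(kept), len(reads))
    return kept


def gc_content(reads: Iterable[SequenceRead]) -> float:
    """Percent G+C over unmasked bases; masked/N bases are excluded."""
    gc = at = 0
    for r in reads:
        for c in r.sequence:
            if c in ("G", "C"):
                gc += 1
            elif c in ("A", "T"):
                at += 1
    if gc + at == 0:
        raise ValueError("no unmasked bases to measure")
    return 100.0 * gc / (gc + at)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def find_ssrs(
    read: SequenceRead, min_copies: int = 7, max_unit: int = 10
) -> list[SSRMotif]:
    """All maximal perfect tandem repeats with >= min_copies full copies.

    Only primitive units are reported, so an AC array is never double-counted
    as ACAC; the reported span covers full copies only.  Masked (N/lowercase)
    bases terminate arrays.  Motifs are returned sorted by start, then unit
    size.
    """
    s = read.sequence
    n = len(s)
    valid = [c in UNMASKED for c in s]
    motifs: list[SSRMotif] = []
    for k in range(1, max_unit + 1):
        j = k
        while j < n:
            if not (valid[j] and valid[j - k] and s[j] == s[j - k]):
                j += 1
                continue
            run_start = j  # first matching offset of this maximal run
            while j < n and valid[j] and s[j] == s[j - k]:
                j += 1
            array_start = run_start - k
            array_len = (j - run_start) + k
            copies = array_len // k
            unit = s[array_start:array_start + k]
            if copies >= min_copies and _is_primitive(unit):
                motifs.append(
                    SSRMotif(
                        read.read_id,
                        canonical_unit(unit),
                        copies,
                        array_start,
                        array_start + copies * k,
                    )
                )
    motifs.sort(key=lambda m: (m.start, len(m.unit)))
    return motifs


def pick_representative(motifs: Sequence[SSRMotif]) -> Optional[SSRMotif]:
    """Longest motif in bp; ties break to the leftmost."""
    if not motifs:
        return None
    return min(motifs, key=lambda m: (-m.length_bp, m.start))


def clone_marker_selection(
    sp6: Optional[tuple[SequenceRead, Sequence[SSRMotif]]],
    t7: Optional[tuple[SequenceRead, Sequence[SSRMotif]]],
) -> Optional[tuple[SequenceRead, SSRMotif]]:
    """Per-clone marker choice: the SP6 end's representative motif if any,
    otherwise the T7 end's, otherwise none."""
    if sp6 is None and t7 is None:
        raise ValueError("neither end-read present")
    for entry in (sp6, t7):
        if entry is None:
            continue
        read, motifs = entry
        rep = pick_representative(motifs)
        if rep is not None:
            return read, rep
    return None


def ssr_tally(
    motifs: Sequence[SSRMotif], total_sequence_bp: Optional[int] = None
) -> dict[str, pd.DataFrame | float | int]:
    """Distribution report: counts per unit-length class and per unit family,
    total bp occupied, and (if the surveyed sequence size is given) the
    percent of sequence covered by SSR arrays."""
    class_order = [UNIT_CLASS[k] for k in sorted(UNIT_CLASS)]
    by_class = {c: 0 for c in class_order}
    by_family: dict[tuple[str, str], int] = {}
    bp = 0
    for m in motifs:
        by_class[m.unit_class] += 1
        key = (m.unit_class, unit_family_label(m.unit))
        by_family[key] = by_family.get(key, 0) + 1
        bp += m.length_bp
    class_df = pd.DataFrame(
        {"unit_class": class_order, "count": [by_class[c] for c in class_order]}
    )
    family_df = pd.DataFrame(
        [(c, fam, n) for (c, fam), n in sorted(by_family.items())],
        columns=["unit_class", "family", "count"],
    )
    out: dict[str, pd.DataFrame | float | int] = {
        "by_class": class_df,
        "by_family": family_df,
        "n_motifs": len(motifs),
        "total_bp": bp,
    }
    if total_sequence_bp:
        out["percent_of_sequence"] = 100.0 * bp / total_sequence_bp
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRead]:
    """FASTA with headers '<clone>_SP6' / '<clone>_T7'."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if "_" not in rid:
            raise ValueError(f"cannot parse clone/end from header {rid!r}")
        clone, end = rid.rsplit("_", 1)
        reads.append(SequenceRead(rid, clone, end, str(rec.seq)))
    return reads


def write_fasta(path, reads: Iterable[SequenceRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i:i + 70] + "\n")


def write_motifs_tsv(path, motifs: Iterable[SSRMotif]) -> None:
    """TSV with 1-based inclusive coordinates (internal spans are 0-based
    half-open)."""
    with open(path, "w") as fh:
        fh.write("read_id\tunit\tclass\tcopies\tstart1\tend1\n")
        for m in motifs:
            fh.write(
                f"{m.read_id}\t{m.unit}\t{m.unit_class}\t{m.copies}\t"
                f"{m.start + 1}\t{m.end}\n"
            )
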