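"""Synthetic-data generators with retrievable ground truth.

Three generators mirror the statistical structure of the study's inputs:

* ``simulate_cross`` — a two-parent family (default 90 progeny) segregating
  codominant markers on 24 chromosomes.  Meioses follow a no-interference
  (Haldane/Poisson) crossover process; transmissions are Mendelian 1:1;
  genotyping error flips transmitted alleles and missingness blanks calls,
  each at configurable rates.
* ``generate_ssr_reads`` — masked end-reads with i.i.d. base composition at
  a target GC fraction and perfect SSR arrays planted at known coordinates.
* ``generate_blast_hits`` — tabular hit sets with a planted linkage-group to
  chromosome relation and decoy hits engineered to pass or trigger the
  orthology e-value-ratio rule.

Every generator is deterministic under its seed and returns machine-readable
truth alongside the data; recovery tests consume the truth, never re-derive
it.  A single seed fans out to independent substreams via ``numpy`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genotypes import CrossFamily, MarkerGenotypes, Parent
from .linkage import haldane_theta, kosambi_cm
from .orthology import BlastHit
from .ssr import SequenceRead, canonical_unit, find_ssrs

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# mapping-cross simulator
# ---------------------------------------------------------------------------

@dataclass
class SimMapConfig:
    """Study-scale defaults: 24 chromosomes of ~40-60 cM carrying 29 markers
    each, genotyped in 90 progeny."""

    n_chromosomes: int = 24
    chromosome_lengths_cM: Optional[Sequence[float]] = None  # drawn U(40, 60) if None
    #: explicit per-chromosome marker positions (cM); random uniform if None
    marker_positions_cM: Optional[Sequence[Sequence[float]]] = None
    markers_per_chromosome: int = 29
    n_progeny: int = 90
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0
    #: fractions of markers informative in (both, dam only, sire only)
    informativeness_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one marker")
        if self.n_progeny < 1:
            raise ValueError("need at least one progeny")
        if abs(sum(self.informativeness_mix) - 1.0) > 1e-9:
            raise ValueError("informativeness mix must sum to 1")


@dataclass
class SimTruth:
    """Ground truth retained alongside a simulated genotype set."""

    #: marker -> (chromosome name, position in cM on the Haldane scale)
    true_positions: dict[str, tuple[str, float]]
    #: parent -> (n_markers x n_progeny) matrix of transmitted allele index
    #: (0 = lexicographically first parental allele), before error/missing
    transmissions: dict[str, np.ndarray]
    marker_order: list[str]
    chromosome_of: dict[str, str]

    def markers_on(self, chrom: str) -> list[str]:
        return [m for m in self.marker_order if self.chromosome_of[m] == chrom]

    def true_length_cM(self, chrom: str, scale: str = "kosambi") -> float:
        """Span of a chromosome's markers; ``scale='kosambi'`` converts each
        adjacent Haldane interval to the scale the estimator reports on
        (the simulator is interference-free, the map is Kosambi)."""
        pos = sorted(self.true_positions[m][1] for m in self.markers_on(chrom))
        if scale == "haldane":
            return pos[-1] - pos[0]
        return sum(
            kosambi_cm(haldane_theta(b - a)) for a, b in zip(pos, pos[1:])
        )


def simulate_cross(cfg: SimMapConfig) -> tuple[CrossFamily, list[MarkerGenotypes], SimTruth]:
    """Simulate one outbred family's genotypes with retrievable truth.

    Parents carry distinct alleles per marker (dam a/b, sire c/d when fully
    informative) so the transmitted allele is deducible; the backcross code
    "A" corresponds to transmitted index 0.  Meioses are simulated per
    chromosome as a Markov chain over marker positions with Haldane
    recombination fractions between adjacent markers — equivalent to a
    Poisson crossover process.
    """
    rng = np.random.default_rng(cfg.seed)
    sub = rng.spawn(4)
    rng_map, rng_meiosis, rng_error, rng_missing = sub

    if cfg.chromosome_lengths_cM is None:
        lengths = rng_map.uniform(40.0, 60.0, size=cfg.n_chromosomes)
    else:
        lengths = np.asarray(cfg.chromosome_lengths_cM, dtype=float)
        if len(lengths) != cfg.n_chromosomes:
            raise ValueError("chromosome_lengths_cM length mismatch")

    family = CrossFamily(
        "dam", "sire", tuple(f"p{i + 1:03d}" for i in range(cfg.n_progeny))
    )

    marker_order: list[str] = []
    true_positions: dict[str, tuple[str, float]] = {}
    chromosome_of: dict[str, str] = {}
    dam_trans_rows: list[np.ndarray] = []
    sire_trans_rows: list[np.ndarray] = []
    markers: list[MarkerGenotypes] = []

    if cfg.marker_positions_cM is not None:
        n_markers_total = sum(len(p) for p in cfg.marker_positions_cM)
    else:
        n_markers_total = cfg.n_chromosomes * cfg.markers_per_chromosome
    info_classes = rng_map.choice(
        3, size=n_markers_total, p=cfg.informativeness_mix
    )

    idx = 0
    if cfg.marker_positions_cM is not None and len(cfg.marker_positions_cM) != cfg.n_chromosomes:
        raise ValueError("marker_positions_cM must give one list per chromosome")

    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        if cfg.marker_positions_cM is not None:
            pos = np.sort(np.asarray(cfg.marker_positions_cM[c], dtype=float))
            k = len(pos)
        else:
            k = cfg.markers_per_chromosome
            pos = np.sort(rng_map.uniform(0.0, lengths[c], size=k))
        rec = np.array([haldane_theta(d) for d in np.diff(pos)])

        # meiosis: start haplotype Bernoulli(1/2), switch at interval i w.p. rec[i]
        def meiosis_matrix(r: np.random.Generator) -> np.ndarray:
            start = r.random(cfg.n_progeny) < 0.5
            if k == 1:
                return start[None, :].astype(np.int8)
            switches = r.random((k - 1, cfg.n_progeny)) < rec[:, None]
            states = np.empty((k, cfg.n_progeny), dtype=bool)
            states[0] = start
            np.logical_xor.accumulate(
                np.vstack([start, switches]), axis=0, out=states
            )
            return states.astype(np.int8)

        dam_h = meiosis_matrix(rng_meiosis)
        sire_h = meiosis_matrix(rng_meiosis)

        for j in range(k):
            mid = f"M{c + 1:02d}_{j + 1:02d}"
            marker_order.append(mid)
            true_positions[mid] = (chrom, float(pos[j]))
            chromosome_of[mid] = chrom
            dam_trans_rows.append(dam_h[j])
            sire_trans_rows.append(sire_h[j])

            info = info_classes[idx]
            dam_alleles = ("a", "b")
            sire_alleles = ("c", "d")
            if info == 1:  # dam-only informative
                sire_alleles = ("c", "c")
            elif info == 2:  # sire-only informative
                dam_alleles = ("a", "a")

            dam_t = dam_h[j].copy()
            sire_t = sire_h[j].copy()
            if cfg.error_rate > 0:
                dam_t ^= rng_error.random(cfg.n_progeny) < cfg.error_rate
                sire_t ^= rng_error.random(cfg.n_progeny) < cfg.error_rate
            missing = (
                rng_missing.random(cfg.n_progeny) < cfg.missing_rate
                if cfg.missing_rate > 0
                else np.zeros(cfg.n_progeny, dtype=bool)
            )
            calls = tuple(
                None
                if missing[p]
                else tuple(sorted((dam_alleles[dam_t[p]], sire_alleles[sire_t[p]])))
                for p in range(cfg.n_progeny)
            )
            markers.append(MarkerGenotypes(mid, dam_alleles, sire_alleles, calls))
            idx += 1

    truth = SimTruth(
        true_positions=true_positions,
        transmissions={
            Parent.dam.value: np.vstack(dam_trans_rows),
            Parent.sire.value: np.vstack(sire_trans_rows),
        },
        marker_order=marker_order,
        chromosome_of=chromosome_of,
    )
    return family, markers, truth


# ---------------------------------------------------------------------------
# BES read generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedMotif:
    """Specification and realized location of one planted SSR array."""

    read_id: str
    unit: str
    copies: int
    start: int

    @property
    def end(self) -> int:
        return self.start + self.copies * len(self.unit)

    @property
    def canonical(self) -> str:
        return canonical_unit(self.unit)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _scrub_incidental(
    seq: list[str], rng: np.random.Generator, min_copies: int,
    protected: Sequence[tuple[int, int]] = (),
) -> None:
    """Break chance tandem arrays of >= min_copies copies outside protected
    spans by substituting one base, so planted motifs are the only signal."""
    probe = SequenceRead("probe_SP6", "probe", "SP6", "")
    for _ in range(50):
        hits = find_ssrs(
            SequenceRead(probe.read_id, "probe", "SP6", "".join(seq)),
            min_copies=min_copies, max_unit=10,
        )
        hits = [
            h for h in hits
            if not any(h.start < e and s < h.end for s, e in protected)
        ]
        if not hits:
            return
        for h in hits:
            mid = (h.start + h.end) // 2
            cur = seq[mid]
            seq[mid] = str(rng.choice([b for b in "ACGT" if b != cur]))
    raise RuntimeError("could not scrub incidental repeats")


def generate_ssr_reads(
    n_reads: int,
    read_length: int = 620,
    gc_target: float = 0.4136,
    planted_motifs: Optional[Sequence[tuple[int, str, int]]] = None,
    n_short: int = 0,
    short_length: int = 80,
    scrub: bool = True,
    scrub_min_copies: int = 6,
    seed: int = 0,
) -> tuple[list[SequenceRead], list[PlantedMotif]]:
    """Masked-read FASTA material with planted perfect SSR arrays.

    ``planted_motifs`` is a list of (read index, unit, copies); each array is
    placed at a random interior position with flanking bases forced to break
    the repeat period so planted coordinates are exact.  ``n_short`` extra
    reads of ``short_length`` unmasked bases are appended (they fail the
    >100 bp qualification rule).  With ``scrub=True`` chance background
    arrays of >= ``scrub_min_copies`` copies are removed, making the planted
    truth the complete motif catalogue at that threshold.
    """
    rng = np.random.default_rng(seed)
    planted_by_read: dict[int, list[tuple[str, int]]] = {}
    for read_idx, unit, copies in planted_motifs or []:
        if copies * len(unit) + 2 > read_length:
            raise ValueError(f"motif {unit} x {copies} longer than read")
        planted_by_read.setdefault(read_idx, []).append((unit, copies))

    reads: list[SequenceRead] = []
    truth: list[PlantedMotif] = []
    for i in range(n_reads):
        clone = f"clone{i // 2 + 1:04d}"
        end = "SP6" if i % 2 == 0 else "T7"
        rid = f"{clone}_{end}"
        seq = list(_random_bases(rng, read_length, gc_target))
        spans: list[tuple[int, int]] = []
        if scrub or i in planted_by_read:
            _scrub_incidental(seq, rng, scrub_min_copies)
        for unit, copies in planted_by_read.get(i, []):
            span_len = copies * len(unit)
            # non-overlapping interior placement, 1-base flanks reserved
            for _ in range(200):
                start = int(rng.integers(1, read_length - span_len - 1))
                if not any(start < e + 1 and s - 1 < start + span_len for s, e in spans):
                    break
            else:
                raise ValueError("could not place planted motifs without overlap")
            seq[start:start + span_len] = list(unit * copies)
            # flanks must not extend the array or join it to a neighbour
            left = [b for b in "ACGT" if b != unit[-1]]
            right = [b for b in "ACGT" if b != unit[0]]
            seq[start - 1] = str(rng.choice(left))
            seq[start + span_len] = str(rng.choice(right))
            spans.append((start, start + span_len))
            truth.append(PlantedMotif(rid, unit, copies, start))
        if spans and scrub:
            _scrub_incidental(seq, rng, scrub_min_copies, protected=spans)
        reads.append(SequenceRead(rid, clone, end, "".join(seq)))

    for i in range(n_short):
        clone = f"short{i + 1:04d}"
        seq = "".join(_random_bases(rng, short_length, gc_target))
        reads.append(SequenceRead(f"{clone}_SP6", clone, "SP6", seq))
    return reads, truth


# ---------------------------------------------------------------------------
# BLAST-hit generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedHitTruth:
    query_id: str
    linkage_group: str
    true_chromosome: str
    intended_accept: bool


def generate_blast_hits(
    lg_to_chrom: dict[str, str | Sequence[str]],
    markers_per_lg: int = 10,
    reject_fraction: float = 0.0,
    benign_decoy_fraction: float = 0.0,
    query_length: int = 620,
    seed: int = 0,
) -> tuple[list[BlastHit], list[PlantedHitTruth], dict[str, str]]:
    """Tabular hits realizing a planted linkage-group -> chromosome relation.

    Each marker receives a rank-1 hit on its group's true chromosome (groups
    mapped to two chromosomes split their markers between them: a synthetic
    fusion).  A ``reject_fraction`` of markers additionally get an
    overlapping decoy with e1/e2 in (1e-3, 1], engineered to trigger the
    unclear-orthology rejection; a ``benign_decoy_fraction`` get decoys that
    pass the rule (ratio <= 1e-3 or disjoint interval).  Returns hits, the
    per-marker intended outcome, and the marker -> linkage-group map.
    """
    if reject_fraction + benign_decoy_fraction > 1.0:
        raise ValueError("decoy fractions exceed 1")
    rng = np.random.default_rng(seed)
    hits: list[BlastHit] = []
    truth: list[PlantedHitTruth] = []
    marker_to_lg: dict[str, str] = {}
    all_chroms = sorted(
        {c for v in lg_to_chrom.values() for c in ([v] if isinstance(v, str) else v)}
    )
    for lg in sorted(lg_to_chrom):
        targets = lg_to_chrom[lg]
        targets = [targets] if isinstance(targets, str) else list(targets)
        for j in range(markers_per_lg):
            query = f"{lg}_mk{j + 1:02d}"
            marker_to_lg[query] = lg
            chrom = targets[j % len(targets)]
            qstart = int(rng.integers(1, query_length // 2))
            qend = qstart + int(rng.integers(80, 200))
            e1 = 10.0 ** (-float(rng.uniform(20, 40)))
            hits.append(
                BlastHit(query, f"{chrom}_seq", float(rng.uniform(85, 99)), e1,
                         float(rng.uniform(100, 300)), qstart, qend,
                         subject_chromosome=chrom)
            )
            u = rng.random()
            intended_accept = True
            if u < reject_fraction:
                # overlapping decoy close in significance: e1/e2 = 10^-x, x < 3
                e2 = e1 * 10.0 ** float(rng.uniform(0.0, 2.9))
                intended_accept = False
            elif u < reject_fraction + benign_decoy_fraction:
                e2 = e1 * 10.0 ** float(rng.uniform(4.0, 8.0))  # ratio <= 1e-4
            else:
                e2 = None
            if e2 is not None:
                decoy_chrom = all_chroms[(all_chroms.index(chrom) + 1) % len(all_chroms)]
                hits.append(
                    BlastHit(query, f"{decoy_chrom}_seq", float(rng.uniform(80, 95)),
                             min(e2, 1e-2), float(rng.uniform(50, 150)),
                             qstart + 5, qend + 5, subject_chromosome=decoy_chrom)
                )
            truth.append(PlantedHitTruth(query, lg, chrom, intended_accept))
    return hits, truth, marker_to_lg
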