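#!/usr/bin/env python
"""SSR survey of synthetic masked end-reads with planted truth.

Generates reads at the survey's base composition (41.36% GC, 620 bp) with a
catalogue of planted SSR arrays plus short reads that fail qualification,
then runs the full survey: qualification (>100 unmasked bases), GC content,
motif scanning (>= 7 copies, units 1-10 bp), per-clone marker selection
(SP6 before T7), and the distribution tally.  Writes results/ssr_tally.tsv
and results/ssr_survey.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from seriomap.simulate import generate_ssr_reads
from seriomap.ssr import (
    clone_marker_selection,
    find_ssrs,
    gc_content,
    qualify_reads,
    ssr_tally,
    write_motifs_tsv,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-reads", type=int, default=400)
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    units = ["A", "AC", "AC", "AC", "AG", "AT", "AAT", "AGC", "AAAC", "AGAT",
             "AACGT", "ACGCGT"]
    planted = [
        (int(rng.integers(0, args.n_reads)), units[int(rng.integers(len(units)))],
         int(rng.integers(7, 15)))
        for _ in range(args.n_reads // 5)
    ]
    # one planted array per read at most (overlap-free planting is per read,
    # but keep the truth simple to summarize)
    seen: set[int] = set()
    planted = [p for p in planted if not (p[0] in seen or seen.add(p[0]))]

    reads, truth = generate_ssr_reads(
        args.n_reads, read_length=620, gc_target=0.4136,
        planted_motifs=planted, n_short=args.n_reads // 6,
        seed=int(rng.integers(0, 2**31)),
    )
    qualified = qualify_reads(reads)
    gc = gc_content(qualified)
    print(f"{len(qualified)}/{len(reads)} reads qualified (>100 unmasked bp); "
          f"GC {gc:.2f}%")

    motifs_by_read = {r.read_id: find_ssrs(r) for r in qualified}
    motifs = [m for ms in motifs_by_read.values() for m in ms]
    print(f"{len(motifs)} SSR arrays found vs {len(truth)} planted")

    by_clone: dict[str, dict] = {}
    for r in qualified:
        by_clone.setdefault(r.clone_id, {})[r.end] = (r, motifs_by_read[r.read_id])
    markers = []
    for clone, ends in sorted(by_clone.items()):
        chosen = clone_marker_selection(ends.get("SP6"), ends.get("T7"))
        if chosen:
            markers.append(chosen)
    print(f"{len(markers)} clones yield an SSR marker (SP6 first, then T7)")

    total_bp = sum(r.effective_length for r in qualified)
    report = ssr_tally(motifs, total_sequence_bp=total_bp)
    print(report["by_class"].to_string(index=False))
    print(f"SSR bp {report['total_bp']} = "
          f"{report['percent_of_sequence']:.3f}% of qualified sequence")

    OUT.mkdir(exist_ok=True)
    write_motifs_tsv(OUT / "ssr_motifs.tsv", motifs)
    report["by_family"].to_csv(OUT / "ssr_tally.tsv", sep="\t", index=False)
    (OUT / "ssr_survey.json").write_text(json.dumps({
        "seed": args.seed,
        "n_reads": len(reads),
        "n_qualified": len(qualified),
        "gc_percent": round(gc, 2),
        "n_motifs": len(motifs),
        "n_planted": len(truth),
        "n_clone_markers": len(markers),
        "ssr_percent_of_sequence": round(report["percent_of_sequence"], 3),
    }, indent=2) + "\n")
    print(f"wrote {OUT / 'ssr_tally.tsv'} and {OUT / 'ssr_survey.json'}")


if __name__ == "__main__":
    main()
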