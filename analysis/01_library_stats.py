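#!/usr/bin/env python
"""BAC-library and end-sequence survey arithmetic.

Converts the flow-cytometry C-value to a genome size, works out how many
clones carry inserts, the total insert length and the fold coverage of the
library, and summarizes the qualified end-read survey (average read length,
fraction of the genome sampled).  Writes results/library_stats.json.
"""

import json
from pathlib import Path

from seriomap import published as pub
from seriomap.map_stats import bes_survey_stats, genome_size_from_cvalue, library_stats

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    genome_bp = genome_size_from_cvalue(pub.LIBRARY["c_value_pg"])
    lib = library_stats(
        pub.LIBRARY["total_clones"], pub.LIBRARY["insert_rate"],
        pub.LIBRARY["mean_insert_bp"], genome_bp,
    )
    avg_len, genome_pct = bes_survey_stats(
        pub.BES_SURVEY["total_qualified_bp"], pub.BES_SURVEY["n_qualified"],
        genome_bp,
    )

    print(f"C-value {pub.LIBRARY['c_value_pg']} pg -> genome {genome_bp / 1e6:.1f} Mb")
    print(f"{lib.clones_with_insert:,} of {lib.total_clones:,} clones carry inserts "
          f"({100 * lib.insert_rate:.0f}%)")
    print(f"total insert DNA {lib.total_insert_bp / 1e9:.2f} Gb = "
          f"{lib.fold_coverage:.1f}x the genome (~{lib.fold_coverage_rounded}x)")
    print(f"qualified end reads: {pub.BES_SURVEY['n_qualified']:,} averaging "
          f"{avg_len:.0f} bp, sampling {genome_pct:.2f}% of the genome")

    OUT.mkdir(exist_ok=True)
    (OUT / "library_stats.json").write_text(json.dumps({
        "genome_size_mb": round(genome_bp / 1e6, 1),
        "clones_with_insert": lib.clones_with_insert,
        "total_insert_gb": round(lib.total_insert_bp / 1e9, 2),
        "fold_coverage": round(lib.fold_coverage, 2),
        "fold_coverage_rounded": lib.fold_coverage_rounded,
        "bes_mean_length_bp": round(avg_len, 1),
        "bes_percent_of_genome": round(genome_pct, 3),
    }, indent=2) + "\n")
    print(f"wrote {OUT / 'library_stats.json'}")


if __name__ == "__main__":
    main()
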