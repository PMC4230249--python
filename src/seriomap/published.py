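"""Published yellowtail (Seriola quinqueradiata) map and library figures.

Per-linkage-group summaries of the published female and male SSR linkage
maps (marker counts, framework-marker counts, observed Kosambi lengths,
and the printed L1/L2 genome-length cells for cross-checking), plus the
BAC-library and BAC-end-sequence survey constants.  These are the fixed
inputs the map-statistics analyses run on; framework counts are taken as
published, never recomputed.
"""

from __future__ import annotations

from .map_stats import MapSummaryRow

# group_id, n_markers, n_framework, length_cM, printed L1, printed L2
_FEMALE = [
    ("Squ1", 33, 11, 48.19, 58.11, 57.83),
    ("Squ2", 49, 14, 49.27, 59.19, 56.85),
    ("Squ3", 29, 10, 40.17, 50.09, 49.10),
    ("Squ4", 28, 9, 42.82, 52.74, 53.52),
    ("Squ5", 38, 9, 59.51, 69.43, 74.39),
    ("Squ6", 30, 5, 50.31, 60.23, 75.47),
    ("Squ7", 29, 14, 50.66, 60.58, 58.45),
    ("Squ8", 26, 8, 54.83, 64.75, 70.49),
    ("Squ9", 37, 10, 30.22, 40.14, 36.94),
    ("Squ10", 35, 7, 40.60, 50.52, 54.13),
    ("Squ11", 10, 1, 0.00, 9.92, 0.00),
    ("Squ12", 26, 12, 26.74, 36.66, 31.60),
    ("Squ13", 26, 10, 48.03, 57.95, 58.71),
    ("Squ14", 34, 9, 56.36, 66.28, 70.45),
    ("Squ15", 35, 14, 37.23, 47.15, 42.96),
    ("Squ16", 25, 8, 36.12, 46.04, 46.44),
    ("Squ17", 20, 10, 40.32, 50.24, 49.28),
    ("Squ18", 37, 10, 45.12, 55.04, 55.15),
    ("Squ19", 30, 9, 40.52, 50.44, 50.65),
    ("Squ20", 22, 9, 51.21, 61.13, 64.01),
    ("Squ21", 29, 12, 44.90, 54.82, 53.06),
    ("Squ22", 26, 12, 45.87, 55.79, 54.21),
    ("Squ23", 25, 7, 41.67, 51.59, 55.56),
    ("Squ24", 4, 4, 15.67, 25.59, 26.12),
    ("Squ24'", 32, 8, 30.31, 40.23, 38.97),
]

_MALE = [
    ("Squ1", 34, 15, 49.28, 57.91, 56.32),
    ("Squ2", 48, 18, 43.45, 52.09, 48.56),
    ("Squ3", 29, 18, 54.97, 63.60, 61.43),
    ("Squ4", 25, 3, 5.57, 14.20, 11.14),
    ("Squ5", 39, 17, 50.24, 58.87, 56.52),
    ("Squ6", 23, 11, 42.62, 51.26, 51.15),
    ("Squ7", 32, 11, 40.41, 49.04, 48.49),
    ("Squ8", 23, 12, 51.60, 60.24, 60.99),
    ("Squ9", 36, 10, 52.89, 61.53, 64.65),
    ("Squ10", 36, 7, 28.60, 37.24, 38.14),
    ("Squ11", 11, 6, 59.19, 67.82, 82.86),
    ("Squ12", 27, 10, 52.09, 60.73, 63.67),
    ("Squ13", 25, 10, 42.63, 51.27, 52.10),
    ("Squ14", 33, 11, 45.39, 54.02, 54.47),
    ("Squ15", 36, 11, 55.44, 64.07, 66.52),
    ("Squ16", 27, 14, 51.66, 60.29, 59.61),
    ("Squ17", 22, 7, 44.55, 53.18, 59.39),
    ("Squ18", 33, 13, 57.00, 65.64, 66.51),
    ("Squ19", 26, 14, 58.45, 67.08, 67.44),
    ("Squ20", 24, 10, 40.38, 49.02, 49.36),
    ("Squ21", 3, 2, 1.11, 9.75, 3.33),
    ("Squ21'", 25, 5, 7.78, 16.42, 11.68),
    ("Squ22", 26, 11, 54.03, 62.67, 64.84),
    ("Squ23", 26, 10, 44.03, 52.67, 53.82),
    ("Squ24", 29, 11, 17.79, 26.42, 21.34),
    ("Squ24'", 4, 4, 6.68, 15.31, 11.13),
]


def female_map_rows() -> list[MapSummaryRow]:
    """The 25 published female linkage-group rows."""
    return [MapSummaryRow(g, n, f, ln) for g, n, f, ln, _, _ in _FEMALE]


def male_map_rows() -> list[MapSummaryRow]:
    """The 26 published male linkage-group rows."""
    return [MapSummaryRow(g, n, f, ln) for g, n, f, ln, _, _ in _MALE]


def printed_length_estimates(sex: str) -> dict[str, tuple[float, float]]:
    """group -> (printed L1, printed L2) for cross-checking recomputation."""
    table = _FEMALE if sex == "female" else _MALE
    return {g: (l1, l2) for g, _, _, _, l1, l2 in table}


#: printed per-sex totals and coverage (L1, L2, coverage% from L1, from L2)
PUBLISHED_TOTALS = {
    "female": {"length_cM": 1026.65, "L1": 1274.64, "L2": 1284.34,
               "coverage_L1_pct": 83.56, "coverage_L2_pct": 83.33,
               "d_cM": 4.96, "n_markers": 715, "n_framework": 232},
    "male": {"length_cM": 1057.83, "L1": 1282.35, "L2": 1285.45,
             "coverage_L1_pct": 83.88, "coverage_L2_pct": 83.81,
             "d_cM": 4.32, "n_markers": 702, "n_framework": 271},
}

#: BAC library and genome-size survey constants
LIBRARY = {
    "total_clones": 110_592,
    "insert_rate": 0.71,
    "mean_insert_bp": 140_700.0,   # 140.7 kb average insert
    "c_value_pg": 0.7,             # flow-cytometry haploid DNA content
}

#: end-sequencing survey constants
BES_SURVEY = {
    "n_raw_reads": 5_920,
    "n_qualified": 4_956,
    "n_qualified_sp6": 2_471,
    "n_qualified_t7": 2_485,
    "total_qualified_bp": 3_074_133,
    "gc_percent": 41.36,
}
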