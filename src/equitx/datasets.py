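"""Bundled small datasets.

``SEVEN_TISSUE_READ_STATS`` holds the published per-sample read counts of
the seven-sample equine immune-tissue RNA-seq dataset (SOLiD 50 bp reads;
EBI SRA study ERP001116): raw reads, reads surviving trimming, and reads
aligned to the EquCab2 genome. These counts are inputs to the report
arithmetic (percent trimmed, percent aligned, average coverage), not
outputs of this package.
"""

from __future__ import annotations

import pandas as pd

from .quantify import CoverageSpec, coverage, percent

__all__ = [
    "SEVEN_TISSUE_READ_STATS",
    "EQUINE_COVERAGE_SPEC",
    "read_statistics_report",
]

#: Published per-sample read counts (raw, trimmed, aligned).
SEVEN_TISSUE_READ_STATS = pd.DataFrame(
    [
        ("Lymphocyte A", 20_853_992, 18_243_283, 7_856_017),
        ("Lymphocyte B", 32_050_093, 27_315_182, 11_659_787),
        ("Jejunum", 19_902_170, 17_241_772, 7_659_938),
        ("Kidney", 33_158_285, 27_746_321, 10_937_750),
        ("Liver", 23_176_545, 19_982_256, 8_565_159),
        ("Lymph node", 24_671_029, 21_444_476, 9_221_340),
        ("Spleen", 30_421_675, 26_828_834, 12_708_499),
    ],
    columns=["sample", "raw_reads", "trimmed_reads", "aligned_reads"],
).set_index("sample")

#: EquCab2 genome size and post-trimming mean read length.
EQUINE_COVERAGE_SPEC = CoverageSpec(genome_size=2_428_790_173, mean_read_length=47.0)


def read_statistics_report(
    stats: pd.DataFrame = SEVEN_TISSUE_READ_STATS,
    spec: CoverageSpec = EQUINE_COVERAGE_SPEC,
) -> pd.DataFrame:
    """Derive the percentage and coverage columns of a read-statistics table.

    ``stats`` needs columns raw_reads, trimmed_reads, aligned_reads indexed
    by sample. Adds pct_raw_trimmed, pct_trimmed_aligned (nearest-integer
    percent) and avg_coverage (2 dp), matching the published report
    conventions.
    """
    out = stats.copy()
    out["pct_raw_trimmed"] = [
        percent(t, r) for t, r in zip(stats["trimmed_reads"], stats["raw_reads"])
    ]
    out["pct_trimmed_aligned"] = [
        percent(a, t) for a, t in zip(stats["aligned_reads"], stats["trimmed_reads"])
    ]
    out["avg_coverage"] = [coverage(a, spec) for a in stats["aligned_reads"]]
    return out
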