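"""Published reference values for DRS degradation time courses.

Summary metrics reported for an 8-hour freeze-thaw degradation series of
SH-SY5Y neuroblastoma RNA (15 DRS runs across six time points), used as
arithmetic cross-checks for the bookkeeping routines: the per-time-point
integrity metrics and the sizes of the four K-means degradation clusters.
These are reference data shipped with the package, not outputs of it.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .metrics import SampleMetrics

__all__ = [
    "TIME_SERIES_METRICS",
    "CLUSTER_COUNTS",
    "metrics_at_time",
    "cluster_percentages",
]

#: Integrity metrics per time point (h) of the reference degradation series.
TIME_SERIES_METRICS = pd.DataFrame(
    [
        # time, RIN,  N50, med_aln, %FL95, %FLends, read_cov, iso_cov, genes/1M, iso/1M
        (0.0, 9.80, 1378.0, 773.0, 25.0, 20.0, 0.68, 0.53, 14727, 33502),
        (0.5, 9.60, 1460.0, 774.0, 24.0, 19.0, 0.67, 0.52, 14849, 34387),
        (1.0, 9.30, 1203.0, 697.0, 20.0, 17.0, 0.57, 0.42, 14942, 34431),
        (3.5, 8.70, 1009.0, 628.0, 19.0, 17.0, 0.53, 0.38, 14733, 35164),
        (6.0, 8.20, 925.6, 607.0, 20.0, 18.0, 0.53, 0.35, 14663, 34043),
        (8.0, 7.25, 777.0, 518.0, 16.0, 16.0, 0.47, 0.29, 14459, 33806),
    ],
    columns=[
        "time_h",
        "rin",
        "n50",
        "median_aligned_len",
        "pct_full_length_95",
        "pct_full_length_ends",
        "median_read_cov_frac",
        "median_isoform_cov_frac",
        "genes_per_1m",
        "isoforms_per_1m",
    ],
)

#: Sizes of the four degradation clusters in the reference gene-level run.
CLUSTER_COUNTS: Mapping[str, int] = {
    "up": 383,
    "stable": 1500,
    "slow": 3820,
    "fast": 2161,
}


def metrics_at_time(time_h: float) -> SampleMetrics:
    """The reference integrity metrics at one time point, as SampleMetrics."""
    row = TIME_SERIES_METRICS.loc[TIME_SERIES_METRICS["time_h"] == time_h]
    if row.empty:
        raise KeyError(f"no reference metrics at {time_h} h")
    r = row.iloc[0]
    return SampleMetrics(
        n50=float(r["n50"]),
        median_aligned_len=float(r["median_aligned_len"]),
        pct_full_length_95=float(r["pct_full_length_95"]),
        pct_full_length_ends=float(r["pct_full_length_ends"]),
        median_read_cov_frac=float(r["median_read_cov_frac"]),
        median_isoform_cov_frac=float(r["median_isoform_cov_frac"]),
        genes_per_1m=float(r["genes_per_1m"]),
        isoforms_per_1m=float(r["isoforms_per_1m"]),
    )


def cluster_percentages(counts: Mapping[str, int] | None = None) -> dict[str, float]:
    """Cluster shares (%) and the clustered-feature total."""
    counts = dict(counts if counts is not None else CLUSTER_COUNTS)
    total = sum(counts.values())
    out = {f"pct_{k}": 100.0 * v / total for k, v in counts.items()}
    out["total"] = float(total)
    return out
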