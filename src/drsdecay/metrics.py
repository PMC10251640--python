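"""Integrity metrics for transcriptome-space DRS alignments.

Implements per-read coverage fractions and full-length classification,
NanoCount-style alignment filtering, per-sample summary metrics (N50,
median aligned length, full-length percentages, features detected per 1M
reads), meta-transcript gene-body coverage and length-stratified views.

Conventions: the aligned length of a read is the reference span of its best
alignment (``target_end - target_start``), which is compared against the
annotated isoform length; the 95% full-length boundary is inclusive and is
evaluated in integer arithmetic (``aligned_len * 100 >= 95 * length``) so
the boundary cannot drift with floating point; end-window boundaries are
inclusive (<= 25 nt at the 5' end, <= 50 nt at the 3' end); medians use the
midpoint convention for even counts.  All sample-level metrics are computed
over pass reads, using each read's best (primary) alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ReadAlignment, TranscriptModel

__all__ = [
    "ReadMetricsColumns",
    "SampleMetrics",
    "best_alignment",
    "best_alignments_table",
    "read_coverage_fraction",
    "classify_full_length",
    "compute_read_metrics",
    "isoform_coverage_fraction",
    "nanocount_filter",
    "sample_summary",
    "n50",
    "gene_body_coverage",
    "read_length_proportions",
    "detection_by_length",
    "percent_reduction",
]

logger = logging.getLogger(__name__)

#: Columns of the per-read metrics table.
ReadMetricsColumns = [
    "read_id",
    "transcript_id",
    "aligned_len",
    "coverage_fraction",
    "full_length_95",
    "full_length_ends",
    "dist5",
    "dist3",
    "n_secondary",
    "read_length",
]


@dataclass
class SampleMetrics:
    """Per-sample integrity summary (one row of a metrics table)."""

    n50: float
    median_aligned_len: float
    pct_full_length_95: float
    pct_full_length_ends: float
    median_read_cov_frac: float
    median_isoform_cov_frac: float
    genes_per_1m: float
    isoforms_per_1m: float
    pct_reads_ge5_secondary: float | None = None
    subsampled: bool = True  # False when fewer than 1M reads were available

    def to_dict(self) -> dict[str, float]:
        d = {
            "n50": self.n50,
            "median_aligned_len": self.median_aligned_len,
            "pct_full_length_95": self.pct_full_length_95,
            "pct_full_length_ends": self.pct_full_length_ends,
            "median_read_cov_frac": self.median_read_cov_frac,
            "median_isoform_cov_frac": self.median_isoform_cov_frac,
            "genes_per_1m": self.genes_per_1m,
            "isoforms_per_1m": self.isoforms_per_1m,
        }
        if self.pct_reads_ge5_secondary is not None:
            d["pct_reads_ge5_secondary"] = self.pct_reads_ge5_secondary
        return d


def _length_map(transcripts: Sequence[TranscriptModel] | Mapping[str, int]) -> dict[str, int]:
    if isinstance(transcripts, Mapping):
        return dict(transcripts)
    return {t.transcript_id: t.length for t in transcripts}


def _gene_map(transcripts: Sequence[TranscriptModel]) -> dict[str, str]:
    return {t.transcript_id: t.gene_id for t in transcripts}


# ---------------------------------------------------------------------------
# Per-read operations
# ---------------------------------------------------------------------------

def best_alignment(alignments: Sequence[ReadAlignment]) -> ReadAlignment:
    """The highest-score alignment of one read.

    Ties break by longer aligned span, then lexicographically smallest
    transcript id.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    return min(alignments, key=lambda a: (-a.score, -a.span, a.transcript_id))


def best_alignments_table(aln: pd.DataFrame) -> pd.DataFrame:
    """One row per read: its best alignment (same tie-breaks as above)."""
    df = aln.assign(_span=aln["target_end"] - aln["target_start"])
    df = df.sort_values(
        ["read_id", "score", "_span", "transcript_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return df.drop_duplicates("read_id", keep="first").drop(columns="_span")


def read_coverage_fraction(
    best: ReadAlignment, transcript: TranscriptModel
) -> float:
    """Aligned span of the best alignment over the annotated isoform length,
    clipped to <= 1."""
    return min(best.span / transcript.length, 1.0)


def classify_full_length(
    best: ReadAlignment, transcript: TranscriptModel
) -> tuple[bool, bool]:
    """(>=95% coverage rule, 25 nt 5'/50 nt 3' end-window rule)."""
    span = min(best.span, transcript.length)
    fl95 = span * 100 >= 95 * transcript.length
    fl_ends = (
        transcript.length - best.target_end
    ) <= 50 and best.target_start <= 25
    return fl95, fl_ends


def compute_read_metrics(
    aln: pd.DataFrame,
    transcripts: Sequence[TranscriptModel] | Mapping[str, int],
    pass_only: bool = True,
) -> pd.DataFrame:
    """Per-read metrics from an alignment table.

    Takes each pass read's best alignment against the annotation; reads
    assigned to unannotated references are dropped and counted in
    ``result.attrs['n_unannotated']`` (and logged).
    """
    lens = _length_map(transcripts)
    df = aln[aln["pass"]] if pass_only else aln
    n_secondary = (
        df.loc[~df["is_primary"], "read_id"].value_counts()
        if (~df["is_primary"]).any()
        else pd.Series(dtype=int)
    )
    best = best_alignments_table(df)
    tlen = best["transcript_id"].map(lens)
    unannot = tlen.isna()
    if unannot.any():
        logger.warning(
            "%d reads assigned to unannotated references; excluded from metrics",
            int(unannot.sum()),
        )
    best = best[~unannot]
    tlen = tlen[~unannot].astype(np.int64)
    span = (best["target_end"] - best["target_start"]).to_numpy()
    span_clip = np.minimum(span, tlen.to_numpy())
    out = pd.DataFrame(
        {
            "read_id": best["read_id"].to_numpy(),
            "transcript_id": best["transcript_id"].to_numpy(),
            "aligned_len": span,
            "coverage_fraction": span_clip / tlen.to_numpy(),
            "full_length_95": span_clip * 100 >= 95 * tlen.to_numpy(),
            "full_length_ends": (
                (tlen.to_numpy() - best["target_end"].to_numpy() <= 50)
                & (best["target_start"].to_numpy() <= 25)
            ),
            "dist5": best["target_start"].to_numpy(),
            "dist3": tlen.to_numpy() - best["target_end"].to_numpy(),
            "n_secondary": best["read_id"].map(n_secondary).fillna(0).astype(int).to_numpy(),
            "read_length": best["read_length"].to_numpy(),
        }
    )
    out.attrs["n_unannotated"] = int(unannot.sum())
    return out


def isoform_coverage_fraction(read_metrics: pd.DataFrame) -> pd.Series:
    """Median read coverage fraction per detected isoform."""
    return read_metrics.groupby("transcript_id")["coverage_fraction"].median()


# ---------------------------------------------------------------------------
# NanoCount-style filtering
# ---------------------------------------------------------------------------

def nanocount_filter(
    aln: pd.DataFrame,
    transcripts: Sequence[TranscriptModel] | Mapping[str, int],
) -> pd.DataFrame:
    """Drop 3'-distal and low-scoring alignments (idempotent).

    Alignments ending more than 50 nt from the annotated 3' end are
    removed; among each read's survivors, alignments scoring below 95% of
    that read's best surviving score are removed.  Reads left with no
    alignment disappear from the output (excluded from quantification).
    """
    lens = _length_map(transcripts)
    tlen = aln["transcript_id"].map(lens)
    keep = (tlen - aln["target_end"]) <= 50
    out = aln[keep.fillna(False)]
    if out.empty:
        return out
    best = out.groupby("read_id")["score"].transform("max")
    return out[out["score"] >= 0.95 * best]


# ---------------------------------------------------------------------------
# Sample summaries
# ---------------------------------------------------------------------------

def n50(read_lengths: np.ndarray | Sequence[int]) -> int:
    """Largest X such that reads of length >= X hold >= 50% of sequenced bases."""
    lens = np.sort(np.asarray(read_lengths, dtype=np.int64))[::-1]
    if lens.size == 0:
        raise ValueError("no reads")
    csum = np.cumsum(lens)
    return int(lens[np.searchsorted(csum, csum[-1] / 2.0)])


def sample_summary(
    read_metrics: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    seed: int = 0,
    subsample_size: int = 1_000_000,
) -> SampleMetrics:
    """Summary integrity metrics for one sample.

    Genes/isoforms per 1M reads are counted in a single seeded subsample of
    ``subsample_size`` best alignments (all reads, flagged, when fewer are
    available).
    """
    if read_metrics.empty:
        raise ValueError("sample has no pass reads")
    gmap = _gene_map(transcripts)
    rl = read_metrics["read_length"].to_numpy()
    iso_cov = isoform_coverage_fraction(read_metrics)

    if len(read_metrics) > subsample_size:
        rng = np.random.default_rng(seed)
        sub = read_metrics.sample(
            n=subsample_size, random_state=np.random.RandomState(seed)
        )
        subsampled = True
        scale = 1.0
    else:
        sub = read_metrics
        subsampled = False
        scale = 1.0  # reported as features per 1M equivalent of available reads
    genes = sub["transcript_id"].map(gmap).nunique()
    isoforms = sub["transcript_id"].nunique()

    return SampleMetrics(
        n50=float(n50(rl)),
        median_aligned_len=float(np.median(read_metrics["aligned_len"])),
        pct_full_length_95=100.0 * float(read_metrics["full_length_95"].mean()),
        pct_full_length_ends=100.0 * float(read_metrics["full_length_ends"].mean()),
        median_read_cov_frac=float(np.median(read_metrics["coverage_fraction"])),
        median_isoform_cov_frac=float(np.median(iso_cov)),
        genes_per_1m=float(genes) * scale,
        isoforms_per_1m=float(isoforms) * scale,
        pct_reads_ge5_secondary=100.0
        * float((read_metrics["n_secondary"] >= 5).mean()),
        subsampled=subsampled,
    )


def percent_reduction(early: SampleMetrics, late: SampleMetrics) -> dict[str, float]:
    """Percent reduction of the headline metrics between two samples
    (typically the first and last time points of a series)."""
    out = {}
    for key in (
        "n50",
        "median_aligned_len",
        "pct_full_length_95",
        "pct_full_length_ends",
        "median_read_cov_frac",
        "median_isoform_cov_frac",
    ):
        a, b = getattr(early, key), getattr(late, key)
        out[key] = 100.0 * (a - b) / a
    return out


# ---------------------------------------------------------------------------
# Gene-body coverage and stratifications
# ---------------------------------------------------------------------------

def gene_body_coverage(
    read_metrics: pd.DataFrame,
    transcripts: Sequence[TranscriptModel] | Mapping[str, int],
    n_bins: int = 100,
) -> np.ndarray:
    """Meta-transcript coverage profile (5' = bin 0, 3' = last bin).

    Each transcript's per-base coverage from its assigned best alignments
    is rescaled onto ``n_bins`` positional bins; the mean across transcripts
    with at least one read is reported, normalized so the maximum bin is 1.
    """
    lens = _length_map(transcripts)
    df = read_metrics
    L = df["transcript_id"].map(lens).to_numpy(float)
    s = (df["dist5"].to_numpy(float)) * n_bins / L
    e = (L - df["dist3"].to_numpy(float)) * n_bins / L
    tcode, tids = pd.factorize(df["transcript_id"])
    n_t = len(tids)
    prof = np.zeros((n_t, n_bins))
    for k in range(n_bins):
        contrib = np.clip(np.minimum(e, k + 1) - np.maximum(s, k), 0.0, 1.0)
        prof[:, k] = np.bincount(tcode, weights=contrib, minlength=n_t)
    mean_prof = prof.mean(axis=0)
    peak = mean_prof.max()
    return mean_prof / peak if peak > 0 else mean_prof


def read_length_proportions(
    read_lengths: np.ndarray | Sequence[int], bin_width: int = 500
) -> pd.Series:
    """Proportion of reads per length bin (bins indexed by start; sums to 1)."""
    rl = np.asarray(read_lengths, dtype=np.int64)
    if rl.size == 0:
        raise ValueError("no reads")
    bins = (rl // bin_width) * bin_width
    props = pd.Series(bins).value_counts(normalize=True).sort_index()
    props.index.name = "bin_start"
    return props


def detection_by_length(
    counts: pd.Series,
    feature_lengths: Mapping[str, int] | pd.Series,
    bin_width: int = 1000,
) -> pd.DataFrame:
    """Detection rate (count >= 1) per feature-length bin.

    ``counts`` is indexed by feature id over the full annotated feature set
    (zeros included); the result has one row per length bin with annotated
    and detected feature numbers and their ratio.
    """
    lens = pd.Series(feature_lengths)
    lens = lens.reindex(counts.index)
    if lens.isna().any():
        raise ValueError("feature lengths missing for some counted features")
    bins = (lens // bin_width * bin_width).astype(int)
    df = pd.DataFrame({"bin_start": bins, "detected": counts.to_numpy() >= 1})
    g = df.groupby("bin_start").agg(
        annotated=("detected", "size"), detected=("detected", "sum")
    )
    g["rate"] = g["detected"] / g["annotated"]
    return g.reset_index()
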