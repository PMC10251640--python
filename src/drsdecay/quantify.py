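"""Feature counting and normalization for filtered DRS alignments.

Isoform quantification follows the NanoCount idea: after the 3'-end /
score filter, uniquely-aligned reads contribute weight 1 to their target
and multi-aligned reads are split across their surviving targets in
proportion to the current abundance estimates, iterated to convergence
(an EM for the multinomial mixture of isoforms).  Gene counts are sums of
isoform counts, or plain tallies of primary alignments in simple mode.
Size factors use the median-of-ratios method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import TranscriptModel

__all__ = [
    "em_quantify",
    "em_log_likelihood",
    "gene_counts",
    "primary_gene_counts",
    "build_count_matrix",
    "size_factors",
    "normalize_counts",
    "de_filter",
    "tpm_from_counts",
    "tpm_concordance",
    "ConcordanceResult",
]


def _em_arrays(aln: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.Index]:
    """Factorized (read, target) pairs sorted by read, with segment bounds."""
    df = aln.sort_values("read_id", kind="mergesort")
    rcode, _ = pd.factorize(df["read_id"])
    tcode, tids = pd.factorize(df["transcript_id"])
    bounds = np.flatnonzero(np.r_[True, np.diff(rcode) != 0])
    return rcode, tcode, bounds, tids


def em_quantify(
    aln: pd.DataFrame,
    transcripts: Sequence[TranscriptModel] | Mapping[str, int],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Expected isoform counts and TPM from filtered alignments (one sample).

    Returns a DataFrame indexed by transcript id with columns ``est_count``
    and ``tpm``; ``est_count`` sums to the number of quantified reads.
    TPM divides counts by annotated length (native RNA reads are whole
    molecules, not fragments, so no fragment-length correction applies).
    """
    if isinstance(transcripts, Mapping):
        lens = pd.Series(transcripts, dtype=float)
    else:
        lens = pd.Series({t.transcript_id: float(t.length) for t in transcripts})
    if aln.empty:
        warnings.warn("no quantifiable reads; returning empty column", stacklevel=2)
        return pd.DataFrame(columns=["est_count", "tpm"], dtype=float)

    rcode, tcode, bounds, tids = _em_arrays(aln)
    n_reads = bounds.size
    n_t = tids.size
    p = np.full(n_t, 1.0 / n_t)
    for _ in range(max_iter):
        pr = p[tcode]
        denom = np.add.reduceat(pr, bounds)
        w = pr / denom[rcode]
        counts = np.bincount(tcode, weights=w, minlength=n_t)
        p_new = counts / n_reads
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            break
    est = pd.Series(p * n_reads, index=tids, name="est_count")
    rate = est / lens.reindex(tids)
    tpm = 1e6 * rate / rate.sum()
    return pd.DataFrame({"est_count": est, "tpm": tpm})


def em_log_likelihood(aln: pd.DataFrame, abundance: pd.Series) -> float:
    """Multinomial-mixture log likelihood of an abundance vector (for
    monotonicity checks on small instances)."""
    rcode, tcode, bounds, tids = _em_arrays(aln)
    p = abundance.reindex(tids).to_numpy(float)
    denom = np.add.reduceat(p[tcode], bounds)
    return float(np.log(denom).sum())


def gene_counts(
    isoform_counts: pd.DataFrame | pd.Series,
    transcripts: Sequence[TranscriptModel],
) -> pd.DataFrame | pd.Series:
    """Sum isoform counts to gene level (isoforms without a gene are
    bucketed under 'unassigned')."""
    gmap = {t.transcript_id: t.gene_id for t in transcripts}
    idx = isoform_counts.index
    genes = idx.map(lambda t: gmap.get(t, "unassigned"))
    return isoform_counts.groupby(genes).sum()


def primary_gene_counts(
    aln: pd.DataFrame, transcripts: Sequence[TranscriptModel]
) -> pd.Series:
    """Simple-mode gene counts: tally of primary alignments per gene."""
    gmap = {t.transcript_id: t.gene_id for t in transcripts}
    prim = aln[aln["is_primary"]]
    genes = prim["transcript_id"].map(lambda t: gmap.get(t, "unassigned"))
    return genes.value_counts().sort_index()


def build_count_matrix(
    per_sample: Mapping[str, pd.Series], features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Assemble per-sample count Series into a features x samples matrix."""
    df = pd.DataFrame(per_sample)
    if features is not None:
        df = df.reindex(features)
    return df.fillna(0.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Follows the standard construction: per feature, counts are divided by
    the feature's geometric mean across samples; the per-sample median of
    these ratios (over features positive in all samples) is the factor.
    When no feature is positive everywhere, falls back to per-sample
    medians over that sample's positive features, with a warning.
    """
    c = counts.to_numpy(float)
    all_pos = (c > 0).all(axis=1)
    if all_pos.any():
        logc = np.log(c[all_pos])
        loggeo = logc.mean(axis=1)
        ratios = logc - loggeo[:, None]
        logsf = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no feature has positive counts in all samples; falling back to "
            "positive-count median-of-ratios",
            stacklevel=2,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            logc = np.where(c > 0, np.log(np.where(c > 0, c, 1.0)), np.nan)
        loggeo = np.nanmean(logc, axis=1)
        ratios = logc - loggeo[:, None]
        logsf = np.nanmedian(ratios, axis=0)
    logsf = logsf - logsf.mean()  # rescale to geometric mean 1
    return pd.Series(np.exp(logsf), index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts.div(sf, axis=1)


def de_filter(
    normalized: pd.DataFrame, min_count: float = 10.0, min_samples: int = 5
) -> pd.Series:
    """Features considered for DE: >= ``min_count`` normalized counts in at
    least ``min_samples`` samples (boundaries inclusive)."""
    return (normalized >= min_count).sum(axis=1) >= min_samples


def tpm_from_counts(
    counts: pd.Series | pd.DataFrame, lengths: pd.Series
) -> pd.Series | pd.DataFrame:
    """TPM with effective length = annotated length."""
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    return 1e6 * rate / rate.sum()


@dataclass
class ConcordanceResult:
    pearson_r: float
    spearman_rho: float
    slope: float
    n: int


def tpm_concordance(tpm_a: pd.Series, tpm_b: pd.Series) -> ConcordanceResult:
    """Cross-sample TPM concordance on log10(TPM + 1), over features
    detected (TPM > 0) in either sample."""
    common = tpm_a.index.intersection(tpm_b.index)
    a, b = tpm_a.reindex(common), tpm_b.reindex(common)
    mask = (a > 0) | (b > 0)
    x = np.log10(a[mask].to_numpy() + 1.0)
    y = np.log10(b[mask].to_numpy() + 1.0)
    fit = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    return ConcordanceResult(
        pearson_r=float(stats.pearsonr(x, y).statistic),
        spearman_rho=float(rho),
        slope=float(fit.slope),
        n=int(mask.sum()),
    )
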