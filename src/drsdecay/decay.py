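"""Degradation-trajectory clustering, decay fitting and architecture tests.

Features are clustered (K-means, k=4) on their per-time log2 fold changes
versus 0 h; the cluster with the smallest mean |log2FC| centroid is the
"stable" class and its centroid is subtracted from every trajectory.  This
stable-centroid normalization removes the compositional drift that makes
stable features appear upregulated as the rest of the library degrades.
Features that vanish by the final time point are called "undetectable"
under three criteria (early presence, terminal absence, exponential-decay
fit quality), and cluster membership is associated with gene/isoform
architecture (GC, UTR/CDS/total lengths) by one-way ANOVA with Tukey HSD
and eta-squared effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .core_io import SampleInfo, TranscriptModel

__all__ = [
    "ClusterResult",
    "DecayFit",
    "ArchitectureTest",
    "CLUSTER_LABELS",
    "cluster_trajectories",
    "centroid_normalize",
    "call_undetectable",
    "architecture_anova",
    "feature_architecture",
]

CLUSTER_LABELS = ("up", "stable", "slow", "fast")


@dataclass
class ClusterResult:
    """K-means degradation classes.

    ``labels`` maps feature -> {up, stable, slow, fast}; ``centroids`` is a
    4 x timepoints frame indexed by those labels.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    inertia: float

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(list(CLUSTER_LABELS), fill_value=0)


def _assign_cluster_names(centroids: np.ndarray) -> list[str]:
    """Name raw K-means clusters by their centroid shapes.

    stable = smallest mean |log2FC|; among the rest, up = largest and
    fast = smallest final-time value; the remaining cluster is slow.
    """
    k = centroids.shape[0]
    if k != 4:
        raise ValueError("expected exactly 4 clusters")
    stable = int(np.argmin(np.abs(centroids).mean(axis=1)))
    rest = [i for i in range(k) if i != stable]
    finals = centroids[rest, -1]
    up = rest[int(np.argmax(finals))]
    fast = rest[int(np.argmin(finals))]
    if up == fast:  # degenerate tie; keep deterministic order
        up, fast = rest[0], rest[-1]
    slow = next(i for i in rest if i not in (up, fast))
    names = [""] * k
    names[up], names[stable], names[slow], names[fast] = CLUSTER_LABELS
    return names


def cluster_trajectories(
    lfc: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 25,
    max_iter: int = 100,
) -> ClusterResult:
    """K-means on log2FC trajectories (features x non-reference times).

    Runs ``n_restarts`` seeded restarts of at most ``max_iter`` iterations,
    keeps the lowest within-cluster sum of squares, and names the clusters
    from their centroids.  Raises for fewer than k distinct trajectories.
    """
    if lfc.isna().any().any():
        raise ValueError("trajectories contain missing values; exclude "
                         "features with untested contrasts first")
    X = lfc.to_numpy(float)
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(
            f"need at least {k} distinct trajectories to form {k} clusters"
        )
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
    ).fit(X)
    names = _assign_cluster_names(km.cluster_centers_)
    labels = pd.Series(
        [names[c] for c in km.labels_], index=lfc.index, name="cluster"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_, index=pd.Index(names, name="cluster"), columns=lfc.columns
    ).loc[list(CLUSTER_LABELS)]
    return ClusterResult(labels=labels, centroids=centroids, inertia=float(km.inertia_))


def centroid_normalize(lfc: pd.DataFrame, clusters: ClusterResult) -> pd.DataFrame:
    """Subtract the stable-cluster centroid from every trajectory."""
    stable = clusters.centroids.loc["stable"]
    return lfc.sub(stable, axis=1)


# ---------------------------------------------------------------------------
# Undetectable features and decay fits
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    feature_id: str
    y0: float | None
    k_decay: float | None
    pearson_r_fit: float | None
    fit_ok: bool
    undetectable: bool


def _exp_decay(t: np.ndarray, y0: float, k: float) -> np.ndarray:
    return y0 * np.exp(-k * t)


def call_undetectable(
    normalized: pd.DataFrame,
    samples: Sequence[SampleInfo] | pd.DataFrame,
    min_early_count: float = 5.0,
    n_early_required: int = 4,
    r_threshold: float = 0.5,
    r_mode: str = "fitted",
) -> pd.DataFrame:
    """Flag features that can no longer be detected at the final time point.

    Criteria (all required):

    1. >= ``min_early_count`` normalized counts in at least
       ``n_early_required`` of the first five samples (the samples at the
       two earliest time points; if the design does not give exactly five,
       the earliest five samples by time are used);
    2. zero normalized counts in every sample at the final time point;
    3. an exponential decay fit ``y(t) = y0 * exp(-k t)`` (nonlinear least
       squares, initialized from a log-linear regression on the positive
       counts) with Pearson r >= ``r_threshold``.  ``r_mode='fitted'``
       correlates observed with fitted values; ``r_mode='time'`` correlates
       counts with time.

    Returns a per-feature frame with the criterion flags and fit
    parameters; fit non-convergence fails criterion 3 and is flagged.
    """
    if r_mode not in ("fitted", "time"):
        raise ValueError("r_mode must be 'fitted' or 'time'")
    from .de import _samples_frame

    sm = _samples_frame(samples)
    order = sm.sort_values(["time_h", "sample_id"], kind="mergesort")
    times_sorted = sorted(order["time_h"].unique())
    early_two = order[order["time_h"].isin(times_sorted[:2])]["sample_id"]
    early = (
        early_two if len(early_two) == 5 else order["sample_id"].head(5)
    ).tolist()
    final = order.loc[order["time_h"] == times_sorted[-1], "sample_id"].tolist()

    t_all = sm.set_index("sample_id")["time_h"].reindex(normalized.columns).to_numpy()
    rows = []
    early_ok = (normalized[early] >= min_early_count).sum(axis=1) >= n_early_required
    late_zero = (normalized[final] == 0).all(axis=1)
    for fid in normalized.index:
        e_ok = bool(early_ok[fid])
        l_ok = bool(late_zero[fid])
        y0 = k = r = None
        fit_ok = False
        if e_ok and l_ok:
            y = normalized.loc[fid].to_numpy(float)
            pos = y > 0
            if pos.sum() >= 2:
                slope, intercept = np.polyfit(t_all[pos], np.log(y[pos]), 1)
                p0 = (float(np.exp(intercept)), float(max(-slope, 1e-3)))
            else:
                p0 = (float(max(y.max(), 1.0)), 0.5)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(
                        _exp_decay,
                        t_all,
                        y,
                        p0=p0,
                        bounds=([0.0, 0.0], [np.inf, np.inf]),
                        maxfev=2000,
                    )
                y0, k = float(popt[0]), float(popt[1])
                fitted = _exp_decay(t_all, y0, k)
                if r_mode == "fitted":
                    r = float(stats.pearsonr(y, fitted).statistic)
                else:
                    r = float(stats.pearsonr(y, t_all).statistic)
                fit_ok = np.isfinite(r)
            except (RuntimeError, ValueError):
                fit_ok = False
        rows.append(
            {
                "feature": fid,
                "early_ok": e_ok,
                "late_zero": l_ok,
                "y0": y0,
                "k_decay": k,
                "r_fit": r,
                "fit_ok": fit_ok,
                "undetectable": bool(
                    e_ok and l_ok and fit_ok and r is not None and r >= r_threshold
                ),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Architecture association
# ---------------------------------------------------------------------------

ARCHITECTURE_METRICS = ("gc_frac", "utr5_len", "utr3_len", "cds_len", "total_len")


def feature_architecture(
    transcripts: Sequence[TranscriptModel], by_gene: bool = False
) -> pd.DataFrame:
    """Per-feature architecture table (GC, UTR/CDS lengths, total length).

    With ``by_gene`` the representative transcript of each gene is its
    longest isoform.
    """
    rows = {}
    for t in transcripts:
        key = t.gene_id if by_gene else t.transcript_id
        if by_gene and key in rows and rows[key]["total_len"] >= t.length:
            continue
        rows[key] = {
            "gc_frac": t.gc_frac,
            "utr5_len": t.utr5_len,
            "utr3_len": t.utr3_len,
            "cds_len": t.cds_len,
            "total_len": t.length,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature")


@dataclass
class ArchitectureTest:
    metric: str
    f_statistic: float
    p_value: float
    eta_squared: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, flagged
    group_means: pd.Series


def architecture_anova(
    clusters: ClusterResult,
    architecture: pd.DataFrame,
    metrics: Sequence[str] = ARCHITECTURE_METRICS,
) -> dict[str, ArchitectureTest]:
    """One-way ANOVA of each architecture metric across the 4 clusters.

    Outliers are included.  Eta-squared = SS_between / SS_total.  Tukey HSD
    p-values cover all 6 cluster pairs; pairs involving a cluster with < 2
    members are flagged.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    common = clusters.labels.index.intersection(architecture.index)
    labels = clusters.labels.reindex(common)
    out: dict[str, ArchitectureTest] = {}
    for metric in metrics:
        if metric not in architecture.columns:
            continue
        vals = architecture.loc[common, metric].astype(float)
        ok = vals.notna()
        if not ok.any():
            warnings.warn(
                f"{metric}: no values available (e.g. GC without a FASTA); "
                "metric skipped",
                stacklevel=2,
            )
            continue
        v, g = vals[ok], labels[ok]
        groups = [v[g == lab].to_numpy() for lab in CLUSTER_LABELS if (g == lab).any()]
        if len(groups) < 2:
            raise ValueError(f"{metric}: fewer than two non-empty clusters")
        f_stat, p = stats.f_oneway(*groups)
        grand = v.mean()
        ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
        ss_total = float(((v - grand) ** 2).sum())
        eta2 = ss_between / ss_total if ss_total > 0 else 0.0
        small = {lab for lab in CLUSTER_LABELS if (g == lab).sum() < 2}
        if small:
            warnings.warn(
                f"{metric}: clusters with <2 members: {sorted(small)}; "
                "Tukey pairs involving them are flagged",
                stacklevel=2,
            )
        res = pairwise_tukeyhsd(v.to_numpy(), g.to_numpy())
        tukey = pd.DataFrame(
            res.summary().data[1:],
            columns=[str(c) for c in res.summary().data[0]],
        )[["group1", "group2", "meandiff", "p-adj"]].rename(
            columns={"p-adj": "p_adj"}
        )
        tukey["flagged"] = tukey.apply(
            lambda r: r["group1"] in small or r["group2"] in small, axis=1
        )
        out[metric] = ArchitectureTest(
            metric=metric,
            f_statistic=float(f_stat),
            p_value=float(p),
            eta_squared=float(eta2),
            tukey=tukey,
            group_means=v.groupby(g).mean(),
        )
    return out
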