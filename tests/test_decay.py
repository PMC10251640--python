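"""decay_analysis: trajectory clustering, normalization, undetectable
feature calling and architecture association."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import drsdecay as dd
from drsdecay.core_io import SampleInfo
from drsdecay.decay import (
    CLUSTER_LABELS,
    architecture_anova,
    call_undetectable,
    centroid_normalize,
    cluster_trajectories,
    feature_architecture,
)

TIMES = [0.5, 1.0, 4.0, 6.0, 8.0]


def planted_lfc(n_per_class=40, noise=0.05, seed=0):
    """Four archetypes: flat 0; rising to +2; falling to -1; falling to -4."""
    rng = np.random.default_rng(seed)
    t = np.array(TIMES)
    shapes = {
        "stable": np.zeros(5),
        "up": 2.0 * t / t[-1],
        "slow": -1.0 * t / t[-1],
        "fast": -4.0 * t / t[-1],
    }
    rows, truth = [], []
    for label, base in shapes.items():
        for i in range(n_per_class):
            rows.append(base + rng.normal(0, noise, 5))
            truth.append(label)
    idx = [f"f{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx, columns=TIMES), pd.Series(truth, index=idx)


class TestClustering:
    def test_planted_archetypes_recovered(self):
        lfc, truth = planted_lfc()
        cl = cluster_trajectories(lfc, seed=0)
        assert adjusted_rand_score(truth, cl.labels.reindex(truth.index)) == 1.0
        # labels match the archetype semantics, not just the partition
        assert (cl.labels == truth).all()

    def test_identical_trajectories_rejected(self):
        lfc = pd.DataFrame(np.ones((10, 5)), columns=TIMES)
        with pytest.raises(ValueError, match="distinct"):
            cluster_trajectories(lfc)

    def test_missing_values_rejected(self):
        lfc, _ = planted_lfc(n_per_class=5)
        lfc.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cluster_trajectories(lfc)

    def test_same_seed_same_labels(self):
        lfc, _ = planted_lfc(noise=0.8, seed=3)
        a = cluster_trajectories(lfc, seed=11)
        b = cluster_trajectories(lfc, seed=11)
        assert (a.labels == b.labels).all()

    def test_sizes_sum_to_features(self):
        lfc, _ = planted_lfc()
        cl = cluster_trajectories(lfc, seed=0)
        assert cl.sizes().sum() == len(lfc)
        assert set(cl.centroids.index) == set(CLUSTER_LABELS)


class TestCentroidNormalize:
    def test_feature_equal_to_centroid_goes_to_zero(self):
        lfc, _ = planted_lfc(noise=0.0)
        cl = cluster_trajectories(lfc, seed=0)
        norm = centroid_normalize(lfc, cl)
        stable_rows = norm.loc[cl.labels == "stable"]
        assert np.allclose(stable_rows, 0.0, atol=1e-12)

    def test_plain_subtraction(self):
        lfc, _ = planted_lfc(noise=0.0)
        cl = cluster_trajectories(lfc, seed=0)
        # shift the stable centroid artificially and check the arithmetic
        cl.centroids.loc["stable"] = [0.5, 1.0, 0.5, 1.0, 0.5]
        norm = centroid_normalize(lfc, cl)
        zero_row = norm.loc[(lfc == 0).all(axis=1)].iloc[0]
        assert np.allclose(zero_row, [-0.5, -1.0, -0.5, -1.0, -0.5])

    @given(st.lists(st.floats(-0.3, 0.3), min_size=5, max_size=5))
    @settings(derandomize=True, max_examples=25)
    def test_invariance_to_common_shift(self, shift):
        # adding a shared compositional drift c(t) to every trajectory must
        # not change the normalized trajectories (the point of the
        # normalization); drifts are bounded so that the stable archetype
        # remains the smallest-|centroid| cluster
        lfc, _ = planted_lfc(n_per_class=10, seed=4)
        shifted = lfc.add(pd.Series(shift, index=lfc.columns), axis=1)
        cl = cluster_trajectories(lfc, seed=0)
        cl_s = cluster_trajectories(shifted, seed=0)
        a = centroid_normalize(lfc, cl)
        b = centroid_normalize(shifted, cl_s)
        # compare per-feature regardless of any label permutation
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)


def _samples_for_counts(columns):
    times = {"t0": 0.0, "t0.5": 0.5, "t1": 1.0, "t4": 4.0, "t6": 6.0, "t8": 8.0}
    out = []
    for c in columns:
        stem = c.rsplit("_", 1)[0]
        out.append(SampleInfo(c, times[stem], 9.0, batch="B1"))
    return out


class TestCallUndetectable:
    def _counts(self, early, late, mid=None):
        cols = [
            "t0_r1", "t0_r2", "t0_r3", "t0.5_r1", "t0.5_r2",
            "t1_r1", "t1_r2", "t4_r1", "t4_r2", "t4_r3",
            "t6_r1", "t6_r2", "t6_r3", "t8_r1", "t8_r2",
        ]
        mid = mid if mid is not None else [4.0, 4.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0]
        vals = list(early) + mid + list(late)
        return pd.DataFrame([vals], columns=cols, index=["f"]), _samples_for_counts(cols)

    def test_clean_exponential_is_flagged(self):
        counts, samples = self._counts([8, 8, 8, 8, 8], [0, 0])
        out = call_undetectable(counts, samples)
        assert bool(out.loc["f", "undetectable"])
        assert out.loc["f", "r_fit"] > 0.95
        assert out.loc["f", "k_decay"] > 0

    def test_insufficient_early_counts(self):
        counts, samples = self._counts([8, 8, 8, 2, 2], [0, 0])
        out = call_undetectable(counts, samples)
        assert not bool(out.loc["f", "early_ok"])
        assert not bool(out.loc["f", "undetectable"])

    def test_single_late_read_disqualifies(self):
        counts, samples = self._counts([8, 8, 8, 8, 8], [1, 0])
        out = call_undetectable(counts, samples)
        assert not bool(out.loc["f", "late_zero"])
        assert not bool(out.loc["f", "undetectable"])

    def test_poor_fit_correlation_disqualifies(self):
        # early presence and terminal absence but an erratic trajectory
        counts, samples = self._counts(
            [8, 8, 8, 8, 8], [0, 0], mid=[0.0, 0.0, 30.0, 0.0, 30.0, 0.0, 30.0, 0.0]
        )
        out = call_undetectable(counts, samples)
        assert bool(out.loc["f", "early_ok"]) and bool(out.loc["f", "late_zero"])
        assert not bool(out.loc["f", "undetectable"])

    def test_intact_series_flags_nothing(self):
        txome = dd.simulate_transcriptome(80, seed=17)
        cfg = dd.SimConfig(lambda_cleave=0.0, n_reads_per_sample=4000, seed=17)
        res = dd.simulate_experiment(cfg, txome)
        from drsdecay.quantify import build_count_matrix, normalize_counts, primary_gene_counts

        cols = {
            s.sample_id: primary_gene_counts(
                res.alignments[s.sample_id], res.transcriptome.transcripts
            )
            for s in res.samples
        }
        norm = normalize_counts(build_count_matrix(cols))
        out = call_undetectable(norm, res.samples)
        assert int(out["undetectable"].sum()) == 0


def brute_anova(groups):
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ((allv - grand) ** 2).sum()
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, ss_between / ss_total, ss_between + ss_within - ss_total


class TestArchitectureAnova:
    def _cluster(self, labels, index):
        from drsdecay.decay import ClusterResult

        return ClusterResult(
            labels=pd.Series(labels, index=index),
            centroids=pd.DataFrame(
                np.zeros((4, 2)), index=list(CLUSTER_LABELS), columns=[4.0, 8.0]
            ),
            inertia=0.0,
        )

    def test_identical_groups_give_zero_f(self):
        idx = [f"f{i}" for i in range(12)]
        labels = [lab for lab in CLUSTER_LABELS for _ in range(3)]
        arch = pd.DataFrame({"total_len": [1, 2, 3] * 4}, index=idx)
        out = architecture_anova(self._cluster(labels, idx), arch, metrics=["total_len"])
        assert out["total_len"].f_statistic == pytest.approx(0.0, abs=1e-12)
        assert out["total_len"].eta_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(2)
        idx = [f"f{i}" for i in range(40)]
        labels = [CLUSTER_LABELS[i % 4] for i in range(40)]
        vals = rng.normal(100, 20, 40) + np.array(
            [{"up": 0, "stable": 5, "slow": 10, "fast": 30}[l] for l in labels]
        )
        arch = pd.DataFrame({"gc_frac": vals}, index=idx)
        out = architecture_anova(self._cluster(labels, idx), arch, metrics=["gc_frac"])
        groups = [vals[np.array(labels) == lab] for lab in CLUSTER_LABELS]
        F, eta2, resid = brute_anova(groups)
        assert out["gc_frac"].f_statistic == pytest.approx(F, abs=1e-10)
        assert out["gc_frac"].eta_squared == pytest.approx(eta2, abs=1e-10)
        assert abs(resid) < 1e-9  # SS_between + SS_within == SS_total
        assert len(out["gc_frac"].tukey) == 6

    def test_null_groups_have_small_effect(self):
        rng = np.random.default_rng(3)
        n = 2000
        idx = [f"f{i}" for i in range(n)]
        labels = [CLUSTER_LABELS[i % 4] for i in range(n)]
        arch = pd.DataFrame({"utr3_len": rng.normal(500, 100, n)}, index=idx)
        out = architecture_anova(self._cluster(labels, idx), arch, metrics=["utr3_len"])
        assert out["utr3_len"].eta_squared < 0.01

    def test_tiny_cluster_flagged(self):
        idx = [f"f{i}" for i in range(10)]
        labels = ["up"] + ["stable"] * 3 + ["slow"] * 3 + ["fast"] * 3
        arch = pd.DataFrame({"cds_len": np.arange(10.0)}, index=idx)
        with pytest.warns(UserWarning, match="<2 members"):
            out = architecture_anova(
                self._cluster(labels, idx), arch, metrics=["cds_len"]
            )
        tk = out["cds_len"].tukey
        assert tk.loc[(tk["group1"] == "up") | (tk["group2"] == "up"), "flagged"].all()


@pytest.fixture(scope="module")
def pipeline(default_sim, default_gene_counts):
    from drsdecay.de import DegradationDEModel

    m = DegradationDEModel(default_gene_counts, default_sim.samples)
    r = m.fit()
    lfc = r.lfc_matrix()
    spikes = {t.gene_id for t in default_sim.transcriptome.transcripts if t.is_spikein}
    lfc = lfc.loc[[f for f in lfc.index if f not in spikes]]
    cl = cluster_trajectories(lfc, seed=0)
    return default_sim, lfc, cl


class TestEndToEndDecay:
    def test_fast_cluster_architecture_directionality(self, pipeline):
        """The simulator plants GC-dependent fragility on top of the
        3'-anchored length dependence, so the fast cluster must sit at
        lower GC and longer 3' UTRs than the stable cluster."""
        sim, lfc, cl = pipeline
        arch = feature_architecture(
            [t for t in sim.transcriptome.transcripts if not t.is_spikein],
            by_gene=True,
        )
        tests = architecture_anova(cl, arch)
        gm_gc = tests["gc_frac"].group_means
        gm_u3 = tests["utr3_len"].group_means
        gm_len = tests["total_len"].group_means
        assert gm_gc["fast"] < gm_gc["stable"]
        assert gm_u3["fast"] > gm_u3["stable"]
        assert gm_len["fast"] > gm_len["stable"]

    def test_stable_centroid_near_zero_after_normalization(self, pipeline):
        _, lfc, cl = pipeline
        norm = centroid_normalize(lfc, cl)
        stable_mean = norm.loc[cl.labels == "stable"].mean()
        assert (stable_mean.abs() < 0.15).all()
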