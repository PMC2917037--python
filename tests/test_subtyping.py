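"""Tests for region matrices, clustering, supervised tests, and centroids."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cnakit import gistic as gs
from cnakit import simulate as sim
from cnakit import subtyping as st
from cnakit.io import ExpressionMatrix
from cnakit.segmentation import STATE_GAIN, CallCohort, SegmentedCohort, call_cohort, segment_cohort

from conftest import make_probe_map


def region_table(pm, specs):
    """specs: list of (kind, chrom, wide_probe_span, peak_probe_span)."""
    t = pm.table
    regions = []
    for kind, chrom, wide, peak in specs:
        regions.append(
            gs.GisticRegion(
                kind=kind,
                chrom=chrom,
                wide_start=int(t["start"].iloc[wide[0]]),
                wide_end=int(t["end"].iloc[wide[-1]]),
                peak_start=int(t["start"].iloc[peak[0]]),
                peak_end=int(t["end"].iloc[peak[-1]]),
                peak_probes=tuple(peak),
                wide_probes=tuple(wide),
                gscore=1.0,
                qvalue=0.01,
                frequency=0.2,
            )
        )
    return gs.GisticRegionTable(regions, pm)


def make_seg(pm, values, samples):
    df = pd.DataFrame(values, index=pm.probe_ids, columns=samples)
    sizes = pd.DataFrame(
        np.full(df.shape, len(pm), dtype=int), index=df.index, columns=df.columns
    )
    return SegmentedCohort(df, sizes, [], pm)


def make_matrix(values, samples):
    """RegionSampleMatrix directly from a regions x samples array."""
    df = pd.DataFrame(values, columns=samples)
    return st.RegionSampleMatrix(df, df, df.mean(axis=1), df.std(axis=1, ddof=0))


class TestBuildRegionMatrix:
    def test_raw_mean_before_scaling(self):
        pm = make_probe_map({"chr1": 10}, spacing=50_000, width=30_000)
        vals = np.zeros((10, 3))
        vals[2, 0], vals[3, 0] = 0.2, 0.4
        seg = make_seg(pm, vals, ["S1", "S2", "S3"])
        table = region_table(pm, [("gain", "chr1", range(2, 4), range(2, 4))])
        mat = st.build_region_matrix(table, seg)
        assert mat.raw.loc[0, "S1"] == pytest.approx(0.3)

    def test_scaled_rows_mean_zero_sd_one(self):
        pm = make_probe_map({"chr1": 20}, spacing=50_000, width=30_000)
        rng = np.random.default_rng(0)
        seg = make_seg(pm, rng.normal(0, 0.4, (20, 8)), [f"S{i}" for i in range(8)])
        table = region_table(
            pm, [("gain", "chr1", range(0, 5), range(1, 3)), ("loss", "chr1", range(10, 16), range(12, 14))]
        )
        mat = st.build_region_matrix(table, seg)
        z = mat.values.to_numpy()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_constant_region_emitted_as_zeros(self, caplog):
        pm = make_probe_map({"chr1": 10}, spacing=50_000, width=30_000)
        seg = make_seg(pm, np.ones((10, 4)), [f"S{i}" for i in range(4)])
        table = region_table(pm, [("gain", "chr1", range(0, 4), range(1, 3))])
        with caplog.at_level("INFO", logger="cnakit.subtyping"):
            mat = st.build_region_matrix(table, seg)
        assert np.allclose(mat.values.to_numpy(), 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_empty_region_table_rejected(self):
        pm = make_probe_map({"chr1": 10}, spacing=50_000, width=30_000)
        seg = make_seg(pm, np.zeros((10, 2)), ["S1", "S2"])
        with pytest.raises(st.SubtypingError):
            st.build_region_matrix(gs.GisticRegionTable([], pm), seg)


class TestClusterSubtypes:
    def two_class_matrix(self, n_per=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        a = np.array([2.0, 0.0, 2.0, 0.0, 1.0, -1.0, 0.5, -0.5])
        b = np.array([0.0, 2.0, -1.0, 1.0, -2.0, 0.0, -0.5, 0.5])
        cols, truth = [], []
        for i in range(n_per):
            cols.append(a + rng.normal(0, noise, len(a)))
            truth.append("A")
        for i in range(n_per):
            cols.append(b + rng.normal(0, noise, len(b)))
            truth.append("B")
        samples = [f"S{i}" for i in range(2 * n_per)]
        return make_matrix(np.array(cols).T, samples), pd.Series(truth, index=samples)

    def test_two_noise_free_archetypes_perfect_partition(self):
        mat, truth = self.two_class_matrix(noise=0.0)
        assign = st.cluster_subtypes(mat, k=2)
        assert adjusted_rand_score(truth, assign.labels) == 1.0

    def test_affine_invariance_per_sample(self):
        mat, truth = self.two_class_matrix(noise=0.3, seed=3)
        rng = np.random.default_rng(1)
        x = mat.values.to_numpy()
        scaled = x * rng.uniform(0.5, 3.0, x.shape[1]) + rng.normal(0, 5, x.shape[1])
        mat2 = make_matrix(scaled, list(mat.values.columns))
        a = st.cluster_subtypes(mat, k=2)
        b = st.cluster_subtypes(mat2, k=2)
        assert adjusted_rand_score(a.labels, b.labels) == 1.0

    def test_affine_copy_joins_same_cluster(self):
        mat, _ = self.two_class_matrix(noise=0.2, seed=5)
        vals = mat.values.copy()
        vals["COPY"] = 2.0 * vals["S0"] + 3.0  # d(x, 2x+3) = 0
        mat2 = make_matrix(vals.to_numpy(), list(vals.columns))
        assign = st.cluster_subtypes(mat2, k=2)
        assert assign.labels["COPY"] == assign.labels["S0"]

    def test_zero_variance_sample_error_names_sample(self):
        mat, _ = self.two_class_matrix()
        vals = mat.values.copy()
        vals["FLAT"] = 1.0
        mat2 = make_matrix(vals.to_numpy(), list(vals.columns))
        with pytest.raises(st.SubtypingError, match="FLAT"):
            st.cluster_subtypes(mat2, k=2)

    def test_k_bounds(self):
        mat, _ = self.two_class_matrix(n_per=3)
        with pytest.raises(st.SubtypingError):
            st.cluster_subtypes(mat, k=1)
        with pytest.raises(st.SubtypingError):
            st.cluster_subtypes(mat, k=7)

    def test_default_cohort_ari(self):
        """Default 6-archetype cohort, n=120, noise sd 0.1: ARI >= 0.9."""
        cfg = sim.GeneratorConfig(n_samples=120, noise_sd=0.1, n_probes=2500)
        pm, cn, expr, clin, truth = sim.generate_cohort(cfg, seed=13)
        seg = segment_cohort(cn, seed=13)
        calls = call_cohort(cn, seg)
        regions = gs.run_gistic(seg, calls, n_perm=200, seed=13)
        mat = st.build_region_matrix(regions, seg)
        assign = st.cluster_subtypes(mat, k=6)
        assert adjusted_rand_score(truth.subtypes, assign.labels) >= 0.9


class TestNameClustersByTemplate:
    def test_matching_maximizes_profile_correlation(self):
        pm = make_probe_map({"chr1": 30}, spacing=50_000, width=30_000)
        prof_a = np.zeros(30)
        prof_a[5:12] = 0.6
        prof_b = np.zeros(30)
        prof_b[18:25] = -0.5
        rng = np.random.default_rng(0)
        cols = {}
        for i in range(4):
            cols[f"A{i}"] = prof_a + rng.normal(0, 0.05, 30)
        for i in range(4):
            cols[f"B{i}"] = prof_b + rng.normal(0, 0.05, 30)
        seg = make_seg(pm, np.array(list(cols.values())).T, list(cols))
        labels = pd.Series(
            ["cluster_1"] * 4 + ["cluster_2"] * 4,
            index=pd.Index(list(cols), name="sample_id"),
        )
        assign = st.SubtypeAssignment(labels, np.zeros((0, 4)), 2)
        templates = pd.DataFrame({"alpha": prof_a, "beta": prof_b}, index=pm.probe_ids)
        named = st.name_clusters_by_template(assign, seg, templates)
        assert named.name_map == {"cluster_1": "alpha", "cluster_2": "beta"}
        assert set(named.labels.unique()) == {"alpha", "beta"}


class TestSupervisedRegionTests:
    def build(self, delta=1.0, sd=0.2, n_regions=100, freq_a=1.0, freq_b=0.0, seed=0):
        n_a = n_b = 20
        samples = [f"S{i}" for i in range(n_a + n_b)]
        pm = make_probe_map({"chr1": n_regions}, spacing=50_000, width=30_000)
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1.0, (n_regions, n_a + n_b))
        vals[0, :n_a] = rng.normal(delta, sd, n_a)
        vals[0, n_a:] = rng.normal(0.0, sd, n_b)
        mat = make_matrix(vals, samples)
        table = region_table(
            pm, [("gain", "chr1", range(k, k + 1), range(k, k + 1)) for k in range(n_regions)]
        )
        states = np.zeros((n_regions, n_a + n_b), dtype=np.int8)
        states[0, : int(freq_a * n_a)] = STATE_GAIN
        states[0, n_a : n_a + int(freq_b * n_b)] = STATE_GAIN
        calls = CallCohort(
            pd.DataFrame(states, index=pm.probe_ids, columns=samples),
            pd.DataFrame(False, index=pm.probe_ids, columns=samples),
            pd.DataFrame(True, index=pm.probe_ids, columns=samples),
            pd.DataFrame({"tau_gain": 0.1, "tau_loss": -0.1}, index=samples),
            pm,
        )
        groups = pd.Series(["a"] * n_a + ["b"] * n_b, index=samples)
        return mat, table, groups, calls

    def test_identical_groups_empty_table(self):
        mat, table, groups, calls = self.build(delta=0.0)
        vals = mat.values.copy()
        vals.iloc[:, 20:] = vals.iloc[:, :20].to_numpy()  # group b == group a
        mat2 = st.RegionSampleMatrix(vals, vals, vals.mean(axis=1), vals.std(axis=1, ddof=0))
        out = st.supervised_region_tests(mat2, table, groups, calls)
        assert out.empty

    def test_planted_differential_region_retained(self):
        mat, table, groups, calls = self.build(delta=1.0, sd=0.2)
        out = st.supervised_region_tests(mat, table, groups, calls)
        assert list(out["region"]) == [0]
        assert out.loc[0, "p_bonferroni"] < 0.05
        assert out.loc[0, "more_aberrant_group"] == "a"

    def test_low_frequency_region_excluded(self):
        mat, table, groups, calls = self.build(delta=1.0, sd=0.2, freq_a=0.1, freq_b=0.1)
        out = st.supervised_region_tests(mat, table, groups, calls, freq_cut=0.2)
        assert out.empty

    def test_group_validation(self):
        mat, table, groups, calls = self.build()
        with pytest.raises(st.SubtypingError):
            st.supervised_region_tests(mat, table, groups.map({"a": "x", "b": "x"}), calls)


def make_expr(values_by_sample, genes):
    vals = pd.DataFrame(values_by_sample)
    vals.index = pd.Index(genes, name="gene_id")
    meta = pd.DataFrame(
        {
            "gene_id": genes,
            "chrom": "chr1",
            "start": np.arange(len(genes)) * 1000 + 1,
            "end": np.arange(len(genes)) * 1000 + 500,
        },
        index=vals.index,
    )
    return ExpressionMatrix(vals, meta)


class TestCentroids:
    def test_single_sample_centroid_equals_sample(self):
        genes = [f"G{i}" for i in range(6)]
        expr = make_expr({"S1": np.arange(6.0)}, genes)
        labels = pd.Series(["alpha"], index=pd.Index(["S1"], name="sample_id"))
        assign = st.SubtypeAssignment(labels, np.zeros((0, 4)), 2)
        cents = st.build_centroids(expr, assign, genes)
        assert np.allclose(cents["alpha"], np.arange(6.0))

    def test_mean_of_two_samples(self):
        genes = ["G0"]
        expr = make_expr({"S1": [1.0], "S2": [3.0]}, genes)
        labels = pd.Series(["alpha", "alpha"], index=pd.Index(["S1", "S2"], name="sample_id"))
        assign = st.SubtypeAssignment(labels, np.zeros((0, 4)), 2)
        cents = st.build_centroids(expr, assign, genes)
        assert cents.loc["G0", "alpha"] == pytest.approx(2.0)

    def test_missing_gene_dropped_symmetrically(self):
        genes = [f"G{i}" for i in range(5)]
        expr = make_expr({"S1": np.ones(5), "S2": np.zeros(5)}, genes)
        labels = pd.Series(["a", "b"], index=pd.Index(["S1", "S2"], name="sample_id"))
        assign = st.SubtypeAssignment(labels, np.zeros((0, 4)), 2)
        cents = st.build_centroids(expr, assign, genes + ["ABSENT"])
        assert list(cents.index) == genes
        assert set(cents.columns) == {"a", "b"}

    def test_no_listed_genes_rejected(self):
        expr = make_expr({"S1": [1.0]}, ["G0"])
        labels = pd.Series(["a"], index=pd.Index(["S1"], name="sample_id"))
        assign = st.SubtypeAssignment(labels, np.zeros((0, 4)), 2)
        with pytest.raises(st.SubtypingError):
            st.build_centroids(expr, assign, ["MISSING"])


class TestClassifyByCentroid:
    def centroids(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(10)]
        return pd.DataFrame(
            {"alpha": rng.normal(0, 1, 10), "beta": rng.normal(0, 1, 10)}, index=genes
        )

    def test_sample_equal_to_centroid(self):
        cents = self.centroids()
        label, corrs = st.classify_by_centroid(cents["alpha"], cents)
        assert label == "alpha"
        assert corrs["alpha"] == pytest.approx(1.0)

    def test_tie_broken_by_declared_order(self, caplog):
        genes = [f"G{i}" for i in range(6)]
        v = pd.Series([1.0, -1.0, 2.0, 0.0, 0.5, -0.5], index=genes)
        cents = pd.DataFrame({"first": v, "second": v})
        with caplog.at_level("INFO", logger="cnakit.subtyping"):
            label, corrs = st.classify_by_centroid(v, cents)
        assert label == "first"
        assert any("tie" in r.message for r in caplog.records)

    def test_min_r_yields_unclassified(self):
        genes = [f"G{i}" for i in range(6)]
        cents = pd.DataFrame(
            {"alpha": [1.0, 0, 0, 0, 0, 0], "beta": [0, 1.0, 0, 0, 0, 0]}, index=genes
        )
        sample = pd.Series([-1.0, -1.0, 0, 0, 0, 0], index=genes)
        label, corrs = st.classify_by_centroid(sample, cents, min_r=0.1)
        assert (corrs <= 0).all()
        assert label == "unclassified"

    def test_too_few_shared_genes_rejected(self):
        cents = self.centroids()
        sample = pd.Series([1.0, 2.0], index=["G0", "G1"])
        with pytest.raises(st.SubtypingError):
            st.classify_by_centroid(sample, cents)

    def test_classify_cohort_shape(self):
        cents = self.centroids()
        expr = make_expr(
            {"S1": cents["alpha"].to_numpy(), "S2": cents["beta"].to_numpy()},
            list(cents.index),
        )
        out = st.classify_cohort(expr, cents)
        assert out.loc["S1", "label"] == "alpha"
        assert out.loc["S2", "label"] == "beta"
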