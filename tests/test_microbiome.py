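"""Count-matrix statistics against hand computations, brute-force oracles
and independent library implementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import baripath as bp
from baripath import microbiome as mb
from conftest import toy_count_matrix


class TestRarefy:
    def test_identity_at_full_depth(self):
        cm = toy_count_matrix(np.array([[5, 3], [7, 9]]))
        out = bp.rarefy(cm, 12, seed=1)
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_exact_depth_and_determinism(self, community):
        out1 = bp.rarefy(community["cm"], 48_000, seed=711)
        out2 = bp.rarefy(community["cm"], 48_000, seed=711)
        assert (out1.counts.sum(axis=0) == 48_000).all()
        pd.testing.assert_frame_equal(out1.counts, out2.counts)
        out3 = bp.rarefy(community["cm"], 48_000, seed=712)
        assert not out3.counts.equals(out1.counts)

    def test_hypergeometric_mean(self):
        counts = np.array([[600], [300], [100]])
        cm = toy_count_matrix(counts)
        depth = 200
        draws = np.stack([bp.rarefy(cm, depth, seed=s).counts.to_numpy()[:, 0]
                          for s in range(200)])
        expected = depth * counts[:, 0] / counts.sum()
        # hypergeometric variance: n*p*(1-p)*(N-n)/(N-1)
        N = counts.sum()
        var = depth * (counts[:, 0] / N) * (1 - counts[:, 0] / N) * (N - depth) / (N - 1)
        se = np.sqrt(var / 200)
        assert (np.abs(draws.mean(axis=0) - expected) < 2 * se + 1e-9).all()

    def test_shallow_sample_listed_in_error(self):
        cm = toy_count_matrix(np.array([[5, 100], [5, 100]]))
        with pytest.raises(ValueError, match="s0"):
            bp.rarefy(cm, 50, seed=1)


class TestFilters:
    def test_prevalence_boundary(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, 0] = 5            # 1/10 samples -> dropped at 20 %
        counts[1, :2] = 5           # 2/10 samples -> kept (boundary)
        counts = np.vstack([counts, np.full((1, 10), 3)])
        cm = toy_count_matrix(counts)
        out = bp.filter_prevalence(cm, 0.20)
        assert "t0" not in out.taxa and "t1" in out.taxa

    def test_min_prev_zero_is_identity(self, community):
        out = bp.filter_prevalence(community["cm"], 0.0)
        assert out.counts.shape == community["cm"].counts.shape

    def test_empty_result_rejected(self):
        cm = toy_count_matrix(np.zeros((2, 10), dtype=int))
        with pytest.raises(ValueError):
            bp.filter_prevalence(cm, 0.5)

    def test_relative_abundance_sums_to_one(self, community):
        rel = bp.relative_abundance(community["cm"])
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)
        cm = toy_count_matrix(np.array([[30], [10]]))
        assert bp.relative_abundance(cm).iloc[:, 0].tolist() == [0.75, 0.25]

    def test_mean_abundance_boundary_and_recount(self):
        rng = np.random.default_rng(4)
        rel = pd.DataFrame(rng.dirichlet(np.full(50, 0.3), size=12).T,
                           index=[f"t{i}" for i in range(50)])
        keep = bp.filter_mean_abundance(rel, 0.001)
        brute = [t for t in rel.index if rel.loc[t].mean() >= 0.001]
        assert list(keep) == brute
        flat = pd.DataFrame({"s0": [0.001, 0.0005], "s1": [0.001, 0.0005]},
                            index=["hi", "lo"])
        kept = bp.filter_mean_abundance(flat, 0.001)
        assert "hi" in kept and "lo" not in kept


class TestAggregation:
    def test_additivity_and_conservation(self):
        counts = np.array([[10, 1], [20, 2], [5, 7]])
        cm = toy_count_matrix(counts)
        cm.lineage["genus"] = ["gA", "gA", "gB"]
        out = bp.aggregate_rank(cm, "genus")
        assert out.counts.loc["gA"].tolist() == [30, 3]
        assert (out.counts.sum(axis=0) == cm.counts.sum(axis=0)).all()

    def test_unknown_rank_rejected(self, community):
        with pytest.raises(ValueError, match="unknown rank"):
            bp.aggregate_rank(community["cm"], "phylum")

    def test_class_table_no_larger_than_distinct_classes(self, community):
        out = bp.aggregate_rank(community["cm"], "class")
        assert out.counts.shape[0] <= community["cm"].lineage["class"].nunique()


class TestAlphaDiversity:
    def test_closed_forms(self):
        cm = toy_count_matrix(np.array([[10, 99, 50], [10, 1, 50], [10, 0, 0]]))
        out = bp.alpha_diversity(cm)
        assert out.loc["s0", "observed"] == 3
        assert out.loc["s0", "shannon"] == pytest.approx(np.log(3))
        assert out.loc["s2", "shannon"] > out.loc["s1", "shannon"]
        single = bp.alpha_diversity(toy_count_matrix(np.array([[7]])))
        assert single.iloc[0].tolist() == [1, 0.0, 0.0]


class TestBrayCurtis:
    def test_hand_example_and_bounds(self):
        table = pd.DataFrame({"x": [1.0, 1.0], "y": [1.0, 3.0]})
        D = bp.bray_curtis(table)
        assert D.loc["x", "y"] == pytest.approx(2 / 6)
        assert D.loc["x", "x"] == 0

    def test_disjoint_supports_give_one(self):
        table = pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 2.0]})
        assert bp.bray_curtis(table).loc["x", "y"] == pytest.approx(1.0)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            bp.bray_curtis(pd.DataFrame({"x": [-1.0], "y": [1.0]}))

    def test_matches_scikit_bio(self):
        skbio_diversity = pytest.importorskip("skbio.diversity")
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.integers(0, 50, size=(20, 8)).astype(float))
        ours = bp.bray_curtis(table).to_numpy()
        theirs = skbio_diversity.beta_diversity(
            "braycurtis", table.to_numpy().T).data
        assert np.allclose(ours, theirs, atol=1e-12)


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        from scipy.spatial import procrustes
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 2))
        D = pd.DataFrame(squareform(pdist(pts)))
        res = bp.pcoa(D)
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy()[:, :2])
        assert disparity < 1e-8

    def test_two_sample_closed_form(self):
        D = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        coords = bp.pcoa(D).coordinates.to_numpy().ravel()
        assert np.allclose(np.sort(coords), [-1.5, 1.5])

    def test_centered_and_sorted(self, community):
        rel = bp.relative_abundance(community["cm"])
        res = bp.pcoa(bp.bray_curtis(rel.iloc[:, :15]))
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            bp.pcoa(D)

    def test_eigenvalues_match_scikit_bio(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 4))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        ours = bp.pcoa(pd.DataFrame(D))
        theirs = skbio_ordination.pcoa(DistanceMatrix(D))
        k = len(ours.proportion_explained)
        assert np.allclose(ours.eigenvalues[:k], theirs.eigvals.to_numpy()[:k],
                           atol=1e-8)


class TestDbrda:
    @pytest.fixture(scope="class")
    def dissimilarity(self, community):
        rel = bp.relative_abundance(
            bp.aggregate_rank(bp.filter_prevalence(
                bp.rarefy(community["cm"].subset_samples(
                    community["cm"].sample_ids[:20]), 48_000, seed=711)), "genus"))
        return bp.bray_curtis(rel)

    def test_self_predictor_explains_first_axis(self, dissimilarity):
        ordination = bp.pcoa(dissimilarity)
        axis1 = ordination.coordinates.iloc[:, 0]
        res = bp.dbrda_univariate(dissimilarity, axis1, seed=1)
        lam = ordination.eigenvalues[ordination.eigenvalues > 0]
        assert res["r2"] == pytest.approx(lam[0] / lam.sum(), rel=1e-6)
        assert res["p"] <= 0.001

    def test_constant_predictor_rejected(self, dissimilarity):
        with pytest.raises(ValueError, match="constant"):
            bp.dbrda_univariate(dissimilarity, np.ones(len(dissimilarity)))

    def test_exhaustive_permutation_oracle_at_tiny_n(self):
        # binary predictor on 10 samples: only C(10,5)=252 distinct
        # label assignments -> the exact permutation p is enumerable
        from itertools import combinations
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        from scipy.spatial.distance import pdist, squareform
        D = pd.DataFrame(squareform(pdist(pts)))
        x = np.array([1.0] * 5 + [0.0] * 5)
        ordination = bp.pcoa(D)
        Y = ordination.coordinates.to_numpy()
        total = ordination.eigenvalues[ordination.eigenvalues > 0].sum()

        def r2_of(v):
            vc = v - v.mean()
            return ((Y.T @ vc) ** 2).sum() / (vc @ vc) / total

        r2_obs = r2_of(x)
        exact = []
        for ones in combinations(range(10), 5):
            v = np.zeros(10)
            v[list(ones)] = 1.0
            exact.append(r2_of(v))
        p_exact = np.mean(np.array(exact) >= r2_obs - 1e-12)
        res = bp.dbrda_univariate(D, x, n_perm=9_999, seed=4)
        # Monte-Carlo estimate within ~3 binomial standard errors
        se = np.sqrt(p_exact * (1 - p_exact) / 9_999)
        assert abs(res["p"] - p_exact) < 3 * se + 2e-4


class TestFitVectors:
    def test_axis_aligned_taxon_and_noise(self, community):
        rel = bp.relative_abundance(community["cm"]).iloc[:, :20]
        ordination = bp.pcoa(bp.bray_curtis(rel))
        probe = pd.DataFrame({
            "axis_taxon": ordination.coordinates.iloc[:, 0].to_numpy(),
            "noise_taxon": np.random.default_rng(5).normal(size=20),
        }).T
        probe.columns = rel.columns
        out = bp.fit_vectors(ordination, probe, n_perm=199, seed=6)
        assert out.loc["axis_taxon", "r2"] == pytest.approx(1.0, abs=1e-9)
        assert out.loc["axis_taxon", "flagged"]
        assert out.loc["noise_taxon", "r2"] < 0.5
        assert not out.loc["noise_taxon", "flagged"]

    def test_zero_variance_taxon_skipped(self, community):
        rel = bp.relative_abundance(community["cm"]).iloc[:, :20]
        ordination = bp.pcoa(bp.bray_curtis(rel))
        flat = pd.DataFrame([np.ones(20)], index=["flat"], columns=rel.columns)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = bp.fit_vectors(ordination, flat, n_perm=99, seed=7)
        assert "flat" not in out.index


def _brute_delta(a, b):
    gt = sum(x > y for x in a for y in b)
    lt = sum(x < y for x in a for y in b)
    return (gt - lt) / (len(a) * len(b))


class TestCliffsDelta:
    @pytest.mark.parametrize("a,b,expect", [
        ([4, 5, 6], [1, 2, 3], 1.0),
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2], [2, 3], -0.75),
    ])
    def test_hand_examples(self, a, b, expect):
        assert bp.cliffs_delta(a, b).delta == expect

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=12),
           st.lists(st.integers(-5, 5), min_size=1, max_size=12))
    def test_matches_brute_force_pair_count(self, a, b):
        assert bp.cliffs_delta(a, b).delta == pytest.approx(_brute_delta(a, b))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=12),
           st.lists(st.floats(-10, 10), min_size=2, max_size=12))
    def test_ci_brackets_estimate_within_range(self, a, b):
        res = bp.cliffs_delta(a, b)
        assert -1 <= res.ci_low <= res.delta <= res.ci_high <= 1

    def test_ci_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        widths = []
        for n in (10, 40, 160):
            a, b = rng.normal(0.5, 1, n), rng.normal(0, 1, n)
            res = bp.cliffs_delta(a, b)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bp.cliffs_delta([], [1, 2])


class TestBenjaminiHochberg:
    def test_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=25))
    def test_matches_step_up_definition(self, ps):
        from statsmodels.stats.multitest import multipletests
        got = multipletests(ps, method="fdr_bh")[1]
        m = len(ps)
        order = np.argsort(ps)
        ranked = np.array(ps)[order]
        stepup = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(stepup, 1.0)
        assert np.allclose(got, expect)


class TestDifferentialAbundance:
    def test_planted_taxa_detected(self, community):
        cm = bp.filter_prevalence(bp.rarefy(community["cm"], 48_000, seed=711))
        rel = bp.relative_abundance(cm)
        rel = rel.loc[bp.filter_mean_abundance(rel)]
        res = bp.differential_abundance(rel, community["labels"])
        hits = res[res["q"] < 0.1]
        detected = sum(t in hits.index for t in community["planted"])
        assert detected >= 11
        assert (hits.loc[[t for t in community["planted"] if t in hits.index],
                         "delta"] > 0).all()

    def test_permuted_labels_control_false_positives(self, community):
        cm = bp.filter_prevalence(bp.rarefy(community["cm"], 48_000, seed=711))
        rel = bp.relative_abundance(cm)
        rel = rel.loc[bp.filter_mean_abundance(rel)]
        rng = np.random.default_rng(9)
        fp = []
        for rep in range(10):
            perm = pd.Series(rng.permutation(community["labels"].to_numpy()),
                             index=community["labels"].index)
            res = bp.differential_abundance(rel, perm)
            fp.append((res["q"] < 0.1).sum())
        assert np.mean(fp) <= 1.0

    def test_stratified_robustness_flag(self, community):
        cm = bp.filter_prevalence(bp.rarefy(community["cm"], 48_000, seed=711))
        rel = bp.relative_abundance(cm)
        rel = rel.loc[bp.filter_mean_abundance(rel)]
        rng = np.random.default_rng(10)
        strata = pd.Series(rng.integers(0, 2, len(community["labels"])),
                           index=community["labels"].index)
        res = bp.differential_abundance(rel, community["labels"], strata=strata)
        planted_in = [t for t in community["planted"] if t in res.index]
        # a balanced random stratum does not wash out a real signal
        assert res.loc[planted_in, "robust"].mean() > 0.8

    def test_tiny_group_rejected(self, community):
        rel = bp.relative_abundance(community["cm"])
        labels = pd.Series(["Severe"] + ["Mild"] * 59, index=rel.columns)
        with pytest.raises(ValueError):
            bp.differential_abundance(rel, labels)


class TestRosner:
    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 100)
        x[17] = 50.0
        flagged = bp.rosner_outliers(x, k=5, alpha=0.001)
        assert flagged == [17]

    def test_clean_sample_rarely_flagged(self):
        rng = np.random.default_rng(12)
        n_flagged = sum(bool(bp.rosner_outliers(rng.normal(0, 1, 100), k=5, alpha=0.001))
                        for _ in range(50))
        assert n_flagged <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            bp.rosner_outliers(np.ones(50), k=5, alpha=0.001)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            bp.rosner_outliers(np.arange(6.0), k=5, alpha=0.001)


class TestCorrelateClinical:
    def test_monotone_and_tied_examples(self):
        rel = pd.DataFrame(
            {f"s{i}": [v, 10 - v] for i, v in enumerate([1.0, 2.0, 3.0, 4.0])},
            index=["up", "down"])
        clinical = pd.DataFrame({"v": [1.0, 8.0, 27.0, 64.0]},
                                index=[f"s{i}" for i in range(4)])
        out = bp.correlate_clinical(rel, clinical).set_index("taxon")
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)
        tied = bp.correlate_clinical(
            pd.DataFrame({"s0": [1.0], "s1": [1.0], "s2": [2.0]}, index=["t"]),
            pd.DataFrame({"v": [3.0, 3.0, 4.0]}, index=["s0", "s1", "s2"]))
        assert tied["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_variable_reported_missing(self):
        rel = pd.DataFrame({"s0": [1.0], "s1": [2.0], "s2": [3.0]}, index=["t"])
        clinical = pd.DataFrame({"v": [5.0, 5.0, 5.0]}, index=["s0", "s1", "s2"])
        out = bp.correlate_clinical(rel, clinical)
        assert out["rho"].isna().all()
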