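import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from peakamp.genome import GenomicInterval, IntervalSet
from peakamp.peaks import PeakTable
from peakamp.stats import (AffinityMatrix, amplification_analysis,
                           exclusive_peak_correlations, mann_whitney,
                           pca_affinity, sample_correlation_clustering, spearman)
from peakamp.tracks import CoverageTrack
from peakamp.genome import Genome

from oracles import enum_mann_whitney_p, enum_spearman_p


class TestMannWhitney:
    def test_identical_samples_near_one(self):
        x = np.arange(8.0)
        res = mann_whitney(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p == pytest.approx(1.0)

    def test_small_separated_groups_exact_third(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.method == "exact"
        assert res.p == pytest.approx(1 / 3, abs=1e-4)

    def test_exact_branch_equals_enumeration(self):
        rng = np.random.default_rng(6)
        for n_x in (2, 3, 5, 8):
            for n_y in (2, 4, 8):
                x = rng.normal(size=n_x)
                y = rng.normal(0.8, size=n_y)
                res = mann_whitney(x, y)
                assert res.method == "exact"
                assert res.p == pytest.approx(enum_mann_whitney_p(x, y), abs=1e-12)

    def test_exact_branch_handles_ties_via_midranks(self):
        x = [1.0, 2.0, 2.0]
        y = [2.0, 3.0, 3.0]
        res = mann_whitney(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(enum_mann_whitney_p(x, y), abs=1e-12)

    def test_approximate_branch_close_to_enumeration(self):
        """At the sizes where the normal approximation is actually used,
        it tracks the exact permutation p closely."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=9)
            y = rng.normal(0.7, size=9)
            res = mann_whitney(x, y)
            assert res.method == "normal_approx"
            assert res.p == pytest.approx(enum_mann_whitney_p(x, y), abs=0.01)

    def test_u_statistics_sum_to_product(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
               st.lists(st.floats(-50, 50), min_size=1, max_size=12))
        def check(x, y):
            u_x = mann_whitney(x, y).statistic
            u_y = mann_whitney(y, x).statistic
            assert u_x + u_y == pytest.approx(len(x) * len(y))

        check()

    def test_degenerate_identical_values(self):
        res = mann_whitney([2.0] * 5, [2.0] * 7)
        assert res.p == 1.0 and res.method == "degenerate"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(6.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_exact_permutation_p_matches_enumeration_n5(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            _, p = spearman(x, y)
            assert p == pytest.approx(enum_spearman_p(x, y), abs=1e-9)

    def test_constant_input_is_na(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_large_n_agrees_with_scipy(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        rho, p = spearman(x, y)
        ref = ss.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=0.05)


def _uniform_track(genome, value=0.0):
    t = CoverageTrack(genome)
    for c in t.data:
        t.data[c][:] = value
    return t


class TestAmplification:
    def test_all_zero_track_degenerate(self):
        genome = Genome({"chr1": 10_000})
        peaks = PeakTable.from_intervals(
            [GenomicInterval("chr1", 1_000, 1_300), GenomicInterval("chr1", 3_000, 3_300)])
        bg = IntervalSet([GenomicInterval("chr1", 5_000, 5_300),
                          GenomicInterval("chr1", 7_000, 7_300)])
        summary, tests = amplification_analysis(
            {"r1": _uniform_track(genome)}, peaks, bg)
        assert summary.loc[0, "peak_median"] == 0.0
        assert tests["r1"].p == 1.0

    def test_planted_basal_signal_detected(self, small_sim):
        """NHS signal at stimulus-exclusive site locations exceeds background
        because the generator plants basal intensity there."""
        from peakamp.peaks import BackgroundSpec, sample_background
        from peakamp.synth import sample_id

        sites = small_sim.truth.sites
        hs_only = sites[sites["treatment_class"] == "HS_only"]
        if len(hs_only) < 3:
            pytest.skip("too few exclusive sites in this draw")
        peaks = PeakTable.from_intervals(
            [GenomicInterval(r.chrom, r.center - 150, r.center + 150)
             for r in hs_only.itertuples() if r.in_A])
        excl = IntervalSet(
            [GenomicInterval(r.chrom, r.center - 300, r.center + 300)
             for r in sites.itertuples()])
        bg = sample_background(
            BackgroundSpec(300, 300, excl, seed=3), small_sim.genome)
        nhs = {f"r{r}": small_sim.chip_tracks[sample_id("A", "NHS", "chip", r)]
               for r in (1, 2)}
        summary, tests = amplification_analysis(nhs, peaks, bg)
        assert (summary["peak_median"] > summary["background_median"]).all()
        assert all(t.p < 0.01 for t in tests.values())

    def test_empty_peak_class_rejected(self):
        genome = Genome({"chr1": 1_000})
        with pytest.raises(ValueError):
            amplification_analysis({"r1": _uniform_track(genome)},
                                   PeakTable.from_intervals([]), IntervalSet())


def _affinity(df):
    return AffinityMatrix(df, transform="linear").log2_transform()


class TestAffinityAnalyses:
    def test_duplicated_column_correlates_perfectly(self):
        rng = np.random.default_rng(14)
        base = rng.lognormal(2, 1, 50)
        df = pd.DataFrame({"nhs": base, "hs": base, "other": rng.lognormal(2, 1, 50)})
        aff = _affinity(df)
        out = exclusive_peak_correlations(
            aff, {"all": np.ones(50, bool)}, [("nhs", "hs")])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_small_class_reports_na(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 3, 4, 5]})
        aff = _affinity(df)
        mask = np.array([True, True, False, False])
        out = exclusive_peak_correlations(aff, {"tiny": mask}, [("a", "b")])
        assert np.isnan(out.loc[0, "rho"])

    def test_clustering_places_duplicate_samples_adjacent(self):
        rng = np.random.default_rng(15)
        base = rng.lognormal(2, 1, 80)
        df = pd.DataFrame({
            "s1": base * np.exp(rng.normal(0, 0.05, 80)),
            "s2": base * np.exp(rng.normal(0, 0.05, 80)),
            "s3": rng.lognormal(2, 1, 80),
            "s4": rng.lognormal(2, 1, 80),
        })
        corr, _, order = sample_correlation_clustering(_affinity(df))
        assert corr.loc["s1", "s2"] > 0.9
        assert abs(order.index("s1") - order.index("s2")) == 1

    def test_correlation_invariant_to_peak_order(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.lognormal(2, 1, (60, 4)), columns=list("abcd"))
        aff1 = _affinity(df)
        aff2 = _affinity(df.sample(frac=1, random_state=1))
        c1, _, _ = sample_correlation_clustering(aff1)
        c2, _, _ = sample_correlation_clustering(aff2)
        pd.testing.assert_frame_equal(c1, c2)


class TestPca:
    def test_identical_samples_collapse_to_origin(self):
        df = pd.DataFrame({"a": [1.0, 5, 2, 8], "b": [1.0, 5, 2, 8]})
        scores, _ = pca_affinity(_affinity(df))
        assert np.allclose(scores["PC1"], 0.0, atol=1e-9)

    def test_block_structure_separates_groups_on_pc1(self):
        """Two sample groups with disjoint hot peak sets land on opposite
        PC1 sides; checked against a direct SVD of the centered matrix."""
        hot = 100.0
        rows_a = np.array([[hot, hot, 0, 0]] * 10)
        rows_b = np.array([[0, 0, hot, hot]] * 10)
        df = pd.DataFrame(np.vstack([rows_a, rows_b]),
                          columns=["a1", "a2", "b1", "b2"])
        aff = _affinity(df)
        scores, var = pca_affinity(aff)
        a_side = np.sign(scores.loc[["a1", "a2"], "PC1"])
        b_side = np.sign(scores.loc[["b1", "b2"], "PC1"])
        assert set(a_side) != set(b_side)
        # verify against an independent SVD
        X = aff.df.to_numpy()
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert var[0] == pytest.approx(100 * s[0] ** 2 / np.sum(s ** 2))

    def test_scores_invariant_to_row_permutation(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(rng.lognormal(2, 1, (40, 3)), columns=list("xyz"))
        s1, _ = pca_affinity(_affinity(df))
        s2, _ = pca_affinity(_affinity(df.sample(frac=1, random_state=2)))
        np.testing.assert_allclose(np.abs(s1.to_numpy()), np.abs(s2.to_numpy()),
                                   atol=1e-6)

    def test_variance_explained_sums_to_100(self):
        rng = np.random.default_rng(19)
        df = pd.DataFrame(rng.lognormal(0, 1, (30, 4)), columns=list("abcd"))
        _, var = pca_affinity(_affinity(df))
        assert np.sum(var) == pytest.approx(100.0)
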