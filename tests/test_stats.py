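"""Statistics layer: correlations, Bland-Altman, normality, power, clustering, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from grainmri.errors import ValidationError
from grainmri.stats import (bland_altman, cluster_traits, normality_check, pearson_matrix,
                            pearson_pair, required_sample_size, trait_pca)


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": x})
        r, p, n = pearson_matrix(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelation_is_minus_one(self):
        x = np.arange(10.0)
        r, _, _ = pearson_matrix(pd.DataFrame({"a": x, "b": -x}))
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_p_values_match_scipy_oracle(self):
        """The N-2-df t transform must agree with scipy.stats.pearsonr."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = pearson_pair(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp)
        assert res.p == pytest.approx(p_sp, rel=1e-10)

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        r, p, n = pearson_matrix(df)
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert (n == 20).all().all()

    def test_pairwise_complete_handling_of_missing_cells(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=12), "b": rng.normal(size=12)})
        df.loc[0:3, "b"] = np.nan
        _, _, n = pearson_matrix(df)
        assert n.loc["a", "b"] == 8

    def test_zero_variance_column_warns_and_yields_nan(self):
        df = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        with pytest.warns(UserWarning, match="zero-variance"):
            r, _, _ = pearson_matrix(df)
        assert np.isnan(r.loc["a", "b"])

    def test_p_decreases_with_absolute_r_at_fixed_n(self):
        from grainmri.stats import _pearson_p
        ps = [_pearson_p(r, 20) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestBlandAltman:
    def test_identical_series_have_zero_bias_and_loa(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert res.loa == (0.0, 0.0)

    def test_constant_offset_gives_bias_with_zero_width_loa(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a + 0.1, a)
        assert res.bias == pytest.approx(0.1)
        assert res.loa[0] == pytest.approx(res.loa[1])

    def test_recovers_planted_difference_model(self):
        rng = np.random.default_rng(3)
        n = 1000
        b = rng.uniform(5, 7, n)
        d = rng.normal(0.05, 0.2, n)
        res = bland_altman(b + d, b)
        se = 0.2 / np.sqrt(n)
        assert res.bias == pytest.approx(0.05, abs=3 * se)
        assert res.sd == pytest.approx(0.2, rel=0.1)
        assert res.loa[0] == pytest.approx(res.bias - 1.96 * res.sd)
        assert res.loa[1] == pytest.approx(res.bias + 1.96 * res.sd)
        assert res.bias_ci[0] < res.bias < res.bias_ci[1]

    def test_hand_computed_example(self):
        # d = (0.1, -0.1, 0.3, -0.3): mean 0, sd sqrt(0.2/3)
        a = np.array([1.1, 1.9, 2.3, 1.7])
        b = np.array([1.0, 2.0, 2.0, 2.0])
        res = bland_altman(a, b)
        sd = np.sqrt(0.2 / 3)
        assert res.bias == pytest.approx(0.0)
        assert res.loa == (pytest.approx(-1.96 * sd), pytest.approx(1.96 * sd))
        np.testing.assert_allclose(res.relative_differences, (a - b) / b)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0, 2.0], [1.0])


class TestNormality:
    def test_normal_samples_rarely_rejected(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            _, reject, _ = normality_check(x)
            rejections += reject
        assert rejections <= 5

    def test_exponential_samples_mostly_rejected(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=500)
            _, reject, _ = normality_check(x)
            rejections += reject
        assert rejections >= 95

    def test_qq_pairs_of_normal_quantiles_lie_on_identity(self):
        probs = (np.arange(1, 201) - 0.5) / 200
        x = sps.norm.ppf(probs)
        _, _, qq = normality_check(x)
        np.testing.assert_allclose(qq[:, 0], qq[:, 1], atol=0.05)

    def test_constant_vector_raises(self):
        with pytest.raises(ValidationError):
            normality_check(np.ones(20))


class TestSampleSize:
    def test_closed_form_benchmark_case(self):
        # ((1.9600 + 0.8416) / 1)^2 = 7.849 -> 8 per group
        assert required_sample_size(1.0, alpha=0.05, power=0.8) == 8

    def test_n_nondecreasing_in_power(self):
        ns = [required_sample_size(0.5, power=p) for p in (0.5, 0.7, 0.8, 0.9, 0.99)]
        assert all(a <= b for a, b in zip(ns, ns[1:]))

    def test_doubling_effect_quarters_n(self):
        # before rounding: n(d) = c/d^2, so n(2d) = n(d)/4
        n1 = required_sample_size(0.25, power=0.9)
        n2 = required_sample_size(0.5, power=0.9)
        assert n2 == pytest.approx(n1 / 4, abs=1)

    def test_zero_effect_raises(self):
        with pytest.raises(ValidationError):
            required_sample_size(0.0)


class TestClustering:
    def test_identical_rows_merge_first_at_zero_height(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 5.0], "y": [2.0, 2.0, 9.0]})
        merges, labels = cluster_traits(df, groups=["a", "b", "c"])
        assert merges[0, 2] == pytest.approx(0.0)

    def test_complete_linkage_uses_farthest_distance(self):
        # one-dimensional points 0, 1, 10 (z-scored internally): the second
        # merge height must be the *maximum* pairwise distance to the pair
        df = pd.DataFrame({"x": [0.0, 1.0, 10.0]})
        merges, _ = cluster_traits(df, groups=list("abc"))
        z = (np.array([0.0, 1.0, 10.0]) - 11 / 3) / np.std([0, 1, 10])
        d01, d02 = abs(z[0] - z[1]), abs(z[0] - z[2])
        assert merges[0, 2] == pytest.approx(d01)
        assert merges[1, 2] == pytest.approx(d02)  # farthest member of the pair

    def test_row_order_permutation_keeps_heights(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("xyz"))
        groups = list("aabbccdd")
        m1, _ = cluster_traits(df, groups)
        perm = rng.permutation(8)
        m2, _ = cluster_traits(df.iloc[perm].reset_index(drop=True),
                               [groups[i] for i in perm])
        np.testing.assert_allclose(np.sort(m1[:, 2]), np.sort(m2[:, 2]), atol=1e-12)

    def test_missing_values_refused(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0, 4.0]})
        with pytest.raises(ValidationError, match="missing"):
            cluster_traits(df, groups=list("abab"))


class TestPCA:
    def test_variance_fractions_non_increasing_and_sum_to_one(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        _, evr = trait_pca(df)
        assert all(a >= b - 1e-12 for a, b in zip(evr, evr[1:]))
        assert evr.sum() == pytest.approx(1.0)

    def test_rank_two_data_explained_by_two_components(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=30)
        v = rng.normal(size=30)
        df = pd.DataFrame({"a": u, "b": v, "c": u + v, "d": u - 2 * v})
        _, evr = trait_pca(df)
        assert evr[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicating_rows_keeps_component_directions(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        _, evr1 = trait_pca(df)
        _, evr2 = trait_pca(pd.concat([df, df], ignore_index=True))
        np.testing.assert_allclose(evr1, evr2, atol=1e-10)


class TestPlantedCorrelationRecovery:
    def test_planted_linear_dependence_recovered_within_analytic_ci(self):
        """Am = beta*Vm + noise: the estimated r must fall inside the
        Fisher-z 95% CI around the population correlation."""
        rng = np.random.default_rng(9)
        n = 200
        vm = rng.normal(10, 2, n)
        noise_sd = 1.5
        am = 3.0 * vm + rng.normal(0, noise_sd, n)
        rho = 3.0 * 2 / np.sqrt((3.0 * 2) ** 2 + noise_sd ** 2)
        res = pearson_pair(vm, am)
        z = np.arctanh(res.r)
        half = 1.96 / np.sqrt(n - 3)
        assert z - half < np.arctanh(rho) < z + half
        assert res.p < 0.001
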