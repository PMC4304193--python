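"""Closed-form combiners: frozen oracle values, identities, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pcombine import (
    DegreesOfFreedom,
    GammaShapeSpec,
    StudyPValues,
    WeightSpec,
    adaptive_gamma_statistic,
    chen_nadarajah_combine,
    fisher_combine,
    gamma_combine,
    lancaster_combine,
    stouffer_combine,
    validate_pvalues,
    weighted_z_combine,
)
from pcombine.combiners import (
    WILSON_HILFERTY_SHAPE_THRESHOLD,
    gamma_upper_quantile,
)


class TestValidatePValues:
    def test_published_five_survive_unchanged(self):
        p = validate_pvalues([0.94, 0.0015, 0.97, 0.79, 0.81])
        assert p.K == 5
        np.testing.assert_array_equal(p.values, [0.94, 0.0015, 0.97, 0.79, 0.81])

    def test_boundary_values_are_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = validate_pvalues([0.0, 1.0], epsilon=1e-15)
        np.testing.assert_allclose(p.values, [1e-15, 1 - 1e-15], rtol=0)

    def test_single_study(self):
        assert validate_pvalues([0.5]).K == 1

    @pytest.mark.parametrize("bad", [[], [1.2], [-0.1], [np.nan], [0.5, np.inf]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            validate_pvalues(bad)

    def test_error_names_offending_index(self):
        with pytest.raises(ValueError, match="index 2"):
            validate_pvalues([0.5, 0.5, 1.5])


# expected values frozen from direct evaluation of each statistic's defining
# formula with scipy's quantile/CDF routines (and closed forms where noted)
class TestFrozenExamples:
    def test_stouffer_symmetric_pair(self):
        r = stouffer_combine(validate_pvalues([0.5, 0.5]))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.combined_p == pytest.approx(0.5, abs=1e-12)

    def test_stouffer_two_significant_studies(self):
        # Z = 2 Phi^-1(0.05)/sqrt(2)
        r = stouffer_combine(validate_pvalues([0.05, 0.05]))
        assert r.statistic == pytest.approx(-2.3261743074, abs=1e-9)
        assert r.combined_p == pytest.approx(0.0100046269, abs=1e-9)

    def test_sample_size_weighted_z(self):
        # Z = (100+400) Phi^-1(0.05) / sqrt(100^2+400^2)
        r = weighted_z_combine(
            validate_pvalues([0.05, 0.05]),
            WeightSpec("sample_size", sample_sizes=[100, 400]),
        )
        assert r.statistic == pytest.approx(-1.9946780125, abs=1e-9)
        assert r.combined_p == pytest.approx(0.0230390045, abs=1e-9)

    def test_fisher_closed_form_chi2_df4(self):
        # survival of chi-square(4) at x is exp(-x/2)(1+x/2)
        r = fisher_combine(validate_pvalues([0.05, 0.05]))
        x = -4 * np.log(0.05)
        assert r.statistic == pytest.approx(x, rel=1e-12)
        assert r.combined_p == pytest.approx(np.exp(-x / 2) * (1 + x / 2), rel=1e-10)
        assert r.combined_p == pytest.approx(0.0174786614, abs=1e-9)

    def test_lancaster_single_df(self):
        r = lancaster_combine(validate_pvalues([0.05, 0.05]), DegreesOfFreedom([1, 1]))
        assert r.statistic == pytest.approx(7.6829176414, abs=1e-8)
        assert r.combined_p == pytest.approx(0.0214622689, abs=1e-9)

    def test_gamma_unit_shape_scale_one_is_erlang(self):
        # T = -2 ln 0.05; Erlang(2,1) survival exp(-T)(1+T)
        r = gamma_combine(validate_pvalues([0.05, 0.05]), GammaShapeSpec([1.0, 1.0], scale=1.0))
        T = -2 * np.log(0.05)
        assert r.statistic == pytest.approx(T, rel=1e-12)
        assert r.combined_p == pytest.approx(np.exp(-T) * (1 + T), rel=1e-10)

    def test_adaptive_statistic_median_pair(self):
        # two p=0.5 terms, each the gamma(2,1) median
        t = adaptive_gamma_statistic(validate_pvalues([0.5, 0.5]))
        assert t == pytest.approx(3.3566939800, abs=1e-8)

    def test_adaptive_statistic_published_five(self):
        # regression value frozen from the gamma-quantile oracle
        t = adaptive_gamma_statistic(validate_pvalues([0.94, 0.0015, 0.97, 0.79, 0.81]))
        assert t == pytest.approx(746.7235441667, abs=1e-6)


class TestKOneIdentity:
    """Combining a single p-value must return it, for every closed-form test."""

    @pytest.mark.parametrize("p", [0.001, 0.05, 0.3141592653589793, 0.5, 0.77, 0.999])
    def test_every_combiner_returns_input(self, p):
        sp = validate_pvalues([p])
        for res in (
            stouffer_combine(sp),
            weighted_z_combine(sp, WeightSpec("explicit", weights=[2.5])),
            fisher_combine(sp),
            lancaster_combine(sp, DegreesOfFreedom([3.0])),
            chen_nadarajah_combine(sp),
            gamma_combine(sp, GammaShapeSpec([0.7], scale=1.3)),
        ):
            assert res.combined_p == pytest.approx(p, rel=1e-10), res.method


class TestFamilyCollapses:
    """The named special cases must agree to full numerical precision."""

    def _random_pvectors(self, n=1000, seed=7):
        rng = np.random.default_rng(seed)
        for _ in range(n):
            K = int(rng.integers(1, 8))
            yield StudyPValues(rng.uniform(1e-6, 1 - 1e-6, K))

    def test_lancaster_df2_is_fisher(self):
        for p in self._random_pvectors():
            a = lancaster_combine(p, DegreesOfFreedom(np.full(p.K, 2.0))).combined_p
            b = fisher_combine(p).combined_p
            assert a == pytest.approx(b, rel=1e-10)

    def test_lancaster_df1_is_chen_nadarajah(self):
        for p in self._random_pvectors(seed=8):
            a = lancaster_combine(p, DegreesOfFreedom(np.ones(p.K))).combined_p
            b = chen_nadarajah_combine(p).combined_p
            assert a == pytest.approx(b, rel=1e-10)

    @pytest.mark.parametrize("v", [1.0, 2.0, 3.5])
    def test_gamma_halfdf_scale2_is_lancaster(self, v):
        for p in self._random_pvectors(n=300, seed=9):
            a = gamma_combine(p, GammaShapeSpec(np.full(p.K, v / 2), scale=2.0)).combined_p
            b = lancaster_combine(p, DegreesOfFreedom(np.full(p.K, v))).combined_p
            assert a == pytest.approx(b, rel=1e-10)

    def test_equal_weights_is_stouffer(self):
        for p in self._random_pvectors(seed=10):
            a = weighted_z_combine(p, WeightSpec("explicit", weights=np.full(p.K, 3.7))).combined_p
            b = stouffer_combine(p).combined_p
            assert a == pytest.approx(b, rel=1e-10)


class TestWeightHandling:
    def test_weight_scaling_invariance(self, rng):
        p = StudyPValues(rng.uniform(0.01, 0.99, 4))
        w = rng.uniform(0.5, 5.0, 4)
        a = weighted_z_combine(p, WeightSpec("explicit", weights=w)).combined_p
        b = weighted_z_combine(p, WeightSpec("explicit", weights=123.4 * w)).combined_p
        assert a == pytest.approx(b, rel=1e-12)

    def test_sqrt_sample_size_mode(self):
        p = validate_pvalues([0.05, 0.5])
        a = weighted_z_combine(p, WeightSpec("sqrt_sample_size", sample_sizes=[100, 400]))
        b = weighted_z_combine(p, WeightSpec("explicit", weights=[10.0, 20.0]))
        assert a.combined_p == pytest.approx(b.combined_p, rel=1e-12)

    def test_vanishing_weight_recovers_remaining_study(self):
        p = validate_pvalues([0.05, 0.5])
        r = weighted_z_combine(p, WeightSpec("explicit", weights=[1.0, 1e-12]))
        assert r.combined_p == pytest.approx(0.05, rel=1e-6)

    @pytest.mark.parametrize(
        "spec",
        [
            WeightSpec("explicit", weights=[1.0, 0.0]),
            WeightSpec("explicit", weights=[1.0, -2.0]),
            WeightSpec("explicit", weights=[1.0]),
            WeightSpec("sample_size"),
            WeightSpec("inverse_se"),
            WeightSpec("nonsense"),
        ],
    )
    def test_invalid_weight_specs_rejected(self, spec):
        with pytest.raises(ValueError):
            weighted_z_combine(validate_pvalues([0.2, 0.4]), spec)

    def test_df_and_shape_length_mismatch_rejected(self):
        p = validate_pvalues([0.2, 0.4])
        with pytest.raises(ValueError):
            lancaster_combine(p, DegreesOfFreedom([1.0]))
        with pytest.raises(ValueError):
            gamma_combine(p, GammaShapeSpec([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            DegreesOfFreedom([1.0, -1.0])
        with pytest.raises(ValueError):
            GammaShapeSpec([1.0], scale=0.0)


class TestGammaScaleInvariance:
    def test_combined_p_independent_of_scale(self, rng):
        p = StudyPValues(rng.uniform(0.01, 0.99, 5))
        shapes = rng.uniform(0.3, 4.0, 5)
        ps = [
            gamma_combine(p, GammaShapeSpec(shapes, scale=b)).combined_p
            for b in (0.1, 1.0, 2.0, 17.0)
        ]
        np.testing.assert_allclose(ps, ps[0], rtol=1e-9)


class TestAdaptiveStatistic:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=6),
        st.integers(0, 5),
        st.floats(0.05, 0.95),
    )
    def test_strictly_decreasing_in_each_pvalue(self, ps, idx, frac):
        idx = idx % len(ps)
        t0 = adaptive_gamma_statistic(StudyPValues(np.array(ps)))
        smaller = list(ps)
        smaller[idx] = ps[idx] * frac
        t1 = adaptive_gamma_statistic(StudyPValues(np.array(smaller)))
        assert t1 > t0

    def test_wilson_hilferty_branch_matches_exact_at_boundary(self):
        # shapes straddling the switchover: both branches must agree closely
        thr = WILSON_HILFERTY_SHAPE_THRESHOLD
        for a in (thr / 2, thr * 0.99, thr * 1.01, thr * 2):
            for q in (0.5, 0.01, 1e-6):
                from scipy import special

                exact = special.gammainccinv(a, q)
                approx = gamma_upper_quantile(np.array(a), np.array(q))
                assert approx == pytest.approx(exact, rel=1e-7)


class TestNullUniformity:
    """Closed-form combined p-values are Uniform(0,1) under the global null."""

    @pytest.mark.parametrize(
        "combine",
        [
            stouffer_combine,
            fisher_combine,
            chen_nadarajah_combine,
            lambda p: gamma_combine(p, GammaShapeSpec(np.full(p.K, 0.8), scale=1.0)),
        ],
        ids=["z", "fisher", "cn", "gamma"],
    )
    def test_ks_uniform(self, combine):
        rng = np.random.default_rng(4242)
        K = 3
        ps = [combine(StudyPValues(rng.random(K))).combined_p for _ in range(10_000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBruteForceNullTail:
    """Closed-form tail probabilities agree with direct null simulation."""

    @pytest.mark.parametrize("K", [2, 5])
    def test_fisher_and_stouffer_vs_mc(self, K):
        rng = np.random.default_rng(555)
        obs = StudyPValues(rng.uniform(0.01, 0.4, K))
        n = 1_000_000
        u = rng.random((n, K))
        # Fisher
        t_obs = -2 * np.log(obs.values).sum()
        tail = (-2 * np.log(u).sum(axis=1) >= t_obs).mean()
        se = np.sqrt(tail * (1 - tail) / n)
        assert abs(fisher_combine(obs).combined_p - tail) < 3 * se + 1e-12
        # Stouffer (left tail: small p-values give negative Z)
        z_obs = stats.norm.ppf(obs.values).sum() / np.sqrt(K)
        tail = (stats.norm.ppf(u).sum(axis=1) / np.sqrt(K) <= z_obs).mean()
        se = np.sqrt(tail * (1 - tail) / n)
        assert abs(stouffer_combine(obs).combined_p - tail) < 3 * se + 1e-12
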