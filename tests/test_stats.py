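"""Permutation inference, mixed models, BIC comparison, correlations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import betadose as bd
from betadose.stats import (StatsConfig, compare_models, fit_dose_model,
                            fit_velocity_model, paired_permutation_test,
                            per_subject_correlation)


def exhaustive_signflip_p(d):
    """Independent oracle: enumerate all sign patterns of the differences."""
    d = np.asarray(d, dtype=float)
    obs = abs(d.mean())
    count = 0
    for signs in itertools.product([-1, 1], repeat=len(d)):
        if abs(np.mean(np.array(signs) * np.abs(d) * 0 + np.array(signs) * d)) >= obs - 1e-12:
            count += 1
    return count / 2 ** len(d)


class TestPairedPermutation:
    def test_identical_samples_give_p_one(self):
        x = np.arange(8.0)
        res = paired_permutation_test(x, x)
        assert res.p_value == 1.0

    def test_exhaustive_one_sided_extreme_n10(self):
        x = np.full(10, 2.0)
        y = np.full(10, 1.0)
        res = paired_permutation_test(x, y)
        assert res.exhaustive and res.n_used == 1024
        assert res.p_value == pytest.approx(2 / 1024)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x, y = rng.normal(size=7), rng.normal(size=7)
            res = paired_permutation_test(x, y)
            assert res.exhaustive
            assert res.p_value == pytest.approx(exhaustive_signflip_p(x - y))

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(2)
        cfg_mc = StatsConfig(n_permutations=4000, rng_seed=5)
        for rep in range(10):
            x, y = rng.normal(0.4, 1, size=12), rng.normal(size=12)
            exact = exhaustive_signflip_p(x - y)
            mc = paired_permutation_test(x, y, cfg_mc)
            assert not mc.exhaustive
            tol = 3 * np.sqrt(max(exact * (1 - exact), 1e-6) / cfg_mc.n_permutations)
            assert abs(mc.p_value - exact) <= tol + 2 / cfg_mc.n_permutations

    def test_p_never_below_floor(self):
        x = np.arange(20.0) + 100.0
        y = np.arange(20.0)
        cfg = StatsConfig(n_permutations=500, rng_seed=0)
        res = paired_permutation_test(x, y, cfg)
        assert res.p_value >= 1 / (res.n_used + 1)

    @pytest.mark.parametrize("x,y", [
        (np.arange(5.0), np.arange(4.0)),
        (np.arange(2.0), np.arange(2.0)),
    ])
    def test_invalid_inputs(self, x, y):
        with pytest.raises(bd.InvalidArgumentError):
            paired_permutation_test(x, y)


class TestMixedModels:
    def _groups(self, n_sub=5, per=6):
        return np.repeat([f"s{i}" for i in range(n_sub)], per)

    def test_noiseless_velocity_model_identity(self):
        rng = np.random.default_rng(0)
        power = rng.uniform(1, 9, size=30)
        vel = 1.5 - 0.002 * power
        m = fit_velocity_model(power, vel, self._groups())
        assert m.coefficient == pytest.approx(-0.002, abs=1e-6)
        assert m.r2 > 0.999

    def test_noiseless_dose_model_identity(self):
        amp = np.tile(np.arange(6) * 0.5, 5)
        power = np.exp(1.0 - 1.66 * amp)
        m = fit_dose_model(power, amp, self._groups())
        assert m.coefficient == pytest.approx(-1.66, abs=1e-6)

    def test_nonpositive_power_rejected(self):
        amp = np.tile(np.arange(6) * 0.5, 5)
        power = np.exp(-amp)
        power[3] = 0.0
        with pytest.raises(bd.InvalidArgumentError):
            fit_dose_model(power, amp, self._groups())

    def test_subject_offsets_absorbed_by_random_intercept(self):
        rng = np.random.default_rng(3)
        groups = self._groups(8, 6)
        power = rng.uniform(1, 9, size=48)
        offsets = np.repeat(rng.normal(0, 1.0, 8), 6)
        vel = 2.0 - 0.1 * power + offsets + rng.normal(0, 0.01, 48)
        m = fit_velocity_model(power, vel, groups)
        assert m.coefficient == pytest.approx(-0.1, rel=0.05)
        assert m.n_groups == 8

    def test_group_requirements(self):
        with pytest.raises(bd.InvalidArgumentError):
            fit_velocity_model([1, 2, 3], [1, 2, 3], ["a", "a", "a"])


class TestCompareModels:
    def _mk(self, bic, n_obs=50):
        from betadose.stats import MixedModelResult
        return MixedModelResult(coefficient=0, se=1, p_value=1, r2=0, bic=bic,
                                n_obs=n_obs, n_groups=5, formula_label="m")

    def test_published_bic_pair(self):
        cmp = compare_models(self._mk(-393.35), self._mk(-380.57))
        assert cmp.delta_bic == pytest.approx(12.78)
        assert cmp.label == "strong" and cmp.preferred == "a"

    def test_identical_models(self):
        cmp = compare_models(self._mk(-100.0), self._mk(-100.0))
        assert cmp.delta_bic == 0 and cmp.label == "none"

    def test_boundary_is_not_strong(self):
        cmp = compare_models(self._mk(-106.0), self._mk(-100.0))
        assert cmp.delta_bic == 6.0 and cmp.label == "not strong"

    def test_antisymmetric(self):
        a, b = self._mk(-393.35), self._mk(-380.57)
        assert compare_models(a, b).delta_bic == -compare_models(b, a).delta_bic

    def test_n_obs_mismatch_rejected(self):
        with pytest.raises(bd.InvalidArgumentError):
            compare_models(self._mk(-10, 50), self._mk(-9, 40))


class TestPerSubjectCorrelation:
    def test_linear_gaussian_uses_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        res = per_subject_correlation(x, 2 * x + 1)
        assert res.method == "pearson" and res.r == pytest.approx(1.0)

    def test_monotone_heavy_tail_uses_spearman(self):
        rng = np.random.default_rng(1)
        x = rng.standard_cauchy(size=40)
        res = per_subject_correlation(x, np.exp(np.clip(x, -10, 10)))
        assert res.method == "spearman" and res.r == pytest.approx(1.0)

    def test_constant_input_degenerate(self):
        with pytest.raises(bd.DegenerateInputError):
            per_subject_correlation(np.ones(10), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(bd.InvalidArgumentError):
            per_subject_correlation([1, 2, 3], [1, 2, 3])

    def test_null_calibration_within_binomial_bounds(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            res = per_subject_correlation(rng.normal(size=50), rng.normal(size=50))
            rejections += res.p < 0.05
        # binomial(200, 0.05): mean 10, sd ~3.1
        assert 1 <= rejections <= 22


class TestPermutationProperties:
    """Structural invariants of the sign-flip test, property-based."""

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=12),
           st.lists(st.floats(-100, 100), min_size=3, max_size=12))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_p_value_bounds_and_swap_symmetry(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.asarray(xs[:n]), np.asarray(ys[:n])
        res_xy = paired_permutation_test(x, y)
        res_yx = paired_permutation_test(y, x)
        assert 0 < res_xy.p_value <= 1.0
        # two-sided test: swapping the samples negates the statistic only
        assert res_xy.observed_stat == pytest.approx(-res_yx.observed_stat)
        assert res_xy.p_value == pytest.approx(res_yx.p_value)
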