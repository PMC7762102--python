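"""Unit tests for the complexity metrics and the stationarity gate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvcomplexity.entropy import (
    EntropyParams,
    check_stationarity,
    conditional_entropy,
    conditional_entropy_from_joint,
    phillips_perron,
    quantile_bin,
    sample_entropy,
    truncate_common,
)

from conftest import conden_bruteforce, sampen_bruteforce


class TestSampleEntropy:
    def test_alternating_series_is_perfectly_regular(self):
        # every length-2 template match extends to length 3
        x = [0, 1, 0, 1, 0, 1, 0, 1]
        assert sample_entropy(x, EntropyParams(m=2, tau=1), r=0.5) == pytest.approx(0.0)

    def test_hand_enumerated_binary_series(self):
        # exhaustive enumeration gives B=8, A=2 ordered pairs -> -ln(1/4)
        x = [0, 1, 0, 0, 1, 0, 1, 1]
        result = sample_entropy(x, EntropyParams(m=2, tau=1), r=0.5)
        assert result == pytest.approx(math.log(4), abs=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("tau", [1, 2])
    def test_matches_bruteforce_oracle(self, m, tau):
        rng = np.random.default_rng(100 * m + tau)
        checked = 0
        while checked < 8:
            n = int(rng.integers(20, 120))
            x = rng.standard_normal(n)
            r = 0.2 * x.std()
            try:
                expected = sampen_bruteforce(x, m, tau, r)
            except ValueError:  # no template matches at this (m, tau, N)
                continue
            got = sample_entropy(x, EntropyParams(m=m, tau=tau), r=r)
            assert got == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_affine_invariance_with_relative_tolerance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(150)
        params = EntropyParams(m=2, r_factor=0.2)
        assert sample_entropy(3.5 * x - 2.0, params) == pytest.approx(
            sample_entropy(x, params), abs=1e-12
        )

    def test_noise_is_more_irregular_than_sinusoid(self):
        params = EntropyParams()
        higher = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(400)
            t = np.arange(400)
            sine = np.sqrt(2.0) * np.sin(2 * np.pi * t / 40 + rng.uniform(0, 2 * np.pi))
            higher += sample_entropy(noise, params) > sample_entropy(sine, params)
        assert higher == 50

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            sample_entropy(np.ones(50))
        with pytest.raises(ValueError, match="too short"):
            sample_entropy([1.0, 2.0, 3.0], EntropyParams(m=2, tau=2))
        with pytest.raises(ValueError, match="matches"):
            # diverging tails: length-2 matches never extend to length 3
            sample_entropy(np.array([0, 1, 0, 10, 100, 1000, 1e4, 1e5]), r=0.5)


class TestConditionalEntropy:
    def test_identical_series_has_zero_residual_entropy(self):
        x = np.random.default_rng(0).standard_normal(400)
        assert conditional_entropy(x, x, bins=8) == pytest.approx(0.0, abs=1e-12)

    def test_independent_two_bin_uniform_gives_ln2(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert conditional_entropy(x, y, bins=2) == pytest.approx(math.log(2), abs=1e-12)

    def test_printed_joint_table(self):
        expected = 0.75 * (math.log(3) - (2.0 / 3.0) * math.log(2))
        assert conditional_entropy_from_joint([[2, 1], [0, 1]]) == pytest.approx(
            expected, abs=1e-12
        )

    def test_joint_evaluation_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            joint = rng.integers(0, 10, size=(rng.integers(2, 6), rng.integers(2, 6)))
            if joint.sum() == 0:
                continue
            assert conditional_entropy_from_joint(joint) == pytest.approx(
                conden_bruteforce(joint), abs=1e-12
            )

    def test_bounded_by_marginal_entropy(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.standard_normal(300)
            y = rng.standard_normal(300)
            h_cond = conditional_entropy(x, y, bins=6)
            h_y = conditional_entropy(np.zeros(300), y, bins=6)  # constant predictor
            assert -1e-12 <= h_cond <= h_y + 1e-12

    def test_constant_predictor_returns_marginal_entropy(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(500)
        yi = quantile_bin(y, 8)
        counts = np.bincount(yi)
        p = counts[counts > 0] / counts.sum()
        h_y = -(p * np.log(p)).sum()
        assert conditional_entropy(np.full(500, 3.3), y, bins=8) == pytest.approx(
            h_y, abs=1e-12
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        base = conditional_entropy(x, y, bins=5)
        assert conditional_entropy(np.exp(x), y, bins=5) == pytest.approx(base, abs=1e-12)
        assert conditional_entropy(x, np.arctan(y), bins=5) == pytest.approx(
            base, abs=1e-12
        )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            conditional_entropy(np.zeros(10), np.zeros(11))
        with pytest.raises(ValueError, match="bins"):
            conditional_entropy(np.arange(10.0), np.arange(10.0), bins=1)
        with pytest.warns(UserWarning, match="sparse"):
            conditional_entropy(np.arange(10.0), np.arange(10.0), bins=8)


class TestStationarityGate:
    def test_trend_statistic_matches_r_reference(self):
        # frozen from R stats::PP.test on the same seeded series
        rng = np.random.default_rng(42)
        x = rng.standard_normal(500)
        rw = np.cumsum(rng.standard_normal(500))
        stat_wn, _ = phillips_perron(x, trend="ct", lshort=True)
        stat_rw, _ = phillips_perron(rw, trend="ct", lshort=True)
        assert stat_wn == pytest.approx(-20.044031, abs=1e-4)
        assert stat_rw == pytest.approx(-2.2864173, abs=1e-4)

    def test_white_noise_passes_without_detrending(self):
        passed = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(1000)
            verdict, _ = check_stationarity(x)
            passed += verdict.stationary and not verdict.detrended
        assert passed >= 95

    def test_linear_ramp_is_detrended_then_stationary(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = 0.01 * np.arange(1000) + 0.1 * rng.standard_normal(1000)
            verdict, out = check_stationarity(x)
            assert verdict.detrended and verdict.stationary
            assert abs(np.polyfit(np.arange(1000), out, 1)[0]) < 1e-3

    def test_random_walk_flagged_in_majority_of_seeds(self):
        flagged = 0
        for seed in range(60):
            rw = np.cumsum(np.random.default_rng(seed).standard_normal(1000))
            verdict, _ = check_stationarity(rw)
            flagged += not verdict.stationary
        assert flagged > 30

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="constant"):
            check_stationarity(np.ones(100))


class TestTruncateCommon:
    def test_cuts_to_shortest_keeping_initial_samples(self):
        epochs = [np.arange(100), np.arange(80), np.arange(120)]
        out = truncate_common(epochs)
        assert [len(e) for e in out] == [80, 80, 80]
        assert np.array_equal(out[2], np.arange(80))

    def test_equal_lengths_and_single_epoch_unchanged(self):
        x = np.arange(50)
        assert np.array_equal(truncate_common([x, x.copy()])[0], x)
        assert np.array_equal(truncate_common([x])[0], x)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            truncate_common([])
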