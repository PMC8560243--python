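"""Wall/blood separation: sigma estimation, thresholding, classification,
the optimized separator and the two baselines."""

import dataclasses
import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import null_blood_config, null_wall_config
from ddsim import (SampledSignal, SeparationSettings, SimConfig,
                   ThresholdSettings, adaptive_threshold,
                   baseline_emd_truncation, baseline_highpass, classify_layers,
                   decompose, estimate_sigma1, layer_sigmas, separate,
                   simulate_composite, tracks_from_imfs)


class TestEstimateSigma1:
    def test_hand_computed_mad(self):
        # median 3, |deviations| [2,1,0,1,2], MAD 1 -> 1/0.6745
        assert estimate_sigma1(np.array([1.0, 2, 3, 4, 5, 1, 2, 3])) > 0
        x = np.array([1.0, 2, 3, 4, 5, 5, 3, 1, 2, 4, 3, 1, 5, 2, 4])
        # direct brute-force evaluation as the oracle
        med = np.median(x)
        expected = np.median(np.abs(x - med)) / 0.6745
        assert estimate_sigma1(x) == pytest.approx(expected, rel=1e-14)

    def test_five_point_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        assert estimate_sigma1(x) == pytest.approx(1.0 / 0.6745)

    def test_constant_series_gives_zero(self):
        assert estimate_sigma1(np.full(16, 2.5)) == 0.0

    def test_gaussian_consistency(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert 0.98 < estimate_sigma1(x) < 1.02


class TestLayerSigmas:
    def test_first_layer_is_sigma1_under_both_rules(self):
        for decay in ("half-energy", "literal"):
            s = layer_sigmas(2.0, 4, ThresholdSettings(sigma_decay=decay))
            assert s[0] == 2.0

    def test_half_energy_rule_third_layer(self):
        assert layer_sigmas(2.0, 3)[2] == pytest.approx(1.0)

    def test_literal_rule_third_layer(self):
        s = layer_sigmas(2.0, 3, ThresholdSettings(sigma_decay="literal"))
        assert s[2] == pytest.approx(0.5)

    def test_ladder_strictly_decreasing(self):
        for decay in ("half-energy", "literal"):
            s = layer_sigmas(1.0, 8, ThresholdSettings(sigma_decay=decay))
            assert np.all(np.diff(s) < 0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            layer_sigmas(-1.0, 3)


class TestAdaptiveThreshold:
    def test_zero_sigma_is_identity(self):
        x = np.random.default_rng(0).standard_normal(64)
        assert np.array_equal(adaptive_threshold(x, 0.0), x)

    def test_reduces_to_soft_threshold_at_zero_steepness(self):
        x = np.linspace(-5, 5, 201)
        out = adaptive_threshold(x, 1.0, ThresholdSettings(sigmoid_steepness=0.0))
        soft = np.where(np.abs(x) > 1.0, np.sign(x) * (np.abs(x) - 1.0), 0.0)
        assert np.allclose(out, soft, atol=1e-14)

    def test_large_inputs_pass_unshrunk(self):
        x = np.array([100.0, -250.0])
        out = adaptive_threshold(x, 1.0, ThresholdSettings(sigmoid_steepness=1.0))
        assert np.max(np.abs(out - x) / np.abs(x)) < 1e-6

    def test_printed_formula_at_reference_point(self):
        # x=1.5, sigma=1, L=1 against arbitrary-precision evaluation
        expected = float(sympy.N(
            sympy.Rational(3, 2)
            - 2 / (1 + sympy.exp(sympy.Rational(9, 4) - 1)), 30))
        out = adaptive_threshold(np.array([1.5]), 1.0,
                                 ThresholdSettings(sigmoid_steepness=1.0))
        assert out[0] == pytest.approx(expected, rel=1e-14)

    def test_below_threshold_zeroed(self):
        x = np.array([0.5, -0.9, 1.0])
        out = adaptive_threshold(x, 1.0)
        assert np.array_equal(out, np.zeros(3))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.ones(4), -0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 10.0),
           st.one_of(st.none(), st.floats(0.0, 100.0)))
    def test_shrinkage_never_exceeds_input(self, seed, sigma, L):
        x = np.random.default_rng(seed).standard_normal(64) * 3
        out = adaptive_threshold(x, sigma, ThresholdSettings(sigmoid_steepness=L))
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)
        assert np.all(np.sign(out) * np.sign(x) >= 0)


class TestClassifyLayers:
    def test_single_tone_is_all_blood(self):
        fs = 10_000.0
        t = np.arange(int(fs)) / fs
        imfset = decompose(SampledSignal(np.sin(2 * np.pi * 300 * t), fs))
        cls = classify_layers(imfset)
        assert cls.k >= 2          # layer 1 is blood
        assert cls.M == cls.N + 1 or cls.M > 1

    def test_all_blood_layers_use_boundary_convention(self):
        fs = 10_000.0
        t = np.arange(int(0.5 * fs)) / fs
        x = np.sin(2 * np.pi * 400 * t) + np.sin(2 * np.pi * 900 * t)
        imfset = decompose(SampledSignal(x, fs))
        cls = classify_layers(imfset)
        assert cls.k == cls.M
        assert len(list(cls.wall_layers)) + len(list(cls.mixed_layers)) \
            + len(list(cls.blood_layers)) == cls.N

    def test_zero_layers_rejected(self):
        imfset = decompose(SampledSignal(np.linspace(0, 1, 64), fs=64.0))
        with pytest.raises(ValueError, match="layer"):
            classify_layers(imfset)

    def test_partition_respects_ground_truth_dominance(self):
        """Wall-dominated layers land in the wall partition and
        blood-dominated layers stay out of it, across seeded runs."""
        good = 0
        n_runs = 10
        for seed in range(n_runs):
            truth = simulate_composite(SimConfig(seed=seed, duration=1.0))
            x = truth.composite.real_view()
            b = truth.blood_truth.real_view().samples
            w = truth.wall_truth.real_view().samples
            imfset = decompose(x)
            res = separate(truth.composite, imfset=imfset)
            M, N = res.classification.M, res.classification.N
            consistent = True
            for i in range(1, N + 1):
                layer = imfset.layer(i)
                energy = np.sum(layer ** 2)
                wall_en = np.dot(layer, w) ** 2 / np.sum(w * w)
                blood_en = np.dot(layer, b) ** 2 / np.sum(b * b)
                if wall_en > 0.9 * energy and i < M:
                    consistent = False
                if blood_en > 0.5 * energy and i >= M:
                    consistent = False
            good += consistent
        assert good >= 0.9 * n_runs


class TestSeparate:
    def test_conservation(self, default_truth):
        res = separate(default_truth.composite)
        x = default_truth.composite.real_view().samples
        err = np.max(np.abs(res.blood.samples + res.wall.samples - x))
        assert err <= 1e-9 * np.max(np.abs(x))

    def test_null_wall_recovery(self):
        for seed in range(3):
            truth = simulate_composite(null_wall_config(seed))
            res = separate(truth.composite)
            assert res.wall.rms() < 0.10 * res.blood.rms()

    def test_null_blood_recovery(self):
        for seed in range(3):
            truth = simulate_composite(null_blood_config(seed))
            res = separate(truth.composite)
            assert res.blood.rms() < 0.10 * res.wall.rms()

    def test_beats_baselines_on_correlation(self):
        wins = 0
        n_runs = 5
        for seed in range(n_runs):
            truth = simulate_composite(SimConfig(seed=seed, duration=1.0))
            ref = truth.blood_truth.real_view().samples
            imfset = decompose(truth.composite.real_view())
            corr = {}
            corr["opt"] = np.corrcoef(
                separate(truth.composite, imfset=imfset).blood.samples, ref)[0, 1]
            corr["trunc"] = np.corrcoef(
                baseline_emd_truncation(truth.composite, imfset=imfset).blood.samples,
                ref)[0, 1]
            corr["hpf"] = np.corrcoef(
                baseline_highpass(truth.composite).blood.samples, ref)[0, 1]
            wins += corr["opt"] >= max(corr.values())
        assert wins >= n_runs - 1

    def test_idempotence_on_separated_blood(self):
        truth = simulate_composite(SimConfig(seed=7, duration=1.0))
        first = separate(truth.composite)
        second = separate(first.blood)
        change = np.sqrt(np.mean((second.blood.samples - first.blood.samples) ** 2))
        assert change < 0.15 * first.blood.rms()

    def test_sigma_ladder_reported(self, default_truth):
        res = separate(default_truth.composite)
        assert res.per_layer_sigma is not None
        assert len(res.per_layer_sigma) == res.classification.N


class TestBaselineTruncation:
    def test_keep_all_layers_returns_composite(self, short_truth):
        x = short_truth.composite.real_view()
        imfset = decompose(x)
        res = baseline_emd_truncation(short_truth.composite, n_keep=imfset.n_imfs,
                                      imfset=imfset)
        # blood = all IMFs, wall = residual only
        assert np.allclose(res.wall.samples, imfset.residual)

    def test_zero_keep_rejected(self, short_truth):
        with pytest.raises(ValueError):
            baseline_emd_truncation(short_truth.composite, n_keep=0)

    def test_excess_keep_clamps_with_warning(self, short_truth):
        with pytest.warns(UserWarning, match="clamp"):
            baseline_emd_truncation(short_truth.composite, n_keep=99)

    def test_conservation(self, short_truth):
        res = baseline_emd_truncation(short_truth.composite)
        x = short_truth.composite.real_view().samples
        assert np.max(np.abs(res.blood.samples + res.wall.samples - x)) < 1e-9


class TestBaselineHighpass:
    def test_low_cutoff_passes_nearly_everything(self, two_tone):
        # with no content near DC, a near-zero cutoff approaches identity
        # (interior: the zero-phase filter's long impulse response leaves
        # edge transients at such low cutoffs)
        res = baseline_highpass(two_tone, cutoff=0.5)
        g = slice(500, -500)
        assert np.corrcoef(res.blood.samples[g], two_tone.samples[g])[0, 1] > 0.99

    def test_slow_tone_is_removed(self):
        fs = 10_000.0
        t = np.arange(int(fs)) / fs
        tone = SampledSignal(np.sin(2 * np.pi * 10 * t), fs)
        res = baseline_highpass(tone, cutoff=100.0)
        assert res.blood.rms() < 0.05 * tone.rms()

    def test_conservation_exact(self, short_truth):
        res = baseline_highpass(short_truth.composite)
        x = short_truth.composite.real_view().samples
        assert np.allclose(res.blood.samples + res.wall.samples, x, atol=1e-12)

    def test_cutoff_out_of_range_rejected(self, short_truth):
        with pytest.raises(ValueError):
            baseline_highpass(short_truth.composite, cutoff=short_truth.composite.fs)
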