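"""Hybrid EMD + AR features: normalization, padding, least-squares fits,
IMF screening, eigenvectors and class templates."""

import numpy as np
import pytest

from vi_emdar.containers import FeatureMatrix
from vi_emdar.emd import decompose, IMFDecomposition
from vi_emdar.emdar import (energy_normalize, pad_imf_count, fpe_order,
                            ls_ar_fit, screen_imfs, emdar_features,
                            emdar_feature_matrix, class_templates)
from vi_emdar.preprocess import preprocess_trials
from vi_emdar.synth import generate_dataset, SynthConfig
from test_ar import simulate_ar

FS = 1000.0
T4 = np.arange(4000) / FS


class TestEnergyNormalize:
    def test_unit_energy_after_normalization(self):
        c = np.random.default_rng(0).standard_normal(1000)
        dt = 1e-3
        cbar = energy_normalize(c, dt)
        assert np.sum(cbar ** 2) * dt == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_on_unit_energy_input(self):
        c = np.random.default_rng(1).standard_normal(500)
        dt = 2e-3
        once = energy_normalize(c, dt)
        twice = energy_normalize(once, dt)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_scale_invariance(self):
        c = np.random.default_rng(2).standard_normal(500)
        np.testing.assert_allclose(energy_normalize(7.0 * c, 1e-3),
                                   energy_normalize(c, 1e-3), atol=1e-12)

    def test_all_zero_returned_unchanged(self):
        np.testing.assert_array_equal(energy_normalize(np.zeros(100), 1e-3),
                                      np.zeros(100))

    def test_literal_variant_divides_by_energy(self):
        c = np.full(100, 2.0)
        lit = energy_normalize(c, 1.0, literal=True)
        np.testing.assert_allclose(lit, c / 400.0)


class TestPadImfCount:
    def _dec(self, n_imfs, length=64):
        rng = np.random.default_rng(n_imfs)
        return IMFDecomposition([rng.standard_normal(length) for _ in range(n_imfs)],
                                np.zeros(length), [1] * n_imfs)

    def test_all_padded_to_maximum(self):
        out = pad_imf_count([self._dec(6), self._dec(8), self._dec(7)])
        assert [d.n for d in out] == [8, 8, 8]
        np.testing.assert_array_equal(out[0].imfs[6], 0.0)
        np.testing.assert_array_equal(out[0].imfs[7], 0.0)

    def test_genuine_imfs_preserved_in_order(self):
        d6 = self._dec(6)
        out = pad_imf_count([d6, self._dec(8)])
        for j in range(6):
            np.testing.assert_array_equal(out[0].imfs[j], d6.imfs[j])

    def test_equal_counts_unchanged(self):
        ds = [self._dec(5), self._dec(5)]
        assert pad_imf_count(ds) == ds

    def test_single_decomposition_unchanged(self):
        d = self._dec(4)
        assert pad_imf_count([d]) == [d]


class TestLsArFit:
    def test_recovers_known_generator(self):
        """c(t) = 0.5 c(t-1) + e(t) maps to h1 = -0.5 in the
        c(t) + sum h_k c(t-k) = e(t) convention."""
        c = simulate_ar([0.5], 10_000, seed=0)
        ev = ls_ar_fit(c, 1)
        assert abs(ev.h[0] - (-0.5)) < 0.03
        assert ev.e2 == pytest.approx(1.0, rel=0.05)

    def test_zero_padded_imf_convention(self):
        ev = ls_ar_fit(np.zeros(1000), 4)
        np.testing.assert_array_equal(ev.h, 0.0)
        assert ev.e2 == 0.0 and ev.padded

    def test_ls_agrees_with_burg_after_sign_mapping(self):
        from vi_emdar.ar import burg_fit
        y = simulate_ar([1.5, -0.75], 20_000, seed=1)
        ls = ls_ar_fit(y, 2)
        bg = burg_fit(y, 2)
        assert np.max(np.abs(-ls.h - bg.coeffs)) < 0.02

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ls_ar_fit(np.full(1000, 3.0), 2)


class TestFpeOrder:
    def test_modal_order_on_simulated_ar2(self):
        orders = [fpe_order(simulate_ar([1.5, -0.75], 4_000, seed=s), 8)
                  for s in range(20)]
        values, counts = np.unique(orders, return_counts=True)
        assert values[np.argmax(counts)] == 2

    def test_white_noise_modal_selection_low(self):
        orders = [fpe_order(np.random.default_rng(s).standard_normal(4_000), 8)
                  for s in range(20)]
        values, counts = np.unique(orders, return_counts=True)
        assert values[np.argmax(counts)] <= 2

    def test_mmax_one(self):
        assert fpe_order(simulate_ar([0.5], 1_000, seed=0), 1) == 1


class TestScreenImfs:
    def test_two_tone_contribution_split(self):
        """Tones with variances 4 and 1 screen to roughly 80/20."""
        x = 2.0 * np.sin(2 * np.pi * 10 * T4) + np.sin(2 * np.pi * 1 * T4)
        dec = decompose(x)
        rep = screen_imfs(dec, x)
        assert abs(rep.contribution_pct[0] - 80.0) < 5.0
        assert abs(rep.contribution_pct[1] - 20.0) < 5.0

    def test_rates_sum_to_hundred(self):
        x = np.random.default_rng(0).standard_normal(2000)
        rep = screen_imfs(decompose(x), x)
        assert rep.contribution_pct.sum() == pytest.approx(100.0, abs=0.01)
        assert np.all(rep.contribution_pct >= 0)
        assert np.all(np.abs(rep.correlation) <= 1.0 + 1e-12)

    def test_single_imf_full_contribution(self):
        x = np.sin(2 * np.pi * 10 * np.arange(2000) / FS)
        dec = decompose(x)
        rep = screen_imfs(IMFDecomposition(dec.imfs[:1], dec.residual, [1]), x)
        assert rep.contribution_pct[0] == pytest.approx(100.0)
        assert rep.selected == [1]

    def test_minimum_selection_of_four(self):
        x = np.random.default_rng(1).standard_normal(4000)
        rep = screen_imfs(decompose(x), x)
        assert len(rep.selected) >= min(4, len(rep.contribution_pct))

    def test_empty_decomposition(self):
        rep = screen_imfs(IMFDecomposition([], np.zeros(100), []), np.zeros(100))
        assert rep.selected == [] and rep.contribution_pct.size == 0


class TestEmdarFeatures:
    def test_dimension_arithmetic_and_names(self):
        trial = np.random.default_rng(0).standard_normal((2, 1000))
        v, names, _ = emdar_features(trial, ["FP2", "F8"], k_imfs=4, m=4)
        assert v.shape == (2 * 4 * 5,)
        assert names[0] == "FP2_IMF1_h1" and names[4] == "FP2_IMF1_e2"
        assert names[-1] == "F8_IMF4_e2"

    def test_zero_trial_all_zero_with_padding_flags(self):
        v, _, padded = emdar_features(np.zeros((2, 1000)), ["FP2", "F8"])
        np.testing.assert_array_equal(v, 0.0)
        assert all(padded)

    def test_deterministic(self):
        trial = np.random.default_rng(1).standard_normal((2, 1000))
        v1, _, _ = emdar_features(trial, ["FP2", "F8"])
        v2, _, _ = emdar_features(trial, ["FP2", "F8"])
        np.testing.assert_array_equal(v1, v2)

    def test_scale_invariance_of_feature_vector(self):
        """Energy normalization makes every coordinate invariant to positive
        rescaling of the trial."""
        trial = np.random.default_rng(2).standard_normal((2, 1000))
        v1, _, _ = emdar_features(trial, ["FP2", "F8"])
        v2, _, _ = emdar_features(3.7 * trial, ["FP2", "F8"])
        np.testing.assert_allclose(v2, v1, atol=1e-6)

    def test_fpe_mode_runs(self):
        trial = np.random.default_rng(3).standard_normal((2, 1000))
        v, names, _ = emdar_features(trial, ["FP2", "F8"], k_imfs=2, m="fpe")
        assert np.all(np.isfinite(v)) and len(names) == len(v)


class TestFeatureMatrixAndTemplates:
    def test_rectangular_matrix_under_imf_padding(self, tiny_cfg):
        ts = preprocess_trials(generate_dataset(tiny_cfg), band=None, notch=True)
        fm = emdar_feature_matrix(ts, k_imfs=4, m=4)
        assert fm.X.shape == (ts.n_trials, 40)
        assert np.all(np.isfinite(fm.X))

    def test_templates_average_class_rows(self):
        X = np.array([[1.0, 2.0, 0.5], [3.0, 4.0, 1.5], [10.0, 20.0, 5.0]])
        fm = FeatureMatrix(X, ["FP2_IMF1_h1", "FP2_IMF1_h2", "FP2_IMF1_e2"],
                           np.array(["static", "static", "moving"]))
        tmpl = {(t.class_label, t.imf_index): t for t in class_templates(fm)}
        np.testing.assert_allclose(tmpl[("static", 1)].h_bar, [2.0, 3.0])
        assert tmpl[("static", 1)].e2_bar == pytest.approx(1.0)
        np.testing.assert_allclose(tmpl[("moving", 1)].h_bar, [10.0, 20.0])

    def test_identical_samples_give_their_own_template(self):
        X = np.array([[1.0, 0.5], [1.0, 0.5], [2.0, 0.25]])
        fm = FeatureMatrix(X, ["F8_IMF2_h1", "F8_IMF2_e2"],
                           np.array(["static", "static", "moving"]))
        tmpl = {t.class_label: t for t in class_templates(fm)}
        np.testing.assert_allclose(tmpl["static"].h_bar, [1.0])
        assert tmpl["static"].e2_bar == pytest.approx(0.5)

    def test_missing_class_rejected(self):
        fm = FeatureMatrix(np.ones((2, 2)), ["F8_IMF1_h1", "F8_IMF1_e2"],
                           np.array(["static", "static"]))
        with pytest.raises(ValueError, match="moving"):
            class_templates(fm)

    def test_templates_separate_classes_on_contrasted_data(self):
        cfg = SynthConfig(n_trials_per_class=15, fs=250.0, seed=21, alpha_contrast=2.0)
        ts = preprocess_trials(generate_dataset(cfg), band=None, notch=True)
        fm = emdar_feature_matrix(ts, k_imfs=4, m=4)
        tmpl = class_templates(fm)
        stat = {(t.imf_index,): t for t in tmpl if t.class_label == "static"}
        # at least one FP2 coordinate separates by > 2 pooled SEs
        sep = False
        for t in tmpl:
            if t.class_label != "moving":
                continue
            other = stat[(t.imf_index,)]
            col_mask = fm.labels == "moving"
            diff = np.abs(np.r_[t.h_bar, t.e2_bar] - np.r_[other.h_bar, other.e2_bar])
            pooled_se = fm.X.std(axis=0).mean() / np.sqrt(col_mask.sum()) + 1e-12
            if np.any(diff > 2 * pooled_se):
                sep = True
        assert sep
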