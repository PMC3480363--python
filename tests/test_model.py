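"""Mutual-information selection, calibration fit, and BASM scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import attentrain as at
from attentrain.model import (basm_score, calibration_features,
                              epoch_features, leave_one_out_accuracy,
                              mutual_information, select_features)


class TestMutualInformation:
    def test_perfect_separation_near_one_bit(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        x = np.concatenate([rng.normal(-5, 0.1, n // 2),
                            rng.normal(5, 0.1, n // 2)])
        assert mutual_information(x, y) == pytest.approx(1.0, abs=0.05)

    def test_constant_feature_zero(self):
        assert mutual_information(np.ones(50), np.repeat([0, 1], 25)) == 0.0

    def test_symmetric_under_label_relabelling(self, rng):
        x = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        assert mutual_information(x, y) == mutual_information(x, 1 - y)

    def test_independent_feature_below_permutation_null(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = np.repeat([0, 1], n // 2)
        observed = mutual_information(x, y)
        null = np.array([mutual_information(x, rng.permutation(y))
                         for _ in range(1000)])
        assert observed <= np.quantile(null, 0.95)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=80)
        y = r.integers(0, 2, size=80)
        base = mutual_information(x, y)
        assert mutual_information(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert mutual_information(3 * x - 7, y) == pytest.approx(base, abs=1e-12)

    def test_bounds_for_binary_labels(self, rng):
        for _ in range(20):
            x = rng.normal(size=60)
            y = rng.integers(0, 2, size=60)
            mi = mutual_information(x, y)
            assert 0.0 <= mi <= 1.0


class TestSelectFeatures:
    def test_k_equals_all_returns_every_index(self, rng):
        F = rng.normal(size=(60, 24))
        y = rng.integers(0, 2, size=60)
        assert sorted(select_features(F, y, k=24)) == list(range(24))

    def test_exact_tie_broken_by_lower_index(self, rng):
        y = np.repeat([0, 1], 30)
        x = rng.normal(size=60)
        F = np.column_stack([x, x])  # identical features, identical MI
        assert select_features(F, y, k=2) == [0, 1]

    def test_informative_band_features_selected(self, separated_calibration):
        # the default profiles differ only in theta amplitude, so selection
        # must favour features in bands overlapping 4-8 Hz
        F, y = calibration_features(separated_calibration, at.default_bank())
        selected = select_features(F, y, k=6)
        theta_bands = {j for j, (lo, hi) in enumerate(at.default_bank().bands)
                       if lo < 8.0}
        assert all((j % 8) in theta_bands for j in selected)

    def test_invalid_k_rejected(self, rng):
        F = rng.normal(size=(10, 24))
        y = np.repeat([0, 1], 5)
        for k in (0, -1, 25):
            with pytest.raises(ValueError):
                select_features(F, y, k=k)


class TestFitAttentionModel:
    def test_refit_is_deterministic(self, separated_calibration):
        m1 = at.fit_attention_model(separated_calibration)
        m2 = at.fit_attention_model(separated_calibration)
        assert m1.selected == m2.selected
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.display_center == m2.display_center

    def test_single_label_rejected(self):
        rec = at.simulate_eeg(at.ATTENTIVE_PROFILE, 10.0, seed=0)
        with pytest.raises(ValueError):
            at.CalibrationDataset(epochs=[(rec, "attentive")] * 4)

    def test_class_means_anchor_display_map(self, separated_calibration,
                                            fitted_model):
        F, y = calibration_features(separated_calibration, fitted_model.bank)
        att_mean = F[y > 0].mean(axis=0)
        rel_mean = F[y < 0].mean(axis=0)
        assert basm_score(fitted_model, att_mean).display >= 50.0
        assert basm_score(fitted_model, att_mean).display == pytest.approx(75.0, abs=1.0)
        assert basm_score(fitted_model, rel_mean).display == pytest.approx(25.0, abs=1.0)


class TestBASMScore:
    def test_logistic_limits_and_monotonicity(self, fitted_model):
        lo = fitted_model.display_score(-1e9)
        hi = fitted_model.display_score(1e9)
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(100.0, abs=1e-9)
        raws = np.linspace(-10, 10, 101)
        displays = [fitted_model.display_score(r) for r in raws]
        assert np.all(np.diff(displays) >= 0)

    def test_raw_unbounded_display_clamped(self, fitted_model):
        assert 0.0 <= fitted_model.display_score(1e6) <= 100.0

    def test_feature_length_mismatch_rejected(self, fitted_model):
        with pytest.raises(ValueError):
            fitted_model.raw_score(np.zeros(23))

    def test_bank_mismatch_rejected(self, fitted_model, rng):
        from attentrain.features import FFT_LENGTH
        from attentrain.recording import Block
        blk = Block(start=0.0, fs=128.0, data=rng.normal(size=(2, FFT_LENGTH)))
        fv = at.extract_features([blk], bank=at.classical_bank())
        with pytest.raises(ValueError):
            basm_score(fitted_model, fv)

    def test_json_round_trip_lossless(self, fitted_model, tmp_path,
                                      separated_calibration):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        back = at.AttentionModel.from_json(path)
        epoch, _ = separated_calibration.epochs[0]
        fv = epoch_features(epoch, fitted_model.bank)
        s1 = basm_score(fitted_model, fv)
        s2 = basm_score(back, fv)
        assert s1.raw == pytest.approx(s2.raw, abs=1e-12)
        assert s1.display == pytest.approx(s2.display, abs=1e-12)


class TestEndToEndDiscrimination:
    def test_separated_profiles_high_loo_accuracy(self, separated_calibration):
        assert leave_one_out_accuracy(separated_calibration) >= 0.90

    def test_shuffled_labels_fall_to_chance(self, separated_calibration):
        F, y = calibration_features(separated_calibration, at.default_bank())
        shuffled = np.random.default_rng(17).permutation(y)
        acc = leave_one_out_accuracy(separated_calibration,
                                     labels_override=shuffled)
        assert 0.35 <= acc <= 0.65
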