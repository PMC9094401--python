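"""AUC scoring, calibration fitting, and comparison summaries."""

import numpy as np
import pytest

from voxeldecode import (
    CalibrationModel,
    DecodingResult,
    auc,
    auc_threshold_for_t,
    fit_calibration,
    rank_models,
    summarize_comparison,
    t_for_auc,
)


def brute_force_auc(scores, labels, positive="SI"):
    """Exhaustive positive-negative pair enumeration with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.2, 0.1], ["SI", "SI", "VG", "VG"]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, ["SI", "VG"] * 3) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], ["SI", "SI"])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        # random score/label sets of size <= 8, with deliberate tie mass
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        labels = np.array(["VG"] * n)
        labels[rng.permutation(n)[: max(1, n // 2)]] = "SI"
        if len(set(labels)) < 2:
            labels[0] = "SI" if labels[0] == "VG" else "VG"
        scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=n)
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(5))
    def test_invariances(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        scores = rng.standard_normal(n)  # continuous: no ties
        labels = np.array(["SI", "VG"] * (n // 2))
        base = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(base)
        assert auc(-scores, labels) == pytest.approx(1.0 - base)


class TestCalibration:
    def test_exact_linear_data(self):
        aucs = np.array([0.5, 0.6, 0.7, 0.8])
        model = fit_calibration(aucs, 10.0 * aucs - 2.0)
        assert model.slope == pytest.approx(10.0)
        assert model.intercept == pytest.approx(-2.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_two_points_interpolate(self):
        model = fit_calibration([0.5, 0.9], [1.0, 7.0])
        assert model.r_squared == pytest.approx(1.0)
        assert model.n_points == 2

    def test_noisy_recovery_within_ten_percent(self):
        # |T| = 20*AUC - 8 + N(0, 0.5), n = 100
        rng = np.random.default_rng(123)
        aucs = rng.uniform(0.5, 0.9, 100)
        ts = 20.0 * aucs - 8.0 + rng.normal(0, 0.5, 100)
        model = fit_calibration(aucs, ts)
        assert model.slope == pytest.approx(20.0, rel=0.1)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([0.6, 0.6, 0.6], [1.0, 2.0, 3.0])

    def test_threshold_round_trip_through_reference_point(self):
        # a calibration passing through (AUC 0.61, |T| 4.08) must map back
        model = CalibrationModel(slope=20.0, intercept=4.08 - 20.0 * 0.61,
                                 r_squared=0.95, n_points=800)
        assert t_for_auc(model, 0.61) == pytest.approx(4.08)
        assert auc_threshold_for_t(model, 4.08) == pytest.approx(0.61)

    def test_identity_model_and_exact_inverse(self):
        ident = CalibrationModel(slope=1.0, intercept=0.0, r_squared=1.0, n_points=2)
        assert auc_threshold_for_t(ident, 0.7) == pytest.approx(0.7)
        model = CalibrationModel(slope=-3.7, intercept=1.3, r_squared=0.5, n_points=10)
        for value in (0.51, 0.61, 0.93):
            assert auc_threshold_for_t(model, t_for_auc(model, value)) == pytest.approx(
                value, abs=1e-12
            )

    def test_zero_slope_rejected(self):
        flat = CalibrationModel(slope=0.0, intercept=1.0, r_squared=0.0, n_points=5)
        with pytest.raises(ValueError):
            auc_threshold_for_t(flat, 4.08)


def _result(voxel, band, method, auc_mean):
    return DecodingResult(
        voxel_id=voxel, band_label=band, method=method, auc_mean=auc_mean,
        auc_per_repetition=[auc_mean], split_seed=0, n_repetitions=1,
    )


class TestComparisonSummary:
    def test_hand_counted_toy(self):
        cnn_aucs = [0.7, 0.65, 0.5, 0.62]
        alff_aucs = [0.62, 0.5, 0.63, 0.59]
        cnn = [_result("v", f"b{i}", "cnn", a) for i, a in enumerate(cnn_aucs)]
        alff = [_result("v", f"b{i}", "alff", a) for i, a in enumerate(alff_aucs)]
        s = summarize_comparison(cnn, alff, 0.61)
        assert s.n_pairs == 4
        assert s.n_efficient_cnn == 3
        assert s.n_efficient_alff == 2
        assert s.n_efficient_both == 1
        assert s.n_efficient_either == 4

    def test_nothing_efficient(self):
        cnn = [_result("v", f"b{i}", "cnn", 0.55) for i in range(3)]
        alff = [_result("v", f"b{i}", "alff", 0.5) for i in range(3)]
        s = summarize_comparison(cnn, alff, 0.61)
        assert (s.n_efficient_cnn, s.n_efficient_alff, s.n_efficient_either) == (0, 0, 0)
        assert s.frac_cnn_higher_within_both is None
        assert s.frac_cnn_higher_within_either is None

    def test_ties_favor_neither(self):
        cnn = [_result("v", f"b{i}", "cnn", 0.8) for i in range(4)]
        alff = [_result("v", f"b{i}", "alff", 0.8) for i in range(4)]
        s = summarize_comparison(cnn, alff, 0.61)
        assert s.n_efficient_both == 4
        assert s.frac_cnn_higher_within_both == 0.0

    def test_unpaired_records_rejected(self):
        cnn = [_result("v", "b0", "cnn", 0.7)]
        alff = [_result("v", "b1", "alff", 0.7)]
        with pytest.raises(ValueError, match="unpaired"):
            summarize_comparison(cnn, alff, 0.61)

    @pytest.mark.parametrize("seed", range(5))
    def test_inclusion_exclusion_identity(self, seed):
        rng = np.random.default_rng(seed)
        keys = [(f"v{i}", f"b{j}") for i in range(3) for j in range(5)]
        cnn = [_result(v, b, "cnn", rng.uniform(0.3, 0.95)) for v, b in keys]
        alff = [_result(v, b, "alff", rng.uniform(0.3, 0.95)) for v, b in keys]
        s = summarize_comparison(cnn, alff, 0.61)
        assert s.n_efficient_either == (
            s.n_efficient_cnn + s.n_efficient_alff - s.n_efficient_both
        )
        assert s.n_efficient_both <= min(s.n_efficient_cnn, s.n_efficient_alff)


class TestRankModels:
    def _voxel_results(self, voxel, band_aucs, original_auc):
        results = [_result(voxel, f"b{i}", "cnn", a) for i, a in enumerate(band_aucs)]
        results.append(_result(voxel, "original", "cnn", original_auc))
        return results

    def test_original_best_everywhere(self):
        results = []
        for v in ("v1", "v2"):
            results += self._voxel_results(v, np.linspace(0.5, 0.7, 32), 0.95)
        _, mean_rank = rank_models(results)
        assert mean_rank == 1.0

    def test_original_worst_everywhere(self):
        results = []
        for v in ("v1", "v2"):
            results += self._voxel_results(v, np.linspace(0.5, 0.7, 32), 0.2)
        _, mean_rank = rank_models(results)
        assert mean_rank == 33.0

    def test_hand_ranked_toy(self):
        # voxel A: original is 2nd of 3; voxel B: original is 3rd of 3
        results = self._voxel_results("A", [0.9, 0.5], 0.7)
        results += self._voxel_results("B", [0.9, 0.8], 0.7)
        per_voxel, mean_rank = rank_models(results, n_expected=3)
        assert per_voxel == {"A": 2.0, "B": 3.0}
        assert mean_rank == pytest.approx(2.5)

    def test_wrong_model_count_rejected(self):
        with pytest.raises(ValueError, match="expected 33"):
            rank_models(self._voxel_results("A", [0.6, 0.7], 0.5))
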