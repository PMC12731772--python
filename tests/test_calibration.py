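"""PAV isotonic regression, monotone spline fitting and simplex-preserving
multi-class calibration."""

import numpy as np
import pytest
from sklearn.isotonic import IsotonicRegression

from t2drisk.calibration import (
    CalibrationModel,
    MonotoneSpline,
    apply_calibration,
    fit_calibration,
    fit_monotone_spline,
    one_vs_all_labels,
    pav_isotonic,
)


class TestOneVsAll:
    def test_definition(self):
        assert one_vs_all_labels([1, 2, 1, 3], 1).tolist() == [1, 0, 1, 0]

    def test_partition_sums_to_one(self):
        y = np.array([1, 2, 3, 2, 1, 3])
        total = sum(one_vs_all_labels(y, c) for c in (1, 2, 3))
        assert np.array_equal(total, np.ones(6))

    def test_degenerate_single_class(self):
        assert one_vs_all_labels([2, 2, 2], 2).tolist() == [1, 1, 1]


class TestPAV:
    def test_no_violators_identity(self):
        y = np.array([0.0, 0.2, 0.5, 0.9])
        assert np.allclose(pav_isotonic(np.sort(np.random.rand(4)), y), y)

    def test_single_pooled_block(self):
        assert pav_isotonic([0.2, 0.8], [1.0, 0.0]).tolist() == [0.5, 0.5]

    def test_alternating_pattern(self):
        fit = pav_isotonic([0.1, 0.3, 0.6, 0.9], [0.0, 1.0, 0.0, 1.0])
        assert np.allclose(fit, [0.0, 0.5, 0.5, 1.0])

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            pav_isotonic([0.5, 0.2], [0, 1])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pav_isotonic([0.1, 0.2], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_isotonic(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        p = np.sort(rng.random(n))
        y = (rng.random(n) < p).astype(float)
        ours = pav_isotonic(p, y)
        ref = IsotonicRegression().fit(p, y).predict(p)
        assert np.allclose(ours, ref, atol=1e-10)


class TestMonotoneSpline:
    def test_nodes_reproduce_pav_block_values(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(40))
        y = rng.integers(0, 2, 40).astype(float)
        spline = fit_monotone_spline(p, y)
        assert np.allclose(spline(spline.node_x), spline.node_y, atol=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_monotone_and_within_blocks_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        p = np.sort(rng.random(n))
        y = (rng.random(n) < p).astype(float)
        spline = fit_monotone_spline(p, y)
        grid = np.linspace(0, 1, 500)
        vals = spline(grid)
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals.min() >= 0 and vals.max() <= 1
        # exact agreement with PAV block values at the nodes
        assert np.allclose(spline(spline.node_x), spline.node_y, atol=1e-12)
        # no overshoot between consecutive nodes
        for lo, hi, vlo, vhi in zip(
            spline.node_x[:-1], spline.node_x[1:], spline.node_y[:-1], spline.node_y[1:]
        ):
            seg = vals[(grid >= lo) & (grid <= hi)]
            if seg.size:
                assert seg.min() >= vlo - 1e-9 and seg.max() <= vhi + 1e-9

    def test_step_data_brackets_half(self):
        p = np.linspace(0, 1, 20)
        y = (p > 0.5).astype(float)
        spline = fit_monotone_spline(p, y)
        assert spline(0.1) <= 0.5 and spline(0.9) >= 0.5

    def test_constant_labels_constant_spline(self):
        spline = fit_monotone_spline([0.1, 0.4, 0.9], [0.3, 0.3, 0.3])
        assert np.allclose(spline(np.linspace(0, 1, 50)), 0.3)

    def test_constant_extrapolation(self):
        spline = fit_monotone_spline([0.3, 0.4, 0.6], [0.0, 0.5, 1.0])
        assert spline(0.0) == spline(0.3)
        assert spline(1.0) == spline(0.6)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_monotone_spline([0.5], [1.0])

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            fit_monotone_spline([0.9, 0.1], [0, 1])

    def test_identity_recovery_on_bernoulli_labels(self):
        """With y ~ Bernoulli(p) the calibration map should approach the
        identity; mean absolute deviation on [0.1, 0.9] below 0.1 at n=2000."""
        rng = np.random.default_rng(12)
        p = np.sort(rng.random(2000))
        y = (rng.random(2000) < p).astype(float)
        spline = fit_monotone_spline(p, y)
        grid = np.linspace(0.1, 0.9, 200)
        assert np.mean(np.abs(spline(grid) - grid)) < 0.1


class TestCalibrationModel:
    def test_uniform_probabilities_fit_class_frequency(self):
        # fully tied raw scores pool to a single node at the class frequency
        n = 400
        y = np.repeat(["A", "B", "C", "D"], n // 4)
        P = np.full((n, 4), 0.25)
        model = fit_calibration(P, y)
        for cls in "ABCD":
            assert model.splines[cls](0.25) == pytest.approx(0.25, abs=1e-12)

    def test_tied_samples_with_opposite_labels_pool_to_half(self):
        P = np.tile([[0.6, 0.4]], (4, 1))
        model = fit_calibration(P, np.array(["A", "B", "A", "B"]), classes=("A", "B"))
        assert model.splines["A"](0.6) == pytest.approx(0.5)

    def test_absent_class_raises(self):
        P = np.full((4, 4), 0.25)
        with pytest.raises(ValueError, match="C"):
            fit_calibration(P, np.array(["A", "B", "A", "B"]))

    def test_rank_preservation_per_class(self, fitted_results):
        model = fitted_results.calibration
        grid = np.linspace(0, 1, 300)
        for cls in model.classes:
            vals = model.splines[cls](grid)
            assert np.all(np.diff(vals) >= -1e-12)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        P = rng.dirichlet(np.ones(4), 100)
        y = np.array(list("ABCD") * 25)
        model = fit_calibration(P, y)
        path = tmp_path / "cal.json"
        model.to_json(path)
        model2 = CalibrationModel.from_json(path)
        x = rng.random(50)
        for cls in "ABCD":
            assert np.allclose(model.splines[cls](x), model2.splines[cls](x))


class TestApplyCalibration:
    def _model(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(4), n)
        y = rng.choice(list("ABCD"), n)
        return fit_calibration(P, y), P, y

    def test_simplex_conservation(self):
        model, P, _ = self._model()
        P2 = np.random.default_rng(5).dirichlet(np.ones(4), 1000)
        out = apply_calibration(model, P2)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert (out >= 0).all()

    def test_identity_splines_are_noop(self):
        splines = {c: MonotoneSpline([0.0, 1.0], [0.0, 1.0]) for c in "ABCD"}
        model = CalibrationModel(splines=splines, classes=tuple("ABCD"))
        P = np.random.default_rng(2).dirichlet(np.ones(4), 50)
        assert np.allclose(apply_calibration(model, P), P, atol=1e-12)

    def test_constant_splines_give_uniform(self):
        splines = {c: MonotoneSpline([0.5], [0.3]) for c in "ABCD"}
        model = CalibrationModel(splines=splines, classes=tuple("ABCD"))
        out = apply_calibration(model, np.random.default_rng(3).dirichlet(np.ones(4), 20))
        assert np.allclose(out, 0.25)

    def test_degenerate_row_uniform_fallback_warns(self):
        splines = {c: MonotoneSpline([0.0, 1.0], [0.0, 0.0]) for c in "ABCD"}
        model = CalibrationModel(splines=splines, classes=tuple("ABCD"))
        with pytest.warns(UserWarning, match="fallback"):
            out = apply_calibration(model, np.full((3, 4), 0.25))
        assert np.allclose(out, 0.25)

    def test_does_not_degrade_training_log_loss(self):
        """Isotonic-style refitting should not worsen one-vs-all log-loss on
        the data it was fitted to, beyond a small tolerance."""
        rng = np.random.default_rng(8)
        n = 2000
        # miscalibrated scores: true P(class) distorted by a power transform
        base = rng.dirichlet(np.ones(4) * 2, n)
        y_idx = np.array([rng.choice(4, p=row) for row in base])
        y = np.array(list("ABCD"))[y_idx]
        P_raw = base ** 2
        P_raw /= P_raw.sum(axis=1, keepdims=True)
        model = fit_calibration(P_raw, y)
        P_cal = apply_calibration(model, P_raw)

        def ovr_log_loss(P):
            eps = 1e-9
            total = 0.0
            for i, cls in enumerate("ABCD"):
                t = (y == cls).astype(float)
                total += -np.mean(t * np.log(P[:, i] + eps)
                                  + (1 - t) * np.log(1 - P[:, i] + eps))
            return total / 4

        assert ovr_log_loss(P_cal) <= ovr_log_loss(P_raw) + 0.02
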