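import numpy as np
import pytest

from gliopid import (
    EvaluationWindow,
    InsufficientDataError,
    ReferenceScanError,
    SimulationConfig,
    VolumeTrajectory,
    compute_delta_pid,
    growth_rate,
    integrate_volume_curve,
    simulate_cohort,
    tumor_burden,
)
from gliopid.pipeline import cohort_deltas

POST = EvaluationWindow(0.0, 6.0, reference_time=0.0)


class TestIntegrateVolumeCurve:
    def test_trapezoid_exact_on_linear_growth(self, linear_trajectory):
        # area between V(t) = 12 + t/3 and V(0) over [0, 6]: triangle 0.5*6*2
        assert integrate_volume_curve(linear_trajectory, POST, "trapezoid") == 6.0

    def test_simpson_exact_on_quadratic(self):
        traj = VolumeTrajectory("sq", [0, 3, 6], [0, 9, 36])  # V(t) = t^2
        window = EvaluationWindow(0.0, 6.0, reference_time=0.0)
        assert integrate_volume_curve(traj, window, "simpson") == pytest.approx(
            72.0, abs=1e-12
        )

    @pytest.mark.parametrize("method", ["trapezoid", "midpoint", "simpson"])
    def test_methods_agree_on_linear_data(self, linear_trajectory, method):
        assert integrate_volume_curve(linear_trajectory, POST, method) == pytest.approx(
            6.0, abs=1e-12
        )

    @staticmethod
    def _errors(method, power, exact, grids=(8, 16, 32)):
        errs = []
        for n in grids:
            t = np.linspace(0, 6, n + 1)
            traj = VolumeTrajectory("poly", t, t**power)
            window = EvaluationWindow(0.0, 6.0, reference_time=0.0)
            errs.append(abs(integrate_volume_curve(traj, window, method) - exact))
        return errs

    @pytest.mark.parametrize("method", ["trapezoid", "midpoint"])
    def test_second_order_convergence_on_cubic(self, method):
        # V(t) = t^3 on [0, 6], exact integral 324; halving h quarters the error
        errors = self._errors(method, 3, 324.0)
        orders = [np.log2(e1 / e2) for e1, e2 in zip(errors, errors[1:])]
        assert all(o > 1.5 for o in orders)

    def test_simpson_superconvergent_on_cubic_even_grid(self):
        # symmetric panels integrate cubics exactly, i.e. better than order 4
        assert all(e < 1e-9 for e in self._errors("simpson", 3, 324.0))

    def test_simpson_fourth_order_on_quartic(self):
        # V(t) = t^4 on [0, 6], exact integral 1555.2
        errors = self._errors("simpson", 4, 1555.2)
        orders = [np.log2(e1 / e2) for e1, e2 in zip(errors, errors[1:])]
        assert all(o > 3.5 for o in orders)

    def test_uneven_simpson_still_exact_for_quadratic(self):
        t = np.array([0.0, 1.0, 3.5, 4.0, 6.0])
        traj = VolumeTrajectory("sq", t, t**2)
        window = EvaluationWindow(0.0, 6.0, reference_time=0.0)
        # panels (0,1,3.5) and (3.5,4,6): each quadratic fit is exact
        assert integrate_volume_curve(traj, window, "simpson") == pytest.approx(72.0)

    def test_insufficient_samples_raise(self, linear_trajectory):
        with pytest.raises(InsufficientDataError):
            integrate_volume_curve(
                linear_trajectory, EvaluationWindow(10.0, 12.0), "trapezoid"
            )

    def test_missing_reference_scan_raises(self):
        traj = VolumeTrajectory("x", [0.0, 3.0, 6.0], [1.0, 2.0, 3.0])
        window = EvaluationWindow(0.0, 6.0, reference_time=4.6)
        with pytest.raises(ReferenceScanError):
            integrate_volume_curve(traj, window, "trapezoid", tolerance=1.0)


class TestTumorBurden:
    def test_nearest_scan_within_tolerance(self):
        traj = VolumeTrajectory("x", [0.0, 6.1], [12.0, 14.02])
        assert tumor_burden(traj, 6.0, tolerance=1.0) == 14.02

    def test_anchor_lookup(self, linear_trajectory):
        assert tumor_burden(linear_trajectory, 0.0) == 12.0

    def test_equidistant_tie_breaks_to_earlier_scan(self):
        traj = VolumeTrajectory("x", [-1.0, 0.0, 1.0], [5.0, 6.0, 7.0])
        assert tumor_burden(traj, 0.5, tolerance=1.0) == 6.0

    def test_out_of_tolerance_raises(self, linear_trajectory):
        with pytest.raises(ReferenceScanError):
            tumor_burden(linear_trajectory, 10.0)


class TestGrowthRate:
    def test_exact_linear_fit(self):
        traj = VolumeTrajectory("x", [0, 3, 6], [10, 11, 12])
        assert growth_rate(traj, POST) == pytest.approx(1 / 3)

    def test_flat_trajectory(self):
        traj = VolumeTrajectory("x", [0, 3, 6], [10, 10, 10])
        assert growth_rate(traj, POST) == 0.0

    def test_single_point_raises(self, linear_trajectory):
        with pytest.raises(InsufficientDataError):
            growth_rate(linear_trajectory, EvaluationWindow(4.8, 7.0), tolerance=0.5)


class TestComputeDeltaPid:
    def test_noiseless_control_deltas(self, linear_trajectory):
        d = compute_delta_pid(linear_trajectory)
        assert d.delta_lambda1 == pytest.approx(0.0, abs=1e-12)
        assert d.delta_lambda2 == pytest.approx(2.0)
        assert d.delta_lambda3 == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_treated_deltas(self, stabilized_trajectory):
        d = compute_delta_pid(stabilized_trajectory)
        assert d.delta_lambda1 == pytest.approx(-6.0)
        assert d.delta_lambda2 == pytest.approx(0.0)
        assert d.delta_lambda3 == pytest.approx(-1 / 3)

    def test_delta_identities_hold_by_recomputation(self, default_cohort):
        for rec in default_cohort[::7]:
            d = compute_delta_pid(rec.trajectory)
            assert d.delta_lambda1 == d.post.lambda1 - d.pre.lambda1
            assert d.delta_lambda3 == d.post.lambda3 - d.pre.lambda3

    def test_error_tagged_with_failing_window(self):
        traj = VolumeTrajectory("x", [-6, -3, 0], [10, 11, 12])
        with pytest.raises(InsufficientDataError, match="post window"):
            compute_delta_pid(traj)


class TestDifferenceVariance:
    def test_delta_slope_variance_reflects_shared_anchor(self):
        """Var(delta_lambda3) is ~3x the single-window slope variance.

        Differencing two independent equally-noisy estimates doubles the
        variance; here the pre and post windows additionally share the
        anchor scan, whose noise enters the two 3-point OLS slopes with
        opposite-sign weights (+-1/6), adding Cov = -sigma^2/36 and lifting
        the ratio from 2 to an analytic 3.
        """
        cfg = SimulationConfig(
            n_subjects=10_000, randomization_ratio=(10_000, 0), seed=7
        )
        deltas = cohort_deltas(simulate_cohort(cfg))["control"]
        pre = np.array([d.pre.lambda3 for d in deltas])
        post = np.array([d.post.lambda3 for d in deltas])
        diff = np.array([d.delta_lambda3 for d in deltas])
        ratio = diff.var(ddof=1) / np.mean([pre.var(ddof=1), post.var(ddof=1)])
        assert 2.8 < ratio < 3.2

    def test_independent_window_differencing_doubles_variance(self):
        """Without a shared scan the classical variance doubling holds.

        Slopes fitted on disjoint scan subsets ({-6,-3} vs {+3,+6}) have
        independent errors, so Var(post - pre) / Var(single) is ~2.
        """
        cfg = SimulationConfig(
            n_subjects=10_000, randomization_ratio=(10_000, 0),
            scan_jitter_sd=0.0, seed=8,
        )
        cohort = simulate_cohort(cfg)
        pre_w = EvaluationWindow(-6.0, -3.0)
        post_w = EvaluationWindow(3.0, 6.0)
        pre, post = [], []
        for rec in cohort:
            pre.append(growth_rate(rec.trajectory, pre_w, tolerance=0.0))
            post.append(growth_rate(rec.trajectory, post_w, tolerance=0.0))
        pre, post = np.array(pre), np.array(post)
        diff = post - pre
        ratio = diff.var(ddof=1) / np.mean([pre.var(ddof=1), post.var(ddof=1)])
        assert 1.8 < ratio < 2.2
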