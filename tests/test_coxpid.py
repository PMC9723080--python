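import numpy as np
import pytest

from gliopid import (
    CountingProcessRecord,
    DataError,
    HazardCoefficients,
    MonotoneLikelihoodError,
    VolumeTrajectory,
    build_covariate_process,
    covariate_steps,
    fit_cox_pid,
    partial_log_likelihood,
    partial_log_likelihood_gradient,
)
from conftest import make_survival_cohort


def toy_records():
    """Three subjects with fixed covariates; events at t=5 (A) and t=7 (B)."""
    return [
        CountingProcessRecord("A", 0.0, 5.0, (1.0, 2.0, 0.5), True),
        CountingProcessRecord("B", 0.0, 3.0, (0.5, 1.0, -0.2), False),
        CountingProcessRecord("B", 3.0, 7.0, (2.0, 1.5, 0.1), True),
        CountingProcessRecord("C", 0.0, 9.0, (1.5, 0.5, 0.3), False),
    ]


class TestCovariateProcess:
    def test_constant_volume_rectangle_integral(self):
        traj = VolumeTrajectory(
            "c", [0, 3, 6, 9, 12], [10] * 5, require_anchor=True
        )
        knots, X = covariate_steps(traj)
        k6 = int(np.flatnonzero(knots == 6.0)[0])
        assert X[k6, 0] == pytest.approx(60.0)  # running integral
        assert X[k6, 1] == 10.0  # current volume
        assert X[k6, 2] == pytest.approx(0.0, abs=1e-12)  # slope

    def test_linear_volume_closed_form_integral(self):
        t = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        traj = VolumeTrajectory("l", t, 10.0 + t)
        knots, X = covariate_steps(traj)
        k6 = int(np.flatnonzero(knots == 6.0)[0])
        assert X[k6, 0] == pytest.approx(10 * 6 + 36 / 2)  # 78
        assert X[k6, 2] == pytest.approx(1.0)

    def test_event_before_first_interval_is_degenerate(self, linear_trajectory):
        with pytest.raises(DataError):
            build_covariate_process(linear_trajectory, (0.0, True))

    def test_records_truncate_at_event_time(self, linear_trajectory):
        records = build_covariate_process(linear_trajectory, (4.5, True))
        assert records[-1].interval_stop == 4.5
        assert records[-1].event_in_interval is True
        assert records[0].interval_start == 0.0

    def test_censoring_carries_last_covariates_forward(self, linear_trajectory):
        records = build_covariate_process(linear_trajectory, (24.0, False))
        assert records[-1].interval_stop == 24.0
        assert not any(r.event_in_interval for r in records)


class TestPartialLogLikelihood:
    def test_zero_betas_closed_form(self):
        # at beta = 0 each event contributes -log(risk set size): sizes 3 and 2
        ll = partial_log_likelihood(toy_records(), (0.0, 0.0, 0.0))
        assert ll == pytest.approx(-(np.log(3) + np.log(2)), abs=1e-12)

    def test_matches_hand_enumerated_product(self):
        """Brute-force enumeration of the two risk sets on the toy data."""
        betas = np.array([0.3, -0.2, 0.7])
        x_a = np.array([1.0, 2.0, 0.5])
        x_b1 = np.array([0.5, 1.0, -0.2])
        x_b2 = np.array([2.0, 1.5, 0.1])
        x_c = np.array([1.5, 0.5, 0.3])
        # event at t=5: at risk A (0,5], B via (3,7], C via (0,9]
        term1 = x_a @ betas - np.log(
            np.exp(x_a @ betas) + np.exp(x_b2 @ betas) + np.exp(x_c @ betas)
        )
        # event at t=7: at risk B via (3,7], C via (0,9]
        term2 = x_b2 @ betas - np.log(np.exp(x_b2 @ betas) + np.exp(x_c @ betas))
        del x_b1  # never at risk at an event time: interval (0,3] covers neither
        assert partial_log_likelihood(toy_records(), betas) == pytest.approx(
            term1 + term2, abs=1e-10
        )

    def test_invariant_to_volume_location_shift(self):
        betas = (0.1, 0.25, -0.4)
        shifted = [
            CountingProcessRecord(
                r.subject_id,
                r.interval_start,
                r.interval_stop,
                (r.covariates[0], r.covariates[1] + 7.0, r.covariates[2]),
                r.event_in_interval,
            )
            for r in toy_records()
        ]
        assert partial_log_likelihood(shifted, betas) == pytest.approx(
            partial_log_likelihood(toy_records(), betas), abs=1e-10
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        records = toy_records()
        betas = rng.normal(0, 0.5, size=3)
        grad = partial_log_likelihood_gradient(records, betas)
        h = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            fd = (
                partial_log_likelihood(records, betas + e)
                - partial_log_likelihood(records, betas - e)
            ) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_no_events_is_data_error(self):
        records = [CountingProcessRecord("A", 0.0, 5.0, (1.0, 2.0, 0.5), False)]
        with pytest.raises(DataError):
            partial_log_likelihood(records, (0.0, 0.0, 0.0))


class TestFitCoxPid:
    def test_null_cohort_coefficients_near_zero(self):
        cohort = make_survival_cohort(seed=1, n=200, betas=(0.0, 0.0, 0.0))
        fit = fit_cox_pid(cohort)
        for b, se in zip(fit.betas, fit.standard_errors):
            assert abs(b) < 3 * se

    def test_recovers_generating_burden_coefficient(self):
        cohort = make_survival_cohort(seed=2, n=400, betas=(0.0, 0.05, 0.0))
        fit = fit_cox_pid(cohort)
        assert fit.beta2 == pytest.approx(0.05, abs=3 * fit.standard_errors[1])

    def test_invariant_to_subject_order(self):
        cohort = make_survival_cohort(seed=3, n=100)
        fit1 = fit_cox_pid(cohort)
        fit2 = fit_cox_pid(list(reversed(cohort)))
        np.testing.assert_allclose(fit1.betas, fit2.betas, rtol=1e-8)

    def test_single_event_warns_but_fits_finite_likelihood(self):
        cohort = make_survival_cohort(seed=4, n=30, h0=0.02, followup=6.0)
        n_events = sum(r.survival[1] for r in cohort)
        assert n_events < 10  # sparse-event regime
        with pytest.warns(UserWarning, match="event"):
            fit = fit_cox_pid(cohort)
        assert np.isfinite(fit.log_likelihood)

    def test_burden_only_fit_matches_lifelines(self):
        """Zeroing the integral and slope covariates reduces the model to a
        single-covariate Cox fit, cross-checked against an independent
        implementation (lifelines CoxTimeVaryingFitter)."""
        import pandas as pd
        from lifelines import CoxTimeVaryingFitter

        from gliopid.coxpid import cohort_records, fit_counting_process

        cohort = make_survival_cohort(seed=5, n=150)
        records = [
            CountingProcessRecord(
                r.subject_id, r.interval_start, r.interval_stop,
                (0.0, r.covariates[1], 0.0), r.event_in_interval,
            )
            for r in cohort_records(cohort)
        ]
        fit = fit_counting_process(records)
        assert fit.beta1 == 0.0 and fit.beta3 == 0.0

        df = pd.DataFrame(
            {
                "id": [r.subject_id for r in records],
                "start": [r.interval_start for r in records],
                "stop": [r.interval_stop for r in records],
                "volume": [r.covariates[1] for r in records],
                "event": [int(r.event_in_interval) for r in records],
            }
        )
        ctv = CoxTimeVaryingFitter()
        ctv.fit(df, id_col="id", start_col="start", stop_col="stop",
                event_col="event")
        assert fit.beta2 == pytest.approx(float(ctv.params_["volume"]), abs=1e-6)
        assert fit.standard_errors[1] == pytest.approx(
            float(ctv.standard_errors_["volume"]), rel=1e-4
        )

    def test_separation_raises_monotone_likelihood_error(self):
        # volume perfectly orders the event times: the partial likelihood is
        # monotone in beta2 and the Newton iterates diverge
        from gliopid.coxpid import fit_counting_process

        records = [
            CountingProcessRecord(sid, 0.0, stop, (0.0, vol, 0.0), True)
            for sid, stop, vol in [
                ("A", 1.0, 4.0), ("B", 2.0, 3.0), ("C", 3.0, 2.0), ("D", 4.0, 1.0)
            ]
        ]
        with pytest.raises(MonotoneLikelihoodError):
            with pytest.warns(UserWarning, match="event"):
                fit_counting_process(records)
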