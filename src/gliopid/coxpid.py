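"""Cox proportional-hazards model with PID covariates of the volume trajectory.

The log-relative risk at time t is

    beta1 * integral_0^t V(t') dt'  +  beta2 * V(t)  +  beta3 * dV/dt,

i.e. a linear combination of the running tumor-control integral, the current
tumor burden, and the current growth slope.  Since volumes are only sampled
at scans, the three covariates are operationalized as step functions updated
at scan times (left-continuous: a value applies from its scan until the
next), which puts the data in the standard counting-process format and makes
the partial likelihood exact under the discretized model.

Tied event times use the Breslow approximation; the fit is a Newton
iteration on internally standardized covariates with coefficients and
standard errors back-transformed to natural units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import (
    DataError,
    FittingError,
    InsufficientDataError,
    MonotoneLikelihoodError,
)
from .simulate import SubjectRecord, VolumeTrajectory


@dataclass(frozen=True)
class HazardCoefficients:
    """Coefficients of the PID hazard h(t) = h0 * exp(beta . x(t)).

    h0 is a baseline hazard rate per month, used only for simulation;
    beta1 is per mL*months, beta2 per mL, beta3 per (mL/month).
    """

    beta1: float
    beta2: float
    beta3: float
    h0: Optional[float] = None
    standard_errors: Optional[Tuple[float, float, float]] = None
    log_likelihood: Optional[float] = None
    n_iterations: Optional[int] = None

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta1, self.beta2, self.beta3])


@dataclass(frozen=True)
class CountingProcessRecord:
    """One inter-scan interval of a subject's at-risk process."""

    subject_id: str
    interval_start: float
    interval_stop: float
    covariates: Tuple[float, float, float]  # (running integral, volume, slope)
    event_in_interval: bool

    def __post_init__(self):
        if not self.interval_start < self.interval_stop:
            raise DataError(
                f"subject {self.subject_id!r}: interval start must be < stop"
            )


def covariate_steps(trajectory: VolumeTrajectory) -> Tuple[np.ndarray, np.ndarray]:
    """Step-function PID covariates of a trajectory from treatment start.

    Returns (knots, X): knots are the scan times >= 0 and X[k] the covariate
    triple applying on [knots[k], knots[k+1]) — the cumulative trapezoid of V
    from 0 up to the knot, the volume observed at the knot, and the OLS slope
    of all observations up to the knot (the full history, including
    pre-treatment scans; a two-point slope when only two exist, and the
    slope of the first two observations for a knot preceding the second).
    """
    t = trajectory.times
    v = trajectory.volumes
    post = t >= 0
    knots = t[post]
    if knots.size == 0 or knots[0] != 0.0:
        raise DataError(
            f"subject {trajectory.subject_id!r}: trajectory lacks the time-0 scan"
        )
    vols = v[post]
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * np.diff(knots) * (vols[:-1] + vols[1:]))]
    )
    slopes = np.empty_like(knots)
    for k, tk in enumerate(knots):
        hist = t <= tk
        if hist.sum() < 2:
            hist = np.zeros_like(hist)
            hist[:2] = True  # fall back to the first two observations
        th, vh = t[hist], v[hist]
        tc = th - th.mean()
        slopes[k] = np.dot(tc, vh) / np.dot(tc, tc)
    return knots, np.column_stack([integral, vols, slopes])


def build_covariate_process(
    trajectory: VolumeTrajectory,
    survival: Tuple[float, bool],
) -> list[CountingProcessRecord]:
    """Discretize one subject into counting-process records up to event/censoring."""
    event_time, event = survival
    knots, X = covariate_steps(trajectory)
    if event_time <= knots[0]:
        raise DataError(
            f"subject {trajectory.subject_id!r}: event/censoring at "
            f"{event_time:g} precedes the first post-baseline interval"
        )
    if not np.all(np.isfinite(X)):
        raise DataError(f"subject {trajectory.subject_id!r}: non-finite covariates")

    records = []
    for k in range(knots.size):
        start = knots[k]
        stop = knots[k + 1] if k + 1 < knots.size else np.inf
        stop = min(stop, event_time)
        if stop <= start:
            break
        last = stop >= event_time
        records.append(
            CountingProcessRecord(
                subject_id=trajectory.subject_id,
                interval_start=float(start),
                interval_stop=float(stop),
                covariates=tuple(X[k]),
                event_in_interval=bool(event and last),
            )
        )
        if last:
            break
    return records


def _as_arrays(records: Sequence[CountingProcessRecord]):
    start = np.array([r.interval_start for r in records])
    stop = np.array([r.interval_stop for r in records])
    X = np.array([r.covariates for r in records])
    event = np.array([r.event_in_interval for r in records])
    return start, stop, X, event


def _loglik_parts(start, stop, X, event, betas):
    """Breslow partial log-likelihood with analytic gradient and Hessian.

    A row is at risk at event time t when start < t <= stop; the event row's
    covariates enter the numerator, the at-risk rows' exp(eta) the denominator.
    """
    if not np.any(event):
        raise DataError("no events in the data")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite covariates")
    eta = X @ betas
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(X.shape[1])
    hess = np.zeros((X.shape[1], X.shape[1]))
    for i in np.flatnonzero(event):
        t_i = stop[i]
        at_risk = (start < t_i) & (t_i <= stop)
        if not np.any(at_risk):
            raise DataError(f"empty risk set at event time {t_i:g}")
        wr = w[at_risk]
        Xr = X[at_risk]
        s0 = wr.sum()
        s1 = wr @ Xr
        xbar = s1 / s0
        ll += eta[i] - np.log(s0)
        grad += X[i] - xbar
        s2 = (Xr * wr[:, None]).T @ Xr
        hess -= s2 / s0 - np.outer(xbar, xbar)
    return ll, grad, hess


def partial_log_likelihood(
    records: Sequence[CountingProcessRecord],
    betas: Sequence[float],
) -> float:
    """Cox partial log-likelihood of all subjects' records at ``betas``
    (counting-process formulation, Breslow ties)."""
    start, stop, X, event = _as_arrays(records)
    ll, _, _ = _loglik_parts(start, stop, X, event, np.asarray(betas, dtype=float))
    return float(ll)


def partial_log_likelihood_gradient(
    records: Sequence[CountingProcessRecord],
    betas: Sequence[float],
) -> np.ndarray:
    start, stop, X, event = _as_arrays(records)
    _, grad, _ = _loglik_parts(start, stop, X, event, np.asarray(betas, dtype=float))
    return grad


def cohort_records(cohort: Sequence[SubjectRecord]) -> list[CountingProcessRecord]:
    """Counting-process records of every subject with a survival outcome."""
    records = []
    for rec in cohort:
        if rec.survival is None:
            raise DataError(f"subject {rec.subject_id!r} has no survival outcome")
        records.extend(build_covariate_process(rec.trajectory, rec.survival))
    return records


def fit_cox_pid(
    cohort: Sequence[SubjectRecord],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> HazardCoefficients:
    """Fit the PID hazard model to a cohort with survival outcomes.

    Builds each subject's counting-process records and maximizes the partial
    likelihood by Newton iteration (see ``fit_counting_process``).
    """
    return fit_counting_process(cohort_records(cohort), tol=tol, max_iter=max_iter)


def fit_counting_process(
    records: Sequence[CountingProcessRecord],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> HazardCoefficients:
    """Maximize the partial likelihood by Newton iteration.

    Covariates are z-scored internally for conditioning and the coefficients
    and model-based standard errors (inverse observed information)
    back-transformed to natural units; covariate columns that are constant
    across records (e.g. deliberately zeroed out) carry no information and
    are reported as coefficient 0 with SE NaN.  Convergence: gradient
    max-norm below ``tol`` on the standardized scale.
    """
    start, stop, X, event = _as_arrays(records)
    n_events = int(event.sum())
    if n_events < 1:
        raise DataError("no events in the cohort")
    if n_events < 10:
        warnings.warn(
            f"only {n_events} event(s): coefficient estimates will be unstable",
            stacklevel=2,
        )

    mu = X.mean(axis=0)
    sigma_full = X.std(axis=0)
    active = sigma_full > 0  # constant columns carry no information: excluded
    if not np.any(active):
        raise DataError("all covariates are constant")
    X = X[:, active]
    sigma = sigma_full[active]
    Z = (X - mu[active]) / sigma

    beta = np.zeros(X.shape[1])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, hess = _loglik_parts(start, stop, Z, event, beta)
        gnorm = np.max(np.abs(grad))
        if gnorm < tol:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise FittingError(
                f"singular information matrix at iteration {n_iter}",
                last_beta=beta / sigma,
                gradient_norm=float(gnorm),
            ) from exc
        # step halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, _, _ = _loglik_parts(start, stop, Z, event, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        # a coefficient of 10 per covariate SD means a hazard ratio of e^10
        # across one SD: far outside any plausible fit, so treat as separation
        if np.max(np.abs(beta)) > 10:
            raise MonotoneLikelihoodError(
                "coefficients diverging: likely complete separation "
                "(monotone partial likelihood)",
                last_beta=beta / sigma,
                gradient_norm=float(gnorm),
            )
    else:
        raise FittingError(
            f"no convergence in {max_iter} iterations",
            last_beta=beta / sigma,
            gradient_norm=float(np.max(np.abs(grad))),
        )

    ll, grad, hess = _loglik_parts(start, stop, Z, event, beta)
    cov_z = np.linalg.inv(-hess)
    beta_nat = np.zeros(3)
    se_nat = np.full(3, np.nan)
    beta_nat[active] = beta / sigma
    se_nat[active] = np.sqrt(np.diag(cov_z)) / sigma
    return HazardCoefficients(
        beta1=float(beta_nat[0]),
        beta2=float(beta_nat[1]),
        beta3=float(beta_nat[2]),
        standard_errors=tuple(float(s) for s in se_nat),
        log_likelihood=float(ll),
        n_iterations=n_iter,
    )
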