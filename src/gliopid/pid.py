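"""Per-subject PID treatment-effect parameters.

A volume trajectory V(t) is summarized over an evaluation window by three
parameters borrowed from the proportional/integral/derivative decomposition
of control theory:

* lambda1 ("tumor control", mL*months): quadrature approximation of
  integral(V(t') - V(reference)) dt' over the window.  A stabilized or
  shrinking tumor yields a small or negative area, i.e. better control.
* lambda2 ("tumor burden", mL): the observed volume at a requested time
  (nearest scan within tolerance).
* lambda3 ("growth rate", mL/month): the ordinary-least-squares slope of
  volume on time over the window.

Treatment effect is the pre-to-post change Delta-lambda_n = lambda_n(post)
- lambda_n(pre) computed per subject over matched 6-month windows: the
pre-window integral is anchored at the earliest ("historic") in-window
scan, the post-window integral at the treatment-start scan (time 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError, InsufficientDataError, ReferenceScanError
from .simulate import VolumeTrajectory

#: Half the nominal 3-month scan interval: how far a scan may sit from a
#: window endpoint or reference time and still be matched to it.
DEFAULT_TOLERANCE = 1.5

QUADRATURE_METHODS = ("trapezoid", "midpoint", "simpson")


@dataclass(frozen=True)
class EvaluationWindow:
    """A [start, end] evaluation period in months.

    ``reference_time`` anchors the integrand of lambda1; when None it is
    resolved per trajectory: the earliest in-window scan for a pre-treatment
    window (end <= 0), the window start otherwise.
    """

    start: float
    end: float
    reference_time: Optional[float] = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ConfigurationError("window start must be < end")
        if self.reference_time is not None and not (
            self.start <= self.reference_time <= self.end
        ):
            raise ConfigurationError("reference_time must lie within [start, end]")


@dataclass(frozen=True)
class PIDParameters:
    """The three PID parameters of one trajectory over one window."""

    lambda1: float  # mL*months
    lambda2: float  # mL
    lambda3: float  # mL/month
    window: EvaluationWindow


@dataclass(frozen=True)
class DeltaPID:
    """Post-minus-pre change in each PID parameter for one subject."""

    subject_id: str
    delta_lambda1: float  # mL*months
    delta_lambda2: float  # mL
    delta_lambda3: float  # mL/month
    pre: Optional[PIDParameters] = None
    post: Optional[PIDParameters] = None


def _in_window(
    trajectory: VolumeTrajectory, window: EvaluationWindow, tolerance: float
) -> np.ndarray:
    """Boolean mask of scans inside [start - tol, end + tol].

    The clip tolerance lets a jittered boundary scan (e.g. the nominal
    -6-month scan acquired at -6.4) still count toward its window.
    """
    return (trajectory.times >= window.start - tolerance) & (
        trajectory.times <= window.end + tolerance
    )


def _nearest_scan(
    trajectory: VolumeTrajectory, at_time: float, tolerance: float
) -> int:
    """Index of the scan nearest ``at_time`` within tolerance; ties -> earlier scan."""
    dist = np.abs(trajectory.times - at_time)
    idx = int(np.argmin(dist))  # argmin takes the first (earlier) on ties
    if dist[idx] > tolerance:
        raise ReferenceScanError(
            f"no scan within {tolerance:g} months of t={at_time:g} "
            f"for subject {trajectory.subject_id!r}"
        )
    return idx


def _linear_at(t: np.ndarray, v: np.ndarray, x: float) -> float:
    """Piecewise-linear interpolant of the samples, linearly extended at the ends."""
    if x <= t[0]:
        return float(v[0] + (v[1] - v[0]) * (x - t[0]) / (t[1] - t[0]))
    if x >= t[-1]:
        return float(v[-1] + (v[-1] - v[-2]) * (x - t[-1]) / (t[-1] - t[-2]))
    return float(np.interp(x, t, v))


def _clip_to_window(
    t: np.ndarray, v: np.ndarray, start: float, end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict the sampled curve to exactly [start, end].

    The quadrature runs over the evaluation window itself, not over the
    jittered span the scans happen to cover: boundary segments are linearly
    clipped (scan outside the window) or extended (scan short of the bound)
    so the integration domain is always [start, end].  Without this the
    jitter in the boundary scan dates biases the integral upward by
    slope * Var(jitter) / 2 on average.
    """
    inside = (t > start) & (t < end)
    tt = np.concatenate([[start], t[inside], [end]])
    vv = np.concatenate([[_linear_at(t, v, start)], v[inside], [_linear_at(t, v, end)]])
    return tt, vv


def _quad_trapezoid(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(y, t))


def _quad_midpoint(t: np.ndarray, y: np.ndarray) -> float:
    """Composite midpoint on pairwise panels of the piecewise-linear interpolant.

    Consecutive sample pairs form panels [t_i, t_{i+2}]; each contributes
    width times the interpolant evaluated at the panel midpoint.  A leftover
    final pair falls back to a trapezoid panel.  Exact for linear data.
    """
    total = 0.0
    i = 0
    n = t.size
    while i + 2 <= n - 1:  # full two-interval panel
        lo, hi = t[i], t[i + 2]
        mid = 0.5 * (lo + hi)
        total += (hi - lo) * float(np.interp(mid, t, y))
        i += 2
    if i == n - 2:  # leftover single interval
        total += 0.5 * (t[i + 1] - t[i]) * (y[i] + y[i + 1])
    return total


def _simpson_panel(t0, t1, t2, f0, f1, f2) -> float:
    """Three-point Newton-Cotes on arbitrary nodes: integrates the quadratic
    through (t0,f0),(t1,f1),(t2,f2) over [t0, t2] exactly."""
    h0 = t1 - t0
    h1 = t2 - t1
    common = (h0 + h1) / 6.0
    return common * (
        (2.0 - h1 / h0) * f0
        + ((h0 + h1) ** 2 / (h0 * h1)) * f1
        + (2.0 - h0 / h1) * f2
    )


def _quad_simpson(t: np.ndarray, y: np.ndarray) -> float:
    """Composite Simpson for uneven spacing: quadratic through each consecutive
    sample triplet; a leftover trailing pair is handled by a trapezoid panel."""
    total = 0.0
    i = 0
    n = t.size
    while i + 2 <= n - 1:
        total += _simpson_panel(t[i], t[i + 1], t[i + 2], y[i], y[i + 1], y[i + 2])
        i += 2
    if i == n - 2:  # even sample count leaves one interval: trapezoid fallback
        total += 0.5 * (t[i + 1] - t[i]) * (y[i] + y[i + 1])
    return total


_QUADRATURES = {
    "trapezoid": _quad_trapezoid,
    "midpoint": _quad_midpoint,
    "simpson": _quad_simpson,
}


def integrate_volume_curve(
    trajectory: VolumeTrajectory,
    window: EvaluationWindow,
    method: str = "trapezoid",
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Tumor-control parameter lambda1 (mL*months).

    Quadrature approximation of integral(V(t') - V(reference)) dt' over the
    in-window samples; ``method`` is one of trapezoid, midpoint, simpson.
    """
    if method not in _QUADRATURES:
        raise ConfigurationError(
            f"method must be one of {QUADRATURE_METHODS}, got {method!r}"
        )
    mask = _in_window(trajectory, window, tolerance)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"subject {trajectory.subject_id!r}: need >= 2 scans in "
            f"[{window.start:g}, {window.end:g}], found {int(mask.sum())}"
        )
    t = trajectory.times[mask]
    v = trajectory.volumes[mask]
    ref_time = window.reference_time
    if ref_time is None:
        ref_time = float(t[0]) if window.end <= 0 else window.start
    ref_volume = trajectory.volumes[_nearest_scan(trajectory, ref_time, tolerance)]
    t, v = _clip_to_window(t, v, window.start, window.end)
    return _QUADRATURES[method](t, v - ref_volume)


def tumor_burden(
    trajectory: VolumeTrajectory,
    at_time: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Tumor-burden parameter lambda2 (mL): observed volume of the scan
    nearest ``at_time`` within tolerance (ties break to the earlier scan)."""
    return float(trajectory.volumes[_nearest_scan(trajectory, at_time, tolerance)])


def growth_rate(
    trajectory: VolumeTrajectory,
    window: EvaluationWindow,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Growth-rate parameter lambda3 (mL/month): OLS slope of volume on time
    over the in-window scans."""
    mask = _in_window(trajectory, window, tolerance)
    t = trajectory.times[mask]
    v = trajectory.volumes[mask]
    if t.size < 2 or np.ptp(t) == 0:
        raise InsufficientDataError(
            f"subject {trajectory.subject_id!r}: need >= 2 scans with distinct "
            f"times in [{window.start:g}, {window.end:g}]"
        )
    tc = t - t.mean()
    return float(np.dot(tc, v) / np.dot(tc, tc))


def _window_end_volume(
    trajectory: VolumeTrajectory, window: EvaluationWindow, tolerance: float
) -> float:
    """Volume of the in-window scan nearest the window end.

    More forgiving than ``tumor_burden``: a boundary scan whose jittered
    date drifted past the matching tolerance falls back to the latest scan
    the window did capture, so an evaluable window always yields a burden.
    """
    mask = _in_window(trajectory, window, tolerance)
    if not mask.any():
        raise InsufficientDataError(
            f"subject {trajectory.subject_id!r}: no scans in "
            f"[{window.start:g}, {window.end:g}]"
        )
    t = trajectory.times[mask]
    v = trajectory.volumes[mask]
    return float(v[np.argmin(np.abs(t - window.end))])


def pid_parameters(
    trajectory: VolumeTrajectory,
    window: EvaluationWindow,
    method: str = "trapezoid",
    tolerance: float = DEFAULT_TOLERANCE,
) -> PIDParameters:
    """All three PID parameters over one window (lambda2 at the window end)."""
    return PIDParameters(
        lambda1=integrate_volume_curve(trajectory, window, method, tolerance),
        lambda2=_window_end_volume(trajectory, window, tolerance),
        lambda3=growth_rate(trajectory, window, tolerance),
        window=window,
    )


def default_windows(window_months: float = 6.0) -> tuple[EvaluationWindow, EvaluationWindow]:
    """Matched pre/post evaluation windows: [-w, 0] and [0, +w].

    The pre window's integrand reference resolves per trajectory to the
    earliest ("historic") in-window scan; the post window is anchored at the
    treatment-start scan (time 0).
    """
    pre = EvaluationWindow(-window_months, 0.0, reference_time=None)
    post = EvaluationWindow(0.0, window_months, reference_time=0.0)
    return pre, post


def compute_delta_pid(
    trajectory: VolumeTrajectory,
    pre: Optional[EvaluationWindow] = None,
    post: Optional[EvaluationWindow] = None,
    method: str = "trapezoid",
    tolerance: float = DEFAULT_TOLERANCE,
) -> DeltaPID:
    """Pre-to-post change in the PID parameters for one subject.

    delta_lambda1 = lambda1(post) - lambda1(pre);
    delta_lambda2 = V(post.end) - V(0);
    delta_lambda3 = lambda3(post) - lambda3(pre).
    """
    if pre is None or post is None:
        dpre, dpost = default_windows()
        pre = pre or dpre
        post = post or dpost

    def _tagged(component, fn):
        try:
            return fn()
        except (InsufficientDataError, ReferenceScanError) as exc:
            raise type(exc)(f"[{component} window] {exc}") from exc

    p_pre = _tagged("pre", lambda: pid_parameters(trajectory, pre, method, tolerance))
    p_post = _tagged("post", lambda: pid_parameters(trajectory, post, method, tolerance))
    burden_at_start = trajectory.anchor_volume
    return DeltaPID(
        subject_id=trajectory.subject_id,
        delta_lambda1=p_post.lambda1 - p_pre.lambda1,
        delta_lambda2=p_post.lambda2 - burden_at_start,
        delta_lambda3=p_post.lambda3 - p_pre.lambda3,
        pre=p_pre,
        post=p_post,
    )
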