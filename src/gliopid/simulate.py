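"""Synthetic glioma trial cohorts with piecewise-linear volumetric growth.

The generative model mirrors a slow-growing glioma trial: every subject
carries a tumor that grows linearly at ``growth_rate`` mL/month for
``window_months`` months before treatment start (time 0), then continues at
an arm-specific slope afterwards.  Scans are nominally every
``scan_interval`` months; actual acquisition dates jitter around the nominal
schedule (the treatment-start scan is the fixed anchor), and each measured
volume carries additive Gaussian volumetric noise.  Survival times can be
drawn from a proportional-hazards model whose log-relative risk is a linear
combination of the trajectory's integral (tumor control), proportional
(burden), and derivative (growth rate) components.

Defaults reproduce a cohort of 80 subjects: baseline 10 mL (SD 0.5) six
months before treatment, growth of 1 mL per 3 months, measurement noise
0.25 mL, scans every 3 months with a 2-week-SD date jitter, and a 1:1
randomization between an ineffective arm (growth unchanged) and a
cytostatic arm (growth stabilized at 0 mL/month).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigurationError, InsufficientDataError, ValidationError

logger = logging.getLogger("gliopid")

CONTROL = "control"
TREATED = "treated"


class ScanObservation(NamedTuple):
    """One MRI scan: months relative to treatment start, tumor volume in mL."""

    time: float
    volume: float


class VolumeTrajectory:
    """Ordered (time, volume) scan observations for one subject.

    Times are strictly increasing and, unless ``require_anchor`` is disabled,
    exactly one observation sits at time 0 (the treatment-start scan).
    Volumes are non-negative unless ``allow_negative`` is set (used for
    pseudo-volume signals digitized from qualitative scores, which live in
    score units and may be negative).
    """

    __slots__ = ("subject_id", "times", "volumes")

    def __init__(
        self,
        subject_id: str,
        times: Sequence[float],
        volumes: Sequence[float],
        *,
        require_anchor: bool = True,
        allow_negative: bool = False,
    ):
        times = np.asarray(times, dtype=float)
        volumes = np.asarray(volumes, dtype=float)
        if times.ndim != 1 or times.shape != volumes.shape:
            raise ValidationError("times and volumes must be 1-D and equally long")
        if times.size < 1:
            raise ValidationError("trajectory needs at least one observation")
        if not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"subject {subject_id!r}: observation times must be strictly increasing"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(volumes))):
            raise ValidationError(f"subject {subject_id!r}: non-finite observation")
        if not allow_negative and np.any(volumes < 0):
            raise ValidationError(f"subject {subject_id!r}: negative volume")
        if require_anchor and np.count_nonzero(times == 0.0) != 1:
            raise ValidationError(
                f"subject {subject_id!r}: exactly one anchor scan at time 0 required"
            )
        self.subject_id = subject_id
        self.times = times
        self.volumes = volumes

    @property
    def observations(self) -> list[ScanObservation]:
        return [ScanObservation(t, v) for t, v in zip(self.times, self.volumes)]

    @property
    def anchor_volume(self) -> float:
        """Observed volume of the time-0 scan."""
        idx = int(np.argmin(np.abs(self.times)))
        return float(self.volumes[idx])

    def __len__(self) -> int:
        return self.times.size

    def __iter__(self) -> Iterator[ScanObservation]:
        return iter(self.observations)

    def __repr__(self) -> str:
        return (
            f"VolumeTrajectory({self.subject_id!r}, n={len(self)}, "
            f"span=[{self.times[0]:g}, {self.times[-1]:g}] mo)"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the simulated trial.

    Units: volumes in mL, times in months, rates in mL/month.
    """

    n_subjects: int = 80
    baseline_mean: float = 10.0
    baseline_sd: float = 0.5
    growth_rate: float = 1.0 / 3.0
    post_growth_rate_control: float = 1.0 / 3.0
    post_growth_rate_treated: float = 0.0
    noise_sd: float = 0.25
    scan_interval: float = 3.0
    scan_jitter_sd: float = 0.5  # 2 weeks
    window_months: float = 6.0
    randomization_ratio: Tuple[int, int] = (40, 40)
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_sd", "noise_sd", "scan_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.scan_interval <= 0:
            raise ConfigurationError("scan_interval must be > 0")
        if self.window_months <= 0:
            raise ConfigurationError("window_months must be > 0")
        if len(self.randomization_ratio) != 2 or any(
            n < 0 for n in self.randomization_ratio
        ):
            raise ConfigurationError("randomization_ratio must be two counts >= 0")
        if self.n_subjects != sum(self.randomization_ratio):
            raise ConfigurationError(
                "n_subjects must equal the sum of randomization_ratio"
            )

    @property
    def arms(self) -> Tuple[str, str]:
        return (CONTROL, TREATED)

    def post_growth_rate(self, arm: str) -> float:
        if arm == CONTROL:
            return self.post_growth_rate_control
        if arm == TREATED:
            return self.post_growth_rate_treated
        raise ConfigurationError(f"unknown arm {arm!r}")

    def nominal_scan_times(self) -> np.ndarray:
        """Nominal schedule: every scan_interval across both windows, anchored at 0."""
        n_per_window = int(round(self.window_months / self.scan_interval))
        pre = -self.scan_interval * np.arange(n_per_window, 0, -1)
        post = self.scan_interval * np.arange(1, n_per_window + 1)
        return np.concatenate([pre, [0.0], post])


@dataclass
class SubjectRecord:
    """One randomized subject: trajectory, arm label, optional survival outcome."""

    trajectory: VolumeTrajectory
    arm: str
    survival: Optional[Tuple[float, bool]] = None  # (event_time months, event flag)

    @property
    def subject_id(self) -> str:
        return self.trajectory.subject_id


def true_volume(config: SimulationConfig, arm: str, t: float) -> float:
    """Noise-free volume at time t for a subject with baseline exactly at the mean.

    Piecewise linear and continuous at 0: slope ``growth_rate`` on
    [-window_months, 0], arm-specific slope afterwards.
    """
    v0 = config.baseline_mean + config.growth_rate * config.window_months
    if t <= 0:
        return v0 + config.growth_rate * t
    return v0 + config.post_growth_rate(arm) * t


def simulate_trajectory(
    config: SimulationConfig,
    arm: str,
    stream: np.random.Generator,
    subject_id: str = "subject",
) -> VolumeTrajectory:
    """Draw one subject's scan series.

    The baseline volume is Normal(baseline_mean, baseline_sd^2) at the
    earliest *nominal* scan time; every non-anchor scan time is perturbed by
    Normal(0, scan_jitter_sd^2) while the anchor at 0 stays fixed (treatment
    start defines both evaluation windows); the observed volume is the true
    piecewise-linear volume evaluated at the perturbed time plus
    Normal(0, noise_sd^2) measurement noise, floored at 0 mL.
    """
    config.post_growth_rate(arm)  # validates the arm label
    nominal = config.nominal_scan_times()
    baseline = stream.normal(config.baseline_mean, config.baseline_sd)
    v0 = baseline + config.growth_rate * config.window_months  # true volume at t=0
    post_slope = config.post_growth_rate(arm)

    times = np.empty_like(nominal)
    volumes = np.empty_like(nominal)
    n_floored = 0
    for i, t_nom in enumerate(nominal):
        if t_nom == 0.0:
            t = 0.0
        else:
            t = t_nom + stream.normal(0.0, config.scan_jitter_sd)
        v_true = v0 + (config.growth_rate if t <= 0 else post_slope) * t
        v_obs = v_true + stream.normal(0.0, config.noise_sd)
        if v_obs < 0:
            v_obs = 0.0
            n_floored += 1
        times[i] = t
        volumes[i] = v_obs
    if n_floored:
        logger.info("subject %s: floored %d negative volume(s) to 0", subject_id, n_floored)

    order = np.argsort(times, kind="stable")
    return VolumeTrajectory(subject_id, times[order], volumes[order])


def _subject_stream(seed: int, index: int) -> np.random.Generator:
    """Per-subject PRNG substream keyed by (seed, subject index)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Simulate the full randomized cohort.

    The first ``randomization_ratio[0]`` subjects are controls, the rest
    treated; each subject draws from an independent substream keyed by
    (seed, subject index), so any subject is reproducible in isolation.
    """
    n_control, n_treated = config.randomization_ratio
    records = []
    for i in range(config.n_subjects):
        arm = CONTROL if i < n_control else TREATED
        sid = f"sub-{i:04d}"
        traj = simulate_trajectory(config, arm, _subject_stream(config.seed, i), sid)
        records.append(SubjectRecord(trajectory=traj, arm=arm))
    logger.info(
        "simulated cohort: %d subjects (%d control, %d treated), %d scans each",
        config.n_subjects, n_control, n_treated, config.nominal_scan_times().size,
    )
    return records


def simulate_survival(
    trajectory: VolumeTrajectory,
    coefficients,
    max_followup: float,
    stream: np.random.Generator,
) -> Tuple[float, bool]:
    """Draw an event time from the PID hazard h(t) = h0 * exp(b1*I + b2*V + b3*dV).

    The three covariates (running integral of V from 0, current volume,
    current growth slope) are held piecewise-constant between scan times and
    the last value is carried forward to ``max_followup``, so the cumulative
    hazard is piecewise linear and inverse-transform sampling is exact.
    Returns (event_time, event_indicator); the indicator is False when the
    drawn time exceeds ``max_followup`` (administrative censoring).
    """
    from .coxpid import covariate_steps  # local import to avoid a module cycle

    if coefficients.h0 is None or coefficients.h0 <= 0:
        raise ConfigurationError("h0 must be > 0 for survival simulation")
    if max_followup < 0:
        raise ConfigurationError("max_followup must be >= 0")
    if max_followup == 0:
        return 0.0, False
    if np.count_nonzero(trajectory.times > 0) < 2:
        raise InsufficientDataError(
            "survival simulation needs at least 2 post-baseline scans"
        )

    knots, covs = covariate_steps(trajectory)
    betas = np.asarray([coefficients.beta1, coefficients.beta2, coefficients.beta3])
    rates = coefficients.h0 * np.exp(covs @ betas)  # hazard on [knots[k], knots[k+1])

    target = stream.exponential(1.0)  # -log U
    cum = 0.0
    for k, rate in enumerate(rates):
        t_lo = knots[k]
        t_hi = knots[k + 1] if k + 1 < len(knots) else max_followup
        t_hi = min(t_hi, max_followup)
        if t_hi <= t_lo:
            continue
        step = rate * (t_hi - t_lo)
        if cum + step >= target:
            return t_lo + (target - cum) / rate, True
        cum += step
    return max_followup, False
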