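"""Arm-level statistics for PID treatment-effect parameters.

Per-arm summaries test each Delta-lambda distribution against the no-effect
value of zero (two-sided one-sample t-test, with a sign-flip permutation
alternative); combination-vs-single-agent benefit is the all-pairs
probability p(Delta_combination < Delta_single); and ROC analysis links
volumetric percent changes to binary qualitative calls (progression or
response), selecting the operating cutoff by Youden's J.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .exceptions import DataError, InsufficientDataError
from .pid import DeltaPID

DELTA_FIELDS = ("delta_lambda1", "delta_lambda2", "delta_lambda3")


@dataclass(frozen=True)
class ParameterSummary:
    """Mean, sample SD, and one-sample test of one Delta-lambda against 0."""

    mean: float
    sd: float
    t_statistic: float
    p_value: float
    exactly_determined: bool = False  # SD was 0: the test is degenerate


@dataclass(frozen=True)
class ArmSummary:
    arm: str
    n: int
    parameters: Dict[str, ParameterSummary]


def _one_sample_summary(values: np.ndarray) -> ParameterSummary:
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        # all deltas identical: the location is exactly determined
        t = np.inf * np.sign(mean) if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
        return ParameterSummary(mean, sd, float(t), p, exactly_determined=True)
    t, p = sps.ttest_1samp(values, 0.0)
    return ParameterSummary(mean, sd, float(t), float(p))


def summarize_arm(deltas: Sequence[DeltaPID], arm: str = "") -> ArmSummary:
    """Mean, SD, and two-sided one-sample t-test vs 0 for each Delta-lambda."""
    if len(deltas) < 2:
        raise InsufficientDataError("arm summary needs at least 2 subjects")
    params = {}
    for name in DELTA_FIELDS:
        values = np.array([getattr(d, name) for d in deltas], dtype=float)
        params[name] = _one_sample_summary(values)
    return ArmSummary(arm=arm, n=len(deltas), parameters=params)


def sign_flip_pvalue(
    values: Sequence[float],
    n_permutations: int = 10_000,
    stream: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided sign-flip permutation p-value for a mean of zero.

    Robust companion to the t-test: under the null of a symmetric
    distribution about 0, every sign pattern of the deltas is equally likely.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("sign-flip test needs at least 2 values")
    stream = stream or np.random.default_rng(0)
    observed = abs(values.mean())
    signs = stream.choice([-1.0, 1.0], size=(n_permutations, values.size))
    null_means = np.abs((signs * values).mean(axis=1))
    return float((1 + np.sum(null_means >= observed - 1e-15)) / (1 + n_permutations))


def compare_arms(
    deltas_a: Sequence[float],
    deltas_b: Sequence[float],
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Welch's t-test between two arms' delta distributions.

    ``alternative="less"`` tests the directional hypothesis that arm A's
    parameters are lower (better response) than arm B's.
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each arm needs at least 2 subjects")
    t, p = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(t), float(p)


def prob_lower(
    deltas_combination: Sequence[float], deltas_single: Sequence[float]
) -> float:
    """All-pairs empirical probability p(combination < single), ties counted 1/2.

    Equivalently the Mann-Whitney U statistic of the single-agent sample over
    the combination sample, normalized by the number of pairs.
    """
    a = np.asarray(deltas_combination, dtype=float)
    b = np.asarray(deltas_single, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both delta lists must be non-empty")
    u = sps.mannwhitneyu(b, a, alternative="two-sided").statistic
    return float(u) / (a.size * b.size)


@dataclass(frozen=True)
class ROCResult:
    cutoffs: np.ndarray  # percent-change grid, decreasing
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    selected_cutoff: float  # maximizes Youden's J

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0 + 1e-12):
            raise DataError("AUC outside [0, 1]")


def roc_analysis(
    labels: Sequence[int], percent_changes: Sequence[float]
) -> ROCResult:
    """ROC of a percent-change classifier for a binary qualitative call.

    A comparison is called positive when its percent change is >= the
    cutoff; the sweep visits every observed value (plus a +inf sentinel),
    the AUC is the trapezoid over the resulting (FPR, TPR) staircase, and
    the selected cutoff maximizes Youden's J = sensitivity + specificity - 1
    (first, i.e. highest, cutoff on ties).
    """
    y = np.asarray(labels, dtype=int)
    x = np.asarray(percent_changes, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DataError("labels and percent_changes must be equally long 1-D")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs both classes present")

    cutoffs = np.concatenate([[np.inf], np.unique(x)[::-1]])
    pred = x[None, :] >= cutoffs[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    auc = float(np.trapezoid(sens, 1.0 - spec))
    j = sens + spec - 1.0
    selected = float(cutoffs[int(np.argmax(j))])
    return ROCResult(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        selected_cutoff=selected,
    )


def prob_lower_matrix(groups: Dict[str, Sequence[float]]) -> Dict[str, Dict[str, float]]:
    """Pairwise p(row < column) for named delta groups (diagonal 0.5)."""
    names = list(groups)
    return {
        a: {b: (0.5 if a == b else prob_lower(groups[a], groups[b])) for b in names}
        for a in names
    }
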