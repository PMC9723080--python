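"""Modified Levin scoring of serial brain-tumor imaging.

A reader compares each scan with the previous one and assigns an integer
score in {-3..+3} per tumor compartment (contrast-enhancing disease on
post-contrast T1, non-enhancing disease on T2/FLAIR):

    -3  new lesion or emerging enhancement     -> progressive disease (PD)
    -2  definitely worse                       -> PD
    -1  possibly worse                         -> no event (worse-leaning SD)
     0  no change                              -> stable disease (SD)
    +1  possibly better                        -> no event (better-leaning SD)
    +2  definitely better                      -> partial response (PR)
    +3  complete disappearance                 -> complete response (CR)

For mixed enhancing/non-enhancing tumors the compartments are combined
conservatively: progression in *either* compartment is PD, while PR/CR
require a definite response from *every* assessed compartment.  PD, PR and
CR all require confirmation by a qualifying follow-up at least
``confirmation_window`` weeks later; progression-free survival is dated at
the first assessment of the confirmed pair.

A synthetic rater maps volumetric percent change to scores through
configurable threshold cutpoints, with optional discrete rater noise; it is
used to exercise the engine end-to-end against ground-truth volume rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigurationError, ValidationError

VALID_SCORES = frozenset(range(-3, 4))

PD, SD, PR, CR, NOT_EVALUABLE = "PD", "SD", "PR", "CR", "not-evaluable"


class LevinEntry(NamedTuple):
    """One rated comparison: weeks from treatment start, per-compartment scores."""

    time: float
    enhancing: Optional[int]
    nonenhancing: Optional[int]


@dataclass
class LevinScoreSeries:
    """Dated modified Levin scores for one subject, optionally split by
    enhancing/non-enhancing compartment."""

    subject_id: str
    entries: list[LevinEntry]

    def __post_init__(self):
        times = [e.time for e in self.entries]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"subject {self.subject_id!r}: entry times must be strictly increasing"
            )
        for e in self.entries:
            if e.enhancing is None and e.nonenhancing is None:
                raise ValidationError(
                    f"subject {self.subject_id!r}: entry at week {e.time:g} "
                    "scores neither compartment"
                )
            for s in (e.enhancing, e.nonenhancing):
                if s is not None and s not in VALID_SCORES:
                    raise ValidationError(f"score {s!r} outside {{-3..+3}}")

    @classmethod
    def from_scores(cls, subject_id: str, times, scores) -> "LevinScoreSeries":
        """Single-compartment convenience constructor."""
        return cls(
            subject_id,
            [LevinEntry(float(t), int(s), None) for t, s in zip(times, scores)],
        )


@dataclass(frozen=True)
class ResponseAssessment:
    """Outcome of walking a score series: overall category, onset of the
    first confirmed event, and PFS time (censored when no confirmed PD)."""

    category: str
    onset_time: Optional[float]
    confirmed: bool
    pfs_time: Optional[float]
    pfs_event: bool


def score_to_category(score: int) -> str:
    """Response category of a single score: ±1 and 0 are SD-level (no event)."""
    if score not in VALID_SCORES:
        raise ValidationError(f"score {score!r} outside {{-3..+3}}")
    if score <= -2:
        return PD
    if score == 3:
        return CR
    if score == 2:
        return PR
    return SD


def combine_compartments(
    enhancing: Optional[int], nonenhancing: Optional[int]
) -> str:
    """Overall category of one timepoint from the per-compartment scores.

    PD if either compartment definitely progressed (score <= -2); PR/CR only
    if every assessed compartment reaches the response level; a missing
    compartment defers to the present one.
    """
    present = [s for s in (enhancing, nonenhancing) if s is not None]
    if not present:
        raise ValidationError("at least one compartment must be scored")
    for s in present:
        if s not in VALID_SCORES:
            raise ValidationError(f"score {s!r} outside {{-3..+3}}")
    if any(s <= -2 for s in present):
        return PD
    if all(s == 3 for s in present):
        return CR
    if all(s >= 2 for s in present):
        return PR
    return SD


def _entry_category(entry: LevinEntry) -> str:
    return combine_compartments(entry.enhancing, entry.nonenhancing)


def _worst_score(entry: LevinEntry) -> int:
    return min(s for s in (entry.enhancing, entry.nonenhancing) if s is not None)


def assess_series(
    series: LevinScoreSeries,
    confirmation_window: float = 4.0,
    confirm_new_lesion: bool = True,
) -> ResponseAssessment:
    """Walk a score series chronologically and derive the confirmed response.

    A PD-level timepoint is confirmed by any later timepoint at least
    ``confirmation_window`` weeks after it whose worst compartment score is
    still <= -1 (not improved above the progression threshold).  PR (CR) is
    confirmed by a later PR-or-better (CR) timepoint at least the same gap
    later.  PFS is dated at the first assessment of the confirmed PD pair
    and censored at the last entry otherwise.  ``confirm_new_lesion=False``
    makes a -3 (new lesion) timepoint an immediate, confirmation-free PD.
    """
    entries = series.entries
    if not entries:
        return ResponseAssessment(NOT_EVALUABLE, None, False, None, False)

    categories = [_entry_category(e) for e in entries]
    last_time = entries[-1].time

    def _confirmed_onset(level: str) -> Optional[float]:
        for i, (entry, cat) in enumerate(zip(entries, categories)):
            if cat != level:
                continue
            if level == PD and not confirm_new_lesion and _worst_score(entry) == -3:
                return entry.time
            for later in entries[i + 1 :]:
                if later.time - entry.time < confirmation_window:
                    continue
                if level == PD and _worst_score(later) <= -1:
                    return entry.time
                later_cat = _entry_category(later)
                if level == PR and later_cat in (PR, CR):
                    return entry.time
                if level == CR and later_cat == CR:
                    return entry.time
        return None

    pd_onset = _confirmed_onset(PD)
    pr_onset = _confirmed_onset(PR)
    cr_onset = _confirmed_onset(CR)

    events = [(t, c) for t, c in ((pd_onset, PD), (cr_onset, CR), (pr_onset, PR)) if t is not None]
    if events:
        onset, category = min(events, key=lambda tc: tc[0])
        return ResponseAssessment(
            category=category,
            onset_time=onset,
            confirmed=True,
            pfs_time=pd_onset if pd_onset is not None else last_time,
            pfs_event=pd_onset is not None,
        )
    return ResponseAssessment(SD, None, False, last_time, False)


def levin_pseudovolume(
    series: LevinScoreSeries, compartment: str = "total"
) -> Tuple[np.ndarray, np.ndarray]:
    """Digitize a score series into a pseudo-volume signal (score-units).

    Scores are change ratings, so the pseudo-volume accumulates their
    negation (worsening, i.e. negative scores, drives the signal up):
    Vtilde(t_k) = Vtilde(t_{k-1}) - s_k with Vtilde(t_0) = -s_0.  The
    ``compartment`` selector is "enhancing", "nonenhancing", or "total"
    (sum of assessed compartments).  Returns (times_weeks, pseudo_volume),
    directly usable by the PID estimators on a score-unit scale.
    """
    if compartment not in ("enhancing", "nonenhancing", "total"):
        raise ConfigurationError(f"unknown compartment {compartment!r}")

    def _score(e: LevinEntry) -> float:
        if compartment == "enhancing":
            if e.enhancing is None:
                raise ValidationError(f"entry at week {e.time:g} lacks an enhancing score")
            return e.enhancing
        if compartment == "nonenhancing":
            if e.nonenhancing is None:
                raise ValidationError(
                    f"entry at week {e.time:g} lacks a non-enhancing score"
                )
            return e.nonenhancing
        return sum(s for s in (e.enhancing, e.nonenhancing) if s is not None)

    times = np.array([e.time for e in series.entries])
    scores = np.array([_score(e) for e in series.entries], dtype=float)
    return times, -np.cumsum(scores)


@dataclass(frozen=True)
class RaterModel:
    """Synthetic reader mapping volumetric percent change to Levin scores.

    ``thresholds`` maps lower percent-change cutpoints to scores, scanned in
    decreasing cutpoint order; a change below every cutpoint maps to
    ``floor_score``.  Defaults blend the retrospective calibration anchors:
    definite progression near +50%, the +15% progression ROC cutoff, the
    -20% response ROC cutoff, and possible shrinkage around -40%.
    ``rater_noise_sd`` (score units) drives a +/-1 discrete perturbation
    applied with probability rater_noise_sd^2 (matching its variance),
    clipped to [-2, +2]; the +/-3 levels are reserved for explicit
    new-lesion / disappearance flags and never produced by thresholds or
    noise.
    """

    thresholds: Tuple[Tuple[float, int], ...] = (
        (50.0, -2),
        (15.0, -1),
        (-20.0, 0),
        (-40.0, 1),
    )
    floor_score: int = 2
    rater_noise_sd: float = 0.0

    def __post_init__(self):
        cuts = [c for c, _ in self.thresholds]
        scores = [s for _, s in self.thresholds]
        if any(c2 >= c1 for c1, c2 in zip(cuts, cuts[1:])):
            raise ConfigurationError("threshold cutpoints must be strictly decreasing")
        if any(s2 <= s1 for s1, s2 in zip(scores, scores[1:])) or not all(
            -2 <= s <= 2 for s in scores + [self.floor_score]
        ):
            raise ConfigurationError(
                "threshold scores must increase as cutpoints decrease, within [-2, +2]"
            )
        if self.rater_noise_sd < 0 or self.rater_noise_sd > 1:
            raise ConfigurationError("rater_noise_sd must be in [0, 1]")

    def base_score(self, percent_change: float) -> int:
        for cut, score in self.thresholds:
            if percent_change >= cut:
                return score
        return self.floor_score


def rate_trajectory(
    trajectory,
    model: RaterModel,
    stream: Optional[np.random.Generator] = None,
    weeks_per_month: float = 4.0,
) -> LevinScoreSeries:
    """Score a volume trajectory's post-treatment scans with the synthetic rater.

    Each scan from the first follow-up onward is compared with the previous
    scan as a percent volume change and rated; a volume dropping to exactly 0
    raises the disappearance flag (+3), and regrowth from 0 the new-lesion
    flag (-3).  Times convert from months to weeks at ``weeks_per_month``.
    """
    post = trajectory.times >= 0
    times = trajectory.times[post]
    vols = trajectory.volumes[post]
    entries = []
    for k in range(1, times.size):
        prev, cur = vols[k - 1], vols[k]
        if prev == 0.0:
            score = simulate_rater(0.0, model, stream, new_lesion=cur > 0)
        elif cur == 0.0:
            score = simulate_rater(-100.0, model, stream, disappearance=True)
        else:
            score = simulate_rater(100.0 * (cur - prev) / prev, model, stream)
        entries.append(LevinEntry(float(times[k]) * weeks_per_month, score, None))
    return LevinScoreSeries(trajectory.subject_id, entries)


def simulate_rater(
    percent_change: float,
    model: RaterModel,
    stream: Optional[np.random.Generator] = None,
    new_lesion: bool = False,
    disappearance: bool = False,
) -> int:
    """Rate one scan-to-scan percent volume change.

    Explicit flags assign the reserved levels (-3 for a new lesion, +3 for
    complete disappearance) directly; otherwise the score is a deterministic
    threshold lookup plus optional discrete rater noise.
    """
    if new_lesion:
        return -3
    if disappearance:
        return 3
    score = model.base_score(percent_change)
    if model.rater_noise_sd > 0:
        if stream is None:
            raise ConfigurationError("rater noise requires a random stream")
        if stream.random() < model.rater_noise_sd**2:
            score += int(stream.choice([-1, 1]))
    return int(np.clip(score, -2, 2))
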