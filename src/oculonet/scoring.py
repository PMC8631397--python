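"""Trial classification and per-subject summary measures.

Scores anti-saccade and Go/NoGo trials from their detected event streams:
the primary saccade is the first saccade after peripheral-stimulus onset
with at least a minimum amplitude; its latency must fall inside the
[80, 900] ms window or the trial is discarded regardless of direction.
An anti-saccade away from the stimulus is correct, toward it an error
(reflexive prosaccade); a Go trial is correct when the primary saccade
heads to the stimulus within an angular tolerance, and a NoGo trial is
correct when no qualifying saccade toward the stimulus occurs.

Per-subject summaries hold the six oculomotor network measures — median
correct latencies (ASLs, GnGLs), median error latencies (ASELs, GnGELs)
and error proportions (ASEs, GnGEs) — plus the task performance
accuracies.  Performance accuracy excludes discarded trials from both
numerator and denominator by default so it measures decision quality; the
denominator convention is switchable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import OculomotorEvent
from .exceptions import ComputationError, SummaryError
from .simulate import TrialSpec

__all__ = [
    "ScoringParams",
    "TrialScore",
    "SubjectSummary",
    "primary_saccade",
    "score_antisaccade_trial",
    "score_gonogo_trial",
    "score_trial",
    "performance_accuracy",
    "summarize_subject",
]

LATENCY_WINDOW_MS: tuple[float, float] = (80.0, 900.0)


@dataclass(frozen=True)
class ScoringParams:
    """Scoring conventions.

    ``direction_tolerance_deg`` is half the 45-degree angular spacing of
    the 8-location diamond, so every stimulus owns a disjoint angular
    sector.  ``count_discarded_in_pa`` switches the performance-accuracy
    denominator to include discarded trials.
    """

    latency_window_ms: tuple[float, float] = LATENCY_WINDOW_MS
    min_amplitude_deg: float = 2.0
    direction_tolerance_deg: float = 22.5
    count_discarded_in_pa: bool = False


@dataclass(frozen=True)
class TrialScore:
    """Classification and latency of one scored trial."""

    trial_id: str
    task: str
    condition: str
    classification: str  # correct | error | miss | discarded
    latency_ms: float | None = None
    primary_saccade: OculomotorEvent | None = None
    discard_reason: str = "none"  # none | latency_low | latency_high | no_data

    def __post_init__(self) -> None:
        if self.classification not in ("correct", "error", "miss", "discarded"):
            raise ValueError(f"unknown classification {self.classification!r}")
        if (self.classification == "discarded") == (self.discard_reason == "none"):
            raise ValueError("discarded trials (and only they) need a discard reason")
        if (self.latency_ms is None) != (self.primary_saccade is None):
            raise ValueError("latency present iff a primary saccade exists")


def primary_saccade(
    events: Sequence[OculomotorEvent],
    ps_onset_ms: float,
    min_amplitude_deg: float = 2.0,
) -> OculomotorEvent | None:
    """First saccade at or after PS onset with at least the minimum amplitude."""
    for ev in events:
        if (
            ev.kind == "saccade"
            and ev.onset_ms >= ps_onset_ms
            and ev.amplitude_deg >= min_amplitude_deg
        ):
            return ev
    return None


def _latency_check(latency: float, window: tuple[float, float]) -> str:
    lo, hi = window
    if latency < lo:
        return "latency_low"
    if latency > hi:
        return "latency_high"
    return "none"


def _toward_ps(sac: OculomotorEvent, trial: TrialSpec, tolerance_deg: float) -> bool:
    """Does the saccade head toward the peripheral stimulus (within tolerance)?"""
    dx, dy = sac.direction()
    if dx == 0 and dy == 0:
        return False
    amp = trial.ps_amplitude_deg
    ux, uy = trial.ps_x_deg / amp, trial.ps_y_deg / amp
    cosang = max(-1.0, min(1.0, dx * ux + dy * uy))
    return math.degrees(math.acos(cosang)) <= tolerance_deg


def score_antisaccade_trial(
    trial: TrialSpec,
    events: Sequence[OculomotorEvent],
    params: ScoringParams | None = None,
    trial_id: str = "",
) -> TrialScore:
    """Classify one anti-saccade trial.

    The primary saccade's horizontal direction decides the outcome:
    opposite the stimulus side is a correct anti-saccade, toward it an
    erroneous reflexive saccade.  Latencies outside the window discard the
    trial whatever the direction; no primary saccade is a miss.
    """
    params = params or ScoringParams()
    if trial.task != "AS":
        raise ValueError(f"expected an AS trial, got task {trial.task!r}")
    sac = primary_saccade(events, trial.ps_onset_ms, params.min_amplitude_deg)
    if sac is None:
        return TrialScore(trial_id, "AS", "none", "miss")
    latency = sac.onset_ms - trial.ps_onset_ms
    reason = _latency_check(latency, params.latency_window_ms)
    if reason != "none":
        return TrialScore(trial_id, "AS", "none", "discarded", latency, sac, reason)
    dx = sac.end_xy[0] - sac.start_xy[0]
    toward = dx * trial.ps_x_deg > 0
    cls = "error" if toward else "correct"
    return TrialScore(trial_id, "AS", "none", cls, latency, sac)


def score_gonogo_trial(
    trial: TrialSpec,
    events: Sequence[OculomotorEvent],
    params: ScoringParams | None = None,
    trial_id: str = "",
) -> TrialScore:
    """Classify one Go/NoGo trial.

    Go: a primary saccade toward the stimulus (within the angular
    tolerance) is correct; a saccade elsewhere is an error; no saccade is
    a miss (counted against accuracy).  NoGo: maintained fixation — no
    qualifying saccade toward the stimulus — is correct; a saccade toward
    it is an error whose latency is recorded as an error latency.
    """
    params = params or ScoringParams()
    if trial.task != "GnG":
        raise ValueError(f"expected a GnG trial, got task {trial.task!r}")
    sac = primary_saccade(events, trial.ps_onset_ms, params.min_amplitude_deg)
    cond = trial.condition

    if cond == "Go":
        if sac is None:
            return TrialScore(trial_id, "GnG", cond, "miss")
        latency = sac.onset_ms - trial.ps_onset_ms
        reason = _latency_check(latency, params.latency_window_ms)
        if reason != "none":
            return TrialScore(
                trial_id, "GnG", cond, "discarded", latency, sac, reason
            )
        ok = _toward_ps(sac, trial, params.direction_tolerance_deg)
        return TrialScore(trial_id, "GnG", cond, "correct" if ok else "error",
                          latency, sac)

    # NoGo
    if sac is None or not _toward_ps(sac, trial, params.direction_tolerance_deg):
        return TrialScore(trial_id, "GnG", cond, "correct")
    latency = sac.onset_ms - trial.ps_onset_ms
    reason = _latency_check(latency, params.latency_window_ms)
    if reason != "none":
        return TrialScore(trial_id, "GnG", cond, "discarded", latency, sac, reason)
    return TrialScore(trial_id, "GnG", cond, "error", latency, sac)


def score_trial(
    trial: TrialSpec,
    events: Sequence[OculomotorEvent],
    params: ScoringParams | None = None,
    trial_id: str = "",
) -> TrialScore:
    """Dispatch on the trial's task."""
    if trial.task == "AS":
        return score_antisaccade_trial(trial, events, params, trial_id)
    return score_gonogo_trial(trial, events, params, trial_id)


def performance_accuracy(
    scores: Iterable[TrialScore], count_discarded: bool = False
) -> float:
    """Correct responses divided by counted trials.

    Discarded trials are excluded from both numerator and denominator by
    default; ``count_discarded`` puts them back in the denominator.
    """
    scores = list(scores)
    total = len(scores) if count_discarded else sum(
        s.classification != "discarded" for s in scores
    )
    if total == 0:
        raise ComputationError("no countable trials for performance accuracy")
    correct = sum(s.classification == "correct" for s in scores)
    return correct / total


def _median_or_none(values: list[float]) -> float | None:
    return float(np.median(values)) if values else None


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject oculomotor measures and task accuracies.

    Error-latency medians are ``None`` when the subject made no errors of
    that kind; medians cover non-discarded trials only.
    """

    subject_id: str
    group: str
    as_pa: float
    asl_median_ms: float | None
    asl_mean_ms: float | None
    asel_median_ms: float | None
    ase_proportion: float
    go_pa: float
    nogo_pa: float
    gngl_median_ms: float | None
    gngel_median_ms: float | None
    gnge_proportion: float

    def measures(self) -> dict[str, float | None]:
        """The six network measures keyed by canonical name."""
        return {
            "ASLs": self.asl_median_ms,
            "ASELs": self.asel_median_ms,
            "ASEs": self.ase_proportion,
            "GnGLs": self.gngl_median_ms,
            "GnGELs": self.gngel_median_ms,
            "GnGEs": self.gnge_proportion,
        }


def summarize_subject(
    subject_id: str,
    group: str,
    as_scores: Sequence[TrialScore],
    gng_scores: Sequence[TrialScore],
    count_discarded_in_pa: bool = False,
) -> SubjectSummary:
    """Collapse one subject's trial scores into the six network measures."""
    missing = []
    if not as_scores:
        missing.append("anti-saccade trials")
    if not gng_scores:
        missing.append("Go/NoGo trials")
    if missing:
        raise SummaryError(f"subject {subject_id}: no scorable {', '.join(missing)}")

    as_correct = [s.latency_ms for s in as_scores
                  if s.classification == "correct" and s.latency_ms is not None]
    as_error = [s.latency_ms for s in as_scores
                if s.classification == "error" and s.latency_ms is not None]
    as_counted = [s for s in as_scores if s.classification != "discarded"]
    if not as_counted:
        raise SummaryError(f"subject {subject_id}: all AS trials discarded")

    go = [s for s in gng_scores if s.condition == "Go"]
    nogo = [s for s in gng_scores if s.condition == "NoGo"]
    if not go or not nogo:
        raise SummaryError(f"subject {subject_id}: missing a Go/NoGo condition")
    go_correct = [s.latency_ms for s in go
                  if s.classification == "correct" and s.latency_ms is not None]
    nogo_error = [s.latency_ms for s in nogo
                  if s.classification == "error" and s.latency_ms is not None]
    nogo_counted = [s for s in nogo if s.classification != "discarded"]

    ase_prop = sum(s.classification == "error" for s in as_counted) / len(as_counted)
    gnge_prop = (
        sum(s.classification == "error" for s in nogo_counted) / len(nogo_counted)
        if nogo_counted
        else 0.0
    )
    return SubjectSummary(
        subject_id=subject_id,
        group=group,
        as_pa=performance_accuracy(as_scores, count_discarded_in_pa),
        asl_median_ms=_median_or_none(as_correct),
        asl_mean_ms=float(np.mean(as_correct)) if as_correct else None,
        asel_median_ms=_median_or_none(as_error),
        ase_proportion=ase_prop,
        go_pa=performance_accuracy(go, count_discarded_in_pa),
        nogo_pa=performance_accuracy(nogo, count_discarded_in_pa),
        gngl_median_ms=_median_or_none(go_correct),
        gngel_median_ms=_median_or_none(nogo_error),
        gnge_proportion=gnge_prop,
    )


def summaries_to_dataframe(summaries: Iterable[SubjectSummary]) -> pd.DataFrame:
    """Subject-summary CSV dialect: one row per subject."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "as_pa": s.as_pa,
                "go_pa": s.go_pa,
                "nogo_pa": s.nogo_pa,
                **s.measures(),
            }
        )
    return pd.DataFrame(rows)
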