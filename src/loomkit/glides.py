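"""Glide detection from wingbeat sensor events and glide summaries.

A glide is a pause between consecutive wingbeats longer than ``k`` times the
mean of the preceding ``n_history`` wingbeat intervals (defaults 1.25 and
10).  Glide onset is the time of the last wingbeat signal opening the gap,
stored in ms relative to projected collision; a glide counts as "before
collision" iff its onset is strictly negative.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .spikes import group_summary

__all__ = [
    "WingbeatTrain",
    "GlideEvent",
    "GlideSummary",
    "wingbeat_intervals",
    "detect_glides",
    "glide_onset_relative",
    "glide_proportions",
    "exclude_weak_flight",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WingbeatTrain:
    """Wingbeat sensor event times (ms re: collision) for one presentation.

    ``valid_flight=False`` marks presentations where the animal did not fly
    strongly; such presentations are excluded from every summary.
    """

    individual_id: str
    stim_id: str
    presentation: int
    event_times: np.ndarray
    valid_flight: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("event_times must be one-dimensional")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(
                f"event_times must be strictly increasing (violation at index {bad})"
            )
        object.__setattr__(self, "event_times", t)

    def __len__(self) -> int:
        return len(self.event_times)


@dataclass(frozen=True)
class GlideEvent:
    """A detected glide: the wingbeat pause that exceeded its threshold."""

    onset_time: float
    gap_duration: float
    threshold_used: float
    before_collision: bool

    def __post_init__(self) -> None:
        if self.gap_duration <= self.threshold_used:
            raise ValueError("gap_duration must exceed threshold_used")


def wingbeat_intervals(train: WingbeatTrain) -> np.ndarray:
    """Successive inter-wingbeat intervals (ms); empty for < 2 events."""
    if len(train) < 2:
        return np.empty(0)
    return np.diff(train.event_times)


def detect_glides(
    train: WingbeatTrain, k: float = 1.25, n_history: int = 10
) -> List[GlideEvent]:
    """Detect wingbeat pauses exceeding ``k`` x the recent-interval mean.

    Interval ``i`` is a glide iff its duration exceeds ``k`` times the mean
    of the preceding ``n_history`` interval durations.  The first
    ``n_history`` intervals are ineligible (the rule needs a full history),
    and after a detected glide the history resets and must refill before a
    new detection, so the long glide interval never inflates the baseline.
    Raising ``k`` can only shrink the set of detections.
    """
    if k <= 1:
        raise ValueError(f"k must be > 1, got {k!r}")
    if n_history < 1:
        raise ValueError(f"n_history must be >= 1, got {n_history!r}")
    t = train.event_times
    events: List[GlideEvent] = []
    if len(t) < 2:
        return events
    durations = np.diff(t)
    history: deque = deque(maxlen=n_history)
    for i, dur in enumerate(durations):
        if len(history) == n_history:
            threshold = k * float(np.mean(history))
            if dur > threshold:
                onset = float(t[i])
                events.append(
                    GlideEvent(
                        onset_time=onset,
                        gap_duration=float(dur),
                        threshold_used=threshold,
                        before_collision=onset < 0.0,
                    )
                )
                history.clear()
                continue
        history.append(float(dur))
    return events


def glide_onset_relative(glide: GlideEvent) -> float:
    """Signed glide onset (ms re: collision); negative = before collision.

    Wingbeat trains are already referenced to projected collision, so this
    is the onset itself; the boundary onset == 0 classifies as *not* before
    collision (strict inequality).
    """
    return glide.onset_time


@dataclass(frozen=True)
class GlideSummary:
    """Per-individual and group glide metrics for one stimulus.

    ``before_collision_given_glide`` is computed only over individuals that
    glided at least once; individuals with zero glides are excluded from that
    metric (and from onset timing), not counted as zeros.
    """

    occurrence: Dict[str, float]
    mean_onset: Dict[str, float]
    before_collision_given_glide: Dict[str, float]
    preglide_per_presentation: Dict[str, float]
    occurrence_group: Tuple[float, float, int]
    onset_group: Tuple[float, float, int]
    before_given_glide_group: Tuple[float, float, int]
    preglide_group: Tuple[float, float, int]
    n_excluded: int = 0


def exclude_weak_flight(
    trains: Iterable[WingbeatTrain],
) -> List[WingbeatTrain]:
    """Drop presentations without strong flight; logs the exclusion count."""
    trains = list(trains)
    kept = [tr for tr in trains if tr.valid_flight]
    n_excluded = len(trains) - len(kept)
    if n_excluded:
        logger.info(
            "excluded %d of %d presentations for weak flight",
            n_excluded,
            len(trains),
        )
    return kept


def glide_proportions(
    trains: Iterable[WingbeatTrain],
    k: float = 1.25,
    n_history: int = 10,
    first_glide_only: bool = True,
) -> GlideSummary:
    """Glide occurrence/timing metrics per individual, then across the group.

    For each individual (over its valid presentations of one stimulus):

    * occurrence = presentations with >= 1 glide / valid presentations;
    * mean onset and the before-collision proportion use the first glide of
      each gliding presentation (``first_glide_only=True``, the default) or
      every glide;
    * preglide_per_presentation = presentations whose (first) glide began
      before collision / valid presentations.

    Group statistics are mean +/- SEM across individuals via
    :func:`loomkit.spikes.group_summary`.
    """
    trains = list(trains)
    valid = exclude_weak_flight(trains)
    n_excluded = len(trains) - len(valid)
    if not valid:
        raise ValueError("no valid presentations to summarise")

    by_ind: Dict[str, List[WingbeatTrain]] = {}
    for tr in valid:
        by_ind.setdefault(tr.individual_id, []).append(tr)

    occurrence: Dict[str, float] = {}
    mean_onset: Dict[str, float] = {}
    before_given: Dict[str, float] = {}
    preglide: Dict[str, float] = {}
    for ind, its in by_ind.items():
        n_valid = len(its)
        onsets: List[float] = []
        befores: List[bool] = []
        n_with_glide = 0
        n_pre = 0
        for tr in its:
            glides = detect_glides(tr, k=k, n_history=n_history)
            if not glides:
                continue
            n_with_glide += 1
            used = glides[:1] if first_glide_only else glides
            onsets.extend(g.onset_time for g in used)
            befores.extend(g.before_collision for g in used)
            if used[0].before_collision:
                n_pre += 1
        occurrence[ind] = n_with_glide / n_valid
        preglide[ind] = n_pre / n_valid
        if onsets:
            mean_onset[ind] = float(np.mean(onsets))
            before_given[ind] = float(np.mean(befores))

    return GlideSummary(
        occurrence=occurrence,
        mean_onset=mean_onset,
        before_collision_given_glide=before_given,
        preglide_per_presentation=preglide,
        occurrence_group=group_summary(list(occurrence.values())),
        onset_group=(
            group_summary(list(mean_onset.values()))
            if mean_onset
            else (float("nan"), 0.0, 0)
        ),
        before_given_glide_group=(
            group_summary(list(before_given.values()))
            if before_given
            else (float("nan"), 0.0, 0)
        ),
        preglide_group=group_summary(list(preglide.values())),
        n_excluded=n_excluded,
    )
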