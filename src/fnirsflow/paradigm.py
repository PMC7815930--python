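"""Experimental schedule modelling.

A session is a sequence of sections; each section opens with a long rest and
then runs a series of trials.  One trial is notification -> video -> rating ->
rest.  The module turns such a description into a flat, gap-free event timeline
and derives per-trial sample windows (epochs) for the decoding stages.

Conventions: times are seconds from session start; sample indices are 0-based
with half-open windows ``[start, start + length)``; the onset sample of an
event is ``floor(onset_s * fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PREFERENCES",
    "StimulusVideo",
    "TrialSpec",
    "Section",
    "SessionSpec",
    "Event",
    "EpochWindow",
    "InvalidSpecError",
    "trial_duration",
    "session_duration",
    "build_schedule",
    "epoch_windows",
    "paper_session",
    "task_block_duration",
    "table3_m_samples",
    "tertile_labels",
]

#: Preference classes in canonical (index) order: low, mid, high activation.
PREFERENCES = ("dislike", "so-so", "like")

#: Video durations used in the study design, seconds.
DEFAULT_DURATIONS = (15.0, 30.0, 60.0)

#: Printed network-input lengths (time samples) for each video duration.
#: 208 for the 15 s epoch, with proportionally scaled analogues; these do not
#: equal floor(duration * fs) at 15.625 Hz and are applied by truncation from
#: video onset.
TABLE3_M_SAMPLES = {15.0: 208, 30.0: 416, 60.0: 832}


class InvalidSpecError(ValueError):
    """A paradigm description violates its invariants."""


@dataclass(frozen=True)
class StimulusVideo:
    brand: str = "coca"
    duration_s: float = 15.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidSpecError(f"video duration must be positive, got {self.duration_s}")


@dataclass(frozen=True)
class TrialSpec:
    """One trial: notification, video stimulus, rating, rest."""

    video: StimulusVideo
    notification_s: float = 2.0
    rating_s: float = 5.0
    rest_s: float = 30.0

    def __post_init__(self) -> None:
        for name in ("notification_s", "rating_s", "rest_s"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class Section:
    initial_rest_s: float
    trials: tuple[TrialSpec, ...]

    def __post_init__(self) -> None:
        if self.initial_rest_s < 0:
            raise InvalidSpecError("initial rest must be >= 0")
        if not self.trials:
            raise InvalidSpecError("a section must contain at least one trial")
        object.__setattr__(self, "trials", tuple(self.trials))


@dataclass(frozen=True)
class SessionSpec:
    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        if not self.sections:
            raise InvalidSpecError("a session must contain at least one section")
        object.__setattr__(self, "sections", tuple(self.sections))


@dataclass(frozen=True)
class Event:
    """One tile of the session timeline."""

    kind: str  # rest | notification | video | rating
    onset_s: float
    duration_s: float
    trial_index: int | None = None
    label: str | None = None


@dataclass(frozen=True)
class EpochWindow:
    """Half-open sample window [start, start + length) inside one video event."""

    start: int
    length: int
    trial_index: int
    label: str | None = None


def trial_duration(trial: TrialSpec) -> float:
    """Total trial duration: notification + video + rating + rest, seconds."""
    return trial.notification_s + trial.video.duration_s + trial.rating_s + trial.rest_s


def session_duration(session: SessionSpec) -> float:
    return sum(
        sec.initial_rest_s + sum(trial_duration(t) for t in sec.trials)
        for sec in session.sections
    )


def task_block_duration(durations: Sequence[float] = DEFAULT_DURATIONS,
                        trial: TrialSpec | None = None) -> float:
    """Duration of one task block: the given video durations run back to back.

    With the default 15/30/60 s sequence and default phase lengths this is the
    216 s task process of one section block (52 + 67 + 97 s).
    """
    base = trial if trial is not None else TrialSpec(StimulusVideo())
    return sum(
        trial_duration(replace(base, video=replace(base.video, duration_s=d)))
        for d in durations
    )


def build_schedule(session: SessionSpec,
                   labels: Sequence[str] | None = None) -> list[Event]:
    """Flatten a session into a sorted, gap-free event list.

    Zero-duration phases are dropped (they carry no samples and would break
    the non-overlap invariant only formally).  ``labels``, when given, must
    provide one preference label per trial in session order and is attached to
    that trial's events.
    """
    events: list[Event] = []
    t = 0.0
    trial_idx = 0
    n_trials = sum(len(sec.trials) for sec in session.sections)
    if labels is not None and len(labels) != n_trials:
        raise InvalidSpecError(
            f"got {len(labels)} labels for {n_trials} trials")

    def emit(kind: str, dur: float, idx: int | None, label: str | None) -> None:
        nonlocal t
        if dur > 0:
            events.append(Event(kind, t, dur, idx, label))
            t += dur

    for sec in session.sections:
        emit("rest", sec.initial_rest_s, None, None)
        for trial in sec.trials:
            label = labels[trial_idx] if labels is not None else None
            emit("notification", trial.notification_s, trial_idx, label)
            emit("video", trial.video.duration_s, trial_idx, label)
            emit("rating", trial.rating_s, trial_idx, label)
            emit("rest", trial.rest_s, trial_idx, label)
            trial_idx += 1
    return events


def epoch_windows(schedule: Iterable[Event], fs: float,
                  phase: str = "video",
                  m_samples: int | str = "auto") -> list[EpochWindow]:
    """One sample window per event of the requested phase.

    ``m_samples="auto"`` takes the full phase, ``floor(duration_s * fs)``
    samples; an integer takes the first ``m_samples`` samples of the phase and
    raises if the phase is shorter.
    """
    if fs <= 0:
        raise InvalidSpecError(f"fs must be positive, got {fs}")
    if isinstance(m_samples, int) and m_samples <= 0:
        raise InvalidSpecError(f"m_samples must be positive, got {m_samples}")
    windows: list[EpochWindow] = []
    for ev in schedule:
        if ev.kind != phase:
            continue
        start = int(np.floor(ev.onset_s * fs))
        full = int(np.floor(ev.duration_s * fs))
        if m_samples == "auto":
            length = full
        else:
            length = int(m_samples)
            if length > full:
                raise InvalidSpecError(
                    f"window of {length} samples exceeds the {full}-sample "
                    f"{phase} phase of trial {ev.trial_index}")
        if ev.trial_index is None:
            raise InvalidSpecError(f"{phase} event without a trial index")
        windows.append(EpochWindow(start, length, ev.trial_index, ev.label))
    return windows


def paper_session(brands: Sequence[str] = ("coca", "pepsi"),
                  durations: Sequence[float] = DEFAULT_DURATIONS,
                  initial_rest_s: float = 120.0,
                  repeats_per_section: int = 2) -> SessionSpec:
    """The study session: one section per brand, each opening with a 120 s rest
    followed by the 15/30/60 s duration sequence repeated twice (12 trials,
    1,104 s in total with default phase lengths)."""
    sections = []
    for brand in brands:
        trials = tuple(
            TrialSpec(StimulusVideo(brand=brand, duration_s=d))
            for _ in range(repeats_per_section)
            for d in durations
        )
        sections.append(Section(initial_rest_s, trials))
    return SessionSpec(tuple(sections))


def table3_m_samples(duration_s: float) -> int:
    """Printed input length for a video duration (208/416/832 samples)."""
    try:
        return TABLE3_M_SAMPLES[float(duration_s)]
    except KeyError:
        raise InvalidSpecError(
            f"no printed input length for a {duration_s} s video; "
            f"known durations: {sorted(TABLE3_M_SAMPLES)}") from None


def tertile_labels(ratings: Sequence[float]) -> list[str]:
    """Map continuous ratings to preference labels by tertile thresholding.

    Bottom third -> ``dislike``, middle -> ``so-so``, top -> ``like``.
    Provided as an optional helper; labels normally arrive with the trial
    metadata.
    """
    r = np.asarray(ratings, dtype=float)
    if r.size < 3:
        raise InvalidSpecError("need at least 3 ratings for tertile labels")
    lo, hi = np.quantile(r, [1 / 3, 2 / 3])
    return [PREFERENCES[0] if v <= lo else PREFERENCES[2] if v > hi else PREFERENCES[1]
            for v in r]
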