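"""Composite-outcome labelling within a time horizon.

Each observation is labelled positive when the admission's *first* clinical
event (cardiac arrest, unanticipated ICU admission, or death) falls inside
the half-open window ``(t_obs, t_obs + T]``.  Observations charted at or
after the first event are excluded from analysis.  Simultaneous events are
broken deterministically by type priority: death > cardiac arrest >
unanticipated ICU admission.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence

from .model import ObservationSet

EVENT_TYPES = ("cardiac_arrest", "unanticipated_icu", "death")
_TIE_PRIORITY = {"death": 0, "cardiac_arrest": 1, "unanticipated_icu": 2}


@dataclass(frozen=True)
class ClinicalEvent:
    admission_id: str
    event_type: str
    timestamp: datetime

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"event_type must be one of {EVENT_TYPES}, "
                             f"got {self.event_type!r}")


@dataclass(frozen=True)
class LabeledObservation:
    observation: ObservationSet
    label: bool
    horizon_hours: float
    aggregate_score: int | None = None


def first_event(events: Sequence[ClinicalEvent]) -> ClinicalEvent | None:
    """Earliest event for one admission; ties broken by fixed type priority."""
    events = list(events)
    if not events:
        return None
    if len({e.admission_id for e in events}) > 1:
        raise ValueError("events must share one admission_id")
    return min(events, key=lambda e: (e.timestamp, _TIE_PRIORITY[e.event_type]))


def first_events_by_admission(events: Iterable[ClinicalEvent]
                              ) -> dict[str, ClinicalEvent]:
    grouped: dict[str, list[ClinicalEvent]] = {}
    for event in events:
        grouped.setdefault(event.admission_id, []).append(event)
    return {adm: first_event(evts) for adm, evts in grouped.items()}


def label_observations(observations: Sequence[ObservationSet],
                       events: Sequence[ClinicalEvent],
                       horizon_hours: float,
                       scores: Sequence[int] | None = None,
                       event_types: Sequence[str] | None = None,
                       ) -> tuple[list[LabeledObservation], int]:
    """Label each observation against the admission's first event.

    Positive iff the first event lies in ``(t_obs, t_obs + T]`` (and, when
    ``event_types`` restricts to individual outcomes, is of a listed type).
    Observations at or after the first event are excluded; the exclusion
    count is returned alongside the labelled list so that
    ``len(labelled) + excluded == len(observations)``.
    """
    if horizon_hours <= 0:
        raise ValueError("horizon_hours must be positive")
    if scores is not None and len(scores) != len(observations):
        raise ValueError("scores must align with observations")
    firsts = first_events_by_admission(events)
    window = timedelta(hours=float(horizon_hours))
    wanted = set(event_types) if event_types is not None else None
    labelled: list[LabeledObservation] = []
    excluded = 0
    for i, obs in enumerate(observations):
        fe = firsts.get(obs.admission_id)
        if fe is not None and obs.timestamp >= fe.timestamp:
            excluded += 1
            continue
        positive = (fe is not None
                    and obs.timestamp < fe.timestamp <= obs.timestamp + window
                    and (wanted is None or fe.event_type in wanted))
        labelled.append(LabeledObservation(
            observation=obs, label=bool(positive), horizon_hours=horizon_hours,
            aggregate_score=None if scores is None else int(scores[i])))
    return labelled, excluded
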