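"""Longitudinal minimal-residual-disease monitoring.

Assembles dated hotspot results per patient, classifies each sample, and
flags molecular events.  Default classification is three-tier — a single
mutant molecule is only ``low_positive`` and must be confirmed by a
subsequent non-negative sample within a confirmation window before a
molecular relapse is flagged; an unconfirmed singleton becomes an
``indeterminate`` event.  ``strict_paper_positivity`` collapses this to the
binary rule (any >= 1 mutant molecule is positive), the published behaviour.

Months are reported as days / 30.44 rounded to one decimal, making lead-time
arithmetic deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Optional

from .calling import HotspotResult

DAYS_PER_MONTH = 30.44


class Status(str, enum.Enum):
    negative = "negative"
    low_positive = "low_positive"
    positive = "positive"
    non_evaluable = "non_evaluable"


class EventType(str, enum.Enum):
    molecular_relapse = "molecular_relapse"
    clearance = "clearance"
    indeterminate = "indeterminate"


@dataclass
class SampleStatus:
    sample_id: str
    date: Date
    status: Status
    mutant_count: int
    vaf: Optional[float]


@dataclass
class MonitoringEvent:
    type: EventType
    date: Date
    supporting_samples: list[str]


@dataclass
class PatientTimeSeries:
    patient_id: str
    tracked_hotspot_id: str
    samples: list[SampleStatus] = field(default_factory=list)
    events: list[MonitoringEvent] = field(default_factory=list)

    def add(self, status: SampleStatus) -> None:
        self.samples.append(status)
        self.samples.sort(key=lambda s: s.date)

    def check_dates(self) -> None:
        dates = [s.date for s in self.samples]
        for a, b in zip(dates, dates[1:]):
            if b <= a:
                raise ValueError(
                    f"patient {self.patient_id}: sample dates not strictly "
                    f"increasing ({a} then {b})")


def classify_sample(result: HotspotResult, date: Date,
                    strict_paper_positivity: bool = False) -> SampleStatus:
    """Three-tier status of one sample (binary under strict mode):

    0 mutant molecules -> negative, exactly 1 -> low_positive, >= 2 ->
    positive; undefined depth -> non_evaluable.  Strict mode maps any >= 1
    to positive.
    """
    if not result.evaluable or result.total_consensus_depth == 0:
        return SampleStatus(result.sample_id, date, Status.non_evaluable, 0, None)
    m = result.mutant_consensus_count
    if m == 0:
        status = Status.negative
    elif m == 1 and not strict_paper_positivity:
        status = Status.low_positive
    else:
        status = Status.positive
    return SampleStatus(result.sample_id, date, status, m, result.vaf)


def flag_events(series: PatientTimeSeries,
                confirm_window: int = 1) -> list[MonitoringEvent]:
    """Scan the status sequence and emit monitoring events.

    * ``molecular_relapse`` at the first sample of a run where either a
      ``positive`` (>= 2 molecules) occurs, or a ``low_positive`` is followed
      within ``confirm_window`` subsequent evaluable samples by any
      low_positive/positive.
    * An isolated ``low_positive`` whose next ``confirm_window`` evaluable
      samples are all negative becomes an ``indeterminate`` event (the
      repeat-sample caution for single-molecule findings).
    * ``clearance`` at the first of >= 2 consecutive negatives after any
      positive period.

    Non-evaluable samples are skipped entirely.  The function is pure in the
    date-sorted status sequence.
    """
    if not series.samples:
        raise ValueError("series has no samples")
    series.check_dates()
    evaluable = [s for s in series.samples if s.status != Status.non_evaluable]
    events: list[MonitoringEvent] = []
    in_positive_period = False
    i = 0
    n = len(evaluable)
    while i < n:
        s = evaluable[i]
        if s.status == Status.positive:
            if not in_positive_period:
                events.append(MonitoringEvent(
                    EventType.molecular_relapse, s.date, [s.sample_id]))
                in_positive_period = True
            i += 1
        elif s.status == Status.low_positive:
            if in_positive_period:
                i += 1
                continue
            window = evaluable[i + 1: i + 1 + confirm_window]
            confirm = next((w for w in window
                            if w.status in (Status.low_positive, Status.positive)),
                           None)
            if confirm is not None:
                events.append(MonitoringEvent(
                    EventType.molecular_relapse, s.date,
                    [s.sample_id, confirm.sample_id]))
                in_positive_period = True
            elif len(window) == confirm_window:
                events.append(MonitoringEvent(
                    EventType.indeterminate, s.date, [s.sample_id]))
            else:
                # series ends inside the window: unconfirmed either way
                events.append(MonitoringEvent(
                    EventType.indeterminate, s.date, [s.sample_id]))
            i += 1
        else:  # negative
            if in_positive_period and i + 1 < n \
                    and evaluable[i + 1].status == Status.negative:
                events.append(MonitoringEvent(
                    EventType.clearance, s.date,
                    [s.sample_id, evaluable[i + 1].sample_id]))
                in_positive_period = False
            i += 1
    return events


def lead_time(series: PatientTimeSeries,
              clinical_relapse_date: Date) -> float:
    """Months between the first molecular_relapse event and the clinical
    relapse date (days / 30.44, one decimal)."""
    relapse = next((e for e in series.events
                    if e.type == EventType.molecular_relapse), None)
    if relapse is None:
        raise ValueError(
            f"patient {series.patient_id}: no molecular_relapse event")
    if clinical_relapse_date < relapse.date:
        raise ValueError("clinical relapse date precedes molecular relapse")
    days = (clinical_relapse_date - relapse.date).days
    return round(days / DAYS_PER_MONTH, 1)


def build_time_series(patient_id: str, tracked_hotspot_id: str,
                      dated_results: list[tuple[Date, HotspotResult]],
                      strict_paper_positivity: bool = False,
                      confirm_window: int = 1) -> PatientTimeSeries:
    """Classify dated results and flag events in one step."""
    series = PatientTimeSeries(patient_id, tracked_hotspot_id)
    for date, result in sorted(dated_results, key=lambda dr: dr[0]):
        series.add(classify_sample(result, date, strict_paper_positivity))
    series.events = flag_events(series, confirm_window)
    return series
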