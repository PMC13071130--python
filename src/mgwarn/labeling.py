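"""Deterioration events, daily classification targets and baseline periods.

A deterioration is a dated clinical worsening of one of three subtypes:

* ``qmg`` — a >= 3-point increase of the non-ocular QMG total between two
  consecutive examinations, dated at the later one;
* ``hospitalization`` — an MG-related hospital admission;
* ``self_report`` — an adjudicated self-reported exacerbation (dates are
  consumed as input; their reconstruction is upstream of this package).

The daily classification target is 1 on the ``window_days`` days strictly
before each onset (default 7, accommodating onset-timing uncertainty) and
0 everywhere else, including the onset day itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import QMGRecord, StudyFrame

#: Default pre-onset positive window, in days.
DEFAULT_WINDOW_DAYS = 7
#: "One month" of study used to cap the baseline period, in days.
DEFAULT_BASELINE_DAYS = 30

_SUBTYPE_PRIORITY = {"hospitalization": 0, "qmg": 1, "self_report": 2}


@dataclass(frozen=True)
class DeteriorationEvent:
    subject_id: str
    onset_day: int
    subtype: str

    def __post_init__(self) -> None:
        if self.subtype not in _SUBTYPE_PRIORITY:
            raise ValueError(f"unknown event subtype {self.subtype!r}")


def qmg_nonocular_total(record: QMGRecord) -> int:
    """Sum of QMG item scores over non-ocular items."""
    if record.ocular_mask.shape != record.item_scores.shape:
        raise ValueError("ocular mask length does not match item count")
    return int(record.item_scores[~record.ocular_mask].sum())


def detect_qmg_events(
    records: Sequence[QMGRecord], roster_day_index=None
) -> list[DeteriorationEvent]:
    """Detect QMG-defined deteriorations for one subject.

    Each consecutive pair of date-sorted examinations with a non-ocular
    total increase >= 3 emits one event dated at the later examination.
    ``roster_day_index`` maps a date to a 0-based study day; when omitted,
    dates are interpreted relative to the first record's date.
    """
    recs = sorted(records, key=lambda r: r.date)
    if not recs:
        return []
    if roster_day_index is None:
        origin = recs[0].date

        def roster_day_index(d):
            return int((np.datetime64(d, "D") - origin) / np.timedelta64(1, "D"))

    events = []
    totals = [qmg_nonocular_total(r) for r in recs]
    for prev, cur, t0, t1 in zip(recs, recs[1:], totals, totals[1:]):
        if t1 - t0 >= 3:
            events.append(
                DeteriorationEvent(
                    subject_id=cur.subject_id,
                    onset_day=roster_day_index(cur.date),
                    subtype="qmg",
                )
            )
    return events


def assemble_events(
    qmg_events: Iterable[DeteriorationEvent],
    external_events: Iterable[DeteriorationEvent],
) -> list[DeteriorationEvent]:
    """Merge QMG-derived and externally adjudicated events.

    Same-subject same-day duplicates collapse to a single event with
    subtype priority hospitalization > qmg > self_report (hospitalization
    dates being the most objectively anchored).
    """
    best: dict[tuple[str, int], DeteriorationEvent] = {}
    for ev in list(qmg_events) + list(external_events):
        key = (ev.subject_id, ev.onset_day)
        cur = best.get(key)
        if cur is None or _SUBTYPE_PRIORITY[ev.subtype] < _SUBTYPE_PRIORITY[cur.subtype]:
            best[key] = ev
    return sorted(best.values(), key=lambda e: (e.subject_id, e.onset_day))


def events_from_study(study: StudyFrame) -> list[DeteriorationEvent]:
    """Derive the full event list of a StudyFrame: QMG rule applied to the
    QMG records plus the external (hospitalization/self-report) table."""
    qmg_events: list[DeteriorationEvent] = []
    for sid, recs in study.qmg.items():
        qmg_events.extend(detect_qmg_events(recs, study.roster[sid].day_index))
    external = [
        DeteriorationEvent(
            subject_id=str(r["subject_id"]),
            onset_day=study.roster[str(r["subject_id"])].day_index(r["date"]),
            subtype=str(r["subtype"]),
        )
        for _, r in study.events.iterrows()
    ]
    return assemble_events(qmg_events, external)


def label_days(
    events: Iterable[DeteriorationEvent],
    study_length: int,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> np.ndarray:
    """Daily binary target for one subject.

    Day ``d`` is 1 iff some event has onset ``o`` with
    ``o - window_days <= d <= o - 1``; overlapping windows union. The
    onset day itself and all later days are 0.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    labels = np.zeros(study_length, dtype=np.int8)
    for ev in events:
        lo = max(ev.onset_day - window_days, 0)
        hi = min(ev.onset_day, study_length)  # exclusive
        if lo < hi:
            labels[lo:hi] = 1
    return labels


def build_labels(
    events: Iterable[DeteriorationEvent],
    study_days: dict[str, int],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> dict[str, np.ndarray]:
    """Per-subject label arrays for every rostered subject."""
    per_subject: dict[str, list[DeteriorationEvent]] = {s: [] for s in study_days}
    for ev in events:
        per_subject[ev.subject_id].append(ev)
    return {
        sid: label_days(evs, study_days[sid], window_days)
        for sid, evs in per_subject.items()
    }


def baseline_period(
    events: Iterable[DeteriorationEvent],
    window_days: int = DEFAULT_WINDOW_DAYS,
    baseline_days: int = DEFAULT_BASELINE_DAYS,
) -> tuple[int, int]:
    """Baseline interval (inclusive day indices) for one subject.

    The baseline runs from study start to one pre-onset window before the
    first deterioration, or ``baseline_days`` into the study, whichever
    ends earlier: ``[0, min(first_onset - window_days, baseline_days) - 1]``.
    With no events it is ``[0, baseline_days - 1]``. A first onset within
    the first ``window_days`` days leaves no clean baseline; the interval
    degrades to ``[0, max(first_onset - 1, 0)]`` with a warning.
    """
    onsets = [ev.onset_day for ev in events]
    if not onsets:
        return (0, baseline_days - 1)
    first = min(onsets)
    end_exclusive = min(first - window_days, baseline_days)
    if end_exclusive < 1:
        warnings.warn(
            f"first deterioration on day {first} leaves no clean baseline; "
            f"falling back to days [0, {max(first - 1, 0)}]",
            stacklevel=2,
        )
        return (0, max(first - 1, 0))
    return (0, end_exclusive - 1)
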