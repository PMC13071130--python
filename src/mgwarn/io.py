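"""Reading, writing and validation of the study's file formats.

On-disk dialect (all UTF-8, all timestamps ISO-8601):

* ``signals.csv``  — long format ``subject_id,signal,timestamp,value``;
* ``events.csv``   — ``subject_id,date,subtype`` with subtype in
  ``{hospitalization, self_report}`` (QMG-defined events are derived from
  QMG records, not listed here);
* ``qmg.csv``      — ``subject_id,date,item01..item13`` per-item scores;
* ``roster.json``  — per-subject study interval plus wheelchair and
  step-exclusion intervals.

In memory everything is indexed on 0-based day offsets from each
subject's study start; timestamps only exist at this boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import (
    ALL_SIGNALS,
    CADENCES,
    DEFAULT_OCULAR_ITEMS,
    QMG_N_ITEMS,
    VALUE_RANGES,
)

EVENT_SUBTYPES = ("qmg", "hospitalization", "self_report")
EXTERNAL_SUBTYPES = ("hospitalization", "self_report")


class ValidationError(ValueError):
    """Raised when an input file violates a structural or range invariant."""


@dataclass
class RawSignalSeries:
    """Timestamped observations of one signal for one subject.

    ``timestamps`` are ``datetime64[s]``, strictly increasing; ``values``
    are float64 and finite. ``exclusion_flags`` carry (start, end, reason)
    closed timestamp intervals marked for removal (e.g. wheelchair use).
    """

    subject_id: str
    signal_name: str
    cadence: str
    timestamps: np.ndarray
    values: np.ndarray
    exclusion_flags: list[tuple[np.datetime64, np.datetime64, str]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.values = np.asarray(self.values, dtype=float)
        if self.cadence not in CADENCES:
            raise ValidationError(
                f"{self.subject_id}/{self.signal_name}: unknown cadence "
                f"{self.cadence!r}"
            )
        if self.timestamps.shape != self.values.shape:
            raise ValidationError(
                f"{self.subject_id}/{self.signal_name}: timestamp/value "
                "length mismatch"
            )

    def __len__(self) -> int:
        return len(self.values)

    def validate(self) -> None:
        sid, sig = self.subject_id, self.signal_name
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError(f"{sid}/{sig}: timestamps not strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{sid}/{sig}: non-finite value")
        if sig in VALUE_RANGES:
            lo, hi = VALUE_RANGES[sig]
            bad = (self.values < lo) | (self.values > hi)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{sid}/{sig}: value {self.values[i]} at "
                    f"{self.timestamps[i]} outside [{lo}, {hi}]"
                )


@dataclass
class QMGRecord:
    """One QMG examination: per-item 0-3 scores plus the ocular-item mask."""

    subject_id: str
    date: np.datetime64
    item_scores: np.ndarray
    ocular_mask: np.ndarray

    def __post_init__(self) -> None:
        self.date = np.datetime64(self.date, "D")
        self.item_scores = np.asarray(self.item_scores, dtype=int)
        self.ocular_mask = np.asarray(self.ocular_mask, dtype=bool)
        if self.ocular_mask.shape != self.item_scores.shape:
            raise ValidationError(
                f"{self.subject_id}: QMG mask length {len(self.ocular_mask)} "
                f"!= item count {len(self.item_scores)}"
            )
        if ((self.item_scores < 0) | (self.item_scores > 3)).any():
            raise ValidationError(
                f"{self.subject_id}: QMG item score outside [0, 3] on {self.date}"
            )


@dataclass
class SubjectRoster:
    subject_id: str
    study_start: np.datetime64
    study_end: np.datetime64
    wheelchair_intervals: list[tuple[np.datetime64, np.datetime64]] = field(
        default_factory=list
    )
    step_exclusion_intervals: list[tuple[np.datetime64, np.datetime64]] = field(
        default_factory=list
    )

    @property
    def study_days(self) -> int:
        return int((self.study_end - self.study_start) / np.timedelta64(1, "D")) + 1

    def day_index(self, when) -> int:
        return int(
            (np.datetime64(when, "D") - np.datetime64(self.study_start, "D"))
            / np.timedelta64(1, "D")
        )


@dataclass
class StudyFrame:
    """Validated in-memory study: all raw series, QMG records and events."""

    roster: dict[str, SubjectRoster]
    series: dict[str, dict[str, RawSignalSeries]]
    qmg: dict[str, list[QMGRecord]]
    events: pd.DataFrame  # columns subject_id, date, subtype

    @property
    def subjects(self) -> list[str]:
        return sorted(self.roster)

    def study_days(self, subject_id: str) -> int:
        return self.roster[subject_id].study_days


# ---------------------------------------------------------------------------
# readers


def _infer_cadence(timestamps: np.ndarray) -> str:
    """Infer acquisition cadence from timestamp spacing."""
    if len(timestamps) < 2:
        return "daily"
    days = timestamps.astype("datetime64[D]")
    if len(np.unique(days)) < len(days):
        return "per_minute"
    spacing = np.median(np.diff(days).astype(int))
    return "weekly" if spacing >= 6 else "daily"


def read_signals(path: str | Path) -> list[RawSignalSeries]:
    """Parse a long-format signals CSV into validated, sorted series.

    Rows violating range invariants are rejected with their (1-based,
    header-inclusive) row number. Duplicate timestamps within a
    subject/signal keep the last row, with a warning.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "signal": str})
    expected = ["subject_id", "signal", "timestamp", "value"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: expected header {expected}, got {list(df.columns)}")
    if df.empty:
        return []
    df["row"] = np.arange(2, len(df) + 2)  # data starts on file row 2
    unknown = ~df["signal"].isin(ALL_SIGNALS)
    if unknown.any():
        r = df.loc[unknown].iloc[0]
        raise ValidationError(
            f"{path} row {r['row']}: unknown signal {r['signal']!r}"
        )
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable timestamp ({exc})") from None
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    bad = ~np.isfinite(df["value"])
    for sig, (lo, hi) in VALUE_RANGES.items():
        m = df["signal"] == sig
        bad |= m & ((df["value"] < lo) | (df["value"] > hi))
    if bad.any():
        r = df.loc[bad].iloc[0]
        raise ValidationError(
            f"{path} row {r['row']}: subject {r['subject_id']} signal "
            f"{r['signal']} value {r['value']} out of range or non-finite"
        )
    out: list[RawSignalSeries] = []
    for (sid, sig), grp in df.groupby(["subject_id", "signal"], sort=True):
        grp = grp.sort_values(["timestamp", "row"])
        dup = grp["timestamp"].duplicated(keep="last")
        if dup.any():
            warnings.warn(
                f"{sid}/{sig}: {int(dup.sum())} duplicate timestamp(s), keeping last",
                stacklevel=2,
            )
            grp = grp[~dup]
        ts = grp["timestamp"].to_numpy().astype("datetime64[s]")
        series = RawSignalSeries(
            subject_id=str(sid),
            signal_name=str(sig),
            cadence=_infer_cadence(ts),
            timestamps=ts,
            values=grp["value"].to_numpy(),
        )
        series.validate()
        out.append(series)
    return out


def read_events(path: str | Path, roster: dict[str, SubjectRoster] | None = None) -> pd.DataFrame:
    """Read the adjudicated external event table (hospitalizations,
    self-reported exacerbations)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "subtype": str})
    expected = ["subject_id", "date", "subtype"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: expected header {expected}, got {list(df.columns)}")
    if df.empty:
        return pd.DataFrame(columns=expected)
    bad = ~df["subtype"].isin(EXTERNAL_SUBTYPES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path} row {i + 2}: unknown subtype {df['subtype'].iloc[i]!r}"
        )
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.floor("D")
    if roster is not None:
        for _, r in df.iterrows():
            sid = r["subject_id"]
            if sid not in roster:
                raise ValidationError(f"{path}: event for unknown subject {sid!r}")
            ros = roster[sid]
            d = np.datetime64(r["date"], "D")
            if d < ros.study_start or d > ros.study_end:
                raise ValidationError(
                    f"{path}: subject {sid} event on {d} outside study interval "
                    f"[{ros.study_start}, {ros.study_end}]"
                )
    return df.reset_index(drop=True)


def read_qmg(
    path: str | Path, ocular_items: tuple[int, ...] = DEFAULT_OCULAR_ITEMS
) -> dict[str, list[QMGRecord]]:
    """Read per-item QMG examinations; ``ocular_items`` selects the
    0-based item indices masked from the deterioration rule."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    item_cols = [c for c in df.columns if c.startswith("item")]
    if not item_cols:
        raise ValidationError(f"{path}: no item columns found")
    mask = np.zeros(len(item_cols), dtype=bool)
    for i in ocular_items:
        if i >= len(item_cols):
            raise ValidationError(
                f"ocular item index {i} out of range for {len(item_cols)} items"
            )
        mask[i] = True
    out: dict[str, list[QMGRecord]] = {}
    for _, r in df.iterrows():
        rec = QMGRecord(
            subject_id=str(r["subject_id"]),
            date=np.datetime64(pd.Timestamp(r["date"]).date()),
            item_scores=r[item_cols].to_numpy(dtype=int),
            ocular_mask=mask,
        )
        out.setdefault(rec.subject_id, []).append(rec)
    for recs in out.values():
        recs.sort(key=lambda rec: rec.date)
    return out


def read_roster(path: str | Path) -> dict[str, SubjectRoster]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    entries = payload["subjects"] if isinstance(payload, dict) else payload

    def _iv(pairs):
        return [
            (np.datetime64(a, "D"), np.datetime64(b, "D")) for a, b in (pairs or [])
        ]

    roster: dict[str, SubjectRoster] = {}
    for e in entries:
        sid = str(e["subject_id"])
        roster[sid] = SubjectRoster(
            subject_id=sid,
            study_start=np.datetime64(e["study_start"], "D"),
            study_end=np.datetime64(e["study_end"], "D"),
            wheelchair_intervals=_iv(e.get("wheelchair_intervals")),
            step_exclusion_intervals=_iv(e.get("step_exclusion_intervals")),
        )
    return roster


def assemble_study(
    signals: list[RawSignalSeries],
    qmg: dict[str, list[QMGRecord]],
    events: pd.DataFrame,
    roster: dict[str, SubjectRoster],
) -> StudyFrame:
    """Assemble validated inputs into one StudyFrame.

    Subjects in the roster without some signal are retained with that
    signal absent; a signal for a subject missing from the roster is an
    error.
    """
    series: dict[str, dict[str, RawSignalSeries]] = {sid: {} for sid in roster}
    for s in signals:
        if s.subject_id not in roster:
            raise ValidationError(
                f"signal {s.signal_name} references subject {s.subject_id!r} "
                "missing from roster"
            )
        series[s.subject_id][s.signal_name] = s
    for sid in qmg:
        if sid not in roster:
            raise ValidationError(f"QMG records reference unknown subject {sid!r}")
    if len(events):
        for _, r in events.iterrows():
            sid = r["subject_id"]
            if sid not in roster:
                raise ValidationError(f"event references unknown subject {sid!r}")
            ros = roster[sid]
            d = np.datetime64(pd.Timestamp(r["date"]).date())
            if d < ros.study_start or d > ros.study_end:
                raise ValidationError(
                    f"subject {sid}: event on {d} outside study interval"
                )
    return StudyFrame(roster=roster, series=series, qmg=qmg, events=events)


def load_study(directory: str | Path) -> StudyFrame:
    """Load ``signals.csv``, ``events.csv``, ``qmg.csv`` (optional) and
    ``roster.json`` from one directory."""
    directory = Path(directory)
    roster = read_roster(directory / "roster.json")
    signals = read_signals(directory / "signals.csv")
    events_path = directory / "events.csv"
    if events_path.exists():
        events = read_events(events_path, roster)
    else:
        events = pd.DataFrame(columns=["subject_id", "date", "subtype"])
    qmg_path = directory / "qmg.csv"
    qmg = read_qmg(qmg_path) if qmg_path.exists() else {}
    return assemble_study(signals, qmg, events, roster)


# ---------------------------------------------------------------------------
# writers


def _fmt_ts(timestamps: np.ndarray, cadence: str) -> np.ndarray:
    if cadence == "per_minute":
        return np.datetime_as_string(timestamps.astype("datetime64[s]"), unit="s")
    return np.datetime_as_string(timestamps.astype("datetime64[D]"), unit="D")


def write_signals(series: list[RawSignalSeries], path: str | Path) -> None:
    frames = []
    for s in sorted(series, key=lambda s: (s.subject_id, s.signal_name)):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "signal": s.signal_name,
                    "timestamp": _fmt_ts(s.timestamps, s.cadence),
                    "value": np.round(s.values, 9),
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["subject_id", "signal", "timestamp", "value"])
    )
    df.to_csv(path, index=False)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    df = events.copy()
    if len(df):
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, columns=["subject_id", "date", "subtype"])


def write_qmg(qmg: dict[str, list[QMGRecord]], path: str | Path) -> None:
    rows = []
    for sid in sorted(qmg):
        for rec in qmg[sid]:
            row: dict[str, object] = {"subject_id": sid, "date": str(rec.date)}
            for i, v in enumerate(rec.item_scores, start=1):
                row[f"item{i:02d}"] = int(v)
            rows.append(row)
    cols = ["subject_id", "date"] + [f"item{i:02d}" for i in range(1, QMG_N_ITEMS + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_roster(roster: dict[str, SubjectRoster], path: str | Path) -> None:
    payload = {
        "subjects": [
            {
                "subject_id": r.subject_id,
                "study_start": str(r.study_start),
                "study_end": str(r.study_end),
                "wheelchair_intervals": [[str(a), str(b)] for a, b in r.wheelchair_intervals],
                "step_exclusion_intervals": [
                    [str(a), str(b)] for a, b in r.step_exclusion_intervals
                ],
            }
            for r in sorted(roster.values(), key=lambda r: r.subject_id)
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
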