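"""Raw series -> clean daily panel.

Pipeline per subject: artifact filters on per-minute wearables (SpO2
pulse-gating and plateau removal; step-count exclusion intervals), daily
aggregation (mean for vitals, sum for steps), weekly-to-daily linear
interpolation for PPMs/PROMs, interior gap interpolation, and per-subject
z-standardization. Leading/trailing missing days are never extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RawSignalSeries, StudyFrame
from .signals import ALL_SIGNALS, DAILY_AGGREGATION

OBSERVED, INTERPOLATED, MISSING = "observed", "interpolated", "missing"

#: Minimum run length (minutes) of identical SpO2 values treated as a
#: sensor plateau artifact; ">= 1 h" at 1/min resolution.
PLATEAU_MINUTES = 60


@dataclass
class DailyPanel:
    """Day-indexed signal matrix for one subject.

    ``values`` is a float DataFrame indexed 0..D-1 with one column per
    signal (NaN = missing); ``provenance`` is a same-shaped string frame
    with entries observed/interpolated/missing.
    """

    subject_id: str
    values: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def n_days(self) -> int:
        return len(self.values)

    def signal(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()


@dataclass
class DailySeries:
    """Intermediate per-signal daily vector with provenance."""

    values: np.ndarray  # float, NaN = missing
    provenance: np.ndarray  # str array


def _minute_keys(series: RawSignalSeries) -> np.ndarray:
    return series.timestamps.astype("datetime64[m]")


def filter_spo2(spo2: RawSignalSeries, pulse: RawSignalSeries | None) -> RawSignalSeries:
    """Pulse-gate and plateau-filter per-minute SpO2.

    Keeps only SpO2 minutes with a pulse sample in the same minute (pulse
    is the more stable channel; SpO2 without it is suspect), then removes
    every minute belonging to a maximal run of >= 60 consecutive identical
    SpO2 values (a sensor stuck-value artifact). Gaps in the minute grid
    break a run.
    """
    if spo2.cadence != "per_minute":
        raise ValueError("filter_spo2 requires a per-minute SpO2 series")
    ts, vals = spo2.timestamps, spo2.values
    if pulse is not None:
        if pulse.cadence != "per_minute":
            raise ValueError("filter_spo2 requires a per-minute pulse series")
        keep = np.isin(_minute_keys(spo2), _minute_keys(pulse))
        ts, vals = ts[keep], vals[keep]
    if len(vals):
        contiguous = np.diff(ts.astype("datetime64[m]")).astype(int) == 1
        same = (vals[1:] == vals[:-1]) & contiguous
        run_id = np.concatenate([[0], np.cumsum(~same)])
        _, inverse, counts = np.unique(run_id, return_inverse=True, return_counts=True)
        keep = counts[inverse] < PLATEAU_MINUTES
        ts, vals = ts[keep], vals[keep]
    return RawSignalSeries(
        subject_id=spo2.subject_id,
        signal_name=spo2.signal_name,
        cadence="per_minute",
        timestamps=ts,
        values=vals,
        exclusion_flags=list(spo2.exclusion_flags),
    )


def filter_steps(
    steps: RawSignalSeries,
    exclusion_intervals: list[tuple[np.datetime64, np.datetime64]],
) -> RawSignalSeries:
    """Drop step samples inside any exclusion interval (wheelchair use,
    device double-counting). Intervals are closed; overlaps are unioned
    (a sample is removed once, by membership)."""
    if not exclusion_intervals:
        return steps
    ts = steps.timestamps
    remove = np.zeros(len(ts), dtype=bool)
    for a, b in exclusion_intervals:
        a = np.datetime64(a).astype("datetime64[s]")
        # closed end: a date interval end covers that entire day
        b64 = np.datetime64(b)
        if b64.dtype == np.dtype("datetime64[D]"):
            b_s = (b64 + np.timedelta64(1, "D")).astype("datetime64[s]") - np.timedelta64(1, "s")
        else:
            b_s = b64.astype("datetime64[s]")
        remove |= (ts >= a) & (ts <= b_s)
    return RawSignalSeries(
        subject_id=steps.subject_id,
        signal_name=steps.signal_name,
        cadence=steps.cadence,
        timestamps=ts[~remove],
        values=steps.values[~remove],
        exclusion_flags=list(steps.exclusion_flags),
    )


def minute_to_daily(
    series: RawSignalSeries, study_start: np.datetime64, n_days: int, how: str | None = None
) -> DailySeries:
    """Aggregate a per-minute series to one value per study day.

    Vitals average over the day's valid minutes; step counts sum. Days
    with zero valid minutes are missing.
    """
    if series.cadence != "per_minute":
        raise ValueError("minute_to_daily requires a per-minute series")
    how = how or DAILY_AGGREGATION.get(series.signal_name, "mean")
    day = (
        (series.timestamps.astype("datetime64[D]") - np.datetime64(study_start, "D"))
        / np.timedelta64(1, "D")
    ).astype(int)
    keep = (day >= 0) & (day < n_days)
    day, vals = day[keep], series.values[keep]
    out = np.full(n_days, np.nan)
    if len(day):
        sums = np.bincount(day, weights=vals, minlength=n_days)
        counts = np.bincount(day, minlength=n_days)
        present = counts > 0
        if how == "sum":
            out[present] = sums[present]
        else:
            out[present] = sums[present] / counts[present]
    prov = np.where(np.isnan(out), MISSING, OBSERVED)
    return DailySeries(values=out, provenance=prov)


def weekly_to_daily(
    series: RawSignalSeries, study_start: np.datetime64, n_days: int
) -> DailySeries:
    """Place weekly/daily assessments on the day grid and linearly
    interpolate strictly interior gaps.

    Multiple same-day assessments average. Days before the first or after
    the last observation stay missing (no extrapolation).
    """
    if series.cadence == "per_minute":
        raise ValueError("weekly_to_daily requires a daily or weekly series")
    day = (
        (series.timestamps.astype("datetime64[D]") - np.datetime64(study_start, "D"))
        / np.timedelta64(1, "D")
    ).astype(int)
    keep = (day >= 0) & (day < n_days)
    day, vals = day[keep], series.values[keep]
    out = np.full(n_days, np.nan)
    if len(day):
        sums = np.bincount(day, weights=vals, minlength=n_days)
        counts = np.bincount(day, minlength=n_days)
        present = counts > 0
        out[present] = sums[present] / counts[present]
    observed = ~np.isnan(out)
    interpolated = pd.Series(out).interpolate(method="linear", limit_area="inside").to_numpy()
    prov = np.full(n_days, MISSING, dtype=object)
    prov[~np.isnan(interpolated)] = INTERPOLATED
    prov[observed] = OBSERVED
    return DailySeries(values=interpolated, provenance=prov.astype(str))


def interpolate_gaps(daily: DailySeries) -> DailySeries:
    """Linearly fill interior missing days of an already-daily series."""
    observed_like = daily.provenance != MISSING
    filled = pd.Series(daily.values).interpolate(method="linear", limit_area="inside").to_numpy()
    prov = daily.provenance.astype(object).copy()
    newly = (~observed_like) & ~np.isnan(filled)
    prov[newly] = INTERPOLATED
    return DailySeries(values=filled, provenance=prov.astype(str))


def z_transform(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardize by the subject's own mean/SD over non-missing days.

    Population (``ddof=0``) denominator by default; downstream Pearson
    similarities are invariant to the choice, but it must be fixed. A
    zero-SD (constant) series maps to all zeros with a warning.
    """
    out = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(out)
    if obs.sum() == 0:
        return out
    mu = out[obs].mean()
    sd = out[obs].std(ddof=ddof) if obs.sum() > ddof else 0.0
    if sd == 0:
        warnings.warn("degenerate subject-signal: zero variance, z-scores set to 0", stacklevel=2)
        out[obs] = 0.0
        return out
    out[obs] = (out[obs] - mu) / sd
    return out


def build_daily_panel(
    study: StudyFrame,
    signals: tuple[str, ...] = ALL_SIGNALS,
    standardize: bool = True,
) -> dict[str, DailyPanel]:
    """Full preprocessing of a StudyFrame into per-subject daily panels."""
    panels: dict[str, DailyPanel] = {}
    for sid in study.subjects:
        ros = study.roster[sid]
        n_days = ros.study_days
        subj = study.series.get(sid, {})
        cols: dict[str, np.ndarray] = {}
        provs: dict[str, np.ndarray] = {}
        for sig in signals:
            series = subj.get(sig)
            try:
                daily = _clean_one(series, sig, subj, ros, n_days)
            except ValueError as exc:
                raise ValueError(f"subject {sid}, signal {sig}: {exc}") from exc
            daily = interpolate_gaps(daily)
            vals = daily.values
            if standardize:
                vals = z_transform(vals)
            cols[sig] = vals
            provs[sig] = daily.provenance
        idx = pd.RangeIndex(n_days, name="day")
        panels[sid] = DailyPanel(
            subject_id=sid,
            values=pd.DataFrame(cols, index=idx),
            provenance=pd.DataFrame(provs, index=idx),
        )
    return panels


def _clean_one(series, sig, subj, ros, n_days) -> DailySeries:
    if series is None:
        empty = np.full(n_days, np.nan)
        return DailySeries(
            values=empty, provenance=np.full(n_days, MISSING, dtype=object).astype(str)
        )
    if series.cadence == "per_minute":
        if sig == "spo2":
            series = filter_spo2(series, subj.get("pulse"))
        elif sig == "steps":
            series = filter_steps(
                series, ros.wheelchair_intervals + ros.step_exclusion_intervals
            )
        return minute_to_daily(series, ros.study_start, n_days)
    if sig == "steps":
        series = filter_steps(
            series, ros.wheelchair_intervals + ros.step_exclusion_intervals
        )
    return weekly_to_daily(series, ros.study_start, n_days)


def export_panels(panels: dict[str, DailyPanel], values_path, provenance_path=None) -> None:
    """Write panels as wide CSV (one row per subject-day), optionally with
    a provenance sidecar of the same shape."""
    rows = []
    provs = []
    for sid in sorted(panels):
        p = panels[sid]
        v = p.values.copy()
        v.insert(0, "day", p.values.index)
        v.insert(0, "subject_id", sid)
        rows.append(v)
        q = p.provenance.copy()
        q.insert(0, "day", p.provenance.index)
        q.insert(0, "subject_id", sid)
        provs.append(q)
    pd.concat(rows, ignore_index=True).to_csv(values_path, index=False)
    if provenance_path is not None:
        pd.concat(provs, ignore_index=True).to_csv(provenance_path, index=False)
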