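"""Pre-deterioration templates and sliding-correlation similarity series.

For each signal, a template is the baseline-subtracted signal averaged
over the T days immediately preceding each training deterioration onset
(all subtypes pooled, averaged across events position-wise). Sliding the
template causally over a subject's daily signal yields, for every day t,
the Pearson correlation R between the trailing T-day segment
(days t-T+1 ... t) and the template, mapped to a similarity in [0, 1] by
(R + 1) / 2. The similarity is invariant to positive affine transforms of
the subject's signal, which is what makes the per-subject z-transform
optional for prospectively new subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .labeling import (
    DEFAULT_BASELINE_DAYS,
    DEFAULT_WINDOW_DAYS,
    DeteriorationEvent,
    baseline_period,
)
from .preprocess import DailyPanel

NEUTRAL_SIMILARITY = 0.5


class TemplateError(ValueError):
    """No usable training events (or an ill-posed template) for a signal."""


@dataclass
class Template:
    """Average baseline-subtracted pre-onset trajectory of one signal.

    ``values[k]`` is the averaged deviation on day ``onset - T + k``
    (k = 0 ... T-1), i.e. the last entry is the day before onset.
    """

    signal_name: str
    lookback: int
    values: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.lookback:
            raise ValueError("template length does not equal the look-back T")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("template contains non-finite values")


@dataclass
class SimilaritySeries:
    """Daily similarity of one subject's signal to a template.

    ``valid`` is False on days lacking a complete T-day trailing segment
    (including the first T-1 days and days whose segment contains missing
    values) and on degenerate zero-variance segments; those days carry
    the neutral value 0.5 so downstream inputs stay rectangular.
    """

    subject_id: str
    signal_name: str
    values: np.ndarray
    valid: np.ndarray


def subject_baseline(panel: DailyPanel, signal: str, interval: tuple[int, int]) -> float:
    """Mean of a signal over the non-missing days of the baseline interval
    (inclusive day indices). NaN if the interval holds no data."""
    lo, hi = interval
    window = panel.signal(signal)[lo : hi + 1]
    if np.all(np.isnan(window)):
        return float("nan")
    return float(np.nanmean(window))


def build_template(
    panels: dict[str, DailyPanel],
    events: Iterable[DeteriorationEvent],
    signal: str,
    T: int,
    window_days: int = DEFAULT_WINDOW_DAYS,
    baseline_days: int = DEFAULT_BASELINE_DAYS,
) -> Template:
    """Average the baseline-subtracted pre-onset windows of the training
    events into a template.

    Only events whose day range ``onset-T ... onset-1`` lies inside the
    study contribute; missing positions within a contributing window are
    ignored position-wise. Cross-validation discipline (training events
    only) is the caller's responsibility.
    """
    if T < 2:
        raise ValueError("look-back T must be >= 2")
    events = list(events)
    by_subject: dict[str, list[DeteriorationEvent]] = {}
    for ev in events:
        by_subject.setdefault(ev.subject_id, []).append(ev)
    baselines: dict[str, float] = {}
    for sid, evs in by_subject.items():
        if sid not in panels:
            raise KeyError(f"event subject {sid!r} has no panel")
        interval = baseline_period(evs, window_days=window_days, baseline_days=baseline_days)
        bl = subject_baseline(panels[sid], signal, interval)
        if np.isnan(bl):
            warnings.warn(
                f"subject {sid}, signal {signal}: all-missing baseline interval; "
                "excluded from template building",
                stacklevel=2,
            )
        baselines[sid] = bl
    windows = []
    for ev in events:
        if ev.onset_day - T < 0 or ev.onset_day > panels[ev.subject_id].n_days:
            continue
        bl = baselines[ev.subject_id]
        if np.isnan(bl):
            continue
        seg = panels[ev.subject_id].signal(signal)[ev.onset_day - T : ev.onset_day]
        windows.append(seg - bl)
    if not windows:
        raise TemplateError(f"signal {signal}: no usable training events for T={T}")
    stack = np.vstack(windows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN positions
        values = np.nanmean(stack, axis=0)
    values = np.where(np.isnan(values), 0.0, values)
    return Template(signal_name=signal, lookback=T, values=values, n_events=len(windows))


def similarity_series(panel: DailyPanel, signal: str, template: Template) -> SimilaritySeries:
    """Causal sliding-Pearson similarity of a subject's daily signal to a
    template: similarity(t) = (R + 1)/2 over days t-T+1 ... t."""
    tmpl = template.values
    T = template.lookback
    tc = tmpl - tmpl.mean()
    t_norm = float(np.sqrt((tc**2).sum()))
    if t_norm == 0.0:
        raise TemplateError(
            f"signal {signal}: zero-variance template is ill-posed for correlation"
        )
    x = panel.signal(signal)
    n = len(x)
    sims = np.full(n, NEUTRAL_SIMILARITY)
    valid = np.zeros(n, dtype=bool)
    if n >= T:
        win = sliding_window_view(x, T)  # row i ends on day i + T - 1
        complete = ~np.isnan(win).any(axis=1)
        if complete.any():
            w = win[complete]
            wc = w - w.mean(axis=1, keepdims=True)
            seg_norm = np.sqrt((wc**2).sum(axis=1))
            denom = seg_norm * t_norm
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (wc @ tc) / np.where(denom > 0, denom, 1.0), 0.0)
            r = np.clip(r, -1.0, 1.0)
            days = np.flatnonzero(complete) + T - 1
            sims[days] = (r + 1.0) / 2.0
            valid[days] = seg_norm > 0
    return SimilaritySeries(
        subject_id=panel.subject_id, signal_name=signal, values=sims, valid=valid
    )


def build_templates(
    panels: dict[str, DailyPanel],
    events: Iterable[DeteriorationEvent],
    signals: Iterable[str],
    T: int,
    window_days: int = DEFAULT_WINDOW_DAYS,
    baseline_days: int = DEFAULT_BASELINE_DAYS,
) -> dict[str, Template]:
    """Templates for several signals from the same training events."""
    events = list(events)
    return {
        sig: build_template(panels, events, sig, T, window_days, baseline_days)
        for sig in signals
    }


def export_templates(templates: dict[str, Template], path) -> None:
    """CSV export (signal, offset, value, n_events) with offsets
    -T ... -1 relative to onset, mirroring the template plots."""
    import pandas as pd

    rows = []
    for sig in sorted(templates):
        t = templates[sig]
        for k, v in enumerate(t.values):
            rows.append(
                {
                    "signal": sig,
                    "offset": k - t.lookback,
                    "value": v,
                    "n_events": t.n_events,
                }
            )
    pd.DataFrame(rows, columns=["signal", "offset", "value", "n_events"]).to_csv(
        path, index=False
    )
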