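"""Event-level ROC evaluation under leave-one-subject-out cross-validation.

The operating characteristic is non-standard by design: varying the
threshold on the daily probability output, the x-axis is the daily-level
false-alarm rate per week (7 x the pooled fraction of non-deterioration
days flagged positive, maximum 7) and the y-axis is the event-level
sensitivity (fraction of deterioration events with at least one flagged
day inside their pre-onset window, maximum 1), so the best attainable
area is 7; dividing by 7 recovers the conventional 0-1 scale. The module
also provides the Bernoulli random-predictor null, subject-level
bootstrap confidence intervals, signal-importance summaries across folds
and the assessment-interval downsampling experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import ModelWeights, fit_weights, model_output
from .labeling import (
    DEFAULT_BASELINE_DAYS,
    DEFAULT_WINDOW_DAYS,
    DeteriorationEvent,
    build_labels,
)
from .preprocess import DailyPanel, INTERPOLATED, OBSERVED
from .templates import Template, TemplateError, build_templates, similarity_series

MAX_FA_PER_WEEK = 7.0


@dataclass
class RocCurve:
    """Event-level ROC on the false-alarms-per-week scale."""

    thresholds: np.ndarray  # descending
    fa_per_week: np.ndarray  # non-decreasing, in [0, 7]
    event_sensitivity: np.ndarray  # non-decreasing, in [0, 1]
    auroc_0_7: float
    auroc_0_1: float


@dataclass
class CvResult:
    """Pooled held-out outputs of a leave-one-subject-out run."""

    outputs: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    events: list[DeteriorationEvent]
    roc: RocCurve
    fold_weights: dict[str, ModelWeights]
    fold_templates: dict[str, dict[str, Template]]
    signals: tuple[str, ...]
    lookback: int
    skipped_folds: list[str] = field(default_factory=list)


def _event_window(ev: DeteriorationEvent, n_days: int, window_days: int) -> tuple[int, int]:
    return max(ev.onset_day - window_days, 0), min(ev.onset_day, n_days)  # [lo, hi)


def roc_curve(
    outputs: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    events: Sequence[DeteriorationEvent],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> RocCurve:
    """Build the event-level ROC by sweeping all observed output values.

    At threshold theta a day is flagged iff output >= theta. False alarms
    pool flagged label-0 days over all subjects; an event counts as
    detected iff some day strictly inside its pre-onset window is
    flagged. Sentinel thresholds above the maximum and at the minimum
    anchor the curve at false-alarm rates 0 and 7, and the area is the
    trapezoid over the full [0, 7] support.
    """
    events = list(events)
    if not events:
        raise ValueError("roc_curve requires at least one deterioration event")
    neg_vals = np.concatenate(
        [outputs[sid][labels[sid] == 0] for sid in outputs]
    )
    if len(neg_vals) == 0:
        raise ValueError("roc_curve requires at least one non-deterioration day")
    event_peaks = []
    for ev in events:
        out = outputs.get(ev.subject_id)
        if out is None:
            raise KeyError(f"no outputs for event subject {ev.subject_id!r}")
        lo, hi = _event_window(ev, len(out), window_days)
        event_peaks.append(out[lo:hi].max() if hi > lo else -np.inf)
    event_peaks = np.array(event_peaks)

    all_vals = np.concatenate([outputs[sid] for sid in outputs])
    uniq = np.unique(all_vals)
    thresholds = np.concatenate([[uniq[-1] + 1.0], uniq[::-1]])  # descending
    neg_sorted = np.sort(neg_vals)
    peaks_sorted = np.sort(event_peaks[np.isfinite(event_peaks)])
    n_neg, n_events = len(neg_vals), len(events)
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    det = len(peaks_sorted) - np.searchsorted(peaks_sorted, thresholds, side="left")
    fa = MAX_FA_PER_WEEK * fp / n_neg
    sens = det / n_events
    auroc = float(np.trapezoid(sens, fa))
    return RocCurve(
        thresholds=thresholds,
        fa_per_week=fa,
        event_sensitivity=sens,
        auroc_0_7=auroc,
        auroc_0_1=auroc / MAX_FA_PER_WEEK,
    )


def sensitivity_at_fa(curve: RocCurve, fa_target: float) -> float:
    """Event sensitivity at a false-alarm budget, linearly interpolated
    along the curve (ties at equal rates resolve to the best
    sensitivity attained there)."""
    if not 0 <= fa_target <= MAX_FA_PER_WEEK:
        raise ValueError("fa_target must lie in [0, 7]")
    fa, sens = curve.fa_per_week, curve.event_sensitivity
    best = {}
    for f, s in zip(fa, sens):
        best[f] = max(best.get(f, 0.0), s)
    xs = np.array(sorted(best))
    ys = np.array([best[x] for x in xs])
    return float(np.interp(fa_target, xs, ys))


# ---------------------------------------------------------------------------
# cross-validation


def _similarity_matrix(
    panel: DailyPanel, templates: dict[str, Template], signals: Sequence[str]
) -> np.ndarray:
    return np.column_stack(
        [similarity_series(panel, sig, templates[sig]).values for sig in signals]
    )


def loso_cv(
    panels: dict[str, DailyPanel],
    events: Sequence[DeteriorationEvent],
    T: int,
    signals: Sequence[str],
    seed: int = 0,
    window_days: int = DEFAULT_WINDOW_DAYS,
    baseline_days: int = DEFAULT_BASELINE_DAYS,
    labels: dict[str, np.ndarray] | None = None,
) -> CvResult:
    """Leave-one-subject-out evaluation of the full model.

    Per fold, templates and weights come from the training subjects only;
    the held-out subject's similarities are computed against those
    training templates, so nothing derived from held-out data can leak
    into training. Folds whose training set has no usable event are
    skipped with a warning and recorded. Held-out outputs are pooled
    across folds into one ROC.
    """
    subjects = sorted(panels)
    if len(subjects) < 2:
        raise ValueError("LOSO cross-validation needs at least 2 subjects")
    signals = tuple(signals)
    events = sorted(
        (e for e in events if e.subject_id in panels),
        key=lambda e: (e.subject_id, e.onset_day),
    )
    if labels is None:
        labels = build_labels(events, {s: panels[s].n_days for s in subjects}, window_days)
    outputs: dict[str, np.ndarray] = {}
    fold_weights: dict[str, ModelWeights] = {}
    fold_templates: dict[str, dict[str, Template]] = {}
    skipped: list[str] = []
    for idx, held in enumerate(subjects):
        train = [s for s in subjects if s != held]
        train_events = [e for e in events if e.subject_id != held]
        train_panels = {s: panels[s] for s in train}
        try:
            templates = build_templates(
                train_panels, train_events, signals, T, window_days, baseline_days
            )
        except TemplateError as exc:
            warnings.warn(f"fold {held}: skipped ({exc})", stacklevel=2)
            skipped.append(held)
            continue
        X_train = np.vstack([_similarity_matrix(panels[s], templates, signals) for s in train])
        y_train = np.concatenate([labels[s] for s in train])
        if (y_train == 1).sum() == 0:
            warnings.warn(f"fold {held}: skipped (no positive training days)", stacklevel=2)
            skipped.append(held)
            continue
        fold_seed = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)
        w = fit_weights(
            X_train, y_train, signals, seed=fold_seed, lookback=T, fold_id=held
        )
        X_test = _similarity_matrix(panels[held], templates, signals)
        outputs[held] = model_output(X_test, w)
        fold_weights[held] = w
        fold_templates[held] = templates
    if not outputs:
        raise ValueError("every fold was skipped; no evaluable outputs")
    eval_events = [e for e in events if e.subject_id in outputs]
    curve = roc_curve(outputs, {s: labels[s] for s in outputs}, eval_events, window_days)
    return CvResult(
        outputs=outputs,
        labels={s: labels[s] for s in outputs},
        events=eval_events,
        roc=curve,
        fold_weights=fold_weights,
        fold_templates=fold_templates,
        signals=signals,
        lookback=T,
        skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# random-predictor null


def random_predictor(p: float, n_days: int, rng: np.random.Generator) -> np.ndarray:
    """Daily Bernoulli(p) alarms; p is the training positive-day proportion."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return (rng.random(n_days) < p).astype(float)


def null_cv(
    labels: dict[str, np.ndarray],
    events: Sequence[DeteriorationEvent],
    seed: int = 0,
    n_draws: int = 100,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> tuple[float, np.ndarray]:
    """AUROC of the Bernoulli random predictor under the same LOSO
    folding: each held-out subject receives daily alarms with probability
    equal to the training subjects' pooled positive-day proportion.
    Returns (mean over draws, per-draw values)."""
    subjects = sorted(labels)
    events = [e for e in events if e.subject_id in labels]
    p_held = {}
    for held in subjects:
        train_y = np.concatenate([labels[s] for s in subjects if s != held])
        p_held[held] = float(train_y.mean())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4242]))
    aurocs = np.empty(n_draws)
    for b in range(n_draws):
        outputs = {
            sid: random_predictor(p_held[sid], len(labels[sid]), rng) for sid in subjects
        }
        aurocs[b] = roc_curve(outputs, labels, events, window_days).auroc_0_7
    return float(aurocs.mean()), aurocs


# ---------------------------------------------------------------------------
# uncertainty and summaries


def bootstrap_ci(
    statistic: Callable[[list], float],
    units: Sequence,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval of ``statistic`` over resampled
    units (subjects, by default) with replacement."""
    units = list(units)
    if len(units) < 2:
        raise ValueError("bootstrap needs at least 2 resample units")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9181]))
    n = len(units)
    stats = np.empty(B)
    for b in range(B):
        pick = rng.integers(0, n, n)
        stats[b] = statistic([units[i] for i in pick])
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(stats, alpha)),
        float(np.quantile(stats, 1.0 - alpha)),
    )


def auroc_ci(
    cv: CvResult, B: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Subject-level bootstrap CI of the pooled AUROC (0-7 scale)."""
    by_subject = {s: [e for e in cv.events if e.subject_id == s] for s in cv.outputs}

    def stat(resample: list) -> float:
        outputs, labels, events = {}, {}, []
        for j, sid in enumerate(resample):
            alias = f"{sid}#{j}"
            outputs[alias] = cv.outputs[sid]
            labels[alias] = cv.labels[sid]
            events.extend(
                DeteriorationEvent(alias, e.onset_day, e.subtype) for e in by_subject[sid]
            )
        if not events:
            return np.nan
        try:
            return roc_curve(outputs, labels, events).auroc_0_7
        except ValueError:
            return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo, hi = bootstrap_ci(stat, sorted(cv.outputs), B=B, level=level, seed=seed)
    return lo, hi


def importance_summary(cv: CvResult, B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Signal importances: mean fitted weight across LOSO folds with a
    bootstrap CI over folds; zero-mean signals are flagged excluded."""
    folds = sorted(cv.fold_weights)
    if not folds:
        raise ValueError("no completed folds")
    W = np.vstack([cv.fold_weights[f].coefficients for f in folds])
    rows = []
    for j, sig in enumerate(cv.signals):
        col = W[:, j]
        if len(folds) >= 2:
            lo, hi = bootstrap_ci(lambda u: float(np.mean(u)), list(col), B=B, seed=seed + j)
        else:
            lo = hi = float(col.mean())
        rows.append(
            {
                "signal": sig,
                "mean_weight": float(col.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "excluded": bool(abs(col.mean()) < 1e-12),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assessment-interval experiment


def thin_signal(panel: DailyPanel, signal: str, interval: int) -> DailyPanel:
    """Keep every ``interval``-th daily value of one signal and
    re-interpolate interior gaps linearly, emulating a sparser assessment
    schedule."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if interval >= panel.n_days:
        raise ValueError(
            f"interval {interval} is not smaller than the series length {panel.n_days}"
        )
    if interval == 1:
        return panel
    vals = panel.values.copy()
    prov = panel.provenance.copy()
    col = vals[signal].to_numpy().copy()
    keep = np.zeros(len(col), dtype=bool)
    keep[::interval] = True
    col[~keep] = np.nan
    filled = pd.Series(col).interpolate(method="linear", limit_area="inside").to_numpy()
    vals[signal] = filled
    pcol = np.full(len(col), "missing", dtype=object)
    pcol[~np.isnan(filled)] = INTERPOLATED
    pcol[keep & ~np.isnan(col)] = OBSERVED
    prov[signal] = pcol.astype(str)
    return DailyPanel(subject_id=panel.subject_id, values=vals, provenance=prov)


def downsample_experiment(
    panels: dict[str, DailyPanel],
    events: Sequence[DeteriorationEvent],
    signal: str,
    intervals: Sequence[int],
    T: int,
    seed: int = 0,
    window_days: int = DEFAULT_WINDOW_DAYS,
    fa_targets: Sequence[float] = (1.0, 2.0),
) -> pd.DataFrame:
    """Univariate performance of one signal at sparser assessment
    intervals: per interval k, thin the signal to every k-th day,
    re-interpolate, and re-run the univariate LOSO evaluation."""
    rows = []
    for k in intervals:
        thinned = {sid: thin_signal(p, signal, int(k)) for sid, p in panels.items()}
        cv = loso_cv(thinned, events, T, (signal,), seed=seed, window_days=window_days)
        row = {
            "signal": signal,
            "interval": int(k),
            "auroc_0_7": cv.roc.auroc_0_7,
            "auroc_0_1": cv.roc.auroc_0_1,
        }
        for fa in fa_targets:
            row[f"sens_at_{fa:g}"] = sensitivity_at_fa(cv.roc, fa)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def run_report(
    results: dict[tuple[str, int], CvResult],
    fa_targets: Sequence[float] = (1.0, 2.0),
    B: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate AUROC (both scales) and operating-point sensitivities per
    (signal subset, look-back) run; ``B > 0`` adds subject-level
    bootstrap CIs for the AUROC."""
    rows = []
    for (subset, T), cv in sorted(results.items()):
        row: dict[str, object] = {
            "subset": subset,
            "lookback": T,
            "n_subjects": len(cv.outputs),
            "n_events": len(cv.events),
            "auroc_0_7": cv.roc.auroc_0_7,
            "auroc_0_1": cv.roc.auroc_0_1,
        }
        for fa in fa_targets:
            row[f"sens_at_{fa:g}"] = sensitivity_at_fa(cv.roc, fa)
        if B > 0:
            lo, hi = auroc_ci(cv, B=B, seed=seed)
            row["auroc_ci_low"], row["auroc_ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)
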