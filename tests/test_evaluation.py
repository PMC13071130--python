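"""Event-level ROC, LOSO-CV, null predictor, bootstrap, downsampling."""

import numpy as np
import pandas as pd
import pytest

from mgwarn.evaluation import (
    CvResult,
    bootstrap_ci,
    downsample_experiment,
    importance_summary,
    loso_cv,
    null_cv,
    random_predictor,
    roc_curve,
    run_report,
    sensitivity_at_fa,
    thin_signal,
)
from mgwarn.labeling import DeteriorationEvent, build_labels
from mgwarn.preprocess import build_daily_panel


def brute_force_roc(outputs, labels, events, window_days=7):
    """Oracle: per-threshold enumeration with plain Python loops."""
    all_vals = sorted({v for o in outputs.values() for v in o})
    thresholds = [all_vals[-1] + 1.0] + list(reversed(all_vals))
    points = []
    n_neg = sum(int((labels[s] == 0).sum()) for s in outputs)
    for theta in thresholds:
        fp = sum(
            int(((outputs[s] >= theta) & (labels[s] == 0)).sum()) for s in outputs
        )
        detected = 0
        for ev in events:
            out = outputs[ev.subject_id]
            lo, hi = max(ev.onset_day - window_days, 0), min(ev.onset_day, len(out))
            if any(out[d] >= theta for d in range(lo, hi)):
                detected += 1
        points.append((7.0 * fp / n_neg, detected / len(events)))
    fa = np.array([p[0] for p in points])
    sens = np.array([p[1] for p in points])
    return fa, sens, float(np.trapezoid(sens, fa))


def _toy_cohort(seed=0, n_subjects=3, n_days=20):
    rng = np.random.default_rng(seed)
    subjects = [f"S{i}" for i in range(n_subjects)]
    events = []
    for i, sid in enumerate(subjects):
        if i % 3 != 2:  # most subjects get one event
            events.append(DeteriorationEvent(sid, int(rng.integers(8, n_days)), "qmg"))
    labels = build_labels(events, {s: n_days for s in subjects})
    outputs = {s: np.round(rng.random(n_days), 2) for s in subjects}
    return outputs, labels, events


def test_oracle_scores_reach_the_auroc_ceiling():
    outputs, labels, events = _toy_cohort(seed=1)
    oracle = {s: labels[s].astype(float) for s in outputs}
    curve = roc_curve(oracle, labels, events)
    assert curve.auroc_0_7 == 7.0
    assert curve.auroc_0_1 == 1.0


def test_constant_score_hits_the_all_positive_corner():
    outputs, labels, events = _toy_cohort(seed=2)
    const = {s: np.full_like(outputs[s], 0.5) for s in outputs}
    curve = roc_curve(const, labels, events)
    assert curve.fa_per_week[-1] == pytest.approx(7.0)
    assert curve.event_sensitivity[-1] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_roc_matches_brute_force_enumeration(seed):
    outputs, labels, events = _toy_cohort(seed=seed)
    curve = roc_curve(outputs, labels, events)
    fa, sens, auroc = brute_force_roc(outputs, labels, events)
    assert np.allclose(curve.fa_per_week, fa, atol=1e-12)
    assert np.allclose(curve.event_sensitivity, sens, atol=1e-12)
    assert curve.auroc_0_7 == pytest.approx(auroc, abs=1e-12)
    assert curve.auroc_0_1 == pytest.approx(auroc / 7, abs=1e-12)


def test_roc_monotone_as_threshold_decreases():
    outputs, labels, events = _toy_cohort(seed=3)
    curve = roc_curve(outputs, labels, events)
    assert (np.diff(curve.fa_per_week) >= 0).all()
    assert (np.diff(curve.event_sensitivity) >= 0).all()


def test_roc_requires_events():
    outputs, labels, _ = _toy_cohort(seed=4)
    with pytest.raises(ValueError, match="event"):
        roc_curve(outputs, labels, [])


def test_sensitivity_interpolation():
    outputs, labels, events = _toy_cohort(seed=1)
    oracle = {s: labels[s].astype(float) for s in outputs}
    curve = roc_curve(oracle, labels, events)
    assert sensitivity_at_fa(curve, 1.0) == pytest.approx(1.0)
    assert sensitivity_at_fa(curve, 7.0) == pytest.approx(curve.event_sensitivity.max())
    piecewise = CvResult.__new__(CvResult)  # dummy holder not needed; build curve directly
    from mgwarn.evaluation import RocCurve

    pw = RocCurve(
        thresholds=np.array([2.0, 1.0]),
        fa_per_week=np.array([0.0, 2.0]),
        event_sensitivity=np.array([0.0, 1.0]),
        auroc_0_7=6.0,
        auroc_0_1=6.0 / 7,
    )
    assert sensitivity_at_fa(pw, 1.0) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# LOSO


def test_two_subjects_two_folds(small_panels, small_daily_cohort):
    with_events = sorted({e.subject_id for e in small_daily_cohort.events})
    assert len(with_events) >= 2, "fixture cohort must plant events in >= 2 subjects"
    two = {sid: small_panels[sid] for sid in with_events[:2]}
    cv = loso_cv(two, small_daily_cohort.events, T=6, signals=("spo2", "pulse"), seed=0)
    assert len(cv.outputs) + len(cv.skipped_folds) == 2


def test_pooled_outputs_invariant_to_subject_order(small_panels, small_daily_cohort):
    events = small_daily_cohort.events
    cv1 = loso_cv(small_panels, events, T=6, signals=("spo2", "mgadl"), seed=5)
    reordered = dict(reversed(list(small_panels.items())))
    cv2 = loso_cv(reordered, events, T=6, signals=("spo2", "mgadl"), seed=5)
    assert sorted(cv1.outputs) == sorted(cv2.outputs)
    for sid in cv1.outputs:
        assert np.array_equal(cv1.outputs[sid], cv2.outputs[sid])


def test_no_leakage_from_held_out_subject(small_panels, small_daily_cohort):
    """Perturbing a held-out subject's data must leave that fold's trained
    templates and weights bit-identical."""
    events = small_daily_cohort.events
    held = sorted(small_panels)[0]
    cv1 = loso_cv(small_panels, events, T=6, signals=("spo2", "pulse"), seed=6)
    perturbed = dict(small_panels)
    import copy

    twin = copy.deepcopy(perturbed[held])
    twin.values["spo2"] += 5.0
    twin.values["pulse"] *= 2.0
    perturbed[held] = twin
    cv2 = loso_cv(perturbed, events, T=6, signals=("spo2", "pulse"), seed=6)
    assert np.array_equal(
        cv1.fold_weights[held].coefficients, cv2.fold_weights[held].coefficients
    )
    for sig in ("spo2", "pulse"):
        assert np.array_equal(
            cv1.fold_templates[held][sig].values, cv2.fold_templates[held][sig].values
        )


# ---------------------------------------------------------------------------
# null predictor


def test_random_predictor_degenerate_probabilities():
    rng = np.random.default_rng(0)
    assert random_predictor(0.0, 50, rng).sum() == 0
    assert random_predictor(1.0, 50, rng).sum() == 50


def test_random_predictor_concentration():
    rng = np.random.default_rng(1)
    draws = random_predictor(0.2, 100_000, rng)
    assert draws.mean() == pytest.approx(0.2, abs=0.005)


def test_null_cv_determinism(small_panels, small_daily_cohort):
    labels = build_labels(
        small_daily_cohort.events, {s: p.n_days for s, p in small_panels.items()}
    )
    m1, a1 = null_cv(labels, small_daily_cohort.events, seed=3, n_draws=10)
    m2, a2 = null_cv(labels, small_daily_cohort.events, seed=3, n_draws=10)
    assert m1 == m2 and np.array_equal(a1, a2)
    assert 0 <= m1 <= 7


# ---------------------------------------------------------------------------
# bootstrap & importances


def test_bootstrap_constant_statistic_zero_width():
    lo, hi = bootstrap_ci(lambda u: 3.14, ["a", "b", "c"], B=50, seed=0)
    assert lo == hi == 3.14


def test_bootstrap_two_subject_mean_endpoints():
    lo, hi = bootstrap_ci(lambda u: float(np.mean(u)), [0.0, 1.0], B=2000, seed=1)
    assert lo in (0.0, 0.5, 1.0) and hi in (0.0, 0.5, 1.0)


def test_bootstrap_deterministic_given_seed():
    stat = lambda u: float(np.sum(u))
    assert bootstrap_ci(stat, [1, 2, 3, 4], B=200, seed=7) == bootstrap_ci(
        stat, [1, 2, 3, 4], B=200, seed=7
    )


def test_importance_summary_flags_zero_signals(small_panels, small_daily_cohort):
    cv = loso_cv(
        small_panels, small_daily_cohort.events, T=6, signals=("spo2", "sbct"), seed=8
    )
    summary = importance_summary(cv, B=100, seed=0)
    assert list(summary["signal"]) == ["spo2", "sbct"]
    row = summary.set_index("signal").loc["spo2"]
    assert row["ci_low"] <= row["mean_weight"] <= row["ci_high"]
    W = np.vstack([w.coefficients for w in cv.fold_weights.values()])
    for j, sig in enumerate(("spo2", "sbct")):
        expected_excluded = abs(W[:, j].mean()) < 1e-12
        assert bool(summary.set_index("signal").loc[sig, "excluded"]) == expected_excluded


def test_identical_fold_weights_give_zero_width_cis(small_panels, small_daily_cohort):
    cv = loso_cv(small_panels, small_daily_cohort.events, T=6, signals=("spo2",), seed=0)
    summary = importance_summary(cv, B=100, seed=0)
    assert summary.loc[0, "mean_weight"] == 1.0
    assert summary.loc[0, "ci_low"] == summary.loc[0, "ci_high"] == 1.0


# ---------------------------------------------------------------------------
# downsampling


def test_thin_signal_identity_and_bounds(small_panels):
    sid = sorted(small_panels)[0]
    panel = small_panels[sid]
    assert thin_signal(panel, "spo2", 1) is panel
    with pytest.raises(ValueError, match="length"):
        thin_signal(panel, "spo2", panel.n_days)
    thinned = thin_signal(panel, "spo2", 3)
    kept = panel.signal("spo2")[::3]
    assert np.allclose(thinned.signal("spo2")[::3], kept, equal_nan=True)
    assert np.array_equal(thinned.signal("pulse"), panel.signal("pulse"), equal_nan=True)


def test_downsample_interval_one_matches_plain_univariate(small_panels, small_daily_cohort):
    events = small_daily_cohort.events
    table = downsample_experiment(small_panels, events, "spo2", [1, 2], T=6, seed=1)
    cv = loso_cv(small_panels, events, T=6, signals=("spo2",), seed=1)
    assert table.loc[table["interval"] == 1, "auroc_0_7"].iloc[0] == pytest.approx(
        cv.roc.auroc_0_7
    )
    assert set(table.columns) >= {"interval", "auroc_0_7", "sens_at_1", "sens_at_2"}


# ---------------------------------------------------------------------------
# reporting


def test_run_report_shapes(small_panels, small_daily_cohort):
    events = small_daily_cohort.events
    results = {
        ("all", T): loso_cv(small_panels, events, T, ("spo2", "mgadl"), seed=0)
        for T in (4, 5, 6)
    }
    report = run_report(results, B=0)
    assert len(report) == 3
    assert (report["auroc_0_1"] == report["auroc_0_7"] / 7).all()
    single = run_report({("all", 6): results[("all", 6)]}, B=50, seed=0)
    assert len(single) == 1
    assert single.loc[0, "auroc_ci_low"] <= single.loc[0, "auroc_ci_high"]
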