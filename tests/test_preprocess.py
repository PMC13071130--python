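"""Artifact filters, daily aggregation, interpolation, standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgwarn.io import RawSignalSeries
from mgwarn.preprocess import (
    build_daily_panel,
    filter_spo2,
    filter_steps,
    interpolate_gaps,
    minute_to_daily,
    weekly_to_daily,
    z_transform,
)

START = np.datetime64("2024-01-01", "D")


def minute_series(values, signal="spo2", start_minute=0, subject="S01"):
    ts = (
        START.astype("datetime64[s]")
        + (start_minute + np.arange(len(values))) * np.timedelta64(60, "s")
    )
    return RawSignalSeries(subject, signal, "per_minute", ts, np.asarray(values, float))


def daily_series(day_values: dict[int, float], signal="fvc", subject="S01", cadence="weekly"):
    days = sorted(day_values)
    ts = START.astype("datetime64[s]") + np.array(days) * np.timedelta64(86400, "s")
    return RawSignalSeries(
        subject, signal, cadence, ts, np.array([day_values[d] for d in days], float)
    )


# ---------------------------------------------------------------------------
# SpO2 filters


@pytest.mark.parametrize(
    "run_length,expect_removed",
    [(59, False), (60, True), (61, True)],
    ids=["run59-kept", "run60-removed", "run61-removed"],
)
def test_plateau_boundary_is_exact(run_length, expect_removed):
    values = np.concatenate([np.full(run_length, 97.0), [95.0, 96.0]])
    spo2 = minute_series(values)
    pulse = minute_series(np.full(len(values), 70.0), signal="pulse")
    out = filter_spo2(spo2, pulse)
    if expect_removed:
        assert len(out) == 2
        assert not (out.values == 97.0).any()
    else:
        assert len(out) == len(values)


def test_minute_gap_breaks_a_plateau_run():
    # 30 identical minutes, a 5-minute gap, 30 more: two short runs, all kept
    a = minute_series(np.full(30, 97.0))
    b = minute_series(np.full(30, 97.0), start_minute=35)
    spo2 = RawSignalSeries(
        "S01", "spo2", "per_minute",
        np.concatenate([a.timestamps, b.timestamps]),
        np.concatenate([a.values, b.values]),
    )
    pulse = minute_series(np.full(70, 70.0))
    assert len(filter_spo2(spo2, pulse)) == 60


def test_spo2_minutes_without_pulse_are_removed():
    spo2 = minute_series([96.0, 97.0, 98.0])
    pulse = minute_series([70.0, 71.0], signal="pulse")  # minutes 0 and 1 only
    out = filter_spo2(spo2, pulse)
    assert out.values.tolist() == [96.0, 97.0]


# ---------------------------------------------------------------------------
# step exclusions


def test_no_intervals_is_identity():
    steps = minute_series([10, 0, 30], signal="steps")
    assert filter_steps(steps, []) is steps


def test_whole_study_interval_empties_series():
    steps = minute_series(np.arange(100.0), signal="steps")
    out = filter_steps(steps, [(START, START + np.timedelta64(2, "D"))])
    assert len(out) == 0


def test_overlapping_intervals_remove_the_union():
    n = 500
    steps = minute_series(np.arange(float(n)), signal="steps")
    iv1 = (steps.timestamps[50], steps.timestamps[200])
    iv2 = (steps.timestamps[150], steps.timestamps[300])
    out = filter_steps(steps, [iv1, iv2])
    # oracle: brute-force membership per sample
    keep = [
        not (iv1[0] <= t <= iv1[1] or iv2[0] <= t <= iv2[1]) for t in steps.timestamps
    ]
    assert np.array_equal(out.values, steps.values[keep])


# ---------------------------------------------------------------------------
# daily aggregation


def test_constant_pulse_day_averages_to_itself():
    s = minute_series(np.full(1440, 80.0), signal="pulse")
    daily = minute_to_daily(s, START, 1)
    assert daily.values[0] == pytest.approx(80.0)


def test_alternating_minutes_average_to_midpoint():
    s = minute_series(np.tile([60.0, 100.0], 720), signal="pulse")
    assert minute_to_daily(s, START, 1).values[0] == pytest.approx(80.0)


def test_day_without_valid_minutes_is_missing():
    s = minute_series([70.0, 71.0], signal="pulse")  # day 0 only
    daily = minute_to_daily(s, START, 3)
    assert np.isnan(daily.values[1:]).all()
    assert (daily.provenance[1:] == "missing").all()


def test_steps_aggregate_by_daily_sum():
    s = minute_series([100.0, 50.0, 25.0], signal="steps")
    assert minute_to_daily(s, START, 1).values[0] == pytest.approx(175.0)


# ---------------------------------------------------------------------------
# weekly -> daily


def test_linear_interpolation_between_weekly_assessments():
    s = daily_series({0: 10.0, 7: 12.0})
    daily = weekly_to_daily(s, START, 10)
    assert daily.values[3] == pytest.approx(10 + 3 * (2 / 7))
    assert daily.provenance[0] == "observed"
    assert daily.provenance[3] == "interpolated"
    assert np.isnan(daily.values[8:]).all()  # no extrapolation past last obs


def test_single_observation_no_extrapolation():
    daily = weekly_to_daily(daily_series({4: 3.0}), START, 10)
    assert np.isnan(np.delete(daily.values, 4)).all()
    assert daily.values[4] == 3.0


def test_same_day_assessments_average():
    ts = np.array(
        ["2024-01-01T08:00:00", "2024-01-01T18:00:00"], dtype="datetime64[s]"
    )
    s = RawSignalSeries("S01", "fvc", "daily", ts, np.array([3.0, 4.0]))
    assert weekly_to_daily(s, START, 2).values[0] == pytest.approx(3.5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    obs=st.dictionaries(
        st.integers(0, 29), st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8
    )
)
def test_interpolation_stays_within_bracketing_hull(obs):
    daily = weekly_to_daily(daily_series(obs), START, 30)
    days = sorted(obs)
    for lo, hi in zip(days, days[1:]):
        seg = daily.values[lo : hi + 1]
        assert np.nanmin(seg) >= min(obs[lo], obs[hi]) - 1e-9
        assert np.nanmax(seg) <= max(obs[lo], obs[hi]) + 1e-9


def test_gap_interpolation_leaves_edges_missing():
    vals = np.array([np.nan, 1.0, np.nan, 3.0, np.nan])
    from mgwarn.preprocess import DailySeries

    filled = interpolate_gaps(
        DailySeries(vals, np.where(np.isnan(vals), "missing", "observed").astype(str))
    )
    assert filled.values[2] == pytest.approx(2.0)
    assert np.isnan(filled.values[0]) and np.isnan(filled.values[4])


# ---------------------------------------------------------------------------
# standardization


def test_z_transform_hand_example_population_sd():
    out = z_transform(np.array([1.0, 2.0, 3.0]))
    assert np.allclose(out, [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])  # SD = sqrt(2/3)


def test_z_transform_idempotent_on_standardized_input():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    z = z_transform(x)
    assert np.allclose(z_transform(z), z, atol=1e-12)
    assert abs(np.nanmean(z)) < 1e-9 and abs(np.nanstd(z) - 1) < 1e-9


def test_constant_series_warns_and_zeroes():
    with pytest.warns(UserWarning, match="zero variance"):
        out = z_transform(np.full(5, 7.0))
    assert (out == 0).all()


# ---------------------------------------------------------------------------
# full panel


def test_panel_matches_generator_latent_truth(small_daily_cohort):
    """Clean daily cohort: the unstandardized panel equals the generator's
    latent daily means wherever observed (oracle = ground truth)."""
    panels = build_daily_panel(
        small_daily_cohort.to_study_frame(), standardize=False
    )
    for sid, panel in panels.items():
        lat = small_daily_cohort.latent[sid]["pulse"]
        obs = (panel.provenance["pulse"] == "observed").to_numpy()
        assert obs.sum() > 0
        assert np.allclose(panel.signal("pulse")[obs], lat[obs], atol=1e-9)


def test_subject_without_wearables_keeps_prom_columns(small_daily_cohort):
    study = small_daily_cohort.to_study_frame()
    sid = study.subjects[0]
    for sig in ("spo2", "pulse", "steps"):
        study.series[sid].pop(sig, None)
    panels = build_daily_panel(study, standardize=False)
    assert np.isnan(panels[sid].signal("spo2")).all()
    assert np.isfinite(panels[sid].signal("mgadl")).any()


def test_panel_invariant_to_input_row_order(tmp_path):
    import pandas as pd

    from mgwarn.io import load_study
    from mgwarn.synthetic import generate_cohort, recovery_config, write_cohort

    cohort = generate_cohort(recovery_config(n_subjects=3, study_days=56, seed=2))
    write_cohort(cohort, tmp_path)
    df = pd.read_csv(tmp_path / "signals.csv")
    shuffled = df.sample(frac=1.0, random_state=0)
    shuffled.to_csv(tmp_path / "signals.csv", index=False)
    panels = build_daily_panel(load_study(tmp_path))
    reference = build_daily_panel(cohort.to_study_frame())
    for sid in reference:
        a, b = reference[sid].values, panels[sid].values
        assert np.allclose(a.to_numpy(), b.to_numpy(), equal_nan=True, atol=1e-9)
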