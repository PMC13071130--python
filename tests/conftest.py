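import numpy as np
import pandas as pd
import pytest

from mgwarn.preprocess import DailyPanel, INTERPOLATED, MISSING, OBSERVED
from mgwarn.synthetic import (
    SignalSpec,
    SyntheticConfig,
    generate_cohort,
    recovery_config,
)


def make_panel(values: dict[str, np.ndarray], subject_id: str = "S01") -> DailyPanel:
    """DailyPanel from raw per-signal daily arrays (NaN = missing)."""
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()})
    df.index.name = "day"
    provenance = pd.DataFrame(
        np.where(df.isna(), MISSING, OBSERVED), index=df.index, columns=df.columns
    )
    return DailyPanel(subject_id=subject_id, values=df, provenance=provenance)


def single_daily_signal_config(**overrides) -> SyntheticConfig:
    """Minimal one-signal daily config used by construction-level tests."""
    defaults = dict(
        n_subjects=2,
        study_days=60,
        signals=[SignalSpec("spo2", "daily", 96.0, 1.0, 0.5)],
        event_rate=1.0,
        effect_profiles={"spo2": {-1: -2.0}},
        missingness={},
        seed=7,
        max_events=2,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_daily_cohort():
    """8-subject daily-cadence cohort with the default planted profiles."""
    cfg = recovery_config(n_subjects=8, study_days=84, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_panels(small_daily_cohort):
    from mgwarn.preprocess import build_daily_panel

    return build_daily_panel(small_daily_cohort.to_study_frame())
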