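"""Registry of the monitored signals and their modality groupings.

The cohort is remotely monitored along three modalities:

* wearable vitals sampled by a wrist device — peripheral oxygen
  saturation (``spo2``, %), pulse rate (``pulse``, bpm) and step count
  (``steps``, steps/day after aggregation);
* weekly patient-performed measures (PPMs) — forced vital capacity
  (``fvc``, litres) and the single-breath count test (``sbct``, counts);
* weekly patient-reported outcome measures (PROMs) — MG-ADL
  (``mgadl``, 0-24), MG-QoL15r (``mgqol15r``, 0-30) and the Single
  Simple Question (``ssq``, 0-100 %).
"""

from __future__ import annotations

WEARABLE_SIGNALS: tuple[str, ...] = ("spo2", "pulse", "steps")
PPM_SIGNALS: tuple[str, ...] = ("fvc", "sbct")
PROM_SIGNALS: tuple[str, ...] = ("mgadl", "mgqol15r", "ssq")
ALL_SIGNALS: tuple[str, ...] = WEARABLE_SIGNALS + PPM_SIGNALS + PROM_SIGNALS

#: Named subsets used when fitting modality-restricted models.
SIGNAL_SUBSETS: dict[str, tuple[str, ...]] = {
    "wearable": WEARABLE_SIGNALS,
    "ppm": PPM_SIGNALS,
    "prom": PROM_SIGNALS,
    "all": ALL_SIGNALS,
}

CADENCES: frozenset[str] = frozenset({"per_minute", "daily", "weekly"})

#: Hard validity ranges (inclusive) enforced at ingest; signals without an
#: entry only need to be finite.
VALUE_RANGES: dict[str, tuple[float, float]] = {
    "spo2": (0.0, 100.0),
    "steps": (0.0, float("inf")),
    "mgadl": (0.0, 24.0),
    "mgqol15r": (0.0, 30.0),
    "ssq": (0.0, 100.0),
}

#: Cadence each signal is acquired at in the monitored cohort.
DEFAULT_CADENCE: dict[str, str] = {
    "spo2": "per_minute",
    "pulse": "per_minute",
    "steps": "per_minute",
    "fvc": "weekly",
    "sbct": "weekly",
    "mgadl": "weekly",
    "mgqol15r": "weekly",
    "ssq": "weekly",
}

#: Daily aggregation rule for per-minute signals: step counts accumulate,
#: vitals average.
DAILY_AGGREGATION: dict[str, str] = {
    "spo2": "mean",
    "pulse": "mean",
    "steps": "sum",
}

#: Number of items on the quantitative MG examination (QMG), each scored 0-3.
QMG_N_ITEMS = 13

#: Default 0-based indices of the ocular QMG items (ptosis, diplopia),
#: excluded from the deterioration score rule; configurable at ingest.
DEFAULT_OCULAR_ITEMS: tuple[int, ...] = (0, 1)


def resolve_subset(subset: str | list[str] | tuple[str, ...]) -> tuple[str, ...]:
    """Resolve a subset name or explicit signal list to signal names."""
    if isinstance(subset, str):
        try:
            return SIGNAL_SUBSETS[subset]
        except KeyError:
            raise ValueError(
                f"unknown signal subset {subset!r}; expected one of "
                f"{sorted(SIGNAL_SUBSETS)} or an explicit list"
            ) from None
    names = tuple(subset)
    unknown = [s for s in names if s not in ALL_SIGNALS]
    if unknown:
        raise ValueError(f"unknown signal name(s) {unknown}; known: {ALL_SIGNALS}")
    return names
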