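"""Synthetic remote-monitoring cohorts with planted pre-deterioration dynamics.

The generator emulates the statistical structure the analysis assumes: a
~30-subject, 12-week cohort with per-minute wearable vitals, weekly
patient-performed and patient-reported measures, sparse QMG examinations,
deterioration events, missingness and wearable artifacts. Each subject's
signal follows a latent daily mean

    latent[d] = subject_baseline + noise_sd * eps[d] + effect[d],

where the effect term adds each event's per-signal deviation profile (in
units of the signal's between-subject baseline SD) on the profiled
offsets before the onset. Cadence sampling happens after the latent
construction, so weekly instruments undersample the same dynamics the
daily ones see.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mgio
from .io import QMGRecord, RawSignalSeries, StudyFrame, SubjectRoster
from .labeling import DeteriorationEvent
from .signals import CADENCES, DEFAULT_CADENCE, QMG_N_ITEMS, VALUE_RANGES

MINUTES_PER_DAY = 1440
DEFAULT_STUDY_START = np.datetime64("2024-01-01", "D")

#: Relative probability of each planted event subtype.
SUBTYPE_WEIGHTS = {"hospitalization": 0.3, "self_report": 0.45, "qmg": 0.25}


@dataclass
class SignalSpec:
    """Population model of one signal.

    ``baseline_mean``/``baseline_sd`` describe the between-subject spread
    of individual baselines; ``noise_sd`` the day-to-day latent
    variability; ``minute_noise_sd`` the additional within-day jitter of
    per-minute samples (ignored for other cadences; steps use Poisson
    minute counts instead).
    """

    name: str
    cadence: str
    baseline_mean: float
    baseline_sd: float
    noise_sd: float
    minute_noise_sd: float = 0.0

    def validate(self) -> None:
        if self.cadence not in CADENCES:
            raise ValueError(f"signal {self.name}: unknown cadence {self.cadence!r}")
        if min(self.baseline_sd, self.noise_sd, self.minute_noise_sd) < 0:
            raise ValueError(f"signal {self.name}: SDs must be >= 0")


def default_signal_specs() -> list[SignalSpec]:
    """The eight monitored signals at their study cadences, with
    physiologically plausible population parameters."""
    return [
        SignalSpec("spo2", "per_minute", 96.0, 1.0, 0.5, 2.0),
        SignalSpec("pulse", "per_minute", 75.0, 8.0, 3.0, 6.0),
        SignalSpec("steps", "per_minute", 7000.0, 2000.0, 1500.0),
        SignalSpec("fvc", "weekly", 3.5, 0.5, 0.15),
        SignalSpec("sbct", "weekly", 40.0, 8.0, 3.0),
        SignalSpec("mgadl", "weekly", 6.0, 2.5, 1.0),
        SignalSpec("mgqol15r", "weekly", 12.0, 5.0, 2.0),
        SignalSpec("ssq", "weekly", 65.0, 12.0, 5.0),
    ]


def default_mg_profiles(magnitude: float = 1.0) -> dict[str, dict[int, float]]:
    """Pre-onset deviation profiles shaped like the cohort's averaged
    pre-deterioration trajectories.

    Offsets are days relative to onset (negative = before); deviations
    are in baseline-SD units with peak magnitude ``magnitude``. Shapes:
    SpO2 declines to a minimum in the last 1-2 days; pulse and step count
    rise (peaks ~3 and ~2 days out) then drop; FVC decreases steadily
    across the whole 10-day span; SBCT bottoms ~2 days out; MG-ADL and
    MG-QoL15r peak ~3 days out and stay elevated; SSQ bottoms ~3 days
    out. All profiles are zero earlier than 10 days before onset.
    """
    m = magnitude
    profiles = {
        "spo2": {-6: -0.15, -5: -0.3, -4: -0.5, -3: -0.7, -2: -0.9, -1: -1.0},
        "pulse": {-6: 0.2, -5: 0.45, -4: 0.75, -3: 1.0, -2: 0.45, -1: -0.3},
        "steps": {-5: 0.2, -4: 0.45, -3: 0.75, -2: 1.0, -1: -0.35},
        "fvc": {o: -0.1 * (11 + o) for o in range(-10, 0)},
        "sbct": {-6: -0.15, -5: -0.3, -4: -0.55, -3: -0.8, -2: -1.0, -1: -0.7},
        "mgadl": {-6: 0.2, -5: 0.4, -4: 0.65, -3: 1.0, -2: 0.9, -1: 0.8},
        "mgqol15r": {-6: 0.15, -5: 0.35, -4: 0.6, -3: 1.0, -2: 0.9, -1: 0.85},
        "ssq": {-6: -0.2, -5: -0.4, -4: -0.65, -3: -1.0, -2: -0.9, -1: -0.8},
    }
    return {sig: {o: m * v for o, v in prof.items()} for sig, prof in profiles.items()}


@dataclass
class SyntheticConfig:
    """Complete, reproducible description of a synthetic cohort."""

    n_subjects: int = 30
    study_days: int = 84
    signals: list[SignalSpec] = field(default_factory=default_signal_specs)
    event_rate: float = 0.8
    effect_profiles: dict[str, dict[int, float]] = field(default_factory=default_mg_profiles)
    missingness: dict[str, float] = field(default_factory=dict)
    artifact_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    # event-planting controls: few, well-separated events per subject
    max_events: int = 3
    min_event_spacing: int = 14
    min_onset_day: int = 15

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.study_days < 1:
            raise ValueError("study_days must be >= 1")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        for spec in self.signals:
            spec.validate()
        for name, p in self.missingness.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missingness probability for {name!r} outside [0, 1]: {p}")
        for name, r in self.artifact_rates.items():
            if r < 0:
                raise ValueError(f"artifact rate {name!r} must be >= 0: {r}")
        if self.event_rate > 0:
            max_onset = self.study_days - 1
            if self.min_onset_day > max_onset:
                raise ValueError(
                    "no feasible onset day: min_onset_day "
                    f"{self.min_onset_day} exceeds last study day {max_onset}"
                )
            span = max_onset - self.min_onset_day
            if (self.max_events - 1) * self.min_event_spacing > span:
                raise ValueError(
                    f"event spacing infeasible: {self.max_events} events with "
                    f"spacing {self.min_event_spacing} need {((self.max_events - 1) * self.min_event_spacing)} "
                    f"days but only {span} are available; reduce event_rate/max_events "
                    "or spacing, or lengthen the study"
                )

    def signal_spec(self, name: str) -> SignalSpec:
        for s in self.signals:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_profiles"] = {
            sig: {str(o): v for o, v in prof.items()}
            for sig, prof in self.effect_profiles.items()
        }
        return d


@dataclass
class ArtifactRecord:
    subject_id: str
    signal_name: str
    kind: str  # spo2_plateau | pulse_dropout | steps_flagged
    start: np.datetime64
    end: np.datetime64
    length: int  # samples (plateau/dropout) or days (flagged interval)


@dataclass
class SyntheticCohort:
    """A generated cohort plus every piece of ground truth about it."""

    config: SyntheticConfig
    study_start: np.datetime64
    series: dict[str, dict[str, RawSignalSeries]]
    events: list[DeteriorationEvent]
    qmg: dict[str, list[QMGRecord]]
    informative_signals: tuple[str, ...]
    latent: dict[str, dict[str, np.ndarray]]
    artifact_log: list[ArtifactRecord] = field(default_factory=list)
    step_exclusions: dict[str, list[tuple[np.datetime64, np.datetime64]]] = field(
        default_factory=dict
    )

    @property
    def subjects(self) -> list[str]:
        return sorted(self.series)

    def to_study_frame(self) -> StudyFrame:
        """Bridge to the ingest representation (as if read from disk)."""
        import pandas as pd

        roster = {
            sid: SubjectRoster(
                subject_id=sid,
                study_start=self.study_start,
                study_end=self.study_start + np.timedelta64(self.config.study_days - 1, "D"),
                step_exclusion_intervals=list(self.step_exclusions.get(sid, [])),
            )
            for sid in self.series
        }
        rows = [
            {
                "subject_id": ev.subject_id,
                "date": self.study_start + np.timedelta64(ev.onset_day, "D"),
                "subtype": ev.subtype,
            }
            for ev in self.events
            if ev.subtype != "qmg"
        ]
        events = pd.DataFrame(rows, columns=["subject_id", "date", "subtype"])
        return StudyFrame(
            roster=roster,
            series={sid: dict(sigs) for sid, sigs in self.series.items()},
            qmg={sid: list(recs) for sid, recs in self.qmg.items()},
            events=events,
        )


# ---------------------------------------------------------------------------
# generation


def _subject_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    # fixed splitting of the global seed; independent of iteration order
    return np.random.default_rng(np.random.SeedSequence([seed, index, stream]))


def _plant_onsets(rng: np.random.Generator, config: SyntheticConfig) -> list[int]:
    k = int(min(rng.poisson(config.event_rate), config.max_events))
    if k == 0:
        return []
    lo, hi = config.min_onset_day, config.study_days - 1
    spacing = config.min_event_spacing
    # uniform order statistics with a deterministic spacing offset
    slack = hi - lo - (k - 1) * spacing
    base = np.sort(rng.integers(lo, lo + slack + 1, size=k))
    return [int(b + i * spacing) for i, b in enumerate(base)]


def _clip_range(name: str, values: np.ndarray) -> np.ndarray:
    if name in VALUE_RANGES:
        lo, hi = VALUE_RANGES[name]
        np.clip(values, lo, hi if np.isfinite(hi) else None, out=values)
    return values


def _latent_series(
    rng: np.random.Generator,
    spec: SignalSpec,
    config: SyntheticConfig,
    onsets: list[int],
) -> np.ndarray:
    D = config.study_days
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
    latent = baseline + spec.noise_sd * rng.standard_normal(D)
    profile = config.effect_profiles.get(spec.name, {})
    for onset in onsets:
        for offset, dev in profile.items():
            d = onset + int(offset)
            if 0 <= d < D:
                latent[d] += dev * spec.baseline_sd
    return latent


def _sample_cadence(
    rng: np.random.Generator,
    spec: SignalSpec,
    latent: np.ndarray,
    config: SyntheticConfig,
    subject_id: str,
    study_start: np.datetime64,
) -> RawSignalSeries:
    D = config.study_days
    p_miss = config.missingness.get(spec.name, 0.0)
    start_s = study_start.astype("datetime64[s]")
    if spec.cadence == "per_minute":
        n = D * MINUTES_PER_DAY
        if spec.name == "steps":
            rate = np.maximum(latent, 0.0) / MINUTES_PER_DAY
            vals = rng.poisson(np.repeat(rate, MINUTES_PER_DAY)).astype(float)
        else:
            vals = np.repeat(latent, MINUTES_PER_DAY) + spec.minute_noise_sd * rng.standard_normal(n)
        ts = start_s + np.arange(n) * np.timedelta64(60, "s")
        if p_miss > 0:
            keep = rng.random(n) >= p_miss
            ts, vals = ts[keep], vals[keep]
    else:
        step = 7 if spec.cadence == "weekly" else 1
        days = np.arange(0, D, step)
        vals = latent[days].copy()
        ts = start_s + days * np.timedelta64(86400, "s")
        if p_miss > 0:
            keep = rng.random(len(days)) >= p_miss
            ts, vals = ts[keep], vals[keep]
    _clip_range(spec.name, vals)
    return RawSignalSeries(
        subject_id=subject_id,
        signal_name=spec.name,
        cadence=spec.cadence,
        timestamps=ts,
        values=vals,
    )


def _qmg_records(
    rng: np.random.Generator,
    subject_id: str,
    onsets_qmg: list[int],
    config: SyntheticConfig,
    study_start: np.datetime64,
) -> list[QMGRecord]:
    """Plant QMG exams so the >=3-point consecutive-pair rule recovers
    exactly the intended qmg-subtype events: a baseline exam, an elevated
    exam on each onset, a recovery exam a week later when it fits, and a
    closing exam at study end."""
    mask = np.zeros(QMG_N_ITEMS, dtype=bool)
    mask[:2] = True  # ocular items
    base = np.zeros(QMG_N_ITEMS, dtype=int)
    nono = np.flatnonzero(~mask)
    for _ in range(int(rng.integers(5, 10))):
        base[rng.choice(nono)] += 1
    base = np.minimum(base, 3)

    def elevated() -> np.ndarray:
        items = base.copy()
        bump = 4
        for i in rng.permutation(nono):
            room = 3 - items[i]
            take = min(room, bump)
            items[i] += take
            bump -= take
            if bump == 0:
                break
        return items

    exam_days: dict[int, np.ndarray] = {0: base}
    last_day = config.study_days - 1
    for onset in onsets_qmg:
        exam_days[onset] = elevated()
        recovery = onset + 7
        if recovery < last_day:
            exam_days[recovery] = base
    exam_days.setdefault(last_day, base)
    return [
        QMGRecord(
            subject_id=subject_id,
            date=study_start + np.timedelta64(day, "D"),
            item_scores=items,
            ocular_mask=mask,
        )
        for day, items in sorted(exam_days.items())
    ]


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort from a validated config.

    Byte-identical for identical (config, seed); per-subject randomness
    is derived from the global seed by fixed splitting.
    """
    config.validate()
    width = max(2, len(str(config.n_subjects)))
    series: dict[str, dict[str, RawSignalSeries]] = {}
    latent: dict[str, dict[str, np.ndarray]] = {}
    qmg: dict[str, list[QMGRecord]] = {}
    events: list[DeteriorationEvent] = []
    for idx in range(config.n_subjects):
        sid = f"S{idx + 1:0{width}d}"
        ev_rng = _subject_rng(config.seed, idx, 0)
        onsets = _plant_onsets(ev_rng, config)
        subtypes = [
            str(ev_rng.choice(list(SUBTYPE_WEIGHTS), p=list(SUBTYPE_WEIGHTS.values())))
            for _ in onsets
        ]
        events.extend(
            DeteriorationEvent(subject_id=sid, onset_day=o, subtype=st)
            for o, st in zip(onsets, subtypes)
        )
        series[sid] = {}
        latent[sid] = {}
        for j, spec in enumerate(config.signals):
            sig_rng = _subject_rng(config.seed, idx, 1 + j)
            lat = _latent_series(sig_rng, spec, config, onsets)
            latent[sid][spec.name] = lat
            series[sid][spec.name] = _sample_cadence(
                sig_rng, spec, lat, config, sid, DEFAULT_STUDY_START
            )
        qmg_onsets = [o for o, st in zip(onsets, subtypes) if st == "qmg"]
        qmg[sid] = _qmg_records(
            _subject_rng(config.seed, idx, 99), sid, qmg_onsets, config, DEFAULT_STUDY_START
        )
    informative = tuple(
        sig
        for sig, prof in config.effect_profiles.items()
        if any(v != 0 for v in prof.values())
    )
    cohort = SyntheticCohort(
        config=config,
        study_start=DEFAULT_STUDY_START,
        series=series,
        events=sorted(events, key=lambda e: (e.subject_id, e.onset_day)),
        qmg=qmg,
        informative_signals=informative,
        latent=latent,
    )
    _apply_configured_artifacts(cohort)
    return cohort


# ---------------------------------------------------------------------------
# artifacts


def inject_plateau(
    series: RawSignalSeries, start_index: int, length: int
) -> tuple[RawSignalSeries, ArtifactRecord]:
    """Overwrite ``length`` samples from ``start_index`` with a constant
    (the value at the start), emulating a stuck SpO2 sensor."""
    if series.cadence != "per_minute":
        raise ValueError("plateau injection requires a per-minute series")
    if start_index + length > len(series):
        raise ValueError("plateau does not fit in the series")
    vals = series.values.copy()
    vals[start_index : start_index + length] = vals[start_index]
    out = dataclasses.replace(series, values=vals)
    rec = ArtifactRecord(
        subject_id=series.subject_id,
        signal_name=series.signal_name,
        kind="spo2_plateau",
        start=series.timestamps[start_index],
        end=series.timestamps[start_index + length - 1],
        length=length,
    )
    return out, rec


def inject_pulse_dropout(
    series: RawSignalSeries, start_index: int, length: int
) -> tuple[RawSignalSeries, ArtifactRecord]:
    """Delete a run of pulse samples, leaving SpO2 minutes unpaired."""
    if series.cadence != "per_minute":
        raise ValueError("dropout injection requires a per-minute series")
    keep = np.ones(len(series), dtype=bool)
    keep[start_index : start_index + length] = False
    rec = ArtifactRecord(
        subject_id=series.subject_id,
        signal_name=series.signal_name,
        kind="pulse_dropout",
        start=series.timestamps[start_index],
        end=series.timestamps[min(start_index + length, len(series)) - 1],
        length=int((~keep).sum()),
    )
    out = dataclasses.replace(
        series, timestamps=series.timestamps[keep], values=series.values[keep]
    )
    return out, rec


def inject_step_flag(
    series: RawSignalSeries, start_day: np.datetime64, n_days: int, factor: float = 10.0
) -> tuple[RawSignalSeries, ArtifactRecord]:
    """Inflate step counts over whole days (double-counting artifact) and
    return the exclusion interval to be recorded in the roster."""
    start_day = np.datetime64(start_day, "D")
    end_day = start_day + np.timedelta64(n_days - 1, "D")
    days = series.timestamps.astype("datetime64[D]")
    hit = (days >= start_day) & (days <= end_day)
    vals = series.values.copy()
    vals[hit] = vals[hit] * factor
    out = dataclasses.replace(series, values=vals)
    rec = ArtifactRecord(
        subject_id=series.subject_id,
        signal_name=series.signal_name,
        kind="steps_flagged",
        start=start_day,
        end=end_day,
        length=n_days,
    )
    return out, rec


def inject_artifacts(
    series: RawSignalSeries, config: SyntheticConfig, seed: int | None = None
) -> tuple[RawSignalSeries, list[ArtifactRecord]]:
    """Inject signal-appropriate artifacts at the configured rates.

    ``plateau_rate``/``dropout_rate``/``flag_rate`` are expected artifact
    counts per subject-study (Poisson). Returns the perturbed series and
    the ground-truth log. Weekly series are rejected.
    """
    if series.cadence == "weekly":
        raise ValueError("artifact injection applies to per-minute series only")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, hash(series.subject_id) % (2**31), 7])
    )
    log: list[ArtifactRecord] = []
    rates = config.artifact_rates
    if series.signal_name == "spo2":
        for _ in range(rng.poisson(rates.get("plateau_rate", 0.0))):
            length = int(rng.integers(60, 181))
            start = _contiguous_start(series, length, rng)
            if start is None:
                warnings.warn("no contiguous slot for plateau injection", stacklevel=2)
                continue
            series, rec = inject_plateau(series, start, length)
            log.append(rec)
    elif series.signal_name == "pulse":
        for _ in range(rng.poisson(rates.get("dropout_rate", 0.0))):
            length = int(rng.integers(30, 240))
            if len(series) <= length:
                continue
            start = int(rng.integers(0, len(series) - length))
            series, rec = inject_pulse_dropout(series, start, length)
            log.append(rec)
    elif series.signal_name == "steps":
        for _ in range(rng.poisson(rates.get("flag_rate", 0.0))):
            n_days = int(rng.integers(1, 4))
            days = np.unique(series.timestamps.astype("datetime64[D]"))
            if len(days) <= n_days:
                continue
            start = days[int(rng.integers(0, len(days) - n_days))]
            series, rec = inject_step_flag(series, start, n_days)
            log.append(rec)
    return series, log


def _contiguous_start(series: RawSignalSeries, length: int, rng) -> int | None:
    if len(series) < length:
        return None
    minutes = series.timestamps.astype("datetime64[m]").astype("int64")
    contig = np.diff(minutes) == 1
    # start i is usable iff the length-1 steps from i onward are all gap-free
    cs = np.concatenate([[0], np.cumsum(contig)])
    n_starts = len(series) - length + 1
    ok = cs[length - 1 : length - 1 + n_starts] - cs[:n_starts] == length - 1
    candidates = np.flatnonzero(ok)
    if len(candidates) == 0:
        return None
    return int(rng.choice(candidates))


def _apply_configured_artifacts(cohort: SyntheticCohort) -> None:
    rates = cohort.config.artifact_rates
    if not any(rates.get(k, 0) for k in ("plateau_rate", "dropout_rate", "flag_rate")):
        return
    for sid in cohort.subjects:
        for sig in ("spo2", "pulse", "steps"):
            s = cohort.series[sid].get(sig)
            if s is None or s.cadence == "weekly":
                continue
            s, log = inject_artifacts(s, cohort.config)
            cohort.series[sid][sig] = s
            cohort.artifact_log.extend(log)
            for rec in log:
                if rec.kind == "steps_flagged":
                    cohort.step_exclusions.setdefault(sid, []).append((rec.start, rec.end))


# ---------------------------------------------------------------------------
# persistence


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write the cohort in the pipeline's input dialect plus ground truth
    (events CSV) and a JSON run manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study = cohort.to_study_frame()
    all_series = [s for sigs in cohort.series.values() for s in sigs.values()]
    mgio.write_signals(all_series, directory / "signals.csv")
    mgio.write_events(study.events, directory / "events.csv")
    mgio.write_qmg(cohort.qmg, directory / "qmg.csv")
    mgio.write_roster(study.roster, directory / "roster.json")
    import pandas as pd

    pd.DataFrame(
        [
            {"subject_id": e.subject_id, "onset_day": e.onset_day, "subtype": e.subtype}
            for e in cohort.events
        ],
        columns=["subject_id", "onset_day", "subtype"],
    ).to_csv(directory / "ground_truth_events.csv", index=False)
    manifest = {
        "config": cohort.config.to_dict(),
        "seed": cohort.config.seed,
        "study_start": str(cohort.study_start),
        "informative_signals": list(cohort.informative_signals),
        "n_events": len(cohort.events),
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# canned configurations


def recovery_config(
    n_subjects: int = 30,
    study_days: int = 84,
    informative_signal: str = "spo2",
    effect_sd: float = 2.0,
    seed: int = 0,
    event_rate: float = 0.8,
) -> SyntheticConfig:
    """Study conditions for parameter-recovery experiments: one
    informative signal carrying the default profile shape scaled to a
    peak of ``effect_sd`` baseline-SD units, all other signals pure
    noise. Wearables are generated at daily cadence (the latent daily
    resolution the analysis operates at); PPMs/PROMs stay weekly."""
    specs = []
    for spec in default_signal_specs():
        if spec.cadence == "per_minute":
            spec = dataclasses.replace(spec, cadence="daily", minute_noise_sd=0.0)
        specs.append(spec)
    profiles = {informative_signal: default_mg_profiles(effect_sd)[informative_signal]}
    return SyntheticConfig(
        n_subjects=n_subjects,
        study_days=study_days,
        signals=specs,
        event_rate=event_rate,
        effect_profiles=profiles,
        missingness={s.name: (0.1 if s.cadence == "weekly" else 0.05) for s in specs},
        seed=seed,
    )
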