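"""Synthetic multi-subject PPG/ABP cohort generator.

Emulates the statistical structure of an ICU-style waveform cohort used for
hypertension screening: each subject has a stable systolic blood pressure
(SBP) level on one side of the 130 mmHg threshold, repeated timestamped
120-s recordings at 125 Hz, and a beat-level pulse morphology that differs
systematically between normotensive (NTS) and hypertensive (HTS) subjects.
Optional slow drift moves both SBP and pulse shape over hours to days.

The pulse model is deliberately simple phenomenology, not validated
hemodynamics: each beat is a sum of positive lobes (systolic peak,
reflected wave, dicrotic component).  Hypertensive morphology has a larger
reflected-wave fraction, a broader systolic peak and a damped dicrotic
component, which is the standard qualitative picture of arterial stiffening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

NTS = "NTS"
HTS = "HTS"

#: Morphology scale: SBP (mmHg) mapped to a dimensionless shape coordinate m
#: with m = 0 at a mid-normotensive pressure and m = 1 at a mid-hypertensive
#: pressure.  Pulse-shape parameters vary linearly in m (unclipped, so drift
#: keeps changing the shape even deep inside a class).
_M_CENTER_MMHG = 112.5
_M_SPAN_MMHG = 37.5

# Per-subject recording offsets (hours) of the study-shaped default schedule.
# Gaps populate all four calibration bins: <1 h, 1-6 h, 6-24 h, >24 h.
_STUDY_OFFSETS_H = (
    0.0, 0.5, 1.0, 3.0, 6.0, 18.0, 30.0, 60.0, 90.0, 90.5, 92.0, 98.0,
    116.0, 144.0, 144.5,
)


@dataclass
class CohortConfig:
    """Generator configuration; defaults give a small separable cohort."""

    n_nts_subjects: int = 10
    n_hts_subjects: int = 10
    #: int (same count for everyone) or one count per subject.
    recordings_per_subject: int | Sequence[int] = 4
    recording_duration_s: float = 120.0
    fs_hz: float = 125.0
    #: "uniform" (gap timestamp_gap_s), "study" (the mixed multi-day
    #: pattern), or an explicit sequence of offsets in seconds.
    timestamp_schedule: str | Sequence[float] = "uniform"
    timestamp_gap_s: float = 1800.0
    sbp_range_nts: tuple[float, float] = (100.0, 125.0)
    sbp_range_hts: tuple[float, float] = (135.0, 165.0)
    hr_bpm_range: tuple[float, float] = (55.0, 95.0)
    #: scales the class-dependent component of the pulse shape (1 = default
    #: separation; 0 = identical morphology for both classes).
    morphology_effect: float = 1.0
    #: magnitude of a linear SBP drift; the sign is drawn per subject.
    drift_mmHg_per_hour: float = 0.0
    #: std of a per-subject Brownian drift of the shape coordinate m per
    #: sqrt(hour); models slow morphology change uncoupled from SBP.
    shape_drift_per_sqrt_hour: float = 0.0
    #: additive waveform noise, as a fraction of pulse amplitude (PPG) and
    #: of pulse pressure (ABP).
    noise_sd: float = 0.02
    seed: int = 0
    #: set true to permit SBP ranges that straddle 130 with drift disabled.
    allow_threshold_straddle: bool = False

    def validate(self) -> None:
        if self.n_nts_subjects < 0 or self.n_hts_subjects < 0:
            raise ValueError("subject counts must be non-negative")
        if self.recording_duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        lo, hi = self.sbp_range_nts
        lo2, hi2 = self.sbp_range_hts
        if lo > hi or lo2 > hi2:
            raise ValueError("SBP ranges must be ordered (low, high)")
        drifting = self.drift_mmHg_per_hour != 0.0
        if not drifting and not self.allow_threshold_straddle:
            if hi > 130.0:
                raise ValueError(
                    "NTS SBP range extends above 130 mmHg with drift disabled"
                )
            if lo2 <= 130.0:
                raise ValueError(
                    "HTS SBP range reaches 130 mmHg or below with drift disabled"
                )
        if self.hr_bpm_range[0] <= 0:
            raise ValueError("heart rate must be positive")

    def recordings_for(self, subject_index: int, n_subjects: int) -> int:
        if isinstance(self.recordings_per_subject, int):
            return self.recordings_per_subject
        counts = list(self.recordings_per_subject)
        if len(counts) != n_subjects:
            raise ValueError(
                f"recordings_per_subject has {len(counts)} entries "
                f"for {n_subjects} subjects"
            )
        return int(counts[subject_index])


@dataclass
class Subject:
    subject_id: str
    true_class: str  # NTS or HTS
    baseline_sbp: float  # mmHg
    pulse_params: dict[str, float] = field(default_factory=dict)
    drift_sign: float = 0.0
    hr_bpm: float = 70.0
    pulse_pressure: float = 42.0


@dataclass
class Recording:
    subject_id: str
    t0: float  # seconds since cohort epoch
    fs_hz: float
    ppg: np.ndarray  # arbitrary units, zero mean
    abp: np.ndarray  # mmHg
    duration_s: float
    recording_id: str = ""

    def __post_init__(self) -> None:
        n = int(round(self.duration_s * self.fs_hz))
        if len(self.ppg) != n or len(self.abp) != n:
            raise ValueError("channel lengths must equal duration_s * fs_hz")


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[Subject]
    recordings: list[Recording]

    def manifest(self) -> pd.DataFrame:
        cls = {s.subject_id: s.true_class for s in self.subjects}
        rows = [
            {
                "recording_id": r.recording_id,
                "subject_id": r.subject_id,
                "true_class": cls[r.subject_id],
                "t0": r.t0,
                "fs_hz": r.fs_hz,
                "duration_s": r.duration_s,
            }
            for r in self.recordings
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "recording_id", "subject_id", "true_class", "t0", "fs_hz",
                "duration_s",
            ],
        )


def study_cohort_config(seed: int = 0) -> CohortConfig:
    """The study-shaped default: 69 subjects (45 NTS, 24 HTS) and 974
    timestamped 120-s recordings at 125 Hz, spread over days so every
    calibration-interval bin is populated.

    974 = 69 x 14 + 8, so the first 8 subjects contribute 15 recordings and
    the remaining 61 contribute 14.
    """
    counts = [15] * 8 + [14] * 61
    return CohortConfig(
        n_nts_subjects=45,
        n_hts_subjects=24,
        recordings_per_subject=counts,
        timestamp_schedule="study",
        seed=seed,
    )


def separable_cohort_config(seed: int = 0, n_per_class: int = 10,
                            recordings_per_subject: int = 4) -> CohortConfig:
    """Drift-free cohort with default class-separable morphology and
    recordings every 30 min, so every subject qualifies for the <1 h bin."""
    return CohortConfig(
        n_nts_subjects=n_per_class,
        n_hts_subjects=n_per_class,
        recordings_per_subject=recordings_per_subject,
        timestamp_schedule="uniform",
        timestamp_gap_s=1800.0,
        seed=seed,
    )


#: Recording offsets (hours) giving each subject a qualifying chain in all
#: four calibration bins (gaps: 0.5, 0.5, 2, 3, 12, 12, 30, 30 h).
TREND_OFFSETS_H = (0.0, 0.5, 1.0, 3.0, 6.0, 18.0, 30.0, 60.0, 90.0)


def drifting_cohort_config(seed: int = 0, n_per_class: int = 6) -> CohortConfig:
    """Cohort with strong slow SBP and morphology drift over its multi-day
    schedule, used to probe how accuracy decays with calibration interval.

    SBP ranges are pulled 10 mmHg back from the 130 mmHg threshold so the
    0.25 mmHg/h drift rarely flips labels over the 90 h span; the shape
    coordinate additionally follows a Brownian drift of 0.2 / sqrt(hour),
    which degrades long-interval calibration without touching labels.
    """
    return CohortConfig(
        n_nts_subjects=n_per_class,
        n_hts_subjects=n_per_class,
        recordings_per_subject=len(TREND_OFFSETS_H),
        timestamp_schedule=[h * 3600.0 for h in TREND_OFFSETS_H],
        sbp_range_nts=(100.0, 120.0),
        sbp_range_hts=(140.0, 160.0),
        drift_mmHg_per_hour=0.25,
        shape_drift_per_sqrt_hour=0.2,
        seed=seed,
    )


def schedule_timestamps(
    config: CohortConfig, subject_index: int, n_subjects: int,
    start_s: float = 0.0,
) -> np.ndarray:
    """Per-subject acquisition timestamps (seconds since cohort epoch).

    Offsets are relative to ``start_s``; the result is strictly increasing.
    """
    n = config.recordings_for(subject_index, n_subjects)
    if n < 0:
        raise ValueError("recordings_per_subject must be non-negative")
    sched = config.timestamp_schedule
    if isinstance(sched, str):
        if sched == "uniform":
            offsets = np.arange(n) * float(config.timestamp_gap_s)
        elif sched == "study":
            if n > len(_STUDY_OFFSETS_H):
                raise ValueError(
                    f"study schedule supports at most {len(_STUDY_OFFSETS_H)} "
                    f"recordings per subject, got {n}"
                )
            offsets = np.asarray(_STUDY_OFFSETS_H[:n]) * 3600.0
        else:
            raise ValueError(f"unknown schedule rule {sched!r}")
    else:
        offsets = np.asarray(list(sched), dtype=float)[:n]
        if len(offsets) != n:
            raise ValueError("explicit schedule shorter than recording count")
    if np.any(offsets < 0):
        raise ValueError("schedule offsets must be non-negative")
    ts = start_s + offsets
    if n > 1 and not np.all(np.diff(ts) > 0):
        raise ValueError("timestamps must be strictly increasing")
    return ts


def _gauss(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((tau - center) / width) ** 2)


def _pulse_shape_params(m: float, effect: float, jitter: dict[str, float]):
    """Pulse-shape parameters at shape coordinate m (0 ~ NTS, 1 ~ HTS)."""
    e = effect
    return {
        # systolic peak width (s): broader with stiffer arteries
        "w_sys": float(np.clip(0.09 + 0.04 * e * m + jitter.get("w_sys", 0.0),
                               0.05, 0.22)),
        # reflected-wave fraction: up with hypertension
        "r_refl": float(np.clip(0.25 + 0.45 * e * m + jitter.get("r_refl", 0.0),
                                0.02, 1.3)),
        # reflected-wave delay (s)
        "d_refl": float(np.clip(0.20 + 0.05 * m + jitter.get("d_refl", 0.0),
                                0.12, 0.34)),
        # dicrotic-component amplitude: damped with hypertension
        "a_dicr": float(np.clip(0.30 - 0.18 * e * m + jitter.get("a_dicr", 0.0),
                                0.02, 0.65)),
        # dicrotic delay (s)
        "d_dicr": 0.36,
    }


def _shape_coordinate(sbp_mmHg: float) -> float:
    return (sbp_mmHg - _M_CENTER_MMHG) / _M_SPAN_MMHG


def synth_recording(
    subject: Subject,
    t0: float,
    config: CohortConfig,
    rng: np.random.Generator,
    shape_drift: float = 0.0,
    recording_id: str = "",
) -> Recording:
    """Synthesize one paired PPG/ABP recording starting at cohort time t0.

    Every ABP beat is rescaled so its sampled systolic maximum equals the
    target SBP for that beat (baseline + drift + noise), which keeps the
    SBP label machinery exact on the discrete grid.
    """
    fs = float(config.fs_hz)
    n = int(round(config.recording_duration_s * fs))
    t_hours = t0 / 3600.0
    sbp_eff = subject.baseline_sbp + subject.drift_sign * \
        config.drift_mmHg_per_hour * t_hours
    m = _shape_coordinate(sbp_eff) + shape_drift
    params = _pulse_shape_params(m, config.morphology_effect,
                                 subject.pulse_params)

    ppg = np.zeros(n)
    abp = np.full(n, sbp_eff - subject.pulse_pressure)
    t_beat = 0.0
    while t_beat < config.recording_duration_s:
        hr = subject.hr_bpm + rng.normal(0.0, 2.0)  # beat-to-beat HR jitter
        period = 60.0 / max(hr, 20.0)
        i0 = int(round(t_beat * fs))
        i1 = min(int(round((t_beat + period) * fs)), n)
        if i1 <= i0:
            break
        tau = (np.arange(i0, i1) - t_beat * fs) / fs

        amp = rng.normal(1.0, 0.02)  # multiplicative amplitude jitter
        pulse = (
            _gauss(tau, 0.15, params["w_sys"])
            + params["r_refl"] * _gauss(tau, 0.15 + params["d_refl"], 0.14)
            + params["a_dicr"] * _gauss(tau, 0.15 + params["d_dicr"], 0.08)
        )
        ppg[i0:i1] += amp * pulse

        # ABP beat: fixed shape, rescaled so the sampled max is the target SBP
        sbp_k = sbp_eff
        dbp_k = sbp_k - subject.pulse_pressure
        q = _gauss(tau, 0.15, 0.12) + 0.35 * _gauss(tau, 0.45, 0.12)
        qmin, qmax = q.min(), q.max()
        if qmax > qmin:
            abp[i0:i1] = dbp_k + (sbp_k - dbp_k) * (q - qmin) / (qmax - qmin)
        t_beat += period

    if config.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, config.noise_sd, n)
        abp = abp + rng.normal(0.0, config.noise_sd * subject.pulse_pressure, n)
    np.clip(abp, 20.0, 300.0, out=abp)
    ppg = ppg - ppg.mean()  # PPG is zero-mean, arbitrary units

    return Recording(
        subject_id=subject.subject_id, t0=float(t0), fs_hz=fs,
        ppg=ppg, abp=abp, duration_s=float(config.recording_duration_s),
        recording_id=recording_id or f"{subject.subject_id}_r{int(t0)}",
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Deterministically generate the full cohort for ``config.seed``."""
    config.validate()
    n_total = config.n_nts_subjects + config.n_hts_subjects
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(max(n_total, 1))

    subjects: list[Subject] = []
    recordings: list[Recording] = []
    for i in range(n_total):
        rng = np.random.default_rng(subject_seeds[i])
        is_hts = i >= config.n_nts_subjects
        cls = HTS if is_hts else NTS
        lo, hi = config.sbp_range_hts if is_hts else config.sbp_range_nts
        baseline = rng.uniform(lo, hi)
        jitter = {
            "w_sys": rng.normal(0.0, 0.006),
            "r_refl": rng.normal(0.0, 0.02),
            "d_refl": rng.normal(0.0, 0.01),
            "a_dicr": rng.normal(0.0, 0.015),
        }
        subject = Subject(
            subject_id=f"S{i:03d}",
            true_class=cls,
            baseline_sbp=float(baseline),
            pulse_params=jitter,
            drift_sign=float(rng.choice([-1.0, 1.0])),
            hr_bpm=float(rng.uniform(*config.hr_bpm_range)),
            pulse_pressure=float(rng.uniform(35.0, 50.0)
                                 + 0.15 * (baseline - 120.0)),
        )
        subjects.append(subject)

        start = float(rng.uniform(0.0, 24 * 3600.0))
        ts = schedule_timestamps(config, i, n_total, start_s=start)
        # Brownian morphology drift sampled at the recording times
        drifts = np.zeros(len(ts))
        if config.shape_drift_per_sqrt_hour > 0 and len(ts) > 0:
            gaps_h = np.diff(np.concatenate([[ts[0]], ts])) / 3600.0
            steps = rng.normal(0.0, 1.0, len(ts)) * \
                config.shape_drift_per_sqrt_hour * np.sqrt(gaps_h)
            drifts = np.cumsum(steps)
        for k, t0 in enumerate(ts):
            recordings.append(
                synth_recording(
                    subject, t0, config, rng,
                    shape_drift=float(drifts[k]),
                    recording_id=f"{subject.subject_id}_r{k:02d}",
                )
            )
    return Cohort(config=config, subjects=subjects, recordings=recordings)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write one directory per cohort: per-channel two-column CSVs
    (sample_index, value), a manifest CSV and the config as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    cls = {s.subject_id: s.true_class for s in cohort.subjects}
    for rec in cohort.recordings:
        rec_dir = out / rec.recording_id
        rec_dir.mkdir(exist_ok=True)
        for name, series in (("ppg", rec.ppg), ("abp", rec.abp)):
            pd.DataFrame(
                {"sample_index": np.arange(len(series)), "value": series}
            ).to_csv(rec_dir / f"{name}.csv", index=False)
        rows.append({
            "subject_id": rec.subject_id,
            "class": cls[rec.subject_id],
            "recording_path": rec.recording_id,
            "t0": rec.t0,
            "fs_hz": rec.fs_hz,
        })
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    cfg = {k: (list(v) if isinstance(v, (tuple, list)) else v)
           for k, v in vars(cohort.config).items()}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    """Inverse of :func:`write_cohort`."""
    src = Path(in_dir)
    raw = yaml.safe_load((src / "config.yaml").read_text())
    for key in ("sbp_range_nts", "sbp_range_hts", "hr_bpm_range"):
        raw[key] = tuple(raw[key])
    if isinstance(raw["timestamp_schedule"], list):
        raw["timestamp_schedule"] = list(raw["timestamp_schedule"])
    config = CohortConfig(**raw)
    manifest = pd.read_csv(src / "manifest.csv", float_precision="round_trip")
    subjects_seen: dict[str, Subject] = {}
    recordings = []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        if sid not in subjects_seen:
            subjects_seen[sid] = Subject(
                subject_id=sid, true_class=row["class"], baseline_sbp=math.nan
            )
        rec_dir = src / row["recording_path"]
        ppg = pd.read_csv(rec_dir / "ppg.csv",
                          float_precision="round_trip")["value"].to_numpy()
        abp = pd.read_csv(rec_dir / "abp.csv",
                          float_precision="round_trip")["value"].to_numpy()
        recordings.append(Recording(
            subject_id=sid, t0=float(row["t0"]), fs_hz=float(row["fs_hz"]),
            ppg=ppg, abp=abp, duration_s=len(ppg) / float(row["fs_hz"]),
            recording_id=str(row["recording_path"]),
        ))
    return Cohort(config=config, subjects=list(subjects_seen.values()),
                  recordings=recordings)


__all__ = [
    "NTS", "HTS", "CohortConfig", "Subject", "Recording", "Cohort",
    "study_cohort_config", "schedule_timestamps", "synth_recording",
    "generate_cohort", "write_cohort", "read_cohort",
]
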