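"""SBP labeling, PPG filtering/downsampling and 10-s segmentation.

The label pipeline reads the ABP channel only: mean systolic-peak pressure
over a recording defines its SBP, and SBP > 130 mmHg defines the
hypertensive (HTS) class.  The PPG channel is band-pass filtered
(Chebyshev II, 0.5-10 Hz, zero phase), decimated from 125 Hz to 25 Hz and
cut into 10-s sub-segments of 250 samples, the unit the downstream image
classifier sees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import Cohort, NTS, HTS

logger = logging.getLogger(__name__)

SBP_THRESHOLD_MMHG = 130.0
SEGMENT_LEN_S = 10.0
TARGET_FS_HZ = 25.0

# SBP peak detection: local maxima at most 180 bpm apart with >= 10 mmHg
# prominence, so dicrotic shoulders are not counted as beats.
_MIN_PEAK_DISTANCE_S = 0.33
_MIN_PEAK_PROMINENCE_MMHG = 10.0


@dataclass
class FilterConfig:
    """Band-pass Chebyshev type II design (order = design order passed to
    scipy.signal.cheby2; the band-pass realization has twice the poles)."""

    order: int = 4
    low_cut_hz: float = 0.5
    high_cut_hz: float = 10.0
    stopband_atten_db: float = 40.0
    zero_phase: bool = True

    def sos(self, fs_hz: float) -> np.ndarray:
        if not 0 < self.low_cut_hz < self.high_cut_hz < fs_hz / 2:
            raise ValueError(
                f"cutoffs must satisfy 0 < {self.low_cut_hz} < "
                f"{self.high_cut_hz} < Nyquist {fs_hz / 2}"
            )
        return signal.cheby2(
            self.order, self.stopband_atten_db,
            [self.low_cut_hz, self.high_cut_hz],
            btype="bandpass", fs=fs_hz, output="sos",
        )


@dataclass
class SubSegment:
    """A labeled 10-s PPG window (250 samples at 25 Hz)."""

    subject_id: str
    recording_id: str
    parity_index: int  # 1-based position within its recording
    t0: float  # seconds since cohort epoch
    fs_hz: float
    ppg: np.ndarray
    sbp: float  # mmHg, inherited from the parent recording
    label: str  # NTS or HTS

    @property
    def segment_id(self) -> str:
        return f"{self.recording_id}_s{self.parity_index:02d}"


def extract_sbp(abp: np.ndarray, fs_hz: float, recording_id: str = "") -> float:
    """SBP of a recording: the arithmetic mean of detected systolic peaks."""
    abp = np.asarray(abp, dtype=float)
    peaks, _ = signal.find_peaks(
        abp,
        distance=max(int(round(_MIN_PEAK_DISTANCE_S * fs_hz)), 1),
        prominence=_MIN_PEAK_PROMINENCE_MMHG,
    )
    if len(peaks) == 0:
        raise ValueError(
            f"no systolic peaks detected in recording {recording_id or '<unnamed>'}"
        )
    return float(abp[peaks].mean())


def assign_label(sbp: float, threshold: float = SBP_THRESHOLD_MMHG) -> str:
    """HTS iff sbp > threshold; exactly at threshold counts as NTS."""
    if not np.isfinite(sbp):
        raise ValueError(f"SBP must be finite, got {sbp}")
    return HTS if sbp > threshold else NTS


def filter_ppg(ppg: np.ndarray, fs_hz: float,
               cfg: FilterConfig | None = None) -> np.ndarray:
    """Zero-phase band-pass; output has the input's length, DC removed."""
    cfg = cfg or FilterConfig()
    sos = cfg.sos(fs_hz)
    ppg = np.asarray(ppg, dtype=float)
    if cfg.zero_phase:
        return signal.sosfiltfilt(sos, ppg)
    return signal.sosfilt(sos, ppg)


def downsample_ppg(ppg: np.ndarray, fs_in: float = 125.0,
                   fs_out: float = TARGET_FS_HZ) -> np.ndarray:
    """Decimate by the integer factor fs_in/fs_out.

    The signal is assumed already band-limited below fs_out/2 by the 10 Hz
    band-pass, so plain sample selection is alias-free.
    """
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"fs_in/fs_out must be a positive integer, got {fs_in}/{fs_out}"
        )
    return np.asarray(ppg, dtype=float)[:: int(round(factor))]


def segment_recording(
    ppg: np.ndarray,
    fs_hz: float,
    sbp: float,
    subject_id: str,
    recording_id: str,
    t0: float = 0.0,
    seg_len_s: float = SEGMENT_LEN_S,
    threshold: float = SBP_THRESHOLD_MMHG,
) -> list[SubSegment]:
    """Cut a (filtered, downsampled) PPG series into labeled 10-s windows.

    A trailing remainder shorter than seg_len_s is dropped with a warning.
    """
    n_per = int(round(seg_len_s * fs_hz))
    n = len(ppg)
    if n < n_per:
        raise ValueError(
            f"recording {recording_id} shorter ({n / fs_hz:.1f} s) than one "
            f"{seg_len_s:.0f}-s segment"
        )
    count = n // n_per
    if n % n_per:
        logger.warning(
            "recording %s: dropping %.1f-s remainder after %d segments",
            recording_id, (n - count * n_per) / fs_hz, count,
        )
    label = assign_label(sbp, threshold)
    return [
        SubSegment(
            subject_id=subject_id,
            recording_id=recording_id,
            parity_index=k + 1,
            t0=t0 + k * seg_len_s,
            fs_hz=fs_hz,
            ppg=np.asarray(ppg[k * n_per:(k + 1) * n_per], dtype=float),
            sbp=sbp,
            label=label,
        )
        for k in range(count)
    ]


@dataclass
class PreprocessedCohort:
    """Labeled recordings plus their 10-s sub-segments after exclusion."""

    segments: list[SubSegment]
    #: one row per surviving recording: recording_id, subject_id, t0, sbp, label
    recordings: pd.DataFrame
    excluded_subjects: list[str] = field(default_factory=list)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "segment_id": s.segment_id,
                    "subject_id": s.subject_id,
                    "recording_id": s.recording_id,
                    "parity_index": s.parity_index,
                    "t0": s.t0,
                    "sbp": s.sbp,
                    "label": s.label,
                }
                for s in self.segments
            ],
            columns=[
                "segment_id", "subject_id", "recording_id", "parity_index",
                "t0", "sbp", "label",
            ],
        )


def label_recordings(cohort: Cohort,
                     threshold: float = SBP_THRESHOLD_MMHG) -> pd.DataFrame:
    """Per-recording SBP and class label from the ABP channel."""
    rows = []
    for rec in cohort.recordings:
        sbp = extract_sbp(rec.abp, rec.fs_hz, rec.recording_id)
        rows.append({
            "recording_id": rec.recording_id,
            "subject_id": rec.subject_id,
            "t0": rec.t0,
            "sbp": sbp,
            "label": assign_label(sbp, threshold),
        })
    return pd.DataFrame(
        rows, columns=["recording_id", "subject_id", "t0", "sbp", "label"]
    )


def exclude_fluctuating(labeled: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop subjects whose recordings carry mixed NTS/HTS labels.

    Returns the surviving rows and the excluded subject ids.
    """
    if labeled.empty:
        return labeled, []
    n_labels = labeled.groupby("subject_id")["label"].nunique()
    excluded = sorted(n_labels[n_labels > 1].index.tolist())
    if excluded:
        logger.info("excluding %d fluctuating subjects: %s",
                    len(excluded), excluded)
    kept = labeled[~labeled["subject_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def preprocess_cohort(
    cohort: Cohort,
    filter_cfg: FilterConfig | None = None,
    threshold: float = SBP_THRESHOLD_MMHG,
) -> PreprocessedCohort:
    """Full preprocessing: label, exclude, filter, downsample, segment."""
    labeled = label_recordings(cohort, threshold)
    kept, excluded = exclude_fluctuating(labeled)
    keep_ids = set(kept["recording_id"])
    sbp_of = dict(zip(labeled["recording_id"], labeled["sbp"]))

    segments: list[SubSegment] = []
    for rec in cohort.recordings:
        if rec.recording_id not in keep_ids:
            continue
        filtered = filter_ppg(rec.ppg, rec.fs_hz, filter_cfg)
        down = downsample_ppg(filtered, rec.fs_hz, TARGET_FS_HZ)
        segments.extend(
            segment_recording(
                down, TARGET_FS_HZ, sbp_of[rec.recording_id],
                rec.subject_id, rec.recording_id, t0=rec.t0,
                threshold=threshold,
            )
        )
    return PreprocessedCohort(segments=segments, recordings=kept,
                              excluded_subjects=excluded)


__all__ = [
    "SBP_THRESHOLD_MMHG", "SEGMENT_LEN_S", "TARGET_FS_HZ",
    "FilterConfig", "SubSegment", "PreprocessedCohort",
    "extract_sbp", "assign_label", "filter_ppg", "downsample_ppg",
    "segment_recording", "label_recordings", "exclude_fluctuating",
    "preprocess_cohort",
]
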