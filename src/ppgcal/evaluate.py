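"""Confusion counts, the four headline statistics and the four-bin
calibration experiment.

HTS is the positive class.  Accuracy, sensitivity, specificity and F1 are
computed per image (10-s sub-segment):

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Se  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    F1  = 2 TP / (2 TP + FP + FN)

F1 is the count form (equivalently the harmonic mean of precision and
recall); the alternative "harmonic mean of Se and Acc" reading sometimes
seen in the clinical literature is exposed as ``f1_se_acc_harmonic`` for
comparison but is not the primary statistic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort import Cohort, NTS, HTS
from .classifier import TrainConfig, build_model, predict, train_model, TrainHistory
from .preprocess import FilterConfig, preprocess_cohort
from .scalogram import RenderConfig, WaveletConfig, render_segments
from .splits import STANDARD_BINS, IntervalBin, build_split, CalibrationSplit

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int  # correctly classified HTS segments
    tn: int  # correctly classified NTS segments
    fp: int  # NTS segments predicted HTS
    fn: int  # HTS segments predicted NTS

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with HTS positive."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    bad = {v for v in set(y_true) | set(y_pred)} - {NTS, HTS}
    if bad:
        raise ValueError(f"unknown labels {bad}")
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == HTS and p == HTS)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == NTS and p == NTS)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == NTS and p == HTS)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == HTS and p == NTS)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class MetricsReport:
    bin_name: str
    n_val: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    f1_se_acc_harmonic: float = math.nan
    epochs: int = 0
    skipped: bool = False

    def as_percent(self) -> dict[str, float]:
        """The four statistics on the 0-100 scale, rounded to two decimals."""
        return {
            k: round(getattr(self, k) * 100.0, 2)
            for k in ("accuracy", "sensitivity", "specificity", "f1")
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        return cls(**json.loads(text))


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator)", name)
        return math.nan
    return num / den


def compute_metrics(c: ConfusionCounts, bin_name: str = "",
                    epochs: int = 0) -> MetricsReport:
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated images")
    acc = (c.tp + c.tn) / c.total
    se = _safe_div(c.tp, c.tp + c.fn, "sensitivity")
    sp = _safe_div(c.tn, c.tn + c.fp, "specificity")
    f1 = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    if math.isnan(se) or (se + acc) == 0:
        f1_alt = math.nan
    else:
        f1_alt = 2 * se * acc / (se + acc)
    return MetricsReport(
        bin_name=bin_name, n_val=c.total, accuracy=acc, sensitivity=se,
        specificity=sp, f1=f1, f1_se_acc_harmonic=f1_alt, epochs=epochs,
    )


@dataclass
class ExperimentResult:
    reports: list[MetricsReport]
    histories: dict[str, TrainHistory]
    accounting: list[dict]
    splits: dict[str, CalibrationSplit]

    def summary(self) -> pd.DataFrame:
        """Per-bin table in the style of the study's results table."""
        rows = []
        for r in self.reports:
            row = {"bin": r.bin_name, "n_val": r.n_val, "epochs": r.epochs,
                   "skipped": r.skipped}
            row.update({k: (round(v * 100, 2) if not r.skipped else math.nan)
                        for k, v in (("acc_pct", r.accuracy),
                                     ("se_pct", r.sensitivity),
                                     ("sp_pct", r.specificity),
                                     ("f1_pct", r.f1))})
            rows.append(row)
        return pd.DataFrame(rows)


def run_experiment(
    cohort: Cohort,
    bins: tuple[IntervalBin, ...] = STANDARD_BINS,
    train_cfg: TrainConfig | None = None,
    filter_cfg: FilterConfig | None = None,
    wavelet_cfg: WaveletConfig | None = None,
    render_cfg: RenderConfig | None = None,
) -> ExperimentResult:
    """The full calibration-interval experiment on one cohort.

    Preprocesses once, renders every scalogram image once, then builds a
    split, trains a fresh model and evaluates validation images for each
    interval bin.  Bins whose validation set is empty are reported as
    skipped.
    """
    train_cfg = train_cfg or TrainConfig()
    pre = preprocess_cohort(cohort, filter_cfg)
    manifest = pre.manifest()
    images = render_segments(pre.segments, wavelet_cfg, render_cfg)

    reports: list[MetricsReport] = []
    histories: dict[str, TrainHistory] = {}
    accounting: list[dict] = []
    splits: dict[str, CalibrationSplit] = {}
    for bin_ in bins:
        split = build_split(manifest, pre.recordings, bin_)
        splits[bin_.name] = split
        accounting.append(split.accounting())
        if split.empty_validation or len(split.train_images) == 0:
            logger.warning("bin %s skipped (empty train or validation)",
                           bin_.name)
            reports.append(MetricsReport(
                bin_name=bin_.name, n_val=0, accuracy=math.nan,
                sensitivity=math.nan, specificity=math.nan, f1=math.nan,
                skipped=True,
            ))
            continue
        model = build_model(train_cfg)
        model, hist = train_model(model, split, train_cfg, images)
        histories[bin_.name] = hist
        X_val = np.stack([images[s] for s in split.val_images["segment_id"]])
        y_pred, _ = predict(model, X_val)
        counts = confusion_counts(split.val_images["label"], y_pred)
        reports.append(compute_metrics(counts, bin_.name,
                                       epochs=hist.epochs_completed))
    return ExperimentResult(reports=reports, histories=histories,
                            accounting=accounting, splits=splits)


__all__ = [
    "ConfusionCounts", "MetricsReport", "ExperimentResult",
    "confusion_counts", "compute_metrics", "run_experiment",
]
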