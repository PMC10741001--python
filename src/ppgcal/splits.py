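"""Calibration-interval train/validation splits.

The experimental design asks how well a classifier works when the labeled
"calibration" measurements of a subject and the measurements being
classified are separated by a given time interval.  For each interval bin
(<1 h, 1-6 h, 6-24 h, >24 h) a subject qualifies if it has a chronological
chain of at least two recordings whose consecutive gaps all fall in the
bin.  Odd chain positions (1st, 3rd, ...) are calibration/training
recordings, even positions are validation; all 12 scalogram images of a
recording follow their recording.  Every image of a subject with no
qualifying chain is added to the training set, which enlarges training
without leaking any validation subject's held-out data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalBin:
    name: str
    lower_s: float  # inclusive
    upper_s: float  # exclusive (inf for the open-ended bin)

    def __post_init__(self) -> None:
        if not self.lower_s < self.upper_s:
            raise ValueError("lower_s must be < upper_s")

    def contains(self, gap_s: float) -> bool:
        return self.lower_s <= gap_s < self.upper_s


HOUR = 3600.0
STANDARD_BINS = (
    IntervalBin("lt1h", 0.0, 1 * HOUR),
    IntervalBin("1to6h", 1 * HOUR, 6 * HOUR),
    IntervalBin("6to24h", 6 * HOUR, 24 * HOUR),
    IntervalBin("gt24h", 24 * HOUR, np.inf),
)
# lower bound of lt1h is exclusive-zero in spirit; simultaneous recordings
# do not occur (timestamps are strictly increasing per subject).


def select_interval_sequence(t0s: np.ndarray | list[float],
                             bin_: IntervalBin) -> list[int]:
    """Longest chronological chain of recording indices whose consecutive
    gaps all fall within the bin.

    ``t0s`` must be sorted ascending.  Recordings may be skipped (the gap is
    measured between consecutive *chosen* recordings).  Ties go to the
    chain that starts earliest, then to the lexicographically smallest index
    sequence.  Chains shorter than 2 mean the subject is unselected; an
    empty list is returned.
    """
    t = np.asarray(t0s, dtype=float)
    n = len(t)
    if n and np.any(np.diff(t) < 0):
        raise ValueError("recordings must be sorted by t0")
    if n < 2:
        return []
    # DP over sorted recordings: best[j] = (length, chain) of the best chain
    # ending at j.  Scanning predecessors in ascending order with a strict
    # improvement test yields the earliest-start, lexicographically smallest
    # optimum among maximal-length chains.
    best: list[list[int]] = [[j] for j in range(n)]
    for j in range(n):
        for i in range(j):
            if bin_.contains(t[j] - t[i]) and len(best[i]) + 1 > len(best[j]):
                best[j] = best[i] + [j]
    chain = max(best, key=len)
    if len(chain) < 2:
        return []
    # among equal-length chains prefer the earliest start then smallest seq
    cands = [c for c in best if len(c) == len(chain)]
    return min(cands)


@dataclass
class CalibrationSplit:
    bin: IntervalBin
    train_images: pd.DataFrame
    val_images: pd.DataFrame
    selected_subjects: list[str] = field(default_factory=list)
    unselected_subjects: list[str] = field(default_factory=list)
    #: per-subject qualifying chain as recording_ids
    chains: dict[str, list[str]] = field(default_factory=dict)

    @property
    def empty_validation(self) -> bool:
        return len(self.val_images) == 0

    def accounting(self) -> dict:
        """Split accounting in the three-column style of the study table:
        odd (calibration) segments, not-selected subjects' segments, even
        (validation) segments."""
        sel = set(self.selected_subjects)
        odd = int((self.train_images["subject_id"].isin(sel)).sum())
        not_sel = int(len(self.train_images) - odd)
        return {
            "bin": self.bin.name,
            "odd_segments": odd,
            "not_selected_segments": not_sel,
            "even_segments": int(len(self.val_images)),
            "n_selected_subjects": len(sel),
            "n_unselected_subjects": len(self.unselected_subjects),
        }


def build_split(image_manifest: pd.DataFrame,
                recordings: pd.DataFrame,
                bin_: IntervalBin) -> CalibrationSplit:
    """Assemble the train/validation image manifests for one interval bin.

    ``image_manifest`` needs columns segment_id, subject_id, recording_id,
    label; ``recordings`` needs recording_id, subject_id, t0.  Recordings of
    a selected subject that are not on its qualifying chain are used in
    neither set.
    """
    required = {"segment_id", "subject_id", "recording_id", "label"}
    if not required.issubset(image_manifest.columns):
        raise ValueError(f"image manifest missing {required - set(image_manifest.columns)}")

    train_rec_ids: set[str] = set()
    val_rec_ids: set[str] = set()
    selected: list[str] = []
    unselected: list[str] = []
    chains: dict[str, list[str]] = {}

    for sid, grp in recordings.groupby("subject_id", sort=True):
        grp = grp.sort_values("t0")
        chain_idx = select_interval_sequence(grp["t0"].to_numpy(), bin_)
        rec_ids = grp["recording_id"].to_list()
        if chain_idx:
            selected.append(sid)
            chain = [rec_ids[i] for i in chain_idx]
            chains[sid] = chain
            for pos, rid in enumerate(chain, start=1):  # 1-based parity
                (train_rec_ids if pos % 2 == 1 else val_rec_ids).add(rid)
        else:
            unselected.append(sid)
            train_rec_ids.update(rec_ids)

    in_train = image_manifest["recording_id"].isin(train_rec_ids)
    in_val = image_manifest["recording_id"].isin(val_rec_ids)
    split = CalibrationSplit(
        bin=bin_,
        train_images=image_manifest[in_train].reset_index(drop=True),
        val_images=image_manifest[in_val].reset_index(drop=True),
        selected_subjects=selected,
        unselected_subjects=unselected,
        chains=chains,
    )
    if split.empty_validation:
        logger.warning("bin %s: no selected subjects; validation set is empty",
                       bin_.name)
    return split


def write_split(split: CalibrationSplit, path) -> None:
    """Split manifest CSV with a set column, plus a JSON accounting file."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    train = split.train_images.assign(set="train")
    val = split.val_images.assign(set="val")
    cols = ["set", "segment_id", "subject_id", "recording_id", "label"]
    pd.concat([train, val])[cols].to_csv(
        path / f"split_{split.bin.name}.csv", index=False
    )
    (path / f"accounting_{split.bin.name}.json").write_text(
        json.dumps(split.accounting(), indent=2)
    )


__all__ = [
    "HOUR", "IntervalBin", "STANDARD_BINS", "CalibrationSplit",
    "select_interval_sequence", "build_split", "write_split",
]
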