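"""Calibration-interval chain selection and train/validation assembly."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from ppgcal import (
    HOUR, IntervalBin, STANDARD_BINS, build_split, select_interval_sequence,
)

LT1H = STANDARD_BINS[0]
GT24H = STANDARD_BINS[3]


def brute_force_longest_chain(t0s, bin_):
    """Oracle: enumerate every subsequence and keep the longest whose
    consecutive gaps all fall inside the bin (earliest start, then
    lexicographically smallest, on ties)."""
    n = len(t0s)
    best = []
    for r in range(2, n + 1):
        for comb in itertools.combinations(range(n), r):
            gaps = [t0s[b] - t0s[a] for a, b in zip(comb, comb[1:])]
            if all(bin_.contains(g) for g in gaps):
                if len(comb) > len(best) or (
                        len(comb) == len(best) and list(comb) < list(best)):
                    best = list(comb)
    return best


def test_standard_bins_partition_positive_axis():
    edges = [b.lower_s for b in STANDARD_BINS] + [STANDARD_BINS[-1].upper_s]
    assert edges == [0.0, HOUR, 6 * HOUR, 24 * HOUR, np.inf]
    for gap in [1.0, 3599.0, 3600.0, 5 * HOUR, 23 * HOUR, 100 * HOUR]:
        assert sum(b.contains(gap) for b in STANDARD_BINS) == 1


def test_invalid_bin_rejected():
    with pytest.raises(ValueError):
        IntervalBin("bad", 10.0, 10.0)


class TestChainSelection:
    def test_uniform_half_hour_chain_of_four(self):
        t = np.array([0, 30, 60, 90]) * 60.0
        assert select_interval_sequence(t, LT1H) == [0, 1, 2, 3]

    def test_single_recording_unselected(self):
        assert select_interval_sequence([0.0], LT1H) == []

    def test_gap_outside_bin_unselected(self):
        assert select_interval_sequence([0.0, 10 * HOUR], LT1H) == []

    def test_skipping_allowed(self):
        # 0 and 30 h bracket a 12 h recording; only the skip chain qualifies
        t = np.array([0.0, 12 * HOUR, 30 * HOUR])
        assert select_interval_sequence(t, GT24H) == [0, 2]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            select_interval_sequence([10.0, 5.0], LT1H)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        t = np.sort(rng.uniform(0, 80 * HOUR, n))
        for bin_ in STANDARD_BINS:
            got = select_interval_sequence(t, bin_)
            expected = brute_force_longest_chain(list(t), bin_)
            assert got == expected, f"bin {bin_.name}: {got} vs {expected}"


def _image_manifest(recordings, images_per_recording=12):
    rows = []
    for rid, sid, label in recordings:
        for k in range(1, images_per_recording + 1):
            rows.append({"segment_id": f"{rid}_s{k:02d}", "subject_id": sid,
                         "recording_id": rid, "label": label})
    return pd.DataFrame(rows)


class TestBuildSplit:
    def test_selected_plus_unselected_accounting(self):
        recs = pd.DataFrame({
            "recording_id": ["a1", "a2", "a3", "a4", "b1", "b2"],
            "subject_id": ["a"] * 4 + ["b"] * 2,
            "t0": [0, 1800, 3600, 5400, 0, 10 * HOUR],
        })
        man = _image_manifest([
            ("a1", "a", "NTS"), ("a2", "a", "NTS"), ("a3", "a", "NTS"),
            ("a4", "a", "NTS"), ("b1", "b", "HTS"), ("b2", "b", "HTS"),
        ])
        split = build_split(man, recs, LT1H)
        # odd chain positions (a1, a3) + both unselected b recordings train;
        # even positions (a2, a4) validate
        assert len(split.train_images) == 48
        assert len(split.val_images) == 24
        acc = split.accounting()
        assert acc["odd_segments"] == 24
        assert acc["not_selected_segments"] == 24
        assert acc["even_segments"] == 24

    def test_two_recording_chain_no_unselected(self):
        recs = pd.DataFrame({"recording_id": ["a1", "a2"],
                             "subject_id": ["a", "a"], "t0": [0.0, 1800.0]})
        man = _image_manifest([("a1", "a", "NTS"), ("a2", "a", "NTS")])
        split = build_split(man, recs, LT1H)
        assert len(split.train_images) == 12 and len(split.val_images) == 12

    def test_no_leakage(self, small_cohort):
        from ppgcal import preprocess_cohort
        pre = preprocess_cohort(small_cohort)
        man = pre.manifest()
        for bin_ in STANDARD_BINS:
            split = build_split(man, pre.recordings, bin_)
            train_ids = set(split.train_images["segment_id"])
            val_ids = set(split.val_images["segment_id"])
            assert not train_ids & val_ids
            # no unselected subject contributes validation images
            assert not set(split.val_images["subject_id"]) & \
                set(split.unselected_subjects)
            assert len(train_ids) + len(val_ids) <= len(man)

    def test_parity_brute_force_rederivation(self, small_cohort):
        """Position parity in each qualifying chain fully determines set
        membership for the selected subjects' recordings."""
        from ppgcal import preprocess_cohort
        pre = preprocess_cohort(small_cohort)
        man = pre.manifest()
        split = build_split(man, pre.recordings, LT1H)
        for sid, chain in split.chains.items():
            for pos, rid in enumerate(chain, start=1):
                frame = split.train_images if pos % 2 == 1 else split.val_images
                other = split.val_images if pos % 2 == 1 else split.train_images
                assert (frame["recording_id"] == rid).sum() == 12
                assert (other["recording_id"] == rid).sum() == 0

    def test_calibration_betweenness(self, small_cohort):
        """Interior validation recordings sit chronologically between two
        calibration (training) recordings of the same subject."""
        from ppgcal import preprocess_cohort
        pre = preprocess_cohort(small_cohort)
        t0 = dict(zip(pre.recordings["recording_id"], pre.recordings["t0"]))
        split = build_split(pre.manifest(), pre.recordings, LT1H)
        for sid, chain in split.chains.items():
            for pos in range(2, len(chain), 2):  # even, with a successor
                if pos < len(chain):
                    assert t0[chain[pos - 2]] < t0[chain[pos - 1]] < t0[chain[pos]]

    def test_empty_validation_flagged_not_crash(self, caplog):
        recs = pd.DataFrame({"recording_id": ["a1", "a2"],
                             "subject_id": ["a", "a"], "t0": [0.0, 1800.0]})
        man = _image_manifest([("a1", "a", "NTS"), ("a2", "a", "NTS")])
        with caplog.at_level(logging.WARNING, logger="ppgcal.splits"):
            split = build_split(man, recs, GT24H)
        assert split.empty_validation
        assert len(split.train_images) == 24  # everything trains
        assert any("empty" in m for m in caplog.messages)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_split(pd.DataFrame({"segment_id": []}),
                        pd.DataFrame({"recording_id": [], "subject_id": [],
                                      "t0": []}), LT1H)
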