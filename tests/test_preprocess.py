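"""SBP labeling, filtering, decimation, segmentation and exclusion rules."""

import logging

import numpy as np
import pytest
from scipy import signal as sps

from ppgcal import (
    FilterConfig, assign_label, downsample_ppg, exclude_fluctuating,
    extract_sbp, filter_ppg, preprocess_cohort, segment_recording,
)
import pandas as pd


def _abp_with_peaks(peak_values, fs=125.0, period_s=0.8):
    """ABP-like series of Gaussian pulses whose maxima hit peak_values."""
    n_per = int(period_s * fs)
    tau = np.arange(n_per) / fs
    pulse = np.exp(-0.5 * ((tau - period_s / 2) / 0.08) ** 2)
    pulse /= pulse.max()
    out = []
    for v in peak_values:
        out.append(80.0 + (v - 80.0) * pulse)
    return np.concatenate(out)


class TestExtractSbp:
    def test_constant_peaks(self):
        abp = _abp_with_peaks([140.0] * 20)
        assert extract_sbp(abp, 125.0) == pytest.approx(140.0, abs=1e-9)

    def test_alternating_peaks_mean(self):
        abp = _abp_with_peaks([120.0, 130.0] * 10)
        assert extract_sbp(abp, 125.0) == pytest.approx(125.0, abs=1e-9)

    def test_recovers_generator_ground_truth(self):
        from ppgcal import CohortConfig, generate_cohort
        cfg = CohortConfig(n_nts_subjects=1, n_hts_subjects=0,
                           recordings_per_subject=1,
                           sbp_range_nts=(115.0, 115.0), seed=17)
        rec = generate_cohort(cfg).recordings[0]
        assert extract_sbp(rec.abp, rec.fs_hz) == pytest.approx(115.0, abs=2.0)

    def test_no_peaks_names_recording(self):
        with pytest.raises(ValueError, match="rec_x"):
            extract_sbp(np.full(1000, 90.0), 125.0, recording_id="rec_x")


@pytest.mark.parametrize(
    "sbp,expected",
    [(129.9, "NTS"), (131.0, "HTS"), (130.0, "NTS"), (100.0, "NTS"),
     (165.0, "HTS")],
)
def test_assign_label_threshold(sbp, expected):
    assert assign_label(sbp) == expected


def test_assign_label_rejects_nonfinite():
    with pytest.raises(ValueError):
        assign_label(float("nan"))


class TestFilter:
    fs = 125.0

    def test_dc_removed(self):
        y = filter_ppg(np.full(4000, 5.0), self.fs)
        assert np.max(np.abs(y)) < 1e-3 * 5.0

    def test_passband_amplitude_matches_response(self):
        """Oracle: the designed filter's magnitude response at 5 Hz
        (squared, since zero-phase filtering applies it twice)."""
        cfg = FilterConfig()
        t = np.arange(8000) / self.fs
        x = np.sin(2 * np.pi * 5.0 * t)
        y = filter_ppg(x, self.fs, cfg)
        w, h = sps.sosfreqz(cfg.sos(self.fs), worN=[5.0], fs=self.fs)
        expected = np.abs(h[0]) ** 2
        measured = np.max(np.abs(y[2000:6000]))
        assert measured == pytest.approx(expected, rel=0.02)
        # the 10 Hz stopband edge shades 5 Hz slightly; the tone survives
        assert measured > 0.7

    def test_stopband_attenuation(self):
        cfg = FilterConfig()
        t = np.arange(8000) / self.fs
        x = np.sin(2 * np.pi * 20.0 * t)
        y = filter_ppg(x, self.fs, cfg)
        w, h = sps.sosfreqz(cfg.sos(self.fs), worN=[20.0], fs=self.fs)
        bound = np.abs(h[0]) ** 2
        measured = np.max(np.abs(y[2000:6000]))
        assert measured <= bound * 1.1
        assert measured < 10 ** (-cfg.stopband_atten_db / 20)

    def test_linearity(self, rng):
        x = rng.normal(size=3000)
        y1 = filter_ppg(3.5 * x, self.fs)
        y2 = 3.5 * filter_ppg(x, self.fs)
        np.testing.assert_allclose(y1, y2, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            filter_ppg(np.zeros(100), 15.0, FilterConfig(high_cut_hz=10.0))


class TestDownsample:
    def test_length_divided_by_five(self):
        assert len(downsample_ppg(np.zeros(15000))) == 3000

    def test_sinusoid_matches_closed_form(self):
        t125 = np.arange(1250) / 125.0
        x = np.sin(2 * np.pi * 1.0 * t125)
        y = downsample_ppg(x)
        t25 = np.arange(250) / 25.0
        np.testing.assert_allclose(y, np.sin(2 * np.pi * 1.0 * t25), atol=1e-6)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample_ppg(np.zeros(100), 125.0, 24.0)


class TestSegmentation:
    def test_120s_gives_12_segments(self):
        segs = segment_recording(np.zeros(3000), 25.0, 120.0, "s", "r")
        assert len(segs) == 12
        assert [s.parity_index for s in segs] == list(range(1, 13))
        assert all(len(s.ppg) == 250 for s in segs)
        assert all(s.label == "NTS" and s.sbp == 120.0 for s in segs)

    def test_10s_gives_one_segment(self):
        assert len(segment_recording(np.zeros(250), 25.0, 140.0, "s", "r")) == 1

    def test_remainder_dropped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="ppgcal.preprocess"):
            segs = segment_recording(np.zeros(3125), 25.0, 120.0, "s", "r")
        assert len(segs) == 12
        assert any("remainder" in m for m in caplog.messages)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_recording(np.zeros(100), 25.0, 120.0, "s", "r")

    def test_roundtrip_concatenation(self, rng):
        x = rng.normal(size=3000)
        segs = segment_recording(x, 25.0, 120.0, "s", "r")
        np.testing.assert_array_equal(np.concatenate([s.ppg for s in segs]), x)


class TestExclusion:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["recording_id", "subject_id",
                                           "t0", "sbp", "label"])

    def test_homogeneous_subject_retained(self):
        t = self._table([("r1", "a", 0, 120, "NTS"), ("r2", "a", 1, 121, "NTS"),
                         ("r3", "a", 2, 119, "NTS")])
        kept, excluded = exclude_fluctuating(t)
        assert excluded == [] and len(kept) == 3

    def test_mixed_subject_excluded(self):
        t = self._table([("r1", "a", 0, 120, "NTS"), ("r2", "a", 1, 140, "HTS"),
                         ("r3", "b", 0, 150, "HTS")])
        kept, excluded = exclude_fluctuating(t)
        assert excluded == ["a"]
        assert set(kept["subject_id"]) == {"b"}

    def test_empty_cohort(self):
        kept, excluded = exclude_fluctuating(self._table([]))
        assert excluded == [] and kept.empty


def test_pipeline_count_identity_and_label_stability(small_cohort):
    pre = preprocess_cohort(small_cohort)
    assert len(pre.segments) == 12 * len(pre.recordings)
    man = pre.manifest()
    assert (man.groupby("subject_id")["label"].nunique() == 1).all()
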