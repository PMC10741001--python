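import numpy as np
import pytest

from ppgcal import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 NTS + 3 HTS subjects, 3 recordings each, 30-min spacing."""
    cfg = CohortConfig(
        n_nts_subjects=4, n_hts_subjects=3, recordings_per_subject=3,
        timestamp_schedule="uniform", timestamp_gap_s=1800.0, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_band_images(n, cls, rng, size=224):
    """Synthetic scalogram-like images: a bright horizontal band in the top
    half (cls=1) or bottom half (cls=0), plus pixel noise."""
    imgs = np.zeros((n, size, size, 3), dtype=np.uint8)
    row0 = size // 8 if cls == 1 else 5 * size // 8
    for i in range(n):
        img = rng.integers(0, 40, (size, size, 3))
        r = row0 + int(rng.integers(-8, 9))
        img[r:r + 24, :, :] = rng.integers(180, 255, (24, size, 3))
        imgs[i] = img.astype(np.uint8)
    return imgs
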