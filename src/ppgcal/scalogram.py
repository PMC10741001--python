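"""Continuous wavelet transform scalograms of PPG sub-segments.

Implements the analytic generalized Morse wavelet family in the frequency
domain,

    psi_hat(w) = 2 * (w / w_p)^beta * exp((beta/gamma) * (1 - (w/w_p)^gamma)),
    w > 0,   w_p = (beta / gamma)^(1/gamma),

normalized to a peak value of 2 at the wavelet's peak (angular) frequency
w_p.  The defaults are the (gamma, P^2) = (3, 60) member, i.e. beta =
P^2 / gamma = 20, sampled at 12 voices per octave.  For a unit sinusoid the
coefficient magnitude near the matching scale is then ~1, and the row of
maximal energy sits at the tone's frequency, which is what the tests pin.

The cone of influence (COI) is derived from the numerically measured
one-sided e-folding time of the mother wavelet's envelope: coefficients at
frequency f within C/f seconds of either edge are boundary-contaminated,
where C is the e-folding time expressed in periods of the peak frequency.

Rendering maps |coefficients|, min-max normalized per image, through a
fixed colormap, resizes bilinearly to 224 x 224 RGB, and overdraws the COI
as one-pixel white lines.  No axes, ticks or margins are rendered.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

IMAGE_SIZE = 224
WHITE = (255, 255, 255)


@dataclass(frozen=True)
class WaveletConfig:
    gamma: float = 3.0
    time_bandwidth: float = 60.0  # P^2 = beta * gamma
    voices_per_octave: int = 12
    #: frequency limits in Hz; None = automatic (2/T .. fs/2)
    f_min_hz: float | None = None
    f_max_hz: float | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.time_bandwidth <= self.gamma:
            raise ValueError("time_bandwidth must exceed gamma")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma

    @property
    def peak_omega(self) -> float:
        return (self.beta / self.gamma) ** (1.0 / self.gamma)


def morse_psi_hat(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Frequency-domain Morse wavelet, peak-normalized to 2, zero for w<=0."""
    omega = np.asarray(omega, dtype=float)
    wp = (beta / gamma) ** (1.0 / gamma)
    out = np.zeros_like(omega)
    pos = omega > 0
    x = omega[pos] / wp
    out[pos] = 2.0 * np.exp(beta * np.log(x) + (beta / gamma) * (1.0 - x ** gamma))
    return out


@lru_cache(maxsize=8)
def _coi_periods(gamma: float, beta: float) -> float:
    """One-sided e-folding time of the mother wavelet envelope, in periods
    of the peak frequency (computed once numerically per (gamma, beta))."""
    n = 1 << 14
    wp = (beta / gamma) ** (1.0 / gamma)
    dt = (2.0 * np.pi / wp) / 64.0  # 64 samples per peak-frequency period
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=dt)
    psi_t = np.fft.ifft(morse_psi_hat(omega, gamma, beta)) / dt
    env = np.abs(psi_t)
    target = env[0] / np.e
    # first crossing on the positive-time side
    idx = np.argmax(env[: n // 2] < target)
    t_e = idx * dt
    return float(t_e * wp / (2.0 * np.pi))


@dataclass
class Scalogram:
    magnitudes: np.ndarray  # (n_scales, n_samples), >= 0
    freqs_hz: np.ndarray  # per-row center frequency, descending
    coi_hz: np.ndarray  # per-column COI frequency boundary
    segment_id: str = ""


def compute_cwt(ppg: np.ndarray, fs_hz: float,
                cfg: WaveletConfig | None = None,
                segment_id: str = "") -> Scalogram:
    """Morse CWT magnitude of a PPG window.

    The signal is symmetrically extended by half its length on each side
    before the FFT-domain transform; the COI marks what extension cannot
    fix.  Column count equals the input length.
    """
    cfg = cfg or WaveletConfig()
    x = np.asarray(ppg, dtype=float)
    if len(x) < 2:
        raise ValueError("input must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    n = len(x)

    f_max = cfg.f_max_hz if cfg.f_max_hz is not None else fs_hz / 2.0
    f_min = cfg.f_min_hz if cfg.f_min_hz is not None else 2.0 * fs_hz / n
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    n_octaves = np.log2(f_max / f_min)
    n_freqs = int(np.floor(n_octaves * cfg.voices_per_octave)) + 1
    freqs = f_max * 2.0 ** (-np.arange(n_freqs) / cfg.voices_per_octave)

    pad = n // 2
    xe = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]]) if pad else x
    ne = len(xe)
    xhat = np.fft.fft(xe)
    omega = 2.0 * np.pi * np.fft.fftfreq(ne, d=1.0 / fs_hz)

    wp = cfg.peak_omega
    mags = np.empty((n_freqs, n), dtype=float)
    for k, f in enumerate(freqs):
        scale = wp / (2.0 * np.pi * f)
        w = np.fft.ifft(xhat * morse_psi_hat(scale * omega, cfg.gamma, cfg.beta))
        mags[k] = np.abs(w[pad:pad + n])
    # peak value 2 of psi_hat compensates the halved spectrum of a real
    # tone, so a unit sinusoid yields magnitude ~1 at the matching row

    coi_c = _coi_periods(cfg.gamma, cfg.beta)
    t = np.arange(n) / fs_hz
    dist_to_edge = np.minimum(t, t[::-1]) + 0.5 / fs_hz
    coi_hz = np.minimum(coi_c / dist_to_edge, f_max)
    return Scalogram(magnitudes=mags, freqs_hz=freqs, coi_hz=coi_hz,
                     segment_id=segment_id)


@dataclass
class RenderConfig:
    colormap: str = "viridis"
    log_scale: bool = False
    size: int = IMAGE_SIZE


@dataclass
class ScalogramImage:
    pixels: np.ndarray  # (size, size, 3) uint8
    segment_id: str = ""

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)


def render_scalogram(s: Scalogram,
                     render_cfg: RenderConfig | None = None) -> ScalogramImage:
    """Render a scalogram to a 224 x 224 x 3 image.

    Row 0 of the magnitude matrix (highest frequency) becomes the top of the
    image, so low frequencies sit at the bottom.  Rendering is invariant to
    the overall magnitude scale (per-image min-max normalization), and the
    COI is overdrawn in pure white after resizing so the trace stays exactly
    one pixel wide.
    """
    cfg = render_cfg or RenderConfig()
    mags = np.asarray(s.magnitudes, dtype=float)
    if mags.size == 0:
        raise ValueError("empty scalogram")
    if cfg.log_scale:
        mags = np.log1p(mags)
    lo, hi = mags.min(), mags.max()
    norm = (mags - lo) / (hi - lo) if hi > lo else np.zeros_like(mags)

    cmap = colormaps[cfg.colormap]
    rgb = (cmap(norm)[..., :3] * 255).astype(np.uint8)
    img = Image.fromarray(rgb, mode="RGB").resize(
        (cfg.size, cfg.size), resample=Image.BILINEAR
    )
    pixels = np.asarray(img).copy()

    # COI trace: map each output column's time to the nearest frequency row
    n_cols_native = mags.shape[1]
    log_f = np.log2(s.freqs_hz)  # descending
    f_top, f_bot = log_f[0], log_f[-1]
    for col in range(cfg.size):
        native_t = (col + 0.5) * n_cols_native / cfg.size - 0.5
        i = int(np.clip(round(native_t), 0, n_cols_native - 1))
        f_coi = s.coi_hz[i]
        if f_coi <= 0 or np.log2(f_coi) < f_bot or np.log2(f_coi) > f_top:
            continue  # boundary frequency outside the rendered band
        frac = (f_top - np.log2(f_coi)) / (f_top - f_bot)
        row = int(np.clip(round(frac * (cfg.size - 1)), 0, cfg.size - 1))
        pixels[row, col] = WHITE
    return ScalogramImage(pixels=pixels, segment_id=s.segment_id)


def render_segments(segments, wavelet_cfg: WaveletConfig | None = None,
                    render_cfg: RenderConfig | None = None
                    ) -> dict[str, np.ndarray]:
    """Scalogram images for a list of SubSegments, keyed by segment id."""
    images: dict[str, np.ndarray] = {}
    for seg in segments:
        sc = compute_cwt(seg.ppg, seg.fs_hz, wavelet_cfg, seg.segment_id)
        images[seg.segment_id] = render_scalogram(sc, render_cfg).pixels
    return images


def write_images(images: dict[str, np.ndarray], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for seg_id, px in images.items():
        Image.fromarray(px, mode="RGB").save(out / f"{seg_id}.png")


__all__ = [
    "IMAGE_SIZE", "WaveletConfig", "Scalogram", "RenderConfig",
    "ScalogramImage", "morse_psi_hat", "compute_cwt", "render_scalogram",
    "render_segments", "write_images",
]
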