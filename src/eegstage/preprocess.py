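"""Rate normalisation and stationary-wavelet denoising.

The cleaning model: clinically useful EEG content lives in 0.5-32 Hz.
Everything below 0.5 Hz (DC offset, electrode drift) and everything above
32 Hz (muscle bursts, 50 Hz mains and its neighbourhood) is treated as
artifact. At 256 Hz an 8-level stationary wavelet transform tiles the
spectrum dyadically so that the final approximation is exactly 0-0.5 Hz and
the two finest detail levels are 64-128 and 32-64 Hz; zeroing those three
bands and reconstructing removes both artifact families at once. ``sym9``
(Symlet family) is the decomposition basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import resample_poly

from .io import Recording
from .montage import TARGET_FS

__all__ = ["DenoiseConfig", "QualityReport", "downsample", "swt_denoise", "mse", "psnr"]


@dataclass(frozen=True)
class DenoiseConfig:
    """Stationary-wavelet denoiser settings.

    Parameters
    ----------
    wavelet_name
        Wavelet basis (Symlet ``sym9`` by default).
    n_levels
        Decomposition depth. At 256 Hz, 8 levels put the final
        approximation at 0-0.5 Hz exactly (256 / 2**9).
    kill_low
        Zero the final approximation (DC / baseline drift band).
    kill_high_levels
        Number of finest detail levels zeroed; the default 2 removes
        64-128 Hz and 32-64 Hz.
    """

    wavelet_name: str = "sym9"
    n_levels: int = 8
    kill_low: bool = True
    kill_high_levels: int = 2

    def __post_init__(self) -> None:
        if not (self.n_levels >= self.kill_high_levels >= 0):
            raise ValueError("need n_levels >= kill_high_levels >= 0")
        if self.kill_low and TARGET_FS / 2 ** (self.n_levels + 1) > 0.5:
            raise ValueError(
                "n_levels too shallow: the approximation band would extend "
                "above 0.5 Hz and removing it would delete signal"
            )


@dataclass(frozen=True)
class QualityReport:
    """Raw-vs-denoised quality: PSNR in dB and MSE in µV²."""

    psnr: float
    mse: float


def downsample(rec: Recording, target_fs: int = TARGET_FS) -> Recording:
    """Anti-aliased polyphase down-sampling to ``target_fs`` (256 Hz).

    Output length is ``floor(n_samples / factor)``; recordings already at
    the target rate are returned unchanged.
    """
    if target_fs != TARGET_FS:
        raise ValueError(f"target rate is fixed at {TARGET_FS} Hz")
    if rec.fs == target_fs:
        return rec
    if rec.fs % target_fs != 0:
        raise ValueError(f"cannot down-sample {rec.fs} Hz by a non-integer factor")
    factor = rec.fs // target_fs
    out_len = rec.n_samples // factor
    # polyphase FIR low-pass at the new Nyquist, then rate reduction;
    # resample_poly rounds the length up, so trim to the floor contract
    out = resample_poly(rec.data, up=1, down=factor, axis=0)[:out_len]
    return rec.with_data(out, fs=target_fs)


def _swt_denoise_1d(x: np.ndarray, cfg: DenoiseConfig) -> np.ndarray:
    n = x.shape[0]
    block = 2 ** cfg.n_levels
    padded_len = int(math.ceil(n / block)) * block
    if padded_len != n:
        x = np.pad(x, (0, padded_len - n), mode="symmetric")
    coeffs = pywt.swt(x, cfg.wavelet_name, level=cfg.n_levels, trim_approx=True, norm=True)
    # coeffs = [cA_n, cD_n, ..., cD_1]; the last entries are the finest details
    if cfg.kill_low:
        coeffs[0] = np.zeros_like(coeffs[0])
    for k in range(cfg.kill_high_levels):
        coeffs[-1 - k] = np.zeros_like(coeffs[-1 - k])
    out = pywt.iswt(coeffs, cfg.wavelet_name, norm=True)
    return out[:n]


def swt_denoise(rec: Recording, cfg: DenoiseConfig | None = None) -> Recording:
    """Remove the 0-0.5 Hz and (by default) 32-128 Hz bands per channel.

    Each channel is symmetric-padded to a multiple of ``2**n_levels``,
    decomposed with an undecimated wavelet transform, band-zeroed,
    reconstructed and truncated back to the original length.
    """
    cfg = cfg or DenoiseConfig()
    if rec.fs != TARGET_FS:
        raise ValueError("denoising expects a 256 Hz recording; down-sample first")
    filt_len = pywt.Wavelet(cfg.wavelet_name).dec_len
    if rec.n_samples < filt_len:
        raise ValueError(
            f"recording too short for {cfg.wavelet_name}: {rec.n_samples} samples "
            f"< filter support {filt_len}"
        )
    out = np.empty_like(rec.data)
    for ch in range(rec.data.shape[1]):
        out[:, ch] = _swt_denoise_1d(rec.data[:, ch], cfg)
    return rec.with_data(out)


def _paired(raw: Recording | np.ndarray, clean: Recording | np.ndarray):
    a = raw.data if isinstance(raw, Recording) else np.asarray(raw, dtype=float)
    b = clean.data if isinstance(clean, Recording) else np.asarray(clean, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(raw: Recording | np.ndarray, clean: Recording | np.ndarray) -> float:
    """Mean squared difference over all channels and samples (µV²)."""
    a, b = _paired(raw, clean)
    return float(np.mean((a - b) ** 2))


def psnr(raw: Recording | np.ndarray, clean: Recording | np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB.

    The peak is the maximum absolute amplitude of ``raw``; identical inputs
    give ``inf``.
    """
    a, b = _paired(raw, clean)
    peak = float(np.max(np.abs(a)))
    if peak == 0.0:
        raise ValueError("PSNR undefined: raw signal is identically zero")
    err = float(np.mean((a - b) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / err)


def quality(raw: Recording | np.ndarray, clean: Recording | np.ndarray) -> QualityReport:
    return QualityReport(psnr=psnr(raw, clean), mse=mse(raw, clean))
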