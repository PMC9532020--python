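"""Morlet-wavelet time-frequency tensors: the network's input representation.

Each 1-s, 19-channel segment becomes a Z-scored 19 x 45 x 100 power tensor:

* 45 log-spaced frequencies from 0.5 to 45 Hz;
* a complex Morlet wavelet per frequency, its Gaussian envelope specified by
  a full-width-at-half-maximum (FWHM) that shrinks log-spaced from 1.2 s at
  the lowest frequency to 0.2 s at the highest, i.e. finer time resolution at
  higher frequencies;
* power = squared magnitude of the complex convolution, computed over the
  whole recording (a 1.2-s-FWHM wavelet has no support inside an isolated 1-s
  excerpt), then polyphase-resampled along time to 100 Hz and sliced into
  100-sample windows on the 0.5-s onset grid;
* finally each segment's tensor is Z-scored jointly over all channels,
  frequencies and time points.

Wavelets are amplitude-normalized so that a unit-amplitude sinusoid at a
bin's centre frequency yields unit peak power in that bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, NormalizationError, SignalLengthError
from .io import Recording

__all__ = [
    "TFGrid",
    "build_grid",
    "morlet_wavelet",
    "morlet_power",
    "resample_to_100hz",
    "znormalize",
    "recording_tensors",
]

N_FREQS = 45
F_MIN, F_MAX = 0.5, 45.0
FWHM_MAX, FWHM_MIN = 1.2, 0.2
TARGET_HZ = 100


@dataclass(frozen=True)
class TFGrid:
    """Paired frequency / FWHM axes of the time-frequency decomposition."""

    freqs_hz: np.ndarray
    fwhm_s: np.ndarray

    def __post_init__(self):
        if len(self.freqs_hz) != len(self.fwhm_s):
            raise ConfigError("freqs and fwhm must pair index-wise")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ConfigError("frequencies must be strictly increasing")
        if np.any(np.diff(self.fwhm_s) >= 0):
            raise ConfigError("FWHM values must be strictly decreasing")


def build_grid() -> TFGrid:
    """The canonical 45-point grid: 0.5-45 Hz, FWHM 1.2 s down to 0.2 s,
    both geometrically spaced."""
    return TFGrid(
        freqs_hz=np.geomspace(F_MIN, F_MAX, N_FREQS),
        fwhm_s=np.geomspace(FWHM_MAX, FWHM_MIN, N_FREQS),
    )


def morlet_wavelet(freq_hz: float, fwhm_s: float, sr: float) -> np.ndarray:
    """Complex Morlet wavelet: ``exp(i 2 pi f t) * exp(-4 ln2 t^2 / h^2)``.

    The envelope's FWHM is ``h = fwhm_s``; support is truncated at +-2h
    (beyond 4.7 Gaussian SDs).  Amplitude-normalized so convolution with a
    unit sinusoid at ``freq_hz`` peaks at unit magnitude.
    """
    half = int(np.ceil(2.0 * fwhm_s * sr))
    t = np.arange(-half, half + 1) / sr
    envelope = np.exp(-4.0 * np.log(2.0) * t**2 / fwhm_s**2)
    wavelet = np.exp(2j * np.pi * freq_hz * t) * envelope
    return 2.0 * wavelet / envelope.sum()


def morlet_power(
    signal: np.ndarray, grid: TFGrid, sr: float, engine: str = "fft"
) -> np.ndarray:
    """Wavelet power of a (channels, samples) signal: (channels, n_freqs, samples).

    ``engine='fft'`` multiplies in the frequency domain (one FFT per channel
    and per wavelet); ``engine='direct'`` uses time-domain convolution and
    exists as a slow cross-check.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_ch, n_samp = signal.shape
    longest = int(np.ceil(2.0 * grid.fwhm_s.max() * sr)) * 2 + 1
    if n_samp < longest // 2:
        raise SignalLengthError(
            f"{n_samp} samples cannot support a wavelet of {longest} samples"
        )
    out = np.empty((n_ch, len(grid.freqs_hz), n_samp), dtype=np.float32)
    if engine == "direct":
        for fi, (f, h) in enumerate(zip(grid.freqs_hz, grid.fwhm_s)):
            w = morlet_wavelet(f, h, sr)
            half = (len(w) - 1) // 2
            for ci in range(n_ch):
                conv = np.convolve(signal[ci], w)  # full, then centre-crop
                out[ci, fi] = np.abs(conv[half : half + n_samp]) ** 2
        return out
    if engine != "fft":
        raise ConfigError(f"unknown engine {engine!r}")

    max_len = int(np.ceil(2.0 * grid.fwhm_s.max() * sr)) * 2 + 1
    nfft = _next_fast_len(n_samp + max_len - 1)
    sig_f = np.fft.fft(signal, n=nfft, axis=1)
    for fi, (f, h) in enumerate(zip(grid.freqs_hz, grid.fwhm_s)):
        w = morlet_wavelet(f, h, sr)
        half = (len(w) - 1) // 2
        w_f = np.fft.fft(w, n=nfft)
        conv = np.fft.ifft(sig_f * w_f[None, :], axis=1)
        out[:, fi, :] = np.abs(conv[:, half : half + n_samp]) ** 2
    return out


def _next_fast_len(n: int) -> int:
    from scipy.fft import next_fast_len

    return next_fast_len(n)


def resample_to_100hz(power: np.ndarray, sr: float) -> np.ndarray:
    """Resample a 1-s power array (..., sr samples) to exactly 100 samples.

    Polyphase resampling with the exact rational factor ``100 / sr``.
    """
    power = np.asarray(power)
    if power.shape[-1] != int(round(sr)):
        raise SignalLengthError(
            f"expected a 1-s input of {int(round(sr))} samples, got {power.shape[-1]}"
        )
    return _resample_time(power, sr)


def _resample_time(power: np.ndarray, sr: float) -> np.ndarray:
    if int(sr) != sr:
        raise ConfigError("sampling rate must be an integer number of Hz to resample")
    ratio = Fraction(TARGET_HZ, int(sr))
    up, down = ratio.numerator, ratio.denominator
    if up == down:
        return power.astype(np.float32, copy=False)
    # beta=14 Kaiser window: flat passband (constants/ramps preserved to ~1e-8)
    out = sps.resample_poly(
        power.astype(np.float64), up, down, axis=-1,
        padtype="line", window=("kaiser", 14.0),
    )
    return out.astype(np.float32)


def znormalize(tensor: np.ndarray) -> np.ndarray:
    """Z-score a tensor jointly over all its elements (zero mean, unit SD)."""
    tensor = np.asarray(tensor, dtype=np.float64)
    sd = tensor.std()
    if sd == 0 or not np.isfinite(sd):
        raise NormalizationError("constant tensor cannot be Z-scored")
    return ((tensor - tensor.mean()) / sd).astype(np.float32)


def recording_tensors(
    rec: Recording,
    onsets_s: np.ndarray,
    grid: TFGrid | None = None,
) -> np.ndarray:
    """TF tensors for all requested windows of a preprocessed recording.

    Returns an (n_windows, n_channels, 45, 100) float32 array.  Power is
    computed once over the full recording, resampled to 100 Hz, sliced at the
    window onsets, and Z-scored per window.
    """
    if grid is None:
        grid = build_grid()
    power = morlet_power(rec.signal, grid, rec.sr)
    n_100 = int(round(rec.n_samples * TARGET_HZ / rec.sr))
    flat = power.reshape(-1, power.shape[-1])
    res = _resample_time(flat, rec.sr).reshape(power.shape[0], power.shape[1], -1)
    res = res[..., :n_100]

    out = np.empty((len(onsets_s), rec.n_channels, len(grid.freqs_hz), TARGET_HZ), dtype=np.float32)
    for i, onset in enumerate(np.asarray(onsets_s, dtype=float)):
        start = int(round(onset * TARGET_HZ))
        window = res[..., start : start + TARGET_HZ]
        if window.shape[-1] != TARGET_HZ:
            raise SignalLengthError(
                f"window at {onset} s runs past the recording end"
            )
        out[i] = znormalize(window)
    return out
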