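"""Minimal preprocessing: band-pass filtering, channel selection, re-referencing.

The filter is a Hamming-windowed linear-phase FIR band-pass (0.5-45 Hz by
default) whose length is set by the shortest transition bandwidth TB and the
sampling rate SR as ``(3.3 * SR) / TB``, rounded up to the nearest even
integer.  Application is zero-phase up to the half-sample delay inherent to
an even-length filter: the signal is reflection-padded, convolved once
forward, and shifted back by ``(n_taps - 1) // 2`` samples.

Channel selection reduces any cap layout to the fixed 19-channel 10-20
montage (see :mod:`eegannot.montage`); average re-referencing subtracts the
instantaneous across-channel mean.  Bad-channel interpolation is a no-op hook
(:func:`interpolate_bad_channels`) kept for pipeline compatibility with data
that declares bad channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import montage
from .errors import FilterDesignError, MontageError, SignalLengthError
from .io import Recording

__all__ = [
    "FilterSpec",
    "design_bandpass",
    "apply_bandpass",
    "select_channels",
    "average_reference",
    "interpolate_bad_channels",
    "preprocess_recording",
]


def fir_length(sr: float, tb_hz: float) -> int:
    """Filter length ``(3.3 * SR) / TB`` rounded up to the nearest even integer."""
    return 2 * math.ceil(3.3 * sr / tb_hz / 2.0)


@dataclass(frozen=True)
class FilterSpec:
    """A designed Hamming-window FIR band-pass filter."""

    sr: float
    low_cutoff_hz: float
    high_cutoff_hz: float
    tb_low_hz: float
    tb_high_hz: float
    n_taps: int
    coefficients: np.ndarray = field(repr=False)
    window: str = "hamming"


def design_bandpass(
    sr: float,
    low_hz: float = 0.5,
    high_hz: float = 45.0,
    tb_low_hz: float = 0.5,
    tb_high_hz: float = 11.25,
) -> FilterSpec:
    """Design the band-pass filter for a given sampling rate.

    The -6 dB cutoffs sit at ``low_hz`` and ``high_hz``; the transition bands
    are centred on them, so the stop edges are ``low_hz - tb_low/2`` and
    ``high_hz + tb_high/2``.
    """
    if not (tb_low_hz > 0 and tb_high_hz > 0):
        raise FilterDesignError("transition bandwidths must be positive")
    if not (0 < low_hz < high_hz):
        raise FilterDesignError("need 0 < low cutoff < high cutoff")
    nyq = sr / 2.0
    if high_hz >= nyq:
        raise FilterDesignError(f"high cutoff {high_hz} Hz at or above Nyquist {nyq} Hz")
    if low_hz - tb_low_hz / 2.0 < 0:
        raise FilterDesignError("lower transition band extends below 0 Hz")
    if high_hz + tb_high_hz / 2.0 > nyq:
        raise FilterDesignError("upper transition band extends above Nyquist")

    n_taps = fir_length(sr, min(tb_low_hz, tb_high_hz))
    coeffs = sps.firwin(
        n_taps,
        [low_hz, high_hz],
        window="hamming",
        pass_zero=False,
        fs=sr,
    )
    return FilterSpec(
        sr=sr,
        low_cutoff_hz=low_hz,
        high_cutoff_hz=high_hz,
        tb_low_hz=tb_low_hz,
        tb_high_hz=tb_high_hz,
        n_taps=n_taps,
        coefficients=coeffs,
    )


def apply_bandpass(rec: Recording, fs: FilterSpec) -> Recording:
    """Filter every channel, compensating the filter's group delay.

    Edges are handled by reflection padding; annotations are unchanged.
    Raises :class:`SignalLengthError` if the recording is shorter than the
    filter.
    """
    if abs(fs.sr - rec.sr) > 1e-9:
        raise FilterDesignError(
            f"filter designed for {fs.sr} Hz, recording sampled at {rec.sr} Hz"
        )
    n = rec.n_samples
    taps = fs.n_taps
    if n < taps:
        raise SignalLengthError(
            f"recording of {n} samples shorter than the {taps}-tap filter"
        )
    delay = (taps - 1) // 2
    pad = taps  # enough to cover both the delay and the filter tail
    x = np.pad(rec.signal, ((0, 0), (pad, pad)), mode="reflect")
    y = sps.fftconvolve(x, fs.coefficients[None, :], mode="full", axes=1)
    out = y[:, pad + delay : pad + delay + n]
    return rec.copy_with(signal=np.ascontiguousarray(out))


def select_channels(
    rec: Recording, names: tuple[str, ...] = montage.STANDARD_19
) -> Recording:
    """Reduce a recording to the montage channels, in canonical order.

    Matching is case-insensitive and accepts the T7/T8/P7/P8 aliases for
    T3/T4/T5/T6.  Raises :class:`MontageError` listing any missing names.
    """
    available = {montage.canonical_name(ch).lower(): i for i, ch in enumerate(rec.channel_names)}
    missing = [name for name in names if name.lower() not in available]
    if missing:
        raise MontageError(missing)
    idx = [available[name.lower()] for name in names]
    return rec.copy_with(
        signal=np.ascontiguousarray(rec.signal[idx]),
        channel_names=list(names),
    )


def average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels (common average reference)."""
    if rec.n_channels < 2:
        raise MontageError(["<need at least 2 channels to re-reference>"])
    out = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return rec.copy_with(signal=out)


def interpolate_bad_channels(rec: Recording, bads: tuple[str, ...] = ()) -> Recording:
    """Hook for spherical-spline interpolation of bad channels.

    Synthetic recordings declare no bad channels, so this is the identity; a
    caller with real data and an external interpolation implementation can
    swap it out at the pipeline level.
    """
    return rec


def preprocess_recording(
    rec: Recording,
    fs: FilterSpec | None = None,
    names: tuple[str, ...] = montage.STANDARD_19,
    reref_before_select: bool = False,
) -> Recording:
    """Full minimal preprocessing: filter, select montage, average-reference.

    ``reref_before_select`` computes the average reference over the original
    channel set instead of the 19 retained channels (both conventions exist;
    for synthetic 19-channel data they coincide).
    """
    if fs is None:
        fs = design_bandpass(rec.sr)
    rec = apply_bandpass(rec, fs)
    rec = interpolate_bad_channels(rec)
    if reref_before_select:
        rec = average_reference(rec)
        rec = select_channels(rec, names)
    else:
        rec = select_channels(rec, names)
        rec = average_reference(rec)
    return rec
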