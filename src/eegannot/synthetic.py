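"""Synthetic resting-state EEG with ground-truth artifact annotations.

Clinical EEG with expert annotations is rarely shareable, so this module
generates surrogate data with the same plumbing: 19-channel 10-20-montage
recordings at a configurable sampling rate (2048 Hz by default), an ongoing
background of 1/f ("pink") noise plus a posterior-dominant ~10-Hz alpha
rhythm, and interval-annotated artifact events drawn from a homogeneous
Poisson process.

Four artifact families span the patterns an annotator (and the classifier)
must tell apart:

* ``ocular``   - slow, high-amplitude frontal deflections (blink-like pulses);
* ``muscle``   - 20-45-Hz band-limited bursts on the temporal chain;
* ``pop``      - a step offset confined to a single electrode;
* ``movement`` - broadband, high-amplitude transients across all channels.

Everything is a deterministic function of ``(seed, subject_index)``; the event
sampler is exposed separately (:func:`sample_events`) so tests can re-draw the
event process independently of waveform rendering.

A simple rater model (:class:`RaterModel`, :func:`simulate_raters`) produces
imperfect expert decisions over segments for exercising the revision stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from . import montage
from .errors import ConfigError
from .io import AnnotationInterval, Recording

__all__ = [
    "ArtifactSpec",
    "BackgroundSpec",
    "SimConfig",
    "RaterModel",
    "sample_events",
    "generate_recording",
    "generate_dataset",
    "simulate_raters",
]

ARTIFACT_KINDS = ("ocular", "muscle", "pop", "movement")

_DEFAULT_CHANNELS = {
    "ocular": montage.FRONTAL,
    "muscle": montage.TEMPORAL,
    "pop": montage.STANDARD_19,   # one channel drawn per event
    "movement": montage.STANDARD_19,
}


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact family: its event rate, duration range and amplitude.

    ``rate_per_min`` parameterizes a homogeneous Poisson process; durations
    are uniform in ``duration_range_s``; ``amplitude_v`` scales the rendered
    waveform (volts).  ``channels`` defaults to the family's physiologically
    typical site.
    """

    kind: str
    rate_per_min: float
    duration_range_s: tuple[float, float]
    amplitude_v: float
    channels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ARTIFACT_KINDS:
            raise ConfigError(f"unknown artifact kind {self.kind!r}")
        if self.rate_per_min < 0:
            raise ConfigError("artifact rate must be >= 0")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ConfigError("duration range must be positive and ordered")
        if self.channels is not None:
            bad = set(self.channels) - set(montage.STANDARD_19)
            if bad:
                raise ConfigError(f"channels outside montage: {sorted(bad)}")

    @property
    def affected(self) -> tuple[str, ...]:
        return self.channels if self.channels is not None else _DEFAULT_CHANNELS[self.kind]


@dataclass(frozen=True)
class BackgroundSpec:
    """Ongoing background activity: 1/f^beta noise plus posterior alpha."""

    pink_exponent: float = 1.0
    rms_v: float = 15e-6
    alpha_amplitude_v: float = 12e-6
    alpha_hz: float = 10.0


def default_artifact_menu() -> list[ArtifactSpec]:
    """Artifact mix used as the study condition for synthetic experiments.

    Rates and durations put roughly 10-15% of recording time inside artifact
    intervals, which after windowing yields a class imbalance of the order
    seen in annotated clinical resting EEG (artifacts the minority class).
    """
    return [
        ArtifactSpec("ocular", 6.0, (0.2, 0.5), 150e-6),
        ArtifactSpec("muscle", 3.0, (0.5, 2.0), 60e-6),
        ArtifactSpec("pop", 1.0, (0.2, 1.0), 200e-6),
        ArtifactSpec("movement", 1.0, (1.0, 3.0), 120e-6),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic dataset."""

    n_subjects: int = 10
    duration_s: float = 60.0
    sr: float = 2048.0
    channel_names: tuple[str, ...] = montage.STANDARD_19
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    artifact_menu: tuple[ArtifactSpec, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.sr <= 0:
            raise ConfigError("sampling rate must be positive")

    @property
    def menu(self) -> list[ArtifactSpec]:
        return list(self.artifact_menu) if self.artifact_menu is not None else default_artifact_menu()


@dataclass(frozen=True)
class RaterModel:
    """Stochastic expert: reproduces the true label with probability
    ``p_agree_true``, votes "uncertain" or "gray" with the given
    probabilities, and otherwise flips the label."""

    p_agree_true: float = 0.9
    p_uncertain: float = 0.0
    p_gray: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_agree_true, self.p_uncertain, self.p_gray):
            if not 0 <= p <= 1:
                raise ConfigError("rater probabilities must be in [0, 1]")
        if self.p_agree_true + self.p_uncertain + self.p_gray > 1 + 1e-12:
            raise ConfigError("rater probabilities sum above 1")


# ---------------------------------------------------------------------------
# event process
# ---------------------------------------------------------------------------

def _event_rng(cfg: SimConfig, subject_index: int, kind_index: int) -> Generator:
    return default_rng(SeedSequence([cfg.seed & 0x7FFFFFFF, subject_index, kind_index, 0xE5E7]))


def sample_events(
    cfg: SimConfig, subject_index: int, spec: ArtifactSpec, kind_index: int
) -> list[tuple[float, float]]:
    """Draw one artifact family's (onset, duration) events for one subject.

    The count is Poisson with mean ``rate_per_min * duration_s / 60``;
    durations are uniform in the family's range (clipped to the recording
    length) and onsets uniform over positions where the event fits, so no
    interval extends past the recording end.  Deterministic given
    ``(cfg.seed, subject_index, kind_index)``.
    """
    rng = _event_rng(cfg, subject_index, kind_index)
    n = rng.poisson(spec.rate_per_min * cfg.duration_s / 60.0)
    lo, hi = spec.duration_range_s
    events = []
    for _ in range(n):
        dur = min(float(rng.uniform(lo, hi)), cfg.duration_s)
        onset = float(rng.uniform(0.0, cfg.duration_s - dur))
        events.append((onset, dur))
    events.sort()
    return events


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _pink_noise(rng: Generator, n_channels: int, n_samples: int, sr: float, beta: float) -> np.ndarray:
    """1/f^beta noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sr)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-beta / 2.0)
    shaping[0] = 0.0  # no DC
    return np.fft.irfft(spectrum * shaping, n=n_samples, axis=1)


def _raised_cosine(n: int) -> np.ndarray:
    """Tukey-like onset/offset envelope over n samples (full Hann window)."""
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1))


def _channel_indices(names: tuple[str, ...], cfg: SimConfig) -> np.ndarray:
    lookup = {name: i for i, name in enumerate(cfg.channel_names)}
    return np.array([lookup[n] for n in names if n in lookup], dtype=int)


def _render_event(
    signal: np.ndarray, spec: ArtifactSpec, onset: float, dur: float,
    cfg: SimConfig, rng: Generator,
) -> None:
    sr = cfg.sr
    i0 = int(round(onset * sr))
    n = max(int(round(dur * sr)), 2)
    n = min(n, signal.shape[1] - i0)
    idx = _channel_indices(spec.affected, cfg)
    amp = spec.amplitude_v * rng.uniform(0.8, 1.2)
    t = np.arange(n) / sr

    if spec.kind == "ocular":
        # blink-like positive deflection, strongest at Fp1/Fp2
        pulse = np.sin(np.pi * t / (n / sr)) ** 2 * amp
        weights = np.where(
            np.isin(idx, _channel_indices(("Fp1", "Fp2"), cfg)), 1.0, 0.6
        )
        signal[np.ix_(idx, i0 + np.arange(n))] += weights[:, None] * pulse[None, :]
    elif spec.kind == "muscle":
        # band-limited (20-45 Hz) noise burst with Hann envelope
        burst = rng.standard_normal((idx.size, n))
        spec_f = np.fft.rfft(burst, axis=1)
        freqs = np.fft.rfftfreq(n, 1.0 / sr)
        mask = (freqs >= 20.0) & (freqs <= 45.0)
        burst = np.fft.irfft(spec_f * mask, n=n, axis=1)
        rms = np.sqrt(np.mean(burst**2, axis=1, keepdims=True))
        rms[rms == 0] = 1.0
        burst = burst / rms * amp
        weights = rng.uniform(0.5, 1.0, size=(idx.size, 1))
        signal[np.ix_(idx, i0 + np.arange(n))] += weights * burst * _raised_cosine(n)[None, :]
    elif spec.kind == "pop":
        # step offset on a single electrode
        ch = int(rng.choice(idx))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        signal[ch, i0 : i0 + n] += sign * amp
    elif spec.kind == "movement":
        # broadband multichannel transient
        sway = _pink_noise(rng, idx.size, n, sr, beta=0.5)
        rms = np.sqrt(np.mean(sway**2, axis=1, keepdims=True))
        rms[rms == 0] = 1.0
        sway = sway / rms * amp
        signal[np.ix_(idx, i0 + np.arange(n))] += sway * _raised_cosine(n)[None, :]


def generate_recording(cfg: SimConfig, subject_index: int) -> Recording:
    """Generate one subject's recording with ground-truth annotations.

    Bit-identical for repeated calls with the same ``(cfg.seed,
    subject_index)``.  Every injected event appears as an
    :class:`~eegannot.io.AnnotationInterval` labelled with its artifact kind.
    """
    if not 0 <= subject_index < cfg.n_subjects:
        raise ConfigError(
            f"subject_index {subject_index} out of range for {cfg.n_subjects} subjects"
        )
    n_samples = int(round(cfg.duration_s * cfg.sr))
    bg_rng = default_rng(SeedSequence([cfg.seed & 0x7FFFFFFF, subject_index, 0xB6]))
    bg = cfg.background

    signal = _pink_noise(bg_rng, len(cfg.channel_names), n_samples, cfg.sr, bg.pink_exponent)
    rms = np.sqrt(np.mean(signal**2, axis=1, keepdims=True))
    signal = signal / rms * bg.rms_v

    # posterior-dominant alpha with slow random amplitude modulation
    t = np.arange(n_samples) / cfg.sr
    post = _channel_indices(montage.POSTERIOR, cfg)
    if post.size:
        phases = bg_rng.uniform(0, 2 * np.pi, size=post.size)
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t + bg_rng.uniform(0, 2 * np.pi))
        alpha = np.sin(2 * np.pi * bg.alpha_hz * t[None, :] + phases[:, None])
        signal[post] += bg.alpha_amplitude_v * envelope[None, :] * alpha

    annotations: list[AnnotationInterval] = []
    for kind_index, spec in enumerate(cfg.menu):
        events = sample_events(cfg, subject_index, spec, kind_index)
        wf_rng = default_rng(
            SeedSequence([cfg.seed & 0x7FFFFFFF, subject_index, kind_index, 0xF0F0])
        )
        for onset, dur in events:
            _render_event(signal, spec, onset, dur, cfg, wf_rng)
            annotations.append(AnnotationInterval(onset, dur, spec.kind))
    annotations.sort(key=lambda iv: (iv.onset_s, iv.duration_s, iv.label))

    sid = f"S{subject_index:03d}"
    return Recording(
        subject_id=sid,
        recording_id=f"{sid}R00",
        sr=cfg.sr,
        channel_names=list(cfg.channel_names),
        signal=signal,
        annotations=annotations,
    )


def generate_dataset(cfg: SimConfig) -> list[Recording]:
    """All subjects' recordings for a configuration."""
    return [generate_recording(cfg, i) for i in range(cfg.n_subjects)]


# ---------------------------------------------------------------------------
# raters
# ---------------------------------------------------------------------------

def _rate_one(labels: list[str], rm: RaterModel, rater_index: int) -> list[str]:
    rng = default_rng(SeedSequence([rm.seed & 0x7FFFFFFF, rater_index, 0x6A7E]))
    out = []
    for label in labels:
        u = rng.random()
        if u < rm.p_gray:
            out.append("gray")
        elif u < rm.p_gray + rm.p_uncertain:
            out.append("uncertain")
        elif u < rm.p_gray + rm.p_uncertain + rm.p_agree_true:
            out.append(label)
        else:
            out.append("nonartifact" if label == "artifact" else "artifact")
    return out


def simulate_raters(true_labels: list[str], rm: RaterModel) -> tuple[list[str], list[str]]:
    """Two independent simulated raters' decisions over segment labels.

    Each decision is in ``{artifact, nonartifact, uncertain, gray}``; the
    marginal probability of reproducing the true label is ``p_agree_true``.
    Deterministic given ``rm.seed``.
    """
    bad = {l for l in true_labels if l not in ("artifact", "nonartifact")}
    if bad:
        raise ConfigError(f"true labels must be artifact/nonartifact, got {sorted(bad)}")
    return _rate_one(list(true_labels), rm, 1), _rate_one(list(true_labels), rm, 2)
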