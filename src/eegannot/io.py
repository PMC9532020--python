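"""Readers and writers for recordings, annotations, and the pipeline's tables.

Two recording formats are supported:

* a native sidecar format (``.f32``): raw little-endian float32 samples in
  channel-major order next to a ``<name>.f32.json`` header with the sampling
  rate, channel names and ids.  This is the canonical round-trip format - it
  preserves the signal to full float32 precision, unlike EDF's 16-bit encoding;
* EDF/BDF (read-only), via :mod:`mne`.

Annotations are interval lists in plain CSV (``onset_s,duration_s,label``),
with onsets in seconds from the start of the recording and half-open
``[onset, onset + duration)`` semantics.  Segment tables, prediction tables and
rater-decision tables are ordinary CSV files handled with pandas; the column
contracts are documented on the functions that write them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

__all__ = [
    "AnnotationInterval",
    "Recording",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_table",
    "write_table",
]


@dataclass(frozen=True)
class AnnotationInterval:
    """A labelled half-open interval ``[onset_s, onset_s + duration_s)``."""

    onset_s: float
    duration_s: float
    label: str = "artifact"

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValidationError(f"negative onset {self.onset_s}")
        if self.duration_s <= 0:
            raise ValidationError(f"non-positive duration {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Recording:
    """A continuous multichannel EEG recording.

    ``signal`` is a (n_channels, n_samples) float array in volts; ``sr`` the
    sampling rate in Hz; ``annotations`` the expert-marked artifact intervals.
    """

    subject_id: str
    recording_id: str
    sr: float
    channel_names: list[str]
    signal: np.ndarray
    annotations: list[AnnotationInterval] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.sr <= 0:
            raise ValidationError(f"non-positive sampling rate {self.sr}")
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_names):
            raise IntegrityError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite values")
        for iv in self.annotations:
            if iv.end_s > self.duration_s + 1e-9:
                raise ValidationError(
                    f"annotation [{iv.onset_s}, {iv.end_s}) extends past "
                    f"recording end {self.duration_s}"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sr

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the native float32 + JSON-header format.

    ``path`` should end in ``.f32``; the header goes to ``<path>.json``.
    Annotations are embedded in the header for convenience (they also
    round-trip independently through :func:`write_annotations`).
    """
    path = Path(path)
    if path.suffix != ".f32":
        raise FormatError(f"native recordings use the .f32 extension, got {path.name}")
    data = np.ascontiguousarray(rec.signal, dtype="<f4")
    header = {
        "format": "eegannot-recording",
        "version": 1,
        "subject_id": rec.subject_id,
        "recording_id": rec.recording_id,
        "sr": rec.sr,
        "channel_names": list(rec.channel_names),
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "order": "channel-major",
        "annotations": [
            {"onset_s": iv.onset_s, "duration_s": iv.duration_s, "label": iv.label}
            for iv in rec.annotations
        ],
    }
    data.tofile(path)
    Path(str(path) + ".json").write_text(json.dumps(header, indent=1))


def _read_native(path: Path) -> Recording:
    header_path = Path(str(path) + ".json")
    if not header_path.exists():
        raise FormatError(f"missing header {header_path}")
    header = json.loads(header_path.read_text())
    n_ch, n_samp = header["n_channels"], header["n_samples"]
    data = np.fromfile(path, dtype=header["dtype"])
    if data.size != n_ch * n_samp:
        raise IntegrityError(
            f"{path}: {data.size} samples on disk, header says {n_ch}x{n_samp}"
        )
    if len(header["channel_names"]) != n_ch:
        raise IntegrityError(f"{path}: channel name count mismatch with header")
    return Recording(
        subject_id=header["subject_id"],
        recording_id=header["recording_id"],
        sr=header["sr"],
        channel_names=list(header["channel_names"]),
        signal=data.reshape(n_ch, n_samp),
        annotations=[AnnotationInterval(**iv) for iv in header.get("annotations", [])],
    )


def _read_edf(path: Path) -> Recording:
    import mne

    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    annotations = [
        AnnotationInterval(onset_s=float(on), duration_s=float(du), label=str(desc))
        for on, du, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
        if du > 0
    ]
    return Recording(
        subject_id=path.stem,
        recording_id=path.stem,
        sr=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        signal=raw.get_data(),
        annotations=annotations,
    )


def read_recording(path: str | Path) -> Recording:
    """Read a recording; format is dispatched on the file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".f32":
        return _read_native(path)
    if suffix in (".edf", ".bdf"):
        return _read_edf(path)
    raise FormatError(f"unknown recording format: {path.name}")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = ["onset_s", "duration_s", "label"]


def write_annotations(intervals: list[AnnotationInterval], path: str | Path) -> None:
    """Write intervals as CSV sorted by onset (canonical serialization)."""
    rows = sorted(intervals, key=lambda iv: (iv.onset_s, iv.duration_s, iv.label))
    with open(path, "w", newline="") as fh:
        fh.write(",".join(_ANNOT_COLUMNS) + "\n")
        for iv in rows:
            fh.write(f"{iv.onset_s!r},{iv.duration_s!r},{iv.label}\n")


def read_annotations(path: str | Path) -> list[AnnotationInterval]:
    """Read an annotation CSV; returns intervals ordered by onset."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                AnnotationInterval(
                    onset_s=float(row.onset_s),
                    duration_s=float(row.duration_s),
                    label=str(row.label),
                )
            )
        except ValidationError as exc:
            raise ValidationError(str(exc), row=i) from None
    out.sort(key=lambda iv: (iv.onset_s, iv.duration_s, iv.label))
    return out


# ---------------------------------------------------------------------------
# generic tables (segments, predictions, rater decisions)
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline table as CSV (no index column)."""
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def float32_roundtrip_bound(amplitude: float) -> float:
    """Worst-case absolute quantization error when storing values of the given
    peak amplitude as IEEE float32 (half an ulp at that magnitude)."""
    return 0.5 * float(np.spacing(np.float32(abs(amplitude))))
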