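"""Sliding-window segmentation and label assignment.

Recordings are cut into 1-s windows on a 0.5-s onset grid (50% overlap).
Each window is compared against the expert's artifact intervals using
half-open interval arithmetic in continuous seconds:

* **nonartifact** - the window intersects no interval at all;
* **artifact**    - some single interval overlaps the window by at least
  ``min_intersection_s`` (0.1 s), or an interval of duration at most 0.1 s
  overlaps it by any positive amount (brief events count in full);
* **ignored**     - only marginal overlaps (< 0.1 s) with longer intervals;
  these windows are excluded from training and evaluation but written to an
  audit table.

The artifact test is per-interval: overlaps from different intervals are not
summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import AnnotationInterval, Recording

__all__ = [
    "LabelRule",
    "window_onsets",
    "assign_label",
    "segment_recording",
    "segment_dataset",
    "segment_id",
]

_EPS = 1e-9


@dataclass(frozen=True)
class LabelRule:
    window_s: float = 1.0
    overlap: float = 0.5
    min_intersection_s: float = 0.1

    def __post_init__(self):
        if not 0 < self.overlap < 1:
            raise ConfigError("overlap must be in (0, 1)")
        if not 0 < self.min_intersection_s < self.window_s:
            raise ConfigError("min_intersection_s must be in (0, window_s)")

    @property
    def step_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)


def window_onsets(duration_s: float, rule: LabelRule = LabelRule()) -> np.ndarray:
    """Onsets of all full windows: 0, step, 2*step, ... (empty if too short)."""
    if duration_s < rule.window_s - _EPS:
        return np.empty(0)
    n = int(np.floor((duration_s - rule.window_s + _EPS) / rule.step_s)) + 1
    return np.arange(n) * rule.step_s


def assign_label(
    onset_s: float,
    intervals: list[AnnotationInterval],
    rule: LabelRule = LabelRule(),
) -> str:
    """Label for the window ``[onset_s, onset_s + window_s)``."""
    w0, w1 = onset_s, onset_s + rule.window_s
    any_overlap = False
    for iv in intervals:
        inter = min(w1, iv.end_s) - max(w0, iv.onset_s)
        if inter <= _EPS:
            continue
        any_overlap = True
        if inter >= rule.min_intersection_s - _EPS:
            return "artifact"
        if iv.duration_s <= rule.min_intersection_s + _EPS:
            return "artifact"
    return "ignored" if any_overlap else "nonartifact"


def segment_id(recording_id: str, onset_s: float) -> str:
    """Stable identifier for a (recording, onset) pair; onsets on the 0.5-s
    grid are encoded in milliseconds."""
    return f"{recording_id}:{int(round(onset_s * 1000)):08d}"


def segment_recording(rec: Recording, rule: LabelRule = LabelRule()) -> pd.DataFrame:
    """Segment table for one recording (all windows, including ignored)."""
    onsets = window_onsets(rec.duration_s, rule)
    rows = {
        "segment_id": [segment_id(rec.recording_id, o) for o in onsets],
        "recording_id": rec.recording_id,
        "subject_id": rec.subject_id,
        "onset_s": onsets,
        "label": [assign_label(o, rec.annotations, rule) for o in onsets],
    }
    return pd.DataFrame(rows)


def segment_dataset(
    recordings: list[Recording], rule: LabelRule = LabelRule()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every recording.

    Returns ``(segments, audit)``: ``segments`` holds the artifact/nonartifact
    windows that form the dataset; ``audit`` the ignored windows.  Columns:
    ``segment_id, recording_id, subject_id, onset_s, label``.
    """
    tables = [segment_recording(rec, rule) for rec in recordings]
    all_windows = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["segment_id", "recording_id", "subject_id", "onset_s", "label"])
    )
    keep = all_windows["label"] != "ignored"
    return (
        all_windows[keep].reset_index(drop=True),
        all_windows[~keep].reset_index(drop=True),
    )


def class_counts(segments: pd.DataFrame) -> dict[str, int]:
    """Per-class segment counts."""
    return segments["label"].value_counts().to_dict()
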