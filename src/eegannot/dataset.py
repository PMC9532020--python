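"""Assembly of recordings into a labelled, tensorized segment dataset."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .io import Recording
from .preprocess import FilterSpec, preprocess_recording
from .segmentation import LabelRule, segment_recording
from .tf_features import TFGrid, build_grid, recording_tensors

__all__ = ["SegmentDataset", "build_dataset"]


@dataclass
class SegmentDataset:
    """Aligned segment table and time-frequency tensors.

    ``segments`` holds one row per kept (artifact / nonartifact) window with
    columns ``segment_id, recording_id, subject_id, onset_s, label``;
    ``tensors`` is the matching ``(N, channels, 45, 100)`` float32 array;
    ``audit`` records the windows ignored by the labelling rule.
    """

    segments: pd.DataFrame
    tensors: np.ndarray
    audit: pd.DataFrame

    def __post_init__(self):
        if len(self.segments) != len(self.tensors):
            raise IntegrityError(
                f"{len(self.segments)} segment rows but {len(self.tensors)} tensors"
            )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def labels(self) -> np.ndarray:
        return self.segments["label"].to_numpy()

    def with_labels(self, labels) -> "SegmentDataset":
        """Copy of the dataset with replaced labels (same segments/tensors)."""
        seg = self.segments.copy()
        seg["label"] = list(labels)
        return SegmentDataset(seg, self.tensors, self.audit)

    def subset(self, mask: np.ndarray) -> "SegmentDataset":
        mask = np.asarray(mask)
        return SegmentDataset(
            self.segments[mask].reset_index(drop=True),
            self.tensors[mask],
            self.audit,
        )


def build_dataset(
    recordings: list[Recording],
    rule: LabelRule = LabelRule(),
    grid: TFGrid | None = None,
    preprocess: bool = True,
    filter_spec: FilterSpec | None = None,
) -> SegmentDataset:
    """Segment, label and tensorize a list of recordings.

    With ``preprocess=True`` each recording first goes through the minimal
    pipeline (band-pass, montage selection, average reference).  Windows
    labelled ``ignored`` are excluded from the dataset but kept in ``audit``.
    """
    grid = grid or build_grid()
    seg_tables, audit_tables, tensor_blocks = [], [], []
    for rec in recordings:
        if preprocess:
            rec = preprocess_recording(rec, filter_spec)
        table = segment_recording(rec, rule)
        keep = table["label"] != "ignored"
        kept = table[keep].reset_index(drop=True)
        seg_tables.append(kept)
        audit_tables.append(table[~keep].reset_index(drop=True))
        if len(kept):
            tensor_blocks.append(recording_tensors(rec, kept["onset_s"].to_numpy(), grid))
    segments = pd.concat(seg_tables, ignore_index=True)
    audit = pd.concat(audit_tables, ignore_index=True)
    tensors = (
        np.concatenate(tensor_blocks, axis=0)
        if tensor_blocks
        else np.empty((0, 19, 45, 100), np.float32)
    )
    return SegmentDataset(segments, tensors, audit)
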