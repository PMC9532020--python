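"""Per-sample artifact-probability traces for display alongside the signal.

Window predictions live on the 0.5-s onset grid; for visualization each time
sample gets a probability by averaging the windows nearest in time: the
three nearest windows for interior samples, only two within the first and
last second of the recording (where a third overlapping window does not
exist).  The trace is banded into five equal-width probability categories
([0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0] -> 1..5) for the
color strip under the traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .segmentation import LabelRule, window_onsets

__all__ = ["ProbabilityTrace", "interpolate_trace", "categorize", "trace_table"]


@dataclass(frozen=True)
class ProbabilityTrace:
    recording_id: str
    trace_sr: float
    p_artifact: np.ndarray   # per sample, in [0, 1]
    category: np.ndarray     # per sample, in 1..5

    def __len__(self) -> int:
        return len(self.p_artifact)


def categorize(p) -> np.ndarray | int:
    """Probability category 1..5 (equal-width bins; 1.0 falls in category 5)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ConfigError("probabilities must lie in [0, 1]")
    # multiply, don't divide: 0.6 / 0.2 rounds below 3 in binary floating point
    cats = np.minimum((arr * 5.0).astype(int) + 1, 5)
    return int(cats) if np.isscalar(p) or arr.ndim == 0 else cats


def interpolate_trace(
    window_p: np.ndarray,
    duration_s: float,
    recording_id: str = "",
    trace_sr: float = 100.0,
    rule: LabelRule = LabelRule(),
) -> ProbabilityTrace:
    """Per-sample probability trace from overlapping-window predictions.

    ``window_p[i]`` is the artifact probability of the window at onset
    ``i * 0.5`` s; predictions must cover every full window of the recording.
    Each output sample is the arithmetic mean of its contributing windows'
    probabilities (3 nearest windows in the interior, 2 in the first and
    last second).
    """
    onsets = window_onsets(duration_s, rule)
    window_p = np.asarray(window_p, dtype=float)
    if len(window_p) != len(onsets):
        raise IntegrityError(
            f"{len(window_p)} window predictions but {len(onsets)} windows "
            f"for a {duration_s}-s recording"
        )
    if len(onsets) == 0:
        raise ConfigError("recording shorter than one window")
    n_samples = int(round(duration_s * trace_sr))
    t = np.arange(n_samples) / trace_sr
    centers = onsets + rule.window_s / 2.0

    # number of contributing windows per sample
    m = np.where((t < 1.0) | (t >= duration_s - 1.0), 2, 3)
    m = np.minimum(m, len(onsets))

    dist = np.abs(t[:, None] - centers[None, :])
    order = np.argsort(dist, axis=1, kind="stable")
    p = np.empty(n_samples)
    for k in np.unique(m):
        rows = m == k
        p[rows] = window_p[order[rows, :k]].mean(axis=1)
    return ProbabilityTrace(
        recording_id=recording_id,
        trace_sr=trace_sr,
        p_artifact=p,
        category=categorize(p),
    )


def trace_table(trace: ProbabilityTrace) -> pd.DataFrame:
    """CSV-ready table: t (s), p_artifact, category."""
    t = np.arange(len(trace)) / trace.trace_sr
    return pd.DataFrame(
        {"t": t, "p_artifact": trace.p_artifact, "category": trace.category}
    )
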