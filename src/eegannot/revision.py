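"""The model-guided revision loop: candidate selection, dual-rater merging,
inter-rater agreement, and application of the revised gold standard.

After a final model is fitted to the whole dataset, segments it confidently
misclassifies are re-examined: nonartifact-labelled segments predicted
artifact with probability in [p_fp, 1] (putative false positives, default
p_fp = 0.65), artifact-labelled segments predicted with probability in
[0, p_fn] (putative false negatives, default p_fn = 0.40), and - regardless
of probability - the windows immediately adjacent in time to either (the
previous and next onsets on the 0.5-s grid, the only windows sharing samples
with the selected one).

Two independent raters then decide per candidate segment: keep the current
annotation, change it to artifact / nonartifact, mark it uncertain, or mark
it "gray" (brain-related activity to exclude from wakefulness analyses).
Merging: a gray vote by either rater drops the segment; two matching
concrete votes (with "keep" resolving to the original label) replace the
annotation; any disagreement, or a double "uncertain", keeps the original.

Agreement between the raters is summarized by Cohen's kappa,
``(p_o - p_e) / (1 - p_e)`` with chance agreement from the raters' marginal
category counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SegmentDataset
from .errors import ConfigError, IntegrityError
from .segmentation import LabelRule

__all__ = [
    "RevisionConfig",
    "KappaResult",
    "select_candidates",
    "cohens_kappa",
    "merge_decisions",
    "merge_decision_table",
    "apply_revision",
    "stratified_subsets",
]

CONCRETE = ("artifact", "nonartifact")
DECISIONS = ("keep", "artifact", "nonartifact", "uncertain", "gray")


@dataclass(frozen=True)
class RevisionConfig:
    """Probability bands for candidate selection."""

    p_fp: float = 0.65   # nonartifact segments predicted in [p_fp, 1]
    p_fn: float = 0.40   # artifact segments predicted in [0, p_fn]
    include_adjacent: bool = True

    def __post_init__(self):
        if not 0 < self.p_fn < self.p_fp < 1:
            raise ConfigError("need 0 < p_fn < p_fp < 1")


def select_candidates(
    predictions: pd.DataFrame,
    cfg: RevisionConfig = RevisionConfig(),
    rule: LabelRule = LabelRule(),
) -> pd.DataFrame:
    """Confidently misclassified segments plus their temporal neighbors.

    ``predictions`` needs columns ``segment_id, recording_id, onset_s, label,
    p_artifact``.  Returns the candidate rows with a ``selection_reason``
    column in {fp_band, fn_band, adjacent}; neighbors of neighbors are not
    added (the adjacency closure stops at band-selected segments).
    """
    required = {"segment_id", "recording_id", "onset_s", "label", "p_artifact"}
    missing = required - set(predictions.columns)
    if missing:
        raise IntegrityError(f"prediction table missing columns {sorted(missing)}")
    p = predictions["p_artifact"].to_numpy()
    label = predictions["label"].to_numpy()
    fp_band = (label == "nonartifact") & (p >= cfg.p_fp)
    fn_band = (label == "artifact") & (p <= cfg.p_fn)
    in_band = fp_band | fn_band

    reason = np.where(fp_band, "fp_band", np.where(fn_band, "fn_band", ""))
    if cfg.include_adjacent:
        step = rule.step_s
        onset_key = predictions["onset_s"].round(6)
        band_idx = predictions.index[in_band]
        band_onsets = set(zip(predictions.loc[band_idx, "recording_id"],
                              onset_key[band_idx]))
        neighbor = np.zeros(len(predictions), bool)
        for delta in (-step, step):
            shifted = set((r, round(o + delta, 6)) for r, o in band_onsets)
            neighbor |= [
                (r, o) in shifted
                for r, o in zip(predictions["recording_id"], onset_key)
            ]
        neighbor &= ~in_band
        reason = np.where(neighbor, "adjacent", reason)
        selected = in_band | neighbor
    else:
        selected = in_band
    out = predictions[selected].copy()
    out["selection_reason"] = reason[selected]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_o: float
    p_e: float
    n: int
    counts_1: dict[str, int]
    counts_2: dict[str, int]
    band: str

    @staticmethod
    def interpret(kappa: float) -> str:
        if np.isnan(kappa):
            return "undefined"
        if kappa <= 0:
            return "no agreement"
        for hi, name in [(0.20, "none to slight"), (0.40, "fair"), (0.60, "moderate"),
                         (0.80, "substantial"), (1.00, "almost perfect")]:
            if kappa <= hi + 1e-12:
                return name
        return "almost perfect"


def cohens_kappa(decisions1, decisions2) -> KappaResult:
    """Cohen's kappa over two aligned decision sequences.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_e = (1/N^2) sum_m n_m1 n_m2``
    over the categories present.  If both raters are constant and identical
    (p_e = 1) kappa is undefined and reported as NaN.
    """
    d1, d2 = list(decisions1), list(decisions2)
    if len(d1) != len(d2):
        raise ConfigError("decision sequences must be aligned (equal length)")
    if not d1:
        raise ConfigError("need at least one observation")
    n = len(d1)
    cats = sorted(set(d1) | set(d2))
    c1 = {c: d1.count(c) for c in cats}
    c2 = {c: d2.count(c) for c in cats}
    p_o = sum(a == b for a, b in zip(d1, d2)) / n
    p_e = sum(c1[c] * c2[c] for c in cats) / n**2
    kappa = float("nan") if abs(1.0 - p_e) < 1e-15 else (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=kappa, p_o=p_o, p_e=p_e, n=n, counts_1=c1, counts_2=c2,
                       band=KappaResult.interpret(kappa))


# ---------------------------------------------------------------------------
# merging dual-rater decisions
# ---------------------------------------------------------------------------

def merge_decisions(original_label: str, d1: str, d2: str) -> str:
    """Merge one segment's two rater decisions into an outcome.

    Returns the revised label, or ``"drop"`` if either rater voted gray.
    ``keep`` votes resolve to the original label; the annotation changes only
    when both raters' resolved votes are the same concrete label; otherwise
    (disagreement, or both uncertain) the original label is retained.
    """
    if original_label not in CONCRETE:
        raise ConfigError(f"original label must be concrete, got {original_label!r}")
    for d in (d1, d2):
        if d not in DECISIONS:
            raise ConfigError(f"unknown rater decision {d!r}")
    if "gray" in (d1, d2):
        return "drop"
    r1 = original_label if d1 == "keep" else d1
    r2 = original_label if d2 == "keep" else d2
    if r1 == r2 and r1 in CONCRETE:
        return r1
    return original_label


def merge_decision_table(candidates: pd.DataFrame, d1, d2) -> pd.DataFrame:
    """Vectorized merge over a candidate table; adds ``rater1, rater2,
    outcome`` columns (outcome is the merged label or "drop")."""
    out = candidates.copy()
    out["rater1"] = list(d1)
    out["rater2"] = list(d2)
    out["outcome"] = [
        merge_decisions(lab, a, b)
        for lab, a, b in zip(out["label"], out["rater1"], out["rater2"])
    ]
    return out


# ---------------------------------------------------------------------------
# applying the revision
# ---------------------------------------------------------------------------

def apply_revision(
    ds: SegmentDataset, merged: pd.DataFrame
) -> tuple[SegmentDataset, dict]:
    """Apply merged outcomes to a dataset.

    ``merged`` needs ``segment_id, label, outcome`` (from
    :func:`merge_decision_table`).  Returns the revised dataset (dropped
    segments removed, changed labels replaced) and a change report with
    counts of reviewed / changed / dropped / kept segments.
    """
    ids = ds.segments["segment_id"]
    unknown = set(merged["segment_id"]) - set(ids)
    if unknown:
        raise IntegrityError(f"outcomes refer to unknown segments: {sorted(unknown)[:5]}")
    outcome_by_id = dict(zip(merged["segment_id"], merged["outcome"]))
    new_labels, drop_mask = [], []
    n_changed = n_dropped = 0
    for sid, lab in zip(ids, ds.segments["label"]):
        out = outcome_by_id.get(sid)
        if out is None:
            new_labels.append(lab)
            drop_mask.append(False)
        elif out == "drop":
            new_labels.append(lab)
            drop_mask.append(True)
            n_dropped += 1
        else:
            new_labels.append(out)
            drop_mask.append(False)
            n_changed += int(out != lab)
    revised = ds.with_labels(new_labels).subset(~np.asarray(drop_mask))
    report = {
        "n_reviewed": int(len(merged)),
        "n_changed": int(n_changed),
        "n_dropped": int(n_dropped),
        "n_kept": int(len(merged) - n_changed - n_dropped),
        "counts_before": ds.segments["label"].value_counts().to_dict(),
        "counts_after": revised.segments["label"].value_counts().to_dict(),
    }
    return revised, report


def stratified_subsets(
    revised: SegmentDataset, merged: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Partition the surviving segments into three evaluation subsets.

    * ``revision_changed`` - reviewed segments whose annotation changed;
    * ``revision_agreed``  - reviewed segments whose annotation survived
      (including disagreements resolved by keeping the original);
    * ``non_revised``      - everything never sent to the raters.

    Returns boolean masks over ``revised.segments`` rows; the masks are
    mutually exclusive and jointly exhaustive.
    """
    outcome_by_id = dict(zip(merged["segment_id"], merged["outcome"]))
    orig_by_id = dict(zip(merged["segment_id"], merged["label"]))
    ids = revised.segments["segment_id"]
    changed = np.array([
        sid in outcome_by_id and outcome_by_id[sid] != orig_by_id[sid] for sid in ids
    ])
    agreed = np.array([
        sid in outcome_by_id and outcome_by_id[sid] == orig_by_id[sid] for sid in ids
    ])
    return {
        "revision_changed": changed,
        "revision_agreed": agreed,
        "non_revised": ~(changed | agreed),
    }
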