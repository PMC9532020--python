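"""Candidate selection, Cohen's kappa, decision merging, revision accounting."""

import numpy as np
import pandas as pd
import pytest

from eegannot.dataset import SegmentDataset
from eegannot.errors import ConfigError, IntegrityError
from eegannot.revision import (
    RevisionConfig,
    apply_revision,
    cohens_kappa,
    merge_decision_table,
    merge_decisions,
    select_candidates,
    stratified_subsets,
)


def _pred_table(rows):
    """rows: list of (recording_id, onset_s, label, p)."""
    return pd.DataFrame(
        {
            "segment_id": [f"{r}:{int(o * 1000):08d}" for r, o, _, _ in rows],
            "recording_id": [r for r, _, _, _ in rows],
            "onset_s": [o for _, o, _, _ in rows],
            "label": [l for _, _, l, _ in rows],
            "p_artifact": [p for _, _, _, p in rows],
        }
    )


class TestSelectCandidates:
    def test_fp_and_fn_bands(self):
        preds = _pred_table([
            ("r", 0.0, "nonartifact", 0.70),   # FP band
            ("r", 5.0, "artifact", 0.30),      # FN band
            ("r", 10.0, "artifact", 0.90),     # confident and correct
            ("r", 15.0, "nonartifact", 0.10),  # confident and correct
        ])
        out = select_candidates(preds)
        got = dict(zip(out["segment_id"], out["selection_reason"]))
        assert got == {"r:00000000": "fp_band", "r:00005000": "fn_band"}

    def test_band_edges_inclusive(self):
        preds = _pred_table([
            ("r", 0.0, "nonartifact", 0.65),
            ("r", 5.0, "artifact", 0.40),
        ])
        assert len(select_candidates(preds)) == 2

    def test_adjacent_windows_selected_regardless_of_probability(self):
        preds = _pred_table([
            ("r", 0.0, "nonartifact", 0.10),
            ("r", 0.5, "nonartifact", 0.70),   # band
            ("r", 1.0, "nonartifact", 0.50),   # neighbor
            ("r", 1.5, "nonartifact", 0.10),   # neighbor of neighbor: NOT selected
        ])
        out = select_candidates(preds)
        got = dict(zip(out["onset_s"], out["selection_reason"]))
        assert got == {0.0: "adjacent", 0.5: "fp_band", 1.0: "adjacent"}

    def test_adjacency_does_not_cross_recordings(self):
        preds = _pred_table([
            ("a", 0.0, "nonartifact", 0.70),
            ("b", 0.5, "nonartifact", 0.10),  # same grid slot, other recording
        ])
        out = select_candidates(preds)
        assert list(out["recording_id"]) == ["a"]

    def test_adjacency_can_be_disabled(self):
        preds = _pred_table([
            ("r", 0.0, "nonartifact", 0.70),
            ("r", 0.5, "nonartifact", 0.50),
        ])
        out = select_candidates(preds, RevisionConfig(include_adjacent=False))
        assert list(out["selection_reason"]) == ["fp_band"]

    def test_invalid_band_config_rejected(self):
        with pytest.raises(ConfigError):
            RevisionConfig(p_fp=0.4, p_fn=0.65)


class TestCohensKappa:
    def test_identical_sequences_kappa_one(self):
        d = ["a", "b", "a", "c", "b"] * 4
        assert cohens_kappa(d, d).kappa == pytest.approx(1.0)

    def test_hand_evaluated_2x2_table(self):
        # contingency a=45, b=15, c=25, d=15 (rows rater1, cols rater2)
        d1 = ["art"] * 60 + ["non"] * 40
        d2 = ["art"] * 45 + ["non"] * 15 + ["art"] * 25 + ["non"] * 15
        res = cohens_kappa(d1, d2)
        assert res.p_o == pytest.approx(0.60)
        assert res.p_e == pytest.approx((60 * 70 + 40 * 30) / 100**2)
        assert res.kappa == pytest.approx((0.60 - 0.54) / (1 - 0.54))

    def test_matches_sklearn_on_random_tables(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            n = int(rng.integers(10, 200))
            cats = ["w", "x", "y", "z"][: int(rng.integers(2, 5))]
            d1 = list(rng.choice(cats, n))
            d2 = list(rng.choice(cats, n))
            ours = cohens_kappa(d1, d2).kappa
            theirs = cohen_kappa_score(d1, d2)
            if np.isnan(theirs):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(theirs, abs=1e-12)

    def test_independent_raters_near_zero(self, rng):
        d1 = list(rng.choice(["a", "b"], 10_000))
        d2 = list(rng.choice(["a", "b"], 10_000))
        assert abs(cohens_kappa(d1, d2).kappa) < 0.05

    def test_interpretation_bands(self):
        assert cohens_kappa(["a", "b"] * 10, ["a", "b"] * 10).band == "almost perfect"

    def test_degenerate_constant_raters(self):
        res = cohens_kappa(["a"] * 5, ["a"] * 5)
        assert np.isnan(res.kappa)
        assert res.band == "undefined"

    def test_relabelling_invariance(self, rng):
        d1 = list(rng.choice(["a", "b", "c"], 500))
        d2 = list(rng.choice(["a", "b", "c"], 500))
        mapping = {"a": "z", "b": "q", "c": "m"}
        k1 = cohens_kappa(d1, d2).kappa
        k2 = cohens_kappa([mapping[x] for x in d1], [mapping[x] for x in d2]).kappa
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ConfigError):
            cohens_kappa(["a"], ["a", "b"])


class TestMergeDecisions:
    @pytest.mark.parametrize(
        "original, d1, d2, expected",
        [
            ("nonartifact", "artifact", "artifact", "artifact"),   # agreed change
            ("nonartifact", "gray", "keep", "drop"),               # gray drops
            ("artifact", "artifact", "gray", "drop"),
            ("nonartifact", "artifact", "nonartifact", "nonartifact"),  # disagreement
            ("artifact", "uncertain", "uncertain", "artifact"),    # both uncertain
            ("artifact", "keep", "keep", "artifact"),
            ("artifact", "keep", "artifact", "artifact"),          # keep == original
            ("nonartifact", "uncertain", "artifact", "nonartifact"),  # conservative
        ],
    )
    def test_merge_rules(self, original, d1, d2, expected):
        assert merge_decisions(original, d1, d2) == expected

    def test_symmetric_in_raters(self):
        for original in ("artifact", "nonartifact"):
            for d1 in ("keep", "artifact", "nonartifact", "uncertain", "gray"):
                for d2 in ("keep", "artifact", "nonartifact", "uncertain", "gray"):
                    assert merge_decisions(original, d1, d2) == merge_decisions(original, d2, d1)

    def test_unknown_decision_rejected(self):
        with pytest.raises(ConfigError):
            merge_decisions("artifact", "maybe", "keep")


def _toy_dataset(rng, n=20):
    labels = ["artifact" if i % 3 == 0 else "nonartifact" for i in range(n)]
    seg = pd.DataFrame({
        "segment_id": [f"r:{i:08d}" for i in range(n)],
        "recording_id": "r", "subject_id": "s",
        "onset_s": np.arange(n) * 0.5, "label": labels,
    })
    return SegmentDataset(seg, rng.standard_normal((n, 2, 3, 4)).astype(np.float32), pd.DataFrame())


class TestApplyRevision:
    def test_no_changes_identity(self, rng):
        ds = _toy_dataset(rng)
        cands = ds.segments.head(4).copy()
        merged = merge_decision_table(cands, ["keep"] * 4, ["keep"] * 4)
        revised, report = apply_revision(ds, merged)
        assert report["n_changed"] == 0 and report["n_dropped"] == 0
        pd.testing.assert_frame_equal(revised.segments, ds.segments)

    def test_single_flip_shifts_counts_by_one(self, rng):
        ds = _toy_dataset(rng)
        target = ds.segments[ds.segments["label"] == "nonartifact"].head(1)
        merged = merge_decision_table(target.copy(), ["artifact"], ["artifact"])
        revised, report = apply_revision(ds, merged)
        before = ds.segments["label"].value_counts()
        after = revised.segments["label"].value_counts()
        assert after["artifact"] == before["artifact"] + 1
        assert after["nonartifact"] == before["nonartifact"] - 1

    def test_randomized_outcomes_conserve_counts(self, rng):
        ds = _toy_dataset(rng, n=40)
        cands = ds.segments.sample(15, random_state=0).copy()
        decisions = list(rng.choice(["keep", "artifact", "nonartifact", "uncertain", "gray"], 15))
        merged = merge_decision_table(cands, decisions, decisions)
        revised, report = apply_revision(ds, merged)
        # brute-force recount oracle
        expected_n = len(ds) - report["n_dropped"]
        assert len(revised) == expected_n
        assert report["n_changed"] + report["n_dropped"] + report["n_kept"] == len(merged)

    def test_unknown_segment_rejected(self, rng):
        ds = _toy_dataset(rng)
        merged = pd.DataFrame(
            {"segment_id": ["bogus:0"], "label": ["artifact"], "outcome": ["artifact"]}
        )
        with pytest.raises(IntegrityError):
            apply_revision(ds, merged)


class TestStratifiedSubsets:
    def test_no_revision_everything_non_revised(self, rng):
        ds = _toy_dataset(rng)
        merged = merge_decision_table(ds.segments.head(0).copy(), [], [])
        revised, _ = apply_revision(ds, merged)
        subsets = stratified_subsets(revised, merged)
        assert subsets["non_revised"].all()
        assert not subsets["revision_changed"].any()

    def test_all_candidates_changed_leaves_agreed_empty(self, rng):
        ds = _toy_dataset(rng)
        cands = ds.segments.head(3).copy()
        flip = ["nonartifact" if l == "artifact" else "artifact" for l in cands["label"]]
        merged = merge_decision_table(cands, flip, flip)
        revised, _ = apply_revision(ds, merged)
        subsets = stratified_subsets(revised, merged)
        assert not subsets["revision_agreed"].any()
        assert subsets["revision_changed"].sum() == 3

    def test_subsets_partition_surviving_segments(self, rng):
        ds = _toy_dataset(rng, n=40)
        cands = ds.segments.sample(12, random_state=1).copy()
        d = list(rng.choice(["keep", "artifact", "nonartifact", "gray"], 12))
        merged = merge_decision_table(cands, d, d)
        revised, _ = apply_revision(ds, merged)
        subsets = stratified_subsets(revised, merged)
        total = sum(m.astype(int) for m in subsets.values())
        assert (total == 1).all()
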