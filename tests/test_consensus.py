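import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crossfeednet._exceptions import ValidationError
from crossfeednet.consensus import (
    NONE_LABEL,
    ConsensusMatrix,
    LabelMatrix,
    consensus_matrix,
    pcps_to_labels,
    score_against_reference,
)
from crossfeednet.encoding import COMPETITION, CROSS_FEEDING


def _score_frame(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"s{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=labels, columns=labels)


def _label_frame(entries, labels):
    return LabelMatrix(pd.DataFrame(entries, index=labels, columns=labels))


class TestPcpsToLabels:
    def test_sign_trichotomy(self):
        scores = _score_frame([[0, 0.5, 0], [0.5, 0, -0.2], [0, -0.2, 0]])
        lm = pcps_to_labels(scores)
        assert lm.frame.iat[0, 1] == CROSS_FEEDING
        assert lm.frame.iat[0, 2] == NONE_LABEL
        assert lm.frame.iat[1, 2] == COMPETITION

    def test_all_zero_matrix_is_all_none(self):
        lm = pcps_to_labels(_score_frame(np.zeros((4, 4))))
        assert (lm.frame.values == NONE_LABEL).all()

    def test_label_counts_equal_sign_counts(self, rng):
        # sign-count oracle on random matrices
        for _ in range(20):
            vals = rng.normal(size=(6, 6))
            np.fill_diagonal(vals, 0.0)
            lm = pcps_to_labels(_score_frame(vals))
            counts = lm.label_counts()
            off = ~np.eye(6, dtype=bool)
            assert counts.get(CROSS_FEEDING, 0) == int((vals[off] > 0).sum())
            assert counts.get(COMPETITION, 0) == int((vals[off] < 0).sum())

    @given(st.floats(min_value=0.01, max_value=100))
    def test_invariant_under_positive_scaling(self, factor):
        vals = np.array([[0, 1.5, -0.3], [1.5, 0, 0], [-0.3, 0, 0]])
        base = pcps_to_labels(_score_frame(vals))
        scaled = pcps_to_labels(_score_frame(vals * factor))
        assert base.frame.equals(scaled.frame)

    def test_nan_rejected_with_coordinates(self):
        vals = np.zeros((3, 3))
        vals[0, 2] = np.nan
        with pytest.raises(ValidationError, match=r"\(s0, s2\)"):
            pcps_to_labels(_score_frame(vals))


class TestConsensusMatrix:
    def test_agreement_rules(self):
        labels = ["a", "b", "c", "d"]
        cf, co, no = CROSS_FEEDING, COMPETITION, NONE_LABEL
        x = _label_frame([[no, cf, co, cf],
                          [cf, no, cf, co],
                          [co, cf, no, no],
                          [cf, co, no, no]], labels)
        y = _label_frame([[no, cf, co, co],
                          [cf, no, co, co],
                          [co, co, no, cf],
                          [co, co, cf, no]], labels)
        cm = consensus_matrix(x, y)
        assert cm.frame.at["a", "b"] == 1      # cf + cf
        assert cm.frame.at["a", "c"] == -1     # co + co
        assert cm.frame.at["b", "c"] == 0      # cf + co
        assert cm.frame.at["c", "d"] == 0      # none + cf
        assert cm.frame.at["b", "d"] == -1

    def test_self_consensus_counts_non_none_entries(self, rng):
        vals = rng.normal(size=(8, 8))
        np.fill_diagonal(vals, 0)
        lm = pcps_to_labels(_score_frame(vals))
        cm = consensus_matrix(lm, lm)
        counts = cm.pair_counts()
        iu = np.triu_indices(8, k=1)
        non_none = int((lm.frame.values[iu] != NONE_LABEL).sum())
        assert counts["cross_feeding_consensus"] + counts["competition_consensus"] == non_none

    def test_matches_exhaustive_cell_tally(self, rng):
        # brute-force oracle: compare every off-diagonal cell by hand
        labels = [f"s{i}" for i in range(7)]
        choices = [CROSS_FEEDING, COMPETITION, NONE_LABEL]
        for _ in range(20):
            a_entries = rng.choice(choices, size=(7, 7))
            b_entries = rng.choice(choices, size=(7, 7))
            a = _label_frame(a_entries, labels)
            b = _label_frame(b_entries, labels)
            cm = consensus_matrix(a, b)
            for i in range(7):
                for j in range(7):
                    if i == j:
                        assert cm.frame.iat[i, j] == 0
                        continue
                    ai, bi = a.frame.iat[i, j], b.frame.iat[i, j]
                    expected = (1 if ai == bi == CROSS_FEEDING
                                else -1 if ai == bi == COMPETITION else 0)
                    assert cm.frame.iat[i, j] == expected

    def test_symmetric_in_arguments(self, rng):
        labels = [f"s{i}" for i in range(5)]
        choices = [CROSS_FEEDING, COMPETITION, NONE_LABEL]
        a = _label_frame(rng.choice(choices, size=(5, 5)), labels)
        b = _label_frame(rng.choice(choices, size=(5, 5)), labels)
        assert consensus_matrix(a, b).frame.equals(consensus_matrix(b, a).frame)

    def test_label_set_mismatch_reported(self):
        a = _label_frame([[NONE_LABEL] * 2] * 2, ["x", "y"])
        b = _label_frame([[NONE_LABEL] * 2] * 2, ["x", "z"])
        with pytest.raises(ValidationError, match="organism sets differ"):
            consensus_matrix(a, b)

    def test_entries_restricted_to_trichotomy(self):
        with pytest.raises(ValidationError):
            ConsensusMatrix(pd.DataFrame([[0, 2], [0, 0]],
                                         index=["a", "b"], columns=["a", "b"]))


class TestScoreAgainstReference:
    def test_identical_matrices_score_perfectly(self, rng):
        vals = rng.normal(size=(6, 6))
        np.fill_diagonal(vals, 0)
        lm = pcps_to_labels(_score_frame(vals))
        counts, panel = score_against_reference(lm, lm)
        assert panel.accuracy == 1.0
        iu = np.triu_indices(6, k=1)
        assert counts.total == int((lm.frame.values[iu] != NONE_LABEL).sum())

    def test_all_none_reference_is_an_error(self):
        lm = pcps_to_labels(_score_frame(np.zeros((4, 4))))
        with pytest.raises(ValidationError, match="no labelled reference"):
            score_against_reference(lm, lm)

    def test_hand_tallied_disagreement_pattern(self):
        # 10 organisms; reference labels the 5 pairs (0,1)..(8,9); predictions
        # disagree on exactly two of them and call one pair "none"
        labels = [f"o{i}" for i in range(10)]
        cf, co, no = CROSS_FEEDING, COMPETITION, NONE_LABEL
        ref = np.full((10, 10), no, dtype=object)
        pred = np.full((10, 10), no, dtype=object)
        truth = {(0, 1): cf, (2, 3): cf, (4, 5): co, (6, 7): co, (8, 9): cf}
        guess = {(0, 1): cf, (2, 3): co, (4, 5): co, (6, 7): cf, (8, 9): no}
        for (i, j), lab in truth.items():
            ref[i, j] = ref[j, i] = lab
        for (i, j), lab in guess.items():
            pred[i, j] = pred[j, i] = lab
        counts, panel = score_against_reference(
            _label_frame(pred, labels), _label_frame(ref, labels))
        # cf pairs: (0,1) correct, (2,3) wrong, (8,9) predicted none -> wrong
        # co pairs: (4,5) correct, (6,7) wrong
        assert (counts.tp_cf, counts.fn_cf) == (1, 2)
        assert (counts.tp_co, counts.fn_co) == (1, 1)
        assert panel.accuracy == pytest.approx(2 / 5)

    def test_scored_pairs_equal_reference_non_none_count(self, rng):
        labels = [f"o{i}" for i in range(8)]
        choices = [CROSS_FEEDING, COMPETITION, NONE_LABEL]
        ref = _label_frame(rng.choice(choices, size=(8, 8)), labels)
        pred_vals = rng.normal(size=(8, 8))
        pred = pcps_to_labels(_score_frame(pred_vals, labels))
        counts, _ = score_against_reference(pred, ref, discard_none=True)
        iu = np.triu_indices(8, k=1)
        assert counts.total == int((ref.frame.values[iu] != NONE_LABEL).sum())

    def test_without_discard_a_none_bearing_reference_is_rejected(self):
        labels = ["a", "b", "c"]
        entries = [[NONE_LABEL, CROSS_FEEDING, NONE_LABEL],
                   [CROSS_FEEDING, NONE_LABEL, COMPETITION],
                   [NONE_LABEL, COMPETITION, NONE_LABEL]]
        lm = _label_frame(entries, labels)
        with pytest.raises(ValidationError, match="discard_none"):
            score_against_reference(lm, lm, discard_none=False)
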