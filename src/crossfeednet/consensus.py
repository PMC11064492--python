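"""Comparing interaction predictions with external pairwise score matrices.

External methods (e.g. potential-cooperation scores, PCPS) report a real
number per ordered pair of organisms whose sign encodes the interaction:
positive = cross-feeding, zero = no interaction, negative = competition.
This module turns such matrices into label matrices, builds the consensus
matrix between two label matrices (+1 both cross-feeding, -1 both
competition, 0 otherwise) and scores a prediction matrix against a labelled
reference with the reference's "no interaction" pairs discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .encoding import COMPETITION, CROSS_FEEDING
from .metrics import ConfusionCounts, MetricPanel, panel_from_counts

logger = logging.getLogger(__name__)

NONE_LABEL = "none"
TRICHOTOMY = (CROSS_FEEDING, COMPETITION, NONE_LABEL)


@dataclass
class LabelMatrix:
    """Square organism-by-organism matrix of interaction labels."""

    frame: pd.DataFrame  # entries in TRICHOTOMY, diagonal forced to "none"

    def __post_init__(self):
        f = self.frame
        if f.shape[0] != f.shape[1]:
            raise ValidationError("label matrix must be square")
        if list(f.index) != list(f.columns):
            raise ValidationError("label matrix row/column organisms differ")
        bad = set(np.unique(f.values)) - set(TRICHOTOMY)
        if bad:
            raise ValidationError(f"labels outside the trichotomy: {sorted(bad)}")
        np.fill_diagonal(self.frame.values, NONE_LABEL)

    @property
    def organisms(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def pair_label(self, a: str, b: str) -> str:
        """Label of an unordered pair: the upper-triangle (row < column) cell."""
        order = list(self.frame.index)
        i, j = order.index(a), order.index(b)
        if i == j:
            raise ValidationError(f"self-pair {a}")
        i, j = min(i, j), max(i, j)
        return self.frame.iat[i, j]

    def label_counts(self) -> dict[str, int]:
        off = ~np.eye(len(self.frame), dtype=bool)
        vals, counts = np.unique(self.frame.values[off], return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @classmethod
    def from_predictions(cls, predictions: pd.DataFrame, organisms=None) -> "LabelMatrix":
        """Build a symmetric label matrix from an all-pairs prediction table."""
        if organisms is None:
            organisms = sorted(set(predictions["organism_a"]) | set(predictions["organism_b"]))
        frame = pd.DataFrame(NONE_LABEL, index=list(organisms), columns=list(organisms))
        for _, row in predictions.iterrows():
            frame.at[row["organism_a"], row["organism_b"]] = row["label"]
            frame.at[row["organism_b"], row["organism_a"]] = row["label"]
        return cls(frame)


@dataclass
class ConsensusMatrix:
    """+1 where both methods say cross-feeding, -1 where both say competition, else 0."""

    frame: pd.DataFrame

    def __post_init__(self):
        bad = set(np.unique(self.frame.values)) - {-1, 0, 1}
        if bad:
            raise ValidationError(f"consensus entries outside {{-1,0,1}}: {sorted(bad)}")

    def pair_counts(self) -> dict[str, int]:
        """Numbers of unordered pairs with cross-feeding / competition consensus."""
        vals = self.frame.values
        iu = np.triu_indices(vals.shape[0], k=1)
        upper = vals[iu]
        return {
            "cross_feeding_consensus": int((upper == 1).sum()),
            "competition_consensus": int((upper == -1).sum()),
            "no_consensus": int((upper == 0).sum()),
        }


def pcps_to_labels(scores: pd.DataFrame) -> LabelMatrix:
    """Sign-threshold a real score matrix into the interaction trichotomy.

    score > 0 -> cross-feeding, score == 0 -> none, score < 0 -> competition;
    the diagonal is forced to none.  The transformation is invariant under
    scaling by any positive constant.
    """
    values = scores.values.astype(float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(f"NaN score at ({scores.index[i]}, {scores.columns[j]})")
    labels = np.where(values > 0, CROSS_FEEDING, np.where(values < 0, COMPETITION, NONE_LABEL))
    frame = pd.DataFrame(labels, index=scores.index, columns=scores.columns)
    asym = int((values != values.T).sum() // 2)
    if asym:
        logger.warning("score matrix is asymmetric at %d unordered pairs; "
                       "unordered-pair labels use the (row < column) cell", asym)
    return LabelMatrix(frame)


def _align(a: LabelMatrix, b: LabelMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    sa, sb = set(a.organisms), set(b.organisms)
    if sa != sb:
        raise ValidationError(
            f"organism sets differ: only-in-first={sorted(sa - sb)[:5]}, "
            f"only-in-second={sorted(sb - sa)[:5]}"
        )
    order = list(a.organisms)
    return a.frame, b.frame.loc[order, order]


def consensus_matrix(a: LabelMatrix, b: LabelMatrix) -> ConsensusMatrix:
    """Cell-wise agreement of two label matrices (order reconciled by name)."""
    fa, fb = _align(a, b)
    both_cf = (fa.values == CROSS_FEEDING) & (fb.values == CROSS_FEEDING)
    both_co = (fa.values == COMPETITION) & (fb.values == COMPETITION)
    vals = np.where(both_cf, 1, np.where(both_co, -1, 0))
    np.fill_diagonal(vals, 0)
    return ConsensusMatrix(pd.DataFrame(vals, index=fa.index, columns=fa.columns))


def score_against_reference(
    predictions: LabelMatrix,
    reference: LabelMatrix,
    discard_none: bool = True,
) -> tuple[ConfusionCounts, MetricPanel]:
    """Score a prediction matrix against a labelled reference.

    Works over unordered pairs (upper triangle).  With ``discard_none`` the
    reference's "no interaction" pairs are dropped before scoring, matching
    the convention of evaluating only pairs with a reported interaction.  A
    predicted "none" on a scored pair counts as a misclassification of the
    reference class.
    """
    fp, fr = _align(predictions, reference)
    n = fp.shape[0]
    if n < 2:
        raise ValidationError("need at least two shared organisms")
    iu = np.triu_indices(n, k=1)
    pred = fp.values[iu]
    ref = fr.values[iu]
    if discard_none:
        keep = ref != NONE_LABEL
        pred, ref = pred[keep], ref[keep]
    elif (ref == NONE_LABEL).any():
        raise ValidationError(
            "reference contains 'none' pairs; two-class scoring requires discard_none=True"
        )
    if len(ref) == 0:
        raise ValidationError("no labelled reference pairs to score")
    counts = ConfusionCounts(
        tp_co=int(((ref == COMPETITION) & (pred == COMPETITION)).sum()),
        fn_co=int(((ref == COMPETITION) & (pred != COMPETITION)).sum()),
        fn_cf=int(((ref == CROSS_FEEDING) & (pred != CROSS_FEEDING)).sum()),
        tp_cf=int(((ref == CROSS_FEEDING) & (pred == CROSS_FEEDING)).sum()),
    )
    return counts, panel_from_counts(counts)
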