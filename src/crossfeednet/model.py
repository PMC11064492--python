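"""Model/Results front door over the cross-validation machinery.

``InteractionModel`` bundles an encoded pair dataset with a classifier
specification and fold parameters; ``fit()`` runs the leakage-aware
cross-validation and returns an ``InteractionResults`` carrying pooled
predictions, confusion counts, the scalar metric panel, ROC/PR curves and a
printable ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import ClassifierSpec, PredictionSet, cross_validate
from .encoding import COMPETITION, CROSS_FEEDING, PairDataset
from .folding import FoldAssignment, assemble_folds, audit_leakage, cluster_pairs
from .metrics import (
    ConfusionCounts,
    CurveResult,
    MetricPanel,
    panel_from_counts,
    pr_curve_and_auc,
    random_baseline_precision,
    roc_curve_and_auc,
)


class InteractionModel:
    """A classifier to be evaluated on an encoded pair dataset.

    Parameters
    ----------
    dataset : the oriented, augmented pair dataset.
    classifier : a ``ClassifierSpec``; defaults to the KNN baseline
        (k=3, Euclidean, uniform votes).
    folds : a ready ``FoldAssignment``; if omitted, folds are built by
        k-means clustering (``n_clusters``) merged greedily into ``n_folds``.
    """

    def __init__(
        self,
        dataset: PairDataset,
        classifier: ClassifierSpec | None = None,
        folds: FoldAssignment | None = None,
        n_clusters: int = 10,
        n_folds: int = 4,
        seed: int = 0,
    ):
        self.dataset = dataset
        self.classifier = classifier or ClassifierSpec("knn", {"k": 3}, seed=seed)
        self.seed = seed
        if folds is None:
            clusters = cluster_pairs(dataset, n_clusters=n_clusters, seed=seed)
            folds = assemble_folds(clusters, dataset, n_folds=n_folds)
        self.folds = folds

    @classmethod
    def from_components(cls, records, profiles, pool, **kwargs) -> "InteractionModel":
        """Build from raw interaction records and organism profiles."""
        from .encoding import augment_dataset

        return cls(augment_dataset(records, profiles, pool), **kwargs)

    def fit(self, threshold: float = 0.5) -> "InteractionResults":
        predictions, counts = cross_validate(
            self.classifier, self.dataset, self.folds, threshold=threshold
        )
        return InteractionResults(self, predictions, counts)


@dataclass
class InteractionResults:
    """Pooled cross-validation results for one classifier."""

    model: InteractionModel
    predictions: PredictionSet
    counts: ConfusionCounts

    @property
    def panel(self) -> MetricPanel:
        return panel_from_counts(self.counts)

    @property
    def accuracy(self) -> float:
        return self.panel.accuracy

    @property
    def balanced_accuracy(self) -> float:
        return self.panel.balanced_accuracy

    def roc(self, target: str = COMPETITION) -> CurveResult:
        return roc_curve_and_auc(self.predictions.true_labels, self.predictions.scores, target)

    def pr(self, target: str = COMPETITION) -> CurveResult:
        return pr_curve_and_auc(self.predictions.true_labels, self.predictions.scores, target)

    def random_baselines(self) -> dict[str, float]:
        return random_baseline_precision(self.model.dataset.class_counts)

    def leakage_audit(self):
        return audit_leakage(self.model.folds, self.model.dataset)

    def to_report(self) -> dict:
        from .metrics import metric_report

        report = metric_report(
            self.model.classifier.describe(),
            self.counts,
            true_labels=self.predictions.true_labels,
            scores_cf=self.predictions.scores,
        )
        report["pool_hash"] = self.model.dataset.pool.content_hash
        report["n_vectors"] = len(self.model.dataset)
        report["n_folds"] = self.model.folds.n_folds
        report["random_baseline_precision"] = self.random_baselines()
        report["leakage_audit"] = self.leakage_audit().to_json()
        return report

    def summary(self) -> str:
        """Printable summary in the style of a fitted-model report."""
        p = self.panel
        d = p.display()
        base = self.random_baselines()
        lines = [
            "Pairwise interaction classification (pooled cross-validation)",
            "=" * 62,
            f"classifier:        {self.model.classifier.describe()}",
            f"pair vectors:      {len(self.model.dataset)}  "
            f"(P={len(self.model.dataset.pool)}, 2P={2 * len(self.model.dataset.pool)})",
            f"folds:             {self.model.folds.n_folds}  (leakage audit: "
            f"{'clean' if self.leakage_audit().ok else 'VIOLATIONS'})",
            "-" * 62,
            f"counts:            TP_co={self.counts.tp_co}  FN_co={self.counts.fn_co}  "
            f"FN_cf={self.counts.fn_cf}  TP_cf={self.counts.tp_cf}",
            f"competition:       P={d['precision_co']}  R={d['recall_co']}  F1={d['f1_co']}  "
            f"(random-precision baseline {base.get(COMPETITION, float('nan')):.2f})",
            f"cross-feeding:     P={d['precision_cf']}  R={d['recall_cf']}  F1={d['f1_cf']}  "
            f"(random-precision baseline {base.get(CROSS_FEEDING, float('nan')):.2f})",
            f"accuracy:          {d['accuracy']}",
            f"balanced accuracy: {d['balanced_accuracy']}",
            f"ROC AUC (co/cf):   {self.roc(COMPETITION).area:.3f} / "
            f"{self.roc(CROSS_FEEDING).area:.3f}",
            f"PR AUC (co/cf):    {self.pr(COMPETITION).area:.3f} / "
            f"{self.pr(CROSS_FEEDING).area:.3f}",
            "=" * 62,
        ]
        return "\n".join(lines)

    def per_fold_counts(self) -> list[ConfusionCounts]:
        out = []
        for f in range(self.model.folds.n_folds):
            mask = self.predictions.fold_indices == f
            out.append(ConfusionCounts.from_labels(
                self.predictions.true_labels[np.asarray(mask)],
                self.predictions.predicted_labels[np.asarray(mask)],
            ))
        return out
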