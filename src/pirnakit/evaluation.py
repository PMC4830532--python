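"""Threshold and ranking metrics plus the 10-fold cross-validation driver.

Sensitivity SN = TP / (TP + FN), specificity SP = TN / (TN + FP),
accuracy ACC = (TP + TN) / total, and the area under the ROC curve
(AUC), the threshold-free primary metric. ACC/SN/SP are reported at a
probability threshold of 0.5.

The outer evaluation is 10-fold cross-validation: the labeled dataset
is split into 10 stratified folds; for each fold a full model (including
any feature-subset selection) is built on the other nine and scored on
the held-out one. Per-fold metrics are averaged; pooled-over-folds AUC
is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from pirnakit.model_training import CombinationModel, _labels_to_y
from pirnakit.sequence_io import SequenceSet


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    auc: float
    acc: float
    sn: float
    sp: float
    confusion: ConfusionCounts


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation results."""

    folds: list[FoldMetrics]
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR from pooled scores
    pooled_auc: float
    seed: int
    fold_assignment: dict[str, int]
    selected_subsets: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    @property
    def mean_acc(self) -> float:
        return float(np.mean([f.acc for f in self.folds]))

    @property
    def mean_sn(self) -> float:
        return float(np.mean([f.sn for f in self.folds]))

    @property
    def mean_sp(self) -> float:
        return float(np.mean([f.sp for f in self.folds]))

    def save(self, directory: str | Path) -> None:
        """Write report.json plus a ROC-points TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "seed": self.seed,
            "mean": {
                "AUC": self.mean_auc,
                "ACC": self.mean_acc,
                "SN": self.mean_sn,
                "SP": self.mean_sp,
            },
            "pooled_AUC": self.pooled_auc,
            "folds": [
                {
                    "fold": f.fold,
                    "AUC": f.auc,
                    "ACC": f.acc,
                    "SN": f.sn,
                    "SP": f.sp,
                    "TP": f.confusion.TP,
                    "FP": f.confusion.FP,
                    "TN": f.confusion.TN,
                    "FN": f.confusion.FN,
                }
                for f in self.folds
            ],
            "selected_subsets": [list(s) for s in self.selected_subsets],
            "fold_assignment": self.fold_assignment,
        }
        (directory / "report.json").write_text(json.dumps(payload, indent=2))
        with open(directory / "roc.tsv", "w") as fh:
            fh.write("FPR\tTPR\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")


def metrics_at_threshold(
    scores: Sequence[float], labels: Sequence, threshold: float = 0.5
) -> dict:
    """SN, SP, ACC and the confusion counts at a score threshold.

    A record is called positive when its score is >= the threshold.
    """
    from pirnakit.model_training import _as_y

    y = _as_y(labels)
    _check_two_classes(y)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    counts = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    return {
        "SN": tp / (tp + fn),
        "SP": tn / (tn + fp),
        "ACC": (tp + tn) / counts.total,
        "confusion": counts,
    }


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve (equals the Mann-Whitney statistic)."""
    from pirnakit.model_training import _as_y

    y = _as_y(labels)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def tenfold_cv(
    dataset: SequenceSet,
    builder: Callable[[SequenceSet], CombinationModel],
    seed: int,
    folds: int = 10,
    annotations: Optional[Mapping] = None,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold (default 10) cross-validation of a model recipe.

    ``builder`` maps a training SequenceSet to a fitted
    CombinationModel; everything the model learns -- including any
    feature-subset selection -- happens inside the builder on the
    training folds only. Metrics are computed per held-out fold and
    averaged; the ROC curve and a pooled AUC are computed from all
    held-out scores together.
    """
    y = _labels_to_y(dataset.labels())
    _check_two_classes(y)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} records per class for {folds}-fold CV, "
            f"got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics: list[FoldMetrics] = []
    subsets: list[tuple[str, ...]] = []
    pooled_scores = np.zeros(len(y))
    assignment: dict[str, int] = {}
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_set = dataset.subset(tr)
        test_set = dataset.subset(te)
        model = builder(train_set)
        scores = model.predict_scores(test_set, annotations=annotations)
        pooled_scores[te] = scores
        for i in te:
            assignment[dataset[i].id] = f
        m = metrics_at_threshold(scores, y[te], threshold)
        fold_metrics.append(
            FoldMetrics(
                fold=f,
                auc=float(roc_auc_score(y[te], scores)),
                acc=m["ACC"],
                sn=m["SN"],
                sp=m["SP"],
                confusion=m["confusion"],
            )
        )
        subsets.append(tuple(model.selected_features))
    fpr, tpr, _ = roc_curve(y, pooled_scores)
    return CVReport(
        folds=fold_metrics,
        roc_points=np.column_stack([fpr, tpr]),
        pooled_auc=float(roc_auc_score(y, pooled_scores)),
        seed=seed,
        fold_assignment=assignment,
        selected_subsets=subsets,
    )
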