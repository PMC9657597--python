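"""Training protocol, cross-validation, metrics and candidate ranking.

The evaluation protocol mirrors the standard link-prediction setup for
curated association databases: known associations are positives, an equal
number of uniformly sampled zero entries are negatives, the pooled samples
are split into k folds, and in every round the held-out positives are
removed from the adjacency matrix *before* any subgraph is extracted so the
supervised label never leaks into model inputs.

Metrics at a fixed threshold are ACC, precision, recall, FPR and MCC from
the confusion matrix; AUROC and AUPR are threshold-free areas obtained by
trapezoidal integration over the score curves.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from . import nn
from .data import (
    AssociationMatrix,
    PairSample,
    make_cv_folds,
    mask_test_positives,
    sample_negative_pairs,
)
from .model import ModelConfig, TrainedModel
from .subgraph import LabelEncoding, batch_extract

__all__ = [
    "TrainSpec",
    "MetricsReport",
    "CVResult",
    "train",
    "predict_pairs",
    "compute_metrics",
    "cross_validate",
    "rank_candidates",
    "mean_metrics",
]


@dataclass
class TrainSpec:
    """Optimization settings: adaptive-moment gradient descent (Adam)."""

    epochs: int = 50
    batch_size: int = 50
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class MetricsReport:
    """The six evaluation metrics plus curve points for one evaluation."""

    acc: float
    precision: float
    recall: float
    fpr: float
    auroc: float
    aupr: float
    mcc: float
    threshold: float
    roc_points: list[tuple[float, float]] | None = None
    pr_points: list[tuple[float, float]] | None = None
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        return {
            m: getattr(self, m)
            for m in ("acc", "precision", "recall", "fpr", "auroc", "aupr", "mcc")
        }

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["metric", "value"])
            for k, v in self.summary().items():
                w.writerow([k, f"{v:.6f}"])


def train(
    subgraphs: Sequence,
    config: ModelConfig,
    spec: TrainSpec,
) -> TrainedModel:
    """Train the classifier on labeled subgraphs (thin wrapper over the
    :class:`~linkgnn.estimator.SubgraphGNNClassifier` estimator)."""
    from .estimator import SubgraphGNNClassifier

    clf = SubgraphGNNClassifier.from_config(config, spec)
    clf.fit(list(subgraphs))
    return clf.model_


def predict_pairs(
    model: TrainedModel,
    mat: AssociationMatrix,
    pairs: Sequence[tuple[int, int] | PairSample],
    h: int,
) -> np.ndarray:
    """Score arbitrary (row, col) pairs; each pair's own edge is masked
    during extraction, so a score never uses the link it predicts."""
    encoding = LabelEncoding(cap=model.feature_width - 2)
    samples = [
        s if isinstance(s, PairSample) else PairSample(int(s[0]), int(s[1]), 0)
        for s in pairs
    ]
    if not samples:
        return np.zeros(0)
    subs = batch_extract(mat, samples, h, encoding)
    batches = nn.make_batches(subs, batch_size=64, prop_names=model.config.propagators)
    scores = []
    for b in batches:
        logp, _ = nn.net_forward(model.parameters, model.config, b, model.resolved_k)
        scores.append(np.exp(logp[:, 1]))
    return np.concatenate(scores)


def _brute_counts(scores, labels, threshold):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def compute_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    curves: bool = True,
) -> MetricsReport:
    """Confusion-matrix metrics at ``threshold`` plus AUROC/AUPR.

    Zero-denominator metrics are reported as 0 with a warning flag rather
    than raising; AUROC/AUPR require both classes and raise otherwise.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC/AUPR undefined with a single class")

    tp, fp, tn, fn = _brute_counts(scores, labels, threshold)
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name}: zero denominator")
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    fpr = ratio(fp, fp + tn, "fpr")
    acc = (tp + tn) / len(labels)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.append("mcc: zero denominator")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)

    fpr_c, tpr_c, _ = roc_curve(labels, scores)
    auroc = float(np.trapezoid(tpr_c, fpr_c))
    prec_c, rec_c, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve returns recall in decreasing order
    aupr = float(-np.trapezoid(prec_c, rec_c))

    return MetricsReport(
        acc=float(acc),
        precision=float(precision),
        recall=float(recall),
        fpr=float(fpr),
        auroc=auroc,
        aupr=aupr,
        mcc=float(mcc),
        threshold=threshold,
        roc_points=list(zip(fpr_c.tolist(), tpr_c.tolist())) if curves else None,
        pr_points=list(zip(rec_c.tolist(), prec_c.tolist())) if curves else None,
        warnings=flags,
    )


def mean_metrics(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Average the scalar metrics over folds (curves are dropped)."""
    return MetricsReport(
        **{m: float(np.mean([getattr(r, m) for r in reports]))
           for m in ("acc", "precision", "recall", "fpr", "auroc", "aupr", "mcc")},
        threshold=reports[0].threshold,
    )


@dataclass
class CVResult:
    folds: list[MetricsReport]
    mean: MetricsReport
    fold_plan: object = None


def cross_validate(
    mat: AssociationMatrix,
    h: int,
    config: ModelConfig,
    spec: TrainSpec,
    n_folds: int = 10,
    seed: int = 0,
    rounds: int | None = None,
    encoding: LabelEncoding | None = None,
    threshold: float = 0.5,
) -> CVResult:
    """k-fold cross-validation over pooled positive and sampled negatives.

    Per round the fold's positives are removed from Y, train and test
    subgraphs are extracted from the masked matrix, the model is trained on
    the training folds and evaluated on the held-out fold.  ``rounds``
    limits how many folds are evaluated (``rounds=1`` is a single 1/n_folds
    holdout split).
    """
    if encoding is None:
        encoding = LabelEncoding()
    positives = mat.positive_pairs()
    negatives = sample_negative_pairs(mat, len(positives), seed=seed)
    samples = positives + negatives
    plan = make_cv_folds(samples, n_folds, seed=seed)

    reports: list[MetricsReport] = []
    n_rounds = n_folds if rounds is None else min(rounds, n_folds)
    for fold in range(n_rounds):
        test = [samples[i] for i in plan.test_indices(fold)]
        train_set = [samples[i] for i in plan.train_indices(fold)]
        masked = mask_test_positives(mat, test)
        train_subs = batch_extract(masked, train_set, h, encoding)
        test_subs = batch_extract(masked, test, h, encoding)
        model = train(train_subs, config, spec)
        batches = nn.make_batches(
            test_subs, batch_size=64, prop_names=config.propagators
        )
        scores = np.concatenate([
            np.exp(nn.net_forward(model.parameters, config, b, model.resolved_k)[0][:, 1])
            for b in batches
        ])
        labels = np.array([s.label for s in test])
        reports.append(compute_metrics(scores, labels, threshold, curves=True))
    return CVResult(folds=reports, mean=mean_metrics(reports), fold_plan=plan)


def rank_candidates(
    model: TrainedModel,
    mat: AssociationMatrix,
    target: str,
    h: int,
) -> list[tuple[str, float]]:
    """Rank every unobserved side-A partner of one side-B entity.

    Scores all zero entries of the target's column, sorted by descending
    score with ties broken by identifier for determinism.
    """
    if target not in mat.col_ids:
        raise KeyError(f"unknown target id {target!r}")
    j = mat.col_ids.index(target)
    rows = np.flatnonzero(mat.Y[:, j] == 0)
    if len(rows) == 0:
        return []
    pairs = [(int(r), j) for r in rows]
    scores = predict_pairs(model, mat, pairs, h)
    ranked = sorted(
        zip((mat.row_ids[r] for r in rows), scores.tolist()),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked
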