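"""Balanced-sampling cross-validation, RBF-SVM training, and residue-level metrics.

Binding residues are rare (roughly one in seven), so each fold's
classifier is trained on *all* positive residues of its training
partition plus an equal-size random draw of negatives (without
replacement).  Evaluation keeps the natural imbalance: every held-out
sample — positives and all negatives — is scored, and metrics are pooled
over the concatenated held-out scores.

Metrics: ACC, SN (recall), SP, PR (precision), F1, MCC in standard form
(with the square root over the four-factor denominator product), and ROC
AUC by trapezoid over the threshold sweep.  A metric whose denominator is
zero is reported as ``None`` (undefined), never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from pssmpp.encoders import WindowSpec, build_feature_matrix
from pssmpp.pssm import PSSMProfile, ResidueSample


class CVPlanError(ValueError):
    """The requested fold structure is infeasible for the data."""


class SingleClassError(ValueError):
    """Training or scoring requires both classes present."""


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )


@dataclass
class MetricsReport:
    """Residue-level metric suite; undefined metrics are ``None``."""

    ACC: float | None
    SN: float | None
    SP: float | None
    PR: float | None
    MCC: float | None
    F1: float | None
    AUC: float | None
    threshold: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "ACC": self.ACC, "SN": self.SN, "SP": self.SP, "PR": self.PR,
            "MCC": self.MCC, "F1": self.F1, "AUC": self.AUC,
            "threshold": self.threshold,
            "TP": self.counts.TP, "FP": self.counts.FP,
            "TN": self.counts.TN, "FN": self.counts.FN,
        }


@dataclass
class CVPlan:
    """Fold assignment plus the balanced negative draw, fixed by a seed.

    ``assignment[i]`` is the fold holding sample ``i`` out; the training
    partition of fold k is every positive outside fold k plus
    ``negative_draw[k]`` (an equal number of negatives drawn uniformly
    without replacement).
    """

    folds: int
    assignment: np.ndarray
    negative_draw: list[np.ndarray]
    seed: int
    grouping: str = "chain"

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def train_indices(self, k: int, labels: np.ndarray) -> np.ndarray:
        outside = self.assignment != k
        pos = np.flatnonzero(outside & (labels == 1))
        return np.concatenate([pos, self.negative_draw[k]])


def build_cv_plan(
    samples: Sequence[ResidueSample],
    folds: int = 5,
    seed: int = 0,
    grouping: str = "chain",
) -> CVPlan:
    """Deterministic balanced-CV plan.

    ``grouping="chain"`` (default) assigns whole chains to folds so
    overlapping windows of one chain never straddle a train/test split;
    ``grouping="residue"`` partitions residues directly.
    """
    if grouping not in ("chain", "residue"):
        raise ValueError(f"grouping must be 'chain' or 'residue', got {grouping!r}")
    labels = np.array([s.label for s in samples], dtype=int)
    n = len(samples)
    rng = np.random.default_rng(seed)

    if grouping == "chain":
        chains = sorted({s.chain_id for s in samples})
        if len(chains) < folds:
            raise CVPlanError(
                f"{len(chains)} chains cannot fill {folds} folds; use fewer folds"
            )
        order = rng.permutation(len(chains))
        chain_fold = {chains[idx]: k % folds for k, idx in enumerate(order)}
        assignment = np.array([chain_fold[s.chain_id] for s in samples], dtype=int)
    else:
        if n < folds:
            raise CVPlanError(f"{n} samples cannot fill {folds} folds; use fewer folds")
        assignment = np.empty(n, dtype=int)
        assignment[rng.permutation(n)] = np.arange(n) % folds

    negative_draw: list[np.ndarray] = []
    for k in range(folds):
        held_out = assignment == k
        if labels[held_out].sum() == 0:
            raise CVPlanError(f"fold {k} contains no positive residues; use fewer folds")
        outside = ~held_out
        n_pos = int(labels[outside].sum())
        neg_pool = np.flatnonzero(outside & (labels == 0))
        if n_pos == 0:
            raise CVPlanError(f"training partition of fold {k} has no positives; use fewer folds")
        if len(neg_pool) < n_pos:
            raise CVPlanError(
                f"training partition of fold {k} has {len(neg_pool)} negatives "
                f"for {n_pos} positives; balanced draw infeasible"
            )
        drawn = rng.choice(neg_pool, size=n_pos, replace=False)
        negative_draw.append(np.sort(drawn))
    return CVPlan(folds=folds, assignment=assignment, negative_draw=negative_draw,
                  seed=seed, grouping=grouping)


def train_classifier(X: np.ndarray, y: np.ndarray) -> SVC:
    """Fit an RBF-kernel SVM at library-default hyperparameters.

    The returned classifier exposes a real-valued decision score per
    sample via ``decision_function``.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training set contains a single class")
    clf = SVC(kernel="rbf")
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics_from_counts(counts: ConfusionCounts, threshold: float = 0.0) -> MetricsReport:
    """Metric suite from a 2x2 confusion table (AUC left unset)."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sn = _ratio(tp, tp + fn)
    pr = _ratio(tp, tp + fp)
    mcc_den = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / sqrt(mcc_den)
    f1 = None if sn is None or pr is None or (sn + pr) == 0 else 2 * sn * pr / (sn + pr)
    return MetricsReport(
        ACC=_ratio(tp + tn, counts.total),
        SN=sn,
        SP=_ratio(tn, tn + fp),
        PR=pr,
        MCC=mcc,
        F1=f1,
        AUC=None,
        threshold=threshold,
        counts=counts,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, list[tuple[float, float]]]:
    """ROC AUC (trapezoid over the threshold sweep) plus the ROC point list.

    Equivalent to the Mann–Whitney statistic with midrank tie handling.
    Points are (1-specificity, sensitivity) pairs.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise SingleClassError("ROC undefined: only one class present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), list(zip(fpr.tolist(), tpr.tolist()))


def counts_at_threshold(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionCounts:
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


@dataclass
class CVResult:
    pooled: MetricsReport
    fold_reports: list[MetricsReport]
    scores: np.ndarray  # held-out decision score per sample, aligned with samples
    plan: CVPlan
    samples: list[ResidueSample] = field(default_factory=list)


def cross_validate(
    profiles: dict[str, PSSMProfile],
    samples: Sequence[ResidueSample],
    plan: CVPlan,
    encoder_name: str = "pssmpp",
    spec: WindowSpec | None = None,
    scales=None,
    threshold: float = 0.0,
) -> CVResult:
    """Run the balanced-CV protocol and pool held-out predictions.

    Per fold: train on the balanced training partition, score every
    held-out sample.  The pooled report applies ``threshold`` to the
    concatenated held-out scores (SVM decision value 0 by default) and
    computes AUC over them; per-fold reports carry fold-local counts and
    AUC where both classes are present in the fold.
    """
    spec = spec or WindowSpec()
    fm = build_feature_matrix(encoder_name, profiles, samples, spec, scales)
    return cross_validate_features(fm.values, samples, plan, threshold)


def cross_validate_features(
    X: np.ndarray,
    samples: Sequence[ResidueSample],
    plan: CVPlan,
    threshold: float = 0.0,
) -> CVResult:
    """As :func:`cross_validate`, on an already-encoded feature matrix."""
    labels = np.array([s.label for s in samples], dtype=int)
    scores = np.empty(len(samples), dtype=float)
    fold_reports: list[MetricsReport] = []
    for k in range(plan.folds):
        train_idx = plan.train_indices(k, labels)
        test_idx = plan.test_indices(k)
        try:
            clf = train_classifier(X[train_idx], labels[train_idx])
        except SingleClassError as exc:
            raise SingleClassError(f"fold {k}: {exc}") from exc
        fold_scores = clf.decision_function(X[test_idx])
        scores[test_idx] = fold_scores
        report = metrics_from_counts(
            counts_at_threshold(fold_scores, labels[test_idx], threshold), threshold
        )
        fold_labels = labels[test_idx]
        if fold_labels.min() != fold_labels.max():
            report.AUC = roc_auc(fold_scores, fold_labels)[0]
        fold_reports.append(report)

    pooled = metrics_from_counts(counts_at_threshold(scores, labels, threshold), threshold)
    pooled.AUC = roc_auc(scores, labels)[0]
    return CVResult(pooled=pooled, fold_reports=fold_reports, scores=scores,
                    plan=plan, samples=list(samples))


def write_metrics_tsv(reports: dict[str, MetricsReport], path) -> None:
    """Metrics table, one row per named report (mirrors the ACC..AUC layout)."""
    cols = ["ACC", "SN", "SP", "PR", "MCC", "F1", "AUC", "TP", "FP", "TN", "FN"]
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(cols) + "\n")
        for name, rep in reports.items():
            d = rep.as_dict()
            fh.write(name + "\t" + "\t".join(
                "NA" if d[c] is None else (f"{d[c]:.6g}" if isinstance(d[c], float) else str(d[c]))
                for c in cols) + "\n")


def write_roc_csv(points: list[tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6g},{tpr:.6g}\n")


def write_predictions_tsv(result: CVResult, profiles: dict[str, PSSMProfile], path) -> None:
    """Per-residue predictions: chain, position, residue, score, predicted, true."""
    with open(path, "w") as fh:
        fh.write("chain_id\tposition\tresidue\tscore\tpredicted\tlabel\n")
        for s, score in zip(result.samples, result.scores):
            residue = profiles[s.chain_id].sequence[s.position - 1]
            pred = int(score > result.pooled.threshold)
            fh.write(f"{s.chain_id}\t{s.position}\t{residue}\t{score:.6g}\t{pred}\t{s.label}\n")
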