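"""Evaluation protocol: stratified split, k-fold CV, macro metrics, FP triage.

Labeled pairs are split 7:3 stratified by interaction type; model quality is
summarized by accuracy, macro-averaged one-vs-rest precision/recall, and a
macro F1 computed as the harmonic mean of macro precision and macro recall.
Abstentions (winning probability below the decision threshold) count as
errors for accuracy and as recall failures per type, but never enter a
precision denominator — abstaining is "no prediction", not a wrong class.
Misclassified pairs sorted by confidence give the false-positive triage list:
the highest-confidence disagreements with the gold standard are the most
interesting candidates for being real but unrecorded interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .feature_model import ModelConfig, ReducedProfiles, predict_batch, train
from .io_formats import DDIPair, PredictionResult

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Metrics for one evaluated prediction set."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_type_accuracy: dict[int, float]
    n_pairs: int
    abstention_rate: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n_pairs": self.n_pairs,
            "abstention_rate": self.abstention_rate,
            "per_type_accuracy": {str(k): v for k, v in self.per_type_accuracy.items()},
        }


def stratified_split(
    pairs: Sequence[DDIPair], train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[DDIPair], list[DDIPair]]:
    """Disjoint, exhaustive per-type split; proportions within one pair of target.

    Types with a single pair go wholly to the training set with a warning —
    they cannot be split.
    """
    if not pairs:
        raise ValidationError("cannot split an empty pair list")
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_type: dict[int, list[int]] = {}
    for i, p in enumerate(pairs):
        by_type.setdefault(p.ddi_type, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for t in sorted(by_type):
        idx = np.array(by_type[t])
        if len(idx) < 2:
            logger.warning("type %d has a single pair; placed wholly in train", t)
            train_idx.extend(idx.tolist())
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[perm[:n_train]].tolist())
        test_idx.extend(idx[perm[n_train:]].tolist())
    return (
        [pairs[i] for i in sorted(train_idx)],
        [pairs[i] for i in sorted(test_idx)],
    )


def stratified_folds(
    pairs: Sequence[DDIPair], k: int = 4, seed: int = 0
) -> list[list[int]]:
    """Indices of k stratified folds; types with < k pairs all land in fold 0."""
    if k < 2:
        raise ValidationError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    by_type: dict[int, list[int]] = {}
    for i, p in enumerate(pairs):
        by_type.setdefault(p.ddi_type, []).append(i)
    for t in sorted(by_type):
        idx = np.array(by_type[t])
        if len(idx) < k:
            logger.warning("type %d has %d < %d pairs; placed in one fold", t, len(idx), k)
            folds[0].extend(idx.tolist())
            continue
        perm = rng.permutation(len(idx))
        for fold_i, chunk in enumerate(np.array_split(idx[perm], k)):
            folds[fold_i].extend(chunk.tolist())
    return [sorted(f) for f in folds]


def compute_metrics(
    truth: Sequence[int],
    predictions: Sequence[PredictionResult],
    n_types: int,
    f1_per_type_mean: bool = False,
) -> EvalReport:
    """Score predictions against true labels.

    Macro precision/recall average one-vs-rest values over the types present
    in the truth set. Macro F1 is by default the harmonic mean of macro
    precision and macro recall; ``f1_per_type_mean=True`` switches to the
    unweighted mean of per-type F1 scores.
    """
    if len(truth) != len(predictions):
        raise ValidationError(
            f"truth/prediction length mismatch: {len(truth)} vs {len(predictions)}"
        )
    if not truth:
        raise ValidationError("nothing to evaluate")
    y = np.array(truth, dtype=int)
    pred = np.array(
        [0 if r.predicted_type is None else r.predicted_type for r in predictions],
        dtype=int,
    )  # 0 encodes abstention; never a valid type
    correct = pred == y
    accuracy = float(correct.mean())
    abstained = pred == 0
    types_present = sorted(set(y.tolist()))
    precisions, recalls, f1s = [], [], []
    per_type_acc: dict[int, float] = {}
    for t in types_present:
        tp = int(np.sum((pred == t) & (y == t)))
        predicted_t = int(np.sum(pred == t))  # abstentions excluded by encoding
        actual_t = int(np.sum(y == t))
        prec = tp / predicted_t if predicted_t else 0.0
        rec = tp / actual_t
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if (prec + rec) else 0.0)
        per_type_acc[t] = rec  # within-type accuracy == one-vs-rest recall
    macro_p = float(np.mean(precisions))
    macro_r = float(np.mean(recalls))
    if f1_per_type_mean:
        macro_f1 = float(np.mean(f1s))
    else:
        macro_f1 = 2 * macro_p * macro_r / (macro_p + macro_r) if (macro_p + macro_r) else 0.0
    return EvalReport(
        accuracy=accuracy,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=float(macro_f1),
        per_type_accuracy=per_type_acc,
        n_pairs=len(y),
        abstention_rate=float(abstained.mean()),
    )


def cross_validate(
    pairs: Sequence[DDIPair],
    reduced: ReducedProfiles,
    config: ModelConfig,
    k: int = 4,
    seed: int = 0,
) -> tuple[list[EvalReport], dict[str, float]]:
    """k-fold stratified cross-validation of the full train/predict cycle.

    Returns one report per held-out fold plus a mean/stdev summary of the
    headline metrics. Fold assignment depends only on (labels, seed), not on
    the input ordering of equal pair lists.
    """
    canonical = sorted(pairs, key=lambda p: (p.drug_a, p.drug_b, p.ddi_type))
    folds = stratified_folds(canonical, k=k, seed=seed)
    reports = []
    for fold_i, test_idx in enumerate(folds):
        test_set = set(test_idx)
        train_pairs = [p for i, p in enumerate(canonical) if i not in test_set]
        test_pairs = [canonical[i] for i in test_idx]
        if not test_pairs:
            logger.warning("fold %d is empty; skipped", fold_i)
            continue
        model = train(train_pairs, reduced, config)
        preds = predict_batch(model, test_pairs, reduced)
        reports.append(
            compute_metrics([p.ddi_type for p in test_pairs], preds, config.n_types)
        )
    accs = [r.accuracy for r in reports]
    f1s = [r.macro_f1 for r in reports]
    summary = {
        "mean_accuracy": float(np.mean(accs)),
        "std_accuracy": float(np.std(accs)),
        "mean_macro_f1": float(np.mean(f1s)),
        "std_macro_f1": float(np.std(f1s)),
        "k": float(len(reports)),
    }
    return reports, summary


def rank_false_positives(
    truth: Sequence[int],
    predictions: Sequence[PredictionResult],
    top_k: int = 10,
) -> list[tuple[tuple[str, str], int, int, float]]:
    """Misclassified, non-abstained pairs by descending confidence (top_k kept).

    Ties in confidence break lexicographically on (drug_a, drug_b) for stable
    reports. These are the candidate novel interactions: confidently
    predicted types that contradict the gold standard.
    """
    if len(truth) != len(predictions):
        raise ValidationError("truth/prediction length mismatch")
    errors = [
        ((r.drug_a, r.drug_b), r.predicted_type, t, r.confidence)
        for t, r in zip(truth, predictions)
        if r.predicted_type is not None and r.predicted_type != t
    ]
    errors.sort(key=lambda e: (-e[3], e[0]))
    return errors[:top_k]
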