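"""Performance evaluation: Sn/Sp/Acc/MCC and cross-validation protocols.

Sensitivity, specificity, accuracy and the Matthews correlation
coefficient are computed from confusion counts::

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is the headline metric: it stays meaningful under class imbalance,
where accuracy is dominated by the majority class.

``cross_validate`` runs stratified k-fold CV once per replicated
negative set and reports the mean ± standard deviation across
replicates.  Within one replicate, confusion counts are pooled over
folds before computing metrics, so setting ``k`` equal to the sample
count degenerates exactly into leave-one-out validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import DatasetBundle, PeptideWindow
from .encoders import EncoderConfig, encode_windows
from .svm import SvmHyperparams, grid_search, predict, train


class EvaluationError(ValueError):
    pass


class LeakageError(EvaluationError):
    """Train/test protein overlap in an independent-test protocol."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    acc: float
    mcc: float
    counts: ConfusionCounts


@dataclass
class CVReport:
    """Cross-validation results over replicated negative sets."""

    per_set: list[MetricSet]
    per_fold: list[list[MetricSet]]
    #: pooled out-of-fold (true, predicted) label arrays per negative set
    predictions: list[tuple[np.ndarray, np.ndarray]]
    k: int
    ratio: int
    seed: int
    window_size: int
    blocks: tuple[str, ...]
    params_per_set: list[SvmHyperparams] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.per_set]))

    def std(self, metric: str) -> float:
        values = [getattr(m, metric) for m in self.per_set]
        if len(values) < 2:
            return 0.0
        return float(np.std(values, ddof=1))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.std(m)) for m in ("sn", "sp", "acc", "mcc")}


def confusion(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionCounts:
    """Exact confusion counts for 0/1 label arrays (1 = positive)."""
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.shape != y_pred.shape:
        raise EvaluationError(
            f"label length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Sn/Sp/Acc/MCC from counts.

    Degenerate denominators follow the standard convention: an undefined
    Sn or Sp is reported as 0 (with a warning), and an MCC whose root
    contains a zero factor is 0.
    """
    if counts.total == 0:
        raise EvaluationError("cannot compute metrics of zero samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0:
        warnings.warn("no positive samples; Sn reported as 0", stacklevel=2)
        sn = 0.0
    else:
        sn = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative samples; Sp reported as 0", stacklevel=2)
        sp = 0.0
    else:
        sp = tn / (tn + fp)
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts)


def kfold_split(
    n_pos: int, n_neg: int, k: int, seed: int
) -> list[np.ndarray]:
    """Stratified k-fold index partition.

    Indices 0..n_pos-1 denote positives and n_pos..n_pos+n_neg-1
    negatives.  Each fold's class sizes differ by at most one from
    n_class/k; folds are disjoint, cover every index, and are
    reproducible from the seed.  ``k == n_pos + n_neg`` requests
    leave-one-out (singleton folds).
    """
    n = n_pos + n_neg
    if k == n:  # leave-one-out
        return [np.array([i]) for i in range(n)]
    if k < 2:
        raise EvaluationError(f"k must be >= 2, got {k}")
    if k > min(n_pos, n_neg):
        raise EvaluationError(
            f"k={k} exceeds the smaller class count "
            f"(n_pos={n_pos}, n_neg={n_neg}); use k={n} for leave-one-out"
        )
    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(n_pos)
    neg_idx = n_pos + rng.permutation(n_neg)
    pos_folds = np.array_split(pos_idx, k)
    neg_folds = np.array_split(neg_idx, k)
    return [np.concatenate([p, q]) for p, q in zip(pos_folds, neg_folds)]


def _evaluate_one_set(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    encoder_config: EncoderConfig,
    params: SvmHyperparams,
    k: int,
    seed: int,
) -> tuple[MetricSet, list[MetricSet], tuple[np.ndarray, np.ndarray]]:
    windows = list(positives) + list(negatives)
    X, y = encode_windows(windows, encoder_config)
    folds = kfold_split(len(positives), len(negatives), k, seed)
    fold_metrics: list[MetricSet] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    y_true_all, y_pred_all = [], []
    for fold in folds:
        test_mask = np.zeros(len(y), dtype=bool)
        test_mask[fold] = True
        model = train(X[~test_mask], y[~test_mask], params, encoder_config.layout())
        labels, _ = predict(model, X[test_mask])
        counts = confusion(y[test_mask], labels)
        pooled = pooled + counts
        y_true_all.append(y[test_mask])
        y_pred_all.append(labels)
        if counts.tp + counts.fn > 0 and counts.tn + counts.fp > 0:
            fold_metrics.append(metrics(counts))
    return (
        metrics(pooled),
        fold_metrics,
        (np.concatenate(y_true_all), np.concatenate(y_pred_all)),
    )


def cross_validate(
    bundle: DatasetBundle,
    encoder_config: EncoderConfig,
    params: Optional[SvmHyperparams] = None,
    k: int = 10,
    seed: int = 0,
    tune_grid: Optional[Sequence[SvmHyperparams]] = None,
    tune_folds: int = 5,
) -> CVReport:
    """Stratified k-fold CV repeated over every replicated negative set.

    When ``tune_grid`` is given, hyperparameters are grid-searched once
    per negative set (on that set's full training data) before the CV
    run; otherwise ``params`` is used throughout.
    """
    if params is None and tune_grid is None:
        params = SvmHyperparams()
    seeds = np.random.SeedSequence(seed).generate_state(
        2 * len(bundle.negative_sets)
    )
    per_set, per_fold, predictions, params_used = [], [], [], []
    for i, negatives in enumerate(bundle.negative_sets):
        set_params = params
        if tune_grid is not None:
            X, y = encode_windows(
                list(bundle.positives) + list(negatives), encoder_config
            )
            set_params = grid_search(
                X, y, tune_grid, folds=tune_folds, seed=int(seeds[2 * i + 1])
            )
        set_metrics, fold_metrics, preds = _evaluate_one_set(
            bundle.positives,
            negatives,
            encoder_config,
            set_params,
            k,
            int(seeds[2 * i]),
        )
        per_set.append(set_metrics)
        per_fold.append(fold_metrics)
        predictions.append(preds)
        params_used.append(set_params)
    return CVReport(
        per_set=per_set,
        per_fold=per_fold,
        predictions=predictions,
        k=k,
        ratio=bundle.ratio,
        seed=seed,
        window_size=encoder_config.window_size,
        blocks=encoder_config.enabled_blocks,
        params_per_set=params_used,
    )


def self_consistency(
    bundle: DatasetBundle,
    encoder_config: EncoderConfig,
    params: Optional[SvmHyperparams] = None,
) -> MetricSet:
    """Train and score on the same data, pooled across negative sets."""
    if params is None:
        params = SvmHyperparams()
    pooled = ConfusionCounts(0, 0, 0, 0)
    for negatives in bundle.negative_sets:
        windows = list(bundle.positives) + list(negatives)
        X, y = encode_windows(windows, encoder_config)
        model = train(X, y, params, encoder_config.layout())
        labels, _ = predict(model, X)
        pooled = pooled + confusion(y, labels)
    return metrics(pooled)


def independent_test(
    train_bundle: DatasetBundle,
    test_windows: Sequence[PeptideWindow],
    encoder_config: EncoderConfig,
    params: Optional[SvmHyperparams] = None,
) -> MetricSet:
    """Score held-out proteins with models trained on the full bundle.

    One model is trained per negative-set replicate; confusion counts of
    the replicate models on the test windows are pooled.  Any protein
    shared between training and test data raises ``LeakageError``.
    """
    if not test_windows:
        raise EvaluationError("independent test set is empty")
    if params is None:
        params = SvmHyperparams()
    overlap = train_bundle.protein_ids & {w.protein_id for w in test_windows}
    if overlap:
        raise LeakageError(
            f"proteins present in both training and test data: {sorted(overlap)[:5]}"
        )
    X_test, y_test = encode_windows(list(test_windows), encoder_config)
    pooled = ConfusionCounts(0, 0, 0, 0)
    for negatives in train_bundle.negative_sets:
        X, y = encode_windows(
            list(train_bundle.positives) + list(negatives), encoder_config
        )
        model = train(X, y, params, encoder_config.layout())
        labels, _ = predict(model, X_test)
        pooled = pooled + confusion(y_test, labels)
    return metrics(pooled)


def write_report(report: CVReport, path) -> None:
    """Serialize a CVReport summary as TSV (metric, mean, std)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("metric\tmean\tstd\n")
        for name, (mean, std) in report.summary().items():
            handle.write(f"{name}\t{mean:.6f}\t{std:.6f}\n")
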