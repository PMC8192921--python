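"""Accuracy metrics (Sn, Sp, Acc, MCC), ROC/AUC, and the three validation
protocols: self-consistency, repeated independent splits, and k-fold
cross-validation.

The four metrics use the error-rate formulation: with P+ true positives
in the data, P- true negatives, fn positives predicted negative and fp
negatives predicted positive,

    Sn  = 1 - fn / P+
    Sp  = 1 - fp / P-
    Acc = 1 - (fn + fp) / (P+ + P-)
    MCC = (1 - (fn/P+ + fp/P-))
          / sqrt((1 + (fp - fn)/P+) * (1 + (fn - fp)/P-))

which is algebraically identical to the familiar TP/TN/FP/FN product-form
Matthews coefficient.  When the MCC denominator vanishes (a predictor
that outputs only one class) the value is 0 by convention and the report
is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .features import FeatureMatrix
from .models import ModelConfig, predict, train

METRIC_KEYS = ("Sn", "Sp", "Acc", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    pos_total: int  # actual drivers
    neg_total: int  # actual passengers
    fn: int  # drivers predicted passenger
    fp: int  # passengers predicted driver

    def __post_init__(self) -> None:
        if self.pos_total < 1 or self.neg_total < 1:
            raise ValueError("both classes must be non-empty")
        if not 0 <= self.fn <= self.pos_total:
            raise ValueError(f"fn={self.fn} out of range [0, {self.pos_total}]")
        if not 0 <= self.fp <= self.neg_total:
            raise ValueError(f"fp={self.fp} out of range [0, {self.neg_total}]")

    @property
    def total(self) -> int:
        return self.pos_total + self.neg_total


@dataclass(frozen=True)
class MetricsReport:
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    counts: ConfusionCounts
    protocol: str = ""
    mcc_degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "Sn": self.Sn,
            "Sp": self.Sp,
            "Acc": self.Acc,
            "MCC": self.MCC,
            "mcc_degenerate": self.mcc_degenerate,
            "counts": {
                "pos_total": self.counts.pos_total,
                "neg_total": self.counts.neg_total,
                "fn": self.counts.fn,
                "fp": self.counts.fp,
            },
        }


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionCounts(
        pos_total=int(np.sum(y_true == 1)),
        neg_total=int(np.sum(y_true == 0)),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def metrics(counts: ConfusionCounts, protocol: str = "") -> MetricsReport:
    """The four accuracy metrics from confusion counts."""
    p, n = counts.pos_total, counts.neg_total
    fn, fp = counts.fn, counts.fp
    sn = 1.0 - fn / p
    sp = 1.0 - fp / n
    acc = 1.0 - (fn + fp) / (p + n)
    denom_sq = (1.0 + (fp - fn) / p) * (1.0 + (fn - fp) / n)
    degenerate = denom_sq <= 0.0
    if degenerate:
        mcc = 0.0
    else:
        mcc = (1.0 - (fn / p + fp / n)) / math.sqrt(denom_sq)
    return MetricsReport(
        Sn=sn, Sp=sp, Acc=acc, MCC=mcc, counts=counts,
        protocol=protocol, mcc_degenerate=degenerate,
    )


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC curve by threshold sweep over unique scores; trapezoidal AUC.

    Equal scores are grouped into a single step, so ties contribute the
    diagonal of their block (equivalently: half credit per tied pair).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must be parallel")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # indices where a new (lower) score value starts: the end of a tie block
    distinct = np.flatnonzero(np.diff(sorted_scores) != 0)
    block_ends = np.r_[distinct, len(sorted_scores) - 1]

    tp_cum = np.cumsum(sorted_labels == 1)[block_ends]
    fp_cum = np.cumsum(sorted_labels == 0)[block_ends]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[block_ends]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class ProtocolResult:
    """Headline (averaged) metrics plus the per-run reports behind them."""

    protocol: str
    mean: dict[str, float]
    std: dict[str, float]
    per_run: list[MetricsReport]
    pooled: MetricsReport
    roc: RocCurve | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "protocol": self.protocol,
            "mean": self.mean,
            "std": self.std,
            "pooled": self.pooled.as_dict(),
            "per_run": [r.as_dict() for r in self.per_run],
            "seed": self.seed,
        }
        if self.roc is not None:
            out["auc"] = self.roc.auc
        out.update(self.extras)
        return out


def _summarize(
    protocol: str,
    reports: list[MetricsReport],
    seed: int | None,
    pooled_counts: ConfusionCounts | None = None,
) -> ProtocolResult:
    """Macro-average per-run reports; pooled-count metrics kept alongside.

    ``reports`` may be a subset of the runs (degenerate single-class folds
    carry no per-fold metrics); ``pooled_counts`` then supplies the full
    accumulation.  If no run had both classes, the pooled metrics stand in
    for the headline averages.
    """
    if pooled_counts is None:
        pooled_counts = ConfusionCounts(
            pos_total=sum(r.counts.pos_total for r in reports),
            neg_total=sum(r.counts.neg_total for r in reports),
            fn=sum(r.counts.fn for r in reports),
            fp=sum(r.counts.fp for r in reports),
        )
    pooled = metrics(pooled_counts, protocol=f"{protocol}-pooled")
    if reports:
        values = {k: np.array([getattr(r, k) for r in reports]) for k in METRIC_KEYS}
        mean = {k: float(v.mean()) for k, v in values.items()}
        std = {
            k: float(v.std(ddof=1)) if len(reports) > 1 else 0.0
            for k, v in values.items()
        }
    else:
        mean = {k: getattr(pooled, k) for k in METRIC_KEYS}
        std = {k: 0.0 for k in METRIC_KEYS}
    return ProtocolResult(
        protocol=protocol,
        mean=mean,
        std=std,
        per_run=reports,
        pooled=pooled,
        seed=seed,
    )


def self_consistency(
    matrix: FeatureMatrix, config: ModelConfig | None = None
) -> ProtocolResult:
    """Train on all rows and evaluate on the same rows, with ROC."""
    config = config or ModelConfig()
    model = train(matrix, config)
    labels, scores = predict(model, matrix)
    report = metrics(confusion(matrix.y, labels), protocol="self-consistency")
    result = _summarize("self-consistency", [report], seed=config.seed)
    result.roc = roc(matrix.y, scores)
    return result


def independent_split_test(
    matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    train_fraction: float = 0.7,
    repeats: int = 10,
    seed: int = 0,
    stratify: bool = True,
) -> ProtocolResult:
    """Repeated random train/test splits, metrics macro-averaged on held-out
    rows."""
    config = config or ModelConfig()
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    reports: list[MetricsReport] = []
    for rep in range(repeats):
        if stratify:
            splitter = StratifiedShuffleSplit(
                n_splits=1,
                train_size=train_fraction,
                random_state=int(rng.integers(2**31 - 1)),
            )
            train_idx, test_idx = next(splitter.split(matrix.X, matrix.y))
        else:
            n = len(matrix)
            perm = rng.permutation(n)
            cut = int(round(train_fraction * n))
            train_idx, test_idx = perm[:cut], perm[cut:]
        reports.append(
            _fit_score(matrix, config, train_idx, test_idx, f"independent-rep{rep}")
        )
    result = _summarize("independent", reports, seed=seed)
    result.extras["repeats"] = repeats
    result.extras["train_fraction"] = train_fraction
    return result


def kfold_cv(
    matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
    stratify: bool = True,
) -> ProtocolResult:
    """Stratified k-fold cross-validation; every sample is tested once."""
    config = config or ModelConfig()
    class_sizes = np.bincount(matrix.y, minlength=2)
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the dataset size {len(matrix)}")
    if stratify and k > class_sizes.min():
        if k == len(matrix):
            # leave-one-out: stratification is meaningless, fall through
            stratify = False
        else:
            raise ValueError(
                f"k={k} exceeds the smallest class size {class_sizes.min()}"
            )
    if stratify:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    reports: list[MetricsReport] = []
    tot = {"pos_total": 0, "neg_total": 0, "fn": 0, "fp": 0}
    for fold, (train_idx, test_idx) in enumerate(splitter.split(matrix.X, matrix.y)):
        y_true, y_pred = _fit_predict(matrix, config, train_idx, test_idx)
        tot["pos_total"] += int(np.sum(y_true == 1))
        tot["neg_total"] += int(np.sum(y_true == 0))
        tot["fn"] += int(np.sum((y_true == 1) & (y_pred == 0)))
        tot["fp"] += int(np.sum((y_true == 0) & (y_pred == 1)))
        if len(np.unique(y_true)) == 2:
            reports.append(
                metrics(confusion(y_true, y_pred), protocol=f"cv-fold{fold}")
            )
    result = _summarize("cv", reports, seed=seed, pooled_counts=ConfusionCounts(**tot))
    result.extras["k"] = k
    return result


def _fit_score(
    matrix: FeatureMatrix,
    config: ModelConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    protocol: str,
) -> MetricsReport:
    y_true, y_pred = _fit_predict(matrix, config, train_idx, test_idx)
    return metrics(confusion(y_true, y_pred), protocol=protocol)


def _fit_predict(
    matrix: FeatureMatrix,
    config: ModelConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    train_m = FeatureMatrix(
        X=matrix.X[train_idx],
        y=matrix.y[train_idx],
        ids=[matrix.ids[i] for i in train_idx],
        names=matrix.names,
    )
    test_m = FeatureMatrix(
        X=matrix.X[test_idx],
        y=matrix.y[test_idx],
        ids=[matrix.ids[i] for i in test_idx],
        names=matrix.names,
    )
    model = train(train_m, config)
    labels, _ = predict(model, test_m)
    return test_m.y, labels
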