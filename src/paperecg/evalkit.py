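"""Classifier evaluation: confusion-matrix metrics and statistics.

Per-class metrics follow the one-vs-rest decomposition of a K x K confusion
matrix (rows actual, columns predicted): recall = TP/(TP+FN),
specificity = TN/(TN+FP), precision = TP/(TP+FP), F1, and the complement
rates FPR, FNR, FDR. Aggregates are macro (unweighted class means); overall
accuracy is trace/total. Also provided: error measures between one-hot
labels and score vectors (MAE/RMSE), Cohen's kappa, the multiclass Matthews
correlation coefficient, an exact Wilcoxon signed-rank test (the full
sign-flip null distribution, computed by dynamic programming, identical to
enumerating all 2^n sign assignments), one-vs-rest ROC curves with
trapezoidal AUC, and a k-fold cross-validation driver.

Undefined ratios (0/0) are reported as NaN sentinels and excluded from
macro averages with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, InputError


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = actual classes, columns = predicted."""

    counts: np.ndarray
    labels: list[str]

    def __init__(self, counts, labels=None):
        counts = np.asarray(counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise InputError("confusion matrix must be square")
        if (counts < 0).any():
            raise InputError("confusion matrix counts must be non-negative")
        self.counts = counts
        self.labels = (list(labels) if labels is not None
                       else [str(i) for i in range(len(counts))])
        if len(self.labels) != len(counts):
            raise InputError("label count does not match matrix size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, cls) -> int:
        if isinstance(cls, str):
            try:
                return self.labels.index(cls)
            except ValueError:
                raise InputError(f"unknown class {cls!r}") from None
        if not 0 <= int(cls) < len(self.labels):
            raise InputError(f"class index {cls} out of range")
        return int(cls)

    @staticmethod
    def from_predictions(y_true, y_pred, labels) -> "ConfusionMatrix":
        labels = list(labels)
        lut = {c: i for i, c in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for a, p in zip(y_true, y_pred):
            counts[lut.get(a, a) if not isinstance(a, (int, np.integer)) else a,
                   lut.get(p, p) if not isinstance(p, (int, np.integer)) else p] += 1
        return ConfusionMatrix(counts, labels)


def per_class_counts(cm: ConfusionMatrix, cls) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for a class."""
    i = cm.index(cls)
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i, :].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = cm.total - tp - fp - fn
    return tp, tn, fp, fn


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.nan
    return num / den


@dataclass
class MetricReport:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    accuracy: float
    labels: list[str] = field(default_factory=list)


_METRIC_KEYS = ("recall", "specificity", "precision", "f1", "fpr", "fnr", "fdr")


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Per-class and macro-averaged one-vs-rest metrics plus overall accuracy."""
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for cls in cm.labels:
        tp, tn, fp, fn = per_class_counts(cm, cls)
        recall = _ratio(tp, tp + fn)
        specificity = _ratio(tn, tn + fp)
        precision = _ratio(tp, tp + fp)
        if math.isnan(recall) or math.isnan(precision) or precision + recall == 0:
            f1 = math.nan if math.isnan(recall) or math.isnan(precision) else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        per_class[cls] = {
            "recall": recall,
            "specificity": specificity,
            "precision": precision,
            "f1": f1,
            # complement rates share their denominators with the metrics
            # above, so they are computed as exact complements
            "fpr": 1.0 - specificity,
            "fnr": 1.0 - recall,
            "fdr": 1.0 - precision,
        }
    macro = {}
    for key in _METRIC_KEYS:
        vals = [per_class[c][key] for c in cm.labels]
        finite = [v for v in vals if not math.isnan(v)]
        if len(finite) < len(vals):
            warnings.warn(f"{key}: undefined for some classes; macro over defined ones")
        macro[key] = float(np.mean(finite)) if finite else math.nan
    accuracy = np.trace(cm.counts) / cm.total
    return MetricReport(per_class=per_class, macro=macro,
                        accuracy=float(accuracy), labels=list(cm.labels))


def mae_rmse(y_true, scores) -> tuple[float, float]:
    """MAE and RMSE between one-hot actual vectors and score vectors.

    Averaged over all ``n * K`` vector entries.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise InputError("scores must be an n x K matrix")
    y_true = np.asarray(y_true)
    n, k = scores.shape
    if len(y_true) != n:
        raise InputError("label/score length mismatch")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y_true] = 1.0
    diff = onehot - scores
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    return mae, rmse


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from observed vs marginal-chance agreement."""
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise InputError("empty confusion matrix")
    po = np.trace(c) / total
    pe = float((c.sum(axis=0) * c.sum(axis=1)).sum()) / total**2
    if 1.0 - pe == 0:
        return math.nan
    return float((po - pe) / (1.0 - pe))


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient (generalized over K x K)."""
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise InputError("empty confusion matrix")
    t = c.sum(axis=1)  # actual per class
    p = c.sum(axis=0)  # predicted per class
    cov_yp = np.trace(c) * total - float(t @ p)
    cov_yy = total**2 - float(t @ t)
    cov_pp = total**2 - float(p @ p)
    if cov_yy == 0 or cov_pp == 0:
        return math.nan
    return float(cov_yp / math.sqrt(cov_yy * cov_pp))


def wilcoxon_signed_rank(x, y, exact_limit: int = 25) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples; two-sided p.

    Zero differences are dropped and ties midranked. For n <= exact_limit
    the p-value is exact over the sign-flip null (all 2^n assignments,
    aggregated by dynamic programming over the rank-sum distribution);
    larger n uses the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return math.nan, math.nan
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        # distribution of W+ over 2^n sign patterns; use doubled ranks so
        # midranks (x.5) become integers
        r2 = np.rint(2 * ranks).astype(int)
        max_sum = int(r2.sum())
        counts = np.zeros(max_sum + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:max_sum + 1 - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = counts[:w2 + 1].sum()
        p_ge = counts[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        # tie-corrected variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(2.0 * (1.0 - _norm_cdf(abs(z))))
    return w_plus, float(p)


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def roc_curve_binary(y_bin, score) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC for one binary problem."""
    y_bin = np.asarray(y_bin, dtype=bool)
    score = np.asarray(score, dtype=float)
    n_pos = int(y_bin.sum())
    n_neg = len(y_bin) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), math.nan
    order = np.argsort(-score, kind="stable")
    ys = y_bin[order]
    ss = score[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # keep the last point of each distinct threshold
    keep = np.append(np.diff(ss) != 0, True)
    tpr = np.concatenate([[0.0], tps[keep] / n_pos])
    fpr = np.concatenate([[0.0], fps[keep] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_auc(y_true, scores) -> dict:
    """One-vs-rest ROC per class and macro AUC over defined classes."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    k = scores.shape[1]
    out: dict = {"per_class": {}}
    aucs = []
    for c in range(k):
        fpr, tpr, auc = roc_curve_binary(y_true == c, scores[:, c])
        out["per_class"][c] = {"fpr": fpr, "tpr": tpr, "auc": auc}
        if not math.isnan(auc):
            aucs.append(auc)
    out["macro_auc"] = float(np.mean(aucs)) if aucs else math.nan
    return out


def kfold_cv(manifest, k: int, trainer, seed: int = 0) -> dict:
    """k-fold cross-validation over a manifest.

    ``trainer(train_manifest, eval_manifest, fold_index)`` must return the
    held-out accuracy of one fold. Folds come from
    :func:`paperecg.datakit.kfold_partition` (k = 1 is the seeded holdout
    convention). Reports per-fold accuracies, their mean, and population SD.
    """
    from .datakit import kfold_partition

    if k < 1:
        raise ConfigurationError("k must be >= 1")
    parts = kfold_partition(manifest, k, seed=seed)
    accs = []
    for fold in range(k):
        eval_df = parts[parts["fold"] == fold]
        train_df = parts[parts["fold"] != fold]
        missing = set(parts["class"].unique()) - set(eval_df["class"].unique())
        if missing:
            warnings.warn(f"fold {fold} is missing classes {sorted(missing)}")
        accs.append(float(trainer(train_df, eval_df, fold)))
    accs_arr = np.asarray(accs)
    return {
        "fold_accuracies": accs,
        "mean": float(accs_arr.mean()),
        "sd": float(accs_arr.std()),  # population SD over folds
    }
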