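"""Diagnostic-accuracy evaluation: 2x2 tables with Wilson/log-method
confidence intervals, LOOCV, a battery of k-fold schemes, out-of-bag
bootstrap, and an exact two-sided Fisher test by hypergeometric
enumeration.

IBS is the positive class throughout.  Percentages are displayed rounded
to the nearest integer and likelihood ratios to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .errors import DegenerateLabelsError, InvalidParameterError
from .model import INDEX_THRESHOLD, fit_logistic, ibs_acoustic_index

DEFAULT_BOOTSTRAP_REPS = 300
_Z95 = spstats.norm.ppf(0.975)


@dataclass
class ContingencyTable:
    """2x2 counts with IBS as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InvalidParameterError("contingency counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(self.tp + other.tp, self.fn + other.fn,
                                self.fp + other.fp, self.tn + other.tn)


@dataclass
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    lr_pos: float                 # may be inf
    lr_neg: float
    ci: dict = field(default_factory=dict)   # metric -> (lo, hi) or None

    def as_rows(self):
        """(metric, point, ci_lo, ci_hi) rows with report rounding:
        proportions as integer percent, likelihood ratios to 2 decimals."""
        rows = []
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            ci = self.ci.get(name)
            rows.append((name, round(100 * v),
                         round(100 * ci[0]) if ci else None,
                         round(100 * ci[1]) if ci else None))
        for name in ("lr_pos", "lr_neg"):
            v = getattr(self, name)
            ci = self.ci.get(name)
            rows.append((name, round(v, 2) if math.isfinite(v) else v,
                         round(ci[0], 2) if ci else None,
                         round(ci[1], 2) if ci else None))
        return rows


def wilson_interval(k: int, n: int, z: float = _Z95) -> tuple:
    """Wilson score 95% interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)   # exact at boundary
    hi = 1.0 if k == n else min(1.0, center + half)
    return (lo, hi)


def _lr_ci(lr: float, a: int, m: int, b: int, n: int) -> tuple | None:
    """Log-method CI for a ratio of two proportions a/m over b/n."""
    if not math.isfinite(lr) or lr <= 0 or a == 0 or b == 0:
        return None
    se = math.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return (lr * math.exp(-_Z95 * se), lr * math.exp(_Z95 * se))


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, predictive values, accuracy and
    likelihood ratios with 95% CIs (Wilson for proportions, log method for
    LRs).  Division by zero yields +inf with an undefined CI."""
    tp, fn, fp, tn = table.tp, table.fn, table.fp, table.tn
    if tp + fn == 0 or tn + fp == 0:
        raise InvalidParameterError("both classes must be represented")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else math.nan
    npv = tn / (tn + fn) if tn + fn else math.nan
    acc = (tp + tn) / table.n
    lr_pos = sens / (1 - spec) if spec < 1 else math.inf
    lr_neg = (1 - sens) / spec if spec > 0 else math.inf
    ci = {
        "sensitivity": wilson_interval(tp, tp + fn),
        "specificity": wilson_interval(tn, tn + fp),
        "ppv": wilson_interval(tp, tp + fp) if tp + fp else None,
        "npv": wilson_interval(tn, tn + fn) if tn + fn else None,
        "accuracy": wilson_interval(tp + tn, table.n),
        "lr_pos": _lr_ci(lr_pos, tp, tp + fn, fp, fp + tn),
        "lr_neg": _lr_ci(lr_neg, fn, tp + fn, tn, fp + tn),
    }
    return DiagnosticMetrics(sens, spec, ppv, npv, acc, lr_pos, lr_neg, ci)


def table_from_predictions(y_true: np.ndarray, y_pred: np.ndarray
                           ) -> ContingencyTable:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)))


# ---------------------------------------------------------------------------
# cross-validation

def _predict_fold(X, y, names, train_idx, test_idx, l2):
    m = fit_logistic(X[train_idx], y[train_idx], names, l2)
    return np.array([ibs_acoustic_index(m, X[i]) for i in test_idx])


def loocv(X: np.ndarray, y: np.ndarray, feature_names, l2: float = 1.0
          ) -> tuple[ContingencyTable, np.ndarray]:
    """Leave-one-out CV.  Standardization and imputation are refit inside
    every fold.  Returns the pooled 2x2 table and the per-participant
    index values (in input order)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n = len(y)
    if n < 3:
        raise InvalidParameterError("need at least 3 participants")
    if y.all() or not y.any():
        raise DegenerateLabelsError("both classes must be present")
    indices = np.arange(n)
    idx_pred = np.empty(n)
    for i in range(n):
        train = indices[indices != i]
        idx_pred[i] = _predict_fold(X, y, feature_names, train, [i], l2)[0]
    table = table_from_predictions(y, idx_pred >= INDEX_THRESHOLD)
    return table, idx_pred


def _kfold_indices(n, k, y, stratified, seed):
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    if stratified:
        pos = 0        # continue round-robin across classes: sizes differ <= 1
        for cls in (True, False):
            cls_idx = np.flatnonzero(y == cls)
            rng.shuffle(cls_idx)
            for i in cls_idx:
                folds[pos % k].append(i)
                pos += 1
    else:
        perm = rng.permutation(n)
        for pos, i in enumerate(perm):
            folds[pos % k].append(i)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def kfold_cv(X: np.ndarray, y: np.ndarray, feature_names, k: int,
             stratified: bool = False, seed: int = 0, l2: float = 1.0
             ) -> tuple[ContingencyTable, np.ndarray]:
    """k-fold CV with fold sizes differing by at most one.

    With ``k == n`` and no shuffling effect on singleton folds this is
    definitionally identical to LOOCV.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n = len(y)
    if not 2 <= k <= n:
        raise InvalidParameterError("k must satisfy 2 <= k <= n")
    folds = _kfold_indices(n, k, y, stratified, seed)
    idx_pred = np.empty(n)
    indices = np.arange(n)
    for fold in folds:
        if fold.size == 0:
            continue
        train = np.setdiff1d(indices, fold)
        if y[train].all() or not y[train].any():
            raise DegenerateLabelsError("a training fold lost a class; "
                                        "use stratified folds")
        idx_pred[fold] = _predict_fold(X, y, feature_names, train, fold, l2)
    table = table_from_predictions(y, idx_pred >= INDEX_THRESHOLD)
    return table, idx_pred


def kfold_battery(X, y, feature_names, seed: int = 0, l2: float = 1.0) -> dict:
    """The default 7-scheme battery: k in {2, 5, 10}, stratified and
    unstratified, plus k = n (LOOCV)."""
    out = {}
    for k in (2, 5, 10):
        for strat in (True, False):
            name = f"k{k}_{'stratified' if strat else 'unstratified'}"
            out[name], _ = kfold_cv(X, y, feature_names, k, strat, seed, l2)
    out["loocv"], _ = loocv(X, y, feature_names, l2)
    return out


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapResult:
    n_reps: int
    pooled_table: ContingencyTable
    metrics: DiagnosticMetrics            # from the pooled table
    rep_accuracy: np.ndarray
    percentile_ci: dict                   # metric -> (lo, hi)
    n_redraws: int = 0


def bootstrap_eval(X: np.ndarray, y: np.ndarray, feature_names,
                   B: int = DEFAULT_BOOTSTRAP_REPS, seed: int = 0,
                   l2: float = 1.0) -> BootstrapResult:
    """Stratified bootstrap with out-of-bag evaluation.

    Each repetition resamples each class with replacement (sizes
    preserved) as a training set and evaluates on the participants never
    drawn.  Repetitions with an empty or single-class out-of-bag set are
    redrawn (counted).  Reports the pooled 2x2 table plus percentile
    intervals of per-repetition metrics.
    """
    if B < 1:
        raise InvalidParameterError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    rng = np.random.default_rng(seed)
    n = len(y)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    pooled = ContingencyTable(0, 0, 0, 0)
    rep_sens, rep_spec, rep_acc = [], [], []
    redraws = 0
    done = 0
    while done < B:
        train = np.concatenate([
            rng.choice(pos_idx, size=pos_idx.size, replace=True),
            rng.choice(neg_idx, size=neg_idx.size, replace=True)])
        oob = np.setdiff1d(np.arange(n), np.unique(train))
        if oob.size == 0 or y[oob].all() or not y[oob].any():
            redraws += 1
            continue
        m = fit_logistic(X[train], y[train], feature_names, l2)
        pred = np.array([ibs_acoustic_index(m, X[i]) for i in oob])
        t = table_from_predictions(y[oob], pred >= INDEX_THRESHOLD)
        pooled = pooled + t
        rep_sens.append(t.tp / t.n_positive)
        rep_spec.append(t.tn / t.n_negative)
        rep_acc.append((t.tp + t.tn) / t.n)
        done += 1
    ci = {
        "sensitivity": tuple(np.percentile(rep_sens, [2.5, 97.5])),
        "specificity": tuple(np.percentile(rep_spec, [2.5, 97.5])),
        "accuracy": tuple(np.percentile(rep_acc, [2.5, 97.5])),
    }
    return BootstrapResult(B, pooled, diagnostic_metrics(pooled),
                           np.asarray(rep_acc), ci, redraws)


# ---------------------------------------------------------------------------
# exact test

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    ``table`` is ((a, b), (c, d)) or a ContingencyTable-like 2x2; the
    p-value sums the probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.
    """
    if isinstance(table, ContingencyTable):
        a, b, c, d = table.tp, table.fn, table.fp, table.tn
    else:
        (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise InvalidParameterError("counts must be >= 0")
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = spstats.hypergeom.pmf(support, n, row1, col1)
    p_obs = spstats.hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)
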