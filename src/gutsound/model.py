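"""L2-penalized logistic regression, the IBS Acoustic Index, and greedy
forward feature selection.

The classifier is fit by damped Newton iterations (iteratively reweighted
least squares) on standardized features with an unpenalized intercept, to a
gradient tolerance of 1e-8.  Standardization means/SDs and missing-value
medians are estimated from the training data only and stored with the
weights, so held-out prediction can never leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import DegenerateLabelsError, InvalidParameterError, SchemaError

INDEX_THRESHOLD = 0.5     # index >= 0.5 predicts IBS (boundary inclusive)
_GRAD_TOL = 1e-8
_MAX_ITER = 200


@dataclass
class ModelWeights:
    """Fitted classifier: standardization, imputation and coefficients."""

    feature_names: list
    means: np.ndarray
    sds: np.ndarray
    medians: np.ndarray            # training medians for imputation
    intercept: float
    coefficients: np.ndarray
    l2: float
    dropped_features: list = field(default_factory=list)  # zero variance

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "medians": self.medians.tolist(),
            "intercept": float(self.intercept),
            "coefficients": self.coefficients.tolist(),
            "l2": float(self.l2),
            "dropped_features": list(self.dropped_features),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelWeights":
        return cls(
            feature_names=list(d["feature_names"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            medians=np.asarray(d["medians"], dtype=float),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            l2=float(d["l2"]),
            dropped_features=list(d.get("dropped_features", [])),
        )


@dataclass
class IndexPrediction:
    participant_id: str
    ibs_acoustic_index: float
    predicted_label: str           # "IBS" or "healthy"


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    X = X.copy()
    missing = ~np.isfinite(X)
    if missing.any():
        X[missing] = np.broadcast_to(medians, X.shape)[missing]
    return X


def _penalized_ll(y, eta, w, l2):
    # log-likelihood written to stay finite for extreme eta
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return ll - 0.5 * l2 * np.dot(w, w)


def fit_logistic(X: np.ndarray, y: np.ndarray, feature_names,
                 l2: float = 1.0) -> ModelWeights:
    """Fit the L2-penalized logistic model.

    ``y`` is boolean (True = IBS).  Missing values are imputed with
    training-column medians; features are standardized; columns with zero
    variance are dropped and recorded.  Deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    feature_names = list(feature_names)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise SchemaError("feature matrix width must match feature names")
    if X.shape[0] < 2:
        raise InvalidParameterError("need at least 2 observations")
    if l2 < 0:
        raise InvalidParameterError("l2 strength must be >= 0")
    if y.all() or not y.any():
        raise DegenerateLabelsError("both classes must be present")

    medians = np.array([
        np.nanmedian(col) if np.isfinite(col).any() else 0.0
        for col in X.T])
    medians[~np.isfinite(medians)] = 0.0
    Xi = _impute(X, medians)
    means = Xi.mean(axis=0)
    sds = Xi.std(axis=0)
    keep = sds > 0
    dropped = [n for n, k in zip(feature_names, keep) if not k]
    Z = (Xi[:, keep] - means[keep]) / sds[keep]
    yf = y.astype(float)
    n, p = Z.shape

    beta = np.zeros(p + 1)         # [intercept, coefficients]
    D = np.column_stack([np.ones(n), Z])
    pen = np.full(p + 1, l2)
    pen[0] = 0.0                   # intercept unpenalized
    ll = _penalized_ll(yf, D @ beta, beta[1:], l2)
    for _ in range(_MAX_ITER):
        eta = D @ beta
        mu = expit(eta)
        grad = D.T @ (yf - mu) - pen * beta
        if np.max(np.abs(grad)) < _GRAD_TOL:
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (D * w[:, None]).T @ D + np.diag(pen)
        step = np.linalg.solve(H, grad)
        # damped Newton: halve until the penalized likelihood improves
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_ll = _penalized_ll(yf, D @ cand, cand[1:], l2)
            if cand_ll >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = _penalized_ll(yf, D @ beta, beta[1:], l2)

    coef = np.zeros(len(feature_names))
    coef[keep] = beta[1:]
    return ModelWeights(
        feature_names=feature_names, means=means, sds=sds, medians=medians,
        intercept=float(beta[0]), coefficients=coef, l2=float(l2),
        dropped_features=dropped)


def ibs_acoustic_index(model: ModelWeights, x, feature_names=None
                       ) -> float:
    """Predicted probability of IBS for one feature vector.

    ``x`` may be an array in the model's feature order or a name->value
    mapping.  Values 0.5 and above predict IBS.
    """
    if isinstance(x, dict):
        try:
            x = np.array([x[n] for n in model.feature_names], dtype=float)
        except KeyError as exc:
            raise SchemaError(f"missing feature {exc.args[0]!r}") from exc
    else:
        x = np.asarray(x, dtype=float)
        if feature_names is not None and list(feature_names) != list(
                model.feature_names):
            raise SchemaError("feature names do not match the model")
        if x.shape != (len(model.feature_names),):
            raise SchemaError("feature vector length does not match the model")
    x = _impute(x[None, :], model.medians)[0]
    keep = model.sds > 0
    z = np.zeros_like(x)
    z[keep] = (x[keep] - model.means[keep]) / model.sds[keep]
    eta = model.intercept + float(np.dot(model.coefficients, z))
    return float(expit(eta))


def classify(index: float) -> str:
    return "IBS" if index >= INDEX_THRESHOLD else "healthy"


def predict(model: ModelWeights, X: np.ndarray) -> np.ndarray:
    """IBS Acoustic Index for each row of ``X`` (model feature order)."""
    X = np.asarray(X, dtype=float)
    return np.array([ibs_acoustic_index(model, row) for row in X])


def _loocv_accuracy(X, y, names, l2) -> float:
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.arange(n) != i
        if y[mask].all() or not y[mask].any():
            continue               # degenerate fold counts as an error
        m = fit_logistic(X[mask], y[mask], names, l2)
        pred = ibs_acoustic_index(m, X[i]) >= INDEX_THRESHOLD
        correct += pred == y[i]
    return correct / n


def select_features(X: np.ndarray, y: np.ndarray, feature_names,
                    l2: float = 1.0, plateau_patience: int = 3,
                    max_features: int | None = None):
    """Greedy forward selection maximizing leave-one-out accuracy.

    Features are added one at a time; selection stops when accuracy has
    failed to improve for ``plateau_patience`` consecutive additions (or
    when features run out).  Returns ``(selected names, trace)`` where the
    trace records every step's candidate and accuracy.  Ties break toward
    the earlier feature in the registry order, so selection is
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    feature_names = list(feature_names)
    if len(feature_names) < 2:
        raise InvalidParameterError("need at least 2 candidate features")
    max_features = max_features or len(feature_names)

    selected: list[int] = []
    trace = []
    best_overall = -np.inf
    stall = 0
    remaining = list(range(len(feature_names)))
    while remaining and len(selected) < max_features:
        best_acc, best_j = -np.inf, None
        for j in remaining:
            cols = selected + [j]
            acc = _loocv_accuracy(X[:, cols], y,
                                  [feature_names[c] for c in cols], l2)
            if acc > best_acc:
                best_acc, best_j = acc, j
        selected.append(best_j)
        remaining.remove(best_j)
        trace.append({"added": feature_names[best_j],
                      "loocv_accuracy": best_acc})
        if best_acc > best_overall + 1e-12:
            best_overall = best_acc
            stall = 0
        else:
            stall += 1
            if stall >= plateau_patience:
                break
    # trim trailing non-improving additions
    while trace and trace[-1]["loocv_accuracy"] <= best_overall - 1e-12:
        trace_last = trace[-1]
        if trace_last["loocv_accuracy"] < best_overall:
            selected.pop()
            trace.pop()
        else:
            break
    return [feature_names[j] for j in selected], trace
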