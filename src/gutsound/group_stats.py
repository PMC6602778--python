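"""Random-intercept linear mixed model for fed/fasted group comparisons.

Fits ``response ~ group * period + (1 | participant)`` by maximum
likelihood, profiling the likelihood over the variance ratio
theta = var(intercept) / var(residual).  For a given theta the per-subject
covariance is ``sigma^2 (I + theta 11')``; its inverse and determinant have
closed forms, so the fixed effects come from generalized least squares and
the residual variance from the ML closed form, leaving a one-dimensional
bounded optimization.  Each fixed effect is tested with a Wald chi-square
on one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as spstats

from .errors import InvalidParameterError

FIXED_EFFECTS = ("intercept", "ibs", "fed", "ibs_x_fed")


@dataclass
class LMMResult:
    estimates: dict          # effect -> coefficient
    std_errors: dict
    wald_chisq: dict
    p_values: dict
    random_intercept_var: float
    residual_var: float
    log_likelihood: float
    n_participants: int
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "effect": list(FIXED_EFFECTS),
            "estimate": [self.estimates[e] for e in FIXED_EFFECTS],
            "se": [self.std_errors[e] for e in FIXED_EFFECTS],
            "wald_chisq": [self.wald_chisq[e] for e in FIXED_EFFECTS],
            "p_value": [self.p_values[e] for e in FIXED_EFFECTS],
        })


def wald_chisq_pvalue(chisq: float, df: int = 1) -> float:
    """Upper-tail chi-square probability."""
    if df < 1:
        raise InvalidParameterError("df must be >= 1")
    if chisq < 0:
        raise InvalidParameterError("chisq must be >= 0")
    return float(spstats.chi2.sf(chisq, df))


def _design(obs: pd.DataFrame):
    required = {"participant_id", "group", "period", "response"}
    if not required.issubset(obs.columns):
        raise InvalidParameterError(f"observations need columns {sorted(required)}")
    ibs = (obs["group"] == "IBS").to_numpy(dtype=float)
    fed = (obs["period"] == "fed").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(obs)), ibs, fed, ibs * fed])
    y = obs["response"].to_numpy(dtype=float)
    groups, subject = np.unique(obs["participant_id"], return_inverse=True)
    return X, y, subject, len(groups)


def _profile_deviance(theta: float, X, y, subject, n_subjects):
    """-2 log-likelihood profiled over beta and sigma^2 at fixed theta.

    Uses the Woodbury identity per subject:
    (I + theta 11')^-1 = I - theta/(1 + n_i theta) 11'.
    """
    n = len(y)
    counts = np.bincount(subject, minlength=n_subjects)
    shrink = theta / (1.0 + counts * theta)          # per subject
    # V^-1 x = x - shrink_subject * 1 (1' x), applied columnwise
    def vinv(M):
        M = np.atleast_2d(M.T).T
        sums = np.zeros((n_subjects, M.shape[1]))
        np.add.at(sums, subject, M)
        return M - (shrink[subject, None] * sums[subject])
    XtVX = X.T @ vinv(X)
    XtVy = X.T @ vinv(y[:, None])[:, 0]
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    quad = float(r @ vinv(r[:, None])[:, 0])
    sigma2 = quad / n
    logdet = float(np.sum(np.log1p(counts * theta)))
    dev = n * np.log(2 * np.pi * sigma2) + logdet + n
    return dev, beta, sigma2, XtVX


def fit_random_intercept_lmm(observations: pd.DataFrame) -> LMMResult:
    """ML fit of ``response ~ group*period + (1|participant)``.

    ``observations`` is long-format with columns participant_id, group
    ("IBS"/"healthy"), period ("fasted"/"fed") and response.  Returns
    fixed-effect estimates with Wald chi-square tests (df=1), plus the
    random-intercept and residual variances.
    """
    X, y, subject, n_subjects = _design(observations)
    for g in ("IBS", "healthy"):
        ids = observations.loc[observations["group"] == g, "participant_id"]
        if ids.nunique() < 2:
            raise InvalidParameterError(f"need >= 2 participants in group {g}")

    def objective(log_theta):
        return _profile_deviance(np.exp(log_theta), X, y, subject,
                                 n_subjects)[0]

    # bracket on log-theta; include the theta -> 0 boundary explicitly
    res = optimize.minimize_scalar(objective, bounds=(-12.0, 12.0),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    dev0, *_ = _profile_deviance(0.0, X, y, subject, n_subjects)
    if dev0 <= res.fun:
        theta = 0.0
        dev = dev0
    else:
        theta = float(np.exp(res.x))
        dev = float(res.fun)
    _, beta, sigma2, XtVX = _profile_deviance(theta, X, y, subject, n_subjects)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    chisq = (beta / se) ** 2
    pvals = np.array([wald_chisq_pvalue(c, 1) for c in chisq])
    return LMMResult(
        estimates=dict(zip(FIXED_EFFECTS, beta)),
        std_errors=dict(zip(FIXED_EFFECTS, se)),
        wald_chisq=dict(zip(FIXED_EFFECTS, chisq)),
        p_values=dict(zip(FIXED_EFFECTS, pvals)),
        random_intercept_var=float(theta * sigma2),
        residual_var=float(sigma2),
        log_likelihood=float(-0.5 * dev),
        n_participants=n_subjects,
        converged=bool(getattr(res, "success", True)),
    )


def profile_deviance_curve(observations: pd.DataFrame,
                           thetas) -> np.ndarray:
    """Profiled -2 log-likelihood at each variance ratio in ``thetas``.

    Exposed so global optimality of the fitted ratio can be audited.
    """
    X, y, subject, n_subjects = _design(observations)
    return np.array([
        _profile_deviance(t, X, y, subject, n_subjects)[0] for t in thetas])


def long_format_observations(feature_df: pd.DataFrame, response: str
                             ) -> pd.DataFrame:
    """Reshape a participant feature matrix into the long format expected
    by the mixed model.

    ``response`` is "quantity_density" or "summed_amplitude"; the matrix
    must contain ``<response>_fasted`` and ``<response>_fed`` columns.
    """
    rows = []
    for _, row in feature_df.iterrows():
        for period in ("fasted", "fed"):
            rows.append({
                "participant_id": row["participant_id"],
                "group": row["label"],
                "period": period,
                "response": row[f"{response}_{period}"],
            })
    return pd.DataFrame(rows)
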