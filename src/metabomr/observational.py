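"""Observational cohort arm: IRNT, incident-case definition, adjusted regressions.

Mirrors a prospective-cohort analysis of a binary cancer outcome: exposures
and biomarkers are inverse-rank-normal transformed to SD units, cases are
restricted to incident diagnoses (diagnosed after assessment), and
associations are estimated by multivariable linear (continuous outcome) or
logistic (binary outcome) regression, first adjusted for age and centre and
then fully adjusted for behavioural and reproductive covariates.

The regressions go through statsmodels (OLS and binomial GLM via IRLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "SeparationError",
    "irnt",
    "define_incident_cases",
    "fit_linear",
    "fit_logistic",
    "metabolome_scan",
]

Z95 = 1.959963984540054

INCIDENT = "incident"
PREVALENT = "prevalent"
CONTROL = "control"


class SeparationError(RuntimeError):
    """Logistic fit diverged (perfect or quasi-separation)."""


@dataclass
class RegressionResult:
    """Coefficient of interest from one adjusted regression."""

    term: str
    estimate: float
    se: float
    pval: float
    model_tag: str
    n_used: int
    outcome: str = ""

    @property
    def ci_low(self) -> float:
        return self.estimate - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "outcome": self.outcome,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "model_tag": self.model_tag,
            "n_used": self.n_used,
        }


def irnt(values) -> np.ndarray:
    """Inverse rank-based normal transformation to SD units.

    Ties receive average ranks; value i maps to the standard-normal quantile
    of (rank_i - 0.5)/n (rank offset 0.5).  Missing values are excluded from
    ranking and stay missing in the output.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("IRNT needs at least 2 non-missing values")
    ranks = stats.rankdata(x[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def define_incident_cases(age_at_assessment, age_at_diagnosis) -> np.ndarray:
    """Classify individuals as incident case, prevalent case or control.

    A diagnosis record with attending age strictly less than diagnosis age is
    an incident case; any other diagnosis record (including equal ages) is
    prevalent and is excluded from analysis downstream; no diagnosis record
    of any kind is a control.
    """
    attend = np.asarray(age_at_assessment, dtype=float)
    diag = np.asarray(age_at_diagnosis, dtype=float)
    if np.any(attend[np.isfinite(attend)] < 0) or np.any(diag[np.isfinite(diag)] < 0):
        raise ValueError("ages must be non-negative")
    has_diag = np.isfinite(diag)
    status = np.where(
        has_diag, np.where(attend < diag, INCIDENT, PREVALENT), CONTROL
    )
    return status.astype(object)


def _design(data: pd.DataFrame, x: str, covariates: list[str]) -> pd.DataFrame:
    """Complete-case design matrix; categoricals expand to dummy columns."""
    cols = [x] + list(covariates)
    sub = data[cols].copy()
    parts = [sub[[x]].astype(float)]
    for c in covariates:
        col = sub[c]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(col.astype(float).to_frame())
    X = pd.concat(parts, axis=1)
    X.insert(0, "const", 1.0)
    return X


def fit_linear(
    data: pd.DataFrame,
    y: str,
    x: str,
    covariates: list[str] | None = None,
    model_tag: str = "age_centre",
) -> RegressionResult:
    """Least-squares coefficient of ``x`` on continuous ``y`` with covariates.

    Complete-case rows only; SE/p from the normal approximation.
    """
    covariates = covariates or []
    keep = data[[y, x] + covariates].dropna()
    X = _design(keep, x, covariates)
    yv = keep[y].astype(float)
    if len(keep) <= X.shape[1]:
        raise ValueError("too few complete cases for the design")
    res = sm.OLS(yv, X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix")
    est, se = float(res.params[x]), float(res.bse[x])
    p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else 1.0
    return RegressionResult(x, est, se, p, model_tag, n_used=len(keep), outcome=y)


def fit_logistic(
    data: pd.DataFrame,
    y: str,
    x: str,
    covariates: list[str] | None = None,
    model_tag: str = "age_centre",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RegressionResult:
    """Maximum-likelihood log-odds coefficient of ``x`` on binary ``y``.

    Fitted by IRLS (binomial GLM, logit link) with convergence tolerance
    1e-8 and at most 50 iterations.  Detected separation (divergence or a
    runaway coefficient) raises :class:`SeparationError`.
    """
    covariates = covariates or []
    keep = data[[y, x] + covariates].dropna()
    yv = keep[y].astype(float)
    classes = set(np.unique(yv))
    if not classes <= {0.0, 1.0} or len(classes) < 2:
        raise ValueError("outcome must be binary with both classes present")
    X = _design(keep, x, covariates)
    model = sm.GLM(yv, X, family=sm.families.Binomial())
    res = model.fit(maxiter=max_iter, tol=tol)
    est, se = float(res.params[x]), float(res.bse[x])
    if not np.isfinite(est) or not np.isfinite(se) or abs(est) > 30:
        raise SeparationError(f"logistic fit for {x} diverged (estimate {est:g})")
    p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else 1.0
    return RegressionResult(x, est, se, p, model_tag, n_used=len(keep), outcome=y)


def metabolome_scan(
    data: pd.DataFrame,
    exposure: str,
    mediators: list[str],
    outcome: str | None = None,
    covariates: list[str] | None = None,
    model_tag: str = "age_centre",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan mediators against the exposure (or against the outcome).

    Two modes mirroring the two screening steps:

    * ``outcome is None`` — hypothesis-free discovery: each mediator is the
      dependent variable in a linear regression on the exposure; the
      discovery flag uses a Bonferroni threshold alpha / (number of
      mediators tested).
    * ``outcome`` given — hypothesis-driven step: the binary outcome is
      regressed on each mediator by logistic regression; the flag uses the
      uncorrected alpha (no multiple-testing correction).

    Returns one row per mediator with the coefficient, p-value, the
    threshold applied, and the discovery flag.
    """
    if not mediators:
        return pd.DataFrame(
            columns=["mediator", "estimate", "se", "pval", "threshold", "discovery", "model_tag"]
        )
    threshold = alpha / len(mediators) if outcome is None else alpha
    rows = []
    for m in mediators:
        if outcome is None:
            res = fit_linear(data, y=m, x=exposure, covariates=covariates, model_tag=model_tag)
        else:
            res = fit_logistic(data, y=outcome, x=m, covariates=covariates, model_tag=model_tag)
        rows.append(
            {
                "mediator": m,
                "estimate": res.estimate,
                "se": res.se,
                "pval": res.pval,
                "threshold": threshold,
                "discovery": res.pval < threshold,
                "model_tag": model_tag,
                "n_used": res.n_used,
            }
        )
    return pd.DataFrame(rows)
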