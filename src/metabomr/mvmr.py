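"""Multivariable two-sample MR with conditional instrument strength.

The workhorse is a weighted regression of outcome betas on K columns of
exposure betas through the origin, estimating each exposure's *direct*
effect conditional on the others.  Instrument strength per exposure is
measured by the conditional F-statistic and heterogeneity by an adapted Q
statistic (Q_A) whose weights absorb the exposure-beta uncertainty.

Summary-statistic covariances between exposures are treated as zero
throughout (the two-sample summary-data setting gives no phenotypic
covariance input); this is a documented limitation, not an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    EmptyInstrumentSetError,
    InstrumentSet,
    MVHarmonizedSet,
    PalindromePolicy,
    VariantAssociation,
    harmonize,
    harmonize_multi,
)
from .uvmr import Z95, MREstimate, ivw_mre, wald_ratio

__all__ = [
    "MVMRFit",
    "mvmr_fit",
    "conditional_f",
    "q_a",
    "direct_effect_scan",
    "AttenuationRow",
    "MultivariableMR",
]


@dataclass
class MVMRFit:
    """Direct-effect estimates for K exposures fitted jointly on L variants."""

    exposure_ids: list[str]
    theta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    n_snp: int
    conditional_f: np.ndarray
    q_a: float
    q_a_pval: float
    outcome_id: str = ""

    @property
    def ci_low(self) -> np.ndarray:
        return self.theta - Z95 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.theta + Z95 * self.se

    def to_frame(self, or_scale: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "exposure": self.exposure_ids,
                "outcome": self.outcome_id,
                "theta": self.theta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "pval": self.pval,
                "conditional_f": self.conditional_f,
                "n_snp": self.n_snp,
                "q_a": self.q_a,
                "q_a_pval": self.q_a_pval,
            }
        )
        if or_scale:
            df["odds_ratio"] = np.exp(df["theta"])
            df["or_ci_low"] = np.exp(df["ci_low"])
            df["or_ci_high"] = np.exp(df["ci_high"])
        return df

    def summary(self) -> str:
        lines = [
            f"Multivariable MR  (L = {self.n_snp} variants, K = {len(self.exposure_ids)} exposures)",
            f"  outcome: {self.outcome_id}",
            f"{'exposure':<24}{'theta':>10}{'se':>10}{'p':>12}{'cond. F':>10}",
        ]
        for i, eid in enumerate(self.exposure_ids):
            lines.append(
                f"{eid:<24}{self.theta[i]:>10.4f}{self.se[i]:>10.4f}"
                f"{self.pval[i]:>12.3g}{self.conditional_f[i]:>10.2f}"
            )
        lines.append(f"  Q_A: {self.q_a:.2f} (p {self.q_a_pval:.3g})")
        return "\n".join(lines)


def mvmr_fit(h: MVHarmonizedSet) -> MVMRFit:
    """Fit the multivariable model by weighted regression through the origin.

    Weights are 1/by_se^2.  Coefficient covariance uses the multiplicative
    residual scale RSS_w/(L-K) with no flooring; with K=1 this reduces
    exactly to the univariable IVW-MRE estimate.
    """
    L, K = h.bx.shape
    if K < 1:
        raise ValueError("need at least one exposure column")
    if L <= K:
        raise ValueError(f"need more variants than exposures (L={L}, K={K})")
    if np.linalg.matrix_rank(h.bx) < K:
        raise np.linalg.LinAlgError("rank-deficient exposure-beta matrix")
    w = 1.0 / h.by_se**2
    xtwx = h.bx.T @ (w[:, None] * h.bx)
    theta = np.linalg.solve(xtwx, h.bx.T @ (w * h.by))
    resid = h.by - h.bx @ theta
    scale = float(np.sum(w * resid**2) / (L - K))
    cov = np.linalg.inv(xtwx) * scale
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, theta / se, np.inf * np.sign(theta))
    pval = 2 * stats.norm.sf(np.abs(z))
    pval = np.where(se > 0, pval, np.where(theta == 0, 1.0, 0.0))
    qa, qa_p = q_a(h, theta)
    return MVMRFit(
        exposure_ids=list(h.exposure_ids),
        theta=theta,
        se=se,
        pval=pval,
        n_snp=L,
        conditional_f=conditional_f(h),
        q_a=qa,
        q_a_pval=qa_p,
    )


def conditional_f(h: MVHarmonizedSet) -> np.ndarray:
    """Conditional instrument strength of each exposure given the others.

    For exposure k, its instrument-beta column is regressed on the other
    exposures' columns with weights 1/bx_se_k^2; the weighted residual sum
    of squares Q_xk, scaled by (L - K + 1), is the conditional F.  Large
    values mean the column carries independent instrument signal.
    """
    L, K = h.bx.shape
    f = np.empty(K)
    for k in range(K):
        y = h.bx[:, k]
        with np.errstate(divide="ignore"):
            w = 1.0 / h.bx_se[:, k] ** 2
        if not np.all(np.isfinite(w)):
            # zero exposure SEs: unweighted limit
            w = np.ones_like(y)
        others = np.delete(h.bx, k, axis=1)
        if others.shape[1] == 0:
            resid = y
        else:
            xtwx = others.T @ (w[:, None] * others)
            coef = np.linalg.solve(xtwx, others.T @ (w * y))
            resid = y - others @ coef
        q_xk = float(np.sum(w * resid**2))
        f[k] = q_xk / (L - K + 1)
    return f


def q_a(h: MVHarmonizedSet, theta: np.ndarray) -> tuple[float, float]:
    """Adapted heterogeneity statistic at the fitted coefficients.

    Q_A = sum_j w_j (by_j - sum_k theta_k bx_kj)^2 with weights
    w_j = 1 / (by_se_j^2 + sum_k theta_k^2 bx_se_kj^2), evaluated once at
    the fitted theta (single pass, no iteration).  Reference distribution:
    chi-square with L - K degrees of freedom.
    """
    theta = np.asarray(theta, dtype=float)
    L, K = h.bx.shape
    denom = h.by_se**2 + (h.bx_se**2 * theta[None, :] ** 2).sum(axis=1)
    if not np.all(np.isfinite(denom)) or np.any(denom <= 0):
        raise ValueError("non-finite Q_A weights")
    resid = h.by - h.bx @ theta
    stat = float(np.sum(resid**2 / denom))
    return stat, float(stats.chi2.sf(stat, L - K))


class MultivariableMR:
    """Model object over a K-exposure harmonized set; ``fit()`` -> MVMRFit."""

    def __init__(self, harmonized: MVHarmonizedSet, outcome_binary: bool = False):
        self.harmonized = harmonized
        self.outcome_binary = outcome_binary

    def fit(self) -> MVMRFit:
        res = mvmr_fit(self.harmonized)
        return res


@dataclass
class AttenuationRow:
    """Univariable total vs MVMR direct exposure effect after one mediator."""

    mediator_id: str
    outcome_id: str
    theta_total: float
    theta_total_se: float
    theta_direct: float
    theta_direct_se: float
    attenuation: float | None
    flag: str | None
    conditional_f_exposure: float
    conditional_f_mediator: float
    n_snp: int

    def to_dict(self) -> dict:
        return {
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "theta_total": self.theta_total,
            "theta_total_se": self.theta_total_se,
            "theta_total_ci_low": self.theta_total - Z95 * self.theta_total_se,
            "theta_total_ci_high": self.theta_total + Z95 * self.theta_total_se,
            "theta_direct": self.theta_direct,
            "theta_direct_se": self.theta_direct_se,
            "theta_direct_ci_low": self.theta_direct - Z95 * self.theta_direct_se,
            "theta_direct_ci_high": self.theta_direct + Z95 * self.theta_direct_se,
            "attenuation": self.attenuation,
            "flag": self.flag,
            "conditional_f_exposure": self.conditional_f_exposure,
            "conditional_f_mediator": self.conditional_f_mediator,
            "n_snp": self.n_snp,
        }


#: |theta_total| below this suppresses the attenuation ratio as undefined
_TOTAL_EFFECT_EPS = 1e-3


def direct_effect_scan(
    exposure_instruments: InstrumentSet,
    exposure_records: Sequence[VariantAssociation],
    mediators: Mapping[str, tuple[InstrumentSet, Sequence[VariantAssociation]]],
    outcome_records: Sequence[VariantAssociation],
    palindrome_policy: PalindromePolicy | None = None,
    theta_total: MREstimate | None = None,
) -> tuple[list[MVMRFit], list[AttenuationRow]]:
    """One two-exposure MVMR per mediator, with an attenuation summary.

    Each fit regresses outcome betas on (exposure, mediator) beta columns
    over the union of both instrument sets, estimating the exposure's direct
    effect conditional on that mediator.  The supplied
    ``exposure_instruments`` may come from a deliberately lower-powered
    exposure GWAS so the mediator's conditional instrument strength is not
    diluted by an overwhelming exposure instrument count.

    The attenuation fraction is 1 - theta_direct/theta_total; when the total
    effect is indistinguishable from zero the ratio is suppressed with an
    ``undefined_ratio`` flag.  Mediators whose instruments cannot be
    harmonized are skipped with a reason, not silently dropped.
    """
    if theta_total is None:
        h_uni = harmonize(exposure_instruments, outcome_records, palindrome_policy)
        theta_total = (
            ivw_mre(h_uni)
            if h_uni.n_snp >= 2
            else wald_ratio(h_uni.bx[0], h_uni.bx_se[0], h_uni.by[0], h_uni.by_se[0])
        )
    fits: list[MVMRFit] = []
    rows: list[AttenuationRow] = []
    outcome_id = outcome_records[0].trait_id if outcome_records else ""
    for mid, (m_instruments, m_records) in mediators.items():
        try:
            hm = harmonize_multi(
                [exposure_instruments, m_instruments],
                {
                    exposure_instruments.trait_id: exposure_records,
                    m_instruments.trait_id: m_records,
                },
                outcome_records,
                palindrome_policy,
            )
            fit = mvmr_fit(hm)
        except (EmptyInstrumentSetError, ValueError, np.linalg.LinAlgError) as exc:
            rows.append(
                AttenuationRow(
                    mediator_id=mid, outcome_id=outcome_id,
                    theta_total=theta_total.theta, theta_total_se=theta_total.se,
                    theta_direct=np.nan, theta_direct_se=np.nan,
                    attenuation=None, flag=f"skipped: {exc}",
                    conditional_f_exposure=np.nan, conditional_f_mediator=np.nan,
                    n_snp=0,
                )
            )
            continue
        fit.outcome_id = outcome_id
        fits.append(fit)
        direct = float(fit.theta[0])
        if abs(theta_total.theta) < _TOTAL_EFFECT_EPS:
            att, flag = None, "undefined_ratio"
        else:
            att, flag = 1.0 - direct / theta_total.theta, None
        rows.append(
            AttenuationRow(
                mediator_id=mid, outcome_id=outcome_id,
                theta_total=theta_total.theta, theta_total_se=theta_total.se,
                theta_direct=direct, theta_direct_se=float(fit.se[0]),
                attenuation=att, flag=flag,
                conditional_f_exposure=float(fit.conditional_f[0]),
                conditional_f_mediator=float(fit.conditional_f[1]),
                n_snp=fit.n_snp,
            )
        )
    return fits, rows
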