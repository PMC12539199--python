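"""Vectorised per-variant association scans.

Simple regression of a trait on each genotype column separately, done for
all columns at once: closed form for continuous traits, batched Newton
scoring for binary traits.  These back the synthetic study generator's
summary-statistics step.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def per_variant_linear(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column simple linear regression slope and SE.

    Monomorphic columns (zero genotype variance) get beta 0 and SE inf.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = (gc.T @ yc) / sxx_safe
    syy = float(yc @ yc)
    rss = syy - beta**2 * sxx_safe
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore"):
        se = np.sqrt(rss / (n - 2) / sxx_safe)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono | (se == 0), np.where(mono, np.inf, se), se)
    se = np.where(mono, np.inf, se)
    return beta, se


def per_variant_logistic(
    G: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column logistic regression (intercept + genotype) slope and SE.

    Newton-Raphson run simultaneously across all columns.  Betas are on the
    log-odds scale.  Monomorphic columns get beta 0 and SE inf.

    Raises
    ------
    ValueError
        If the outcome has no cases or no controls.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, J = G.shape
    n_case = float(y.sum())
    if n_case == 0 or n_case == n:
        raise ValueError("binary trait must include both cases and controls")
    mono = G.var(axis=0) == 0

    a = np.full(J, np.log(n_case / (n - n_case)))
    b = np.zeros(J)
    G2 = G * G
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        mu = expit(eta)
        r = y[:, None] - mu
        W = mu * (1.0 - mu)
        s_a = r.sum(axis=0)
        s_b = np.einsum("ij,ij->j", G, r)
        i_aa = W.sum(axis=0)
        i_ab = np.einsum("ij,ij->j", G, W)
        i_bb = np.einsum("ij,ij->j", G2, W)
        det = i_aa * i_bb - i_ab**2
        det = np.where(det <= 0, np.nan, det)
        da = (i_bb * s_a - i_ab * s_b) / det
        db = (i_aa * s_b - i_ab * s_a) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        a += da
        b += db
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < tol:
            break
    eta = a[None, :] + G * b[None, :]
    mu = expit(eta)
    W = mu * (1.0 - mu)
    i_aa = W.sum(axis=0)
    i_ab = np.einsum("ij,ij->j", G, W)
    i_bb = np.einsum("ij,ij->j", G * G, W)
    det = i_aa * i_bb - i_ab**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(i_aa / det)
    b = np.where(mono, 0.0, b)
    se = np.where(mono, np.inf, se)
    return b, se
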