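"""Random-intercept linear mixed models fitted by profiled REML.

The model is

    y = X beta + Z u + e,   u_g ~ N(0, sigma_f^2),   e ~ N(0, sigma_e^2 I)

with one random intercept per group (family).  Writing lambda =
sigma_f^2 / sigma_e^2, the marginal covariance is sigma_e^2 (I + lambda Z Z'),
block-diagonal over groups, so GLS reduces to a per-group partial demeaning
(the Fuller-Battese transform): within group g of size n_g,

    y_tilde = y - c_g * mean_g(y),   c_g = 1 - sqrt(1 / (1 + lambda n_g)).

Both beta and sigma_e^2 profile out of the restricted likelihood, leaving a
one-dimensional REML criterion in lambda that is minimised numerically.  This
is orders of magnitude faster than a general mixed-model fitter and exact for
the single-random-intercept structure used throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["ModelFit", "RankDeficientError", "fit_lmm"]

# lambda = sigma_f^2 / sigma_e^2 searched on a log grid within these bounds
_LOG_LAMBDA_BOUNDS = (-15.0, 10.0)
_XATOL = 1e-10


class RankDeficientError(np.linalg.LinAlgError):
    """Fixed-effect design is singular after masking."""


@dataclass
class ModelFit:
    """A single coefficient extracted from a mixed-model fit.

    ``wald_chi2 = (beta/se)^2`` and ``p`` is the upper tail of chi-square(1)
    at that statistic.  ``sigma_family`` / ``sigma_resid`` are the REML
    variance-component estimates (SD scale, same units as the response).
    """

    beta: float
    se: float
    wald_chi2: float
    p: float
    n_used: int
    converged: bool
    sigma_family: float = float("nan")
    sigma_resid: float = float("nan")


def _group_codes(groups: np.ndarray) -> np.ndarray:
    _, codes = np.unique(groups, return_inverse=True)
    return codes


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    focal: int = 0,
) -> ModelFit:
    """Fit ``y ~ X`` with a random intercept per group; report one coefficient.

    Parameters
    ----------
    y : response vector (kg for the grip models, expression units for
        coexpression fits).
    X : fixed-effect design, including an intercept column.
    groups : family labels, one per row; at least two distinct groups.
    focal : column of ``X`` whose coefficient, SE, Wald chi-square and
        p-value are reported.

    Raises
    ------
    RankDeficientError
        If ``X`` is column-rank deficient.
    ValueError
        If shapes disagree or fewer than two groups are present.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if y.shape[0] != n or groups.shape[0] != n:
        raise ValueError("y, X and groups must have matching lengths")
    if n <= p + 1:
        raise ValueError(f"too few observations ({n}) for {p} fixed effects")

    codes = _group_codes(groups)
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValueError("need at least two groups for a random intercept")

    if np.linalg.matrix_rank(X) < p:
        raise RankDeficientError("fixed-effect design is rank deficient")

    if np.ptp(y) == 0.0:
        # Degenerate response: no information about any coefficient.
        return ModelFit(0.0, float("inf"), 0.0, 1.0, n, converged=False)

    counts = np.bincount(codes, minlength=n_groups).astype(float)
    # Group means are lambda-free; precompute once.
    ymean = np.bincount(codes, weights=y, minlength=n_groups) / counts
    Xmean = np.empty((n_groups, p))
    for j in range(p):
        Xmean[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
    Xmean /= counts[:, None]

    def profile(log_lam: float) -> tuple[float, np.ndarray, np.ndarray, float]:
        lam = np.exp(log_lam)
        shrink = 1.0 - 1.0 / np.sqrt(1.0 + lam * counts)  # c_g per group
        cg = shrink[codes]
        yt = y - cg * ymean[codes]
        Xt = X - cg[:, None] * Xmean[codes]
        A = Xt.T @ Xt
        b = Xt.T @ yt
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return np.inf, np.full(p, np.nan), A, np.nan
        beta = np.linalg.solve(L.T, np.linalg.solve(L, b))
        resid = yt - Xt @ beta
        rss = float(resid @ resid)
        if rss <= 0.0:
            rss = np.finfo(float).tiny
        logdet_A = 2.0 * float(np.log(np.diag(L)).sum())
        logdet_H = float(np.log1p(lam * counts).sum())
        crit = (n - p) * np.log(rss / (n - p)) + logdet_H + logdet_A
        return crit, beta, A, rss

    res = optimize.minimize_scalar(
        lambda t: profile(t)[0],
        bounds=_LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": _XATOL},
    )
    log_lam = float(res.x)
    crit, beta, A, rss = profile(log_lam)
    # The lower bound acts as the lambda -> 0 (pure OLS) boundary.
    converged = bool(res.success) and np.isfinite(crit)

    sigma2_e = rss / (n - p)
    lam_hat = np.exp(log_lam)
    if log_lam <= _LOG_LAMBDA_BOUNDS[0] + 1e-6:
        lam_hat = 0.0
    cov = sigma2_e * np.linalg.inv(A)
    se = float(np.sqrt(cov[focal, focal]))
    b_focal = float(beta[focal])
    if not np.isfinite(se) or se <= 0.0:
        return ModelFit(b_focal, float("inf"), 0.0, 1.0, n, converged=False)
    wald = (b_focal / se) ** 2
    pval = float(stats.chi2.sf(wald, df=1))
    return ModelFit(
        beta=b_focal,
        se=se,
        wald_chi2=wald,
        p=max(pval, np.finfo(float).tiny),
        n_used=n,
        converged=converged,
        sigma_family=float(np.sqrt(lam_hat * sigma2_e)),
        sigma_resid=float(np.sqrt(sigma2_e)),
    )
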