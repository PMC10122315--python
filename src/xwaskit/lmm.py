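"""Random-intercept linear model for per-CpG association fits.

The per-CpG model is y = X beta + u[plate] + e with a single grouping factor
(bisulfite-conversion plate), u ~ N(0, sigma_u^2), e ~ N(0, sigma_e^2).  The
variance ratio lambda = sigma_u^2 / sigma_e^2 is profiled out of the
restricted likelihood and optimized in one dimension, which makes the fit
fast enough to run over tens of thousands of CpGs and bootstrap replicates.

The covariance V(lambda) = I + lambda Z Z' is block compound-symmetric, so
the GLS pieces decompose exactly into within-plate deviations plus weighted
plate means; each evaluation of the REML criterion costs O(G p^2) after a
one-off O(n p) transform.  When the optimum lies at lambda = 0 the fit is
identical to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from .types import ValidationError


@dataclass
class LmmFit:
    """Fixed-effect estimates and variance components from one fit."""

    coef: np.ndarray
    se: np.ndarray
    sigma2_e: float
    sigma2_u: float
    lam: float
    n: int
    columns: list[str]
    method: str  # "reml" or "ols"

    def wald(self, name: str) -> tuple[float, float, float, float]:
        """(effect, se, z, two-sided normal p) for one coefficient."""
        j = self.columns.index(name)
        eff = float(self.coef[j])
        se = float(self.se[j])
        z = eff / se
        p = 2.0 * float(ndtr(-abs(z)))
        return eff, se, z, max(p, 5e-324)


def check_design(X: np.ndarray, columns: list[str]) -> None:
    """Raise listing (nearly) collinear columns if the design is singular."""
    n, p = X.shape
    if n <= p + 1:
        raise ValidationError(
            f"too few rows ({n}) for {p} fixed-effect columns")
    r = np.linalg.matrix_rank(X)
    if r < p:
        # identify involved columns via small singular vectors
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = vt[s < s[0] * 1e-10]
        involved = sorted({columns[j] for row in bad
                           for j in np.flatnonzero(np.abs(row) > 1e-6)})
        raise ValidationError(f"singular design; collinear columns: {involved}")


def ols_fit(y: np.ndarray, X: np.ndarray, columns: list[str]) -> LmmFit:
    n, p = X.shape
    XtX = X.T @ X
    c, low = cho_factor(XtX)
    coef = cho_solve((c, low), X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * cho_solve((c, low), np.eye(p))
    return LmmFit(coef=coef, se=np.sqrt(np.diag(cov)), sigma2_e=sigma2,
                  sigma2_u=0.0, lam=0.0, n=n, columns=list(columns), method="ols")


def reml_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                          columns: list[str]) -> LmmFit:
    """Profiled-REML fit of the single-random-intercept model.

    ``groups`` are integer-coded plate labels.  With fewer than two distinct
    plates the model degenerates and the OLS fit is returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = _recode(groups)
    G = codes.max() + 1
    check_design(X, columns)
    if G < 2:
        return ols_fit(y, X, columns)

    n, p = X.shape
    ng = np.bincount(codes, minlength=G).astype(float)
    sumX = np.zeros((G, p))
    np.add.at(sumX, codes, X)
    meanX = sumX / ng[:, None]
    meany = np.bincount(codes, weights=y, minlength=G) / ng
    Xd = X - meanX[codes]
    yd = y - meany[codes]
    XdtXd = Xd.T @ Xd
    Xdty = Xd.T @ yd
    ydty = float(yd @ yd)

    def pieces(lam: float):
        w = ng / (1.0 + lam * ng)
        A = XdtXd + (meanX * w[:, None]).T @ meanX
        bvec = Xdty + meanX.T @ (w * meany)
        cval = ydty + float(w @ meany ** 2)
        return A, bvec, cval, w

    def crit(lam: float) -> float:
        A, bvec, cval, _ = pieces(lam)
        try:
            c, low = cho_factor(A)
        except np.linalg.LinAlgError:
            return np.inf
        coef = cho_solve((c, low), bvec)
        rss = cval - float(coef @ bvec)
        if rss <= 0:
            return np.inf
        logdetA = 2.0 * float(np.sum(np.log(np.diag(c))))
        logdetV = float(np.sum(np.log1p(lam * ng)))
        return (n - p) * np.log(rss) + logdetV + logdetA

    res = minimize_scalar(lambda t: crit(np.exp(t)), bounds=(-12.0, 8.0),
                          method="bounded", options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    if crit(0.0) <= res.fun:  # boundary: zero plate variance -> exact OLS
        return ols_fit(y, X, columns)

    A, bvec, cval, _ = pieces(lam)
    c, low = cho_factor(A)
    coef = cho_solve((c, low), bvec)
    rss = cval - float(coef @ bvec)
    sigma2_e = rss / (n - p)
    cov = sigma2_e * cho_solve((c, low), np.eye(p))
    return LmmFit(coef=coef, se=np.sqrt(np.diag(cov)), sigma2_e=float(sigma2_e),
                  sigma2_u=float(lam * sigma2_e), lam=lam, n=n,
                  columns=list(columns), method="reml")


def _recode(groups) -> tuple[np.ndarray, list]:
    vals, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes.astype(int), list(vals)


def fit_cpg(m_values: np.ndarray, X: np.ndarray, columns: list[str],
            plate_ids, effect_column: str = "art"):
    """Fit one CpG and return (effect, se, z, p, n_used) for the exposure
    coefficient.  Rows with missing response are dropped (complete-case);
    the design rows must already be complete."""
    y = np.asarray(m_values, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    Xk = np.asarray(X, dtype=float)[keep]
    plates = np.asarray(plate_ids)[keep]
    fit = reml_random_intercept(y, Xk, plates, columns)
    eff, se, z, p = fit.wald(effect_column)
    return eff, se, z, p, fit.n
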