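"""Empirical-null correction of genome-wide test statistics.

Large-scale association scans frequently show z-statistics whose bulk is not
standard normal: a shift (bias mu0) and a spread (inflation sigma0) of the
null component lead to badly calibrated p-values if the theoretical N(0, 1)
null is used.  Following the Bayesian mixture approach used for EWAS/XWAS
inflation control, the observed z-vector is modelled as a three-component
Gaussian mixture

    pi0 N(mu0, sigma0^2) + pi+ N(mu+, sigma+^2) + pi- N(mu-, sigma-^2),

with the ordering constraint mu- < mu0 < mu+ resolving label switching.  The
posterior is explored with a conjugate Gibbs sampler; posterior means of the
null-component parameters are used to rescale the statistics,

    z_adj = (z - mu0) / sigma0,   p_adj = 2 Phi(-|z_adj|).

A robust median/MAD estimate of (mu0, sigma0) is computed alongside as an
internal cross-check and retained in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from statsmodels.stats.multitest import multipletests

from .types import ValidationError


@dataclass
class EmpiricalNull:
    """Posterior summary of the null component of a z-statistic mixture."""

    mu0: float
    sigma0: float
    pi0: float
    mu_pos: float
    mu_neg: float
    robust_mu0: float
    robust_sigma0: float
    n_iter: int
    burn_in: int
    seed: int

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ValidationError("sigma0 must be positive")


def _truncnorm_draw(rng, mean, sd, lower=-np.inf, upper=np.inf) -> float:
    """One draw from N(mean, sd^2) truncated to (lower, upper), by CDF inversion."""
    a = ndtr((lower - mean) / sd)
    b = ndtr((upper - mean) / sd)
    if b - a < 1e-12:  # numerically empty interval: clamp to nearest bound
        return float(np.clip(mean, lower + 1e-9 * sd, upper - 1e-9 * sd))
    u = rng.uniform(a, b)
    return float(mean + sd * ndtri(u))


def estimate_empirical_null(z, seed: int = 0, n_iter: int = 5000,
                            burn_in: int = 1000, min_n: int = 500,
                            ) -> EmpiricalNull:
    """Gibbs-sample the three-component mixture and return posterior means.

    Priors are conjugate and anchored on the robust location/scale of the
    data: the null mean is normal around the median with SD 2 MAD; the two
    signal-component means sit at median +/- 4 MAD with SD 0.3 MAD, which
    keeps them out of the bulk unless the data demand otherwise; variances
    are inverse-gamma with prior mean MAD^2; and the mixture weights have a
    Dirichlet(90, 5, 5) prior favouring a dominant null, as is appropriate
    for genome-wide scans where most loci are null.  The constraint
    mu- < mu0 < mu+ is enforced by truncated conjugate draws.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < min_n:
        raise ValidationError(f"need at least {min_n} z-statistics, got {len(z)}")
    med = float(np.median(z))
    mad = float(1.4826 * np.median(np.abs(z - med)))
    if mad <= 0 or np.std(z) == 0:
        raise ValidationError("degenerate z vector (zero spread)")

    rng = np.random.default_rng(seed)
    n = len(z)
    K = 3  # 0 = null, 1 = positive signal, 2 = negative signal
    mu = np.array([med, med + 4 * mad, med - 4 * mad])
    sig2 = np.array([mad ** 2, mad ** 2, mad ** 2])
    pi = np.array([0.9, 0.05, 0.05])

    prior_mu = mu.copy()
    prior_tau2 = np.array([(2.0 * mad) ** 2, (0.3 * mad) ** 2, (0.3 * mad) ** 2])
    ig_a, ig_b = 2.0, mad ** 2  # inverse-gamma(shape, scale); mean = scale/(shape-1)
    alpha = np.array([90.0, 5.0, 5.0])

    acc = np.zeros(5)  # mu0, sigma0, pi0, mu+, mu-
    n_acc = 0
    for it in range(n_iter):
        # E-like step: sample component memberships
        logp = (np.log(pi)[None, :]
                - 0.5 * np.log(2 * np.pi * sig2)[None, :]
                - 0.5 * (z[:, None] - mu[None, :]) ** 2 / sig2[None, :])
        logp -= logp.max(axis=1, keepdims=True)
        prob = np.exp(logp)
        prob /= prob.sum(axis=1, keepdims=True)
        u = rng.random(n)
        k = (u[:, None] > np.cumsum(prob, axis=1)).sum(axis=1)

        nk = np.bincount(k, minlength=K).astype(float)
        sk = np.bincount(k, weights=z, minlength=K)
        ssk = np.bincount(k, weights=z * z, minlength=K)

        # weights | assignments
        pi = rng.dirichlet(alpha + nk)

        # means | assignments, variances (truncated to keep the ordering)
        post_v = 1.0 / (nk / sig2 + 1.0 / prior_tau2)
        post_m = post_v * (sk / sig2 + prior_mu / prior_tau2)
        mu[0] = _truncnorm_draw(rng, post_m[0], np.sqrt(post_v[0]),
                                lower=mu[2], upper=mu[1])
        mu[1] = _truncnorm_draw(rng, post_m[1], np.sqrt(post_v[1]), lower=mu[0])
        mu[2] = _truncnorm_draw(rng, post_m[2], np.sqrt(post_v[2]), upper=mu[0])

        # variances | assignments, means (conjugate inverse-gamma)
        sq = ssk - 2 * mu * sk + nk * mu ** 2
        a_post = ig_a + nk / 2.0
        b_post = ig_b + 0.5 * np.maximum(sq, 0.0)
        sig2 = b_post / rng.gamma(a_post)

        if it >= burn_in:
            acc += (mu[0], np.sqrt(sig2[0]), pi[0], mu[1], mu[2])
            n_acc += 1

    mu0, sigma0, pi0, mu_pos, mu_neg = acc / n_acc
    return EmpiricalNull(mu0=float(mu0), sigma0=float(sigma0), pi0=float(pi0),
                         mu_pos=float(mu_pos), mu_neg=float(mu_neg),
                         robust_mu0=med, robust_sigma0=mad,
                         n_iter=n_iter, burn_in=burn_in, seed=seed)


def rescale(z, null: EmpiricalNull):
    """Affine rescale of z by the estimated null: z_adj = (z - mu0)/sigma0,
    p_adj = 2 Phi(-|z_adj|).  Rank order of |z - mu0| is preserved."""
    z = np.asarray(z, dtype=float)
    z_adj = (z - null.mu0) / null.sigma0
    p_adj = np.maximum(2.0 * ndtr(-np.abs(z_adj)), 5e-324)
    return z_adj, p_adj


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return p


def bh_fdr(p):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = _check_p(p)
    return multipletests(p, method="fdr_bh")[1]


def by_fdr(p):
    """Benjamini-Yekutieli adjusted p-values: BH scaled by sum_{i<=m} 1/i."""
    p = _check_p(p)
    return multipletests(p, method="fdr_by")[1]


def adjust_results(results, null: EmpiricalNull, fdr_method=bh_fdr):
    """Append z_adj, p_adj and q columns to an XWAS result table (rows with
    missing raw statistics keep NaN and are excluded from the FDR ranking)."""
    out = results.copy()
    ok = np.isfinite(out["z_raw"].to_numpy(dtype=float))
    z_adj = np.full(len(out), np.nan)
    p_adj = np.full(len(out), np.nan)
    q = np.full(len(out), np.nan)
    za, pa = rescale(out.loc[ok, "z_raw"].to_numpy(), null)
    z_adj[ok] = za
    p_adj[ok] = pa
    q[ok] = fdr_method(pa)
    out["z_adj"] = z_adj
    out["p_adj"] = p_adj
    out["q"] = q
    return out
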