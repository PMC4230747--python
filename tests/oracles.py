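"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's samplers: exact tail
enumeration for the binomial test, log-space grid quadrature for the
Poisson-Gamma and negative-binomial posteriors, and effective-sample-size
based Monte-Carlo standard errors for comparing sampler output against
quadrature.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import special, stats


def exact_binomial_pvalue_enum(y: int, n: int) -> float:
    """Two-sided exact binomial p-value at theta = 1/2 by full enumeration.

    Exact rational arithmetic: doubles the smaller of the two inclusive
    tails of Binomial(n, 1/2), capped at 1.
    """
    denom = Fraction(1, 2 ** n)
    lower = sum(comb(n, k) for k in range(0, y + 1)) * denom
    upper = sum(comb(n, k) for k in range(y, n + 1)) * denom
    return float(min(Fraction(1), 2 * min(lower, upper)))


def bh_adjust_enum(p):
    """Benjamini-Hochberg step-up adjusted p-values by the textbook recursion."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Poisson-Gamma quadrature (single replicate, one allele direction)
# ---------------------------------------------------------------------------

def _pg_log_marginal_alpha(alpha_grid, x, y, q, a_mu=0.5, b_mu=0.5,
                           a_beta=0.5, b_beta=0.5, a_alpha=0.5, b_alpha=0.5,
                           n_mu=4001):
    """log p(alpha | x, y) up to a constant for a single-replicate exon.

    beta is integrated analytically (Gamma integral), mu numerically on a
    grid wide enough for counts up to a few hundred.
    """
    al = np.asarray(alpha_grid, dtype=float)
    c = (1.0 - q) + q * al
    mu_hi = 30.0 * max(4.0, np.sqrt(x + y + 1.0))
    mu = np.linspace(1e-8, mu_hi, n_mu)
    t = x + y
    # joint log density on (alpha, mu), beta integrated out
    lp = (
        (a_alpha + y - 1.0) * np.log(al)[:, None]
        - b_alpha * al[:, None]
        + (a_mu + t - 1.0) * np.log(mu)[None, :]
        - b_mu * mu[None, :]
        - (a_beta + t) * np.log(b_beta + np.outer(c, mu))
        + special.gammaln(a_beta + t)
    )
    lp += y * np.log(q) + x * np.log(1.0 - q)
    m = lp.max()
    with np.errstate(divide="ignore"):
        return np.log(np.trapezoid(np.exp(lp - m), mu, axis=1)) + m


def pg_posterior_quadrature(x: int, y: int, q: float, symmetrize: bool = True,
                            n_alpha: int = 6001, alpha_max: float | None = None):
    """Posterior mean and 95% equal-tailed CI of alpha by grid quadrature.

    With ``symmetrize`` the density is the even mixture of the paternal
    direction and the inverted maternal direction (counts swapped, bias
    complemented), mirroring the package's allele-exchangeable inference.
    """
    if alpha_max is None:
        ratio = (y + 1.0) / (x + 1.0) * (1.0 - q) / q
        alpha_max = max(8.0, 12.0 * ratio)
    al = np.linspace(1e-6, alpha_max, n_alpha)
    lp = _pg_log_marginal_alpha(al, x, y, q)
    dens = np.exp(lp - lp.max())
    if symmetrize:
        # maternal direction on the same alpha grid: density of 1/alpha_m
        lpm = _pg_log_marginal_alpha(1.0 / al[::-1], y, x, 1.0 - q)
        dens_m = np.exp(lpm - lpm.max())[::-1] / al ** 2  # Jacobian of inversion
        dens = dens / np.trapezoid(dens, al) + dens_m / np.trapezoid(dens_m, al)
    dens /= np.trapezoid(dens, al)
    mean = np.trapezoid(dens * al, al)
    cdf = np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(al))
    cdf = np.concatenate([[0.0], cdf])
    cdf /= cdf[-1]
    lo = np.interp(0.025, cdf, al)
    hi = np.interp(0.975, cdf, al)
    return float(mean), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Negative-binomial model quadrature
# ---------------------------------------------------------------------------

def nb_p_posterior_quadrature(x_star_sum: int, y_star_sum: int,
                              prior_a: float = 0.5, prior_b: float = 0.5,
                              n_grid: int = 40001):
    """Posterior mean and 95% CI of the DNA bias p by direct grid quadrature.

    Builds the posterior from the NB likelihood product (not from the Beta
    conjugacy shortcut), so it independently checks the conjugate update.
    The grid is sin^2-spaced to resolve the integrable boundary
    singularities of the Jeffreys-type prior.
    """
    u = np.linspace(1e-6, 1 - 1e-6, n_grid)
    p = np.sin(0.5 * np.pi * u) ** 2
    lp = ((prior_a - 1.0 + y_star_sum) * np.log(p)
          + (prior_b - 1.0 + x_star_sum) * np.log(1.0 - p))
    dens = np.exp(lp - lp.max())
    dens /= np.trapezoid(dens, p)
    mean = np.trapezoid(dens * p, p)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(p))])
    cdf /= cdf[-1]
    return float(mean), (float(np.interp(0.025, cdf, p)),
                         float(np.interp(0.975, cdf, p)))


def nb_theta_posterior_quadrature(x_sum: int, y_sum: int, x_star_sum: int,
                                  y_star_sum: int, kappa: float,
                                  prior_a: float = 0.5, prior_b: float = 0.5,
                                  n_p: int = 801, n_th: int = 8001):
    """Mean and 95% CI of theta under the two-stage (cut) NB model.

    Marginalizes the Beta posterior of p on a grid: the theta density is
    the p-mixture of Beta(kappa*p + Y, kappa*(1-p) + X) laws.
    """
    a_p = prior_a + y_star_sum
    b_p = prior_b + x_star_sum
    # integrate over the central mass of p
    p_lo = stats.beta.ppf(1e-6, a_p, b_p)
    p_hi = stats.beta.ppf(1 - 1e-6, a_p, b_p)
    p = np.linspace(p_lo, p_hi, n_p)
    w = stats.beta.pdf(p, a_p, b_p)
    w /= np.trapezoid(w, p)
    th = np.linspace(1e-9, 1 - 1e-9, n_th)
    dens = np.zeros_like(th)
    for pi, wi in zip(p, w):
        dens += wi * stats.beta.pdf(th, kappa * pi + y_sum,
                                    kappa * (1 - pi) + x_sum)
    dens /= np.trapezoid(dens, th)
    mean = np.trapezoid(dens * th, th)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(th))])
    cdf /= cdf[-1]
    return float(mean), (float(np.interp(0.025, cdf, th)),
                         float(np.interp(0.975, cdf, th)))


# ---------------------------------------------------------------------------
# Monte-Carlo standard errors
# ---------------------------------------------------------------------------

def ess(draws: np.ndarray) -> float:
    """Effective sample size of a (possibly autocorrelated) 1-D chain."""
    import arviz as az

    return float(az.ess(az.convert_to_dataset(np.asarray(draws)[None, :]))["x"])


def mc_se_mean(draws: np.ndarray) -> float:
    """MC standard error of the posterior-mean estimate, ESS-adjusted."""
    d = np.asarray(draws, dtype=float)
    return float(d.std(ddof=1) / np.sqrt(max(ess(d), 4.0)))


def mc_se_quantile(draws: np.ndarray, prob: float) -> float:
    """MC standard error of an estimated posterior quantile (KDE density)."""
    d = np.asarray(draws, dtype=float)
    n_eff = max(ess(d), 4.0)
    q = np.quantile(d, prob)
    dens = stats.gaussian_kde(d[:: max(1, d.size // 4000)])(q)[0]
    return float(np.sqrt(prob * (1 - prob) / n_eff) / max(dens, 1e-12))
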