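"""Independent grid-integration oracle for the intercept-only posterior.

Deliberately built on scipy.stats only (betabinom, norm, expon), sharing no
code with the package's likelihood or sampler: dense 2-D quadrature of the
unnormalized posterior over (alpha, log theta), yielding marginal means and
quantiles of alpha and theta.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import betabinom as sp_betabinom, norm


def grid_posterior_intercept_only(
    infected, tested,
    alpha_lo=-12.0, alpha_hi=12.0, n_alpha=481,
    logtheta_lo=-9.0, logtheta_hi=7.0, n_logtheta=481,
    prior_sd=3.0, theta_rate=1.0,
):
    """Marginal posterior means and quantiles of (alpha, theta) by quadrature.

    Returns dict with 'alpha' and 'theta' entries, each holding 'mean' and
    'quantiles' (callable q -> value).
    """
    infected = np.asarray(infected, dtype=float)
    tested = np.asarray(tested, dtype=float)
    alpha = np.linspace(alpha_lo, alpha_hi, n_alpha)
    logtheta = np.linspace(logtheta_lo, logtheta_hi, n_logtheta)
    A, LT = np.meshgrid(alpha, logtheta, indexing="ij")
    theta = np.exp(LT)
    p = expit(A)
    a = p * theta
    b = (1.0 - p) * theta
    ll = np.zeros_like(A)
    for I_k, n_k in zip(infected, tested):
        ll += sp_betabinom.logpmf(I_k, n_k, a, b)
    # priors: Normal(0, prior_sd) on alpha, Exponential(theta_rate) on theta
    # plus the theta -> log theta Jacobian
    lp = (norm.logpdf(A, 0.0, prior_sd)
          + np.log(theta_rate) - theta_rate * theta + LT)
    logpost = ll + lp
    w = np.exp(logpost - logpost.max())
    w /= w.sum()

    out = {}
    for name, values, axis in (("alpha", alpha, 1), ("theta", np.exp(logtheta), 0)):
        marg = w.sum(axis=axis)
        mean = float(np.sum(values * marg))
        cdf = np.cumsum(marg)

        def quantiles(q, values=values, cdf=cdf):
            return float(np.interp(q, cdf, values))

        out[name] = {"mean": mean, "quantiles": quantiles}
    return out


def mcmc_se_mean(x: np.ndarray, ess: float) -> float:
    return float(x.std(ddof=1) / np.sqrt(max(ess, 1.0)))


def quantile_band(x: np.ndarray, q: float, ess: float, z: float = 3.0):
    """Density-free Monte-Carlo confidence band for a sample quantile."""
    half = z * np.sqrt(q * (1.0 - q) / max(ess, 1.0))
    lo_q = min(max(q - half, 0.0), 1.0)
    hi_q = min(max(q + half, 0.0), 1.0)
    return float(np.quantile(x, lo_q)), float(np.quantile(x, hi_q))
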