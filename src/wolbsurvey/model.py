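"""Beta-binomial likelihood, logit link and priors.

The observation model for species *i* screened ``n_i`` times with ``I_i``
positives is

    I_i ~ BetaBinomial(n_i, pbar_i, theta)
    logit(pbar_i) = alpha + beta * x_i

with ``x_i = 0`` for aquatic and ``1`` for terrestrial larval habitat. The
beta distribution of within-species prevalences is parameterized by its mean
``pbar`` and concentration ``theta`` (shapes ``a = pbar*theta``,
``b = (1-pbar)*theta``); small ``theta`` means strongly bimodal prevalences,
which is what real endosymbiont surveys look like. Priors are
Normal(0, 3) on alpha and beta and Exponential(1) on theta — wide enough that
inference is dominated by the data.

The log-pmf is evaluated through differences of log-beta functions so that
counts of 10^4 individuals or more pose no overflow problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import betaln, expit, gammaln, logit as _logit
from scipy.stats import norm

from .survey import SurveyTable

# guard against p_bar rounding to exactly 0 or 1 inside the link
_P_EPS = 1e-12

DEFAULT_CODING = {"aquatic": 0.0, "terrestrial": 1.0}


@dataclass(frozen=True)
class ModelSpec:
    """Priors, link and covariate coding of the screening model."""

    alpha_prior_mean: float = 0.0
    alpha_prior_sd: float = 3.0
    beta_prior_mean: float = 0.0
    beta_prior_sd: float = 3.0
    theta_prior_rate: float = 1.0
    include_covariate: bool = True
    covariate_coding: dict = field(default_factory=lambda: dict(DEFAULT_CODING))

    def __post_init__(self):
        if self.alpha_prior_sd <= 0 or self.beta_prior_sd <= 0:
            raise ValueError("prior sds must be > 0")
        if self.theta_prior_rate <= 0:
            raise ValueError("exponential prior rate must be > 0")

    @property
    def parameter_names(self) -> list[str]:
        return ["alpha", "beta", "theta"] if self.include_covariate else ["alpha", "theta"]

    def without_covariate(self) -> "ModelSpec":
        return replace(self, include_covariate=False)

    # plain-text key=value serialization
    def to_config(self, path: str | Path | None = None) -> str:
        lines = [
            f"alpha_prior_mean={self.alpha_prior_mean!r}",
            f"alpha_prior_sd={self.alpha_prior_sd!r}",
            f"beta_prior_mean={self.beta_prior_mean!r}",
            f"beta_prior_sd={self.beta_prior_sd!r}",
            f"theta_prior_rate={self.theta_prior_rate!r}",
            f"include_covariate={str(self.include_covariate).lower()}",
        ]
        lines += [f"coding_{k}={v!r}" for k, v in sorted(self.covariate_coding.items())]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_config(cls, source: str | Path) -> "ModelSpec":
        """Parse from key=value text, or from a file path (Path or existing file)."""
        if isinstance(source, Path) or "\n" not in str(source):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        kwargs: dict = {}
        coding: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "include_covariate":
                kwargs[key] = value.lower() in ("true", "1", "yes")
            elif key.startswith("coding_"):
                coding[key[len("coding_"):]] = float(value)
            else:
                kwargs[key] = float(value)
        if coding:
            kwargs["covariate_coding"] = coding
        return cls(**kwargs)


@dataclass(frozen=True)
class ParameterPoint:
    """One point in parameter space: logit-scale intercept and habitat effect
    plus the beta concentration (natural scale)."""

    alpha: float
    theta: float
    beta: float | None = None


def logistic(u):
    """Inverse logit; maps the linear predictor to a probability in (0, 1)."""
    return expit(u)


def logit(p):
    return _logit(p)


def beta_shapes(p_bar, theta):
    """Mean/concentration -> (a, b) shape parameters of the beta distribution."""
    p_bar = np.asarray(p_bar, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(p_bar <= 0) or np.any(p_bar >= 1):
        raise ValueError("p_bar must lie strictly inside (0, 1)")
    if np.any(theta <= 0):
        raise ValueError("theta must be > 0")
    return p_bar * theta, (1.0 - p_bar) * theta


def betabinom_log_pmf(I, n, p_bar, theta):
    """log P(I | n, p_bar, theta) for the beta-binomial, via log-beta functions.

    Broadcasts over array arguments. Stable for n well beyond 10^4.
    """
    I = np.asarray(I)
    n = np.asarray(n)
    if np.any(I < 0) or np.any(I > n):
        raise ValueError("require 0 <= I <= n")
    a, b = beta_shapes(p_bar, theta)
    out = (
        gammaln(n + 1) - gammaln(I + 1) - gammaln(n - I + 1)
        + betaln(I + a, n - I + b) - betaln(a, b)
    )
    return out if out.shape else float(out)


def _design(table: SurveyTable, spec: ModelSpec):
    """Extract (I, n, x) arrays; x from the covariate coding (unused when the
    covariate is off)."""
    df = table.frame
    I = df["n_infected"].to_numpy(dtype=float)
    n = df["n_tested"].to_numpy(dtype=float)
    if spec.include_covariate:
        try:
            x = df["habitat"].map(spec.covariate_coding).to_numpy(dtype=float)
        except (TypeError, ValueError):
            raise ValueError("habitat labels not covered by covariate coding")
        if np.any(np.isnan(x)):
            bad = sorted(set(df["habitat"]) - set(spec.covariate_coding))
            raise ValueError(f"habitat labels not in covariate coding: {bad}")
    else:
        x = np.zeros(len(df))
    return I, n, x


def make_loglik(table: SurveyTable, spec: ModelSpec) -> Callable[[float, float, float], float]:
    """Build a fast closure loglik(alpha, beta, theta) over a fixed table.

    The combinatorial term is precomputed; each call costs two vectorized
    betaln evaluations. ``beta`` is ignored when the covariate is off.
    Accepts scalar parameters or broadcastable arrays (grid integration).
    """
    I, n, x = _design(table, spec)
    lchoose = gammaln(n + 1) - gammaln(I + 1) - gammaln(n - I + 1)
    const = float(np.sum(lchoose))
    use_x = spec.include_covariate

    def loglik(alpha, beta, theta):
        alpha = np.asarray(alpha, dtype=float)[..., None]
        theta = np.asarray(theta, dtype=float)[..., None]
        eta = alpha + (np.asarray(beta, dtype=float)[..., None] * x if use_x else 0.0)
        p = np.clip(expit(eta), _P_EPS, 1.0 - _P_EPS)
        a = p * theta
        b = (1.0 - p) * theta
        ll = np.sum(betaln(I + a, n - I + b) - betaln(a, b), axis=-1) + const
        return float(ll) if ll.shape == () else ll

    return loglik


def log_likelihood(params: ParameterPoint, table: SurveyTable, spec: ModelSpec) -> float:
    """Sum of beta-binomial log-pmfs with pbar_i = logistic(alpha + beta*x_i)."""
    if len(table) == 0:
        return 0.0
    if params.theta <= 0:
        raise ValueError("theta must be > 0")
    beta = params.beta if spec.include_covariate else 0.0
    if spec.include_covariate and params.beta is None:
        raise ValueError("model includes covariate but params.beta is None")
    return make_loglik(table, spec)(params.alpha, beta, params.theta)


def log_prior(params: ParameterPoint, spec: ModelSpec) -> float:
    """Normal priors on the logit-scale terms, Exponential on theta.

    theta <= 0 returns -inf (outside the support), not an exception.
    """
    if params.theta <= 0:
        return -np.inf
    lp = norm.logpdf(params.alpha, spec.alpha_prior_mean, spec.alpha_prior_sd)
    if spec.include_covariate:
        if params.beta is None:
            raise ValueError("model includes covariate but params.beta is None")
        lp += norm.logpdf(params.beta, spec.beta_prior_mean, spec.beta_prior_sd)
    rate = spec.theta_prior_rate
    lp += np.log(rate) - rate * params.theta
    return float(lp)


def log_posterior(params: ParameterPoint, table: SurveyTable, spec: ModelSpec) -> float:
    """Unnormalized log posterior: log_likelihood + log_prior."""
    lp = log_prior(params, spec)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(params, table, spec)
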