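"""Posterior sampling for (alpha, beta, theta) and convergence diagnostics.

The kernel is an adaptive random-walk Metropolis sampler operating on the
unconstrained vector (alpha[, beta], log theta); the log-Jacobian of the
theta -> log theta transform is added to the target so draws follow exactly
the posterior defined in :mod:`wolbsurvey.model` (Exponential(1) prior on
natural theta). During warmup the proposal is tuned in two phases: global
step-size adaptation toward a ~30% acceptance rate, then an empirical
proposal covariance estimated from the warmup history. After warmup the
proposal is frozen, so the retained chains are genuine Markov chains with the
posterior as invariant distribution.

Default protocol: four independent chains, 1,000 warmup + 2,000 retained
iterations each (8,000 retained draws), convergence gated on split-R-hat
< 1.1 for every parameter.

Everything is driven by one integer seed through numpy SeedSequence spawning,
so identical (seed, config, data) gives bit-identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .model import ModelSpec, make_loglik
from .survey import SurveyTable

_INIT_RETRIES = 50


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_iterations: int = 2000  # retained per chain
    n_warmup: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iterations < 1 or self.n_warmup < 0:
            raise ValueError("chain counts and iteration counts must be positive")

    def scaled(self, **kwargs) -> "SamplerConfig":
        return replace(self, **kwargs)


@dataclass
class PosteriorDraws:
    """Retained posterior draws indexed by (chain, iteration), plus diagnostics.

    ``draws[name]`` is an (n_chains, n_iterations) array on the natural scale
    (theta positive). ``diagnostics[name]`` holds split-R-hat and effective
    sample size.
    """

    draws: dict[str, np.ndarray]
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    config: SamplerConfig | None = None

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iterations(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def max_rhat(self) -> float:
        return max(d["rhat"] for d in self.diagnostics.values())

    def converged(self, threshold: float | None = None) -> bool:
        thr = threshold if threshold is not None else (
            self.config.rhat_threshold if self.config else 1.1)
        return self.max_rhat() < thr


# -- kernel -------------------------------------------------------------------

def _adaptive_metropolis(logpost, z0, n_warmup, n_iter, rng):
    """Random-walk Metropolis with warmup step-size and covariance adaptation."""
    d = z0.size
    z = z0.copy()
    lp = logpost(z)
    log_scale = np.log(2.38 / np.sqrt(d))
    chol = np.eye(d)
    history = np.empty((n_warmup, d))
    out = np.empty((n_iter, d))
    target = 0.30
    cov_update_at = max(n_warmup // 2, 1)
    for t in range(n_warmup + n_iter):
        prop = z + np.exp(log_scale) * (chol @ rng.standard_normal(d))
        lp_prop = logpost(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            z, lp = prop, lp_prop
        if t < n_warmup:
            history[t] = z
            # Robbins-Monro drift of the global step size toward ~30% acceptance
            log_scale += (float(accept) - target) / (t + 10) ** 0.6
            if t + 1 == cov_update_at and t >= 2 * d:
                cov = np.cov(history[: t + 1].T)
                cov = np.atleast_2d(cov) + 1e-6 * np.eye(d)
                chol = np.linalg.cholesky(cov)
                log_scale = np.log(2.38 / np.sqrt(d))
        else:
            out[t - n_warmup] = z
    return out


def sample_posterior(table: SurveyTable, spec: ModelSpec,
                     config: SamplerConfig) -> PosteriorDraws:
    """Draw posterior samples of (alpha[, beta], theta) for one table.

    Raises if the table is empty or if no finite starting point is found
    after a bounded number of re-initializations.
    """
    if len(table) == 0:
        raise ValueError("cannot sample from an empty table")
    loglik = make_loglik(table, spec)
    use_beta = spec.include_covariate
    amu, asd = spec.alpha_prior_mean, spec.alpha_prior_sd
    bmu, bsd = spec.beta_prior_mean, spec.beta_prior_sd
    rate = spec.theta_prior_rate
    lograte = np.log(rate)

    if use_beta:
        def logpost(z):
            alpha, beta, logtheta = z
            theta = np.exp(logtheta)
            lp = (-0.5 * ((alpha - amu) / asd) ** 2
                  - 0.5 * ((beta - bmu) / bsd) ** 2
                  + lograte - rate * theta + logtheta)  # + Jacobian
            return lp + loglik(alpha, beta, theta)
    else:
        def logpost(z):
            alpha, logtheta = z
            theta = np.exp(logtheta)
            lp = (-0.5 * ((alpha - amu) / asd) ** 2
                  + lograte - rate * theta + logtheta)
            return lp + loglik(alpha, 0.0, theta)

    dim = 3 if use_beta else 2
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = np.empty((config.n_chains, config.n_iterations, dim))
    for c in range(config.n_chains):
        rng = np.random.default_rng(children[c])
        z0 = None
        for _ in range(_INIT_RETRIES):
            cand = np.concatenate([
                rng.normal(0.0, 1.0, size=dim - 1),
                rng.normal(0.0, 0.5, size=1),  # log theta
            ])
            if np.isfinite(logpost(cand)):
                z0 = cand
                break
        if z0 is None:
            raise RuntimeError(
                f"chain {c}: no finite log-posterior found in {_INIT_RETRIES} "
                "initialization attempts; check the data and model spec"
            )
        chains[c] = _adaptive_metropolis(logpost, z0, config.n_warmup,
                                         config.n_iterations, rng)

    names = spec.parameter_names
    draws: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        col = chains[:, :, j]
        draws[name] = np.exp(col) if name == "theta" else col.copy()
    result = PosteriorDraws(draws=draws, config=config)
    if config.n_chains >= 2:
        result.diagnostics = {
            name: {"rhat": rhat(result, name), "ess": ess(result, name)}
            for name in names
        }
    return result


# -- diagnostics ----------------------------------------------------------------

def _split_chains(x: np.ndarray) -> np.ndarray:
    m, n = x.shape
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 iterations per chain for split diagnostics")
    return np.vstack([x[:, :half], x[:, half: 2 * half]])


def _rhat_from_matrix(x: np.ndarray) -> float:
    m, n = x.shape
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def rhat(draws: PosteriorDraws, parameter: str, rank_normalized: bool = False) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    The classical PSRF computed on split half-chains; with
    ``rank_normalized=True`` draws are rank-transformed to normal scores
    first (the modern bulk-R-hat variant).
    """
    x = draws.draws[parameter]
    if x.shape[0] < 2:
        raise ValueError("r-hat requires at least 2 chains")
    if x.shape[1] < 10:
        raise ValueError("r-hat requires at least 10 iterations per chain")
    xs = _split_chains(x)
    if rank_normalized:
        r = rankdata(xs, axis=None).reshape(xs.shape)
        xs = norm.ppf((r - 0.375) / (xs.size + 0.25))
    return _rhat_from_matrix(xs)


def _chain_autocov(x: np.ndarray) -> np.ndarray:
    """Biased (divide-by-n) autocovariance of each row via FFT."""
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real
    return acov / n


def ess(draws: PosteriorDraws, parameter: str) -> float:
    """Effective sample size across chains (Geyer initial-monotone estimate)."""
    x = draws.draws[parameter]
    xs = _split_chains(x) if x.shape[1] >= 4 else x
    m, n = xs.shape
    acov = _chain_autocov(xs)
    chain_vars = acov[:, 0] * n / (n - 1)
    w = chain_vars.mean()
    var_hat = (n - 1) / n * w + xs.mean(axis=1).var(ddof=1)
    if var_hat == 0:
        return float(m * n)
    rho = 1.0 - (w - acov.mean(axis=0)) / var_hat
    rho[0] = 1.0
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 1.0
    prev_pair = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    return float(m * n / tau)


# -- export --------------------------------------------------------------------

TRACE_COLUMNS = ["chain", "iteration", "parameter", "value"]


def trace_export(draws: PosteriorDraws, path: str | Path,
                 plot_path: str | Path | None = None) -> None:
    """Write per-chain parameter series in long format (chain, iteration,
    parameter, value); optionally render a trace plot to ``plot_path``."""
    frames = []
    for name, arr in draws.draws.items():
        m, n = arr.shape
        frames.append(pd.DataFrame({
            "chain": np.repeat(np.arange(m), n),
            "iteration": np.tile(np.arange(n), m),
            "parameter": name,
            "value": arr.reshape(-1),
        }))
    # %.17g guarantees exact float64 round-trip through text
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")
    if plot_path is not None:
        trace_plot(draws, plot_path)


def read_trace(path: str | Path) -> PosteriorDraws:
    """Inverse of :func:`trace_export` (diagnostics are recomputed lazily)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing column(s): {missing}")
    draws = {}
    for name, g in df.groupby("parameter", sort=False):
        m = int(g["chain"].max()) + 1
        n = int(g["iteration"].max()) + 1
        arr = np.full((m, n), np.nan)
        arr[g["chain"].to_numpy(), g["iteration"].to_numpy()] = g["value"].to_numpy()
        draws[name] = arr
    return PosteriorDraws(draws=draws)


def trace_plot(draws: PosteriorDraws, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = draws.parameter_names
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 2.2 * len(names)),
                             squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        for c in range(draws.n_chains):
            ax.plot(draws.draws[name][c], lw=0.5, alpha=0.8)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
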