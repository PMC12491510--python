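"""Convergence diagnostics, posterior summaries and model selection.

Convergence is judged by the Gelman-Rubin potential scale reduction factor
(psrf, threshold < 1.05) and the effective sample size (ESS, threshold
> 1000), the criteria used for the study fits.  Posterior summaries report
the pooled-chain median and equal-tailed 95% credibility interval per
parameter.  Model selection between the conditional-independence and
conditional-dependence fits keeps the dependence terms only when at least
one covariance's 95% interval excludes zero (inclusive endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import ChainDraws

__all__ = [
    "psrf",
    "autocorrelation",
    "effective_sample_size",
    "ParameterSummary",
    "PosteriorSummary",
    "summarize",
    "ParameterDiagnostics",
    "ConvergenceReport",
    "convergence_report",
    "select_model",
]

#: ESS estimates above this multiple of the number of draws are truncated;
#: mild super-efficiency from antithetic behaviour is allowed, more is noise.
ESS_INFLATION_CAP = 1.5


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is an (m, n) array of m >= 2 chains of n >= 2 draws.  Uses
    the classic two-stage formula sqrt(((n-1)/n * W + B/n) / W) with W the
    mean within-chain variance and B = n * variance of the chain means.
    Two degenerate cases are defined explicitly: identical constant chains
    give 1.0, distinct constant chains give +inf.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("psrf needs at least 2 chains of at least 2 draws")
    m, n = arr.shape
    chain_means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Sample autocorrelation of a single series, computed via FFT.

    Returns lags 0..max_lag (default n-1).  A constant series returns
    zeros (with rho_0 = 1 by convention replaced by 0 to signal no
    information).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    x = x - x.mean()
    if np.all(x == 0.0):
        return np.zeros(max_lag + 1)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f))[: max_lag + 1] / n
    return acov / acov[0]


def _mean_autocovariance(arr: np.ndarray) -> np.ndarray:
    """Autocovariance at every lag, averaged across chains (each chain
    demeaned by its own mean)."""
    m, n = arr.shape
    nfft = 1 << (2 * n - 1).bit_length()
    centered = arr - arr.mean(axis=1, keepdims=True)
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), axis=1)[:, :n] / n
    return acov.mean(axis=0)


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective sample size N / (1 + 2 * sum of autocorrelations).

    Accepts a single series or an (m, n) stack of chains; autocovariances
    are averaged across chains.  The autocorrelation sum is truncated by
    Geyer's initial monotone positive sequence rule on successive lag
    pairs.  Constant chains return 0; the estimate is capped at
    ``ESS_INFLATION_CAP`` times the total number of draws.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = arr.shape
    total = m * n
    if total < 10:
        raise ValueError("effective_sample_size needs at least 10 draws")
    acov = _mean_autocovariance(arr)
    if acov[0] == 0.0:
        return 0.0
    rho = acov / acov[0]

    # Geyer initial monotone positive sequence: sum Gamma_k = rho_{2k} +
    # rho_{2k+1} while positive, enforcing monotone non-increase.
    tau = 0.0
    prev_gamma = np.inf
    k = 0
    while 2 * k + 1 <= n - 1:
        gamma = rho[2 * k] + rho[2 * k + 1]
        if gamma <= 0.0:
            break
        gamma = min(gamma, prev_gamma)
        tau += 2.0 * gamma
        prev_gamma = gamma
        k += 1
    tau -= 1.0  # 2 * sum Gamma_k - 1 = 1 + 2 * sum_{t>=1} rho_t
    tau = max(tau, 1.0 / ESS_INFLATION_CAP)
    return float(min(total / tau, ESS_INFLATION_CAP * total))


@dataclass(frozen=True)
class ParameterSummary:
    """Point estimate, 95% equal-tailed interval and diagnostics."""

    estimate: float
    lower95: float
    upper95: float
    psrf: float
    ess: float

    def __post_init__(self) -> None:
        if not self.lower95 <= self.estimate <= self.upper95:
            raise ValueError(
                f"summary is not ordered: {self.lower95} <= {self.estimate} "
                f"<= {self.upper95} fails"
            )

    def interval_contains(self, value: float) -> bool:
        return self.lower95 <= value <= self.upper95


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior summaries (the shape of the results table)."""

    parameters: dict[str, ParameterSummary]
    point: str = "median"

    def __getitem__(self, name: str) -> ParameterSummary:
        return self.parameters[name]

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.parameters),
                "estimate": [s.estimate for s in self.parameters.values()],
                "lower95": [s.lower95 for s in self.parameters.values()],
                "upper95": [s.upper95 for s in self.parameters.values()],
                "ess": [s.ess for s in self.parameters.values()],
                "psrf": [s.psrf for s in self.parameters.values()],
            }
        )


def summarize(draws: ChainDraws, point: str = "median") -> PosteriorSummary:
    """Pooled-chain posterior summaries for every parameter.

    The point estimate is the pooled median by default (``point="mean"``
    switches to the mean); intervals are equal-tailed 2.5%/97.5% quantiles
    with linear interpolation of order statistics.
    """
    if point not in ("median", "mean"):
        raise ValueError("point must be 'median' or 'mean'")
    summaries = {}
    for name in draws.parameters:
        per_chain = draws.per_chain(name)
        pooled = per_chain.reshape(-1)
        est = float(np.median(pooled) if point == "median" else pooled.mean())
        lower, upper = np.quantile(pooled, [0.025, 0.975])
        summaries[name] = ParameterSummary(
            estimate=est,
            lower95=float(lower),
            upper95=float(upper),
            psrf=psrf(per_chain),
            ess=effective_sample_size(per_chain),
        )
    return PosteriorSummary(parameters=summaries, point=point)


@dataclass(frozen=True)
class ParameterDiagnostics:
    psrf: float
    ess: float
    autocorrelations: np.ndarray
    converged: bool


@dataclass(frozen=True)
class ConvergenceReport:
    """Convergence assessment per parameter against the study thresholds."""

    parameters: dict[str, ParameterDiagnostics]
    psrf_max: float = 1.05
    ess_min: float = 1000.0

    @property
    def all_converged(self) -> bool:
        return all(p.converged for p in self.parameters.values())

    @property
    def failing_parameters(self) -> tuple[str, ...]:
        return tuple(n for n, p in self.parameters.items() if not p.converged)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.parameters),
                "psrf": [p.psrf for p in self.parameters.values()],
                "ess": [p.ess for p in self.parameters.values()],
                "converged": [p.converged for p in self.parameters.values()],
            }
        )


def convergence_report(
    draws: ChainDraws,
    psrf_max: float = 1.05,
    ess_min: float = 1000.0,
    n_lags: int = 50,
) -> ConvergenceReport:
    """Assess convergence of every parameter in a set of chains."""
    params = {}
    for name in draws.parameters:
        per_chain = draws.per_chain(name)
        r = psrf(per_chain)
        ess = effective_sample_size(per_chain)
        acf = autocorrelation(per_chain.reshape(-1), max_lag=n_lags)
        params[name] = ParameterDiagnostics(
            psrf=r,
            ess=ess,
            autocorrelations=acf,
            converged=bool(r < psrf_max and ess > ess_min),
        )
    return ConvergenceReport(parameters=params, psrf_max=psrf_max, ess_min=ess_min)


def select_model(summary_dep: PosteriorSummary) -> str:
    """Choose between the independence and dependence models.

    Returns ``"independence"`` when the 95% credibility intervals of both
    covariance terms contain 0 (closed intervals, endpoints inclusive),
    otherwise ``"dependence"``.
    """
    for name in ("cov_dpos", "cov_dneg"):
        if name not in summary_dep:
            raise ValueError(
                f"summary lacks covariance parameter {name!r}; model selection "
                "requires a dependence-model fit"
            )
    both_contain_zero = all(
        summary_dep[name].interval_contains(0.0)
        for name in ("cov_dpos", "cov_dneg")
    )
    return "independence" if both_contain_zero else "dependence"
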