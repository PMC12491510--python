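"""Posterior samplers for the two-test latent class model.

Two samplers are provided.  For the conditional-independence model,
``gibbs_independence`` runs a data-augmentation Gibbs sampler: for each
population and observed cell, the latent number of true positives is drawn
from its binomial full conditional, after which prevalence, sensitivities
and specificities all have conjugate beta full conditionals.

For the conditional-dependence model, ``mwg_dependence`` runs
Metropolis-within-Gibbs.  Prevalence keeps its exact beta conditional.
Sensitivities and specificities are proposed from the beta conditional of
the independence model and corrected by a Metropolis-Hastings ratio against
the exact augmented likelihood; when the covariances are zero the proposal
is exact and every proposal is accepted, so the sampler reduces to the
independence Gibbs sampler.  The covariance terms themselves are updated by
a reflected Gaussian random walk restricted to their feasible interval.
The joint prior on the covariances is flat over the feasible region.

Plain data augmentation mixes slowly when populations are large: the
latent counts carry most of the information, so successive draws are
highly autocorrelated.  Each iteration therefore appends a small number of
collapsed slice-sampling sweeps (univariate slice updates of every free
parameter against the observed-data multinomial likelihood, with the
latent counts integrated out).  Both component kernels leave the posterior
invariant, so their composition does too; the collapsed sweeps only reduce
autocorrelation.  Set ``n_collapsed_sweeps=0`` for the pure augmented
sampler.

Label switching (the mirror ambiguity of latent class models) is resolved
by relabeling: whenever both tests have Se + Sp < 1 the state is mapped to
its mirror image, which satisfies Se + Sp > 1 for both tests and leaves the
likelihood unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import StudyData
from .model_core import covariance_bounds, within_class_probs
from .priors import PriorSet

__all__ = [
    "McmcConfig",
    "ChainDraws",
    "gibbs_independence",
    "mwg_dependence",
    "enforce_identifiability",
]

_RATE_PARAMS = ("se1", "sp1", "se2", "sp2")


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout and seeding.

    Defaults follow the study protocol: two independent chains, burn-in
    5000, then 10,000 retained iterations, no thinning.  Chain ``c`` is
    driven by ``numpy.random.default_rng(seed + c)`` and initialized by
    drawing from the priors, giving overdispersed starts for the
    Gelman-Rubin diagnostic.
    """

    n_chains: int = 2
    burn_in: int = 5000
    n_iterations: int = 10000
    seed: int = 0
    thin: int = 1
    enforce_identifiability: bool = True
    allow_single_population: bool = False
    n_collapsed_sweeps: int = 2

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for diagnostics")
        if self.burn_in < 0 or self.n_iterations < 1:
            raise ValueError("burn_in must be >= 0 and n_iterations >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_collapsed_sweeps < 0:
            raise ValueError("n_collapsed_sweeps must be >= 0")

    @property
    def n_kept(self) -> int:
        return self.n_iterations // self.thin


@dataclass
class ChainDraws:
    """Per-chain posterior draws for every model parameter.

    ``draws`` maps parameter names (``se1``, ``sp1``, ``se2``, ``sp2``,
    ``prev[<population>]`` and, for the dependence model, ``cov_dpos`` /
    ``cov_dneg``) to arrays of shape ``(n_chains, n_kept)``.
    """

    draws: dict[str, np.ndarray]
    config: McmcConfig
    model: str
    population_ids: tuple[str, ...]
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    relabel_fraction: float = 0.0

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.draws)

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def per_chain(self, name: str) -> np.ndarray:
        return self.draws[name]

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format (chain, iteration, parameter, value)."""
        frames = []
        for name, arr in self.draws.items():
            n_chains, n_kept = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(n_chains), n_kept),
                        "iteration": np.tile(np.arange(n_kept), n_chains),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def enforce_identifiability(state: dict) -> tuple[dict, np.ndarray]:
    """Relabel mirror-image states so that tests are informative.

    States in which both tests have Se + Sp < 1 are the mirror labeling of
    the latent classes; they are mapped to the equivalent state
    ``(se_i, sp_i) -> (1 - sp_i, 1 - se_i)``, ``prev -> 1 - prev`` and, when
    present, ``cov_dpos <-> cov_dneg``.  The transform leaves the
    likelihood invariant and is an involution.

    ``state`` maps parameter names to scalars or aligned arrays; keys
    starting with ``prev`` are treated as prevalences.  Returns the
    relabeled state and the boolean mask of entries that were relabeled.
    """
    se1 = np.asarray(state["se1"], dtype=float)
    sp1 = np.asarray(state["sp1"], dtype=float)
    se2 = np.asarray(state["se2"], dtype=float)
    sp2 = np.asarray(state["sp2"], dtype=float)
    mask = (se1 + sp1 < 1.0) & (se2 + sp2 < 1.0)
    out = dict(state)
    out["se1"] = np.where(mask, 1.0 - sp1, se1)
    out["sp1"] = np.where(mask, 1.0 - se1, sp1)
    out["se2"] = np.where(mask, 1.0 - sp2, se2)
    out["sp2"] = np.where(mask, 1.0 - se2, sp2)
    for key, value in state.items():
        if key.startswith("prev"):
            out[key] = np.where(mask, 1.0 - np.asarray(value, dtype=float), value)
    if "cov_dpos" in state and "cov_dneg" in state:
        cp = np.asarray(state["cov_dpos"], dtype=float)
        cn = np.asarray(state["cov_dneg"], dtype=float)
        out["cov_dpos"] = np.where(mask, cn, cp)
        out["cov_dneg"] = np.where(mask, cp, cn)
    return out, mask


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real number into [lo, hi] by reflection at the endpoints."""
    width = hi - lo
    if width <= 0.0:
        return lo
    y = (x - lo) % (2.0 * width)
    return lo + (width - abs(y - width))


def _validate_inputs(data: StudyData, priors: PriorSet, config: McmcConfig) -> None:
    if data.n_populations < 2 and not config.allow_single_population:
        raise ValueError(
            "the base model needs at least two populations; set "
            "allow_single_population=True when accuracies are fixed or "
            "priors are informative"
        )
    if priors.n_populations != data.n_populations:
        raise ValueError(
            f"priors carry {priors.n_populations} prevalence slots but data "
            f"has {data.n_populations} populations"
        )


def _augmented_rate_counts(y: np.ndarray, z: np.ndarray) -> dict[str, tuple[float, float]]:
    """Successes/failures for each rate parameter given latent counts.

    ``y`` holds latent positives per (population, cell), ``z`` latent
    negatives.  For sensitivities the successes are latent positives that
    tested positive; for specificities, latent negatives that tested
    negative.
    """
    ypos = y.sum(axis=0)
    zneg = z.sum(axis=0)
    return {
        "se1": (ypos[0] + ypos[1], ypos[2] + ypos[3]),
        "sp1": (zneg[2] + zneg[3], zneg[0] + zneg[1]),
        "se2": (ypos[0] + ypos[2], ypos[1] + ypos[3]),
        "sp2": (zneg[1] + zneg[3], zneg[0] + zneg[2]),
    }


def _class_cell_loglik(cell_probs: np.ndarray, cell_counts: np.ndarray) -> float:
    """sum(counts * log probs) over the four within-class cells, -inf if
    a positive count meets a non-positive probability."""
    observed = cell_counts > 0
    if not np.any(observed):
        return 0.0
    probs = cell_probs[observed]
    if np.any(probs <= 0.0):
        return -math.inf
    return float(np.sum(cell_counts[observed] * np.log(probs)))


def _observed_loglik(
    counts_rows: list[tuple[int, int, int, int]],
    prevs: list[float],
    se1: float,
    sp1: float,
    se2: float,
    sp2: float,
    cov_p: float,
    cov_n: float,
) -> float:
    """Observed-data multinomial log-likelihood kernel (latent counts
    integrated out), in scalar arithmetic for speed.

    Returns -inf when a within-class cell probability is negative (the
    covariance bound is violated) or a cell with a positive count has zero
    probability.
    """
    a11 = se1 * se2 + cov_p
    a10 = se1 * (1.0 - se2) - cov_p
    a01 = (1.0 - se1) * se2 - cov_p
    a00 = (1.0 - se1) * (1.0 - se2) + cov_p
    q1 = 1.0 - sp1
    q2 = 1.0 - sp2
    b11 = q1 * q2 + cov_n
    b10 = q1 * sp2 - cov_n
    b01 = sp1 * q2 - cov_n
    b00 = sp1 * sp2 + cov_n
    tol = -1e-12
    if cov_p != 0.0 and (a11 < tol or a10 < tol or a01 < tol or a00 < tol):
        return -math.inf
    if cov_n != 0.0 and (b11 < tol or b10 < tol or b01 < tol or b00 < tol):
        return -math.inf
    total = 0.0
    for k, row in enumerate(counts_rows):
        p = prevs[k]
        q = 1.0 - p
        for n_c, a_c, b_c in zip(
            row, (a11, a10, a01, a00), (b11, b10, b01, b00)
        ):
            if n_c:
                pc = p * a_c + q * b_c
                if pc <= 0.0:
                    return -math.inf
                total += n_c * math.log(pc)
    return total


_SLICE_WIDTH = 0.1
_MAX_SHRINK = 100


def _slice_update(
    x: float,
    logf,
    lo: float,
    hi: float,
    rng: np.random.Generator,
    width: float = _SLICE_WIDTH,
) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)
    restricted to (lo, hi)."""
    fx = logf(x)
    if not math.isfinite(fx):
        return x
    y = fx + math.log(rng.random())
    left = max(x - width * rng.random(), lo)
    right = min(left + width, hi)
    while left > lo and logf(left) > y:
        left = max(left - width, lo)
    while right < hi and logf(right) > y:
        right = min(right + width, hi)
    for _ in range(_MAX_SHRINK):
        x1 = left + rng.random() * (right - left)
        if logf(x1) > y:
            return x1
        if x1 < x:
            left = x1
        else:
            right = x1
    return x


def _collapsed_sweep(
    state: dict[str, float],
    prev: np.ndarray,
    cov_p: float,
    cov_n: float,
    counts_rows: list[tuple[int, int, int, int]],
    prior_by_name: dict,
    prev_alpha: np.ndarray,
    prev_beta: np.ndarray,
    fixed: dict[str, float],
    rng: np.random.Generator,
    update_covs: bool = False,
) -> tuple[np.ndarray, float, float]:
    """One slice-sampling sweep over all free parameters against the
    observed-data likelihood.  Mutates ``state``; returns the updated
    prevalence array and covariance terms."""
    prevs = list(prev)

    def log_prior(x: float, alpha: float, beta: float) -> float:
        if alpha == 1.0 and beta == 1.0:
            return 0.0
        return (alpha - 1.0) * math.log(x) + (beta - 1.0) * math.log1p(-x)

    eps = 1e-12
    for name in _RATE_PARAMS:
        if name in fixed:
            continue
        prior = prior_by_name[name]

        def logf(x: float, name=name, prior=prior) -> float:
            args = {
                "se1": state["se1"],
                "sp1": state["sp1"],
                "se2": state["se2"],
                "sp2": state["sp2"],
            }
            args[name] = x
            ll = _observed_loglik(
                counts_rows, prevs, args["se1"], args["sp1"], args["se2"],
                args["sp2"], cov_p, cov_n,
            )
            if not math.isfinite(ll):
                return ll
            return ll + log_prior(x, prior.alpha, prior.beta)

        state[name] = _slice_update(state[name], logf, eps, 1.0 - eps, rng)
    for k in range(len(prevs)):

        def logf_prev(x: float, k=k) -> float:
            trial = list(prevs)
            trial[k] = x
            ll = _observed_loglik(
                counts_rows, trial, state["se1"], state["sp1"], state["se2"],
                state["sp2"], cov_p, cov_n,
            )
            if not math.isfinite(ll):
                return ll
            return ll + log_prior(x, prev_alpha[k], prev_beta[k])

        prevs[k] = _slice_update(prevs[k], logf_prev, eps, 1.0 - eps, rng)

    if update_covs:
        lo, hi = covariance_bounds(state["se1"], state["se2"])
        if hi > lo:
            cov_p = _slice_update(
                cov_p,
                lambda c: _observed_loglik(
                    counts_rows, prevs, state["se1"], state["sp1"],
                    state["se2"], state["sp2"], c, cov_n,
                ),
                lo,
                hi,
                rng,
                width=min(_SLICE_WIDTH, hi - lo),
            )
        lo, hi = covariance_bounds(state["sp1"], state["sp2"])
        if hi > lo:
            cov_n = _slice_update(
                cov_n,
                lambda c: _observed_loglik(
                    counts_rows, prevs, state["se1"], state["sp1"],
                    state["se2"], state["sp2"], cov_p, c,
                ),
                lo,
                hi,
                rng,
                width=min(_SLICE_WIDTH, hi - lo),
            )
    return np.array(prevs), cov_p, cov_n


def _sample(
    data: StudyData,
    priors: PriorSet,
    config: McmcConfig,
    dependence: bool,
    proposal_sd: float = 0.05,
    fixed: dict[str, float] | None = None,
) -> ChainDraws:
    _validate_inputs(data, priors, config)
    fixed = dict(fixed or {})
    for key in fixed:
        if key not in _RATE_PARAMS:
            raise ValueError(f"only {', '.join(_RATE_PARAMS)} can be fixed, got {key!r}")

    counts = data.counts_matrix()
    counts_rows = [tuple(int(v) for v in row) for row in counts]
    n_k = counts.sum(axis=1)
    if np.any(n_k < 1):
        raise ValueError("every population must contain at least one individual")
    K = data.n_populations

    prior_by_name = {
        "se1": priors.se1,
        "sp1": priors.sp1,
        "se2": priors.se2,
        "sp2": priors.sp2,
    }
    prev_alpha = np.array([p.alpha for p in priors.prevalence])
    prev_beta = np.array([p.beta for p in priors.prevalence])

    param_names = list(_RATE_PARAMS) + [f"prev[{pid}]" for pid in data.population_ids]
    if dependence:
        param_names += ["cov_dpos", "cov_dneg"]
    n_kept = config.n_kept
    out = {name: np.empty((config.n_chains, n_kept)) for name in param_names}

    accept = {name: 0 for name in ("se1", "sp1", "se2", "sp2", "cov_dpos", "cov_dneg")}
    attempts = {name: 0 for name in accept}
    relabel_count = 0
    total_iters = config.n_chains * (config.burn_in + config.n_iterations)

    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed + c)
        # overdispersed initial values drawn from the priors
        state = {
            name: fixed.get(name, prior_by_name[name].sample(rng))
            for name in _RATE_PARAMS
        }
        prev = np.array([p.sample(rng) for p in priors.prevalence])
        cov_p = 0.0
        cov_n = 0.0

        for it in range(config.burn_in + config.n_iterations):
            se1, sp1, se2, sp2 = (
                state["se1"],
                state["sp1"],
                state["se2"],
                state["sp2"],
            )
            # --- data augmentation: latent true-positive counts per cell
            a = np.clip(within_class_probs(se1, se2, cov_p), 0.0, None)
            b = np.clip(within_class_probs(1.0 - sp1, 1.0 - sp2, cov_n), 0.0, None)
            num = prev[:, None] * a[None, :]
            den = num + (1.0 - prev)[:, None] * b[None, :]
            w = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
            y = rng.binomial(counts, w)
            z = counts - y

            # --- prevalence: conjugate beta conditional
            y_k = y.sum(axis=1)
            prev = rng.beta(prev_alpha + y_k, prev_beta + n_k - y_k)

            # --- sensitivities and specificities
            rate_counts = _augmented_rate_counts(y, z)
            if not dependence:
                for name in _RATE_PARAMS:
                    if name in fixed:
                        continue
                    s, f = rate_counts[name]
                    prior = prior_by_name[name]
                    state[name] = float(rng.beta(prior.alpha + s, prior.beta + f))
            else:
                ypos = y.sum(axis=0).astype(float)
                zneg = z.sum(axis=0).astype(float)
                for name in _RATE_PARAMS:
                    if name in fixed:
                        continue
                    s, f = rate_counts[name]
                    prior = prior_by_name[name]
                    cur = state[name]
                    prop = float(rng.beta(prior.alpha + s, prior.beta + f))
                    log_r = _rate_log_ratio(
                        name, cur, prop, state, cov_p, cov_n, ypos, zneg,
                        prior.alpha, prior.beta, s, f,
                    )
                    attempts[name] += 1
                    if math.log(rng.random()) < log_r:
                        state[name] = prop
                        accept[name] += 1

                se1, sp1, se2, sp2 = (
                    state["se1"],
                    state["sp1"],
                    state["se2"],
                    state["sp2"],
                )
                # --- covariance terms: reflected random-walk Metropolis
                if proposal_sd > 0.0:
                    lo, hi = covariance_bounds(se1, se2)
                    cov_p, acc = _cov_update(
                        cov_p, lo, hi, se1, se2, ypos, proposal_sd, rng
                    )
                    attempts["cov_dpos"] += 1
                    accept["cov_dpos"] += acc
                    lo, hi = covariance_bounds(sp1, sp2)
                    cov_n, acc = _cov_update(
                        cov_n, lo, hi, 1.0 - sp1, 1.0 - sp2, zneg, proposal_sd, rng
                    )
                    attempts["cov_dneg"] += 1
                    accept["cov_dneg"] += acc

            # --- collapsed slice sweeps to reduce autocorrelation
            for _ in range(config.n_collapsed_sweeps):
                prev, cov_p, cov_n = _collapsed_sweep(
                    state, prev, cov_p, cov_n, counts_rows, prior_by_name,
                    prev_alpha, prev_beta, fixed, rng,
                    update_covs=dependence and proposal_sd > 0.0,
                )

            # --- identifiability: relabel the mirror-image state
            if config.enforce_identifiability and not fixed:
                se1, sp1 = state["se1"], state["sp1"]
                se2, sp2 = state["se2"], state["sp2"]
                if se1 + sp1 < 1.0 and se2 + sp2 < 1.0:
                    state["se1"], state["sp1"] = 1.0 - sp1, 1.0 - se1
                    state["se2"], state["sp2"] = 1.0 - sp2, 1.0 - se2
                    prev = 1.0 - prev
                    cov_p, cov_n = cov_n, cov_p
                    relabel_count += 1

            kept = it - config.burn_in
            if kept >= 0 and kept % config.thin == 0:
                j = kept // config.thin
                if j < n_kept:
                    for name in _RATE_PARAMS:
                        out[name][c, j] = state[name]
                    for k, pid in enumerate(data.population_ids):
                        out[f"prev[{pid}]"][c, j] = prev[k]
                    if dependence:
                        out["cov_dpos"][c, j] = cov_p
                        out["cov_dneg"][c, j] = cov_n

    acceptance_rates = {
        name: accept[name] / attempts[name]
        for name in accept
        if attempts[name] > 0
    }
    for name in ("cov_dpos", "cov_dneg"):
        rate = acceptance_rates.get(name)
        if rate is not None and not 0.1 <= rate <= 0.6:
            warnings.warn(
                f"Metropolis acceptance rate for {name} is {rate:.2f}, outside "
                "[0.1, 0.6]; consider adjusting proposal_sd",
                RuntimeWarning,
                stacklevel=3,
            )
    return ChainDraws(
        draws=out,
        config=config,
        model="dependence" if dependence else "independence",
        population_ids=data.population_ids,
        acceptance_rates=acceptance_rates,
        relabel_fraction=relabel_count / total_iters,
    )


def _rate_log_ratio(
    name: str,
    cur: float,
    prop: float,
    state: dict[str, float],
    cov_p: float,
    cov_n: float,
    ypos: np.ndarray,
    zneg: np.ndarray,
    prior_alpha: float,
    prior_beta: float,
    s: float,
    f: float,
) -> float:
    """Log MH ratio for a sensitivity/specificity update in the dependence
    model, with the independence beta conditional as proposal.

    The target is prior(x) * augmented within-class likelihood; the
    proposal is Beta(alpha + s, beta + f).  When the relevant covariance is
    zero the ratio is exactly zero (always accept).
    """

    def log_target(x: float) -> float:
        if not 0.0 < x < 1.0:
            return -math.inf
        if name == "se1":
            lo, hi = covariance_bounds(x, state["se2"])
            if not lo <= cov_p <= hi:
                return -math.inf
            ll = _class_cell_loglik(within_class_probs(x, state["se2"], cov_p), ypos)
        elif name == "se2":
            lo, hi = covariance_bounds(state["se1"], x)
            if not lo <= cov_p <= hi:
                return -math.inf
            ll = _class_cell_loglik(within_class_probs(state["se1"], x, cov_p), ypos)
        elif name == "sp1":
            lo, hi = covariance_bounds(x, state["sp2"])
            if not lo <= cov_n <= hi:
                return -math.inf
            ll = _class_cell_loglik(
                within_class_probs(1.0 - x, 1.0 - state["sp2"], cov_n), zneg
            )
        else:  # sp2
            lo, hi = covariance_bounds(state["sp1"], x)
            if not lo <= cov_n <= hi:
                return -math.inf
            ll = _class_cell_loglik(
                within_class_probs(1.0 - state["sp1"], 1.0 - x, cov_n), zneg
            )
        return ll + (prior_alpha - 1.0) * math.log(x) + (prior_beta - 1.0) * math.log1p(-x)

    def log_q(x: float) -> float:
        # unnormalized proposal density; the normalizer cancels in the ratio
        return (prior_alpha + s - 1.0) * math.log(x) + (
            prior_beta + f - 1.0
        ) * math.log1p(-x)

    log_r = log_target(prop) - log_target(cur) - log_q(prop) + log_q(cur)
    if math.isnan(log_r):
        return -math.inf
    return log_r


def _cov_update(
    cov: float,
    lo: float,
    hi: float,
    p1: float,
    p2: float,
    class_counts: np.ndarray,
    proposal_sd: float,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """One reflected random-walk Metropolis step for a covariance term.

    The prior is flat over the feasible interval, so only the augmented
    within-class likelihood enters the acceptance ratio.
    """
    prop = _reflect(cov + rng.normal(0.0, proposal_sd), lo, hi)
    ll_cur = _class_cell_loglik(within_class_probs(p1, p2, cov), class_counts)
    ll_prop = _class_cell_loglik(within_class_probs(p1, p2, prop), class_counts)
    log_r = ll_prop - ll_cur
    if math.isnan(log_r):
        log_r = -math.inf
    if math.log(rng.random()) < log_r:
        return prop, 1
    return cov, 0


def gibbs_independence(
    data: StudyData,
    priors: PriorSet,
    config: McmcConfig | None = None,
    fixed: dict[str, float] | None = None,
) -> ChainDraws:
    """Data-augmentation Gibbs sampler for the conditional-independence model.

    For each population and observed cell the latent true-positive count is
    drawn from Binomial(n_cell, w) with
    ``w = P_k a_c / (P_k a_c + (1-P_k) b_c)``, where ``a_c`` and ``b_c``
    are the within-class cell probabilities among positives and negatives;
    prevalence, sensitivities and specificities are then drawn from their
    conjugate beta full conditionals.  Identical inputs (including the
    seed) produce bit-identical draws.

    ``fixed`` pins any of ``se1, sp1, se2, sp2`` at a known value, e.g. for
    validating the prevalence posterior against its closed form with
    perfect tests.
    """
    return _sample(data, priors, config or McmcConfig(), dependence=False, fixed=fixed)


def mwg_dependence(
    data: StudyData,
    priors: PriorSet,
    config: McmcConfig | None = None,
    proposal_sd: float = 0.05,
    fixed: dict[str, float] | None = None,
) -> ChainDraws:
    """Metropolis-within-Gibbs sampler for the conditional-dependence model.

    Adds within-class covariance terms between the two tests, updated by a
    reflected Gaussian random walk (standard deviation ``proposal_sd``)
    restricted to the feasible interval implied by the current
    sensitivities/specificities.  With ``proposal_sd=0`` the covariances
    stay at zero and the sampler reduces to the independence model.
    Acceptance rates are recorded on the result and a warning is emitted if
    a covariance acceptance rate falls outside [0.1, 0.6].
    """
    return _sample(
        data,
        priors,
        config or McmcConfig(),
        dependence=True,
        proposal_sd=proposal_sd,
        fixed=fixed,
    )
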