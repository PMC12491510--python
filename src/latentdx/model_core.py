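"""The Hui-Walter probability model for two tests and K populations.

Each population k has latent prevalence P_k.  Test i has sensitivity Se_i
and specificity Sp_i, shared across populations.  For the joint outcome
(t1, t2) of the two tests, with sign gamma = +1 when the results agree and
-1 otherwise, the cell probability is

    P(t1, t2 | k) = P_k * [prod_i Se_i^{t_i} (1-Se_i)^{1-t_i} + gamma * cov_d+]
                  + (1-P_k) * [prod_i (1-Sp_i)^{t_i} Sp_i^{1-t_i} + gamma * cov_d-]

where cov_d+ (cov_d-) is the within-class covariance of the two test
results among latent positives (negatives).  Setting both covariances to
zero recovers the conditional-independence model.  The covariances live in
a bounded interval determined by the marginal success probabilities so that
all four within-class cell probabilities stay non-negative.

Predictive values follow the classical identities

    PPV = P*Se / (P*Se + (1-P)(1-Sp))
    NPV = (1-P)*Sp / (P*(1-Se) + (1-P)*Sp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data_model import StudyData

__all__ = [
    "CELLS",
    "TestAccuracy",
    "DependenceTerms",
    "ModelParameters",
    "PredictiveValues",
    "covariance_bounds",
    "within_class_probs",
    "cell_probabilities",
    "log_likelihood",
    "ppv",
    "npv",
]

#: Joint outcome order used everywhere: (test1, test2).
CELLS = ((1, 1), (1, 0), (0, 1), (0, 0))

#: Sign of the covariance contribution per cell: + for concordant cells.
_GAMMA = np.array([1.0, -1.0, -1.0, 1.0])


def covariance_bounds(a: float, b: float) -> tuple[float, float]:
    """Feasible interval for the covariance of two Bernoulli variables.

    ``a`` and ``b`` are the marginal success probabilities (e.g. the two
    sensitivities for the positive class).  The bounds keep all four joint
    cell probabilities non-negative:

        lower = max(-(1-a)(1-b), -a*b),  upper = min(a, b) - a*b.

    The interval always contains 0 and degenerates to {0} for perfect
    tests.  The same interval results from complementing both margins, so
    the bounds for the negative class may be stated either on the
    specificities or on their complements.
    """
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError(f"marginal probabilities must be in [0, 1], got {a}, {b}")
    lower = max(-(1.0 - a) * (1.0 - b), -a * b)
    upper = min(a, b) - a * b
    return lower, upper


def within_class_probs(p1: float, p2: float, cov: float = 0.0) -> np.ndarray:
    """Joint cell probabilities of two Bernoulli margins with covariance.

    Returns the four probabilities in cell order (1,1), (1,0), (0,1),
    (0,0).  ``p1`` and ``p2`` are the success probabilities of the two
    tests within one latent class (Se_i for positives, 1-Sp_i for
    negatives).
    """
    base = np.array(
        [
            p1 * p2,
            p1 * (1.0 - p2),
            (1.0 - p1) * p2,
            (1.0 - p1) * (1.0 - p2),
        ]
    )
    return base + _GAMMA * cov


def _check_probability(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} is not a probability in [0, 1]")
    return value


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity and specificity of one diagnostic test."""

    __test__ = False  # domain class, not a pytest case

    se: float
    sp: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "se", _check_probability(self.se, "se"))
        object.__setattr__(self, "sp", _check_probability(self.sp, "sp"))

    @property
    def youden(self) -> float:
        return self.se + self.sp - 1.0


@dataclass(frozen=True)
class DependenceTerms:
    """Within-class covariances between the two tests.

    ``cov_dpos`` applies among latent positives (bounded by the
    sensitivities), ``cov_dneg`` among latent negatives (bounded by the
    specificities).
    """

    cov_dpos: float = 0.0
    cov_dneg: float = 0.0


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector of the two-test latent class model."""

    test1: TestAccuracy
    test2: TestAccuracy
    prevalence: tuple[float, ...]
    dependence: DependenceTerms | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "prevalence",
            tuple(
                _check_probability(p, f"prevalence[{k}]")
                for k, p in enumerate(self.prevalence)
            ),
        )
        if self.dependence is not None:
            lo, hi = covariance_bounds(self.test1.se, self.test2.se)
            if not lo <= self.dependence.cov_dpos <= hi:
                raise ValueError(
                    f"cov_dpos={self.dependence.cov_dpos:.6g} violates its "
                    f"bound [{lo:.6g}, {hi:.6g}] given se1={self.test1.se}, "
                    f"se2={self.test2.se}"
                )
            lo, hi = covariance_bounds(self.test1.sp, self.test2.sp)
            if not lo <= self.dependence.cov_dneg <= hi:
                raise ValueError(
                    f"cov_dneg={self.dependence.cov_dneg:.6g} violates its "
                    f"bound [{lo:.6g}, {hi:.6g}] given sp1={self.test1.sp}, "
                    f"sp2={self.test2.sp}"
                )

    @property
    def n_populations(self) -> int:
        return len(self.prevalence)

    @property
    def cov_dpos(self) -> float:
        return 0.0 if self.dependence is None else self.dependence.cov_dpos

    @property
    def cov_dneg(self) -> float:
        return 0.0 if self.dependence is None else self.dependence.cov_dneg


def cell_probabilities(params: ModelParameters, population: int = 0) -> np.ndarray:
    """The four joint outcome probabilities for one population.

    Cell order (1,1), (1,0), (0,1), (0,0).  Probabilities are non-negative
    and sum to one for any parameters respecting the covariance bounds.
    """
    if not 0 <= population < params.n_populations:
        raise ValueError(
            f"population index {population} out of range "
            f"(model has {params.n_populations})"
        )
    p = params.prevalence[population]
    pos = within_class_probs(params.test1.se, params.test2.se, params.cov_dpos)
    neg = within_class_probs(
        1.0 - params.test1.sp, 1.0 - params.test2.sp, params.cov_dneg
    )
    return p * pos + (1.0 - p) * neg


def log_likelihood(
    params: ModelParameters, data: StudyData, include_constant: bool = False
) -> float:
    """Multinomial log-likelihood of the observed cross-tabulations.

    By default only the kernel sum(n_c * log p_c) over populations is
    returned; ``include_constant`` adds the multinomial coefficients.  A
    zero cell probability paired with a positive count yields ``-inf``.
    """
    if params.n_populations != data.n_populations:
        raise ValueError(
            f"model has {params.n_populations} prevalences but data has "
            f"{data.n_populations} populations"
        )
    total = 0.0
    for k, pop in enumerate(data.populations):
        counts = pop.as_array()
        probs = cell_probabilities(params, k)
        observed = counts > 0
        if np.any(probs[observed] <= 0.0):
            return float("-inf")
        total += float(np.sum(counts[observed] * np.log(probs[observed])))
        if include_constant:
            total += float(gammaln(pop.total + 1) - np.sum(gammaln(counts + 1)))
    return total


def ppv(se: float, sp: float, prev: float) -> float:
    """Positive predictive value P*Se / (P*Se + (1-P)(1-Sp))."""
    se = _check_probability(se, "se")
    sp = _check_probability(sp, "sp")
    prev = _check_probability(prev, "prev")
    denom = prev * se + (1.0 - prev) * (1.0 - sp)
    if denom <= 0.0:
        raise ValueError(
            f"PPV undefined: no positive results occur for se={se}, sp={sp}, "
            f"prev={prev}"
        )
    return prev * se / denom


def npv(se: float, sp: float, prev: float) -> float:
    """Negative predictive value (1-P)*Sp / (P*(1-Se) + (1-P)*Sp)."""
    se = _check_probability(se, "se")
    sp = _check_probability(sp, "sp")
    prev = _check_probability(prev, "prev")
    denom = prev * (1.0 - se) + (1.0 - prev) * sp
    if denom <= 0.0:
        raise ValueError(
            f"NPV undefined: no negative results occur for se={se}, sp={sp}, "
            f"prev={prev}"
        )
    return (1.0 - prev) * sp / denom


@dataclass(frozen=True)
class PredictiveValues:
    """PPV and NPV of one test in one population."""

    ppv: float
    npv: float
    population_id: str
    test_id: str

    def __post_init__(self) -> None:
        _check_probability(self.ppv, "ppv")
        _check_probability(self.npv, "npv")
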