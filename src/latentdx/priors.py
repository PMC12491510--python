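"""Beta priors for the probability parameters of the latent class model.

Six probability parameters carry priors in the two-population study design:
sensitivity and specificity of each test, and burnout prevalence in each
population.  "Minimally informative" means Beta(1, 1), uniform on (0, 1).
The sensitivity-analysis driver replaces one prior at a time with an
alternative distribution and refits, yielding one model configuration per
prior slot.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BetaPrior",
    "PriorSet",
    "minimally_informative_set",
    "elicit_beta",
    "sensitivity_grid",
    "priors_from_spec",
]


@dataclass(frozen=True)
class BetaPrior:
    """A Beta(alpha, beta) prior for a probability parameter."""

    alpha: float
    beta: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"beta prior shapes must be positive, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def mode(self) -> float:
        """Interior mode (alpha-1)/(alpha+beta-2); requires alpha, beta > 1."""
        if self.alpha <= 1 or self.beta <= 1:
            raise ValueError("mode is interior only for alpha > 1 and beta > 1")
        return (self.alpha - 1) / (self.alpha + self.beta - 2)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))

    def same_shape(self, other: "BetaPrior") -> bool:
        return self.alpha == other.alpha and self.beta == other.beta


#: Order of the six prior slots for a two-population study.
SLOT_LABELS = ("se1", "sp1", "se2", "sp2", "prev1", "prev2")


@dataclass(frozen=True)
class PriorSet:
    """Priors for every probability parameter of the model.

    Covariance terms, when active, carry uniform priors over their feasible
    interval (handled inside the sampler); ``cov_active`` only records
    whether the dependence terms are part of the model.
    """

    se1: BetaPrior
    sp1: BetaPrior
    se2: BetaPrior
    sp2: BetaPrior
    prevalence: tuple[BetaPrior, ...]
    cov_active: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "prevalence", tuple(self.prevalence))
        if len(self.prevalence) < 1:
            raise ValueError("at least one prevalence prior is required")

    @property
    def n_populations(self) -> int:
        return len(self.prevalence)

    def as_tuple(self) -> tuple[BetaPrior, ...]:
        """All priors in slot order: se1, sp1, se2, sp2, then prevalences."""
        return (self.se1, self.sp1, self.se2, self.sp2, *self.prevalence)

    def slot_labels(self) -> tuple[str, ...]:
        return (
            "se1",
            "sp1",
            "se2",
            "sp2",
            *[f"prev{k + 1}" for k in range(self.n_populations)],
        )

    def replace_slot(self, index: int, prior: BetaPrior) -> "PriorSet":
        """Return a copy with the ``index``-th slot replaced."""
        slots = list(self.as_tuple())
        if not 0 <= index < len(slots):
            raise IndexError(f"prior slot {index} out of range")
        slots[index] = prior
        return PriorSet(
            se1=slots[0],
            sp1=slots[1],
            se2=slots[2],
            sp2=slots[3],
            prevalence=tuple(slots[4:]),
            cov_active=self.cov_active,
        )


def minimally_informative_set(
    n_populations: int = 2, allow_single_population: bool = False
) -> PriorSet:
    """Beta(1, 1) priors for every probability parameter.

    With fewer than two populations the base Hui-Walter model is not
    identifiable from the data alone; requesting a single population raises
    unless ``allow_single_population`` is set (for use with informative
    priors or fixed test accuracies).
    """
    if n_populations < 2 and not allow_single_population:
        raise ValueError(
            "the two-test latent class model is not identifiable with fewer "
            "than two populations; pass allow_single_population=True to "
            "override when informative priors or fixed accuracies are used"
        )
    flat = lambda label: BetaPrior(1.0, 1.0, label)  # noqa: E731
    return PriorSet(
        se1=flat("se1"),
        sp1=flat("sp1"),
        se2=flat("se2"),
        sp2=flat("sp2"),
        prevalence=tuple(
            flat(f"prev{k + 1}") for k in range(max(n_populations, 1))
        ),
    )


def elicit_beta(
    mode: float, percentile_value: float, percentile: float = 0.95, label: str = ""
) -> BetaPrior:
    """Find the Beta(alpha, beta) with a given mode and a given percentile.

    Solves for shapes with alpha, beta >= 1 (interior, unique mode) such
    that the density's mode equals ``mode`` and the CDF at
    ``percentile_value`` equals ``percentile``.  For an upper-tail
    constraint supply ``percentile_value > mode`` (e.g. mode 0.9 and 95th
    percentile 0.99); for a lower tail supply ``percentile_value < mode``
    with a small ``percentile``.

    Raises
    ------
    ValueError
        If no beta distribution with alpha, beta >= 1 satisfies the pair of
        constraints.
    """
    for name, value in (
        ("mode", mode),
        ("percentile_value", percentile_value),
        ("percentile", percentile),
    ):
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")
    if percentile_value == mode:
        raise ValueError("percentile_value must differ from the mode")

    def beta_of_alpha(alpha: float) -> float:
        # mode relation: mode = (alpha-1)/(alpha+beta-2)
        return 1.0 + (alpha - 1.0) * (1.0 - mode) / mode

    def residual(alpha: float) -> float:
        return stats.beta.cdf(percentile_value, alpha, beta_of_alpha(alpha)) - percentile

    # The CDF at a fixed point is not monotone in alpha along the
    # constant-mode family (it can dip before concentrating), so bracket a
    # sign change on a geometric grid before root-finding.  When two roots
    # exist the smaller alpha (the less informative prior) is returned.
    grid = np.concatenate(([1.0 + 1e-9], np.geomspace(1.0 + 1e-6, 1e9, 120)))
    values = np.array([residual(a) for a in grid])
    sign_change = np.nonzero(np.diff(np.sign(values)) != 0)[0]
    if values[0] == 0.0:
        alpha = grid[0]
    elif sign_change.size == 0:
        raise ValueError(
            f"no beta distribution with an interior mode at {mode} has its "
            f"{percentile:.4g} quantile at {percentile_value}"
        )
    else:
        i = sign_change[0]
        alpha = optimize.brentq(
            residual, grid[i], grid[i + 1], xtol=1e-13, rtol=8.9e-16
        )
    return BetaPrior(alpha, beta_of_alpha(alpha), label=label)


def sensitivity_grid(base: PriorSet, replacement: BetaPrior) -> list[PriorSet]:
    """One prior configuration per slot, replacing that slot only.

    The study's sensitivity analysis swaps each of the six priors (two
    populations) in turn for the replacement distribution and refits.
    """
    if base.n_populations != 2:
        raise ValueError(
            "the sensitivity grid is defined for the six-prior, "
            f"two-population design; got {base.n_populations} populations"
        )
    return [
        base.replace_slot(
            i, dataclasses.replace(replacement, label=slot.label or label)
        )
        for i, (slot, label) in enumerate(
            zip(base.as_tuple(), base.slot_labels())
        )
    ]


def priors_from_spec(spec: dict, n_populations: int = 2) -> PriorSet:
    """Build a :class:`PriorSet` from a configuration mapping.

    Each entry is either ``{"alpha": a, "beta": b}`` or an elicitation
    ``{"mode": m, "percentile_value": x, "percentile": p}``.  Keys are
    ``se1, sp1, se2, sp2`` and ``prevalence`` (a list, one per population).
    Missing entries default to Beta(1, 1).
    """

    def build(entry, label: str) -> BetaPrior:
        if entry is None:
            return BetaPrior(1.0, 1.0, label)
        if "alpha" in entry:
            return BetaPrior(float(entry["alpha"]), float(entry["beta"]), label)
        if "mode" in entry:
            return elicit_beta(
                float(entry["mode"]),
                float(entry["percentile_value"]),
                float(entry.get("percentile", 0.95)),
                label=label,
            )
        raise ValueError(
            f"prior entry for {label!r} needs either alpha/beta or "
            "mode/percentile_value"
        )

    prevalence_spec = spec.get("prevalence") or [None] * n_populations
    if len(prevalence_spec) != n_populations:
        raise ValueError(
            f"expected {n_populations} prevalence priors, got {len(prevalence_spec)}"
        )
    return PriorSet(
        se1=build(spec.get("se1"), "se1"),
        sp1=build(spec.get("sp1"), "sp1"),
        se2=build(spec.get("se2"), "se2"),
        sp2=build(spec.get("sp2"), "sp2"),
        prevalence=tuple(
            build(e, f"prev{k + 1}") for k, e in enumerate(prevalence_spec)
        ),
        cov_active=bool(spec.get("cov_active", False)),
    )
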