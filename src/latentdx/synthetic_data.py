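"""Synthetic two-test, K-population datasets with known truth.

The generator emulates the burnout study design: two populations (100
Belgian and 42 Swiss patients), two binary tests (EDTB, OLBI), latent
burnout prevalences near 0.52 and 0.82, and test accuracies at the
published posterior point estimates.  Each simulated individual receives a
latent burnout status from Bernoulli(P_k), then a joint test-result
pattern from the within-class bivariate Bernoulli distribution implied by
the sensitivities/specificities and (optionally) the within-class
covariance terms.  OLBI total scores consistent with the dichotomized
result can be attached so the full tabulation pipeline is exercised.

Every dataset is accompanied by a truth manifest recording the generating
parameters and seed, so recovery tests are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    OLBI_CUTOFF,
    OLBI_MAX_SCORE,
    OLBI_MIN_SCORE,
    IndividualRecord,
    PopulationCounts,
    StudyData,
)
from .model_core import (
    CELLS,
    DependenceTerms,
    ModelParameters,
    TestAccuracy,
    within_class_probs,
)

__all__ = [
    "STUDY_POPULATION_SIZES",
    "STUDY_POPULATION_IDS",
    "study_parameters",
    "ScenarioSpec",
    "SimulationResult",
    "simulate",
    "simulate_olbi_scores",
]

STUDY_POPULATION_SIZES = (100, 42)
STUDY_POPULATION_IDS = ("Belgian", "Swiss")


def study_parameters(
    cov_dpos: float = 0.0, cov_dneg: float = 0.0
) -> ModelParameters:
    """Generating parameters matching the published posterior estimates:
    EDTB Se 0.905 / Sp 0.822, OLBI Se 0.730 / Sp 0.726, prevalences 0.518
    (Belgian) and 0.817 (Swiss)."""
    dependence = (
        DependenceTerms(cov_dpos=cov_dpos, cov_dneg=cov_dneg)
        if (cov_dpos != 0.0 or cov_dneg != 0.0)
        else None
    )
    return ModelParameters(
        test1=TestAccuracy(se=0.905, sp=0.822),
        test2=TestAccuracy(se=0.730, sp=0.726),
        prevalence=(0.518, 0.817),
        dependence=dependence,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation scenario: sizes, generating parameters and seed."""

    population_sizes: tuple[int, ...] = STUDY_POPULATION_SIZES
    population_ids: tuple[str, ...] = STUDY_POPULATION_IDS
    params: ModelParameters = field(default_factory=study_parameters)
    seed: int = 0
    emit_olbi_scores: bool = False
    test_names: tuple[str, str] = ("EDTB", "OLBI")

    def __post_init__(self) -> None:
        object.__setattr__(self, "population_sizes", tuple(self.population_sizes))
        object.__setattr__(self, "population_ids", tuple(self.population_ids))
        if any(int(n) != n or n < 1 for n in self.population_sizes):
            raise ValueError(
                f"population sizes must be positive integers, got "
                f"{self.population_sizes}"
            )
        if len(self.population_ids) != len(self.population_sizes):
            raise ValueError("one population id is required per size")
        if len(set(self.population_ids)) != len(self.population_ids):
            raise ValueError("population ids must be unique")
        if self.params.n_populations != len(self.population_sizes):
            raise ValueError(
                f"parameters define {self.params.n_populations} prevalences "
                f"but {len(self.population_sizes)} populations were requested"
            )

    def manifest(self) -> dict:
        """JSON-serializable record of the generating truth."""
        return {
            "population_sizes": list(self.population_sizes),
            "population_ids": list(self.population_ids),
            "seed": self.seed,
            "emit_olbi_scores": self.emit_olbi_scores,
            "test_names": list(self.test_names),
            "parameters": {
                "se1": self.params.test1.se,
                "sp1": self.params.test1.sp,
                "se2": self.params.test2.se,
                "sp2": self.params.test2.sp,
                "prevalence": list(self.params.prevalence),
                "cov_dpos": self.params.cov_dpos,
                "cov_dneg": self.params.cov_dneg,
            },
        }


@dataclass(frozen=True)
class SimulationResult:
    """Simulated dataset plus individual records and the truth manifest."""

    data: StudyData
    records: tuple[IndividualRecord, ...]
    manifest: dict


def simulate(spec: ScenarioSpec) -> SimulationResult:
    """Draw a dataset from the scenario's generating model.

    Within each population the number of latent positives is binomial in
    the prevalence; positives and negatives are then distributed over the
    four joint test-outcome cells by the within-class multinomials.  The
    same seed always reproduces the same dataset.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.params
    pos_probs = within_class_probs(params.test1.se, params.test2.se, params.cov_dpos)
    neg_probs = within_class_probs(
        1.0 - params.test1.sp, 1.0 - params.test2.sp, params.cov_dneg
    )
    pos_probs = np.clip(pos_probs, 0.0, None)
    pos_probs = pos_probs / pos_probs.sum()
    neg_probs = np.clip(neg_probs, 0.0, None)
    neg_probs = neg_probs / neg_probs.sum()

    populations = []
    records: list[IndividualRecord] = []
    for k, (pid, size) in enumerate(zip(spec.population_ids, spec.population_sizes)):
        n_pos = int(rng.binomial(size, params.prevalence[k]))
        pos_cells = rng.multinomial(n_pos, pos_probs)
        neg_cells = rng.multinomial(size - n_pos, neg_probs)
        cells = pos_cells + neg_cells
        populations.append(PopulationCounts(pid, *[int(c) for c in cells]))
        for cell_idx, (t1, t2) in enumerate(CELLS):
            for _ in range(int(cells[cell_idx])):
                records.append(
                    IndividualRecord(
                        population_id=pid, test1_result=t1, test2_result=t2
                    )
                )
    data = StudyData(populations=tuple(populations), test_names=spec.test_names)
    out_records = tuple(records)
    if spec.emit_olbi_scores:
        out_records = simulate_olbi_scores(out_records, rng)
    return SimulationResult(data=data, records=out_records, manifest=spec.manifest())


def simulate_olbi_scores(
    records: tuple[IndividualRecord, ...] | list[IndividualRecord],
    rng: np.random.Generator | int | None = None,
) -> tuple[IndividualRecord, ...]:
    """Attach OLBI total scores consistent with each record's binary result.

    Positive records receive an integer score uniform on [45, 64], negative
    records uniform on [16, 44], so dichotomizing at the strict >44 rule
    reproduces the binary result exactly.  Only the dichotomy enters the
    model, so the uniform stratum distribution is a neutral choice.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for rec in records:
        result = rec.resolved_test2()
        if result == 1:
            score = int(rng.integers(OLBI_CUTOFF + 1, OLBI_MAX_SCORE + 1))
        else:
            score = int(rng.integers(OLBI_MIN_SCORE, OLBI_CUTOFF + 1))
        out.append(
            IndividualRecord(
                population_id=rec.population_id,
                test1_result=rec.test1_result,
                olbi_score=score,
            )
        )
    return tuple(out)
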