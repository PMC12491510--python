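"""End-to-end study pipeline: fit, select, summarize, predict, refit.

``run_study`` reproduces the analysis protocol: fit the latent class model
with and without conditional-dependence terms under the configured priors,
keep the dependence terms only if a covariance 95% interval excludes zero,
summarize the selected fit in the results-table layout, compute PPV/NPV
for the designated test in every population from the posterior point
estimates, and assess convergence against the psrf < 1.05 and ESS > 1000
thresholds.  ``run_sensitivity`` refits once per prior slot with a
replacement distribution and tabulates the deviations from the base fit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import StudyData, read_counts, write_counts
from .diagnostics import (
    ConvergenceReport,
    PosteriorSummary,
    convergence_report,
    select_model,
    summarize,
)
from .mcmc import ChainDraws, McmcConfig, gibbs_independence, mwg_dependence
from .model_core import npv, ppv
from .priors import BetaPrior, PriorSet, minimally_informative_set, priors_from_spec, sensitivity_grid
from .synthetic_data import ScenarioSpec, simulate

__all__ = [
    "RunConfig",
    "StudyReport",
    "SensitivityResult",
    "run_study",
    "run_sensitivity",
    "predictive_value_table",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full study run.

    Exactly one of ``data_path`` (a counts CSV/JSON) or ``scenario`` (a
    synthetic :class:`~latentdx.synthetic_data.ScenarioSpec`) supplies the
    data.  ``pv_test`` selects the test for the predictive-value report
    ("test1" by default, i.e. the clinician-completed instrument).
    """

    data_path: str | Path | None = None
    scenario: ScenarioSpec | None = None
    priors: PriorSet | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    out_dir: str | Path | None = None
    pv_test: str = "test1"
    psrf_max: float = 1.05
    ess_min: float = 1000.0
    proposal_sd: float = 0.05
    fit_dependence: bool = True
    point_estimate: str = "median"

    def __post_init__(self) -> None:
        if (self.data_path is None) == (self.scenario is None):
            raise ValueError(
                "exactly one of data_path and scenario must be provided"
            )
        if self.pv_test not in ("test1", "test2"):
            raise ValueError("pv_test must be 'test1' or 'test2'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML or JSON run configuration."""
        path = Path(path)
        text = path.read_text()
        payload = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        mcmc_kwargs = payload.get("mcmc", {})
        scenario = payload.get("scenario")
        spec = None
        if scenario is not None:
            from .model_core import DependenceTerms, ModelParameters, TestAccuracy

            par = scenario.get("parameters", {})
            params = ModelParameters(
                test1=TestAccuracy(par.get("se1", 0.905), par.get("sp1", 0.822)),
                test2=TestAccuracy(par.get("se2", 0.730), par.get("sp2", 0.726)),
                prevalence=tuple(par.get("prevalence", (0.518, 0.817))),
                dependence=(
                    DependenceTerms(par.get("cov_dpos", 0.0), par.get("cov_dneg", 0.0))
                    if par.get("cov_dpos") or par.get("cov_dneg")
                    else None
                ),
            )
            spec = ScenarioSpec(
                population_sizes=tuple(scenario.get("population_sizes", (100, 42))),
                population_ids=tuple(scenario.get("population_ids", ("Belgian", "Swiss"))),
                params=params,
                seed=scenario.get("seed", 0),
                emit_olbi_scores=scenario.get("emit_olbi_scores", False),
            )
        priors = None
        if "priors" in payload:
            n_pops = len(spec.population_sizes) if spec is not None else 2
            priors = priors_from_spec(payload["priors"], n_populations=n_pops)
        return cls(
            data_path=payload.get("data_path"),
            scenario=spec,
            priors=priors,
            mcmc=McmcConfig(**mcmc_kwargs),
            out_dir=payload.get("out_dir"),
            pv_test=payload.get("pv_test", "test1"),
            psrf_max=payload.get("psrf_max", 1.05),
            ess_min=payload.get("ess_min", 1000.0),
            proposal_sd=payload.get("proposal_sd", 0.05),
            fit_dependence=payload.get("fit_dependence", True),
            point_estimate=payload.get("point_estimate", "median"),
        )


def load_study_data(config: RunConfig) -> StudyData:
    if config.data_path is not None:
        return read_counts(config.data_path)
    return simulate(config.scenario).data


def predictive_value_table(
    summary: PosteriorSummary,
    population_ids: tuple[str, ...],
    test: str = "test1",
    test_label: str | None = None,
) -> pd.DataFrame:
    """PPV and NPV per population from posterior point estimates.

    Evaluates the classical predictive-value identities at the summary's
    point estimates of the designated test's Se/Sp and each population's
    prevalence.
    """
    se_name, sp_name = ("se1", "sp1") if test == "test1" else ("se2", "sp2")
    se = summary[se_name].estimate
    sp = summary[sp_name].estimate
    rows = []
    for pid in population_ids:
        prev = summary[f"prev[{pid}]"].estimate
        rows.append(
            {
                "population": pid,
                "test": test_label or test,
                "prevalence": prev,
                "ppv": ppv(se, sp, prev),
                "npv": npv(se, sp, prev),
            }
        )
    return pd.DataFrame(rows)


def _summary_dict(summary: PosteriorSummary) -> dict:
    return {
        name: {
            "estimate": s.estimate,
            "lower95": s.lower95,
            "upper95": s.upper95,
            "psrf": s.psrf,
            "ess": s.ess,
        }
        for name, s in summary.parameters.items()
    }


@dataclass
class StudyReport:
    """Everything a study run produces, writable as a results bundle."""

    data: StudyData
    selected_model: str
    summary: PosteriorSummary
    summary_independence: PosteriorSummary
    summary_dependence: PosteriorSummary | None
    predictive_values: pd.DataFrame
    convergence: ConvergenceReport
    draws: ChainDraws
    config: RunConfig

    def to_json_dict(self) -> dict:
        return {
            "selected_model": self.selected_model,
            "test_names": list(self.data.test_names),
            "population_ids": list(self.data.population_ids),
            "summary": _summary_dict(self.summary),
            "summary_independence": _summary_dict(self.summary_independence),
            "summary_dependence": (
                None
                if self.summary_dependence is None
                else _summary_dict(self.summary_dependence)
            ),
            "predictive_values": self.predictive_values.to_dict(orient="records"),
            "convergence": {
                "all_converged": self.convergence.all_converged,
                "failing_parameters": list(self.convergence.failing_parameters),
                "psrf_max": self.convergence.psrf_max,
                "ess_min": self.convergence.ess_min,
            },
            "acceptance_rates": dict(self.draws.acceptance_rates),
            "relabel_fraction": self.draws.relabel_fraction,
            "mcmc": {
                "n_chains": self.config.mcmc.n_chains,
                "burn_in": self.config.mcmc.burn_in,
                "n_iterations": self.config.mcmc.n_iterations,
                "seed": self.config.mcmc.seed,
                "thin": self.config.mcmc.thin,
            },
        }

    def write_bundle(self, out_dir) -> Path:
        """Write summary.csv, draws.csv, convergence.csv,
        predictive_values.csv and report.json under ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.summary.to_frame().to_csv(out_dir / "summary.csv", index=False)
        self.draws.to_csv(out_dir / "draws.csv")
        self.convergence.to_frame().to_csv(out_dir / "convergence.csv", index=False)
        self.predictive_values.to_csv(out_dir / "predictive_values.csv", index=False)
        write_counts(self.data, out_dir / "counts.csv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
            fh.write("\n")
        return out_dir


def run_study(config: RunConfig) -> StudyReport:
    """Run the full analysis protocol on one dataset.

    Fits the dependence model (unless disabled), applies the
    interval-based model-selection rule, fits the independence model,
    summarizes the selected fit, computes predictive values for the
    designated test, and assesses convergence.  Writes the results bundle
    when ``config.out_dir`` is set.
    """
    data = load_study_data(config)
    priors = config.priors or minimally_informative_set(data.n_populations)
    if priors.n_populations != data.n_populations:
        raise ValueError(
            f"priors define {priors.n_populations} populations but the data "
            f"has {data.n_populations}"
        )

    summary_dep = None
    draws_dep = None
    if config.fit_dependence:
        draws_dep = mwg_dependence(
            data, replace(priors, cov_active=True), config.mcmc,
            proposal_sd=config.proposal_sd,
        )
        summary_dep = summarize(draws_dep, point=config.point_estimate)
        selected = select_model(summary_dep)
    else:
        selected = "independence"

    draws_ind = gibbs_independence(data, priors, config.mcmc)
    summary_ind = summarize(draws_ind, point=config.point_estimate)

    if selected == "dependence":
        summary, draws = summary_dep, draws_dep
    else:
        summary, draws = summary_ind, draws_ind

    pv = predictive_value_table(
        summary,
        data.population_ids,
        test=config.pv_test,
        test_label=(
            data.test_names[0] if config.pv_test == "test1" else data.test_names[1]
        ),
    )
    convergence = convergence_report(
        draws, psrf_max=config.psrf_max, ess_min=config.ess_min
    )
    report = StudyReport(
        data=data,
        selected_model=selected,
        summary=summary,
        summary_independence=summary_ind,
        summary_dependence=summary_dep,
        predictive_values=pv,
        convergence=convergence,
        draws=draws,
        config=config,
    )
    if config.out_dir is not None:
        report.write_bundle(config.out_dir)
    return report


@dataclass
class SensitivityResult:
    """Base fit plus one refit per replaced prior slot."""

    base_summary: PosteriorSummary
    table: pd.DataFrame
    replacement: BetaPrior

    @property
    def max_abs_delta(self) -> float:
        return float(self.table["max_abs_delta"].max())


def run_sensitivity(config: RunConfig, replacement: BetaPrior) -> SensitivityResult:
    """Refit once per prior slot, replacing that slot with ``replacement``.

    Uses the conditional-independence model (the study's selected model).
    The output table has one row per refit with every parameter's point
    estimate and interval plus the maximum absolute deviation of the point
    estimates from the base fit.
    """
    data = load_study_data(config)
    if data.n_populations != 2:
        raise ValueError("the six-prior sensitivity analysis needs two populations")
    base_priors = config.priors or minimally_informative_set(2)
    base_draws = gibbs_independence(data, base_priors, config.mcmc)
    base_summary = summarize(base_draws, point=config.point_estimate)
    base_estimates = {
        name: s.estimate for name, s in base_summary.parameters.items()
    }

    rows = []
    for label, prior_set in zip(
        base_priors.slot_labels(), sensitivity_grid(base_priors, replacement)
    ):
        draws = gibbs_independence(data, prior_set, config.mcmc)
        summary = summarize(draws, point=config.point_estimate)
        row: dict = {"replaced_prior": label}
        deltas = []
        for name, s in summary.parameters.items():
            row[f"{name}_estimate"] = s.estimate
            row[f"{name}_lower95"] = s.lower95
            row[f"{name}_upper95"] = s.upper95
            deltas.append(abs(s.estimate - base_estimates[name]))
        row["max_abs_delta"] = max(deltas)
        rows.append(row)
    table = pd.DataFrame(rows)
    result = SensitivityResult(
        base_summary=base_summary, table=table, replacement=replacement
    )
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "sensitivity.csv", index=False)
    return result
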