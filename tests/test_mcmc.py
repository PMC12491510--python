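import numpy as np
import pytest
from scipy import stats

from latentdx.data_model import PopulationCounts, StudyData
from latentdx.mcmc import (
    McmcConfig,
    enforce_identifiability,
    gibbs_independence,
    mwg_dependence,
)
from latentdx.diagnostics import effective_sample_size, summarize
from latentdx.priors import minimally_informative_set
from latentdx.synthetic_data import ScenarioSpec, simulate

PERFECT = {"se1": 1.0, "sp1": 1.0, "se2": 1.0, "sp2": 1.0}


class TestConfig:
    def test_study_defaults(self):
        cfg = McmcConfig()
        assert cfg.n_chains == 2
        assert cfg.burn_in == 5000
        assert cfg.n_iterations == 10000

    @pytest.mark.parametrize(
        "kwargs", [{"n_chains": 1}, {"thin": 0}, {"n_iterations": 0}]
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            McmcConfig(**kwargs)


class TestGibbsIndependence:
    def test_conjugate_limit_with_perfect_tests(self):
        """With both tests perfect and fixed, the prevalence posterior is
        Beta(alpha + x, beta + n - x) in closed form."""
        x, n = 13, 40
        data = StudyData(populations=(PopulationCounts("A", x, 0, 0, n - x),))
        cfg = McmcConfig(
            n_chains=2, burn_in=500, n_iterations=4000, seed=3,
            allow_single_population=True,
        )
        draws = gibbs_independence(
            data,
            minimally_informative_set(1, allow_single_population=True),
            cfg,
            fixed=PERFECT,
        )
        p = draws.pooled("prev[A]")
        a, b = 1 + x, 1 + n - x
        exact_mean = a / (a + b)
        exact_var = a * b / ((a + b) ** 2 * (a + b + 1))
        ess = effective_sample_size(draws.per_chain("prev[A]"))
        se_mean = np.sqrt(exact_var / ess)
        assert abs(p.mean() - exact_mean) < 3 * se_mean
        se_var = exact_var * np.sqrt(2.0 / ess)
        assert abs(p.var() - exact_var) < 3 * se_var

    def test_same_seed_reproduces_draws_exactly(self, small_data, flat_priors):
        cfg = McmcConfig(n_chains=2, burn_in=50, n_iterations=200, seed=11)
        d1 = gibbs_independence(small_data, flat_priors, cfg)
        d2 = gibbs_independence(small_data, flat_priors, cfg)
        for name in d1.parameters:
            assert np.array_equal(d1.draws[name], d2.draws[name])

    def test_single_population_needs_override(self):
        data = StudyData(populations=(PopulationCounts("A", 5, 1, 1, 5),))
        with pytest.raises(ValueError, match="two populations"):
            gibbs_independence(
                data,
                minimally_informative_set(1, allow_single_population=True),
                McmcConfig(n_chains=2, burn_in=10, n_iterations=20, seed=0),
            )

    def test_recovers_generating_parameters(self):
        """Short-run recovery on a medium simulation (loose tolerance)."""
        spec = ScenarioSpec(
            population_sizes=(2000, 2000), population_ids=("A", "B"), seed=9
        )
        sim = simulate(spec)
        cfg = McmcConfig(n_chains=2, burn_in=400, n_iterations=2000, seed=17)
        summary = summarize(
            gibbs_independence(sim.data, minimally_informative_set(2), cfg)
        )
        truth = sim.manifest["parameters"]
        assert summary["se1"].estimate == pytest.approx(truth["se1"], abs=0.1)
        assert summary["sp1"].estimate == pytest.approx(truth["sp1"], abs=0.1)
        assert summary["prev[A]"].estimate == pytest.approx(
            truth["prevalence"][0], abs=0.1
        )

    def test_posterior_near_prior_with_one_observation(self):
        """With n=1 per population and flat priors the accuracy posteriors
        stay close to uniform (KS distance below 0.1)."""
        data = StudyData(
            populations=(
                PopulationCounts("A", 1, 0, 0, 0),
                PopulationCounts("B", 0, 0, 0, 1),
            )
        )
        cfg = McmcConfig(
            n_chains=2, burn_in=500, n_iterations=5000, seed=7,
            enforce_identifiability=False,
        )
        draws = gibbs_independence(data, minimally_informative_set(2), cfg)
        for name in ("se1", "sp1", "se2", "sp2"):
            ks = stats.kstest(draws.pooled(name), "uniform").statistic
            assert ks < 0.1

    def test_probability_draws_in_unit_interval(self, small_data, flat_priors):
        cfg = McmcConfig(n_chains=2, burn_in=50, n_iterations=300, seed=2)
        draws = gibbs_independence(small_data, flat_priors, cfg)
        for name in draws.parameters:
            arr = draws.pooled(name)
            assert np.all((arr >= 0) & (arr <= 1))


class TestMwgDependence:
    def test_degenerate_proposal_reduces_to_independence(self, flat_priors):
        """With the covariances pinned at zero the dependence sampler
        targets the same posterior as the independence Gibbs sampler."""
        spec = ScenarioSpec(
            population_sizes=(500, 500), population_ids=("A", "B"), seed=4
        )
        data = simulate(spec).data
        cfg = McmcConfig(n_chains=2, burn_in=500, n_iterations=4000, seed=9)
        s_gibbs = summarize(gibbs_independence(data, flat_priors, cfg))
        s_mwg = summarize(mwg_dependence(data, flat_priors, cfg, proposal_sd=0.0))
        for name in ("se1", "sp1", "se2", "sp2"):
            assert s_mwg[name].estimate == pytest.approx(
                s_gibbs[name].estimate, abs=0.02
            )

    def test_degenerate_proposal_keeps_covariances_at_zero(
        self, small_data, flat_priors
    ):
        cfg = McmcConfig(n_chains=2, burn_in=20, n_iterations=100, seed=1)
        draws = mwg_dependence(small_data, flat_priors, cfg, proposal_sd=0.0)
        assert np.all(draws.pooled("cov_dpos") == 0.0)
        assert np.all(draws.pooled("cov_dneg") == 0.0)

    def test_covariance_draws_respect_bounds(self, simulated_medium, flat_priors):
        from latentdx.model_core import covariance_bounds

        cfg = McmcConfig(n_chains=2, burn_in=100, n_iterations=500, seed=6)
        draws = mwg_dependence(simulated_medium.data, flat_priors, cfg)
        se1 = draws.pooled("se1")
        se2 = draws.pooled("se2")
        cov_p = draws.pooled("cov_dpos")
        for i in range(0, se1.size, 37):
            lo, hi = covariance_bounds(se1[i], se2[i])
            assert lo - 1e-9 <= cov_p[i] <= hi + 1e-9

    def test_acceptance_rates_recorded(self, simulated_medium, flat_priors):
        cfg = McmcConfig(n_chains=2, burn_in=100, n_iterations=400, seed=3)
        draws = mwg_dependence(simulated_medium.data, flat_priors, cfg)
        assert {"cov_dpos", "cov_dneg"} <= set(draws.acceptance_rates)
        assert all(0 <= r <= 1 for r in draws.acceptance_rates.values())


class TestEnforceIdentifiability:
    def test_informative_state_unchanged(self):
        state = {"se1": 0.9, "sp1": 0.7, "se2": 0.8, "sp2": 0.6, "prev1": 0.4}
        out, fired = enforce_identifiability(state)
        assert not fired
        assert float(out["se1"]) == 0.9

    def test_mirror_state_relabeled(self):
        state = {
            "se1": 0.3, "sp1": 0.1, "se2": 0.2, "sp2": 0.4,
            "prev1": 0.4, "cov_dpos": 0.01, "cov_dneg": -0.02,
        }
        out, fired = enforce_identifiability(state)
        assert fired
        assert float(out["se1"]) == pytest.approx(0.9)
        assert float(out["sp1"]) == pytest.approx(0.7)
        assert float(out["prev1"]) == pytest.approx(0.6)
        assert float(out["cov_dpos"]) == pytest.approx(-0.02)
        assert float(out["cov_dneg"]) == pytest.approx(0.01)

    def test_involution(self):
        state = {"se1": 0.3, "sp1": 0.1, "se2": 0.2, "sp2": 0.4, "prev1": 0.4}
        once, fired = enforce_identifiability(state)
        assert fired
        # the relabeled state is informative: applying again changes nothing
        twice, fired2 = enforce_identifiability(once)
        assert not fired2
        for k in state:
            assert float(twice[k]) == pytest.approx(float(once[k]))

    def test_likelihood_invariant_under_relabeling(self):
        """The mirror transform leaves the observed-data likelihood unchanged."""
        from latentdx.model_core import ModelParameters, TestAccuracy, log_likelihood

        data = StudyData(
            populations=(
                PopulationCounts("A", 10, 5, 3, 12),
                PopulationCounts("B", 20, 2, 7, 4),
            )
        )
        state = {"se1": 0.3, "sp1": 0.1, "se2": 0.2, "sp2": 0.4,
                 "prev_a": 0.4, "prev_b": 0.7}
        out, _ = enforce_identifiability(state)

        def ll(s):
            params = ModelParameters(
                TestAccuracy(float(s["se1"]), float(s["sp1"])),
                TestAccuracy(float(s["se2"]), float(s["sp2"])),
                (float(s["prev_a"]), float(s["prev_b"])),
            )
            return log_likelihood(params, data)

        assert ll(out) == pytest.approx(ll(state), abs=1e-9)

    def test_vectorized_over_draws(self):
        se1 = np.array([0.9, 0.3])
        state = {
            "se1": se1, "sp1": np.array([0.7, 0.1]),
            "se2": np.array([0.8, 0.2]), "sp2": np.array([0.6, 0.4]),
            "prev1": np.array([0.4, 0.4]),
        }
        out, fired = enforce_identifiability(state)
        assert list(fired) == [False, True]
        assert out["se1"][0] == 0.9
        assert out["se1"][1] == pytest.approx(0.9)


class TestChainDrawsExport:
    def test_long_format_round_trip(self, small_data, flat_priors, tmp_path):
        cfg = McmcConfig(n_chains=2, burn_in=10, n_iterations=50, seed=5)
        draws = gibbs_independence(small_data, flat_priors, cfg)
        path = tmp_path / "draws.csv"
        draws.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert set(frame.columns) == {"chain", "iteration", "parameter", "value"}
        assert len(frame) == 2 * 50 * len(draws.parameters)
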