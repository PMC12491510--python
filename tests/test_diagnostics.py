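import math

import numpy as np
import pytest

from latentdx.diagnostics import (
    ESS_INFLATION_CAP,
    ParameterSummary,
    PosteriorSummary,
    convergence_report,
    effective_sample_size,
    psrf,
    select_model,
    summarize,
)
from latentdx.mcmc import ChainDraws, McmcConfig


def make_draws(arrays: dict) -> ChainDraws:
    cfg = McmcConfig(n_chains=2, burn_in=0, n_iterations=1, seed=0)
    return ChainDraws(
        draws={k: np.asarray(v, float) for k, v in arrays.items()},
        config=cfg,
        model="independence",
        population_ids=("A",),
    )


class TestPsrf:
    def test_identical_chains_give_sqrt_ratio(self):
        n = 100
        chain = np.random.default_rng(0).normal(size=n)
        value = psrf(np.stack([chain, chain]))
        assert value == pytest.approx(math.sqrt((n - 1) / n))

    def test_hand_arithmetic_example(self):
        value = psrf(np.array([[1, 2, 3, 4], [1, 2, 3, 4]], float))
        assert value == pytest.approx(math.sqrt(3 / 4))

    def test_disjoint_constant_chains_diverge(self):
        assert psrf(np.array([[0, 0, 0, 0], [1, 1, 1, 1]], float)) == math.inf

    def test_all_identical_draws_defined_as_one(self):
        assert psrf(np.full((2, 5), 3.7)) == 1.0

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            psrf(np.array([[1.0, 2.0, 3.0]]))


class TestEffectiveSampleSize:
    def test_iid_draws_near_nominal(self, rng):
        n = 10000
        x = rng.normal(size=n)
        ess = effective_sample_size(x)
        assert 0.8 * n <= ess <= 1.2 * n

    def test_ar1_closed_form_limit(self, rng):
        """AR(1) with coefficient 0.5 has ESS ~= N * (1-rho)/(1+rho) = N/3."""
        n = 50000
        rho = 0.5
        noise = rng.normal(size=n) * math.sqrt(1 - rho**2)
        x = np.empty(n)
        x[0] = noise[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + noise[t]
        ess = effective_sample_size(x)
        assert ess == pytest.approx(n / 3, rel=0.2)

    def test_agrees_with_arviz_on_autocorrelated_chains(self, rng):
        """Independent-route cross-check against arviz's estimator."""
        az = pytest.importorskip("arviz")
        n, rho = 4000, 0.7
        chains = []
        for _ in range(2):
            noise = rng.normal(size=n) * math.sqrt(1 - rho**2)
            x = np.empty(n)
            x[0] = noise[0]
            for t in range(1, n):
                x[t] = rho * x[t - 1] + noise[t]
            chains.append(x)
        arr = np.stack(chains)
        mine = effective_sample_size(arr)
        theirs = float(az.ess(az.convert_to_dataset(arr))["x"])
        assert mine == pytest.approx(theirs, rel=0.25)

    def test_constant_chain_is_zero(self):
        assert effective_sample_size(np.full(100, 2.0)) == 0.0

    def test_never_exceeds_inflation_cap(self, rng):
        # strongly antithetic series inflate the naive estimate
        x = np.tile([1.0, -1.0], 500) + 0.01 * rng.normal(size=1000)
        assert effective_sample_size(x) <= ESS_INFLATION_CAP * 1000

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5.0))


class TestSummarize:
    def test_permutation_median(self, rng):
        chains = np.stack(
            [rng.permutation(np.arange(1, 101)), rng.permutation(np.arange(1, 101))]
        ).astype(float)
        summary = summarize(make_draws({"x": chains}))
        assert summary["x"].estimate == pytest.approx(50.5)

    def test_constant_draws_collapse(self):
        summary = summarize(make_draws({"x": np.full((2, 100), 3.0)}))
        s = summary["x"]
        assert (s.estimate, s.lower95, s.upper95) == (3.0, 3.0, 3.0)

    def test_conjugate_quantiles(self, rng):
        """Quantiles of beta-distributed draws match scipy's closed form."""
        from scipy import stats

        a, b = 14, 28
        chains = rng.beta(a, b, size=(2, 20000))
        summary = summarize(make_draws({"x": chains}))
        assert summary["x"].estimate == pytest.approx(
            stats.beta.ppf(0.5, a, b), abs=0.01
        )
        assert summary["x"].lower95 == pytest.approx(
            stats.beta.ppf(0.025, a, b), abs=0.01
        )
        assert summary["x"].upper95 == pytest.approx(
            stats.beta.ppf(0.975, a, b), abs=0.01
        )

    def test_shift_equivariance(self, rng):
        chains = rng.normal(size=(2, 500))
        s0 = summarize(make_draws({"x": chains}))["x"]
        s1 = summarize(make_draws({"x": chains + 2.5}))["x"]
        assert s1.estimate == pytest.approx(s0.estimate + 2.5)
        assert s1.lower95 == pytest.approx(s0.lower95 + 2.5)
        assert s1.upper95 == pytest.approx(s0.upper95 + 2.5)

    def test_mean_point_option(self, rng):
        chains = rng.normal(size=(2, 500))
        s = summarize(make_draws({"x": chains}), point="mean")
        assert s["x"].estimate == pytest.approx(chains.mean())

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            ParameterSummary(estimate=2.0, lower95=0.0, upper95=1.0, psrf=1.0, ess=10)


def summary_with_covs(cov_p_interval, cov_n_interval):
    def entry(lo, hi):
        return ParameterSummary(
            estimate=(lo + hi) / 2, lower95=lo, upper95=hi, psrf=1.0, ess=5000
        )

    return PosteriorSummary(
        parameters={
            "cov_dpos": entry(*cov_p_interval),
            "cov_dneg": entry(*cov_n_interval),
        }
    )


class TestSelectModel:
    def test_both_intervals_contain_zero_selects_independence(self):
        s = summary_with_covs((-0.02, 0.03), (-0.01, 0.04))
        assert select_model(s) == "independence"

    def test_excluding_interval_selects_dependence(self):
        s = summary_with_covs((0.01, 0.05), (-0.01, 0.04))
        assert select_model(s) == "dependence"

    def test_endpoint_zero_counts_as_containing(self):
        s = summary_with_covs((0.0, 0.05), (-0.01, 0.04))
        assert select_model(s) == "independence"

    def test_missing_covariances_rejected(self):
        s = PosteriorSummary(
            parameters={
                "se1": ParameterSummary(0.9, 0.8, 1.0, 1.0, 5000),
            }
        )
        with pytest.raises(ValueError, match="cov_dpos"):
            select_model(s)


class TestConvergenceReport:
    def test_thresholds_apply_per_parameter(self, rng):
        good = rng.normal(size=(2, 4000))
        bad = np.stack([np.zeros(4000), np.ones(4000)])
        draws = make_draws({"good": good, "bad": bad})
        report = convergence_report(draws, psrf_max=1.05, ess_min=1000)
        assert report.parameters["good"].converged
        assert not report.parameters["bad"].converged
        assert report.failing_parameters == ("bad",)
        assert not report.all_converged
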