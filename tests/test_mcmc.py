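"""Reconstruction sampler: blocks, stationarity oracles, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import kstest

from recensus import (
    MCMCConfig,
    PerturbConfig,
    PriorSpec,
    SimConfig,
    perturbation_loglik,
    publish_tables,
    run_chain,
    simulate_truth,
)
from recensus.mcmc import (
    PosteriorSamples,
    diagnostics,
    init_state,
    update_counts,
    update_field,
    update_scalars,
)

NOOP_PCFG = PerturbConfig(d=0, noise_pmf=(1.0,), tau=0)


def single_unit_system(o_published, n_stated=5):
    """One fine unit, data only at the fine level for age 0-9."""
    h, _ = simulate_truth(
        SimConfig(n_fine=1, n_per_l2=1, n_per_l3=1, n_per_l4=1, seed=0)
    )
    observed = pd.DataFrame(
        {
            "level": "L1",
            "unit_id": "U0000",
            "age_group": ["0-9", "10-14", "15-19"] * 2,
            "category": ["positive"] * 3 + ["negative"] * 3,
            "count": [o_published, 0, 0, n_stated - min(o_published, n_stated), 0, 0],
            "suppressed_flag": False,
        }
    )
    n = np.array([[n_stated, 0, 0]])
    return h, observed, n


@pytest.fixture(scope="module")
def small_system(sim_small):
    cfg, h, truth, tables = sim_small
    return h, truth, tables


class TestInitState:
    def test_published_counts_clipped(self):
        h, observed, _ = single_unit_system(o_published=5)
        n = np.array([[3, 0, 0]])
        state = init_state(observed, h, seed=0, n_stated=n)
        assert state.y[0, 0] == 3  # clip above denominator

    def test_zero_start(self):
        h, observed, n = single_unit_system(o_published=0)
        state = init_state(observed, h, seed=0, n_stated=n)
        assert state.y[0, 0] == 0

    def test_deterministic(self, small_system):
        h, truth, tables = small_system
        s1 = init_state(tables, h, seed=4, n_stated=truth.n_stated)
        s2 = init_state(tables, h, seed=4, n_stated=truth.n_stated)
        assert np.array_equal(s1.y, s2.y)
        assert s1.params.beta0_young == s2.params.beta0_young
        assert np.array_equal(s1.agg_flat, s2.agg_flat)

    def test_missing_fine_rows_rejected(self, small_system):
        h, truth, tables = small_system
        broken = tables[tables.unit_id != "U0003"]
        with pytest.raises(ValueError, match="missing published rows"):
            init_state(broken, h, seed=0, n_stated=truth.n_stated)

    def test_derived_denominators_used_when_absent(self, small_system):
        h, truth, tables = small_system
        state = init_state(tables, h, seed=0)
        assert (state.y <= state.n_stated).all()


class TestUpdateCounts:
    def test_degenerate_mechanism_pins_truth(self, small_system):
        h, truth, _ = small_system
        tables = publish_tables(h, truth, NOOP_PCFG, seed=5)
        state = init_state(tables, h, seed=0, n_stated=truth.n_stated)
        rng = np.random.default_rng(10)
        for _ in range(5):
            update_counts(state, NOOP_PCFG, rng)
        assert np.array_equal(state.y, truth.y)

    def test_counts_stay_within_bounds(self, small_system):
        h, truth, tables = small_system
        pcfg = PerturbConfig()
        state = init_state(tables, h, seed=0, n_stated=truth.n_stated)
        rng = np.random.default_rng(3)
        for _ in range(50):
            update_counts(state, pcfg, rng, count_proposal_sd=3)
        assert (state.y >= 0).all() and (state.y <= state.n_stated).all()

    def test_aggregates_tracked_incrementally(self, small_system):
        h, truth, tables = small_system
        pcfg = PerturbConfig()
        state = init_state(tables, h, seed=0, n_stated=truth.n_stated)
        rng = np.random.default_rng(3)
        for _ in range(20):
            update_counts(state, pcfg, rng)
        assert np.array_equal(state.agg_flat, state.obs.aggregate(state.y))

    def test_stationary_distribution_matches_enumeration(self):
        # core correctness oracle: single cell, brute-force posterior
        pcfg = PerturbConfig()
        h, observed, n = single_unit_system(o_published=3, n_stated=5)
        state = init_state(observed, h, seed=0, n_stated=n)
        p = 0.3
        state.params.beta0_young = float(logit(p))
        state.refresh_eta()
        rng = np.random.default_rng(42)
        counts = np.zeros(6)
        n_sweeps = 100_000
        for _ in range(n_sweeps):
            update_counts(state, pcfg, rng)
            counts[state.y[0, 0]] += 1
        emp = counts / counts.sum()
        from scipy.stats import binom

        post = np.array(
            [
                math.exp(perturbation_loglik(3, y, pcfg)) * binom.pmf(y, 5, p)
                for y in range(6)
            ]
        )
        post /= post.sum()
        tv = 0.5 * np.abs(emp - post).sum()
        assert tv < 0.02


class TestUpdateField:
    def _free_state(self, n_fine=15, seed=0):
        h, truth = simulate_truth(
            SimConfig(n_fine=n_fine, n_per_l2=5, n_per_l3=3, n_per_l4=1, seed=seed)
        )
        tables = publish_tables(h, truth, PerturbConfig(), seed=seed + 1)
        n = np.zeros_like(truth.n_stated)  # no data: posterior = prior
        state = init_state(tables, h, seed=0, n_stated=n)
        state.y = np.zeros_like(state.y)
        state.agg_flat = state.obs.aggregate(state.y)
        return h, state

    def test_no_data_samples_prior_covariance(self):
        h, state = self._free_state()
        rng = np.random.default_rng(8)
        cov_true = state.params.sigma_u**2 * (
            state.chol_corr @ state.chol_corr.T
        )
        draws = []
        for _ in range(3000):
            update_field(state, rng)
            draws.append(state.params.u.copy())
        draws = np.asarray(draws)
        err_early = np.linalg.norm(
            np.cov(draws[:150].T) - cov_true
        ) / np.linalg.norm(cov_true)
        err_late = np.linalg.norm(np.cov(draws.T) - cov_true) / np.linalg.norm(
            cov_true
        )
        assert err_late < err_early
        assert err_late < 0.25

    def test_vanishing_scale_pins_field_to_zero(self):
        h, state = self._free_state()
        state.params.log_sigma_u = math.log(1e-8)
        rng = np.random.default_rng(1)
        for _ in range(200):
            update_field(state, rng)
        assert np.max(np.abs(state.params.u)) < 1e-6

    def test_only_field_block_changes(self):
        h, state = self._free_state()
        rng = np.random.default_rng(2)
        before = state.params.copy()
        update_field(state, rng)
        assert state.params.beta0_young == before.beta0_young
        assert np.array_equal(state.params.gamma_free, before.gamma_free)
        assert abs(state.params.gamma.sum()) < 1e-12
        assert np.array_equal(state.y, np.zeros_like(state.y))


class TestUpdateScalars:
    def test_prior_recovery_under_flat_likelihood(self):
        h, truth = simulate_truth(
            SimConfig(n_fine=10, n_per_l2=5, n_per_l3=2, n_per_l4=1, seed=3)
        )
        tables = publish_tables(h, truth, PerturbConfig(), seed=4)
        n = np.zeros_like(truth.n_stated)
        state = init_state(tables, h, seed=0, n_stated=n)
        state.y = np.zeros_like(state.y)
        state.agg_flat = state.obs.aggregate(state.y)
        priors = PriorSpec()
        rng = np.random.default_rng(5)
        draws = {"beta0_young": [], "beta_ses": [], "log_sigma_u": [], "w": []}
        for it in range(20_000):
            update_field(state, rng)
            update_scalars(
                state, priors, rng,
                adapt=(it < 2000 and it % 50 == 49),
                adapt_step=0.2,
            )
            if it >= 2000 and it % 10 == 0:
                p = state.params
                draws["beta0_young"].append(p.beta0_young)
                draws["beta_ses"].append(p.beta_ses)
                draws["log_sigma_u"].append(p.log_sigma_u)
                draws["w"].append(p.w)
        assert kstest(draws["beta0_young"], "norm", args=(0, 2)).pvalue > 1e-3
        assert kstest(draws["beta_ses"], "norm", args=(0, 2)).pvalue > 1e-3
        assert kstest(draws["log_sigma_u"], "norm", args=(0, 1)).pvalue > 1e-3
        assert kstest(draws["w"], "uniform").pvalue > 1e-3

    def test_adaptation_frozen_after_burn_in(self, small_system):
        h, truth, tables = small_system
        state = init_state(tables, h, seed=0, n_stated=truth.n_stated)
        priors = PriorSpec()
        rng = np.random.default_rng(6)
        for _ in range(20):
            update_scalars(state, priors, rng, adapt=False)
        assert all(
            v == math.log(0.1) for v in state.prop_log_sd.values()
        )  # untouched without adaptation


class TestRunChain:
    def test_single_stored_draw(self, small_system):
        h, truth, tables = small_system
        mcfg = MCMCConfig(n_iter=3, n_burn=2, thin=1, n_chains=1, seed=2)
        s = run_chain(tables, h, PerturbConfig(), PriorSpec(), mcfg,
                      n_stated=truth.n_stated)
        assert s.y.shape[:2] == (1, 1)

    def test_seed_reproducibility(self, small_system):
        h, truth, tables = small_system
        mcfg = MCMCConfig(n_iter=60, n_burn=20, thin=2, n_chains=2, seed=9)
        a = run_chain(tables, h, PerturbConfig(), PriorSpec(), mcfg,
                      n_stated=truth.n_stated)
        b = run_chain(tables, h, PerturbConfig(), PriorSpec(), mcfg,
                      n_stated=truth.n_stated)
        assert np.array_equal(a.y, b.y)
        for k in a.scalars:
            assert np.array_equal(a.scalars[k], b.scalars[k])

    def test_stored_draws_respect_bounds(self, small_system):
        h, truth, tables = small_system
        mcfg = MCMCConfig(n_iter=80, n_burn=40, thin=4, n_chains=1, seed=3)
        s = run_chain(tables, h, PerturbConfig(), PriorSpec(), mcfg,
                      n_stated=truth.n_stated)
        assert (s.y >= 0).all()
        assert (s.y <= truth.n_stated[None, None]).all()

    def test_persistence_round_trip(self, small_system, tmp_path):
        h, truth, tables = small_system
        mcfg = MCMCConfig(n_iter=30, n_burn=20, thin=2, n_chains=1, seed=5)
        s = run_chain(tables, h, PerturbConfig(), PriorSpec(), mcfg,
                      n_stated=truth.n_stated)
        s.save(tmp_path)
        assert (tmp_path / "samples.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        long = pd.read_csv(tmp_path / "samples.csv")
        assert set(long["name"]) >= {"beta0_young", "w", "y"}


def _fake_samples(scalars: dict) -> PosteriorSamples:
    some = next(iter(scalars.values()))
    c, d = some.shape
    return PosteriorSamples(
        y=np.zeros((c, d, 1, 3), dtype=np.int64),
        u=np.zeros((c, d, 1)),
        scalars=scalars,
        fine_ids=["U0000"],
        age_groups=("0-9", "10-14", "15-19"),
        n_stated=np.ones((1, 3), dtype=np.int64),
        manifest={},
    )


class TestDiagnostics:
    def test_constant_chains_flagged(self):
        s = _fake_samples({"beta_ses": np.ones((2, 300))})
        out = diagnostics(s).set_index("parameter")
        assert bool(out.loc["beta_ses", "flagged"])

    def test_white_noise_rhat_near_one(self):
        rng = np.random.default_rng(0)
        s = _fake_samples({"x": rng.standard_normal((2, 1000))})
        out = diagnostics(s).set_index("parameter")
        assert 0.99 < out.loc["x", "rhat"] < 1.01

    def test_ar1_ess_closed_form(self):
        rng = np.random.default_rng(1)
        phi, n = 0.6, 1000
        chains = []
        for _ in range(2):
            x = np.zeros(n)
            for t in range(1, n):
                x[t] = phi * x[t - 1] + math.sqrt(1 - phi**2) * rng.standard_normal()
            chains.append(x)
        s = _fake_samples({"x": np.asarray(chains)})
        out = diagnostics(s).set_index("parameter")
        want = 2 * n * (1 - phi) / (1 + phi)
        assert abs(out.loc["x", "ess"] - want) / want < 0.2

    def test_too_few_draws_rejected(self):
        s = _fake_samples({"x": np.zeros((1, 50))})
        with pytest.raises(ValueError):
            diagnostics(s)


def test_default_run_converges_across_chains():
    """Split R-hat for the slow parameters stays below 1.05 on the
    default-scale synthetic run with two chains."""
    cfg = SimConfig()
    h, truth = simulate_truth(cfg)
    pcfg = PerturbConfig()
    tables = publish_tables(h, truth, pcfg, seed=1)
    samples = run_chain(tables, h, pcfg, PriorSpec(), MCMCConfig(),
                        n_stated=truth.n_stated)
    d = diagnostics(samples).set_index("parameter")
    for name in ("beta0_young", "beta_ses", "log_sigma_u"):
        assert d.loc[name, "rhat"] < 1.05
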