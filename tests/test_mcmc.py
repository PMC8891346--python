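"""Reversible-jump kernel: moves, acceptance rule, thinning, determinism."""

import math
import warnings

import numpy as np
import pytest

from phylofabric.core import FabricState
from phylofabric.mcmc import (ChainConfig, Sampler, lag1_autocorr,
                              mh_accept, propose, run_chain,
                              thin_and_diagnose)
from phylofabric.priors import PriorSpec
from phylofabric.simulate import Scenario, simulate_tree, simulate_traits

SPEC = PriorSpec()


def drive(state, tree, cfg, rng, want, max_tries=2000):
    for _ in range(max_tries):
        prop = propose(state, tree, SPEC, cfg, rng)
        if prop.move == want and prop.state is not None:
            return prop
    raise AssertionError(f"never proposed {want}")


class TestPropose:
    def test_add_then_remove_restores_state(self, rng):
        tree = simulate_tree(12, 1.0, rng)
        cfg = ChainConfig(variant="combined", iterations=100)
        state = FabricState(alpha=0.0, sigma2=1.0)
        add = drive(state, tree, cfg, rng, "add_beta")
        assert len(add.state.beta_map) == 1
        # removing the born effect restores the original exactly
        removed = None
        for _ in range(2000):
            prop = propose(add.state, tree, SPEC, cfg, rng)
            if prop.move == "remove_beta" and prop.state is not None:
                removed = prop
                break
        assert removed.state.beta_map == state.beta_map
        assert removed.state.alpha == state.alpha
        # Hastings corrections of the pair cancel
        assert add.log_hastings + removed.log_hastings == pytest.approx(
            0.0, abs=1e-12)

    def test_brownian_variant_only_continuous_moves(self, rng):
        tree = simulate_tree(8, 1.0, rng)
        cfg = ChainConfig(variant="brownian", iterations=100)
        state = FabricState(alpha=0.0, sigma2=1.0)
        moves = {propose(state, tree, SPEC, cfg, rng).move
                 for _ in range(300)}
        assert moves <= {"alpha", "sigma2"}

    def test_directional_variant_has_no_upsilon_moves(self, rng):
        tree = simulate_tree(8, 1.0, rng)
        cfg = ChainConfig(variant="directional", iterations=100)
        state = FabricState(alpha=0.0, sigma2=1.0)
        moves = {propose(state, tree, SPEC, cfg, rng).move
                 for _ in range(500)}
        assert not any("upsilon" in m for m in moves)
        assert any("beta" in m for m in moves)

    def test_prior_draw_birth_leaves_likelihood_ratio_times_charge(self,
                                                                   rng):
        # the Hastings term plus the per-parameter prior equals exactly
        # -charge for a beta birth: proposal and prior densities cancel
        tree = simulate_tree(10, 1.0, rng)
        cfg = ChainConfig(variant="directional", iterations=100,
                          guided_births=False)
        state = FabricState(alpha=0.0, sigma2=1.0)
        from phylofabric.priors import directional_prior_logpdf
        for _ in range(5):
            add = drive(state, tree, cfg, rng, "add_beta")
            b = add.location
            lp = directional_prior_logpdf(add.state.beta_map[b],
                                          tree.lengths[b], SPEC)
            assert lp + add.log_hastings == pytest.approx(
                -SPEC.directional_charge, abs=1e-10)

    def test_upsilon_birth_value_positive(self, rng):
        tree = simulate_tree(10, 1.0, rng)
        cfg = ChainConfig(variant="evolvability", iterations=100)
        state = FabricState(alpha=0.0, sigma2=1.0)
        add = drive(state, tree, cfg, rng, "add_upsilon")
        assert all(u > 0 for u in add.state.upsilon_map.values())


class TestMhAccept:
    def test_improvement_always_accepted(self, rng):
        assert all(mh_accept(-10.0, -5.0, 0.0, rng) for _ in range(100))

    def test_minus_inf_never_accepted(self, rng):
        assert not any(mh_accept(-5.0, -math.inf, 0.0, rng)
                       for _ in range(100))

    def test_acceptance_frequency_matches_ratio(self, rng):
        # log-ratio log(0.5): accept ~50% of the time
        n = 100_000
        acc = sum(mh_accept(0.0, math.log(0.5), 0.0, rng)
                  for _ in range(n))
        se = math.sqrt(0.25 / n)
        assert abs(acc / n - 0.5) < 3 * se


class TestThinning:
    def _records(self, series):
        return [(FabricState(alpha=0.0, sigma2=1.0), float(v), 0.0)
                for v in series]

    def test_white_noise_interval_one(self, rng):
        cfg = ChainConfig(iterations=100, sample_count=100)
        run = thin_and_diagnose(self._records(rng.normal(size=4000)), cfg)
        assert run.thin == 1

    def test_ar1_interval_matches_decay(self, rng):
        x = np.empty(200_000)
        x[0] = 0.0
        eps = rng.normal(size=len(x))
        for i in range(1, len(x)):
            x[i] = 0.9 * x[i - 1] + eps[i]
        cfg = ChainConfig(iterations=100, sample_count=1000,
                          target_autocorr=0.1)
        run = thin_and_diagnose(self._records(x), cfg)
        # 0.9^k <= 0.1 needs k >= 22; sampling noise allows a little play
        assert run.thin >= 18
        assert run.r <= 0.15

    def test_constant_series_flagged(self):
        cfg = ChainConfig(iterations=100, sample_count=10)
        with pytest.warns(UserWarning, match="constant"):
            run = thin_and_diagnose(self._records(np.ones(100)), cfg)
        assert run.r == 0.0

    def test_lag1_autocorr_degenerate(self):
        assert math.isnan(lag1_autocorr(np.ones(50)))
        assert math.isnan(lag1_autocorr(np.array([1.0, 2.0])))


class TestRunChain:
    def test_seeded_determinism(self, rng):
        sc = Scenario("det", beta_targets=(2.0,), n_tips=30)
        tree, traits, _ = sc.realize(5)
        y = traits.bind(tree)
        cfg = dict(iterations=20_000, sample_count=200, variant="combined")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = run_chain(tree, y, SPEC, ChainConfig(seed=42, **cfg))
            r2 = run_chain(tree, y, SPEC, ChainConfig(seed=42, **cfg))
            r3 = run_chain(tree, y, SPEC, ChainConfig(seed=43, **cfg))
        np.testing.assert_array_equal(r1.logliks, r2.logliks)
        assert r1.beta_inclusion == r2.beta_inclusion
        assert not np.array_equal(r1.logliks, r3.logliks)

    def test_planted_deep_beta_has_highest_inclusion(self):
        sc = Scenario("deep_beta", beta_targets=(2.0,), n_tips=60)
        tree, traits, truth = sc.realize(9)
        y = traits.bind(tree)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_chain(tree, y, SPEC,
                            ChainConfig(iterations=60_000, sample_count=300,
                                        variant="directional", seed=4))
        planted = next(iter(truth.beta_map))
        top = max(run.beta_inclusion, key=run.beta_inclusion.get)
        assert top == planted
        assert run.beta_inclusion[planted] > 0.5

    def test_inclusion_frequencies_in_unit_interval(self, rng):
        tree = simulate_tree(20, 1.0, rng)
        state = FabricState(alpha=0.0, sigma2=0.05)
        y = simulate_traits(tree, state, rng).bind(tree)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_chain(tree, y, SPEC,
                            ChainConfig(iterations=10_000, sample_count=100,
                                        variant="combined", seed=1))
        for p in list(run.beta_inclusion.values()) \
                + list(run.upsilon_inclusion.values()):
            assert 0.0 <= p <= 1.0

    def test_post_burnin_sample_budget_enforced(self, rng):
        tree = simulate_tree(10, 1.0, rng)
        y = simulate_traits(tree, FabricState(alpha=0, sigma2=0.05),
                            rng).bind(tree)
        with pytest.raises(ValueError, match="post-burn-in"):
            run_chain(tree, y, SPEC,
                      ChainConfig(iterations=1000, sample_count=900,
                                  seed=1))


class TestPriorOnly:
    def test_scalar_marginals_match_priors_roughly(self):
        # a fast smoke check; the full KS battery runs in the acceptance
        # suite
        tree = simulate_tree(15, 1.0, 3)
        cfg = ChainConfig(iterations=60_000, burn_in=10_000,
                          sample_count=500, variant="combined_global",
                          seed=2, prior_only=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_chain(tree, None, SPEC, cfg)
        bg = np.array([s.beta_g for s in run.samples])
        al = np.array([s.alpha for s in run.samples])
        assert abs(bg.mean()) < 0.03          # prior mean 0, sd 0.1
        assert abs(al.mean() - (-1.6)) < 0.3  # shifted-Gamma mean -3+1.4
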