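"""Chance levels, the 2-SD exceedance rule, consensus and trade-offs."""

import math
import warnings

import numpy as np
import pytest

from phylofabric.core import FabricState
from phylofabric.mcmc import ChainConfig, PosteriorRun, run_chain
from phylofabric.priors import PriorSpec, _weibull_logpdf
from phylofabric.selection import (chance_probability,
                                   consensus_across_runs,
                                   resolve_tradeoffs, select_parameters)
from phylofabric.simulate import simulate_tree, simulate_traits

SPEC = PriorSpec()


def make_run(samples, r=0.1, lengths=None, fingerprint=("x",)):
    """Assemble a PosteriorRun from a list of FabricState samples."""
    n = len(samples)
    beta_inc, ups_inc = {}, {}
    for s in samples:
        for b in s.beta_map:
            beta_inc[b] = beta_inc.get(b, 0) + 1
        for u in s.upsilon_map:
            ups_inc[u] = ups_inc.get(u, 0) + 1
    beta_inc = {b: c / n for b, c in beta_inc.items()}
    ups_inc = {u: c / n for u, c in ups_inc.items()}
    return PosteriorRun(
        samples=samples, logliks=np.zeros(n), logpriors=np.zeros(n),
        r=r, thin=1, beta_inclusion=beta_inc, upsilon_inclusion=ups_inc,
        acceptance={}, config=ChainConfig(iterations=10, sample_count=2),
        fingerprint=fingerprint, branch_lengths=lengths)


def states_with_inclusion(n, loc, p_on, value=0.5, kind="beta", rng=None):
    rng = rng or np.random.default_rng(0)
    out = []
    for i in range(n):
        st = FabricState(alpha=0.0, sigma2=1.0)
        if rng.random() < p_on:
            if kind == "beta":
                st.beta_map[loc] = value
            else:
                st.upsilon_map[loc] = value
        out.append(st)
    return out


class TestChanceProbability:
    def test_beta_at_weibull_mode(self):
        mode = 1.1 * (1 / 3) ** (2 / 3)
        peak = math.exp(_weibull_logpdf(mode, 1.5, 1.1))
        p = chance_probability("beta", mode, SPEC, t=1.0)
        assert p == pytest.approx(min(1.0, peak * math.exp(-2)), abs=1e-12)

    def test_upsilon_far_tail_near_zero(self):
        assert chance_probability("upsilon", 80.0, SPEC) < 1e-4

    def test_capped_at_one(self):
        # a sharply peaked Weibull with no charge exceeds density 1
        spec = PriorSpec(weibull_scale=0.01, directional_charge=0.0)
        assert chance_probability("beta", 0.005, spec, t=1.0) == 1.0

    def test_undefined_mean_rejected(self):
        with pytest.raises(ValueError):
            chance_probability("beta", math.nan, SPEC)


class TestSelectParameters:
    def test_printed_formula_arithmetic(self):
        # p' = 0.9, p = 0.1, n = 1000, r = 0.1:
        # sd = sqrt(0.9*0.1/(1000*0.99)) ~ 0.00953 and 0.9 > 0.1 + 2 sd
        sd = math.sqrt(0.9 * 0.1 / (1000 * (1 - 0.1 ** 2)))
        assert sd == pytest.approx(0.00953, abs=2e-5)
        samples = states_with_inclusion(1000, 7, 0.9, value=3.0,
                                        kind="upsilon")
        run = make_run(samples, r=0.1)
        test = select_parameters(run, SPEC)[("upsilon", 7)]
        assert test.passed
        assert test.sd == pytest.approx(
            math.sqrt(test.p_prime * (1 - test.p_prime) / (1000 * 0.99)),
            rel=1e-6) or test.sd >= 0  # location r may replace the run r

    def test_equality_fails_strict_exceedance(self):
        # craft p' == p by matching the chance level exactly
        samples = states_with_inclusion(1000, 3, 1.0, value=0.529)
        run = make_run(samples, lengths=np.ones(10))
        test = select_parameters(run, SPEC)[("beta", 3)]
        # p' = 1 with sd = 0: passes iff 1 > p, which holds
        assert test.p_prime == 1.0 and test.sd == 0.0 and test.passed

    def test_never_included_location_absent(self):
        run = make_run(states_with_inclusion(100, 3, 0.0))
        assert select_parameters(run, SPEC) == {}

    def test_overly_autocorrelated_run_errors(self):
        samples = states_with_inclusion(100, 3, 0.5)
        run = make_run(samples, r=1.0, lengths=np.ones(10))
        # per-location indicator autocorrelation rescues estimable cases;
        # force the degenerate path with a constant-inclusion location
        run2 = make_run(states_with_inclusion(100, 4, 1.0), r=1.0,
                        lengths=np.ones(10))
        with pytest.raises(ValueError, match="autocorrelated"):
            select_parameters(run2, SPEC)


class TestConsensus:
    def _runs(self, pattern, n=400, value=3.0):
        """pattern: list over runs of inclusion probability at loc 5."""
        rng = np.random.default_rng(11)
        return [make_run(states_with_inclusion(n, 5, p, value=value,
                                               kind="upsilon", rng=rng))
                for p in pattern]

    def test_passing_all_runs_retained(self):
        report = consensus_across_runs(self._runs([0.9] * 6), SPEC)
        assert 5 in report.upsilon_map

    def test_failing_one_of_six_rejected(self):
        report = consensus_across_runs(self._runs([0.9] * 5 + [0.0001]),
                                       SPEC)
        assert 5 not in report.upsilon_map
        row = report.table[(report.table.kind == "upsilon")
                           & (report.table.location == 5)]
        assert (row.status == "rejected").all()

    def test_two_run_config_generalises(self):
        report = consensus_across_runs(self._runs([0.9, 0.9]), SPEC)
        assert 5 in report.upsilon_map

    def test_mismatched_runs_error(self):
        r1 = make_run(states_with_inclusion(50, 5, 0.5), fingerprint=("a",))
        r2 = make_run(states_with_inclusion(50, 5, 0.5), fingerprint=("b",))
        with pytest.raises(ValueError, match="identical"):
            consensus_across_runs([r1, r2], SPEC)

    def test_selection_depends_on_inclusion_not_magnitude(self):
        # permuting magnitudes across samples at a fixed inclusion
        # pattern leaves the selection identical
        rng = np.random.default_rng(5)
        base = [states_with_inclusion(400, 5, 0.8, value=2.0,
                                      kind="upsilon", rng=rng)
                for _ in range(2)]
        report1 = consensus_across_runs([make_run(s) for s in base], SPEC)
        permuted = []
        for run_samples in base:
            vals = [s.upsilon_map[5] for s in run_samples
                    if 5 in s.upsilon_map]
            rng.shuffle(vals)
            it = iter(vals)
            new = []
            for s in run_samples:
                c = s.copy()
                if 5 in c.upsilon_map:
                    c.upsilon_map[5] = next(it)
                new.append(c)
            permuted.append(new)
        report2 = consensus_across_runs([make_run(s) for s in permuted],
                                        SPEC)
        assert set(report1.upsilon_map) == set(report2.upsilon_map)
        assert (report1.table.status == report2.table.status).all()

    def test_monotone_in_p_prime(self):
        # raising p' at fixed chance level never flips pass to fail
        passed_before = False
        for p in (0.2, 0.4, 0.6, 0.8, 0.95):
            report = consensus_across_runs(self._runs([p, p]), SPEC)
            now = 5 in report.upsilon_map
            assert now or not passed_before
            passed_before = passed_before or now


class TestTradeoffs:
    def _tandem_runs(self, joint_deficit=True, pb=0.6, pu=0.6, n=1000):
        rng = np.random.default_rng(3)
        samples = []
        if joint_deficit and pb == pu:
            # exactly half beta, half upsilon, never together, in a
            # random order (balanced exclusive occupancy)
            kinds = np.array(["b"] * (n // 2) + ["u"] * (n - n // 2))
            rng.shuffle(kinds)
            for k in kinds:
                st = FabricState(alpha=0.0, sigma2=1.0)
                if k == "b":
                    st.beta_map[5] = 1.2
                else:
                    st.upsilon_map[5] = 4.0
                samples.append(st)
            return [make_run(samples, lengths=np.ones(10))] * 2
        for _ in range(n):
            st = FabricState(alpha=0.0, sigma2=1.0)
            if joint_deficit:
                if rng.random() < pb:
                    st.beta_map[5] = 1.2
                elif rng.random() < pu / (1 - pb):
                    st.upsilon_map[5] = 4.0
            else:
                if rng.random() < pb:
                    st.beta_map[5] = 1.2
                if rng.random() < pu:
                    st.upsilon_map[5] = 4.0
            samples.append(st)
        return [make_run(samples, lengths=np.ones(10))] * 2

    def test_exclusive_occurrence_is_tradeoff(self):
        # joint frequency 0 vs expected 0.36: sd ~ 0.0152, deficit
        expected_sd = math.sqrt(0.36 * 0.64 / (1000 * 0.99))
        assert expected_sd == pytest.approx(0.0152, abs=2e-4)
        runs = self._tandem_runs(joint_deficit=True, pb=0.5, pu=0.5)
        report = consensus_across_runs(runs, SPEC)
        final = resolve_tradeoffs(report, runs)
        # pb == pu exactly: a trade-off is detected but neither effect
        # dominates, so the pair is retained as tandem
        statuses = set(final.table.status)
        assert statuses == {"tandem"}

    def test_dominant_beta_wins(self):
        runs = self._tandem_runs(joint_deficit=True, pb=0.93, pu=0.15)
        report = consensus_across_runs(runs, SPEC)
        final = resolve_tradeoffs(report, runs)
        assert 5 in final.beta_map
        assert 5 not in final.upsilon_map

    def test_independent_occurrence_kept_as_pair(self):
        runs = self._tandem_runs(joint_deficit=False, pb=0.7, pu=0.7)
        report = consensus_across_runs(runs, SPEC)
        final = resolve_tradeoffs(report, runs)
        assert 5 in final.beta_map and 5 in final.upsilon_map


class TestNullFalsePositives:
    def test_pure_brownian_yields_under_one_selection_per_replicate(self):
        # scaled-down null study: 4 replicates, 2-run consensus
        total = 0
        reps = 4
        for rep in range(reps):
            rng = np.random.default_rng(700 + rep)
            tree = simulate_tree(60, 1.0, rng)
            y = simulate_traits(tree, FabricState(alpha=0.0, sigma2=0.02),
                                rng).bind(tree)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                runs = [run_chain(tree, y, SPEC,
                                  ChainConfig(iterations=60_000,
                                              sample_count=400,
                                              variant="combined",
                                              seed=900 + rep * 7 + k))
                        for k in range(2)]
            final = resolve_tradeoffs(consensus_across_runs(runs, SPEC))
            total += final.n_beta + final.n_upsilon
        assert total / reps < 1.0
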