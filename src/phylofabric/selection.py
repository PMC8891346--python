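"""Selection of effects from stationary chains, and trade-off resolution.

Reversible-jump chains sample a fluctuating effect set around a stable
core; effects are retained for interpretation on the basis of their
posterior frequency of occurrence, never their magnitude.  For each
candidate location the observed inclusion frequency p' is compared with
a chance level p -- the acceptance probability of a likelihood-neutral
prior-drawn proposal at the location's posterior-mean value -- and the
location passes when

    p' > p + 2 * sqrt(p' (1 - p') / (n (1 - r^2)))

with n the number of thinned samples and r the chain autocorrelation
(the location's own inclusion-indicator autocorrelation when estimable,
else the run's log-likelihood autocorrelation).  A location is retained
only if it passes in every one of the consensus runs (default six in
production; tests use two or three).  Final effect values come from the
single run whose retained-parameter values correlate best, on average,
with the other runs'.

Where a retained branch beta and the upsilon at the same branch's end
node co-occur in the chain significantly less often than the product of
their individual frequencies predicts, the pair is trading off rather
than linked: the location is assigned to whichever effect has the
2-standard-deviation-higher individual frequency, or kept as a tandem
pair when neither dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import priors as pr
from .mcmc import PosteriorRun, lag1_autocorr
from .trees import Phylogeny

__all__ = ["LocationTest", "SelectionReport", "chance_probability",
           "select_parameters", "consensus_across_runs", "resolve_tradeoffs"]


def chance_probability(kind: str, posterior_mean_value: float,
                       priors: pr.PriorSpec, t: float | None = None) -> float:
    """Chance-level inclusion probability p for one effect.

    For a directional effect the Weibull density at the posterior-mean
    branch total |beta*t| times e^{-charge}; for an evolvability effect
    the Gamma density at the posterior-mean multiplier.  Capped at 1.
    ``posterior_mean_value`` is beta*t (signed) for kind='beta' when t is
    folded in by the caller, or beta with ``t`` supplied.
    """
    if posterior_mean_value is None or not math.isfinite(posterior_mean_value):
        raise ValueError("posterior mean undefined; location auto-rejected "
                         "upstream")
    if kind == "beta":
        x = abs(posterior_mean_value * (t if t is not None else 1.0))
        dens = math.exp(pr._weibull_logpdf(x, priors.weibull_shape,
                                           priors.weibull_scale)
                        - priors.directional_charge) if x > 0 else 0.0
        return min(1.0, dens)
    if kind == "upsilon":
        u = posterior_mean_value
        dens = math.exp(pr._gamma_logpdf(u, priors.upsilon_shape,
                                         priors.upsilon_scale)) \
            if u > 0 else 0.0
        return min(1.0, dens)
    raise ValueError(f"kind must be 'beta' or 'upsilon', got {kind!r}")


@dataclass
class LocationTest:
    """Per-run outcome of the 2-SD exceedance test at one location."""

    kind: str
    location: int
    p_prime: float
    chance_p: float
    sd: float
    passed: bool
    mean_value: float   # posterior mean of the effect when present


def _ess_denominator(n: int, r: float) -> float:
    r = 0.0 if math.isnan(r) else r
    denom = n * (1.0 - r * r)
    if denom <= 0:
        raise ValueError(
            f"non-positive adjusted sample size n(1-r^2) = {denom} "
            f"(n={n}, r={r}); the chain is too autocorrelated to test")
    return denom


def _sd(p_prime: float, n: int, r: float) -> float:
    p = min(max(p_prime, 0.0), 1.0)
    return math.sqrt(p * (1.0 - p) / _ess_denominator(n, r))


def _location_r(run: PosteriorRun, kind: str, location: int) -> float:
    r = lag1_autocorr(run.inclusion_series(kind, location))
    return run.r if math.isnan(r) else r


def select_parameters(run: PosteriorRun,
                      priors: pr.PriorSpec) -> dict[tuple, LocationTest]:
    """Apply the exceedance test to every location seen in one run."""
    out: dict[tuple, LocationTest] = {}
    for kind, inc in (("beta", run.beta_inclusion),
                      ("upsilon", run.upsilon_inclusion)):
        for loc, p_prime in inc.items():
            vals = run.effect_values(kind, loc)
            mean_val = float(vals.mean())
            if kind == "beta":
                # chance p is assessed on the branch total beta*t
                t = 1.0 if run.branch_lengths is None \
                    else float(run.branch_lengths[loc])
                p = chance_probability("beta", mean_val, priors, t=t)
            else:
                p = chance_probability("upsilon", mean_val, priors)
            r = _location_r(run, kind, loc)
            sd = _sd(p_prime, run.n, r)
            out[(kind, loc)] = LocationTest(
                kind=kind, location=loc, p_prime=p_prime, chance_p=p,
                sd=sd, passed=p_prime > p + 2.0 * sd, mean_value=mean_val)
    return out


@dataclass
class SelectionReport:
    """Consensus selection outcome across runs."""

    table: pd.DataFrame            # one row per candidate location
    beta_map: dict[int, float]     # final directional effects (rates)
    upsilon_map: dict[int, float]  # final evolvability multipliers
    representative: int            # index of the run supplying the values
    runs: list = field(default_factory=list, repr=False)

    @property
    def n_beta(self) -> int:
        return len(self.beta_map)

    @property
    def n_upsilon(self) -> int:
        return len(self.upsilon_map)


def _check_matched(runs):
    if len(runs) < 2:
        raise ValueError("consensus needs at least 2 runs")
    fp0 = runs[0].fingerprint
    for i, run in enumerate(runs[1:], 1):
        if run.fingerprint != fp0:
            raise ValueError(
                f"run {i} was fitted to different data/tree/variant than "
                "run 0; consensus requires identical inputs")


def consensus_across_runs(runs, priors: pr.PriorSpec) -> SelectionReport:
    """Retain locations passing the exceedance test in every run.

    The number of consensus runs is simply ``len(runs)``.  Effect values
    are taken from the run whose retained values have the highest average
    correlation with the other runs' values.
    """
    _check_matched(runs)
    per_run = [select_parameters(run, priors) for run in runs]
    candidates = sorted({key for tests in per_run for key in tests})
    rows = []
    retained = []
    for key in candidates:
        tests = [tests_i.get(key) for tests_i in per_run]
        passes = [t is not None and t.passed for t in tests]
        ok = all(passes)
        if ok:
            retained.append(key)
        first = next(t for t in tests if t is not None)
        rows.append({
            "kind": key[0], "location": key[1],
            "p_prime": np.mean([t.p_prime if t else 0.0 for t in tests]),
            "chance_p": first.chance_p,
            "sd": first.sd,
            "n_pass": int(sum(passes)), "n_runs": len(runs),
            "status": "candidate" if ok else "rejected",
        })
    table = pd.DataFrame(rows)

    rep = _representative_run(runs, retained)
    beta_map, ups_map = {}, {}
    for kind, loc in retained:
        val = float(runs[rep].effect_values(kind, loc).mean())
        if kind == "beta":
            beta_map[loc] = val
        else:
            ups_map[loc] = val
    if len(table):
        sel = table["status"] == "candidate"
        table.loc[sel & (table["kind"] == "beta"), "status"] = "selected-beta"
        table.loc[sel & (table["kind"] == "upsilon"),
                  "status"] = "selected-upsilon"
    return SelectionReport(table=table, beta_map=beta_map,
                           upsilon_map=ups_map, representative=rep,
                           runs=list(runs))


def _representative_run(runs, retained) -> int:
    """Run index with the highest average cross-run correlation of
    retained parameter values (falls back to 0 for < 3 retained)."""
    if len(retained) < 3 or len(runs) < 2:
        return 0
    vals = np.array([[run.effect_values(kind, loc).mean()
                      for (kind, loc) in retained] for run in runs])
    best, best_score = 0, -np.inf
    for i in range(len(runs)):
        cors = []
        for j in range(len(runs)):
            if i == j:
                continue
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(vals[i], vals[j])[0, 1]
            if np.isfinite(c):
                cors.append(c)
        score = np.mean(cors) if cors else -np.inf
        if score > best_score:
            best, best_score = i, score
    return best


def resolve_tradeoffs(report: SelectionReport,
                      runs=None) -> SelectionReport:
    """Discriminate trade-offs from linked effects among tandem pairs.

    A tandem pair is a retained branch beta whose end node also carries a
    retained upsilon.  If their joint inclusion frequency falls 2 SD
    short of the product of their individual frequencies, the pair is a
    trade-off and the dominant effect (2-SD-higher p') wins; otherwise
    both are kept as a tandem pair.
    """
    runs = runs if runs is not None else report.runs
    if not runs:
        raise ValueError("resolve_tradeoffs needs the posterior runs")
    rep = runs[report.representative]
    n = rep.n
    beta_map = dict(report.beta_map)
    ups_map = dict(report.upsilon_map)
    table = report.table.copy()
    pairs = [loc for loc in beta_map if loc in ups_map]
    for loc in pairs:
        sb = rep.inclusion_series("beta", loc)
        su = rep.inclusion_series("upsilon", loc)
        pb, pu = float(sb.mean()), float(su.mean())
        joint = float((sb * su).mean())
        expected = pb * pu
        r_pair = max(_location_r(rep, "beta", loc),
                     _location_r(rep, "upsilon", loc))
        sd_joint = _sd(expected, n, r_pair) if 0 < expected < 1 else 0.0
        tradeoff = joint < expected - 2.0 * sd_joint
        status = "tandem"
        if tradeoff:
            sd_diff = math.sqrt(_sd(pb, n, _location_r(rep, "beta", loc)) ** 2
                                + _sd(pu, n, _location_r(rep, "upsilon",
                                                         loc)) ** 2)
            if pb > pu + 2.0 * sd_diff:
                del ups_map[loc]
                status = "selected-beta"
            elif pu > pb + 2.0 * sd_diff:
                del beta_map[loc]
                status = "selected-upsilon"
        for kind in ("beta", "upsilon"):
            mask = (table["kind"] == kind) & (table["location"] == loc)
            keep = (kind == "beta" and loc in beta_map) or \
                   (kind == "upsilon" and loc in ups_map)
            table.loc[mask, "status"] = status if status == "tandem" else (
                status if keep else f"tradeoff-lost-to-{status[9:]}")
    return SelectionReport(table=table, beta_map=beta_map,
                           upsilon_map=ups_map,
                           representative=report.representative,
                           runs=list(runs))
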