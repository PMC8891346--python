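"""Reversible-jump Metropolis-Hastings sampler over the model state.

The chain moves between model dimensions with *add/remove* proposals
(a directional effect is born onto a uniformly chosen empty branch with
its branch total |beta*t| drawn from the Weibull prior and a random sign;
an evolvability multiplier is born onto a uniformly chosen eligible node
with its value drawn from the Gamma prior) and *change* proposals
(symmetric random-walk perturbations of an active effect).  Because
births draw from the prior, the prior density cancels against the
proposal density in the acceptance ratio: a beta birth is accepted with
probability min{1, likelihood-ratio * e^(-charge)} and an upsilon birth
with the plain likelihood ratio.  The implied prior over effect
configurations is geometric in the number of effects (e^(-charge) per
beta, flat per upsilon) with placements uniform given the count; the
uniform-placement count terms cancel identically between the proposal
ratio and that prior, so neither appears in the acceptance ratio.
alpha, beta_g and log(sigma2) get random-walk updates (the sigma2
Jacobian is part of the Hastings term).

Model variants gate the move set: 'brownian' (alpha, sigma2 only),
'directional' (+beta), 'evolvability' (+upsilon), 'combined' (both) and
'combined_global' (both plus the global trend beta_g).

Step sizes of the random-walk moves are auto-tuned toward 20-40%
acceptance during burn-in only, then frozen, preserving detailed balance
in the sampled portion of the chain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import priors as pr
from ._pruning import prune_loglik
from .core import FabricState
from .errors import PhyloFabricError
from .likelihood import brownian_reference_fit
from .trees import Phylogeny, TraitTable

__all__ = ["ChainConfig", "PosteriorRun", "Proposal", "propose",
           "mh_accept", "run_chain", "thin_and_diagnose", "Sampler",
           "VARIANTS", "lag1_autocorr"]

VARIANTS = ("brownian", "directional", "evolvability", "combined",
            "combined_global")

_LOG2 = math.log(2.0)


@dataclass
class ChainConfig:
    """Settings for one Markov chain."""

    iterations: int = 200_000
    burn_in: int | None = None          # default: first half
    sample_count: int = 1000
    target_autocorr: float = 0.1
    variant: str = "combined_global"
    seed: int = 0
    # class weights; renormalised over the classes the variant allows
    move_weights: dict = field(default_factory=lambda: {
        "beta": 0.3, "upsilon": 0.3, "continuous": 0.4})
    step_alpha: float = 0.2
    step_log_sigma2: float = 0.3
    step_beta_g: float = 0.05
    step_effect: float = 0.3     # change-move sd on the |beta*t| scale
    step_upsilon: float = 0.4    # change-move sd on log(upsilon)
    record_target: int = 20_000  # max raw post-burn-in records kept
    prior_only: bool = False
    power: float = 1.0           # likelihood tempering exponent
    include_stem: bool = False
    jitter: float = 0.0
    allow_root_upsilon: bool = False
    # deterministic greedy forward-selection start (see Sampler docstring);
    # the chain is free to prune anything it adds
    smart_init: bool = True
    smart_init_max_effects: int = 12
    # margin added to the per-effect posterior cost (inclusion charge +
    # log placement count) that a greedy addition must beat
    smart_init_margin: float = 0.5
    # births mix a prior draw with an independence proposal centred on a
    # deterministic data-derived local estimate; the mixture density enters
    # the Hastings ratio exactly, so the target is unchanged
    guided_births: bool = True
    guided_fraction: float = 0.5

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.sample_count < 2:
            raise ValueError("sample_count must be >= 2")
        if any(w < 0 for w in self.move_weights.values()) \
                or sum(self.move_weights.values()) <= 0:
            raise ValueError("move weights must be nonnegative, sum > 0")

        classes = ["continuous"]
        if self.variant in ("directional", "combined", "combined_global"):
            classes.append("beta")
        if self.variant in ("evolvability", "combined", "combined_global"):
            classes.append("upsilon")
        self._classes = tuple(classes)
        w = [self.move_weights.get(c, 0.0) for c in classes]
        if sum(w) <= 0:
            w = [1.0] * len(classes)
        self._class_weights = tuple(w)
        cont = ["alpha", "sigma2"]
        if self.variant == "combined_global":
            cont.append("beta_g")
        self._continuous = tuple(cont)

    @property
    def effective_burn_in(self) -> int:
        return self.iterations // 2 if self.burn_in is None else self.burn_in

    def move_classes(self) -> tuple[str, ...]:
        return self._classes

    def continuous_params(self) -> tuple[str, ...]:
        return self._continuous


@dataclass
class BirthGuide:
    """Deterministic data-derived centres for guided birth proposals.

    Computed once from the Brownian reference fit before the chain
    starts, hence fixed throughout -- the proposals remain valid
    Metropolis-Hastings moves.  ``xhat``/``xtau`` give the centre and sd
    of a normal component for the branch total beta*t of each branch;
    ``uhat`` gives the centre of a lognormal component (sd ``utau``) for
    the variance multiplier of each internal node.
    """

    xhat: np.ndarray
    xtau: np.ndarray
    uhat: np.ndarray
    utau: float = 0.6

    def beta_logq(self, x: float, b: int, frac: float,
                  priors: pr.PriorSpec) -> float:
        prior_part = math.exp(_weib_logpdf(abs(x), priors)) * 0.5 \
            if x != 0 else 0.0
        tau = self.xtau[b]
        z = (x - self.xhat[b]) / tau
        guide_part = math.exp(-0.5 * z * z) / (tau * math.sqrt(2 * math.pi))
        dens = (1 - frac) * prior_part + frac * guide_part
        return math.log(dens) if dens > 0 else -math.inf

    def upsilon_logq(self, u: float, node: int, frac: float,
                     priors: pr.PriorSpec) -> float:
        if u <= 0:
            return -math.inf
        prior_part = math.exp(pr._gamma_logpdf(u, priors.upsilon_shape,
                                               priors.upsilon_scale))
        z = (math.log(u) - math.log(self.uhat[node])) / self.utau
        guide_part = math.exp(-0.5 * z * z) \
            / (u * self.utau * math.sqrt(2 * math.pi))
        dens = (1 - frac) * prior_part + frac * guide_part
        return math.log(dens) if dens > 0 else -math.inf


@dataclass
class Proposal:
    """One proposed move.  ``state is None`` means the move had no legal
    target and was skipped (logged, never an exception)."""

    move: str
    state: FabricState | None
    log_hastings: float = 0.0
    location: int | None = None


def propose(state: FabricState, tree: Phylogeny, priors: pr.PriorSpec,
            config: ChainConfig, rng: np.random.Generator,
            eligible_beta=None, eligible_upsilon=None,
            guide: BirthGuide | None = None) -> Proposal:
    """Draw one move for the configured variant and return the candidate
    state with the log Hastings correction (log q(reverse)/q(forward),
    including birth-proposal densities)."""
    if eligible_beta is None:
        eligible_beta = _eligible_beta(tree)
    if eligible_upsilon is None:
        eligible_upsilon = _eligible_upsilon(tree, config.allow_root_upsilon)

    classes = config.move_classes()
    weights = config._class_weights
    u = rng.random() * sum(weights)
    cum = 0.0
    cls = classes[-1]
    for c, wt in zip(classes, weights):
        cum += wt
        if u <= cum:
            cls = c
            break

    if cls == "continuous":
        cont = config.continuous_params()
        param = cont[rng.integers(len(cont))]
        cand = state.copy()
        if param == "alpha":
            cand.alpha = state.alpha + rng.normal(0.0, config.step_alpha)
            return Proposal("alpha", cand)
        if param == "beta_g":
            cand.beta_g = state.beta_g + rng.normal(0.0, config.step_beta_g)
            return Proposal("beta_g", cand)
        factor = math.exp(rng.normal(0.0, config.step_log_sigma2))
        cand.sigma2 = state.sigma2 * factor
        return Proposal("sigma2", cand, log_hastings=math.log(factor))

    frac = config.guided_fraction if (guide is not None
                                      and config.guided_births) else 0.0

    def beta_logq(x, b):
        if frac > 0:
            return guide.beta_logq(x, b, frac, priors)
        return _weib_logpdf(abs(x), priors) - _LOG2

    def upsilon_logq(u, node):
        if frac > 0:
            return guide.upsilon_logq(u, node, frac, priors)
        return pr.upsilon_prior_logpdf(u, priors)

    if cls == "beta":
        kind = ("add", "remove", "change")[rng.integers(3)]
        active = list(state.beta_map)
        if kind == "add":
            empty = [b for b in eligible_beta if b not in state.beta_map]
            if not empty:
                return Proposal("add_beta", None)
            b = empty[rng.integers(len(empty))]
            if frac > 0 and rng.random() < frac:
                x = guide.xhat[b] + guide.xtau[b] * rng.normal()
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                x = sign * pr.sample_abs_effect(rng, priors)
            t = tree.lengths[b]
            cand = state.copy()
            cand.beta_map[b] = x / t
            # proposal density cancels against the value prior in the MH
            # ratio; placement count terms cancel the configuration prior
            # (module docstring)
            h = -beta_logq(x, b)
            return Proposal("add_beta", cand, h, b)
        if not active:
            return Proposal(f"{kind}_beta", None)
        b = active[rng.integers(len(active))]
        t = tree.lengths[b]
        if kind == "remove":
            x = state.beta_map[b] * t
            cand = state.copy()
            del cand.beta_map[b]
            h = beta_logq(x, b)
            return Proposal("remove_beta", cand, h, b)
        cand = state.copy()
        x = state.beta_map[b] * t + rng.normal(0.0, config.step_effect)
        cand.beta_map[b] = x / t
        return Proposal("change_beta", cand, 0.0, b)

    kind = ("add", "remove", "change", "relocate")[rng.integers(4)]
    active = list(state.upsilon_map)
    if kind == "relocate":
        # shift an active multiplier to a neighbouring eligible node,
        # value unchanged: adjacent placements differ only by the
        # sibling subtree's scaling and plain add/remove cannot traverse
        # them against the intervening likelihood barrier
        if not active:
            return Proposal("relocate_upsilon", None)
        node = active[rng.integers(len(active))]
        elig = set(eligible_upsilon)

        def free_neighbours(j, occupied):
            out = []
            p = tree.parent[j]
            if p in elig and p not in occupied:
                out.append(p)
            out.extend(c for c in tree.children[j]
                       if c in elig and c not in occupied)
            return out

        nbs = free_neighbours(node, state.upsilon_map)
        if not nbs:
            return Proposal("relocate_upsilon", None)
        alt = nbs[rng.integers(len(nbs))]
        cand = state.copy()
        u = cand.upsilon_map.pop(node)
        cand.upsilon_map[alt] = u
        rev = free_neighbours(alt, cand.upsilon_map)
        h = math.log(len(nbs)) - math.log(max(len(rev), 1))
        if node not in rev:   # irreversible corner: reject outright
            return Proposal("relocate_upsilon", None)
        return Proposal("relocate_upsilon", cand, h, node)
    if kind == "add":
        empty = [u for u in eligible_upsilon if u not in state.upsilon_map]
        if not empty:
            return Proposal("add_upsilon", None)
        node = empty[rng.integers(len(empty))]
        if frac > 0 and rng.random() < frac:
            u = float(guide.uhat[node]
                      * math.exp(guide.utau * rng.normal()))
        else:
            u = pr.sample_upsilon(rng, priors)
        cand = state.copy()
        cand.upsilon_map[node] = u
        h = -upsilon_logq(u, node)
        return Proposal("add_upsilon", cand, h, node)
    if not active:
        return Proposal(f"{kind}_upsilon", None)
    node = active[rng.integers(len(active))]
    if kind == "remove":
        u = state.upsilon_map[node]
        cand = state.copy()
        del cand.upsilon_map[node]
        h = upsilon_logq(u, node)
        return Proposal("remove_upsilon", cand, h, node)
    # multiplicative perturbation: symmetric on the log scale, where the
    # multiplier acts; the Jacobian enters the Hastings term
    cand = state.copy()
    factor = math.exp(rng.normal(0.0, config.step_upsilon))
    cand.upsilon_map[node] = state.upsilon_map[node] * factor
    return Proposal("change_upsilon", cand, math.log(factor), node)


def _weib_logpdf(x, priors):
    return pr._weibull_logpdf(x, priors.weibull_shape, priors.weibull_scale)


def mh_accept(current_logpost: float, candidate_logpost: float,
              log_proposal_ratio: float, rng: np.random.Generator) -> bool:
    """Metropolis-Hastings accept rule.

    Accept with probability min{1, exp(candidate - current + hastings)};
    a candidate with -inf posterior is never accepted.
    """
    if candidate_logpost == -math.inf or math.isnan(candidate_logpost):
        return False
    log_ratio = candidate_logpost - current_logpost + log_proposal_ratio
    return log_ratio >= 0.0 or rng.random() < math.exp(log_ratio)


def _eligible_beta(tree: Phylogeny) -> list[int]:
    # zero-length branches carry no resolvable directional total
    return [int(b) for b in tree.branches() if tree.lengths[b] > 0]


def _eligible_upsilon(tree: Phylogeny, allow_root: bool) -> list[int]:
    counts = tree.clade_tip_counts()
    nodes = [i for i in range(tree.n_nodes)
             if not tree.is_tip[i] and counts[i] >= 2]
    if not allow_root:
        nodes = [i for i in nodes if i != tree.root]
    return nodes


def lag1_autocorr(x: np.ndarray) -> float:
    """Lag-1 autocorrelation; nan for constant or too-short series."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.std(x) == 0.0:
        return float("nan")
    a, b = x[:-1], x[1:]
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


@dataclass
class PosteriorRun:
    """Thinned stationary samples plus per-location inclusion summaries."""

    samples: list[FabricState]
    logliks: np.ndarray
    logpriors: np.ndarray
    r: float                      # lag-1 autocorr of the loglik series
    thin: int
    beta_inclusion: dict[int, float]
    upsilon_inclusion: dict[int, float]
    acceptance: dict[str, tuple[int, int]]   # move -> (accepted, proposed)
    config: ChainConfig
    fingerprint: tuple
    branch_lengths: np.ndarray | None = None  # raw lengths, node-id order

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def ess_factor(self) -> float:
        """n(1 - r^2), the autocorrelation-adjusted sample size."""
        r = 0.0 if math.isnan(self.r) else self.r
        return self.n * (1.0 - r * r)

    def inclusion_series(self, kind: str, location: int) -> np.ndarray:
        """0/1 presence indicator of an effect across the thinned samples."""
        if kind == "beta":
            return np.array([1.0 if location in s.beta_map else 0.0
                             for s in self.samples])
        if kind == "upsilon":
            return np.array([1.0 if location in s.upsilon_map else 0.0
                             for s in self.samples])
        raise ValueError(f"kind must be 'beta' or 'upsilon', got {kind!r}")

    def effect_values(self, kind: str, location: int) -> np.ndarray:
        """Values of an effect in the samples where it is present."""
        if kind == "beta":
            return np.array([s.beta_map[location] for s in self.samples
                             if location in s.beta_map])
        return np.array([s.upsilon_map[location] for s in self.samples
                         if location in s.upsilon_map])

    def to_frame(self):
        """Sample log as a DataFrame (one row per thinned sample)."""
        import pandas as pd
        return pd.DataFrame({
            "loglik": self.logliks,
            "logprior": self.logpriors,
            "alpha": [s.alpha for s in self.samples],
            "sigma2": [s.sigma2 for s in self.samples],
            "beta_g": [s.beta_g for s in self.samples],
            "n_beta": [len(s.beta_map) for s in self.samples],
            "n_upsilon": [len(s.upsilon_map) for s in self.samples],
        })

    def inclusion_table(self):
        """Per-location inclusion frequencies as a DataFrame."""
        import pandas as pd
        rows = [("beta", loc, f) for loc, f in
                sorted(self.beta_inclusion.items())]
        rows += [("upsilon", loc, f) for loc, f in
                 sorted(self.upsilon_inclusion.items())]
        return pd.DataFrame(rows, columns=["kind", "location", "p_prime"])


class Sampler:
    """Stateful driver; reusable across tempering powers (stepping stones).

    ``loglik_fn(state) -> float`` may replace the tree likelihood (used
    for prior-recovery validation and the conjugate stepping-stone toy);
    ``config.prior_only`` is shorthand for a constant zero likelihood.
    """

    def __init__(self, tree: Phylogeny, traits, priors: pr.PriorSpec,
                 config: ChainConfig, loglik_fn=None):
        self.tree = tree
        self.priors = priors
        self.config = replace(config)  # tuning mutates step sizes
        self.rng = np.random.default_rng(config.seed)
        self.eligible_beta = _eligible_beta(tree)
        self.eligible_upsilon = _eligible_upsilon(tree,
                                                  config.allow_root_upsilon)
        if isinstance(traits, TraitTable):
            self.y = traits.bind(tree)
        elif traits is None:
            self.y = np.zeros(tree.n_tips)
        else:
            self.y = np.asarray(traits, dtype=float)
        self._tip_slot = np.full(tree.n_nodes, -1, dtype=np.int64)
        self._tip_slot[tree.tip_ids] = np.arange(tree.n_tips)
        if config.prior_only and loglik_fn is None:
            loglik_fn = lambda state: 0.0  # noqa: E731
        self.loglik_fn = loglik_fn
        self.guide = None
        if loglik_fn is None and config.guided_births:
            self.guide = self._build_guide()
        self.fingerprint = (tree.n_nodes, tree.parent.tobytes(),
                            tree.lengths.tobytes(), self.y.tobytes(),
                            config.variant)
        self.state = self._initial_state()
        self.loglik = self._loglik(self.state)
        self.logprior = self._logprior(self.state)
        if not math.isfinite(self.loglik) or not math.isfinite(self.logprior):
            raise PhyloFabricError(
                "non-finite log-posterior at the initial state "
                f"(loglik={self.loglik}, logprior={self.logprior}); check "
                "the tree for zero-variance tips and alpha against its "
                "prior threshold")
        self.acceptance: dict[str, list[int]] = {}
        self._tune_window: dict[str, list[int]] = {}

    # -- state ----------------------------------------------------------
    def _initial_state(self) -> FabricState:
        spec = self.priors
        alpha0 = spec.alpha_threshold + spec.alpha_shape * spec.alpha_scale
        sigma0 = 1.0
        if self.loglik_fn is None:
            fit = brownian_reference_fit(self.tree, self.y)
            alpha0 = max(fit.alpha, spec.alpha_threshold + 1e-3)
            sigma0 = min(max(fit.sigma2, 10 * spec.sigma2_lower),
                         0.1 * spec.sigma2_upper)
        state = FabricState(alpha=alpha0, sigma2=sigma0, beta_g=0.0)
        if (self.loglik_fn is None and self.config.smart_init
                and self.config.variant != "brownian"):
            # anchor sigma2 at the robust (median-contrast) estimate: the
            # GLS mean is inflated by any variance-scaled clades, which
            # would start the chain in a relabelled chart of the
            # sigma2/upsilon degeneracy
            state.sigma2 = min(max(self._robust_sigma2(),
                                   10 * self.priors.sigma2_lower),
                               0.1 * self.priors.sigma2_upper)
            state = self._greedy_init(state)
        return state

    def _robust_sigma2(self) -> float:
        """Median squared standardized contrast under unit-rate Brownian
        motion, scaled by the chi-square(1) median; robust to a minority
        of clades with rescaled variance."""
        tree, y = self.tree, self.y
        n = tree.n_nodes
        slot = self._tip_slot
        mu = np.zeros(n)
        v = np.zeros(n)
        stats = []   # per internal node: (sum of squared deviations, dof)
        for node in tree.postorder:
            if tree.is_tip[node]:
                mu[node] = y[slot[node]]
                continue
            kids = tree.children[node]
            prec = [1.0 / max(v[c] + tree.lengths[c], 1e-12) for c in kids]
            P = sum(prec)
            m = sum(mu[c] * p for c, p in zip(kids, prec)) / P
            # the deviations around m jointly form a chi-square with
            # (k-1) dof times sigma2; per-child terms alone are biased
            stats.append((sum((mu[c] - m) ** 2 * p
                              for c, p in zip(kids, prec)),
                          len(kids) - 1))
            mu[node] = m
            v[node] = 1.0 / P
        if not stats:
            return 1.0
        binary = [s for s, d in stats if d == 1]
        if len(binary) >= 5:
            return max(float(np.median(binary)) / 0.4549, 1e-10)
        total = sum(s for s, _ in stats)
        dof = sum(d for _, d in stats)
        return max(total / max(dof, 1), 1e-10)

    def _build_guide(self) -> BirthGuide:
        """Per-location birth-proposal centres from the Brownian fit.

        For each internal node: the clade's empirical variance ratio
        (mean squared standardized contrast within the clade) centres
        the lognormal component for upsilon births.  For each branch:
        the standardized contrast between the subtree's conditional
        estimate and its siblings' centres the normal component for
        beta*t births.  All quantities are deterministic functions of
        the data, fixed before the chain starts.
        """
        tree, y = self.tree, self.y
        s2 = self._robust_sigma2()
        n = tree.n_nodes
        slot = self._tip_slot
        mu = np.zeros(n)
        v = np.zeros(n)        # conditional variance in raw time units
        chi = np.zeros(n)      # standardized squared contrasts at node
        dof = np.zeros(n)
        for node in tree.postorder:
            if tree.is_tip[node]:
                mu[node] = y[slot[node]]
                continue
            kids = tree.children[node]
            prec = [1.0 / max(v[c] + tree.lengths[c], 1e-12) for c in kids]
            P = sum(prec)
            m = sum(mu[c] * p for c, p in zip(kids, prec)) / P
            chi[node] = sum((mu[c] - m) ** 2 * p
                            for c, p in zip(kids, prec)) / s2
            dof[node] = len(kids) - 1
            mu[node] = m
            v[node] = 1.0 / P
        agg_chi, agg_dof = chi.copy(), dof.copy()
        for i in tree.postorder:
            p = tree.parent[i]
            if p >= 0:
                agg_chi[p] += agg_chi[i]
                agg_dof[p] += agg_dof[i]
        uhat = np.clip(agg_chi / np.maximum(agg_dof, 1.0), 0.02, 50.0)
        xhat = np.zeros(n)
        xtau = np.full(n, 0.6)
        for b in range(1, n):
            p = tree.parent[b]
            others = [c for c in tree.children[p] if c != b]
            if not others:
                continue
            precs = [1.0 / max(v[c] + tree.lengths[c], 1e-12)
                     for c in others]
            P = sum(precs)
            m_o = sum(mu[c] * q for c, q in zip(others, precs)) / P
            xhat[b] = mu[b] - m_o
            xtau[b] = min(2.0, max(0.2, math.sqrt(
                s2 * (v[b] + tree.lengths[b] + 1.0 / P))))
        return BirthGuide(xhat=xhat, xtau=xtau, uhat=uhat)

    # value grids for the greedy start; coarse on purpose -- the chain's
    # change moves refine anything that survives
    _X_GRID = (-3.0, -2.0, -1.5, -1.0, -0.75, -0.5, -0.25,
               0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0)
    _U_GRID = (0.05, 0.1, 0.25, 0.5, 2.0, 4.0, 8.0, 16.0)
    _S_GRID = (0.5, 0.7, 0.85, 1.2, 1.5, 2.0)

    def _greedy_init(self, state: FabricState) -> FabricState:
        """Deterministic forward selection of strongly supported effects.

        Repeatedly adds the single grid-scored effect with the largest
        log-likelihood gain (if above the configured threshold),
        re-scanning sigma2 after each addition.  This places the chain
        near the high-posterior configuration that very long chains reach
        by diffusion; burn-in then equilibrates and the reversible-jump
        moves prune anything not actually supported.
        """
        cfg = self.config
        use_beta = cfg.variant in ("directional", "combined",
                                   "combined_global")
        use_ups = cfg.variant in ("evolvability", "combined",
                                  "combined_global")
        state = state.copy()
        ll = self._loglik(state)
        # each addition must beat its true posterior cost: the inclusion
        # charge plus the log placement count of the configuration prior
        thr_beta = (self.priors.directional_charge
                    + math.log(max(len(self.eligible_beta), 1))
                    + cfg.smart_init_margin)
        thr_ups = (self.priors.evolvability_charge
                   + math.log(max(len(self.eligible_upsilon), 1))
                   + cfg.smart_init_margin)
        for _ in range(cfg.smart_init_max_effects):
            best_score, best_apply = 0.0, None
            if use_beta:
                for b in self.eligible_beta:
                    if b in state.beta_map:
                        continue
                    t = self.tree.lengths[b]
                    for x in self._X_GRID:
                        state.beta_map[b] = x / t
                        score = self._loglik(state) - ll - thr_beta
                        if score > best_score:
                            best_score = score
                            best_apply = ("beta", b, x / t)
                    del state.beta_map[b]
            if use_ups:
                for node in self.eligible_upsilon:
                    if node in state.upsilon_map:
                        continue
                    for u in self._U_GRID:
                        state.upsilon_map[node] = u
                        score = self._loglik(state) - ll - thr_ups
                        if score > best_score:
                            best_score = score
                            best_apply = ("upsilon", node, u)
                    del state.upsilon_map[node]
            if best_apply is None:
                break
            kind, loc, val = best_apply
            if kind == "beta":
                state.beta_map[loc] = val
            else:
                state.upsilon_map[loc] = val
            ll = self._refine(state)
        self._polish_placements(state)
        return state

    def _polish_placements(self, state: FabricState) -> None:
        """Move each seeded multiplier to a neighbouring node when the
        posterior (likelihood plus value prior) prefers it there.

        Node placement of a multiplier is only softly identified: the
        parent placement differs just by the sibling subtree's scaling.
        Starting every chain at the preferred chart keeps independent
        runs from settling on different neighbouring placements.
        """
        def score(st):
            lp = sum(pr.upsilon_prior_logpdf(u, self.priors)
                     for u in st.upsilon_map.values())
            return self._loglik(st) + lp

        eligible = set(self.eligible_upsilon)
        for _ in range(2):
            moved = False
            for node in list(state.upsilon_map):
                best_s, best_alt = score(state), None
                neighbours = [self.tree.parent[node]] \
                    + list(self.tree.children[node])
                for alt in neighbours:
                    if alt not in eligible or alt in state.upsilon_map:
                        continue
                    trial = state.copy()
                    u = trial.upsilon_map.pop(node)
                    trial.upsilon_map[alt] = u
                    self._refine(trial)
                    sc_val = score(trial)
                    if sc_val > best_s + 0.1:
                        best_s, best_alt = sc_val, trial
                if best_alt is not None:
                    state.upsilon_map = best_alt.upsilon_map
                    state.sigma2 = best_alt.sigma2
                    state.beta_map = best_alt.beta_map
                    moved = True
            if not moved:
                break

    def _refine(self, state: FabricState) -> float:
        """Coordinate-wise re-optimisation of sigma2 and every included
        effect value (multiplicative scans); returns the final loglik."""
        ll = self._loglik(state)
        for _ in range(3):
            improved = False
            for f in self._S_GRID:
                s2 = state.sigma2 * f
                if not (self.priors.sigma2_lower <= s2
                        <= self.priors.sigma2_upper):
                    continue
                old = state.sigma2
                state.sigma2 = s2
                trial = self._loglik(state)
                if trial > ll:
                    ll, improved = trial, True
                else:
                    state.sigma2 = old
            for node in list(state.upsilon_map):
                for f in (0.5, 0.7, 1.4, 2.0):
                    old = state.upsilon_map[node]
                    state.upsilon_map[node] = old * f
                    trial = self._loglik(state)
                    if trial > ll:
                        ll, improved = trial, True
                    else:
                        state.upsilon_map[node] = old
            for b in list(state.beta_map):
                for d in (-0.25, 0.25):
                    old = state.beta_map[b]
                    state.beta_map[b] = old + d / self.tree.lengths[b]
                    trial = self._loglik(state)
                    if trial > ll:
                        ll, improved = trial, True
                    else:
                        state.beta_map[b] = old
            if not improved:
                break
        return ll

    def _loglik(self, state: FabricState) -> float:
        if self.loglik_fn is not None:
            return float(self.loglik_fn(state))
        tree = self.tree
        n = tree.n_nodes
        beta = np.zeros(n)
        for b, v in state.beta_map.items():
            beta[b] = v
        ups = np.ones(n)
        for node, v in state.upsilon_map.items():
            ups[node] = v
        val, status, _ = prune_loglik(
            tree.parent, tree.postorder, tree._child_ptr, tree._child_idx,
            tree.lengths, tree.is_tip, self._tip_slot, self.y, beta, ups,
            state.alpha, state.sigma2, state.beta_g,
            self.config.include_stem, self.config.jitter)
        return float(val) if status == 0 else -math.inf

    def _logprior(self, state: FabricState) -> float:
        spec = self.priors
        lp = pr.global_and_root_prior_logpdf(state, spec)
        for b, v in state.beta_map.items():
            lp += pr.directional_prior_logpdf(v, self.tree.lengths[b], spec)
        for _, u in state.upsilon_map.items():
            lp += pr.upsilon_prior_logpdf(u, spec) - spec.evolvability_charge
        return lp

    # -- iteration ------------------------------------------------------
    def step(self) -> bool:
        cfg = self.config
        prop = propose(self.state, self.tree, self.priors, cfg, self.rng,
                       self.eligible_beta, self.eligible_upsilon,
                       guide=self.guide)
        stats = self.acceptance.setdefault(prop.move, [0, 0])
        if prop.state is None:
            self.acceptance.setdefault("skipped", [0, 0])[1] += 1
            return False
        stats[1] += 1
        cand_lp = self._logprior(prop.state)
        if cand_lp == -math.inf:
            accepted = False
        else:
            cand_ll = self._loglik(prop.state)
            cur = cfg.power * self.loglik + self.logprior
            cand = cfg.power * cand_ll + cand_lp
            accepted = mh_accept(cur, cand, prop.log_hastings, self.rng)
            if accepted:
                self.state = prop.state
                self.loglik = cand_ll
                self.logprior = cand_lp
        if accepted:
            stats[0] += 1
        win = self._tune_window.setdefault(prop.move, [0, 0])
        win[1] += 1
        win[0] += int(accepted)
        return accepted

    _TUNABLE = {"alpha": "step_alpha", "sigma2": "step_log_sigma2",
                "beta_g": "step_beta_g", "change_beta": "step_effect",
                "change_upsilon": "step_upsilon"}

    def _tune(self):
        for move, attr in self._TUNABLE.items():
            win = self._tune_window.get(move)
            if not win or win[1] < 50:
                continue
            rate = win[0] / win[1]
            if rate < 0.2:
                setattr(self.config, attr, getattr(self.config, attr) * 0.7)
            elif rate > 0.4:
                setattr(self.config, attr, getattr(self.config, attr) * 1.4)
            win[0] = win[1] = 0

    def run(self, iterations: int, burn_in: int, record_stride: int,
            tune: bool = True):
        """Advance the chain; return raw post-burn-in records
        (state copy, loglik, logprior) every ``record_stride`` iterations."""
        records = []
        for i in range(iterations):
            self.step()
            if i < burn_in:
                if tune and (i + 1) % 200 == 0:
                    self._tune()
            elif (i - burn_in) % record_stride == 0:
                records.append((self.state.copy(), self.loglik,
                                self.logprior))
        return records


def thin_and_diagnose(records, config: ChainConfig,
                      acceptance=None, fingerprint=(),
                      branch_lengths=None) -> PosteriorRun:
    """Thin raw records to ~sample_count at the smallest spacing whose
    log-likelihood lag-1 autocorrelation meets the target; report the
    achieved autocorrelation and per-location inclusion frequencies."""
    if not records:
        raise ValueError("no post-burn-in records to thin")
    ll = np.array([rec[1] for rec in records])
    diag = ll
    if math.isnan(lag1_autocorr(ll)):
        # constant likelihood (e.g. prior-only runs): diagnose thinning on
        # the log-prior series instead, never silently
        warnings.warn("log-likelihood series is constant or too short; "
                      "thinning diagnosed on the log-prior series",
                      stacklevel=2)
        diag = np.array([rec[2] for rec in records])
    max_stride = max(1, len(ll) // config.sample_count)
    stride, r = 1, float("nan")
    for s in range(1, max_stride + 1):
        stride = s
        r = lag1_autocorr(diag[::s])
        if math.isnan(r):
            r = 0.0
            break
        if r <= config.target_autocorr:
            break
    else:
        warnings.warn(
            f"could not reach target autocorrelation "
            f"{config.target_autocorr}: achieved r={r:.3f} at the widest "
            f"spacing {max_stride} compatible with sample_count="
            f"{config.sample_count}; consider a longer chain", stacklevel=2)
    kept = records[::stride]
    if len(kept) > config.sample_count:
        kept = kept[-config.sample_count:]
    states = [k[0] for k in kept]
    logliks = np.array([k[1] for k in kept])
    logpriors = np.array([k[2] for k in kept])
    r_final = lag1_autocorr(logliks)
    if math.isnan(r_final):
        r_final = 0.0
    n = len(states)
    beta_inc: dict[int, float] = {}
    ups_inc: dict[int, float] = {}
    for s in states:
        for b in s.beta_map:
            beta_inc[b] = beta_inc.get(b, 0.0) + 1.0
        for u in s.upsilon_map:
            ups_inc[u] = ups_inc.get(u, 0.0) + 1.0
    beta_inc = {b: c / n for b, c in beta_inc.items()}
    ups_inc = {u: c / n for u, c in ups_inc.items()}
    return PosteriorRun(
        samples=states, logliks=logliks, logpriors=logpriors, r=r_final,
        thin=stride, beta_inclusion=beta_inc, upsilon_inclusion=ups_inc,
        acceptance={k: (v[0], v[1]) for k, v in (acceptance or {}).items()},
        config=config, fingerprint=tuple(fingerprint),
        branch_lengths=branch_lengths)


def run_chain(tree: Phylogeny, traits, priors: pr.PriorSpec,
              config: ChainConfig, loglik_fn=None) -> PosteriorRun:
    """Run one chain to completion and return the thinned posterior.

    Deterministic given ``config.seed``.  A Geweke-style comparison of
    early versus late post-burn-in log-likelihood means emits a warning
    (never an error) when the chain looks non-stationary.
    """
    sampler = Sampler(tree, traits, priors, config, loglik_fn=loglik_fn)
    burn = config.effective_burn_in
    post = config.iterations - burn
    if post < config.sample_count:
        raise ValueError(
            f"only {post} post-burn-in iterations for "
            f"sample_count={config.sample_count}")
    stride = max(1, post // config.record_target)
    records = sampler.run(config.iterations, burn, stride)
    _geweke_warning(np.array([rec[1] for rec in records]))
    return thin_and_diagnose(records, sampler.config, sampler.acceptance,
                             sampler.fingerprint, tree.lengths)


def _geweke_warning(ll: np.ndarray, z_threshold: float = 4.0):
    if len(ll) < 100 or np.std(ll) == 0:
        return
    a = ll[: len(ll) // 10]
    b = ll[len(ll) // 2:]
    denom = math.sqrt(np.var(a) / len(a) + np.var(b) / len(b))
    if denom == 0:
        return
    z = (a.mean() - b.mean()) / denom
    if abs(z) > z_threshold:
        warnings.warn(
            f"possible non-stationarity: Geweke-style z={z:.2f} comparing "
            "early vs late post-burn-in log-likelihood", stacklevel=3)
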