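"""Multivariate-normal tip likelihood, dense and pruning evaluations.

``loglik_naive`` builds the full tip covariance and evaluates the MVN
density directly: it is the oracle.  ``loglik_pruning`` peels the tree in
linear time and must agree to 1e-8; it is what the samplers call.  Both
always include the full normalising constant -- marginal-likelihood
comparisons depend on it.

Zero-length branches are permitted unless they make the covariance
singular, in which case a :class:`DegenerateCovarianceError` is raised
(no silent jitter; pass ``jitter=1e-8`` explicitly to regularise the
diagonal).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._pruning import prune_loglik
from .core import FabricState, expected_tip_means, phylo_covariance
from .errors import DegenerateCovarianceError
from .trees import Phylogeny, TraitTable

__all__ = ["loglik_naive", "loglik_pruning", "brownian_reference_fit",
           "BrownianFit"]

_LOG2PI = np.log(2.0 * np.pi)


def _as_vector(tree: Phylogeny, traits) -> np.ndarray:
    if isinstance(traits, TraitTable):
        return traits.bind(tree)
    y = np.asarray(traits, dtype=float)
    if y.shape != (tree.n_tips,):
        raise ValueError(
            f"trait vector has shape {y.shape}, expected ({tree.n_tips},) "
            "in tree tip order"
        )
    return y


def loglik_naive(tree: Phylogeny, traits, state: FabricState,
                 include_stem: bool = False, jitter: float = 0.0) -> float:
    """Dense-matrix MVN log-likelihood: -1/2 [n log 2pi + log|V| + r'V^-1 r]."""
    y = _as_vector(tree, traits)
    u = expected_tip_means(tree, state, include_stem)
    V = phylo_covariance(tree, state.upsilon_map, state.sigma2, include_stem)
    if jitter:
        V = V + jitter * np.eye(len(y))
    zero_var = np.flatnonzero(np.diag(V) <= 0)
    if len(zero_var):
        tips = [tree.labels[tree.tip_ids[i]] for i in zero_var]
        raise DegenerateCovarianceError(
            "degenerate covariance: zero-variance tips "
            f"{', '.join(tips)} (zero-length root-to-tip paths)", tips=tips)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DegenerateCovarianceError(
            f"degenerate covariance: V is singular or not PSD ({exc})"
        ) from exc
    r = y - u
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    return float(-0.5 * (len(y) * _LOG2PI + logdet + quad))


def loglik_pruning(tree: Phylogeny, traits, state: FabricState,
                   include_stem: bool = False, jitter: float = 0.0) -> float:
    """Linear-time evaluation; agrees with :func:`loglik_naive` to 1e-8."""
    y = _as_vector(tree, traits)
    state.validate(tree)
    n = tree.n_nodes
    beta = np.zeros(n)
    for b, v in state.beta_map.items():
        beta[b] = v
    ups = np.ones(n)
    for node, v in state.upsilon_map.items():
        ups[node] = v
    tip_slot = np.full(n, -1, dtype=np.int64)
    tip_slot[tree.tip_ids] = np.arange(tree.n_tips)
    val, status, node = prune_loglik(
        tree.parent, tree.postorder, tree._child_ptr, tree._child_idx,
        tree.lengths, tree.is_tip, tip_slot, y, beta, ups,
        float(state.alpha), float(state.sigma2), float(state.beta_g),
        bool(include_stem), float(jitter))
    if status != 0:
        tips = [tree.labels[t] for t in tree.clade_tips(int(node))]
        raise DegenerateCovarianceError(
            "degenerate covariance: zero-variance paths meeting at node "
            f"{int(node)} (tips {', '.join(tips[:6])}"
            f"{'...' if len(tips) > 6 else ''})", tips=tips)
    return float(val)


class BrownianFit(NamedTuple):
    """GLS fit of the pure Brownian baseline (all beta=0, upsilon=1)."""

    alpha: float
    sigma2: float
    loglik: float
    boundary: bool  # True when sigma2 hit the zero-variance boundary


def brownian_reference_fit(tree: Phylogeny, traits) -> BrownianFit:
    """Closed-form ML estimates of (alpha, sigma2) under pure Brownian motion.

    alpha_hat = (1'V0^-1 y)/(1'V0^-1 1) and sigma2_hat = r'V0^-1 r / n with
    V0 the unit-rate covariance; used for chain initialisation and as the
    Brownian baseline.  Constant traits give the sigma2 = 0 boundary,
    flagged with an unbounded likelihood rather than silently propagated.
    """
    y = _as_vector(tree, traits)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 tips")
    V0 = phylo_covariance(tree, {}, 1.0)
    zero_var = np.flatnonzero(np.diag(V0) <= 0)
    if len(zero_var):
        tips = [tree.labels[tree.tip_ids[i]] for i in zero_var]
        raise DegenerateCovarianceError(
            f"degenerate covariance: zero-variance tips {', '.join(tips)}",
            tips=tips)
    try:
        cf = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DegenerateCovarianceError(
            f"degenerate covariance: V is singular or not PSD ({exc})"
        ) from exc
    one = np.ones(n)
    Vi1 = cho_solve(cf, one)
    alpha = float(y @ Vi1 / (one @ Vi1))
    r = y - alpha
    sigma2 = float(r @ cho_solve(cf, r) / n)
    if sigma2 <= 0.0 or not np.isfinite(np.log(sigma2)):
        return BrownianFit(alpha=alpha, sigma2=0.0, loglik=np.inf,
                           boundary=True)
    logdet0 = 2.0 * np.sum(np.log(np.diag(cf[0])))
    loglik = float(-0.5 * (n * _LOG2PI + logdet0 + n * np.log(sigma2) + n))
    return BrownianFit(alpha=alpha, sigma2=sigma2, loglik=loglik,
                       boundary=False)
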