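"""Model state and the tree transforms it implies.

The model augments Brownian motion on a phylogeny with three kinds of
effect:

* a branch-wise directional rate ``beta`` (per unit time) shifting the
  mean of every descendant tip by ``beta * t`` along its branch, with no
  effect on variance;
* a node-wise evolvability multiplier ``upsilon`` (> 0) scaling the
  Brownian variance of the whole descendant clade, realised
  computationally by multiplying descendant branch lengths;
* a global trend ``beta_g`` relating each tip's expected deviation from
  the root state to its variance-adjusted root-to-tip time T_i(upsilon).

Directional effects always use *raw* branch lengths in the mean even when
an upsilon rescales the same branch's variance: the two processes are
orthogonal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EffectLocationError
from .trees import Phylogeny

__all__ = [
    "FabricState",
    "TransformedTree",
    "effective_branch_lengths",
    "variance_adjusted_times",
    "expected_tip_means",
    "phylo_covariance",
    "transform_tree",
]


@dataclass
class FabricState:
    """Full parameter vector of the model.

    Attributes
    ----------
    alpha : ancestral trait value at the root.
    sigma2 : Brownian variance per unit time (> 0).
    beta_g : global trend per unit variance-adjusted time.
    beta_map : branch (child-node id) -> directional rate beta; absent
        branches have beta = 0.
    upsilon_map : internal-node id -> evolvability multiplier (> 0);
        absent nodes have upsilon = 1.
    """

    alpha: float
    sigma2: float
    beta_g: float = 0.0
    beta_map: dict[int, float] = field(default_factory=dict)
    upsilon_map: dict[int, float] = field(default_factory=dict)

    def validate(self, tree: Phylogeny) -> None:
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        counts = tree.clade_tip_counts()
        for node, u in self.upsilon_map.items():
            if not 0 <= node < tree.n_nodes or tree.is_tip[node]:
                raise EffectLocationError(
                    f"upsilon at node {node}: not an internal node of the tree"
                )
            if counts[node] < 2:
                raise EffectLocationError(
                    f"upsilon at node {node}: clade has fewer than 2 tips"
                )
            if not u > 0:
                raise ValueError(f"upsilon at node {node} must be > 0, got {u}")
        for branch in self.beta_map:
            if not 1 <= branch < tree.n_nodes:
                raise EffectLocationError(
                    f"beta on branch {branch}: not a non-root branch of the tree"
                )

    def copy(self) -> "FabricState":
        return FabricState(self.alpha, self.sigma2, self.beta_g,
                           dict(self.beta_map), dict(self.upsilon_map))


@dataclass
class TransformedTree:
    """Derived quantities implied by a state on a tree."""

    effective_lengths: np.ndarray  # per node; upsilon-scaled branch lengths
    T: np.ndarray                  # per tip (tree.tip_ids order)
    V: np.ndarray                  # tip x tip covariance
    mean_offsets: np.ndarray       # per tip: sum of beta*t along the path


def _upsilon_array(tree: Phylogeny, upsilon_map) -> np.ndarray:
    ups = np.ones(tree.n_nodes)
    for node, u in (upsilon_map or {}).items():
        if not u > 0:
            raise ValueError(f"upsilon must be positive, got {u} at node {node}")
        if not 0 <= node < tree.n_nodes or tree.is_tip[node]:
            raise EffectLocationError(
                f"upsilon at node {node}: not an internal node of the tree"
            )
        ups[node] = u
    return ups


def effective_branch_lengths(tree: Phylogeny, upsilon_map,
                             include_stem: bool = False) -> np.ndarray:
    """Branch lengths after applying the evolvability multipliers.

    An upsilon at a node scales every branch *inside* its clade; nested
    upsilons compose multiplicatively.  By default the stem branch of the
    node carrying the upsilon is not scaled (``include_stem=True`` scales
    it too).  Returns an array indexed by node id; entry 0 (root) is 0.
    """
    ups = _upsilon_array(tree, upsilon_map)
    acc = np.ones(tree.n_nodes)  # product of upsilons on root..node path
    eff = np.zeros(tree.n_nodes)
    acc[0] = ups[0]
    for i in range(1, tree.n_nodes):
        p = tree.parent[i]
        acc[i] = acc[p] * ups[i]
        eff[i] = tree.lengths[i] * (acc[i] if include_stem else acc[p])
    return eff


def variance_adjusted_times(tree: Phylogeny, upsilon_map,
                            include_stem: bool = False) -> np.ndarray:
    """Root-to-tip sums of effective branch lengths, T_i(upsilon).

    The 'equivalent number of years of evolution at the background
    Brownian variance' for each tip, in ``tree.tip_ids`` order.
    """
    eff = effective_branch_lengths(tree, upsilon_map, include_stem)
    depth = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        depth[i] = depth[tree.parent[i]] + eff[i]
    return depth[tree.tip_ids]


def expected_tip_means(tree: Phylogeny, state: FabricState,
                       include_stem: bool = False) -> np.ndarray:
    """Expected trait value per tip.

    mean_i = alpha + sum_{branches j on path(i)} beta_j * t_j
           + beta_g * T_i(upsilon),
    with *raw* branch lengths t_j in the directional sum.
    """
    state.validate(tree)
    off = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        off[i] = off[tree.parent[i]] + state.beta_map.get(i, 0.0) * tree.lengths[i]
    T = variance_adjusted_times(tree, state.upsilon_map, include_stem)
    return state.alpha + off[tree.tip_ids] + state.beta_g * T


def phylo_covariance(tree: Phylogeny, upsilon_map, sigma2: float,
                     include_stem: bool = False) -> np.ndarray:
    """Tip covariance V: V[i,i] = sigma2*T_i, V[i,k] = sigma2 * shared
    effective root-to-MRCA path length.  Directional effects do not enter.
    """
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    eff = effective_branch_lengths(tree, upsilon_map, include_stem)
    n = tree.n_tips
    slot = {t: j for j, t in enumerate(tree.tip_ids)}
    V = np.zeros((n, n))
    # every branch contributes its effective length to all tip pairs below it
    tipsets: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for i in tree.postorder:
        if tree.is_tip[i]:
            tipsets[i] = [slot[i]]
        else:
            tipsets[i] = [t for c in tree.children[i] for t in tipsets[c]]
        if i != tree.root and eff[i] != 0.0:
            idx = np.asarray(tipsets[i])
            V[np.ix_(idx, idx)] += eff[i]
    return sigma2 * V


def transform_tree(tree: Phylogeny, state: FabricState,
                   include_stem: bool = False) -> TransformedTree:
    """Bundle all derived quantities for a state (debugging / reporting)."""
    state.validate(tree)
    eff = effective_branch_lengths(tree, state.upsilon_map, include_stem)
    T = variance_adjusted_times(tree, state.upsilon_map, include_stem)
    V = phylo_covariance(tree, state.upsilon_map, state.sigma2, include_stem)
    off = expected_tip_means(tree, state, include_stem) - state.alpha \
        - state.beta_g * T
    return TransformedTree(effective_lengths=eff, T=T, V=V, mean_offsets=off)
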