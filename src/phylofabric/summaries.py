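"""Summary quantities for selected effects.

Fold changes translate a branch total beta*t (log10 units) back to the
un-logged scale: 10^{beta*t}, e.g. 0.73 -> 5.4-fold.  Path counts tally
how many effects of each sign a present-day species inherited along its
root-to-tip path.  Accumulation curves date each effect (a directional
effect at its branch midpoint, an evolvability effect at its node) and
relate the cumulative count to elapsed time and to the number of
concurrent lineages.  The directional-change variance expresses a
branch's shift as the per-unit-time variance a zero-mean Brownian
process would need for its mean-square displacement over the branch to
equal the shift; the formula is pluggable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .priors import f_upsilon_cutpoints
from .trees import Phylogeny

__all__ = ["fold_change", "path_effect_counts", "accumulation_curves",
           "directional_change_variance", "effect_summary",
           "lineages_at"]


def fold_change(beta_times_t):
    """10^{beta*t}: the ratio on the un-logged trait scale."""
    return np.power(10.0, beta_times_t)


def effect_summary(tree: Phylogeny, beta_map, upsilon_map) -> pd.DataFrame:
    """One row per selected effect with its derived quantities.

    Directional rows: branch, beta, t, beta*t, fold change, midpoint
    age.  Evolvability rows: node, upsilon, clade size n, node age and
    the clade-size-specific 5%/95% reference cut-points of the clade
    variance-ratio density.
    """
    depth = tree.node_depths()
    counts = tree.clade_tip_counts()
    rows = []
    for b, beta in sorted((beta_map or {}).items()):
        t = float(tree.lengths[b])
        x = beta * t
        rows.append({
            "kind": "beta", "location": b, "value": beta, "t": t,
            "beta_t": x, "fold_change": float(fold_change(x)),
            "age": float(depth[tree.parent[b]] + t / 2.0),
            "clade_tips": int(counts[b]),
            "cut_low": np.nan, "cut_high": np.nan,
        })
    for node, u in sorted((upsilon_map or {}).items()):
        n = int(counts[node])
        lo, hi = f_upsilon_cutpoints(n)
        rows.append({
            "kind": "upsilon", "location": node, "value": u,
            "t": float(tree.lengths[node]) if node != tree.root else 0.0,
            "beta_t": np.nan, "fold_change": np.nan,
            "age": float(depth[node]), "clade_tips": n,
            "cut_low": float(lo), "cut_high": float(hi),
        })
    return pd.DataFrame(rows, columns=[
        "kind", "location", "value", "t", "beta_t", "fold_change", "age",
        "clade_tips", "cut_low", "cut_high"])


def path_effect_counts(tree: Phylogeny, beta_map,
                       upsilon_map) -> pd.DataFrame:
    """Per tip: counts of beta>0, beta<0, upsilon>1, upsilon<1 inherited
    along the root-to-tip path."""
    beta_map = beta_map or {}
    upsilon_map = upsilon_map or {}
    cols = np.zeros((tree.n_nodes, 4), dtype=int)
    for i in range(1, tree.n_nodes):
        cols[i] = cols[tree.parent[i]]
        b = beta_map.get(i)
        if b is not None:
            cols[i, 0 if b > 0 else 1] += 1
    # an upsilon affects every tip of its clade: count upsilons at
    # ancestors-or-self of the path (its node included)
    ucols = np.zeros((tree.n_nodes, 2), dtype=int)
    for i in range(tree.n_nodes):
        if i > 0:
            ucols[i] = ucols[tree.parent[i]]
        u = upsilon_map.get(i)
        if u is not None:
            ucols[i, 0 if u > 1 else 1] += 1
    out = pd.DataFrame({
        "tip": tree.tip_labels,
        "n_beta_pos": cols[tree.tip_ids, 0],
        "n_beta_neg": cols[tree.tip_ids, 1],
        "n_upsilon_gt1": ucols[tree.tip_ids, 0],
        "n_upsilon_lt1": ucols[tree.tip_ids, 1],
    })
    return out


def lineages_at(tree: Phylogeny, tau: float) -> int:
    """Number of lineages (branches) alive at time ``tau`` from the root."""
    depth = tree.node_depths()
    n = 0
    for i in range(1, tree.n_nodes):
        if depth[tree.parent[i]] <= tau < depth[i]:
            n += 1
    if n == 0 and tau <= 0:
        n = len(tree.children[tree.root])
    return n


def accumulation_curves(tree: Phylogeny, beta_map, upsilon_map):
    """Cumulative effect count against time and concurrent lineage count.

    Directional effects are dated at their branch midpoint, evolvability
    effects at their node's age.  Returns ``(DataFrame, slope)`` where
    the frame holds (time, cumulative_count, lineages) sorted by time
    and the slope is the least-squares coefficient of cumulative count
    on lineage count (zero when there are no effects).
    """
    depth = tree.node_depths()
    events = []
    for b in (beta_map or {}):
        events.append(float(depth[tree.parent[b]] + tree.lengths[b] / 2.0))
    for node in (upsilon_map or {}):
        events.append(float(depth[node]))
    events.sort()
    rows = [(t_ev, k + 1, lineages_at(tree, t_ev))
            for k, t_ev in enumerate(events)]
    df = pd.DataFrame(rows, columns=["time", "cumulative_count", "lineages"])
    if len(df) >= 2 and df["lineages"].std() > 0:
        slope = float(np.polyfit(df["lineages"], df["cumulative_count"],
                                 1)[0])
    else:
        slope = 0.0
    return df, slope


def directional_change_variance(beta: float, t: float,
                                formula=None) -> float:
    """Variance-equivalent of a branch's directional change.

    Default: (beta*t)^2 / t, the per-unit-time variance whose
    mean-square displacement over t matches the shift.  ``formula`` may
    replace it with any callable ``(beta, t) -> float``.
    """
    if not t > 0:
        raise ValueError(f"branch length must be positive, got {t}")
    if formula is not None:
        return float(formula(beta, t))
    return float((beta * t) ** 2 / t)
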