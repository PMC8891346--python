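"""Phylogeny container and Newick / trait-table input-output.

Trees are stored in flat arrays indexed by a *node id* assigned in preorder
(root = 0), so the id of every node is strictly greater than its parent's.
A branch is identified by its child node; the root has no branch.  This
preorder convention makes node ids deterministic for a given Newick string
and lets downstream numerical code traverse the tree with plain loops.

Effect annotations (branch-wise directional effects ``beta``, node-wise
evolvability multipliers ``upsilon``) are carried in NHX-style bracketed
comments, e.g. ``A:1.5[&&NHX:beta=0.25]``, and round-trip exactly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    EffectLocationError,
    MissingBranchLengthError,
    NewickFormatError,
    TraitTableError,
)

__all__ = [
    "Phylogeny",
    "TraitTable",
    "read_newick",
    "read_annotated_newick",
    "read_traits",
    "write_newick",
    "write_annotated_newick",
]


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths, stored in preorder arrays.

    Attributes
    ----------
    parent : (n_nodes,) int array, parent id per node, -1 at the root.
    lengths : (n_nodes,) float array, branch length of the branch *above*
        each node (millions of years); 0.0 and unused at the root.
    labels : list of str, tip label per node ('' for internal nodes).
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list[str]

    # derived, filled in __post_init__
    children: list[list[int]] = field(default_factory=list, repr=False)
    postorder: np.ndarray = field(default=None, repr=False)
    tip_ids: np.ndarray = field(default=None, repr=False)
    is_tip: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.parent)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        if n == 0 or self.parent[0] != -1 or np.sum(self.parent < 0) != 1:
            raise ValueError("tree must have exactly one root with id 0")
        if np.any(self.lengths[1:] < 0):
            raise ValueError("negative branch lengths are not allowed")
        self.children = [[] for _ in range(n)]
        for i in range(1, n):
            if not self.parent[i] < i:
                raise ValueError("node ids must be in preorder")
            self.children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self.tip_ids = np.flatnonzero(self.is_tip)
        labs = [self.labels[i] for i in self.tip_ids]
        if len(set(labs)) != len(labs):
            raise ValueError("tip labels must be unique")
        # iterative postorder (children before parents): reversed preorder
        # works because every child id exceeds its parent's id.
        self.postorder = np.arange(n - 1, -1, -1, dtype=np.int64)
        # CSR children layout for numba kernels
        self._child_ptr = np.zeros(n + 1, dtype=np.int64)
        for i in range(n):
            self._child_ptr[i + 1] = self._child_ptr[i] + len(self.children[i])
        self._child_idx = np.concatenate(
            [np.asarray(c, dtype=np.int64) for c in self.children if c]
        ) if n > 1 else np.zeros(0, dtype=np.int64)

    # -- basic properties ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return 0

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def branches(self) -> np.ndarray:
        """Ids of all branches (every node except the root)."""
        return np.arange(1, self.n_nodes, dtype=np.int64)

    def internal_nodes(self, include_root: bool = True) -> list[int]:
        nodes = [i for i in range(self.n_nodes) if not self.is_tip[i]]
        return nodes if include_root else [i for i in nodes if i != 0]

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length (raw branch lengths) per node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.lengths[i]
        return d

    def clade_tip_counts(self) -> np.ndarray:
        """Number of descendant tips per node (a tip counts itself)."""
        c = np.where(self.is_tip, 1, 0).astype(np.int64)
        for i in self.postorder:
            p = self.parent[i]
            if p >= 0:
                c[p] += c[i]
        return c

    def clade_tips(self, node: int) -> np.ndarray:
        """Tip ids descending from ``node`` (inclusive if node is a tip)."""
        stack, out = [node], []
        while stack:
            k = stack.pop()
            if self.is_tip[k]:
                out.append(k)
            else:
                stack.extend(self.children[k])
        return np.array(sorted(out), dtype=np.int64)

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> position in ``tip_ids`` order."""
        return {self.labels[t]: j for j, t in enumerate(self.tip_ids)}


def _from_dendropy(dtree: dendropy.Tree) -> tuple[Phylogeny, dict, dict]:
    """Convert a dendropy tree; also harvest NHX beta/upsilon comments."""
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    lengths = np.zeros(len(nodes))
    labels = [""] * len(nodes)
    beta_map: dict[int, float] = {}
    upsilon_map: dict[int, float] = {}
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else f"internal node {i}"
                raise MissingBranchLengthError(
                    f"branch above {who!r} has no length; branch lengths are "
                    "required on all non-root edges"
                )
            lengths[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
        for comment in nd.comments:
            if not comment.startswith("&&NHX"):
                continue
            for item in comment.split(":")[1:]:
                key, _, val = item.partition("=")
                if key == "beta":
                    beta_map[i] = float(val)
                elif key == "upsilon":
                    upsilon_map[i] = float(val)
    tree = Phylogeny(parent=parent, lengths=lengths, labels=labels)
    return tree, beta_map, upsilon_map


def _parse(text: str) -> tuple[Phylogeny, dict, dict]:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickFormatError(f"invalid Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Polytomies are preserved; node ids are assigned in preorder and are
    therefore deterministic for a given input string.  Every non-root edge
    must carry a branch length.
    """
    return _parse(text)[0]


def read_annotated_newick(text: str):
    """Parse Newick with NHX effect tags.

    Returns ``(tree, beta_map, upsilon_map)`` where the maps are keyed by
    node id (a beta on the branch above the node; an upsilon at the node).
    """
    return _parse(text)


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_newick(tree: Phylogeny, beta_map=None, upsilon_map=None) -> str:
    """Serialize a tree to Newick, optionally with NHX effect tags.

    Tags are emitted after the branch length, e.g. ``A:1[&&NHX:beta=0.5]``;
    an upsilon at the root (which has no branch) is tagged directly on the
    root node.  ``read_annotated_newick`` recovers them exactly.
    """
    beta_map = dict(beta_map or {})
    upsilon_map = dict(upsilon_map or {})
    for node in list(beta_map) + list(upsilon_map):
        if not 0 <= node < tree.n_nodes:
            raise EffectLocationError(f"effect references unknown node {node}")
    if 0 in beta_map:
        raise EffectLocationError("beta cannot be placed on the root (no branch)")

    def tag(i: int) -> str:
        items = []
        if i in beta_map:
            items.append(f"beta={_fmt(beta_map[i])}")
        if i in upsilon_map:
            items.append(f"upsilon={_fmt(upsilon_map[i])}")
        return "[&&NHX:" + ":".join(items) + "]" if items else ""

    def rec(i: int) -> str:
        if tree.is_tip[i]:
            body = tree.labels[i]
        else:
            body = "(" + ",".join(rec(c) for c in tree.children[i]) + ")"
            if tree.labels[i]:
                body += tree.labels[i]
        if i == tree.root:
            return body + tag(i)
        return body + ":" + _fmt(tree.lengths[i]) + tag(i)

    return rec(tree.root) + ";"


def write_annotated_newick(tree: Phylogeny, effects) -> str:
    """Serialize a tree with the effects of a fitted state.

    ``effects`` is any object with ``beta_map`` and ``upsilon_map``
    attributes (e.g. :class:`phylofabric.core.FabricState`) or a
    ``(beta_map, upsilon_map)`` pair.
    """
    if hasattr(effects, "beta_map"):
        return write_newick(tree, effects.beta_map, effects.upsilon_map)
    beta_map, upsilon_map = effects
    return write_newick(tree, beta_map, upsilon_map)


@dataclass
class TraitTable:
    """One continuous trait value per tip, keyed by tip label.

    Values are on the analysis scale (log10 units where the trait was
    transformed upstream).
    """

    values: dict[str, float]

    def __len__(self):
        return len(self.values)

    def bind(self, tree: Phylogeny) -> np.ndarray:
        """Return trait values ordered as ``tree.tip_ids``.

        Raises :class:`TraitTableError` if any tree tip lacks a value or
        any table label is absent from the tree.
        """
        labels = tree.tip_labels
        missing = [lab for lab in labels if lab not in self.values]
        if missing:
            raise TraitTableError(
                f"trait table is missing tree tips: {', '.join(sorted(missing))}"
            )
        extra = sorted(set(self.values) - set(labels))
        if extra:
            raise TraitTableError(
                f"trait table labels absent from tree: {', '.join(extra)}"
            )
        y = np.array([self.values[lab] for lab in labels], dtype=float)
        if not np.all(np.isfinite(y)):
            bad = [lab for lab, v in zip(labels, y) if not math.isfinite(v)]
            raise TraitTableError(f"non-finite trait values for: {', '.join(bad)}")
        return y


def read_traits(text: str) -> TraitTable:
    """Parse a two-column (label, value) delimited table.

    The delimiter (comma, tab or whitespace) is auto-detected and a header
    row is skipped if its second field is not numeric.  Duplicate labels
    and non-numeric values are errors.
    """
    try:
        df = pd.read_csv(io.StringIO(text), sep=None, engine="python",
                         header=None, comment="#", skip_blank_lines=True,
                         dtype=str)
    except Exception as exc:  # pandas raises several parser error types
        raise TraitTableError(f"cannot parse trait table: {exc}") from exc
    if df.shape[1] != 2:
        raise TraitTableError(
            f"expected 2 columns (label, value), found {df.shape[1]}"
        )
    rows = df.values.tolist()
    if rows:
        try:
            float(rows[0][1])
        except (TypeError, ValueError):
            rows = rows[1:]  # header row
    values: dict[str, float] = {}
    for lab, val in rows:
        lab = str(lab).strip()
        if lab in values:
            raise TraitTableError(f"duplicate tip label {lab!r}")
        try:
            values[lab] = float(val)
        except (TypeError, ValueError):
            raise TraitTableError(
                f"non-numeric trait value {val!r} for tip {lab!r}"
            ) from None
    if not values:
        raise TraitTableError("empty trait table")
    return TraitTable(values)
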