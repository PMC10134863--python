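"""Continuous-trait ancestral reconstruction under Brownian motion.

A trait evolving by Brownian motion (BM) on a rooted tree accumulates
independent Gaussian increments of variance sigma^2 * branch_length along each
edge.  Given observed tip values, the maximum-likelihood state at each
internal node has a closed form built from Felsenstein's independent
contrasts: the estimate at a node equals the root estimate obtained after
re-rooting the tree at that node, i.e. the inverse-path-length weighted
average of the information flowing in from each neighbouring subtree.  The
same pruning recursion yields the estimate's variance (up to the rate
sigma^2, itself estimated from the standardized contrasts), from which
normal-theory 95% intervals follow.

Trees are handled through dendropy; polytomies are resolved to binary with
near-zero branches and zero-length edges are nudged to a small fraction of
tree height so that contrasts are always defined.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree", "read_newick", "write_newick",
    "pic_contrasts", "anc_ml", "root_estimate", "AncestralEstimate",
    "recovery_metrics", "annotate_tree",
]

_Z95 = 1.959963984540054  # standard-normal 97.5% quantile


class Tree:
    """A rooted tree with branch lengths, wrapping a dendropy tree.

    Internal nodes without labels are assigned stable ids ``n<k>`` in
    preorder (``n0`` is the root).  ``binarize()`` resolves polytomies and
    replaces zero/missing branch lengths with ``1e-8 ×`` tree height.
    """

    def __init__(self, dtree: dendropy.Tree) -> None:
        self._t = dtree
        self._label_internals()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse errors
            raise ValueError(f"malformed Newick: {exc}") from exc
        dtree.is_rooted = True
        return cls(dtree)

    def _label_internals(self) -> None:
        k = 0
        for node in self._t.preorder_node_iter():
            if node.is_leaf():
                continue
            if not node.label:
                node.label = f"n{k}"
            k += 1

    # -- basic structure --------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def root(self) -> dendropy.Node:
        return self._t.seed_node

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._t.leaf_node_iter()]

    def internal_labels(self) -> list[str]:
        return [n.label for n in self._t.preorder_node_iter() if not n.is_leaf()]

    def n_tips(self) -> int:
        return len(self.tip_labels())

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        best = 0.0
        for leaf in self._t.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            best = max(best, d)
        return best

    def is_binary(self) -> bool:
        for node in self._t.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) != 2:
                if node is self.root and len(node.child_nodes()) == 2:
                    continue
                return False
        return True

    def binarize(self, min_fraction: float = 1e-8) -> "Tree":
        """Resolve polytomies and enforce strictly positive branch lengths."""
        self._t.resolve_polytomies()
        height = self.height()
        floor = min_fraction * (height if height > 0 else 1.0)
        for node in self._t.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None or node.edge.length <= 0:
                node.edge.length = floor
        self._label_internals()
        return self

    def require_branch_lengths(self) -> None:
        for node in self._t.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise ValueError(
                    f"missing branch length above node "
                    f"{node.taxon.label if node.is_leaf() else node.label!r}"
                )
            if node.edge.length <= 0:
                raise ValueError("non-positive branch length; call binarize() first")

    def to_newick(self) -> str:
        s = self._t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s if s.endswith(";") else s + ";"


def read_newick(source: str | os.PathLike) -> Tree:
    """Read a Newick tree from a file path or a literal Newick string."""
    text = str(source)
    if not text.lstrip().startswith("("):
        with open(source) as fh:
            text = fh.read()
    return Tree.from_newick(text)


def write_newick(tree: Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def _node_name(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def pic_contrasts(tree: Tree, traits: Mapping[str, float]
                  ) -> tuple[list[tuple[float, float]], float]:
    """Felsenstein's independent contrasts on a binary tree.

    Returns the ``n−1`` raw contrasts with their expected variances (in
    branch-length units) and the contrasts-based rate estimate
    ``sigma2_hat = Σ c_i²/v_i / (n−1)``.
    """
    if not tree.is_binary():
        raise ValueError("contrasts require a binary tree; call binarize()")
    tree.require_branch_lengths()
    missing = [t for t in tree.tip_labels() if t not in traits]
    if missing:
        raise KeyError(f"tips without trait values: {missing}")

    contrasts: list[tuple[float, float]] = []
    xhat: dict[int, float] = {}
    vhat: dict[int, float] = {}

    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            xhat[id(node)] = float(traits[node.taxon.label])
            vhat[id(node)] = float(node.edge.length or 0.0)
            continue
        c1, c2 = node.child_nodes()
        x1, v1 = xhat[id(c1)], vhat[id(c1)]
        x2, v2 = xhat[id(c2)], vhat[id(c2)]
        contrasts.append((x1 - x2, v1 + v2))
        xhat[id(node)] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        extra = (v1 * v2) / (v1 + v2)
        vhat[id(node)] = (node.edge.length or 0.0) + extra

    n = tree.n_tips()
    sigma2_hat = sum(c * c / v for c, v in contrasts) / (n - 1)
    return contrasts, sigma2_hat


# ---------------------------------------------------------------------------
# ML ancestral states
# ---------------------------------------------------------------------------

def _subtree_message(node: dendropy.Node, parent: dendropy.Node | None,
                     traits: Mapping[str, float]) -> tuple[float, float]:
    """(estimate, variance-distance) of the subtree hanging off ``node``,
    viewed from its edge toward ``parent`` (pruning on the unrooted graph)."""
    if node.is_leaf():
        return float(traits[node.taxon.label]), 0.0
    neighbours = []
    for child in node.child_nodes():
        if child is parent:
            continue
        x, v = _subtree_message(child, node, traits)
        neighbours.append((x, v + float(child.edge.length)))
    if node.parent_node is not None and node.parent_node is not parent:
        x, v = _subtree_message(node.parent_node, node, traits)
        neighbours.append((x, v + float(node.edge.length)))
    num = sum(x / v for x, v in neighbours)
    den = sum(1.0 / v for x, v in neighbours)
    return num / den, 1.0 / den


def _estimate_at(node: dendropy.Node, traits: Mapping[str, float]) -> tuple[float, float]:
    """ML state and variance factor (× sigma^2) at one internal node: combine the
    messages from every neighbouring subtree, inverse-variance weighted."""
    neighbours = []
    for child in node.child_nodes():
        x, v = _subtree_message(child, node, traits)
        neighbours.append((x, v + float(child.edge.length)))
    if node.parent_node is not None:
        x, v = _subtree_message(node.parent_node, node, traits)
        neighbours.append((x, v + float(node.edge.length)))
    num = sum(x / v for x, v in neighbours)
    den = sum(1.0 / v for x, v in neighbours)
    return num / den, 1.0 / den


@dataclass
class AncestralEstimate:
    """ML states at internal nodes with normal-theory uncertainty."""

    states: dict[str, float]
    variances: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    sigma2_hat: float

    def __getitem__(self, node_label: str) -> float:
        return self.states[node_label]


def root_estimate(tree: Tree, traits: Mapping[str, float]) -> tuple[float, float]:
    """Fast path: ML state and variance factor at the root only."""
    tree.require_branch_lengths()
    return _estimate_at(tree.root, traits)


def anc_ml(tree: Tree, traits: Mapping[str, float]) -> AncestralEstimate:
    """ML ancestral states at every internal node under Brownian motion.

    Each node's state equals the root estimate of the tree re-rooted at
    that node (the re-rooting/contrasts scheme of the classic ``fastAnc``
    estimator); variances are the corresponding pruning variances scaled by
    the contrasts rate estimate.
    """
    if not tree.is_binary():
        raise ValueError("anc_ml requires a binary tree; call binarize()")
    tree.require_branch_lengths()
    _, sigma2_hat = pic_contrasts(tree, traits)

    states: dict[str, float] = {}
    variances: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        x, vfac = _estimate_at(node, traits)
        var = sigma2_hat * vfac
        states[node.label] = x
        variances[node.label] = var
        half = _Z95 * math.sqrt(var)
        ci[node.label] = (x - half, x + half)
    if not all(map(math.isfinite, states.values())):
        raise ValueError("non-finite ancestral estimate")
    return AncestralEstimate(states=states, variances=variances,
                             ci95=ci, sigma2_hat=sigma2_hat)


def recovery_metrics(true_states: Mapping[str, float],
                     estimate: AncestralEstimate) -> tuple[float, float, float]:
    """(RMSE, bias, 95%-CI coverage) of estimates against known truth."""
    keys = sorted(true_states)
    if set(keys) != set(estimate.states):
        raise ValueError("node sets of truth and estimate differ")
    err = np.array([estimate.states[k] - true_states[k] for k in keys])
    inside = np.array([
        estimate.ci95[k][0] <= true_states[k] <= estimate.ci95[k][1]
        for k in keys
    ])
    return (float(np.sqrt(np.mean(err ** 2))), float(np.mean(err)),
            float(np.mean(inside)))


def annotate_tree(tree: Tree, estimate: AncestralEstimate
                  ) -> tuple[str, pd.DataFrame]:
    """Newick with internal labels set to the state (2 decimals) + node TSV."""
    copy = Tree.from_newick(tree.to_newick())
    for node in copy.dendropy_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label not in estimate.states:
            raise KeyError(f"no estimate for internal node {node.label!r}")
    rows = []
    for node in copy.dendropy_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        label = node.label
        state = estimate.states[label]
        rows.append({
            "node": label,
            "state": state,
            "variance": estimate.variances[label],
            "ci_lo": estimate.ci95[label][0],
            "ci_hi": estimate.ci95[label][1],
        })
        node.label = f"{state:.2f}"
    table = pd.DataFrame(rows, columns=["node", "state", "variance", "ci_lo", "ci_hi"])
    return copy.to_newick(), table
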