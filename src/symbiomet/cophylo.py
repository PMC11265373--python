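"""Strain clustering by metabolic profile and tanglegram entanglement.

Entanglement scores the disagreement between the leaf orders of two facing
trees over the same label set.  With leaves at positions 1..n in each tree,

    score = sum_i |pos_a(i) - pos_b(i)|^L / max_sum,   L = 1.5 by default,

where max_sum is the value attained when one order is the exact reversal of
the other.  Zero means the trees can be drawn with no crossing lines; one
means full entanglement.  Because leaf order is only defined up to rotations
of internal nodes, the reported score is minimised by an iterated two-sided
rotation search (rotate every internal node of one tree greedily, then the
other, until no improvement).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .ecology import jaccard_distance
from .tree import Phylogeny

__all__ = ["Dendrogram", "profile_dendrogram", "TanglegramResult", "entanglement"]


class _RNode:
    """Rotatable ordered tree node."""

    __slots__ = ("label", "children", "height")

    def __init__(self, label=None, children=None, height=0.0):
        self.label = label
        self.children = children or []
        self.height = height

    @property
    def is_leaf(self):
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def internal_nodes(self) -> list["_RNode"]:
        out = []
        stack = [self]
        while stack:
            n = stack.pop()
            if not n.is_leaf:
                out.append(n)
                stack.extend(n.children)
        return out


@dataclass
class Dendrogram:
    """Rooted merge tree with heights, produced by hierarchical clustering."""

    root: _RNode
    labels: list[str]
    linkage_matrix: np.ndarray | None = None

    def leaf_order(self) -> list[str]:
        return self.root.leaves()

    @classmethod
    def from_linkage(cls, z: np.ndarray, labels: list[str]) -> "Dendrogram":
        scipy_root = to_tree(z)

        def convert(n) -> _RNode:
            if n.is_leaf():
                return _RNode(label=labels[n.id])
            return _RNode(children=[convert(n.left), convert(n.right)], height=n.dist)

        return cls(root=convert(scipy_root), labels=list(labels), linkage_matrix=z)

    @classmethod
    def from_phylogeny(cls, tree: Phylogeny) -> "Dendrogram":
        depths: dict[int, float] = {}

        def convert(node, depth) -> _RNode:
            if node.is_leaf:
                return _RNode(label=node.label)
            children = [convert(c, depth + (c.length or 0.0)) for c in node.children]
            return _RNode(children=children, height=1.0)

        return cls(root=convert(tree.root, 0.0), labels=tree.tip_labels)


def profile_dendrogram(
    matrix: pd.DataFrame,
    metric: str = "correlation",
    method: str = "complete",
) -> Dendrogram:
    """Hierarchical clustering of strains by their binary family profiles.

    ``metric="correlation"`` uses d = 1 - Pearson r between profiles (a
    zero-variance profile has no defined correlation; such pairs are set to
    distance 1 and reported).  ``metric="jaccard"`` uses the family-set
    Jaccard distance.  ``method`` is "complete" or "upgma" (average linkage).
    """
    if len(matrix) < 2:
        raise ValueError("need at least two strains")
    labels = [str(x) for x in matrix.index]
    if metric == "correlation":
        x = matrix.to_numpy(dtype=float)
        sd = x.std(axis=1)
        degenerate = sd == 0
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(x)
        d = 1.0 - corr
        if degenerate.any():
            import warnings

            warnings.warn(
                f"zero-variance profiles {list(matrix.index[degenerate])}: distance set to 1",
                stacklevel=2,
            )
            d[degenerate, :] = 1.0
            d[:, degenerate] = 1.0
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
        d = (d + d.T) / 2.0
    elif metric == "jaccard":
        d = jaccard_distance(matrix).to_numpy()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    scipy_method = {"complete": "complete", "upgma": "average"}.get(method)
    if scipy_method is None:
        raise ValueError(f"unknown linkage {method!r}")
    z = linkage(squareform(d, checks=False), method=scipy_method)
    return Dendrogram.from_linkage(z, labels)


# ---------------------------------------------------------------------------
# entanglement
# ---------------------------------------------------------------------------

@dataclass
class TanglegramResult:
    entanglement: float
    order_a: list[str]
    order_b: list[str]
    norm_exponent: float
    optimized: bool


def _score(order_a: list[str], order_b: list[str], L: float, max_sum: float) -> float:
    pos_b = {lab: i for i, lab in enumerate(order_b)}
    total = sum(abs(i - pos_b[lab]) ** L for i, lab in enumerate(order_a))
    return total / max_sum if max_sum > 0 else 0.0


def _max_sum(n: int, L: float) -> float:
    return float(sum(abs(2 * i - (n - 1)) ** L for i in range(n)))


def _as_rtree(tree) -> _RNode:
    if isinstance(tree, Dendrogram):
        return tree.root
    if isinstance(tree, Phylogeny):
        return Dendrogram.from_phylogeny(tree).root
    if isinstance(tree, _RNode):
        return tree
    raise TypeError(f"cannot interpret {type(tree)!r} as a tree")


def entanglement(
    tree_a,
    tree_b,
    L: float = 1.5,
    optimize: bool = True,
    max_rounds: int = 20,
) -> TanglegramResult:
    """Post-optimisation entanglement between two trees on one label set."""
    ra, rb = _as_rtree(tree_a), _as_rtree(tree_b)
    set_a, set_b = set(ra.leaves()), set(rb.leaves())
    if set_a != set_b:
        raise ValueError(
            f"leaf label sets differ: only in A {sorted(set_a - set_b)}, "
            f"only in B {sorted(set_b - set_a)}"
        )
    n = len(set_a)
    max_sum = _max_sum(n, L)
    current = _score(ra.leaves(), rb.leaves(), L, max_sum)
    best = (current, ra.leaves(), rb.leaves())
    if optimize:
        # Two-sided rotation search.  Plateau (equal-score) moves are accepted
        # when they lead to an unvisited leaf-order state, which lets the
        # search traverse flat ridges (e.g. a root rotation that only becomes
        # profitable after a second rotation in the other tree); the best
        # state ever visited is returned.
        visited = {(tuple(best[1]), tuple(best[2]))}
        for _ in range(max_rounds):
            moved = False
            for tree in (ra, rb):
                for node in tree.internal_nodes():
                    node.children.reverse()
                    state = (tuple(ra.leaves()), tuple(rb.leaves()))
                    trial = _score(list(state[0]), list(state[1]), L, max_sum)
                    accept = trial < current - 1e-15 or (
                        trial < current + 1e-15 and state not in visited
                    )
                    if accept:
                        current = trial
                        visited.add(state)
                        moved = True
                        if trial < best[0] - 1e-15:
                            best = (trial, list(state[0]), list(state[1]))
                    else:
                        node.children.reverse()
            if not moved:
                break
    return TanglegramResult(
        entanglement=best[0],
        order_a=best[1],
        order_b=best[2],
        norm_exponent=L,
        optimized=optimize,
    )


def exhaustive_entanglement(tree_a, tree_b, L: float = 1.5) -> float:
    """Global minimum over all rotation states of both trees (small n only).

    Enumerates every combination of child-order reversals at every internal
    node; used as the oracle for the greedy search.
    """
    ra, rb = _as_rtree(tree_a), _as_rtree(tree_b)
    n = len(ra.leaves())
    max_sum = _max_sum(n, L)

    def all_orders(node: _RNode) -> list[list[str]]:
        if node.is_leaf:
            return [[node.label]]
        child_orders = [all_orders(c) for c in node.children]
        out = []
        for perm in itertools.permutations(range(len(node.children))):
            for combo in itertools.product(*(child_orders[i] for i in perm)):
                out.append([lab for part in combo for lab in part])
        seen, unique = set(), []
        for o in out:
            key = tuple(o)
            if key not in seen:
                seen.add(key)
                unique.append(o)
        return unique

    best = np.inf
    orders_b = all_orders(rb)
    for oa in all_orders(ra):
        for ob in orders_b:
            best = min(best, _score(oa, ob, L, max_sum))
    return float(best)
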