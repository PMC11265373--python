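"""Rooted phylogeny container shared by the simulation, ASR, and tanglegram code.

A deliberately small tree class: nodes carry a label, a branch length to the
parent, and an ordered child list.  Newick text is parsed with dendropy and
converted, so all format quirks (quoting, comments) are handled by an
established parser; serialisation back to Newick is canonical and loss-free
for labels and branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = ["Node", "Phylogeny"]

DEFAULT_BRANCH_LENGTH = 1.0


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    node_id: str | None = None  # stable id assigned by Phylogeny

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """Rooted tree with unique tip labels and non-negative branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._assign_ids()
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self.postorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length at node {node.node_id}")

    def _assign_ids(self) -> None:
        """Tips keep their label as id; internal nodes get N1.. in postorder."""
        counter = 0
        for node in self.postorder():
            if node.is_leaf:
                node.node_id = node.label
            else:
                counter += 1
                node.node_id = f"N{counter}"

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def node_by_id(self, node_id: str) -> Node:
        for n in self.postorder():
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def tip_set(self, node: Node) -> frozenset[str]:
        """Labels of the tips descending from (and including) ``node``."""
        if node.is_leaf:
            return frozenset([node.label])
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    # -- Newick ------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, default_length: float = DEFAULT_BRANCH_LENGTH) -> "Phylogeny":
        dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)
        missing = False

        def convert(dnode) -> Node:
            nonlocal missing
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            length = dnode.edge.length
            node = Node(label=label, length=length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            if not node.children and length is None:
                missing = True
                node.length = default_length
            elif length is None and node.children and dnode.parent_node is not None:
                missing = True
                node.length = default_length
            return node

        root = convert(dtree.seed_node)
        root.length = None
        if missing:
            warnings.warn(
                f"Newick branch lengths missing; defaulting to {default_length}",
                stacklevel=2,
            )
        if len(root.children) > 2:
            warnings.warn(
                "basal multifurcation treated as the root of a rooted tree",
                stacklevel=2,
            )
        return cls(root)

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node.length is not None:
                core += f":{node.length:.10g}"
            return core

        return fmt(self.root) + ";"

    # -- distances ---------------------------------------------------------
    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """Pairwise tip-to-tip path lengths (unordered pairs, both orders stored)."""
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)

        tips = self.tips()
        anc: dict[int, set[int]] = {}
        for t in tips:
            path = set()
            n: Node | None = t
            while n is not None:
                path.add(id(n))
                n = n.parent
            anc[id(t)] = path

        node_by_oid = {id(n): n for n in self.postorder()}
        out: dict[tuple[str, str], float] = {}
        for i, a in enumerate(tips):
            out[(a.label, a.label)] = 0.0
            for b in tips[i + 1:]:
                common = anc[id(a)] & anc[id(b)]
                mrca_depth = max(depth[oid] for oid in common)
                d = depth[id(a)] + depth[id(b)] - 2 * mrca_depth
                out[(a.label, b.label)] = d
                out[(b.label, a.label)] = d
        del node_by_oid
        return out
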