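"""In-memory phylogenetic tree with branch lengths and bootstrap supports.

A deliberately small node-based tree: the pipeline only needs leaf labels,
branch lengths, supports, rooting, depth queries and a canonical child
order that makes serialization bit-stable. Unrooted trees are represented
with a (usually trifurcating) top node and ``rooted=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TreeNode:
    """One tree node; ``length`` is the branch length to the parent."""

    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def min_leaf_label(self) -> str:
        return min(leaf.label or "" for leaf in self.leaves())

    def postorder(self) -> list["TreeNode"]:
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.postorder())
        out.append(self)
        return out


@dataclass
class PhyloTree:
    """Tree handle: a root node plus a rooted/unrooted flag."""

    root: TreeNode
    rooted: bool = False

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [leaf.label or "" for leaf in self.leaves()]

    def canonicalize(self) -> "PhyloTree":
        """Sort children everywhere by smallest descendant leaf label (in place)."""
        for node in self.root.postorder():
            if node.children:
                node.children.sort(key=lambda c: c.min_leaf_label())
        return self

    def depths(self) -> dict[int, float]:
        """Map ``id(node)`` to root-to-node path length."""
        out: dict[int, float] = {id(self.root): 0.0}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in node.children:
                out[id(c)] = out[id(node)] + c.length
                stack.append(c)
        return out

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(label=node.label, length=node.length, support=node.support)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, one frozenset per internal edge.

        Each split is normalised to the side that does NOT contain the
        lexicographically smallest leaf, so rooted and unrooted layouts of
        the same topology yield identical split sets.
        """
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(leaf.label or "" for leaf in node.leaves())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out
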