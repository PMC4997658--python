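"""Rooted phylogenetic trees: a light pointer-based structure.

The likelihood engine, the MCMC samplers and the parsimony mappers all
operate on this structure; Newick text is parsed through dendropy and
re-serialised deterministically here so that trace files are byte-stable.

Clades are represented as integer bitmasks over a fixed, sorted taxon
namespace, which makes monophyly checks, MRCA location and split counting
cheap and exact.
"""

from __future__ import annotations

import io
from typing import Iterator, Sequence

import dendropy

__all__ = ["Node", "Tree", "TreeError"]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length: float = length
        self.label: str | None = label

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def detach(self) -> "Node":
        """Remove this node (with its subtree) from its parent."""
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self


class Tree:
    """A rooted tree over a fixed taxon namespace.

    Parameters
    ----------
    root : Node
        Root of the tree; its ``length`` is ignored.
    """

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeError(f"could not parse Newick: {exc}") from exc

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        tree = cls(convert(dtree.seed_node))
        labels = [t.label for t in tree.tips()]
        if any(lab is None for lab in labels):
            raise TreeError("tree contains unlabeled tips")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        return tree

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, precision: int = 10, lengths: bool = True) -> str:
        out = io.StringIO()

        def write(node: Node) -> None:
            if node.children:
                out.write("(")
                for i, child in enumerate(node.children):
                    if i:
                        out.write(",")
                    write(child)
                out.write(")")
            if node.label is not None:
                out.write(node.label.replace(" ", "_"))
            if lengths and node.parent is not None:
                out.write(f":{node.length:.{precision}g}")

        write(self.root)
        out.write(";")
        return out.getvalue()

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    # ------------------------------------------------------------ traversal

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    # ----------------------------------------------------- clades & splits

    def taxon_index(self) -> dict[str, int]:
        """Stable label -> bit position map (sorted labels)."""
        return {lab: i for i, lab in enumerate(sorted(self.tip_labels()))}

    def clade_masks(self, index: dict[str, int] | None = None) -> dict[Node, int]:
        """Bitmask of the tip set below each node."""
        index = index or self.taxon_index()
        masks: dict[Node, int] = {}
        for node in self.postorder():
            if node.is_tip:
                masks[node] = 1 << index[node.label]
            else:
                m = 0
                for child in node.children:
                    m |= masks[child]
                masks[node] = m
        return masks

    def mrca(self, taxa: Sequence[str]) -> Node:
        """Most recent common ancestor of a set of tip labels."""
        index = self.taxon_index()
        try:
            target = 0
            for lab in taxa:
                target |= 1 << index[lab]
        except KeyError as exc:
            raise TreeError(f"taxon {exc} not in tree") from exc
        masks = self.clade_masks(index)
        best: Node | None = None
        for node in self.postorder():
            if masks[node] & target == target:
                # postorder: the first covering node is the MRCA
                best = node
                break
        assert best is not None
        return best

    def is_monophyletic(self, taxa: Sequence[str]) -> bool:
        index = self.taxon_index()
        target = 0
        for lab in taxa:
            target |= 1 << index[lab]
        masks = self.clade_masks(index)
        return target in masks.values()

    def splits(self, index: dict[str, int] | None = None) -> set[int]:
        """Nontrivial unrooted splits as canonical bitmasks.

        Each internal edge induces a bipartition; the side not containing
        bit 0 is the canonical representative, so splits are comparable
        across rootings of the same unrooted topology.
        """
        index = index or self.taxon_index()
        full = (1 << len(index)) - 1
        masks = self.clade_masks(index)
        out: set[int] = set()
        for node, m in masks.items():
            if node is self.root:
                continue
            side = m if not (m & 1) else (full & ~m)
            # trivial splits (single tip either side) excluded
            if bin(side).count("1") >= 2 and bin(full & ~side).count("1") >= 2:
                out.add(side)
        return out

    def unrooted_id(self) -> frozenset[int]:
        """Canonical identifier of the unrooted topology."""
        return frozenset(self.splits())

    def rooted_id(self) -> frozenset[int]:
        """Canonical identifier of the rooted topology (clade mask set)."""
        masks = self.clade_masks()
        return frozenset(m for n, m in masks.items() if not n.is_tip)

    # ------------------------------------------------------------- editing

    def suppress_unifurcations(self) -> None:
        """Collapse internal nodes with a single child, summing lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if not node.is_tip and len(node.children) == 1:
                    child = node.children[0]
                    if node.parent is None:
                        child.parent = None
                        child.length = 0.0
                        self.root = child
                    else:
                        parent = node.parent
                        idx = parent.children.index(node)
                        child.length += node.length
                        child.parent = parent
                        parent.children[idx] = child
                    changed = True

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree n_tips={self.n_tips}>"
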