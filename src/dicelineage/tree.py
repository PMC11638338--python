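"""Cell lineage trees: leaf-labelled phylogenies with Newick round-tripping.

The tree is stored rooted (a :class:`TreeNode` with children), but most
consumers treat it as unrooted: tree comparison and clade search work on
the set of leaf bipartitions induced by edges, which is invariant to the
root placement.  Newick parsing and serialisation are delegated to
dendropy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        self.children.append(child)
        return child


class CellLineageTree:
    """Leaf-labelled phylogeny over single cells.

    Inference output is fully resolved (binary, unrooted); input trees for
    evaluation may be multifurcating.  Leaf labels must be unique.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = self.leaf_names()
        if len(names) != len(set(names)):
            seen, dup = set(), None
            for n in names:
                if n in seen:
                    dup = n
                    break
                seen.add(n)
            raise ValueError(f"duplicate leaf label {dup!r}")
        if any(n is None for n in names):
            raise ValueError("every leaf must be labelled")

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- topology ------------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial leaf bipartitions of the unrooted topology.

        Each bipartition is canonicalised as the side that does not contain
        the lexicographically smallest leaf, so two trees on the same leaf
        set produce directly comparable sets.  Trivial splits (single leaf
        or whole set) are excluded; a degree-2 root does not contribute a
        duplicate split.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.name,))
            else:
                clade = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = clade
                if node is self.root:
                    continue
                if 1 < len(clade) < len(all_leaves) - 1:
                    side = clade if anchor not in clade else all_leaves - clade
                    splits.add(side)
        return splits

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets below every node of the rooted tree (incl. leaves/root)."""
        out: list[frozenset[str]] = []
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                clade = frozenset((node.name,))
            else:
                clade = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = clade
            out.append(clade)
        return out

    def cherries(self) -> list[tuple[str, str]]:
        """Leaf pairs that share a parent node (sibling cells).

        At a multifurcating node (including a degree-3 root of an unrooted
        tree) every pair of leaf children is a sibling pair.
        """
        out = []
        for node in self.postorder():
            if node.is_leaf:
                continue
            leaf_children = [c for c in node.children if c.is_leaf]
            for i in range(len(leaf_children)):
                for j in range(i + 1, len(leaf_children)):
                    out.append((leaf_children[i].name, leaf_children[j].name))
        return out

    def is_binary_unrooted(self) -> bool:
        """True if every internal node has unrooted degree 3 (root degree 3)."""
        for node in self.postorder():
            if node.is_leaf:
                continue
            degree = len(node.children) + (0 if node is self.root else 1)
            if degree != 3:
                return False
        return True

    # -- newick --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "CellLineageTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"invalid Newick: {exc}") from exc

        def convert(dnode) -> TreeNode:
            node = TreeNode(
                name=dnode.taxon.label if dnode.taxon is not None else None,
                length=dnode.edge.length,
            )
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def read(cls, path) -> "CellLineageTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def write(self, path, lengths: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(lengths=lengths) + "\n")

    def __repr__(self) -> str:
        return f"CellLineageTree(n_leaves={self.n_leaves})"


def read_newick(path) -> CellLineageTree:
    """Read a Newick file into a :class:`CellLineageTree`."""
    return CellLineageTree.read(path)


def write_newick(tree: CellLineageTree, path, lengths: bool = True) -> None:
    """Write ``tree`` to ``path`` in Newick format."""
    tree.write(path, lengths=lengths)
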