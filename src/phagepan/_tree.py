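"""Minimal rooted-tree structure shared by the clustering and phylogeny
modules (dendrograms with merge heights, NJ trees with branch lengths)."""

from __future__ import annotations

from typing import Callable, Iterator


class Node:
    __slots__ = ("name", "children", "length", "height", "au", "bp")

    def __init__(self, name: str | None = None, children: list["Node"] | None = None,
                 length: float = 0.0, height: float = 0.0):
        self.name = name
        self.children: list[Node] = children or []
        self.length = length      # branch length to parent
        self.height = height      # merge height (dendrograms)
        self.au: float | None = None
        self.bp: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaves())

    def clades(self, min_size: int = 2) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes with at least ``min_size`` leaves."""
        return {
            n.leaf_set() for n in self.walk()
            if not n.is_leaf and len(n.leaf_set()) >= min_size
        }

    def find_leaf(self, name: str) -> "Node | None":
        for n in self.walk():
            if n.is_leaf and n.name == name:
                return n
        return None

    def newick(self, lengths: bool = True,
               comment: Callable[["Node"], str] | None = None) -> str:
        return self._newick(lengths, comment) + ";"

    def _newick(self, lengths, comment) -> str:
        if self.is_leaf:
            s = self.name or ""
        else:
            s = "(" + ",".join(c._newick(lengths, comment) for c in self.children) + ")"
        if comment is not None and not self.is_leaf:
            c = comment(self)
            if c:
                s += f"[{c}]"
        if lengths:
            s += f":{self.length:.6g}"
        return s


def parent_map(root: Node) -> dict[int, Node]:
    """Map id(child) -> parent for path walking."""
    out: dict[int, Node] = {}
    for node in root.walk():
        for c in node.children:
            out[id(c)] = node
    return out
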