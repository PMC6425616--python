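"""Rooted binary trees and forests with the ancestry machinery used by reconciliation.

The species tree and every gene tree share one node-addressable container:
each node knows its parent, its (0 or 2) ordered children, and — for leaves —
its label.  On top of that the tree offers the primitives the duplication–loss
model is written in: the ancestry partial order, lowest common ancestors,
arc-distances between comparable nodes, and the iterated-parent map ``par^k``.

Note on ``par^k``: by convention ``par^0(x) = par(x)`` (one step up), not the
identity, and the parent of a root is the root itself, so ``par^k`` is total
and clamps at the root.  This is the convention the candidate bound of the
branch-and-bound solver is stated in; an identity-at-zero helper is
deliberately not exposed.

Newick parsing is delegated to dendropy; the containers here exist because the
solver needs cheap parent links and O(1) comparability tests (Euler intervals),
which dendropy's general-purpose trees do not prioritise.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy


class NewickError(ValueError):
    """Raised for malformed, non-binary, or otherwise unusable Newick input."""


class Node:
    """A node of a rooted binary tree.

    Leaves carry a ``label`` (unique within the forest).  Internal nodes may
    carry an optional ``name`` (e.g. a species-tree internal label); names play
    no role in the model, which is purely topological.
    """

    __slots__ = (
        "parent", "children", "label", "name", "tree",
        "depth", "tin", "tout", "_canonical",
    )

    def __init__(self, label: Optional[str] = None, name: Optional[str] = None):
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.label = label
        self.name = name
        self.tree: Optional["RootedTree"] = None
        self.depth = 0
        self.tin = -1
        self.tout = -1
        self._canonical: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def canonical_name(self) -> str:
        """Stable node identifier: the leaf label for leaves, else the sorted
        leaf-label set joined by ``|``.  Used in all reported outputs so that
        results do not depend on internal node ids."""
        if self._canonical is None:
            if self.is_leaf:
                self._canonical = self.label or ""
            else:
                self._canonical = "|".join(sorted(l.label for l in self.leaves()))
        return self._canonical

    @property
    def display_name(self) -> str:
        """Explicit name when present (species-tree internal labels), else the
        canonical leaf-set name."""
        return self.name if self.name else self.canonical_name

    def leaves(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                yield n
            else:
                stack.extend(reversed(n.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.display_name}>"


class RootedTree:
    """A rooted binary phylogenetic tree with precomputed ancestry indices."""

    def __init__(self, root: Node):
        self.root = root
        self._postorder: list[Node] = []
        self._reindex()

    # -- construction / indexing ------------------------------------------

    def _reindex(self) -> None:
        self._postorder = []
        timer = 0
        # iterative DFS computing depth, Euler intervals and postorder
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                node.tout = timer
                timer += 1
                self._postorder.append(node)
                continue
            node.tree = self
            node.depth = 0 if node.parent is None else node.parent.depth + 1
            node.tin = timer
            timer += 1
            stack.append((node, True))
            for c in reversed(node.children):
                stack.append((c, False))

    # -- basic traversals --------------------------------------------------

    def postorder(self) -> list[Node]:
        return list(self._postorder)

    def preorder(self) -> list[Node]:
        return sorted(self._postorder, key=lambda n: n.tin)

    @property
    def nodes(self) -> list[Node]:
        return list(self._postorder)

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self._postorder if n.is_leaf]

    def __len__(self) -> int:
        return len(self._postorder)

    # -- ancestry ----------------------------------------------------------

    def is_ancestor_or_equal(self, x: Node, y: Node) -> bool:
        """True iff ``y <= x`` in the ancestry order (x is an ancestor of y,
        possibly x == y)."""
        return x.tin <= y.tin and y.tout <= x.tout

    def comparable(self, x: Node, y: Node) -> bool:
        return self.is_ancestor_or_equal(x, y) or self.is_ancestor_or_equal(y, x)

    def par(self, x: Node) -> Node:
        """Parent of x, defined to be x itself when x is the root."""
        return x.parent if x.parent is not None else x

    def par_k(self, x: Node, k: int) -> Node:
        """k-th parent with ``par_k(x, 0) == par(x)``; clamps at the root."""
        if k < 0:
            raise ValueError("k must be non-negative")
        node = self.par(x)
        for _ in range(k):
            node = self.par(node)
        return node

    def lca(self, x: Node, y: Node) -> Node:
        if x.tree is not self or y.tree is not self:
            raise ValueError(
                "LCA is undefined for nodes belonging to different trees"
            )
        while x is not y:
            if x.depth > y.depth:
                x = x.parent
            elif y.depth > x.depth:
                y = y.parent
            else:
                x = x.parent
                y = y.parent
        return x

    def lca_set(self, nodes: Iterable[Node]) -> Node:
        it = iter(nodes)
        try:
            acc = next(it)
        except StopIteration:
            raise ValueError("LCA of an empty set is undefined")
        for n in it:
            acc = self.lca(acc, n)
        return acc

    def dist(self, x: Node, y: Node) -> int:
        """Number of arcs on the path from x down to y; requires y <= x."""
        if not self.is_ancestor_or_equal(x, y):
            raise ValueError(
                f"dist({x.display_name}, {y.display_name}): "
                "second node is not a descendant of the first"
            )
        return y.depth - x.depth

    # -- naming ------------------------------------------------------------

    def node_by_name(self, name: str) -> Node:
        """Look a node up by explicit name or canonical leaf-set name."""
        for n in self._postorder:
            if n.name == name or n.canonical_name == name or n.label == name:
                return n
        raise KeyError(f"no node named {name!r}")


class Forest:
    """A set of node-disjoint rooted binary trees with globally unique leaf labels."""

    def __init__(self, trees: list[RootedTree]):
        if not trees:
            raise ValueError("a forest must contain at least one tree")
        self.trees = trees
        self._leaf_by_label: dict[str, Node] = {}
        for t in trees:
            for leaf in t.leaves:
                if leaf.label is None:
                    raise NewickError("leaf without a label")
                if leaf.label in self._leaf_by_label:
                    raise NewickError(f"duplicate leaf label {leaf.label!r}")
                self._leaf_by_label[leaf.label] = leaf

    @property
    def nodes(self) -> list[Node]:
        return [n for t in self.trees for n in t.nodes]

    @property
    def leaves(self) -> list[Node]:
        return [n for t in self.trees for n in t.leaves]

    def postorder(self) -> list[Node]:
        return [n for t in self.trees for n in t.postorder()]

    def leaf(self, label: str) -> Node:
        return self._leaf_by_label[label]

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _convert(dnode: dendropy.Node, parent: Optional[Node]) -> Node:
    if dnode.is_leaf():
        if dnode.taxon is None or not dnode.taxon.label:
            raise NewickError("leaf without a label")
        node = Node(label=dnode.taxon.label)
    else:
        name = None
        if dnode.label:
            name = dnode.label
        elif dnode.taxon is not None and dnode.taxon.label:
            name = dnode.taxon.label
        node = Node(name=name)
    node.parent = parent
    kids = dnode.child_nodes()
    if kids and len(kids) != 2:
        where = node.name or "internal node"
        raise NewickError(
            f"non-binary node ({where} has out-degree {len(kids)}; "
            "all internal nodes must have exactly 2 children)"
        )
    for k in kids:
        node.children.append(_convert(k, node))
    return node


def parse_tree(text: str) -> RootedTree:
    """Parse a single rooted binary tree from Newick text.

    Branch lengths and internal labels are accepted; lengths are ignored
    (the model is topology-only) and internal labels are kept as optional
    node names.  Quoted labels are supported; underscores are preserved.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various error classes
        raise NewickError(f"Newick parse error: {exc}") from exc
    root = _convert(dtree.seed_node, None)
    tree = RootedTree(root)
    seen: set[str] = set()
    for leaf in tree.leaves:
        if leaf.label in seen:
            raise NewickError(f"duplicate leaf label {leaf.label!r}")
        seen.add(leaf.label)
    return tree


def parse_forest(text: str) -> Forest:
    """Parse a forest: one rooted binary tree per non-empty line."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise NewickError("empty Newick input (no trees)")
    trees = []
    for i, ln in enumerate(lines, start=1):
        try:
            trees.append(parse_tree(ln))
        except NewickError as exc:
            raise NewickError(f"line {i}: {exc}") from exc
    return Forest(trees)


def parse_newick(text: str, expect: str = "tree"):
    """Spec'd entry point: parse a tree (``expect='tree'``) or a multi-line
    forest (``expect='forest'``)."""
    if expect == "tree":
        return parse_tree(text)
    if expect == "forest":
        return parse_forest(text)
    raise ValueError("expect must be 'tree' or 'forest'")


def _write_node(node: Node, out: io.StringIO, annot=None) -> None:
    if node.is_leaf:
        out.write(node.label)
    else:
        out.write("(")
        for i, c in enumerate(node.children):
            if i:
                out.write(",")
            _write_node(c, out, annot)
        out.write(")")
        if node.name:
            out.write(node.name)
    if annot is not None:
        tag = annot(node)
        if tag:
            out.write(f"[&&{tag}]")


def write_newick(tree: RootedTree, annot=None) -> str:
    """Serialize to Newick.  ``annot(node)`` may return a comment tag appended
    as ``[&&...]`` after the node (used for per-node species/event output)."""
    out = io.StringIO()
    _write_node(tree.root, out, annot)
    out.write(";")
    return out.getvalue()


def write_forest(forest: Forest, annot=None) -> str:
    return "\n".join(write_newick(t, annot) for t in forest.trees) + "\n"
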