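"""Newick input and the canonical edge ordering.

Trees are rooted at the outermost Newick node regardless of whether the
input was written as rooted or unrooted; the root distribution of the
substitution model is placed there.  Polytomies (nodes of any degree) are
accepted.  Branch lengths are mandatory on every edge and are interpreted
as expected numbers of substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = [
    "Node",
    "Edge",
    "Tree",
    "NewickParseError",
    "TreeStructureError",
    "parse_newick",
    "edges_in_output_order",
]


class NewickParseError(ValueError):
    """Raised when the Newick text cannot be parsed or violates tree rules."""


class TreeStructureError(ValueError):
    """Raised when a structurally invalid tree is constructed."""


@dataclass
class Node:
    """A tree node; leaves carry a non-empty name, internal nodes may not."""

    name: str = ""
    children: list["Node"] = field(default_factory=list)
    length: float | None = None  # length of the edge above; None at the root

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __hash__(self) -> int:  # identity semantics: nodes are places in a tree
        return id(self)

    def __eq__(self, other: object) -> bool:
        return self is other


@dataclass(frozen=True)
class Edge:
    """A directed edge (parent -> child) with its branch length."""

    parent: Node
    child: Node
    length: float


class Tree:
    """A rooted tree with named leaves and branch lengths on every edge.

    Child order is the order in which children appeared in the Newick
    source; every ordering convention in the package (FASTA record order,
    parameter-file edge blocks, traversal for simulation) derives from it.
    """

    def __init__(self, root: Node, newick: str = ""):
        self.root = root
        self.newick = newick or self.to_newick()
        self._validate_and_index()

    # -- construction ------------------------------------------------------

    def _validate_and_index(self) -> None:
        self.nodes: list[Node] = list(self.preorder())
        self.leaves: list[Node] = [n for n in self.nodes if n.is_leaf]
        names = [n.name for n in self.leaves]
        if any(not n for n in names):
            raise TreeStructureError("every leaf must carry a non-empty name")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeStructureError(
                f"duplicate leaf names: {', '.join(sorted(dupes))}"
            )
        self.edges: list[Edge] = []
        self._edge_above: dict[Node, Edge] = {}
        for node in self.nodes:
            for child in node.children:
                if child.length is None:
                    raise TreeStructureError(
                        f"edge above {self._describe(child)} has no branch length"
                    )
                e = Edge(node, child, child.length)
                self.edges.append(e)
                self._edge_above[child] = e
        self._labels = self._assign_labels()

    def _assign_labels(self) -> dict[Node, str]:
        """Leaf label = its name; internal labels 'root', 'node1', ... pre-order."""
        labels: dict[Node, str] = {}
        counter = 0
        for node in self.nodes:
            if node.is_leaf:
                labels[node] = node.name
            elif node is self.root:
                labels[node] = "root"
            else:
                counter += 1
                labels[node] = f"node{counter}"
        return labels

    @staticmethod
    def _describe(node: Node) -> str:
        if node.is_leaf:
            return f"leaf '{node.name}'"
        tips = [n.name for n in _preorder(node) if n.is_leaf]
        return "clade (" + ",".join(tips) + ")"

    # -- queries -----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return _preorder(self.root)

    def leaf_names(self) -> list[str]:
        """Leaf names in Newick appearance order."""
        return [n.name for n in self.leaves]

    def edge_above(self, child: Node) -> Edge:
        return self._edge_above[child]

    def node_label(self, node: Node) -> str:
        return self._labels[node]

    def edge_label(self, edge: Edge) -> str:
        """Leaf edges are labelled by the leaf name, internal edges by path."""
        if edge.child.is_leaf:
            return edge.child.name
        return f"{self._labels[edge.parent]}->{self._labels[edge.child]}"

    def to_newick(self) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                core = node.name
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.length is not None:
                core += f":{node.length!r}"
            return core

        return render(self.root) + ";"


def _preorder(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def parse_newick(text: str, *, allow_zero_length: bool = False) -> Tree:
    """Parse a single Newick statement into a rooted :class:`Tree`.

    Every edge must carry a ``:length`` annotation with a positive, finite
    value (zero allowed only with ``allow_zero_length``).  An unrooted tree
    (outermost node of degree >= 3) is rooted at that outermost node.

    Raises
    ------
    NewickParseError
        On malformed syntax (with the position dendropy reports), a missing
        branch length, a duplicate leaf name, or a non-positive length.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick input")
    if not stripped.endswith(";"):
        stripped += ";"
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        children = [convert(c) for c in dnode.child_nodes()]
        if not children:
            name = dnode.taxon.label if dnode.taxon is not None else ""
            if not name:
                raise NewickParseError("leaf without a name in Newick input")
        else:
            name = ""  # internal labels are parsed but ignored
        return Node(name=name, children=children, length=dnode.edge.length)

    root = convert(dtree.seed_node)
    root.length = None  # a length on the outermost node has no edge to live on
    try:
        tree = Tree(root, newick=stripped)
    except TreeStructureError as exc:
        raise NewickParseError(str(exc)) from exc
    for edge in tree.edges:
        lo = 0.0 if allow_zero_length else None
        bad = (
            not _finite(edge.length)
            or edge.length < 0
            or (edge.length == 0 and not allow_zero_length)
        )
        del lo
        if bad:
            raise NewickParseError(
                f"branch length {edge.length!r} above "
                f"{Tree._describe(edge.child)} must be a positive finite number"
            )
    return tree


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def edges_in_output_order(tree: Tree) -> list[Edge]:
    """All edges once, in the order used for parameter output.

    Terminal edges come first, ordered by the appearance of their leaf in
    the Newick text; internal edges follow in breadth-first order from the
    root, siblings in Newick order.
    """
    terminal = [tree.edge_above(leaf) for leaf in tree.leaves]
    internal: list[Edge] = []
    queue = [tree.root]
    while queue:
        node = queue.pop(0)
        for child in node.children:
            if not child.is_leaf:
                internal.append(tree.edge_above(child))
                queue.append(child)
    return terminal + internal
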