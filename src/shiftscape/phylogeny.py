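"""Rooted phylogenies with branch lengths and the global time coordinate.

Trees are read from single-statement Newick strings (dendropy does the
lexing; validation and the simulator-facing structure live here).  Branch
lengths are in expected substitutions per position when the rate matrix is
normalized.  The "global time" of a point is its distance from the root; a
point on a branch is addressed as (child-node name, offset from the parent
end) with ``0 <= offset < branch_length``, so a point falling exactly on a
node belongs to the branches below that node.

Unnamed internal nodes are auto-named ``N1, N2, ...`` in breadth-first
order.  Branch lengths are required on every non-root edge; a bare number
where an internal node label would sit is rejected rather than silently
read as a name, since it is almost always a support value from a tool this
simulator has no use for.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = [
    "TreeNode",
    "Tree",
    "NewickError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "to_newick",
    "tree_stats",
    "bfs_order",
]

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class NewickError(ValueError):
    """Raised for malformed or unsupported Newick input."""


class TreeNode:
    """A node of a rooted tree; root has ``parent is None``."""

    __slots__ = ("name", "branch_length", "children", "parent")

    def __init__(self, name: str = "", branch_length: Optional[float] = None):
        self.name = name
        self.branch_length = branch_length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, bl={self.branch_length}, children={len(self.children)})"


class Tree:
    """A rooted tree plus name index and cached global times."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_names()
        self.node_index: dict[str, TreeNode] = {}
        for node in self.bfs():
            if node.name in self.node_index:
                raise NewickError(f"duplicate node name {node.name!r}")
            self.node_index[node.name] = node
        self.global_time: dict[str, float] = {}
        self.depth: dict[str, int] = {}
        for node in self.bfs():
            if node.parent is None:
                self.global_time[node.name] = 0.0
                self.depth[node.name] = 0
            else:
                self.global_time[node.name] = (
                    self.global_time[node.parent.name] + node.branch_length
                )
                self.depth[node.name] = self.depth[node.parent.name] + 1

    def _assign_names(self) -> None:
        used = {n.name for n in self.bfs() if n.name}
        counter = 1
        for node in self.bfs():
            if not node.name:
                while f"N{counter}" in used:
                    counter += 1
                node.name = f"N{counter}"
                used.add(node.name)

    def bfs(self) -> Iterator[TreeNode]:
        queue = [self.root]
        while queue:
            node = queue.pop(0)
            yield node
            queue.extend(node.children)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.bfs() if n.is_leaf]

    @property
    def total_branch_length(self) -> float:
        return sum(n.branch_length for n in self.bfs() if n.parent is not None)

    @property
    def height(self) -> float:
        return max(self.global_time[leaf.name] for leaf in self.leaves)


def bfs_order(tree: Tree) -> list[TreeNode]:
    """Nodes root-first, every parent before its children, siblings in input order."""
    return list(tree.bfs())


def tree_stats(tree: Tree) -> dict:
    """Leaf count, total branch length and height (max root-to-leaf distance)."""
    return {
        "leaf_count": len(tree.leaves),
        "total_branch_length": tree.total_branch_length,
        "height": tree.height,
    }


def _convert(dnode, validate_lengths: bool) -> TreeNode:
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
    else:
        name = dnode.label or ""
        if name and _NUMBER_RE.match(name):
            raise NewickError(
                f"internal node labelled with a bare number ({name!r}); support "
                "values are not accepted — remove them or quote the label"
            )
    node = TreeNode(name, dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_convert(child, validate_lengths))
    return node


def parse_newick(text: str) -> Tree:
    """Parse one rooted Newick statement into a :class:`Tree`.

    Every non-root edge must carry a branch length; lengths must be >= 0.
    Square-bracket comments are stripped and quoted labels are honoured.
    A leading ``name:length;`` statement (a single branch with no furcation)
    is read as a one-branch tree hanging off an implicit root.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"could not parse Newick: {exc}") from exc
    root = _convert(dtree.seed_node, validate_lengths=True)
    if root.is_leaf and root.branch_length is not None:
        # "A:1;" — a single branch; give it an explicit root so the branch
        # and its length take part in the simulation.
        new_root = TreeNode("")
        new_root.add_child(root)
        root = new_root
    root.branch_length = None  # root edge length, if any, is ignored

    def check(node: TreeNode, is_root: bool) -> None:
        if not is_root:
            label = node.name or "<unnamed>"
            if node.branch_length is None:
                raise NewickError(f"branch leading to {label!r} has no length")
            if node.branch_length < 0:
                raise NewickError(
                    f"branch leading to {label!r} has negative length {node.branch_length}"
                )
        for child in node.children:
            check(child, False)

    check(root, True)
    return Tree(root)


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


_QUOTE_TRIGGER = re.compile(r"[\s()\[\]{}:;,']")


def _format_name(name: str) -> str:
    if _QUOTE_TRIGGER.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _write_node(node: TreeNode, out: io.StringIO) -> None:
    if node.children:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _write_node(child, out)
        out.write(")")
    out.write(_format_name(node.name))
    if node.parent is not None:
        out.write(f":{node.branch_length:.17g}")


def to_newick(tree: Tree) -> str:
    out = io.StringIO()
    _write_node(tree.root, out)
    out.write(";")
    return out.getvalue()


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
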