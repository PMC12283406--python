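"""Lightweight rooted trees for colony phylogenies.

Branches carry mutation identifiers and up to three kinds of length:

* ``molecular`` -- number of mutations assigned to the branch,
* ``clock``     -- number of clock-like (e.g. SBS1+SBS5) mutations,
* ``time``      -- elapsed years, derived from node ages.

The root conventionally represents the zygote (all-reference outgroup) at
age 0 and carries no mutations on a branch of its own.
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeNode:
    """A node of a rooted tree; the branch above the node belongs to it."""

    __slots__ = ("name", "parent", "children", "time", "mutations",
                 "clock_count", "node_id")

    def __init__(self, name: str = "", time: Optional[float] = None):
        self.name = name
        self.parent: Optional["TreeNode"] = None
        self.children: list["TreeNode"] = []
        self.time = time          # years since zygote; None if unset
        self.mutations: list = []  # mutation ids on the branch above
        self.clock_count: Optional[float] = None
        self.node_id: Optional[int] = None

    # -- construction -------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    # -- queries ------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def path_from_root(self) -> list["TreeNode"]:
        """Nodes from the root down to (and including) this node."""
        path = []
        node: Optional[TreeNode] = self
        while node is not None:
            path.append(node)
            node = node.parent
        return list(reversed(path))

    def branch_length(self, length_type: str = "molecular") -> float:
        if length_type == "molecular":
            return float(len(self.mutations))
        if length_type == "clock":
            if self.clock_count is None:
                return float(len(self.mutations))
            return float(self.clock_count)
        if length_type == "time":
            if self.parent is None or self.time is None or self.parent.time is None:
                return 0.0
            return float(self.time - self.parent.time)
        raise ValueError(f"unknown length_type: {length_type!r}")

    def assign_ids(self) -> None:
        """Deterministic integer ids in preorder (root = 0)."""
        for i, node in enumerate(self.preorder()):
            node.node_id = i

    # -- newick -------------------------------------------------------
    def to_newick(self, length_type: Optional[str] = "molecular") -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = _quote(node.name)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + _quote(node.name)
            if length_type is None or node.parent is None:
                return core
            return f"{core}:{node.branch_length(length_type):.10g}"

        return fmt(self) + ";"


def _quote(name: str) -> str:
    if name and any(ch in name for ch in "(),:; \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode` tree.

    Parsed branch lengths are stored as cumulative node times (root at 0),
    so ``branch_length("time")`` round-trips whatever lengths were written.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0
    pending_len: dict[int, float] = {}

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                child, clen = parse_node()
                node.add_child(child)
                pending_len[id(child)] = clen
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character at {pos}: {s[pos]!r}")
        node.name = parse_label()
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            length = float(s[start:pos])
        return node, length

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        return s[start:pos]

    root, _ = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters in newick string")
    # convert pending branch lengths into cumulative node times
    root.time = 0.0
    for node in root.preorder():
        if node.parent is not None:
            node.time = (node.parent.time or 0.0) + pending_len.get(id(node), 0.0)
    return root


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Unweighted Robinson-Foulds distance on shared leaf sets."""
    la, lb = set(a.leaf_names()), set(b.leaf_names())
    if la != lb:
        raise ValueError("trees have different leaf sets")

    def splits(root: TreeNode) -> set[frozenset]:
        full = frozenset(root.leaf_names())
        out = set()
        for node in root.preorder():
            if node.parent is None or node.is_leaf:
                continue
            clade = frozenset(node.leaf_names())
            if 1 < len(clade) < len(full):
                out.add(clade)
        return out

    return len(splits(a) ^ splits(b))


def collapse_unsupported_edges(root: TreeNode) -> TreeNode:
    """Collapse internal edges carrying no mutations (in place).

    Zero-mutation internal edges are unidentifiable from genotype data, so
    comparisons between inferred and generating topologies are made on the
    mutation-supported resolution of the genealogy.
    """
    changed = True
    while changed:
        changed = False
        for node in list(root.preorder()):
            if node.parent is None or node.is_leaf:
                continue
            if len(node.mutations) == 0:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx:idx + 1] = node.children
                for c in node.children:
                    c.parent = parent
                changed = True
    return root
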