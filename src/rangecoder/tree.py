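"""Rooted dated trees: Newick parsing, node ages, ultrametricity checks.

Branch lengths are interpreted as time (Myr). A dated tree is ultrametric:
every tip sits at age 0 and internal node ages increase towards the root.
Ages are derived from root-to-node path lengths, so the parser itself makes
no ultrametricity assumption; :func:`check_ultrametric` enforces it where a
dated tree is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Relative tolerance (fraction of root age) for the ultrametricity check.
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Malformed Newick or invalid tree structure."""


@dataclass(eq=False)  # identity hashing: nodes are used as dict keys
class Node:
    name: str | None = None
    length: float | None = None  # branch length above this node; None at root
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    age: float = 0.0  # filled in by Tree._compute_ages

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Node({self.name!r}, age={self.age:.4g})"


class Tree:
    """A rooted tree with branch lengths and derived node ages."""

    def __init__(self, root: Node):
        self.root = root
        self._compute_ages()

    # -- traversals -------------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                out.append(node)
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            for c in reversed(node.children):
                stack.append(c)
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name or "" for n in self.tips()]

    @property
    def root_age(self) -> float:
        return self.root.age

    # -- ages -------------------------------------------------------------
    def _compute_ages(self) -> None:
        depth: dict[int, float] = {id(self.root): 0.0}
        max_depth = 0.0
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError(
                    f"node {node.name!r} has no branch length; dated trees "
                    "require lengths on every branch"
                )
            if node.length < 0:
                raise TreeError(f"negative branch length at {node.name!r}")
            d = depth[id(node.parent)] + node.length
            depth[id(node)] = d
            if node.is_tip and d > max_depth:
                max_depth = d
        for node in self.preorder():
            node.age = max_depth - depth[id(node)]

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"


def check_ultrametric(tree: Tree, rtol: float = ULTRAMETRIC_RTOL) -> None:
    """Raise :class:`TreeError` naming the most discordant tip pair if tip
    ages differ by more than ``rtol`` x root age."""
    tips = tree.tips()
    if len(tips) < 2:
        return
    lo = min(tips, key=lambda n: n.age)
    hi = max(tips, key=lambda n: n.age)
    scale = max(tree.root_age, 1e-300)
    if (hi.age - lo.age) > rtol * scale:
        raise TreeError(
            f"tree is not ultrametric: tips {hi.name!r} and {lo.name!r} differ "
            f"in age by {hi.age - lo.age:.6g} (root age {tree.root_age:.6g})"
        )


def parse_newick(text: str) -> Tree:
    """Parse a single Newick string (must end with ';')."""
    s = text.strip()
    if not s.endswith(";"):
        raise TreeError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> TreeError:
        return TreeError(f"Newick parse error at position {pos}: {msg}")

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if pos >= len(s):
                    raise error("unexpected end of input inside '('")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"expected ',' or ')', got {s[pos]!r}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            node.name = label
        # branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise error(f"bad branch length {s[start:pos]!r}") from None
        for c in node.children:
            c.parent = node
        return node

    root = parse_clade()
    if pos != len(s):
        raise error("trailing characters after tree")
    if root.is_tip and root.name is None:
        raise TreeError("empty Newick string")
    tree = Tree(root)
    names = tree.tip_names()
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    return tree
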