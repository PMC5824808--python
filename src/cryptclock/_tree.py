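"""Rooted phylogeny with branch annotations and Newick round-trip.

Annotations are written BEAST-style, ``name[&key=value,...]:length``, and
survive a write/read cycle. Trees are rooted; a top-level polytomy of
degree >= 3 is treated as an unrooted tree and rejected by the reader.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional


class TreeParseError(ValueError):
    """Malformed Newick; carries the character position of the failure."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _fmt(value) -> str:
    if isinstance(value, float):
        return format(value, ".9g")
    return str(value)


class Node:
    __slots__ = ("label", "length", "annotations", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.annotations: dict = {}
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def _newick(self) -> str:
        parts = ""
        if self.children:
            parts = "(" + ",".join(c._newick() for c in self.children) + ")"
        s = parts + (self.label or "")
        if self.annotations:
            s += "[&" + ",".join(f"{k}={_fmt(v)}" for k, v in sorted(self.annotations.items())) + "]"
        if self.length is not None:
            s += ":" + _fmt(self.length)
        return s


class Phylogeny:
    """A rooted tree whose tips carry sample labels.

    Branch lengths live on child nodes (length of the branch above the
    node); the root may carry a stem length.
    """

    def __init__(self, root: Node):
        self.root = root

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find(self, label: str) -> Node:
        for n in self.postorder():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not in tree")

    # -- properties ----------------------------------------------------
    @property
    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def depths(self) -> dict[Node, float]:
        """Root-to-node path length, ignoring any stem length on the root."""
        depth = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            depth[node] = depth[node.parent] + (node.length or 0.0)
        return depth

    def copy(self) -> "Phylogeny":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.annotations = dict(n.annotations)
            for c in n.children:
                m.add_child(clone(c))
            return m

        return Phylogeny(clone(self.root))

    def relabel(self, mapping: Callable[[str], str]) -> None:
        for n in self.postorder():
            if n.label is not None:
                n.label = mapping(n.label)

    def newick(self) -> str:
        return self.root._newick() + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({self.newick()})"


_TOKEN_END = set("(),:;[")


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick string (annotations allowed, see module doc)."""
    text = text.strip()
    pos = 0

    def error(msg):
        raise TreeParseError(msg, pos)

    def parse_annotations(node: Node):
        nonlocal pos
        if pos < len(text) and text[pos] == "[":
            close = text.find("]", pos)
            if close < 0:
                error("unterminated annotation block")
            body = text[pos + 1 : close].lstrip("&")
            pos = close + 1
            for item in body.split(","):
                if not item:
                    continue
                if "=" not in item:
                    error(f"annotation {item!r} lacks '='")
                key, _, val = item.partition("=")
                try:
                    node.annotations[key] = float(val)
                except ValueError:
                    node.annotations[key] = val

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in _TOKEN_END:
            pos += 1
        return text[start:pos].strip()

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos >= len(text):
            error("unexpected end of input")
        if text[pos] == "(":
            pos += 1
            node.add_child(parse_node())
            while pos < len(text) and text[pos] == ",":
                pos += 1
                node.add_child(parse_node())
            if pos >= len(text) or text[pos] != ")":
                error("expected ')'")
            pos += 1
        label = parse_label()
        node.label = label or None
        parse_annotations(node)
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and (text[pos] not in _TOKEN_END or text[pos] in "eE"):
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                error(f"bad branch length {text[start:pos]!r}")
            parse_annotations(node)
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        error("expected ';'")
    return Phylogeny(root)
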