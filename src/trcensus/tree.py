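"""Minimal rooted-tree structure with Newick (restricted dialect) I/O.

Dialect: unquoted node names only; branch lengths optional (absent means
0.0); names written to disk are sanitized by replacing ``();:, `` with
``_``. Internal node names are allowed and preserved.
"""

from __future__ import annotations

from typing import Iterator, List, Optional

from .errors import NewickParseError

_FORBIDDEN = set("();:, \t\n")


def sanitize_name(name: str) -> str:
    """Replace characters that are Newick syntax with underscores."""
    return "".join("_" if c in _FORBIDDEN else c for c in name)


class TreeNode:
    """A node of a rooted tree. ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0,
                 children: Optional[List["TreeNode"]] = None):
        self.name = name
        self.length = float(length)
        self.children: List[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        for child in children or []:
            self.add_child(child)

    # -- construction -----------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    # -- queries ----------------------------------------------------------
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
        out: List[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> List["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Optional["TreeNode"]:
        for node in self.preorder():
            if node.name == name:
                return node
        return None

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.name, self.length)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.name or '(internal)'} n_leaves={len(self.leaves())}>"


# -- serialization --------------------------------------------------------

def to_newick(root: TreeNode, include_lengths: bool = True,
              decimals: int = 6) -> str:
    """Serialize a tree to a Newick string (with trailing semicolon)."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            body = sanitize_name(node.name or "")
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            body = f"({inner})" + sanitize_name(node.name or "")
        if include_lengths and not is_root:
            body += f":{node.length:.{decimals}f}"
        return body

    return fmt(root, True) + ";"


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode`.

    Branch lengths are optional and default to 0.0. Raises
    :class:`NewickParseError` with the offending position on syntax errors.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick string", 0)
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def parse_name() -> str:
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in _FORBIDDEN:
            pos += 1
        return text[start:pos]

    def parse_length() -> float:
        nonlocal pos
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and (text[pos].isdigit()
                                       or text[pos] in ".-+eE"):
                pos += 1
            try:
                return float(text[start:pos])
            except ValueError:
                raise error("invalid branch length") from None
        return 0.0

    def parse_subtree() -> TreeNode:
        nonlocal pos
        if pos >= len(text):
            raise error("unexpected end of input")
        if text[pos] == "(":
            pos += 1
            node = TreeNode()
            node.add_child(parse_subtree())
            while pos < len(text) and text[pos] == ",":
                pos += 1
                node.add_child(parse_subtree())
            if pos >= len(text) or text[pos] != ")":
                raise error("unbalanced parentheses")
            pos += 1
            name = parse_name()
            node.name = name or None
            node.length = parse_length()
            return node
        name = parse_name()
        if not name:
            raise error("expected a node name")
        return TreeNode(name, parse_length())

    root = parse_subtree()
    if pos >= len(text) or text[pos] != ";":
        raise error("expected ';' at end of tree")
    pos += 1
    if text[pos:].strip():
        raise error("trailing characters after ';'")
    return root
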