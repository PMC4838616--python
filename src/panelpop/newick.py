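"""Rooted phylogenetic tree container and Newick serialization."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass
class TreeNode:
    """Node of a rooted tree; ``length`` is the branch to the parent.

    ``support`` is an integer bootstrap percentage attached to internal
    nodes (printed as the node label after the closing parenthesis).
    """

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def walk(self) -> Iterator["TreeNode"]:
        """Pre-order traversal with cycle detection."""
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise ValueError("cycle detected in tree")
            seen.add(id(node))
            yield node
            stack.extend(node.children)


#: Alias used throughout the pipeline API.
PhyloTree = TreeNode


def to_newick(tree: TreeNode, include_support: bool = True) -> str:
    """Serialize a rooted tree; internal-node labels carry bootstrap support."""
    list(tree.walk())  # raises on cycles

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if include_support and node.support is not None:
                body += str(int(node.support))
            elif node.name:
                body += node.name
        if is_root:
            return body
        return f"{body}:{node.length:.10g}"

    return fmt(tree, True) + ";"


def write_newick(tree: TreeNode, path, include_support: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, include_support=include_support) + "\n")


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string (names, branch lengths, internal labels)."""
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def parse() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = int(float(label))
                except ValueError:
                    node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    tree = parse()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at offset {pos}")
    return tree
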