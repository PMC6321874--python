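"""Guide phylogeny: Newick parsing, binarization, merge scheduling.

The guide tree only schedules the bottom-up pairwise merges: every
internal node combines the orthogroups of its two children, so the
tree must be rooted and binary.  Multifurcations are resolved into a
deterministic ladder before clustering.  Branch lengths are parsed and
preserved (the simulator uses them) but do not influence clustering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import dendropy


@dataclass(eq=False)
class TreeNode:
    node_id: str
    children: List["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    branch_length: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: List[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def min_leaf_name(self) -> str:
        return min(l.node_id for l in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.node_id!r}, {len(self.children)} children)"


@dataclass
class GuideTree:
    root: TreeNode

    @property
    def nodes(self) -> List[TreeNode]:
        """All nodes in post-order."""
        out: List[TreeNode] = []

        def walk(n: TreeNode) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    @property
    def leaf_names(self) -> List[str]:
        return sorted(l.node_id for l in self.root.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.nodes)

    def node_by_id(self) -> Dict[str, TreeNode]:
        return {n.node_id: n for n in self.nodes}

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                s = n.node_id
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")" + n.node_id
            if n.branch_length is not None:
                s += f":{n.branch_length:g}"
            return s

        return fmt(self.root) + ";"


def parse_newick(text: str) -> GuideTree:
    """Parse a semicolon-terminated Newick string into a guide tree.

    Branch lengths and internal labels are preserved; unlabeled
    internal nodes receive deterministic generated ids (``N0``,
    ``N1``, ... assigned in post-order).  Duplicate leaf names are a
    hard error.  Multifurcating trees parse; :func:`binarize` resolves
    them before scheduling.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        offset = getattr(exc, "column", None)
        loc = f" near character {offset}" if offset is not None else ""
        raise ValueError(f"unparseable Newick{loc}: {exc}") from exc

    counter = [0]

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        else:
            name = f"N{counter[0]}"
            counter[0] += 1
        node = TreeNode(
            node_id=name,
            children=children,
            branch_length=dnode.edge.length,
        )
        for c in children:
            c.parent = node
        return node

    root = convert(dtree.seed_node)
    leaf_names = [l.node_id for l in root.leaves()]
    dupes = sorted({n for n in leaf_names if leaf_names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf names in guide tree: {', '.join(dupes)}")
    return GuideTree(root=root)


def binarize(tree: GuideTree, seed: int = 0) -> GuideTree:
    """Resolve multifurcations into a deterministic binary ladder.

    Children of each multifurcating node are ordered lexicographically
    by their subtree's smallest leaf name, then combined left-to-right
    with zero-length inserted branches: ``(A,B,C)`` becomes
    ``((A,B),C)``.  Already-binary trees are returned unchanged (same
    node objects).  ``seed`` is accepted for interface stability but
    unused by the lexicographic policy.
    """
    if tree.is_binary():
        return tree

    counter = [0]
    existing = {n.node_id for n in tree.nodes}

    def fresh_id() -> str:
        while True:
            nid = f"B{counter[0]}"
            counter[0] += 1
            if nid not in existing:
                existing.add(nid)
                return nid

    def resolve(node: TreeNode) -> TreeNode:
        node.children = [resolve(c) for c in node.children]
        for c in node.children:
            c.parent = node
        if len(node.children) <= 2:
            return node
        ordered = sorted(node.children, key=lambda c: c.min_leaf_name())
        left = ordered[0]
        for nxt in ordered[1:-1]:
            joined = TreeNode(node_id=fresh_id(), children=[left, nxt], branch_length=0.0)
            left.parent = joined
            nxt.parent = joined
            left = joined
        node.children = [left, ordered[-1]]
        for c in node.children:
            c.parent = node
        return node

    return GuideTree(root=resolve(tree.root))


def postorder_schedule(tree: GuideTree) -> List[TreeNode]:
    """Internal nodes in merge order: each appears after both its
    children, the root last.  Deterministic: children are visited in
    lexicographic order of their smallest descendant leaf name."""
    if not tree.is_binary():
        raise ValueError("schedule requires a binary tree; call binarize() first")
    out: List[TreeNode] = []

    def walk(n: TreeNode) -> None:
        for c in sorted(n.children, key=lambda c: c.min_leaf_name()):
            walk(c)
        if not n.is_leaf:
            out.append(n)

    walk(tree.root)
    return out
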