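"""Lightweight rooted-tree view over dendropy, for simulation and pruning."""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class TreeNode:
    index: int
    parent: int | None
    edge_length: float
    label: str | None = None
    children: list[int] = field(default_factory=list)


class SimpleTree:
    """Flattened tree: node 0 is the root, children carry edge lengths."""

    def __init__(self, nodes: list[TreeNode]):
        self.nodes = nodes
        self.postorder = self._postorder()
        self.leaf_labels = [n.label for n in nodes if not n.children]

    @classmethod
    def from_newick(cls, newick: str, require_lengths: bool = True) -> "SimpleTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        nodes: list[TreeNode] = []
        index = {}
        for nd in tree.preorder_node_iter():
            parent = index[id(nd.parent_node)] if nd.parent_node is not None else None
            length = nd.edge.length
            if parent is not None and length is None:
                if require_lengths:
                    raise ValueError("tree has edges without branch lengths")
                length = 0.0
            label = nd.taxon.label if nd.taxon is not None else None
            node = TreeNode(len(nodes), parent, float(length or 0.0), label)
            index[id(nd)] = node.index
            nodes.append(node)
            if parent is not None:
                nodes[parent].children.append(node.index)
        if len(nodes) < 2:
            raise ValueError("tree must have at least two nodes")
        for n in nodes:
            if not n.children and n.label is None:
                raise ValueError("leaf without a taxon label")
        return cls(nodes)

    def _postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.nodes[i].children)
        order.reverse()
        return order

    def scaled(self, factor: float) -> "SimpleTree":
        nodes = [
            TreeNode(n.index, n.parent, n.edge_length * factor, n.label,
                     list(n.children))
            for n in self.nodes
        ]
        return SimpleTree(nodes)

    @property
    def total_length(self) -> float:
        return sum(n.edge_length for n in self.nodes if n.parent is not None)
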