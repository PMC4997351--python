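"""Ultrametric dated species trees (branch lengths in million years)."""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

#: great-ape species tree with splits at 11, 8 and 5 Mya
DEFAULT_GREAT_APE_NEWICK = (
    "(((Human:5,Chimpanzee:5)HC:3,Gorilla:8)HCG:3,Orangutan:11)ROOT;"
)

#: Human/Chimpanzee/Gorilla tree used for the coalescent runs
DEFAULT_HCG_NEWICK = "((Human:5,Chimpanzee:5)HC:3,Gorilla:8)HCG;"


@dataclass
class TreeNode:
    """One node of a dated tree; ``age`` is time before present in Myr."""

    name: str
    age: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class DatedTree:
    """Rooted ultrametric tree with node ages in million years."""

    root: TreeNode

    @property
    def root_age(self) -> float:
        return self.root.age

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def _walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                _walk(child)

        _walk(self.root)
        return out

    def tip_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def _walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for child in node.children:
                    _walk(child)

        _walk(self.root)
        return out

    @classmethod
    def from_newick(cls, newick: str, tol: float = 1e-6) -> "DatedTree":
        """Parse a newick string; validates ultrametricity of tip depths."""
        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def _depth(node) -> float:
            d = 0.0
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            return d

        depths = [_depth(leaf) for leaf in dtree.leaf_node_iter()]
        root_age = max(depths)
        if max(depths) - min(depths) > tol:
            raise ValueError(
                f"tree is not ultrametric: tip depths range "
                f"{min(depths):g}–{max(depths):g}"
            )

        counter = [0]

        def _convert(dnode, depth: float) -> TreeNode:
            if dnode.is_leaf():
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            else:
                counter[0] += 1
                name = f"anc{counter[0]}"
            node = TreeNode(name=name, age=root_age - depth)
            for child in dnode.child_nodes():
                node.children.append(_convert(child, depth + (child.edge.length or 0.0)))
            return node

        return cls(root=_convert(dtree.seed_node, 0.0))


def default_great_ape_tree() -> DatedTree:
    return DatedTree.from_newick(DEFAULT_GREAT_APE_NEWICK)
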