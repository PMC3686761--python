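"""Tree handling: newick I/O with foreground labels, pruning, array form.

Trees are carried as :class:`dendropy.Tree` objects at the interface. The
foreground branch of a branch-site analysis is marked in newick with the
codeml ``#1`` dialect: the label of the node *below* the foreground branch
carries a ``#1`` suffix, e.g. ``((dolphin#1,cow),dog);``. For likelihood
computation and simulation the tree is flattened into postorder index
arrays (:class:`ArrayTree`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

FOREGROUND_SUFFIX = "#1"


def parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


@dataclass
class LabeledTree:
    """A (possibly branch-lengthed) topology with at most one foreground branch.

    ``foreground`` names the node below the flagged branch: a leaf taxon
    label, or an internal node label. A tree used in a branch-site fit must
    have exactly one foreground branch; a freshly pruned tree may have none
    until the pipeline labels it.
    """

    tree: dendropy.Tree
    foreground: str | None = None

    @classmethod
    def from_newick(cls, newick: str) -> "LabeledTree":
        tree = parse_tree(newick)
        foreground = None
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon else node.label
            if label and label.endswith(FOREGROUND_SUFFIX):
                stripped = label[: -len(FOREGROUND_SUFFIX)]
                if foreground is not None:
                    raise ValueError("more than one foreground branch in newick")
                foreground = stripped
                if node.taxon:
                    node.taxon.label = stripped
                else:
                    node.label = stripped
        return cls(tree, foreground)

    def with_foreground(self, label: str) -> "LabeledTree":
        """Return a copy flagged on the branch above the node named `label`."""
        clone = self.tree.clone(depth=1)
        if label not in _node_labels(clone):
            raise ValueError(f"foreground label {label!r} not found in tree")
        return LabeledTree(clone, label)

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def has_branch_lengths(self) -> bool:
        return all(
            node.edge.length is not None
            for node in self.tree.preorder_node_iter()
            if node.parent_node is not None
        )

    def to_newick(self) -> str:
        return _write_newick(self.tree, self.foreground)


def _node_labels(tree: dendropy.Tree) -> set[str]:
    labels = set()
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label:
            labels.add(label)
    return labels


def _write_newick(tree: dendropy.Tree, foreground: str | None) -> str:
    def fmt(node) -> str:
        label = node.taxon.label if node.taxon else (node.label or "")
        if foreground is not None and label == foreground:
            label = label + FOREGROUND_SUFFIX
        if node.is_leaf():
            s = label
        else:
            s = "(" + ",".join(fmt(c) for c in node.child_nodes()) + ")" + label
        if node.parent_node is not None and node.edge.length is not None:
            s += f":{node.edge.length:.10g}"
        return s

    return fmt(tree.seed_node) + ";"


def prune_to_species(tree: dendropy.Tree, species: set[str]) -> dendropy.Tree:
    """Induced subtree on `species`: unary nodes suppressed, lengths additive.

    Path lengths between retained leaves are preserved when the input has
    branch lengths. Root placement is kept as induced; the time-reversible
    codon model is insensitive to it.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(species) - leaves)
    if missing:
        raise ValueError(f"species not in master tree: {missing}")
    if len(species) < 3:
        raise ValueError(f"need at least 3 species to build a tree, got {len(species)}")
    pruned = tree.extract_tree_with_taxa_labels(labels=set(species))
    pruned.purge_taxon_namespace()
    return pruned


@dataclass
class ArrayTree:
    """Postorder-indexed tree for vectorized likelihood and simulation.

    Node ``n_nodes - 1`` is the root; ``lengths[v]`` is the branch above node
    ``v`` (NaN when absent); ``foreground_node`` indexes the node below the
    foreground branch, or -1 when unlabeled.
    """

    parent: np.ndarray
    children: list[list[int]]
    lengths: np.ndarray
    leaf_names: dict[int, str]
    foreground_node: int = -1
    node_labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def has_lengths(self) -> bool:
        return not np.isnan(self.lengths[: self.root]).any()

    @classmethod
    def from_labeled(cls, lt: LabeledTree) -> "ArrayTree":
        nodes = list(lt.tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.intp)
        lengths = np.full(n, np.nan)
        children: list[list[int]] = [[] for _ in range(n)]
        leaf_names: dict[int, str] = {}
        node_labels: dict[int, str] = {}
        foreground_node = -1
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                parent[i] = index[id(node.parent_node)]
                children[parent[i]].append(i)
                if node.edge.length is not None:
                    lengths[i] = node.edge.length
            label = node.taxon.label if node.taxon else node.label
            if node.is_leaf():
                leaf_names[i] = label
            if label:
                node_labels[i] = label
                if lt.foreground is not None and label == lt.foreground:
                    foreground_node = i
        if lt.foreground is not None and foreground_node == -1:
            raise ValueError(f"foreground label {lt.foreground!r} not in tree")
        return cls(parent, children, lengths, leaf_names, foreground_node, node_labels)
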