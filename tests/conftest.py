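"""Shared fixtures and tree helpers for the test suite."""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pytest

from psgscan.trees import LabeledTree


def random_tree_newick(
    n_taxa: int,
    seed: int,
    max_branch: float = 0.5,
    min_branch: float = 0.02,
    leaf_lengths: dict[str, float] | None = None,
) -> str:
    """Random birth-death topology with branch lengths clipped to a sane range.

    `leaf_lengths` pins named terminal branches to stated lengths (used to
    give the foreground lineage a realistic, detectable branch length).
    """
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        taxon_namespace=tns,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(np.clip(edge.length, min_branch, max_branch))
    for leaf in tree.leaf_node_iter():
        override = (leaf_lengths or {}).get(leaf.taxon.label)
        if override is not None:
            leaf.edge.length = override
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


#: terminal branch length given to the foreground lineage in simulation
#: studies: ~0.3 expected substitutions per codon, long enough for the
#: branch-site test to have power while staying in a realistic mammalian range
FOREGROUND_BRANCH = 0.3


def labeled_random_tree(
    n_taxa: int,
    seed: int,
    foreground: str = "t0",
    foreground_length: float = FOREGROUND_BRANCH,
) -> LabeledTree:
    newick = random_tree_newick(
        n_taxa, seed, leaf_lengths={foreground: foreground_length}
    )
    return LabeledTree.from_newick(newick).with_foreground(foreground)


def canonical_topology(tree: dendropy.Tree) -> str:
    """Rotation-invariant topology string (lengths dropped) for comparisons."""

    def fmt(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        parts = sorted(fmt(c) for c in node.child_nodes())
        return "(" + ",".join(parts) + ")"

    return fmt(tree.seed_node)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
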