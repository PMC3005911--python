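"""Shared fixtures: tiny trees, scales, random instances, a brute-force oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from aaflux import SimulationConfig, load_scales, simulate_family
from aaflux.trees import Node, Tree, parse_newick


@pytest.fixture(scope="session")
def scales():
    return load_scales()


@pytest.fixture
def two_leaf_tree():
    return parse_newick("(L1:0.1,L2:0.2);")


@pytest.fixture
def five_leaf_tree():
    # (((x1,x2),(y1,y2)),out) with an outgroup leaf
    return parse_newick("(((x1:0.1,x2:0.1)nx:0.1,(y1:0.1,y2:0.1)ny:0.1)nin:0.1,out:0.3);")


def brute_force_parsimony(tree: Tree, leaf_states: dict[str, str], alphabet: str) -> int:
    """Minimum changes over ALL ancestral labelings, by exhaustive enumeration.

    Missing leaves (absent, '-', 'X') are free to take any state. Used as
    the independent oracle for the dynamic-programming implementation.
    """
    free = [
        n.index
        for n in tree.nodes
        if not n.is_leaf or leaf_states.get(n.name, "-") not in alphabet
    ]
    fixed = {
        n.index: leaf_states[n.name]
        for n in tree.nodes
        if n.is_leaf and leaf_states.get(n.name, "-") in alphabet
    }
    best = np.inf
    for combo in itertools.product(alphabet, repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        changes = sum(
            assign[n.index] != assign[n.parent] for n in tree.nodes[1:]
        )
        best = min(best, changes)
    return int(best)


def random_rooted_tree(rng: np.random.Generator, n_leaves: int) -> Tree:
    """Random rooted bifurcating tree with unit branch lengths."""
    names = [f"L{i}" for i in range(n_leaves)]
    nodes: list[Node] = []

    def build(members: list[str], parent: int | None) -> int:
        index = len(nodes)
        if len(members) == 1:
            nodes.append(Node(index=index, name=members[0], parent=parent, length=1.0))
            return index
        nodes.append(Node(index=index, name=f"i{index}", parent=parent, length=1.0))
        k = int(rng.integers(1, len(members)))
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        nodes[index].children.append(build(shuffled[:k], index))
        nodes[index].children.append(build(shuffled[k:], index))
        return index

    build(names, None)
    return Tree(nodes)


def random_parsimony_instance(rng: np.random.Generator, max_leaves: int = 7, n_states: int = 5):
    """A random (tree, leaf states, alphabet) triple for oracle comparison."""
    n_leaves = int(rng.integers(2, max_leaves + 1))
    tree = random_rooted_tree(rng, n_leaves)
    alphabet = "ACDEF"[:n_states]
    states = {}
    for leaf in tree.leaves():
        if rng.random() < 0.15:
            states[leaf.name] = "-"  # missing
        else:
            states[leaf.name] = alphabet[int(rng.integers(len(alphabet)))]
    return tree, states, alphabet


@pytest.fixture
def simulated_family():
    """One deterministic low-rate family with duplications and truth log."""
    cfg = SimulationConfig(seed=11, n_species=8, seq_length=150, sub_rate=0.03, dup_rate=0.1)
    aln, gtree, log = simulate_family(cfg)
    return cfg, aln, gtree, log
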