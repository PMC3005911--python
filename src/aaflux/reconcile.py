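"""Gene-tree/species-tree reconciliation by LCA mapping.

Each gene-tree node v is mapped to the species-tree node M(v): the species
of the gene for leaves, the species-tree LCA of the children's images for
internal nodes. A node is a duplication iff its image coincides with the
image of at least one child — equivalently, iff the species sets of its two
child subtrees overlap, i.e. paralogs (same-genome homologs) descend from
it. With the gene tree taken as correct this plain LCA mapping yields the
most parsimonious duplication placement.

Branch classes: every branch strictly below a duplication node belongs to
the ``duplicated`` class; the duplication node's own incoming branch and
everything basal to the most ancient duplication stay single-copy
(substitutions there are not more terminal than the duplication event).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConsistencyError
from .io_model import CONTEXTS, DuplicationRecord
from .trees import Tree

__all__ = [
    "ReconciledTree",
    "lca_reconcile",
    "reconcile_from_labels",
    "extract_duplications",
    "partition_branches",
]


@dataclass
class ReconciledTree:
    """Gene tree plus per-node event labels and species mapping.

    ``events[i]`` is ``"leaf"``, ``"speciation"`` or ``"duplication"`` for
    gene-tree node index i; ``mapping[i]`` is the species-tree node index
    (None when reconciliation was bypassed via pre-annotated labels).
    """

    tree: Tree
    events: dict[int, str]
    mapping: dict[int, int | None]

    def duplication_indices(self) -> list[int]:
        return [i for i, e in self.events.items() if e == "duplication"]

    @property
    def has_duplication(self) -> bool:
        return any(e == "duplication" for e in self.events.values())


def _species_lca(stree: Tree, a: int, b: int) -> int:
    ancestors = set(stree.path_to_root(a))
    i = b
    while i not in ancestors:
        i = stree.nodes[i].parent  # type: ignore[assignment]
    return i


def lca_reconcile(gene_tree: Tree, species_tree: Tree) -> ReconciledTree:
    """Label every internal gene-tree node as speciation or duplication."""
    sp_index = {n.name: n.index for n in species_tree.leaves()}
    mapping: dict[int, int | None] = {}
    events: dict[int, str] = {}
    for node in gene_tree.children_first():
        if node.is_leaf:
            if node.species not in sp_index:
                raise ConsistencyError(
                    f"gene {node.name!r} maps to species {node.species!r} "
                    "which is absent from the species tree"
                )
            mapping[node.index] = sp_index[node.species]
            events[node.index] = "leaf"
        else:
            m = mapping[node.children[0]]
            for c in node.children[1:]:
                m = _species_lca(species_tree, m, mapping[c])  # type: ignore[arg-type]
            mapping[node.index] = m
            dup = any(mapping[c] == m for c in node.children)
            events[node.index] = "duplication" if dup else "speciation"
    return ReconciledTree(tree=gene_tree, events=events, mapping=mapping)


def reconcile_from_labels(gene_tree: Tree, suffix: str = "D") -> ReconciledTree:
    """Bypass LCA mapping using pre-annotated internal labels.

    An internal node whose label ends with ``suffix`` (NOTUNG-style
    duplication tag) is taken as a duplication; all other internal nodes as
    speciations. No species mapping is computed.
    """
    events: dict[int, str] = {}
    mapping: dict[int, int | None] = {}
    for node in gene_tree.preorder():
        mapping[node.index] = None
        if node.is_leaf:
            events[node.index] = "leaf"
        else:
            events[node.index] = (
                "duplication" if node.name.endswith(suffix) else "speciation"
            )
    return ReconciledTree(tree=gene_tree, events=events, mapping=mapping)


def extract_duplications(rtree: ReconciledTree) -> list[DuplicationRecord]:
    """One record per duplication node, in preorder.

    ``clade1`` is the child subtree whose lexicographically smallest leaf
    label is smaller; each clade's branch set includes the child's own
    incoming branch. Terminal duplications are those whose both clades are
    single terminal branches. Substitution tallies are left at zero (filled
    by the metrics layer).
    """
    tree = rtree.tree
    out: list[DuplicationRecord] = []
    for i in sorted(rtree.duplication_indices()):
        node = tree.nodes[i]
        clades = []
        for c in node.children:
            idxs = tree.subtree_indices(c)
            branches = tuple(tree.nodes[j].name for j in sorted(idxs))
            ks = sum(tree.nodes[j].length for j in idxs)
            min_leaf = min(tree.nodes[j].name for j in idxs if tree.nodes[j].is_leaf)
            clades.append((min_leaf, branches, ks, len(idxs) == 1))
        clades.sort(key=lambda t: t[0])
        depth_ks = sum(tree.nodes[j].length for j in tree.path_to_root(i))
        out.append(
            DuplicationRecord(
                family_id="",
                dup_node_id=node.name,
                clade1_branches=clades[0][1],
                clade2_branches=clades[1][1],
                clade1_ks=clades[0][2],
                clade2_ks=clades[1][2],
                depth_ks=depth_ks,
                is_terminal=clades[0][3] and clades[1][3],
            )
        )
    return out


def partition_branches(rtree: ReconciledTree) -> dict[str, str]:
    """Map every branch (named by its child node) to its context class."""
    tree = rtree.tree
    has_dup = rtree.has_duplication
    single = CONTEXTS[1] if has_dup else CONTEXTS[0]
    contexts: dict[str, str] = {}
    # propagate a "below a duplication" flag down the preorder list
    below: dict[int, bool] = {0: False}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent = tree.nodes[node.parent]
        below[node.index] = below[node.parent] or (
            rtree.events[parent.index] == "duplication"
        )
        contexts[node.name] = "duplicated" if below[node.index] else single
    return contexts
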