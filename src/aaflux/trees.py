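"""Rooted-tree container used throughout the pipeline.

Trees are stored as a flat preorder list of :class:`Node` objects; a child's
index is always greater than its parent's, so iterating the list in reverse
visits children before parents (sufficient for all dynamic programs here).
Newick input is parsed with dendropy; output is serialized directly from the
node list so that internal-node labels and branch lengths round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterator

import dendropy

from .errors import FormatError

__all__ = ["Node", "Tree", "parse_newick", "default_species"]

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def default_species(gene_id: str) -> str:
    """Species id of a gene: prefix before the first ``|`` (fallback ``_``).

    Gene ids without either separator map to themselves, which treats each
    gene as its own species — convenient for species trees, harmless for
    gene trees with one gene per species.
    """
    if "|" in gene_id:
        return gene_id.split("|", 1)[0]
    if "_" in gene_id:
        return gene_id.split("_", 1)[0]
    return gene_id


@dataclass
class Node:
    index: int
    name: str
    parent: int | None
    length: float
    children: list[int] = field(default_factory=list)
    species: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree over a preorder node list (root at index 0)."""

    def __init__(self, nodes: list[Node]):
        if not nodes:
            raise FormatError("empty tree")
        self.nodes = nodes
        self.name_to_index = {n.name: n.index for n in nodes}
        if len(self.name_to_index) != len(nodes):
            seen: set[str] = set()
            dup = next(n.name for n in nodes if n.name in seen or seen.add(n.name))
            raise FormatError(f"duplicate node name in tree: {dup!r}")

    @property
    def root(self) -> Node:
        return self.nodes[0]

    def __len__(self) -> int:
        return len(self.nodes)

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.nodes if n.is_leaf}

    def preorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def children_first(self) -> Iterator[Node]:
        return reversed(self.nodes)

    def subtree_indices(self, index: int) -> list[int]:
        """All node indices in the subtree rooted at ``index`` (inclusive)."""
        out = [index]
        stack = list(self.nodes[index].children)
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.nodes[i].children)
        return out

    def path_to_root(self, index: int) -> list[int]:
        """Indices from ``index`` up to and including the root."""
        out = [index]
        while self.nodes[out[-1]].parent is not None:
            out.append(self.nodes[out[-1]].parent)
        return out

    def is_ancestor(self, anc: int, desc: int) -> bool:
        """True if ``anc`` is a proper ancestor of ``desc``."""
        i = self.nodes[desc].parent
        while i is not None:
            if i == anc:
                return True
            i = self.nodes[i].parent
        return False

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes[1:])

    # -- serialization ----------------------------------------------------

    def newick(self, lengths: bool = True) -> str:
        def label(n: Node) -> str:
            if _NEEDS_QUOTE.search(n.name):
                return "'" + n.name.replace("'", "''") + "'"
            return n.name

        def emit(i: int) -> str:
            n = self.nodes[i]
            s = label(n)
            if n.children:
                s = "(" + ",".join(emit(c) for c in n.children) + ")" + s
            if lengths and n.parent is not None:
                s += f":{n.length!r}"
            return s

        return emit(0) + ";"


def parse_newick(
    source: str,
    require_lengths: bool = True,
    species_fn: Callable[[str], str] | None = default_species,
) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    The basal node must be a bifurcation; a basal trifurcation denotes an
    unrooted tree and is rejected with instructions to supply a root.
    Internal labels are preserved; unlabeled internal nodes are named
    ``n<preorder-index>``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise FormatError(f"invalid Newick: {exc}") from exc
    seed = dtree.seed_node
    kids = seed.child_nodes()
    if len(kids) != 2:
        raise FormatError(
            f"tree basal node has {len(kids)} children; an unrooted (basal "
            "trifurcation) tree cannot be polarized — supply a rooted tree "
            "with a basal bifurcation"
        )

    nodes: list[Node] = []

    def build(dnode, parent: int | None) -> int:
        index = len(nodes)
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            if not name:
                raise FormatError("leaf without a label")
        else:
            name = dnode.label or f"n{index}"
        length = dnode.edge.length
        if parent is None:
            length = 0.0
        elif length is None:
            if require_lengths:
                raise FormatError(f"branch into {name!r} has no length")
            length = 0.0
        elif length < 0:
            raise FormatError(f"negative branch length into {name!r}")
        node = Node(index=index, name=str(name), parent=parent, length=float(length))
        if dnode.is_leaf() and species_fn is not None:
            node.species = species_fn(node.name)
        nodes.append(node)
        for child in dnode.child_nodes():
            node.children.append(build(child, index))
        return index

    build(seed, None)
    return Tree(nodes)
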