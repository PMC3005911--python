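"""Synthetic gene families with known duplication and substitution history.

The generator emulates the study system: a rooted species tree with branch
lengths in Ks units (synonymous substitutions per 4-fold degenerate site),
gene lineages duplicating as a Poisson birth process along those branches
(both copies survive — no gene loss, keeping the reconciliation oracle
exact), and 20-state Markovian sequence evolution with expected amino-acid
changes per site equal to ``sub_rate`` x branch length. The substitution
model is either symmetric-uniform or polarity-biased with off-diagonal
rates proportional to exp(-strength * (polarity(dest) - polarity(source))),
which favours polar -> non-polar changes for positive strength.

Defaults mirror a drosophilid-scale analysis: 12 species, per-branch Ks
around 0.1, Ka/Ks-like substitution intensity 0.1 per site per Ks unit,
duplication rate 0.05 per lineage per Ks unit. Every draw flows from the
mandatory seed; a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io_model import AMINO_ACIDS, FamilyAlignment
from .scales import load_polarity
from .trees import Node, Tree

__all__ = [
    "SimulationConfig",
    "TruthEvent",
    "TruthLog",
    "generate_species_tree",
    "biased_rate_matrix",
    "simulate_family",
    "inject_gap_blocks",
    "write_family",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated family; ``seed`` is mandatory."""

    seed: int
    species_tree: Tree | None = None
    n_species: int = 12
    mean_branch_ks: float = 0.1
    dup_rate: float = 0.05  # duplication births per lineage per Ks unit
    seq_length: int = 200
    sub_rate: float = 0.1  # expected amino-acid changes per site per Ks unit
    model: str = "symmetric"  # "symmetric" or "biased"
    bias_strength: float = 0.0
    family_id: str = "fam1"

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.sub_rate < 0 or self.bias_strength < 0:
            raise ConfigError("rates and bias strength must be non-negative")
        if self.model not in ("symmetric", "biased"):
            raise ConfigError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class TruthEvent:
    family_id: str
    site: int  # 1-based alignment column
    branch_id: str  # node whose incoming branch carries the event
    source_aa: str
    dest_aa: str
    time: float  # fraction of the branch traversed when the event fired


@dataclass
class TruthLog:
    events: list[TruthEvent] = field(default_factory=list)
    duplication_nodes: list[str] = field(default_factory=list)


def generate_species_tree(
    n_species: int, rng: np.random.Generator, mean_branch_ks: float = 0.1
) -> Tree:
    """Random rooted bifurcating species tree with Exp(mean) branch lengths.

    Topology by random sequential splitting of the species set; species are
    named ``spa``, ``spb``, ... so that gene ids ``spX|gN`` parse back to
    their species.
    """
    if n_species < 2:
        raise ConfigError("need at least 2 species")
    names = [f"sp{_alpha(i)}" for i in range(n_species)]
    nodes: list[Node] = []

    def build(members: list[str], parent: int | None) -> int:
        index = len(nodes)
        length = 0.0 if parent is None else float(rng.exponential(mean_branch_ks))
        if len(members) == 1:
            nodes.append(
                Node(index=index, name=members[0], parent=parent, length=length,
                     species=members[0])
            )
            return index
        nodes.append(Node(index=index, name=f"s{index}", parent=parent, length=length))
        k = int(rng.integers(1, len(members)))
        left, right = members[:k], members[k:]
        nodes[index].children.append(build(left, index))
        nodes[index].children.append(build(right, index))
        return index

    build(names, None)
    return Tree(nodes)


def _alpha(i: int) -> str:
    s = ""
    while True:
        s = chr(ord("a") + i % 26) + s
        i //= 26
        if i == 0:
            return s


def biased_rate_matrix(
    polarity: dict[str, float] | None = None, strength: float = 0.0
) -> np.ndarray:
    """20x20 rate generator with polarity-directed bias.

    rate(x -> y) is proportional to exp(-strength * (P(y) - P(x))); rows sum
    to zero through the diagonal, and the matrix is normalised so that the
    mean leaving rate over states is 1 (branch length x sub_rate is then the
    expected number of changes per site at a uniform state distribution).
    Strength 0 gives the symmetric-uniform model.
    """
    if strength < 0:
        raise ConfigError("bias strength must be non-negative")
    if polarity is None:
        polarity = load_polarity()
    pol = np.array([polarity[a] for a in AMINO_ACIDS])
    Q = np.exp(-strength * (pol[None, :] - pol[:, None]))
    np.fill_diagonal(Q, 0.0)
    leave = Q.sum(axis=1)
    Q /= leave.mean()
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# gene-tree growth
# ---------------------------------------------------------------------------


class _SimNode:
    __slots__ = ("name", "length", "children", "is_dup")

    def __init__(self, name: str, length: float):
        self.name = name
        self.length = length
        self.children: list[_SimNode] = []
        self.is_dup = False


def _grow_gene_tree(
    species_tree: Tree, dup_rate: float, rng: np.random.Generator
) -> tuple[_SimNode, list[str]]:
    """Grow the gene tree along the species tree; returns (root, dup names)."""
    counter = {"internal": 0, "gene": 0}
    dup_names: list[str] = []

    def new_internal() -> str:
        counter["internal"] += 1
        return f"n{counter['internal']}"

    def along_branch(sp_index: int, remaining: float, consumed: float) -> _SimNode:
        """One gene lineage entering the branch into species node sp_index."""
        wait = float(rng.exponential(1.0 / dup_rate)) if dup_rate > 0 else np.inf
        if wait < remaining:
            node = _SimNode(new_internal(), consumed + wait)
            node.is_dup = True
            dup_names.append(node.name)
            node.children.append(along_branch(sp_index, remaining - wait, 0.0))
            node.children.append(along_branch(sp_index, remaining - wait, 0.0))
            return node
        return at_species_node(sp_index, consumed + remaining)

    def at_species_node(sp_index: int, branch_len: float) -> _SimNode:
        sp = species_tree.nodes[sp_index]
        if sp.is_leaf:
            counter["gene"] += 1
            return _SimNode(f"{sp.name}|g{counter['gene']}", branch_len)
        node = _SimNode(new_internal(), branch_len)
        for c in sp.children:
            node.children.append(along_branch(c, species_tree.nodes[c].length, 0.0))
        return node

    root = at_species_node(0, 0.0)
    return root, dup_names


def _to_tree(sim_root: _SimNode) -> Tree:
    nodes: list[Node] = []

    def build(sn: _SimNode, parent: int | None) -> int:
        index = len(nodes)
        species = sn.name.split("|", 1)[0] if "|" in sn.name else None
        nodes.append(
            Node(index=index, name=sn.name, parent=parent, length=sn.length,
                 species=species)
        )
        for c in sn.children:
            nodes[index].children.append(build(c, index))
        return index

    build(sim_root, None)
    return Tree(nodes)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _evolve_site(
    state: int, t: float, Q: np.ndarray, rng: np.random.Generator
) -> list[tuple[float, int, int]]:
    """Gillespie walk of one site over time budget ``t``; returns jumps."""
    jumps: list[tuple[float, int, int]] = []
    clock = 0.0
    while True:
        leave = -Q[state, state]
        clock += float(rng.exponential(1.0 / leave))
        if clock >= t:
            return jumps
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        new = int(rng.choice(len(probs), p=probs))
        jumps.append((clock, state, new))
        state = new


def simulate_family(cfg: SimulationConfig) -> tuple[FamilyAlignment, Tree, TruthLog]:
    """Simulate one family: alignment, gene tree and complete truth log.

    The alignment is the gap-free leaf matrix (use
    :func:`inject_gap_blocks` to exercise the indel mask); the truth log
    carries every substitution with its branch, direction and within-branch
    time, plus the names of all true duplication nodes. When no species
    tree is supplied one is drawn and stored back on ``cfg.species_tree``
    so the caller can reconcile against it.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.species_tree is None:
        cfg.species_tree = generate_species_tree(cfg.n_species, rng, cfg.mean_branch_ks)
    stree = cfg.species_tree
    sim_root, dup_names = _grow_gene_tree(stree, cfg.dup_rate, rng)
    gtree = _to_tree(sim_root)
    strength = cfg.bias_strength if cfg.model == "biased" else 0.0
    Q = biased_rate_matrix(strength=strength)
    L = cfg.seq_length
    root_seq = rng.integers(0, len(AMINO_ACIDS), size=L)
    seqs: dict[int, np.ndarray] = {0: root_seq}
    log = TruthLog(duplication_nodes=list(dup_names))
    for node in gtree.preorder():
        if node.parent is None:
            continue
        parent_seq = seqs[node.parent]
        t = cfg.sub_rate * node.length
        seq = parent_seq.copy()
        if t > 0:
            for site0 in range(L):
                jumps = _evolve_site(int(seq[site0]), t, Q, rng)
                for clock, s, d in jumps:
                    log.events.append(
                        TruthEvent(
                            family_id=cfg.family_id,
                            site=site0 + 1,
                            branch_id=node.name,
                            source_aa=AMINO_ACIDS[s],
                            dest_aa=AMINO_ACIDS[d],
                            time=clock / t,
                        )
                    )
                if jumps:
                    seq[site0] = jumps[-1][2]
        seqs[node.index] = seq
    sequences = {
        n.name: "".join(AMINO_ACIDS[i] for i in seqs[n.index]) for n in gtree.leaves()
    }
    aln = FamilyAlignment(family_id=cfg.family_id, sequences=sequences)
    return aln, gtree, log


def inject_gap_blocks(
    aln: FamilyAlignment,
    block_lengths: Sequence[int],
    seed: int,
) -> tuple[FamilyAlignment, set[int]]:
    """Overwrite random alignment stretches with gap runs.

    One block per entry of ``block_lengths``, each placed in a random
    sequence at a random start, never overlapping or touching another
    block in the same sequence (so the expected mask is exactly the union
    of columns of blocks of length >= 2, returned 1-based).
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(aln.sequences)
    seqs = {g: list(s) for g, s in aln.sequences.items()}
    occupied: dict[str, set[int]] = {g: set() for g in gene_ids}
    expected: set[int] = set()
    for length in block_lengths:
        if length < 1 or length > aln.n_columns:
            raise ConfigError(f"gap block length {length} out of range")
        for _ in range(1000):
            gid = gene_ids[int(rng.integers(len(gene_ids)))]
            start = int(rng.integers(0, aln.n_columns - length + 1))
            span = set(range(start - 1, start + length + 1))  # block + flanks
            if span & occupied[gid]:
                continue
            for i in range(start, start + length):
                seqs[gid][i] = "-"
            occupied[gid].update(range(start, start + length))
            if length >= 2:
                expected.update(range(start + 1, start + length + 1))  # 1-based
            break
        else:
            raise ConfigError("could not place gap block without overlap")
    new = FamilyAlignment(
        family_id=aln.family_id,
        sequences={g: "".join(s) for g, s in seqs.items()},
    )
    return new, expected


def write_family(
    aln: FamilyAlignment, gtree: Tree, log: TruthLog, out_dir: str | Path
) -> None:
    """Write FASTA + Newick + truth TSVs for one simulated family."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = "".join(f">{g}\n{s}\n" for g, s in aln.sequences.items())
    (out / f"{aln.family_id}.fasta").write_text(fasta)
    (out / f"{aln.family_id}.nwk").write_text(gtree.newick() + "\n")
    lines = ["family_id\tsite\tbranch_id\tsource_aa\tdest_aa\ttime"]
    for e in log.events:
        lines.append(
            f"{e.family_id}\t{e.site}\t{e.branch_id}\t{e.source_aa}\t{e.dest_aa}\t{e.time:.6f}"
        )
    (out / f"{aln.family_id}.truth.tsv").write_text("\n".join(lines) + "\n")
    (out / f"{aln.family_id}.dups.txt").write_text(
        "\n".join(log.duplication_nodes) + ("\n" if log.duplication_nodes else "")
    )
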