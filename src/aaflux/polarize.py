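"""Parsimony polarization of amino-acid substitutions.

Per alignment column, unit-cost (Fitch) parsimony over the 20-state
amino-acid alphabet assigns ancestral states on the rooted gene tree.
Missing data (``-`` in retained columns, ``X``) is a wildcard carrying the
full state set at zero cost; a wildcard leaf therefore never nominates an
event on its own terminal branch (copying the parent state is always
strictly cheaper).

Every most parsimonious reconstruction (MPR) places exactly
``parsimony_score`` state changes on branches. An event — a (branch,
source->dest) pair — is *unambiguous* iff it is identical in every MPR;
this subsumes outgroup polarization on a rooted tree, and in particular a
single change straddling the root is always ambiguous (its direction flips
between the root's two child branches across co-optimal reconstructions).

Classification does not require enumerating MPRs: inside/outside
dynamic-programming marginals give, exactly, the set of events possible on
each branch and whether a branch changes state in every MPR. Enumeration
(capped, default 10,000 labelings) is provided for inspection and is
cross-checked against the marginals in the test suite.

Columns lying inside a run of two or more consecutive gaps in any sequence
are masked family-wide before any of this runs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ContractError
from .io_model import AMINO_ACIDS, FamilyAlignment, FamilyMeta, SubstitutionRecord
from .reconcile import ReconciledTree, extract_duplications, partition_branches
from .trees import Tree

__all__ = [
    "SiteMask",
    "MprSet",
    "mask_indel_regions",
    "fitch_score",
    "enumerate_mprs",
    "site_events",
    "polarize_site",
    "polarize_family",
]

logger = logging.getLogger(__name__)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_STATES = len(AMINO_ACIDS)
_BIG = 1 << 20
_GAP_RUN = re.compile(r"-{2,}")

Event = tuple[str, str, str]  # (branch_id, source_aa, dest_aa)


@dataclass
class SiteMask:
    """Boolean exclusion flag per alignment column (True = excluded)."""

    excluded: np.ndarray

    def __len__(self) -> int:
        return len(self.excluded)

    def __getitem__(self, site0: int) -> bool:
        return bool(self.excluded[site0])

    @property
    def n_unmasked(self) -> int:
        return int((~self.excluded).sum())

    def excluded_columns(self) -> set[int]:
        """1-based column numbers that are excluded."""
        return {int(i) + 1 for i in np.flatnonzero(self.excluded)}


def mask_indel_regions(aln: FamilyAlignment) -> SiteMask:
    """Exclude columns inside any run of >=2 consecutive gaps.

    Isolated single-gap columns are retained (the gap is then treated as
    missing data by the parsimony step).
    """
    excluded = np.zeros(aln.n_columns, dtype=bool)
    for seq in aln.sequences.values():
        for m in _GAP_RUN.finditer(seq):
            excluded[m.start() : m.end()] = True
    return SiteMask(excluded=excluded)


# ---------------------------------------------------------------------------
# per-site dynamic programming
# ---------------------------------------------------------------------------


def _leaf_state_vector(tree: Tree, leaf_states: Mapping[str, str]) -> list[int]:
    """Per node index: observed state index for leaves, -1 for wildcard/internal."""
    states = [-1] * len(tree)
    for node in tree.leaves():
        aa = leaf_states.get(node.name, "-")
        states[node.index] = AA_INDEX[aa] if aa in AA_INDEX else -1
    return states


def _down_costs(tree: Tree, states: list[int]) -> np.ndarray:
    """Sankoff vectors D[v, s] = min changes within subtree(v) given state s."""
    n = len(tree)
    D = np.zeros((n, N_STATES), dtype=np.int64)
    for node in tree.children_first():
        i = node.index
        if node.is_leaf:
            if states[i] >= 0:
                D[i, :] = _BIG
                D[i, states[i]] = 0
        else:
            acc = np.zeros(N_STATES, dtype=np.int64)
            for c in node.children:
                acc += np.minimum(D[c], D[c].min() + 1)
            D[i] = acc
    return D


def fitch_score(leaf_states: Mapping[str, str], tree: Tree) -> int:
    """Minimum number of state changes over all ancestral labelings.

    ``leaf_states`` maps leaf name -> residue; ``-``/``X`` (or an absent
    leaf) is missing data carrying the full 20-state set.
    """
    D = _down_costs(tree, _leaf_state_vector(tree, leaf_states))
    return int(D[0].min())


@dataclass
class MprSet:
    """All (or a capped prefix of) minimum-change ancestral labelings."""

    site: int | None
    parsimony_score: int
    labelings: list[dict[str, str]] = field(default_factory=list)
    cap_exceeded: bool = False

    def events_of(self, labeling: dict[str, str], tree: Tree) -> list[Event]:
        out: list[Event] = []
        for node in tree.nodes[1:]:
            s = labeling[tree.nodes[node.parent].name]
            t = labeling[node.name]
            if s != t:
                out.append((node.name, s, t))
        return out


def enumerate_mprs(
    leaf_states: Mapping[str, str],
    tree: Tree,
    cap: int = 10_000,
    site: int | None = None,
) -> MprSet:
    """Backtrack all distinct MPR labelings (truncated beyond ``cap``).

    Labelings assign a residue to every node, leaves included; a wildcard
    leaf copies its parent (any other choice costs an extra change).
    """
    states = _leaf_state_vector(tree, leaf_states)
    D = _down_costs(tree, states)
    score = int(D[0].min())
    root_choices = [int(s) for s in np.flatnonzero(D[0] == score)]
    labelings: list[dict[str, str]] = []
    cap_exceeded = False
    assignment = [0] * len(tree)

    def descend(order_pos: int) -> bool:
        """DFS over nodes in preorder; returns False once the cap is hit."""
        nonlocal cap_exceeded
        if order_pos == len(tree):
            labelings.append(
                {n.name: AMINO_ACIDS[assignment[n.index]] for n in tree.nodes}
            )
            if len(labelings) > cap:
                cap_exceeded = True
                labelings.pop()
                return False
            return True
        node = tree.nodes[order_pos]
        s = assignment[node.parent]
        col = D[order_pos]
        best = min(int(col[s]), int(col.min()) + 1)
        for t in range(N_STATES):
            if int(col[t]) + (1 if t != s else 0) == best:
                assignment[order_pos] = t
                if not descend(order_pos + 1):
                    return False
        return True

    for r in root_choices:
        assignment[0] = r
        if not descend(1):
            break
    return MprSet(
        site=site, parsimony_score=score, labelings=labelings, cap_exceeded=cap_exceeded
    )


@dataclass
class SiteEvents:
    """Exact per-branch event marginals for one column."""

    score: int
    unambiguous: list[Event]
    # every event possible in some MPR, keyed by branch, preorder-sorted
    possible: dict[str, list[tuple[str, str]]]

    def ambiguous_alternatives(self) -> list[Event]:
        unamb = set(self.unambiguous)
        out = [
            (b, s, t)
            for b, pairs in self.possible.items()
            for (s, t) in pairs
            if (b, s, t) not in unamb
        ]
        return out


def site_events(leaf_states: Mapping[str, str], tree: Tree) -> SiteEvents:
    """Classify the column's events via inside/outside DP marginals.

    For branch (v -> c) and states (s, t), the minimum total tree cost with
    v=s and c=t is ``out(v,s) + sibling terms + [s != t] + D(c,t)``; the
    event (c, s->t) occurs in some MPR iff that minimum equals the
    parsimony score, and in every MPR iff additionally no same-state pair
    on the branch attains the score and no other (s', t') does.
    """
    states = _leaf_state_vector(tree, leaf_states)
    D = _down_costs(tree, states)
    score = int(D[0].min())
    n = len(tree)
    # U[v, s]: min cost of everything outside subtree(v), incl. the branch
    # into v, given state(v) = s. Root: zeros.
    U = np.zeros((n, N_STATES), dtype=np.int64)
    base = np.zeros((n, N_STATES), dtype=np.int64)  # U[parent] + sibling terms
    for node in tree.preorder():
        if node.is_leaf:
            continue
        M = [np.minimum(D[c], D[c].min() + 1) for c in node.children]
        total = U[node.index] + sum(M)
        for k, c in enumerate(node.children):
            b = total - M[k]
            base[c] = b
            U[c] = np.minimum(b, b.min() + 1)

    unambiguous: list[Event] = []
    possible: dict[str, list[tuple[str, str]]] = {}
    for node in tree.nodes[1:]:
        c = node.index
        # joint cost J[s, t] = base[c][s] + [s != t] + D[c][t]
        J = base[c][:, None] + D[c][None, :] + (1 - np.eye(N_STATES, dtype=np.int64))
        hits = np.argwhere(J == score)
        ev = [(int(s), int(t)) for s, t in hits if s != t]
        if not ev:
            continue
        pairs = sorted((AMINO_ACIDS[s], AMINO_ACIDS[t]) for s, t in ev)
        possible[node.name] = pairs
        always = all(int(J[s, s]) > score for s in range(N_STATES))
        if always and len(pairs) == 1:
            unambiguous.append((node.name, pairs[0][0], pairs[0][1]))
    return SiteEvents(score=score, unambiguous=unambiguous, possible=possible)


# ---------------------------------------------------------------------------
# record emission
# ---------------------------------------------------------------------------


def polarize_site(
    leaf_states: Mapping[str, str],
    tree: Tree,
    site: int,
    family_id: str = "",
    mask: SiteMask | None = None,
) -> list[SubstitutionRecord]:
    """Emit the column's substitution records (``site`` is 1-based).

    Exactly ``parsimony_score`` records are emitted: one per event that is
    identical across all MPRs (unambiguous), plus one ambiguous record per
    remaining event slot, each carrying the full list of non-universal
    alternatives. Records are ordered by branch preorder index, then
    residue pair; ambiguous records follow unambiguous ones.
    """
    if mask is not None and mask[site - 1]:
        raise ContractError(f"site {site} is masked; polarize_site requires unmasked")
    ev = site_events(leaf_states, tree)
    preorder = {n.name: n.index for n in tree.nodes}
    records: list[SubstitutionRecord] = []
    for b, s, t in sorted(ev.unambiguous, key=lambda e: (preorder[e[0]], e[1], e[2])):
        records.append(
            SubstitutionRecord(
                family_id=family_id,
                site=site,
                source_aa=s,
                dest_aa=t,
                branch_id=b,
                ambiguous=False,
            )
        )
    n_ambiguous = ev.score - len(ev.unambiguous)
    if n_ambiguous:
        alts = tuple(
            sorted(
                ev.ambiguous_alternatives(),
                key=lambda e: (preorder[e[0]], e[1], e[2]),
            )
        )
        b0, s0, t0 = alts[0]
        for _ in range(n_ambiguous):
            records.append(
                SubstitutionRecord(
                    family_id=family_id,
                    site=site,
                    source_aa=s0,
                    dest_aa=t0,
                    branch_id=b0,
                    ambiguous=True,
                    alternatives=alts,
                )
            )
    return records


def polarize_family(
    aln: FamilyAlignment,
    rtree: ReconciledTree,
    mask: SiteMask | None = None,
) -> tuple[list[SubstitutionRecord], FamilyMeta]:
    """Polarize every unmasked column and tag records with their context.

    Context (single-copy vs duplicated) and containing duplication clades
    are assigned from the record's ``branch_id``; for ambiguous records
    that is the first alternative in deterministic order.
    """
    tree = rtree.tree
    if mask is None:
        mask = mask_indel_regions(aln)
    contexts = partition_branches(rtree)
    dups = extract_duplications(rtree)
    records: list[SubstitutionRecord] = []
    n_sites_with_sub = 0
    for site0 in range(aln.n_columns):
        if mask[site0]:
            continue
        column = aln.column(site0)
        observed = {a for a in column.values() if a in AA_INDEX}
        if len(observed) < 2:
            continue  # invariant or all-missing column: zero changes
        recs = polarize_site(column, tree, site0 + 1, family_id=aln.family_id)
        if recs:
            n_sites_with_sub += 1
        records.extend(recs)
    for rec in records:
        rec.context = contexts.get(rec.branch_id)
        rec.clade_ids = tuple(
            f"{d.dup_node_id}/{d.clade_of(rec.branch_id)}"
            for d in dups
            if d.clade_of(rec.branch_id) is not None
        )
    meta = FamilyMeta(
        family_id=aln.family_id,
        n_sequences=len(aln.sequences),
        n_columns=aln.n_columns,
        n_unmasked=mask.n_unmasked,
        n_sites_with_substitution=n_sites_with_sub,
        n_substitutions=len(records),
        n_unambiguous=sum(not r.ambiguous for r in records),
    )
    logger.info(
        "family %s: %d substitutions (%d unambiguous) at %d/%d sites",
        aln.family_id,
        meta.n_substitutions,
        meta.n_unambiguous,
        meta.n_sites_with_substitution,
        meta.n_unmasked,
    )
    return records, meta
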