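"""Input parsing and the relational data model.

The pipeline's results live in seven relational tables (``families``,
``tree_nodes``, ``substitutions`` (+ an ``substitution_alternatives``
child table), ``duplications``, ``flux``, ``family_stats``,
``asymmetry_tests``) written either to a single SQLite file or to a
directory of TSV mirrors. Alignment columns are 1-based in every output
table (biologists' convention); array indices are 0-based internally.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ConsistencyError, FormatError
from .trees import Tree, default_species, parse_newick

__all__ = [
    "AMINO_ACIDS",
    "FamilyAlignment",
    "SubstitutionRecord",
    "DuplicationRecord",
    "FamilyMeta",
    "AnnotationTable",
    "DatabaseBundle",
    "read_family",
    "read_annotation",
    "write_database",
    "read_database",
    "write_table",
    "read_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS) | {"-", "X"}

CONTEXTS = ("single_copy_no_dup_family", "single_copy_in_dup_family", "duplicated")


@dataclass
class FamilyAlignment:
    """One gene family's protein multiple alignment.

    ``sequences`` maps gene id -> aligned amino-acid string over the 20
    standard letters plus ``-`` (gap) and ``X`` (unknown); both of the
    latter are treated as missing data downstream.
    """

    family_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError(f"family {self.family_id}: no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise FormatError(
                f"family {self.family_id}: unequal sequence lengths {sorted(lengths)}"
            )
        if 0 in lengths:
            raise FormatError(f"family {self.family_id}: zero-length alignment")
        for gid, seq in self.sequences.items():
            bad = set(seq) - _ALLOWED
            if bad:
                raise FormatError(
                    f"family {self.family_id}, sequence {gid!r}: "
                    f"illegal characters {sorted(bad)}"
                )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    def column(self, site0: int) -> dict[str, str]:
        """Residues of 0-based column ``site0`` keyed by gene id."""
        return {gid: seq[site0] for gid, seq in self.sequences.items()}


@dataclass
class SubstitutionRecord:
    """One polarized amino-acid substitution.

    ``site`` is the 1-based alignment column. ``branch_id`` names the node
    whose incoming branch carries the event (for ambiguous records: the
    first alternative in deterministic order). ``alternatives`` holds
    (branch_id, source, dest) triples and is non-empty iff ``ambiguous``.
    """

    family_id: str
    site: int
    source_aa: str
    dest_aa: str
    branch_id: str
    ambiguous: bool = False
    alternatives: tuple[tuple[str, str, str], ...] = ()
    context: str | None = None
    clade_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source_aa == self.dest_aa:
            raise FormatError("substitution with identical source and destination")
        if self.ambiguous != bool(self.alternatives):
            raise FormatError("ambiguous flag inconsistent with alternatives list")


@dataclass
class DuplicationRecord:
    """A duplication node and the two clades it generated.

    Clades are branch sets (branch = name of the node it leads into) of the
    two child subtrees, child branch included; ``clade1`` is the clade with
    the lexicographically smallest leaf label. ``depth_ks`` — sum of branch
    lengths from the root down to and including the duplication node's own
    incoming branch — is the age proxy.
    """

    family_id: str
    dup_node_id: str
    clade1_branches: tuple[str, ...]
    clade2_branches: tuple[str, ...]
    clade1_ks: float
    clade2_ks: float
    depth_ks: float
    is_terminal: bool
    clade1_total: float = 0.0
    clade2_total: float = 0.0
    clade1_unambiguous: int = 0
    clade2_unambiguous: int = 0

    def clade_of(self, branch_id: str) -> int | None:
        if branch_id in self.clade1_branches:
            return 1
        if branch_id in self.clade2_branches:
            return 2
        return None


@dataclass
class FamilyMeta:
    """Per-family summary row."""

    family_id: str
    n_sequences: int
    n_columns: int
    n_unmasked: int = 0
    n_sites_with_substitution: int = 0
    n_substitutions: int = 0
    n_unambiguous: int = 0


class AnnotationTable:
    """family_id -> functional-category labels, one per annotated paralog."""

    def __init__(
        self,
        categories: Mapping[str, list[str]],
        vocabulary: Iterable[str] | None = None,
    ):
        self.categories = {k: list(v) for k, v in categories.items()}
        self.vocabulary = set(vocabulary) if vocabulary is not None else None
        if self.vocabulary is not None:
            for fam, cats in self.categories.items():
                unknown = set(cats) - self.vocabulary
                if unknown:
                    raise FormatError(
                        f"family {fam}: categories {sorted(unknown)} not in the "
                        "declared vocabulary"
                    )

    def __getitem__(self, family_id: str) -> list[str]:
        return self.categories[family_id]

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.categories


def read_annotation(path: str | Path, vocabulary: Iterable[str] | None = None) -> AnnotationTable:
    """Read a ``family_id<TAB>category`` annotation TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["family_id", "category"]:
        raise FormatError(
            f"{path}: expected header 'family_id<TAB>category', got {list(df.columns)}"
        )
    cats: dict[str, list[str]] = {}
    for fam, cat in zip(df["family_id"], df["category"]):
        cats.setdefault(fam, []).append(cat)
    return AnnotationTable(cats, vocabulary)


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------


def read_family(
    alignment_path: str | Path,
    tree_path: str | Path,
    family_id: str | None = None,
    species_fn: Callable[[str], str] = default_species,
) -> tuple[FamilyAlignment, Tree]:
    """Read one family's aligned FASTA and rooted Newick gene tree.

    The tree's leaf set must equal the alignment's sequence-id set; the
    basal node must be a bifurcation; all branch lengths (in Ks units,
    synonymous substitutions per 4-fold degenerate site) must be present
    and non-negative.
    """
    alignment_path = Path(alignment_path)
    tree_path = Path(tree_path)
    if family_id is None:
        family_id = alignment_path.stem
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(alignment_path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"family {family_id}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    aln = FamilyAlignment(family_id=family_id, sequences=seqs)
    tree = parse_newick(tree_path.read_text(), species_fn=species_fn)
    tree_leaves = tree.leaf_names()
    aln_ids = set(seqs)
    if tree_leaves != aln_ids:
        missing = sorted(tree_leaves - aln_ids)
        extra = sorted(aln_ids - tree_leaves)
        raise ConsistencyError(
            f"family {family_id}: tree/alignment id mismatch "
            f"(in tree only: {missing}; in alignment only: {extra})"
        )
    return aln, tree


# ---------------------------------------------------------------------------
# relational output
# ---------------------------------------------------------------------------


@dataclass
class DatabaseBundle:
    """In-memory image of the relational database."""

    families: list[FamilyMeta] = field(default_factory=list)
    tree_nodes: pd.DataFrame | None = None
    substitutions: list[SubstitutionRecord] = field(default_factory=list)
    duplications: list[DuplicationRecord] = field(default_factory=list)
    flux: pd.DataFrame | None = None
    family_stats: pd.DataFrame | None = None
    asymmetry_tests: pd.DataFrame | None = None


TREE_NODE_COLUMNS = [
    "family_id",
    "node_id",
    "parent_id",
    "preorder",
    "branch_length",
    "is_leaf",
    "species_id",
    "event",
    "context",
]


def tree_nodes_frame(
    family_id: str,
    tree: Tree,
    events: Mapping[int, str] | None = None,
    contexts: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Flatten a (reconciled) tree into ``tree_nodes`` rows."""
    rows = []
    for n in tree.nodes:
        rows.append(
            {
                "family_id": family_id,
                "node_id": n.name,
                "parent_id": None if n.parent is None else tree.nodes[n.parent].name,
                "preorder": n.index,
                "branch_length": n.length,
                "is_leaf": int(n.is_leaf),
                "species_id": n.species,
                "event": (events or {}).get(n.index),
                "context": (contexts or {}).get(n.name),
            }
        )
    return pd.DataFrame(rows, columns=TREE_NODE_COLUMNS)


def tree_from_frame(df: pd.DataFrame) -> Tree:
    """Rebuild a :class:`Tree` from one family's ``tree_nodes`` rows."""
    df = df.sort_values("preorder")
    from .trees import Node

    nodes: list[Node] = []
    name_to_index: dict[str, int] = {}
    for _, r in df.iterrows():
        idx = len(nodes)
        parent = None if r["parent_id"] is None or pd.isna(r["parent_id"]) else name_to_index[r["parent_id"]]
        node = Node(
            index=idx,
            name=r["node_id"],
            parent=parent,
            length=float(r["branch_length"]),
            species=None if pd.isna(r["species_id"]) else r["species_id"],
        )
        nodes.append(node)
        name_to_index[node.name] = idx
        if parent is not None:
            nodes[parent].children.append(idx)
    return Tree(nodes)


_SCHEMA = """
CREATE TABLE families (
    family_id TEXT PRIMARY KEY, n_sequences INTEGER, n_columns INTEGER,
    n_unmasked INTEGER, n_sites_with_substitution INTEGER,
    n_substitutions INTEGER, n_unambiguous INTEGER);
CREATE TABLE tree_nodes (
    family_id TEXT, node_id TEXT, parent_id TEXT, preorder INTEGER,
    branch_length REAL, is_leaf INTEGER, species_id TEXT, event TEXT,
    context TEXT, PRIMARY KEY (family_id, node_id));
CREATE TABLE substitutions (
    sub_id INTEGER PRIMARY KEY, family_id TEXT, site INTEGER,
    source_aa TEXT, dest_aa TEXT, branch_id TEXT, ambiguous INTEGER,
    context TEXT, clade_ids TEXT);
CREATE TABLE substitution_alternatives (
    sub_id INTEGER REFERENCES substitutions(sub_id), alt_index INTEGER,
    branch_id TEXT, source_aa TEXT, dest_aa TEXT,
    PRIMARY KEY (sub_id, alt_index));
CREATE TABLE duplications (
    family_id TEXT, dup_node_id TEXT, clade1_branches TEXT,
    clade2_branches TEXT, clade1_ks REAL, clade2_ks REAL, depth_ks REAL,
    is_terminal INTEGER, clade1_total REAL, clade2_total REAL,
    clade1_unambiguous INTEGER, clade2_unambiguous INTEGER,
    PRIMARY KEY (family_id, dup_node_id));
"""

_ANALYSIS_TABLES = ("flux", "family_stats", "asymmetry_tests")


def write_database(
    bundle: DatabaseBundle, path: str | Path, format: str = "sqlite"
) -> None:
    """Write the bundle as SQLite (``path`` is a file) or TSV (a directory)."""
    path = Path(path)
    if format == "sqlite":
        _write_sqlite(bundle, path)
    elif format == "tsv":
        _write_tsv(bundle, path)
    else:
        raise FormatError(f"unknown database format {format!r}")


def _bundle_frames(bundle: DatabaseBundle) -> dict[str, pd.DataFrame]:
    fams = pd.DataFrame(
        [vars(f) for f in bundle.families],
        columns=[
            "family_id",
            "n_sequences",
            "n_columns",
            "n_unmasked",
            "n_sites_with_substitution",
            "n_substitutions",
            "n_unambiguous",
        ],
    )
    tn = bundle.tree_nodes
    if tn is None:
        tn = pd.DataFrame(columns=TREE_NODE_COLUMNS)
    subs_rows, alt_rows = [], []
    for i, r in enumerate(bundle.substitutions):
        subs_rows.append(
            {
                "sub_id": i,
                "family_id": r.family_id,
                "site": r.site,
                "source_aa": r.source_aa,
                "dest_aa": r.dest_aa,
                "branch_id": r.branch_id,
                "ambiguous": int(r.ambiguous),
                "context": r.context,
                "clade_ids": json.dumps(list(r.clade_ids)),
            }
        )
        for j, (b, s, d) in enumerate(r.alternatives):
            alt_rows.append(
                {"sub_id": i, "alt_index": j, "branch_id": b, "source_aa": s, "dest_aa": d}
            )
    subs = pd.DataFrame(
        subs_rows,
        columns=[
            "sub_id",
            "family_id",
            "site",
            "source_aa",
            "dest_aa",
            "branch_id",
            "ambiguous",
            "context",
            "clade_ids",
        ],
    )
    alts = pd.DataFrame(
        alt_rows, columns=["sub_id", "alt_index", "branch_id", "source_aa", "dest_aa"]
    )
    dup_rows = []
    for d in bundle.duplications:
        row = vars(d).copy()
        row["clade1_branches"] = json.dumps(list(d.clade1_branches))
        row["clade2_branches"] = json.dumps(list(d.clade2_branches))
        row["is_terminal"] = int(d.is_terminal)
        dup_rows.append(row)
    dups = pd.DataFrame(
        dup_rows,
        columns=[
            "family_id",
            "dup_node_id",
            "clade1_branches",
            "clade2_branches",
            "clade1_ks",
            "clade2_ks",
            "depth_ks",
            "is_terminal",
            "clade1_total",
            "clade2_total",
            "clade1_unambiguous",
            "clade2_unambiguous",
        ],
    )
    frames = {
        "families": fams,
        "tree_nodes": tn,
        "substitutions": subs,
        "substitution_alternatives": alts,
        "duplications": dups,
    }
    for name in _ANALYSIS_TABLES:
        df = getattr(bundle, name)
        if df is not None:
            frames[name] = df
    return frames


def _write_sqlite(bundle: DatabaseBundle, path: Path) -> None:
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        for name, df in _bundle_frames(bundle).items():
            df.to_sql(name, con, if_exists="append" if name not in _ANALYSIS_TABLES else "replace", index=False)
        con.commit()
    finally:
        con.close()


def _write_tsv(bundle: DatabaseBundle, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for name, df in _bundle_frames(bundle).items():
        df.to_csv(path / f"{name}.tsv", sep="\t", index=False, na_rep="")


def write_table(db_path: str | Path, name: str, df: pd.DataFrame) -> None:
    """Write/replace one analysis table in an existing SQLite database."""
    con = sqlite3.connect(db_path)
    try:
        df.to_sql(name, con, if_exists="replace", index=False)
        con.commit()
    finally:
        con.close()


def read_table(db_path: str | Path, name: str) -> pd.DataFrame:
    con = sqlite3.connect(db_path)
    try:
        return pd.read_sql_query(f"SELECT * FROM {name}", con)
    finally:
        con.close()


def read_database(path: str | Path, format: str = "sqlite") -> DatabaseBundle:
    """Read a database back into the in-memory bundle (round-trip of write)."""
    path = Path(path)
    if format == "sqlite":
        con = sqlite3.connect(path)
        try:
            frames = {}
            names = [
                r[0]
                for r in con.execute(
                    "SELECT name FROM sqlite_master WHERE type='table'"
                )
            ]
            for name in names:
                frames[name] = pd.read_sql_query(f"SELECT * FROM {name}", con)
        finally:
            con.close()
    elif format == "tsv":
        frames = {}
        for f in sorted(path.glob("*.tsv")):
            frames[f.stem] = pd.read_csv(f, sep="\t")
    else:
        raise FormatError(f"unknown database format {format!r}")
    return _bundle_from_frames(frames)


def _opt_str(v) -> str | None:
    return None if v is None or (isinstance(v, float) and pd.isna(v)) else str(v)


def _bundle_from_frames(frames: dict[str, pd.DataFrame]) -> DatabaseBundle:
    bundle = DatabaseBundle()
    fams = frames.get("families")
    if fams is not None:
        bundle.families = [
            FamilyMeta(
                family_id=str(r.family_id),
                n_sequences=int(r.n_sequences),
                n_columns=int(r.n_columns),
                n_unmasked=int(r.n_unmasked),
                n_sites_with_substitution=int(r.n_sites_with_substitution),
                n_substitutions=int(r.n_substitutions),
                n_unambiguous=int(r.n_unambiguous),
            )
            for r in fams.itertuples()
        ]
    tn = frames.get("tree_nodes")
    if tn is not None:
        tn = tn.copy()
        for col in ("parent_id", "species_id", "event", "context"):
            tn[col] = [_opt_str(v) for v in tn[col]]
        tn["is_leaf"] = tn["is_leaf"].astype(int)
        tn["preorder"] = tn["preorder"].astype(int)
        tn["branch_length"] = tn["branch_length"].astype(float)
        bundle.tree_nodes = tn[TREE_NODE_COLUMNS].reset_index(drop=True)
    subs = frames.get("substitutions")
    alts = frames.get("substitution_alternatives")
    if subs is not None and len(subs):
        alt_map: dict[int, list[tuple[str, str, str]]] = {}
        if alts is not None and len(alts):
            for r in alts.sort_values(["sub_id", "alt_index"]).itertuples():
                alt_map.setdefault(int(r.sub_id), []).append(
                    (str(r.branch_id), str(r.source_aa), str(r.dest_aa))
                )
        for r in subs.sort_values("sub_id").itertuples():
            bundle.substitutions.append(
                SubstitutionRecord(
                    family_id=str(r.family_id),
                    site=int(r.site),
                    source_aa=str(r.source_aa),
                    dest_aa=str(r.dest_aa),
                    branch_id=str(r.branch_id),
                    ambiguous=bool(r.ambiguous),
                    alternatives=tuple(alt_map.get(int(r.sub_id), [])),
                    context=_opt_str(r.context),
                    clade_ids=tuple(json.loads(r.clade_ids)),
                )
            )
    dups = frames.get("duplications")
    if dups is not None and len(dups):
        for r in dups.itertuples():
            bundle.duplications.append(
                DuplicationRecord(
                    family_id=str(r.family_id),
                    dup_node_id=str(r.dup_node_id),
                    clade1_branches=tuple(json.loads(r.clade1_branches)),
                    clade2_branches=tuple(json.loads(r.clade2_branches)),
                    clade1_ks=float(r.clade1_ks),
                    clade2_ks=float(r.clade2_ks),
                    depth_ks=float(r.depth_ks),
                    is_terminal=bool(r.is_terminal),
                    clade1_total=float(r.clade1_total),
                    clade2_total=float(r.clade2_total),
                    clade1_unambiguous=int(r.clade1_unambiguous),
                    clade2_unambiguous=int(r.clade2_unambiguous),
                )
            )
    for name in _ANALYSIS_TABLES:
        if name in frames:
            setattr(bundle, name, frames[name])
    return bundle
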