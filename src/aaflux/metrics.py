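"""Genome-wide substitution statistics.

Flux: for each amino acid, D = (C - R)/(C + R) where C counts the times the
residue was created by substitutions and R the times it was removed; for an
unordered pair {x, y}, D_pair = (N(x->y) - N(y->x))/(N(x->y) + N(y->x)).
Radicality: |dPolarity| (absolute source/dest polarity difference) and the
exchangeability index (inverse radicality), both on unambiguous
substitutions only. Rates: per family and branch class, Ka = substitutions
per unmasked alignment site and Ks = summed branch lengths (synonymous
substitutions per 4-fold degenerate site), giving Ka/Ks.

Ambiguous substitutions enter rate and flux counts; for branch-resolved
tallies each alternative placement carries weight 1/n_alternatives
(``split`` mode, the default) so totals are preserved without double
counting a branch, while family-level totals count each record once.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .io_model import (
    AMINO_ACIDS,
    CONTEXTS,
    AnnotationTable,
    DuplicationRecord,
    SubstitutionRecord,
)
from .scales import RadicalityScales

__all__ = [
    "FluxTable",
    "flux_table",
    "delta_polarity",
    "exchangeability",
    "ClassStats",
    "FamilyStats",
    "family_ka_ks",
    "CladeAsymmetry",
    "clade_stats",
    "fill_duplication_counts",
    "category_aggregate",
    "flux_correlations",
    "asymmetry_value",
]

logger = logging.getLogger(__name__)

_AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}

BranchFilter = Callable[[str, str], bool]  # (family_id, branch_id) -> selected


@dataclass
class FluxTable:
    """Ordered-pair substitution counts and the D statistics they induce."""

    counts: np.ndarray  # 20x20, counts[source, dest], float (split weights)

    def __post_init__(self) -> None:
        if self.counts.shape != (20, 20):
            raise ContractError("flux counts must be 20x20")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def created(self, aa: str) -> float:
        return float(self.counts[:, _AA_IDX[aa]].sum())

    def removed(self, aa: str) -> float:
        return float(self.counts[_AA_IDX[aa], :].sum())

    def D(self, aa: str) -> float:
        c, r = self.created(aa), self.removed(aa)
        return (c - r) / (c + r) if c + r > 0 else float("nan")

    def pair_count(self, source: str, dest: str) -> float:
        return float(self.counts[_AA_IDX[source], _AA_IDX[dest]])

    def pair_d(self, x: str, y: str) -> float:
        """D of the reciprocal pair, oriented toward net gain of ``y``."""
        fwd, rev = self.pair_count(x, y), self.pair_count(y, x)
        return (fwd - rev) / (fwd + rev) if fwd + rev > 0 else float("nan")

    def mean_abs_pairwise_d(self) -> float:
        vals = [
            abs(self.pair_d(x, y))
            for x, y in itertools.combinations(AMINO_ACIDS, 2)
            if self.pair_count(x, y) + self.pair_count(y, x) > 0
        ]
        return float(np.mean(vals)) if vals else float("nan")

    def aa_frame(self) -> pd.DataFrame:
        rows = [
            {"aa": a, "created": self.created(a), "removed": self.removed(a), "d": self.D(a)}
            for a in AMINO_ACIDS
        ]
        return pd.DataFrame(rows)

    def pair_frame(self) -> pd.DataFrame:
        rows = []
        for x, y in itertools.combinations(AMINO_ACIDS, 2):
            n = self.pair_count(x, y) + self.pair_count(y, x)
            rows.append(
                {
                    "source": x,
                    "dest": y,
                    "n_forward": self.pair_count(x, y),
                    "n_reverse": self.pair_count(y, x),
                    "d_pair": self.pair_d(x, y) if n > 0 else np.nan,
                }
            )
        return pd.DataFrame(rows)


def flux_table(
    records: Iterable[SubstitutionRecord],
    branch_filter: BranchFilter | None = None,
    ambiguous: str = "split",
) -> FluxTable:
    """Tally created/removed counts over the selected branches.

    ``ambiguous='split'`` spreads each ambiguous record over its alternative
    placements with weight 1/n_alternatives; ``'exclude'`` drops ambiguous
    records entirely.
    """
    if ambiguous not in ("split", "exclude"):
        raise ConfigError(f"unknown ambiguous mode {ambiguous!r}")
    counts = np.zeros((20, 20))
    for rec in records:
        if not rec.ambiguous:
            if branch_filter is None or branch_filter(rec.family_id, rec.branch_id):
                counts[_AA_IDX[rec.source_aa], _AA_IDX[rec.dest_aa]] += 1.0
        elif ambiguous == "split":
            w = 1.0 / len(rec.alternatives)
            for b, s, t in rec.alternatives:
                if branch_filter is None or branch_filter(rec.family_id, b):
                    counts[_AA_IDX[s], _AA_IDX[t]] += w
    return FluxTable(counts=counts)


def delta_polarity(
    record: SubstitutionRecord, scales: RadicalityScales
) -> tuple[float, float]:
    """(signed, absolute) polarity change, destination minus source."""
    if record.ambiguous:
        raise ContractError("radicality is defined on unambiguous substitutions only")
    dp = scales.polarity[record.dest_aa] - scales.polarity[record.source_aa]
    return dp, abs(dp)


def exchangeability(record: SubstitutionRecord, scales: RadicalityScales) -> float:
    """Direction-sensitive exchangeability EX(source -> dest)."""
    if record.ambiguous:
        raise ContractError("radicality is defined on unambiguous substitutions only")
    return scales.ex(record.source_aa, record.dest_aa)


# ---------------------------------------------------------------------------
# per-family rates
# ---------------------------------------------------------------------------


@dataclass
class ClassStats:
    """Ka/Ks and radicality summaries for one branch class of one family."""

    n_substitutions: float = 0.0
    n_unambiguous: int = 0
    n_sites: int = 0
    ks_sum: float = 0.0
    ka: float | None = None
    ka_ks: float | None = None
    mean_abs_dpolarity: float | None = None
    mean_exchangeability: float | None = None


@dataclass
class FamilyStats:
    family_id: str
    classes: dict[str, ClassStats] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = []
        for cls, st in self.classes.items():
            row = {"family_id": self.family_id, "branch_class": cls, **vars(st)}
            rows.append(row)
        return pd.DataFrame(rows)


def family_ka_ks(
    family_id: str,
    records: Sequence[SubstitutionRecord],
    n_sites: int,
    ks_by_class: Mapping[str, float],
    scales: RadicalityScales | None = None,
) -> FamilyStats:
    """Per-branch-class Ka, Ks and Ka/Ks for one family.

    ``n_sites`` is the family's unmasked column count; ``ks_by_class`` sums
    branch lengths per context class and defines which classes exist (a
    class with no branches is reported with null fields). Each record
    counts once toward its class (family-level totals use unit weight for
    ambiguous records).
    """
    stats = FamilyStats(family_id=family_id)
    for cls in CONTEXTS:
        if cls not in ks_by_class:
            stats.classes[cls] = ClassStats(n_sites=n_sites)
            continue
        recs = [r for r in records if r.context == cls]
        unamb = [r for r in recs if not r.ambiguous]
        st = ClassStats(
            n_substitutions=float(len(recs)),
            n_unambiguous=len(unamb),
            n_sites=n_sites,
            ks_sum=float(ks_by_class[cls]),
        )
        st.ka = st.n_substitutions / n_sites
        if st.ks_sum > 0:
            st.ka_ks = st.ka / st.ks_sum
        elif st.n_substitutions > 0:
            logger.warning(
                "family %s class %s: %g substitutions on zero Ks; Ka/Ks undefined",
                family_id,
                cls,
                st.n_substitutions,
            )
        else:
            st.ka_ks = 0.0 if st.ka == 0 else None
        if scales is not None and unamb:
            dps = [delta_polarity(r, scales)[1] for r in unamb]
            exs = [exchangeability(r, scales) for r in unamb]
            st.mean_abs_dpolarity = float(np.mean(dps))
            st.mean_exchangeability = float(np.mean(exs))
        stats.classes[cls] = st
    return stats


# ---------------------------------------------------------------------------
# duplication clades
# ---------------------------------------------------------------------------


def asymmetry_value(x1: float | None, x2: float | None) -> float | None:
    """Clade asymmetry A = |x1 - x2| / (x1 + x2), in [0, 1]; None if 0/0."""
    if x1 is None or x2 is None:
        return None
    if x1 + x2 == 0:
        return None
    return abs(x1 - x2) / (x1 + x2)


@dataclass
class CladeAsymmetry:
    """Per-clade statistics and asymmetry values for one duplication."""

    family_id: str
    dup_node_id: str
    is_terminal: bool
    total: tuple[float, float]
    unambiguous: tuple[int, int]
    ks: tuple[float, float]
    rate: tuple[float | None, float | None]
    mean_abs_dpolarity: tuple[float | None, float | None]
    mean_exchangeability: tuple[float | None, float | None]
    a_rate: float | None
    a_polarity: float | None
    a_exchangeability: float | None
    # p-values are filled by the stats module's asymmetry battery
    p_total: float | None = None
    p_unambiguous: float | None = None
    p_polarity: float | None = None
    p_exchangeability: float | None = None


def _clade_tallies(
    dup: DuplicationRecord,
    records: Iterable[SubstitutionRecord],
    ambiguous: str = "split",
) -> tuple[list[float], list[int], list[list[SubstitutionRecord]]]:
    total = [0.0, 0.0]
    unamb = [0, 0]
    unamb_records: list[list[SubstitutionRecord]] = [[], []]
    for rec in records:
        if rec.family_id != dup.family_id:
            continue
        if not rec.ambiguous:
            k = dup.clade_of(rec.branch_id)
            if k is not None:
                total[k - 1] += 1.0
                unamb[k - 1] += 1
                unamb_records[k - 1].append(rec)
        elif ambiguous == "split":
            w = 1.0 / len(rec.alternatives)
            for b, _s, _t in rec.alternatives:
                k = dup.clade_of(b)
                if k is not None:
                    total[k - 1] += w
    return total, unamb, unamb_records


def fill_duplication_counts(
    dup: DuplicationRecord,
    records: Iterable[SubstitutionRecord],
    ambiguous: str = "split",
) -> DuplicationRecord:
    """Fill the per-clade substitution tallies on a duplication record."""
    total, unamb, _ = _clade_tallies(dup, records, ambiguous)
    dup.clade1_total, dup.clade2_total = total
    dup.clade1_unambiguous, dup.clade2_unambiguous = unamb
    return dup


def clade_stats(
    dup: DuplicationRecord,
    records: Iterable[SubstitutionRecord],
    scales: RadicalityScales | None = None,
    ambiguous: str = "split",
) -> CladeAsymmetry:
    """Per-clade rates and radicality plus A-values (tests unfilled).

    Rates are substitutions (ambiguous included, split-weighted) per unit
    of clade Ks; radicality means are over unambiguous records only.
    """
    total, unamb, unamb_records = _clade_tallies(dup, records, ambiguous)
    rate = [
        (total[k] / ks if ks > 0 else None)
        for k, ks in enumerate((dup.clade1_ks, dup.clade2_ks))
    ]
    mdp: list[float | None] = [None, None]
    mex: list[float | None] = [None, None]
    if scales is not None:
        for k in range(2):
            if unamb_records[k]:
                mdp[k] = float(
                    np.mean([delta_polarity(r, scales)[1] for r in unamb_records[k]])
                )
                mex[k] = float(
                    np.mean([exchangeability(r, scales) for r in unamb_records[k]])
                )
    return CladeAsymmetry(
        family_id=dup.family_id,
        dup_node_id=dup.dup_node_id,
        is_terminal=dup.is_terminal,
        total=(total[0], total[1]),
        unambiguous=(unamb[0], unamb[1]),
        ks=(dup.clade1_ks, dup.clade2_ks),
        rate=(rate[0], rate[1]),
        mean_abs_dpolarity=(mdp[0], mdp[1]),
        mean_exchangeability=(mex[0], mex[1]),
        a_rate=asymmetry_value(rate[0], rate[1]),
        a_polarity=asymmetry_value(mdp[0], mdp[1]),
        a_exchangeability=asymmetry_value(mex[0], mex[1]),
    )


# ---------------------------------------------------------------------------
# category aggregation and correlation inputs
# ---------------------------------------------------------------------------


def category_aggregate(
    values_by_family: Mapping[str, float],
    annotation: AnnotationTable,
    statistic: str = "value",
) -> pd.DataFrame:
    """Unweighted per-category means with among-family standard errors.

    Families without annotation are excluded; a family contributes once per
    annotated reference-species paralog (its category list may repeat a
    label, in which case the family's value enters that category's mean
    that many times).
    """
    entries: dict[str, list[float]] = {}
    for fam, value in values_by_family.items():
        if fam not in annotation:
            continue
        for cat in annotation[fam]:
            if annotation.vocabulary is not None and cat not in annotation.vocabulary:
                raise ConfigError(f"unknown category label {cat!r}")
            entries.setdefault(cat, []).append(value)
    rows = []
    for cat in sorted(entries):
        vals = np.asarray(entries[cat], dtype=float)
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append(
            {
                "category": cat,
                "statistic": statistic,
                "n": len(vals),
                "mean": float(vals.mean()),
                "se": se,
            }
        )
    return pd.DataFrame(rows, columns=["category", "statistic", "n", "mean", "se"])


@dataclass
class PairedVectors:
    """Correlation inputs: paired (D, covariate) vectors with labels."""

    x: np.ndarray  # D values
    y: np.ndarray  # covariate
    labels: list[str]
    dropped: list[str]


def flux_correlations(
    flux: FluxTable,
    covariate: str,
    table: Mapping[str, float] | None = None,
    scales: RadicalityScales | None = None,
) -> PairedVectors:
    """Build the paired vectors behind the flux correlations.

    ``covariate='frequency'`` or ``'rank'`` pairs per-amino-acid D with the
    supplied table (amino-acid frequencies from the input alignments, or an
    external rank list). ``'polarity_difference'`` pairs per-pair D
    (oriented toward the alphabetically later residue) with the polarity
    difference destination-minus-source for up to C(20,2)=190 pairs.
    Entries with undefined D are dropped and reported.
    """
    xs: list[float] = []
    ys: list[float] = []
    labels: list[str] = []
    dropped: list[str] = []
    if covariate in ("frequency", "rank"):
        if table is None:
            raise ConfigError(f"covariate {covariate!r} requires a value table")
        missing = [a for a in AMINO_ACIDS if a not in table]
        if missing:
            raise ConfigError(f"covariate table missing entries for {missing}")
        for a in AMINO_ACIDS:
            d = flux.D(a)
            if np.isnan(d):
                dropped.append(a)
                continue
            xs.append(d)
            ys.append(float(table[a]))
            labels.append(a)
    elif covariate == "polarity_difference":
        if scales is None:
            raise ConfigError("covariate 'polarity_difference' requires scales")
        for x, y in itertools.combinations(AMINO_ACIDS, 2):
            d = flux.pair_d(x, y)
            if np.isnan(d):
                dropped.append(x + y)
                continue
            xs.append(d)
            ys.append(scales.polarity[y] - scales.polarity[x])
            labels.append(x + y)
    else:
        raise ConfigError(f"unknown covariate {covariate!r}")
    return PairedVectors(
        x=np.asarray(xs), y=np.asarray(ys), labels=labels, dropped=dropped
    )
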