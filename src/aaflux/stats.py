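"""Hypothesis tests and multiple-test control for clade asymmetries.

Per duplication: a chi-square heterogeneity test on the two clades'
substitution counts (expected split proportional to clade branch lengths by
default, equal split selectable), and Welch t-tests on per-substitution
|dPolarity| and exchangeability values, eligible only when both clades have
at least two unambiguous substitutions. Families of tests are controlled by
Benjamini-Hochberg FDR and by Bonferroni; the number of tests m counts only
the tests actually performed for that statistic. All p-values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import EligibilityError
from .io_model import DuplicationRecord, SubstitutionRecord
from .metrics import delta_polarity, exchangeability
from .scales import RadicalityScales

__all__ = [
    "TestResult",
    "chi2_heterogeneity",
    "welch_t",
    "sign_test",
    "bh_fdr",
    "bonferroni",
    "rank_and_product_correlations",
    "asymmetry_battery",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    df: float | None = None
    n: tuple[int, ...] = ()
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def undefined(self) -> bool:
        return bool(self.flags.get("undefined", False))


def chi2_heterogeneity(
    counts: Sequence[float],
    weights: Sequence[float] = (1.0, 1.0),
    yates: bool = False,
) -> TestResult:
    """Chi-square heterogeneity test of two counts against weighted expectation.

    ``expected_i = total * weight_i / sum(weights)``; the statistic is
    ``sum (obs - exp)^2 / exp`` with df = 1 (no continuity correction unless
    ``yates``). Weights are typically the two clades' Ks sums; equal
    weights give the equal-split null. Both counts zero yields an
    undefined result; an expected value below 1 is flagged but still
    computed.
    """
    o1, o2 = float(counts[0]), float(counts[1])
    w1, w2 = float(weights[0]), float(weights[1])
    if w1 <= 0 or w2 <= 0:
        raise EligibilityError("chi-square weights must be positive")
    total = o1 + o2
    if total == 0:
        return TestResult(
            statistic=float("nan"), p=float("nan"), df=1.0, n=(0, 0),
            flags={"undefined": True},
        )
    e1 = total * w1 / (w1 + w2)
    e2 = total * w2 / (w1 + w2)
    flags = {}
    if min(e1, e2) < 1:
        flags["low_expected"] = True
    def term(o: float, e: float) -> float:
        d = abs(o - e)
        if yates:
            d = max(0.0, d - 0.5)
        return d * d / e
    chi2 = term(o1, e1) + term(o2, e2)
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(statistic=chi2, p=p, df=1.0, n=(int(o1), int(o2)), flags=flags)


def welch_t(
    group1: Sequence[float], group2: Sequence[float], pooled: bool = False
) -> TestResult:
    """Two-sided t-test; Welch (unequal variance) unless ``pooled``."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise EligibilityError(
            f"t-test requires at least 2 values per group (got {len(g1)}, {len(g2)})"
        )
    res = sps.ttest_ind(g1, g2, equal_var=pooled)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=float(res.df),
        n=(len(g1), len(g2)),
    )


def sign_test(k: int, n: int) -> TestResult:
    """Exact two-sided sign test: double the smaller binomial(1/2) tail.

    Ties must be excluded before the call; ``n`` is the number of informative
    trials and ``k`` the successes.
    """
    if n < 1:
        return TestResult(
            statistic=float("nan"), p=float("nan"), n=(0,), flags={"undefined": True}
        )
    if not 0 <= k <= n:
        raise EligibilityError(f"k={k} outside [0, {n}]")
    lower = float(sps.binom.cdf(k, n, 0.5))
    upper = float(sps.binom.sf(k - 1, n, 0.5))
    p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(statistic=float(k), p=p, n=(n,))


def _valid_mask(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    return ~np.isnan(p)


def bh_fdr(pvalues: Sequence[float], q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``.

    NaN entries mark skipped (ineligible) tests: they are excluded from m
    and never rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    reject = np.zeros(len(p), dtype=bool)
    valid = _valid_mask(p)
    if valid.any():
        reject[valid] = multipletests(p[valid], alpha=q, method="fdr_bh")[0]
    return reject


def bonferroni(pvalues: Sequence[float], alpha: float) -> np.ndarray:
    """Reject p_i iff p_i <= alpha/m, with m the number of non-NaN tests."""
    p = np.asarray(pvalues, dtype=float)
    reject = np.zeros(len(p), dtype=bool)
    valid = _valid_mask(p)
    m = int(valid.sum())
    if m:
        reject[valid] = p[valid] <= alpha / m
    return reject


def rank_and_product_correlations(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> TestResult:
    """Spearman (average ranks for ties) or Pearson correlation with p."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise EligibilityError("correlation requires equal-length vectors, n >= 3")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise EligibilityError("correlation requires finite values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return TestResult(
            statistic=float("nan"), p=float("nan"), n=(len(xv),),
            flags={"undefined": True},
        )
    if method == "spearman":
        r, p = sps.spearmanr(xv, yv)
    elif method == "pearson":
        r, p = sps.pearsonr(xv, yv)
    else:
        raise EligibilityError(f"unknown correlation method {method!r}")
    return TestResult(statistic=float(r), p=float(p), n=(len(xv),))


# ---------------------------------------------------------------------------
# the per-duplication test battery
# ---------------------------------------------------------------------------

_STATISTICS = (
    "total_substitutions",
    "unambiguous_substitutions",
    "abs_dpolarity",
    "exchangeability",
)


def asymmetry_battery(
    duplications: Iterable[DuplicationRecord],
    records: Sequence[SubstitutionRecord],
    scales: RadicalityScales,
    fdr_levels: Sequence[float] = (0.01, 0.05),
    bonferroni_alpha: float = 0.01,
    exclude_terminal: bool = False,
    chi2_null: str = "ks",
    min_unambiguous: int = 2,
) -> pd.DataFrame:
    """Run the full clade-asymmetry test battery and control multiplicity.

    For every duplication (optionally excluding terminal ones): chi-square
    heterogeneity on total and on unambiguous substitution counts
    (expectation proportional to clade Ks if ``chi2_null='ks'``, equal
    otherwise), and Welch t-tests on |dPolarity| and exchangeability of the
    two clades' unambiguous substitutions when both clades have at least
    ``min_unambiguous`` of them. Rejection flags per statistic family.
    """
    by_family: dict[str, list[SubstitutionRecord]] = {}
    for r in records:
        by_family.setdefault(r.family_id, []).append(r)
    rows: list[dict] = []
    for dup in duplications:
        if exclude_terminal and dup.is_terminal:
            continue
        fam_records = by_family.get(dup.family_id, [])
        totals = [0.0, 0.0]
        unamb_vals: list[list[SubstitutionRecord]] = [[], []]
        for rec in fam_records:
            if not rec.ambiguous:
                k = dup.clade_of(rec.branch_id)
                if k is not None:
                    totals[k - 1] += 1.0
                    unamb_vals[k - 1].append(rec)
            else:
                w = 1.0 / len(rec.alternatives)
                for b, _s, _t in rec.alternatives:
                    k = dup.clade_of(b)
                    if k is not None:
                        totals[k - 1] += w
        if chi2_null == "ks" and dup.clade1_ks > 0 and dup.clade2_ks > 0:
            weights = (dup.clade1_ks, dup.clade2_ks)
        else:
            weights = (1.0, 1.0)

        def emit(name: str, res: TestResult | None, eligible: bool) -> None:
            rows.append(
                {
                    "family_id": dup.family_id,
                    "dup_node_id": dup.dup_node_id,
                    "statistic_name": name,
                    "statistic": res.statistic if res else np.nan,
                    "df": (res.df if res and res.df is not None else np.nan),
                    "p": res.p if res else np.nan,
                    "eligible": eligible,
                }
            )

        counts_total = totals
        counts_unamb = [len(v) for v in unamb_vals]
        for name, counts in (
            ("total_substitutions", counts_total),
            ("unambiguous_substitutions", counts_unamb),
        ):
            if sum(counts) == 0:
                emit(name, None, eligible=False)
            else:
                emit(name, chi2_heterogeneity(counts, weights), eligible=True)
        eligible_rad = all(len(v) >= min_unambiguous for v in unamb_vals)
        if eligible_rad:
            dp = [[delta_polarity(r, scales)[1] for r in v] for v in unamb_vals]
            ex = [[exchangeability(r, scales) for r in v] for v in unamb_vals]
            emit("abs_dpolarity", welch_t(dp[0], dp[1]), eligible=True)
            emit("exchangeability", welch_t(ex[0], ex[1]), eligible=True)
        else:
            emit("abs_dpolarity", None, eligible=False)
            emit("exchangeability", None, eligible=False)

    df = pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "dup_node_id",
            "statistic_name",
            "statistic",
            "df",
            "p",
            "eligible",
        ],
    )
    if df.empty:
        for q in fdr_levels:
            df[f"fdr_reject_q{_level_tag(q)}"] = pd.Series(dtype=bool)
        df[f"bonferroni_reject_p{_level_tag(bonferroni_alpha)}"] = pd.Series(dtype=bool)
        return df
    for q in fdr_levels:
        col = np.zeros(len(df), dtype=bool)
        for name in _STATISTICS:
            sel = (df["statistic_name"] == name).to_numpy()
            col[sel] = bh_fdr(df.loc[sel, "p"].to_numpy(), q)
        df[f"fdr_reject_q{_level_tag(q)}"] = col
    col = np.zeros(len(df), dtype=bool)
    for name in _STATISTICS:
        sel = (df["statistic_name"] == name).to_numpy()
        col[sel] = bonferroni(df.loc[sel, "p"].to_numpy(), bonferroni_alpha)
    df[f"bonferroni_reject_p{_level_tag(bonferroni_alpha)}"] = col
    return df


def _level_tag(level: float) -> str:
    s = f"{level:g}"
    return s.replace("0.", "").replace(".", "")
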