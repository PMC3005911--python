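"""Flux, radicality, Ka/Ks, clade asymmetry and category aggregation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaflux import (
    AnnotationTable,
    ContractError,
    DuplicationRecord,
    SubstitutionRecord,
    category_aggregate,
    clade_stats,
    delta_polarity,
    exchangeability,
    family_ka_ks,
    fill_duplication_counts,
    flux_correlations,
    flux_table,
)
from aaflux.io_model import AMINO_ACIDS
from aaflux.metrics import asymmetry_value


def rec(src, dst, branch="b1", fam="f1", site=1, ambiguous=False, alts=()):
    return SubstitutionRecord(
        family_id=fam, site=site, source_aa=src, dest_aa=dst, branch_id=branch,
        ambiguous=ambiguous, alternatives=tuple(alts),
    )


class TestFluxTable:
    def test_simple_counts_give_expected_d(self):
        ft = flux_table([rec("A", "C"), rec("A", "C"), rec("C", "A")])
        assert ft.D("C") == pytest.approx(1 / 3)
        assert ft.D("A") == pytest.approx(-1 / 3)
        assert ft.pair_d("A", "C") == pytest.approx(1 / 3)

    def test_balanced_counts_give_zero_d(self):
        ft = flux_table([rec("A", "C"), rec("C", "A"), rec("K", "R"), rec("R", "K")])
        for aa in "ACKR":
            assert ft.D(aa) == 0.0

    def test_single_record_boundary(self):
        ft = flux_table([rec("A", "C")])
        assert ft.D("C") == 1.0 and ft.D("A") == -1.0

    def test_undefined_pairs_excluded_from_mean(self):
        ft = flux_table([rec("A", "C")])
        assert ft.mean_abs_pairwise_d() == 1.0

    def test_conservation_sum_created_equals_sum_removed(self):
        rng = np.random.default_rng(0)
        records = [
            rec(*rng.choice(list(AMINO_ACIDS), size=2, replace=False))
            for _ in range(200)
        ]
        ft = flux_table(records)
        created = sum(ft.created(a) for a in AMINO_ACIDS)
        removed = sum(ft.removed(a) for a in AMINO_ACIDS)
        assert created == removed == 200

    def test_ambiguous_split_weight_preserves_totals(self):
        r = rec("A", "C", ambiguous=True,
                alts=[("b1", "A", "C"), ("b2", "C", "A")])
        ft = flux_table([r])
        assert ft.total == pytest.approx(1.0)
        assert ft.pair_count("A", "C") == pytest.approx(0.5)
        assert flux_table([r], ambiguous="exclude").total == 0.0

    def test_branch_filter_restricts_counts(self):
        records = [rec("A", "C", branch="b1"), rec("K", "R", branch="b2")]
        ft = flux_table(records, branch_filter=lambda fam, b: b == "b1")
        assert ft.total == 1.0 and ft.pair_count("A", "C") == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pair_d_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            rec(*rng.choice(list(AMINO_ACIDS), size=2, replace=False))
            for _ in range(50)
        ]
        ft = flux_table(records)
        for x, y in [("A", "C"), ("K", "R"), ("D", "E")]:
            dxy, dyx = ft.pair_d(x, y), ft.pair_d(y, x)
            if not np.isnan(dxy):
                assert dxy == -dyx


class TestRadicality:
    def test_delta_polarity_sign_and_reciprocity(self, scales):
        dp_ad, abs_ad = delta_polarity(rec("A", "D"), scales)
        dp_da, abs_da = delta_polarity(rec("D", "A"), scales)
        assert dp_ad == pytest.approx(13.0 - 8.1)
        assert dp_ad > 0 and dp_ad == -dp_da and abs_ad == abs_da

    def test_exchangeability_is_matrix_lookup(self, scales):
        val = exchangeability(rec("A", "C"), scales)
        assert val == pytest.approx(float(scales.exchangeability.loc["A", "C"]))

    def test_ambiguous_record_rejected(self, scales):
        r = rec("A", "C", ambiguous=True, alts=[("b1", "A", "C"), ("b2", "C", "A")])
        with pytest.raises(ContractError):
            delta_polarity(r, scales)
        with pytest.raises(ContractError):
            exchangeability(r, scales)

    def test_mean_abs_dpolarity_order_independent(self, scales):
        records = [rec("A", "D"), rec("K", "L"), rec("C", "W")]
        vals = [delta_polarity(r, scales)[1] for r in records]
        assert np.mean(vals) == np.mean(vals[::-1])


class TestFamilyKaKs:
    def _records(self, n, context):
        out = []
        for i in range(n):
            r = rec("A", "C", site=i + 1)
            r.context = context
            out.append(r)
        return out

    def test_arithmetic(self):
        recs = self._records(4, "single_copy_no_dup_family")
        fs = family_ka_ks("f1", recs, 100, {"single_copy_no_dup_family": 0.5})
        st = fs.classes["single_copy_no_dup_family"]
        assert st.ka == pytest.approx(0.04)
        assert st.ka_ks == pytest.approx(0.08)

    def test_zero_substitutions(self):
        fs = family_ka_ks("f1", [], 100, {"single_copy_no_dup_family": 0.5})
        st = fs.classes["single_copy_no_dup_family"]
        assert st.ka == 0.0 and st.ka_ks == 0.0

    def test_class_without_branches_is_null(self):
        fs = family_ka_ks("f1", [], 100, {"single_copy_no_dup_family": 0.5})
        assert fs.classes["duplicated"].ka is None
        assert fs.classes["duplicated"].ka_ks is None

    def test_zero_ks_with_substitutions_gives_null_ka_ks(self):
        recs = self._records(2, "duplicated")
        fs = family_ka_ks("f1", recs, 100, {"duplicated": 0.0})
        st = fs.classes["duplicated"]
        assert st.ka == pytest.approx(0.02) and st.ka_ks is None


def make_dup(**kw):
    base = dict(
        family_id="f1", dup_node_id="d1",
        clade1_branches=("b1",), clade2_branches=("b2",),
        clade1_ks=1.0, clade2_ks=1.0, depth_ks=0.0, is_terminal=False,
    )
    base.update(kw)
    return DuplicationRecord(**base)


class TestCladeStats:
    def test_equal_rates_zero_asymmetry(self, scales):
        dup = make_dup()
        records = [rec("A", "C", branch="b1"), rec("A", "C", branch="b2")]
        cs = clade_stats(dup, records, scales)
        assert cs.a_rate == 0.0

    def test_rates_3_vs_1_give_half(self, scales):
        dup = make_dup(clade1_ks=10.0, clade2_ks=10.0)
        records = [rec("A", "C", branch="b1", site=i) for i in range(1, 4)]
        records += [rec("A", "C", branch="b2")]
        cs = clade_stats(dup, records, scales)
        assert cs.a_rate == pytest.approx(0.5)  # |0.3-0.1|/(0.3+0.1)

    def test_one_empty_clade_asymmetry_one(self, scales):
        dup = make_dup()
        cs = clade_stats(dup, [rec("A", "C", branch="b1")], scales)
        assert cs.a_rate == 1.0

    def test_ambiguous_counts_split_across_clades(self):
        dup = make_dup()
        r = rec("A", "C", ambiguous=True, alts=[("b1", "A", "C"), ("b2", "C", "A")])
        dup = fill_duplication_counts(dup, [r])
        assert dup.clade1_total == pytest.approx(0.5)
        assert dup.clade2_total == pytest.approx(0.5)
        assert dup.clade1_unambiguous == 0

    def test_unambiguous_never_exceeds_total(self, simulated_family, scales):
        from aaflux import extract_duplications, lca_reconcile, polarize_family

        cfg, aln, gtree, log = simulated_family
        rt = lca_reconcile(gtree, cfg.species_tree)
        records, _ = polarize_family(aln, rt)
        for dup in extract_duplications(rt):
            dup.family_id = aln.family_id
            fill_duplication_counts(dup, records)
            assert dup.clade1_unambiguous <= dup.clade1_total + 1e-9
            assert dup.clade2_unambiguous <= dup.clade2_total + 1e-9

    def test_asymmetry_value_bounds(self):
        assert asymmetry_value(0.0, 0.0) is None
        assert asymmetry_value(1.0, 0.0) == 1.0
        assert 0 <= asymmetry_value(0.3, 0.1) <= 1


class TestCategoryAggregate:
    def test_mean_and_multiplicity_rules(self):
        ann = AnnotationTable(
            {"f1": ["enzyme"], "f2": ["enzyme"], "f3": ["receptor", "receptor"]}
        )
        df = category_aggregate({"f1": 0.1, "f2": 0.3, "f3": 0.2, "f4": 9.9}, ann)
        enz = df[df["category"] == "enzyme"].iloc[0]
        assert enz["mean"] == pytest.approx(0.2)
        assert enz["n"] == 2
        # f3 annotated twice -> contributes twice; f4 unannotated -> excluded
        recp = df[df["category"] == "receptor"].iloc[0]
        assert recp["n"] == 2 and recp["mean"] == pytest.approx(0.2)
        assert set(df["category"]) == {"enzyme", "receptor"}


class TestFluxCorrelations:
    def test_all_pairs_defined_gives_190(self, scales):
        rng = np.random.default_rng(1)
        records = []
        for i, x in enumerate(AMINO_ACIDS):
            for y in AMINO_ACIDS[i + 1:]:
                records.append(rec(x, y))
                if rng.random() < 0.5:
                    records.append(rec(y, x))
        ft = flux_table(records)
        pv = flux_correlations(ft, "polarity_difference", scales=scales)
        assert len(pv.x) == 190 and pv.dropped == []

    def test_undefined_pairs_dropped_and_reported(self, scales):
        ft = flux_table([rec("A", "C")])
        pv = flux_correlations(ft, "polarity_difference", scales=scales)
        assert len(pv.x) == 1 and len(pv.dropped) == 189

    def test_frequency_covariate_requires_full_table(self):
        ft = flux_table([rec("A", "C")])
        with pytest.raises(Exception, match="missing"):
            flux_correlations(ft, "frequency", table={"A": 0.1})
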