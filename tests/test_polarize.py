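"""Masking, parsimony scoring, MPR enumeration and polarization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaflux import (
    ContractError,
    FamilyAlignment,
    enumerate_mprs,
    fitch_score,
    lca_reconcile,
    mask_indel_regions,
    polarize_family,
    polarize_site,
    site_events,
)
from aaflux.trees import parse_newick
from conftest import brute_force_parsimony, random_parsimony_instance


class TestMask:
    def test_double_gap_run_masks_its_columns_family_wide(self):
        aln = FamilyAlignment("f", {"g1": "AC--GT", "g2": "ACAAGT"})
        mask = mask_indel_regions(aln)
        assert mask.excluded_columns() == {3, 4}

    def test_single_gap_not_masked(self):
        aln = FamilyAlignment("f", {"g1": "A-CGT", "g2": "AACGT"})
        assert mask_indel_regions(aln).excluded_columns() == set()

    def test_all_gap_sequence_masks_everything(self):
        aln = FamilyAlignment("f", {"g1": "-----", "g2": "ACDEF"})
        assert mask_indel_regions(aln).n_unmasked == 0

    def test_runs_from_different_sequences_union(self):
        aln = FamilyAlignment("f", {"g1": "--CGT", "g2": "ACG--"})
        assert mask_indel_regions(aln).excluded_columns() == {1, 2, 4, 5}


class TestFitchScore:
    def test_invariant_column_scores_zero(self, five_leaf_tree):
        states = {n: "A" for n in five_leaf_tree.leaf_names()}
        assert fitch_score(states, five_leaf_tree) == 0

    def test_two_contiguous_blocks_score_one(self):
        t = parse_newick("((a:1,b:1)x:1,(c:1,d:1)y:1)r;")
        assert fitch_score({"a": "A", "b": "A", "c": "C", "d": "C"}, t) == 1

    def test_interleaved_states_score_two(self):
        t = parse_newick("((a:1,b:1)x:1,(c:1,d:1)y:1)r;")
        assert fitch_score({"a": "A", "b": "C", "c": "A", "d": "C"}, t) == 2

    def test_missing_data_is_free(self):
        t = parse_newick("((a:1,b:1)x:1,(c:1,d:1)y:1)r;")
        assert fitch_score({"a": "A", "b": "-", "c": "X", "d": "C"}, t) == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        tree, states, alphabet = random_parsimony_instance(rng)
        assert fitch_score(states, tree) == brute_force_parsimony(tree, states, alphabet)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_score_at_least_states_minus_one(self, seed):
        rng = np.random.default_rng(seed)
        tree, states, alphabet = random_parsimony_instance(rng)
        observed = {s for s in states.values() if s in alphabet}
        if observed:
            assert fitch_score(states, tree) >= len(observed) - 1


class TestEnumerateMprs:
    def test_invariant_column_single_labeling(self, five_leaf_tree):
        states = {n: "A" for n in five_leaf_tree.leaf_names()}
        m = enumerate_mprs(states, five_leaf_tree)
        assert m.parsimony_score == 0
        assert len(m.labelings) == 1 and not m.cap_exceeded

    def test_two_leaf_tree_has_two_labelings(self, two_leaf_tree):
        m = enumerate_mprs({"L1": "A", "L2": "C"}, two_leaf_tree)
        assert m.parsimony_score == 1
        roots = sorted(lab[two_leaf_tree.root.name] for lab in m.labelings)
        assert roots == ["A", "C"]

    def test_five_leaf_unique_mpr(self, five_leaf_tree):
        states = {"x1": "A", "x2": "A", "y1": "C", "y2": "C", "out": "A"}
        m = enumerate_mprs(states, five_leaf_tree)
        assert m.parsimony_score == 1
        assert len(m.labelings) == 1
        events = m.events_of(m.labelings[0], five_leaf_tree)
        assert events == [("ny", "A", "C")]

    def test_cap_truncates_but_flags(self, five_leaf_tree):
        states = {"x1": "A", "x2": "C", "y1": "D", "y2": "E", "out": "F"}
        full = enumerate_mprs(states, five_leaf_tree)
        capped = enumerate_mprs(states, five_leaf_tree, cap=2)
        assert not full.cap_exceeded and capped.cap_exceeded
        assert len(capped.labelings) == 2 < len(full.labelings)

    def test_every_labeling_attains_the_score(self, five_leaf_tree):
        states = {"x1": "A", "x2": "C", "y1": "A", "y2": "C", "out": "D"}
        m = enumerate_mprs(states, five_leaf_tree)
        for lab in m.labelings:
            assert len(m.events_of(lab, five_leaf_tree)) == m.parsimony_score

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_marginals_agree_with_enumeration(self, seed):
        """Exact DP marginals = union/intersection of events over all MPRs."""
        rng = np.random.default_rng(seed)
        tree, states, _ = random_parsimony_instance(rng, max_leaves=6)
        m = enumerate_mprs(states, tree, cap=100_000)
        assert not m.cap_exceeded
        ev = site_events(states, tree)
        per_mpr = [set(m.events_of(lab, tree)) for lab in m.labelings]
        union = set().union(*per_mpr) if per_mpr else set()
        inter = set.intersection(*per_mpr) if per_mpr else set()
        marginal_union = {
            (b, s, t) for b, pairs in ev.possible.items() for s, t in pairs
        }
        assert marginal_union == union
        assert set(ev.unambiguous) == inter


class TestPolarizeSite:
    def test_five_leaf_unambiguous_record(self, five_leaf_tree):
        states = {"x1": "A", "x2": "A", "y1": "C", "y2": "C", "out": "A"}
        (rec,) = polarize_site(states, five_leaf_tree, site=1)
        assert not rec.ambiguous
        assert (rec.branch_id, rec.source_aa, rec.dest_aa) == ("ny", "A", "C")

    def test_two_leaf_ambiguous_with_two_alternatives(self, two_leaf_tree):
        (rec,) = polarize_site({"L1": "A", "L2": "C"}, two_leaf_tree, site=1)
        assert rec.ambiguous
        assert set(rec.alternatives) == {("L2", "A", "C"), ("L1", "C", "A")}

    def test_root_straddling_change_is_always_ambiguous(self):
        # change between the two halves of a balanced tree: direction flips
        t = parse_newick("((a:1,b:1)x:1,(c:1,d:1)y:1)r;")
        recs = polarize_site({"a": "A", "b": "A", "c": "C", "d": "C"}, t, site=1)
        assert len(recs) == 1 and recs[0].ambiguous
        assert {alt[0] for alt in recs[0].alternatives} == {"x", "y"}

    def test_masked_site_is_contract_violation(self):
        aln = FamilyAlignment("f", {"a": "A--A", "b": "AAAA"})
        mask = mask_indel_regions(aln)
        t = parse_newick("(a:1,b:1);")
        with pytest.raises(ContractError):
            polarize_site(aln.column(1), t, site=2, mask=mask)

    def test_record_count_equals_parsimony_score(self, five_leaf_tree):
        states = {"x1": "A", "x2": "C", "y1": "D", "y2": "C", "out": "A"}
        recs = polarize_site(states, five_leaf_tree, site=1)
        assert len(recs) == fitch_score(states, five_leaf_tree)

    def test_wildcard_leaf_never_carries_an_event(self):
        t = parse_newick("((a:1,b:1)x:1,(c:1,d:1)y:1)r;")
        states = {"a": "A", "b": "-", "c": "C", "d": "C"}
        ev = site_events(states, t)
        assert "b" not in ev.possible


SPECIES3 = parse_newick("((A:1,B:1)ab:1,C:1)r;", require_lengths=False)


class TestPolarizeFamily:
    def test_identical_sequences_no_records(self):
        aln = FamilyAlignment("f", {"A|g1": "MKV", "B|g1": "MKV", "C|g1": "MKV"})
        g = parse_newick("((A|g1:1,B|g1:1)n1:1,C|g1:1)n0;")
        records, meta = polarize_family(aln, lca_reconcile(g, SPECIES3))
        assert records == [] and meta.n_sites_with_substitution == 0

    def test_single_variable_site_totals(self):
        seq = "M" * 50
        aln = FamilyAlignment(
            "f",
            {"A|g1": seq + "A" + seq[:-2] + "K", "B|g1": seq + "A" + seq[:-2] + "K",
             "C|g1": seq + "C" + seq[:-2] + "K"},
        )
        g = parse_newick("((A|g1:1,B|g1:1)n1:1,C|g1:1)n0;")
        records, meta = polarize_family(aln, lca_reconcile(g, SPECIES3))
        assert meta.n_substitutions == 1
        assert meta.n_sites_with_substitution == 1
        assert meta.n_unmasked == 100
        assert records[0].site == 51

    def test_records_tagged_with_context_and_clades(self):
        aln = FamilyAlignment("f", {"A|g1": "MAV", "A|g2": "MCV", "B|g1": "MAV"})
        g = parse_newick("((A|g1:1,A|g2:1)d:1,B|g1:1)n0;")
        records, _ = polarize_family(aln, lca_reconcile(g, SPECIES3))
        assert all(r.context is not None for r in records)
        dup_records = [r for r in records if r.branch_id in ("A|g1", "A|g2")]
        assert dup_records and all(r.context == "duplicated" for r in dup_records)
        assert all(r.clade_ids for r in dup_records)

    def test_simulated_unambiguous_events_subset_of_truth(self, simulated_family):
        cfg, aln, gtree, log = simulated_family
        rt = lca_reconcile(gtree, cfg.species_tree)
        records, _ = polarize_family(aln, rt)
        truth = {(e.site, e.branch_id, e.source_aa, e.dest_aa) for e in log.events}
        for r in records:
            if not r.ambiguous:
                assert (r.site, r.branch_id, r.source_aa, r.dest_aa) in truth
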