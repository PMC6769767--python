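"""Prescription operators: profile ranking, druggability, bulk-vs-ITH
comparison, responder classification and alternative therapies."""

import numpy as np
import pytest

from clonotherapy.evidence_kb import EvidenceEntry, EvidenceKB, query_genes, rank_candidates
from clonotherapy.prescription import (
    Thresholds,
    alternative_therapies,
    bulk_vs_ith,
    classify_response,
    clone_druggability,
    druggable_genes,
    prescribe_profile,
)
from clonotherapy.clonal_model import (
    Clone,
    ClonalArchitecture,
    SampleComposition,
    full_complement,
    predominant_clone,
    region_union_genes,
    trunk_genes,
)

from conftest import random_architecture, random_kb


class TestPrescribeProfile:
    def test_cruk0016_trunk_top_record_is_dasatinib(self, fixtures):
        fx = fixtures["CRUK0016"]
        ranked = prescribe_profile(trunk_genes(fx.arch), fx.kb)
        assert ranked[0].drug == "dasatinib"
        assert ranked[0].best_dscore == 0.95
        assert ranked[0].supporting_genes == {"DDR2"}
        assert ranked[0].associations["DDR2"] == ("direct_target",)

    def test_resistance_only_profile_gives_empty_ranking(self):
        kb = EvidenceKB([
            EvidenceEntry("KRAS", "erlotinib", 0.9, -0.9, "resistance", "biomarker",
                          "approved"),
        ])
        assert prescribe_profile({"KRAS"}, kb) == []

    def test_empty_gene_set_gives_empty_ranking(self, small_kb):
        assert prescribe_profile(set(), small_kb) == []

    def test_matches_query_then_rank_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            kb = random_kb(rng, n_genes=15, n_entries=40)
            genes = {f"G{i}" for i in rng.choice(15, size=6, replace=False)}
            got = prescribe_profile(genes, kb, Thresholds(0.2, 0.1))
            oracle = rank_candidates(query_genes(kb, genes), 0.2, 0.1)
            assert [(r.drug, r.best_dscore, r.best_gscore) for r in got] == \
                [(r.drug, r.best_dscore, r.best_gscore) for r in oracle]


class TestDruggability:
    def test_clone_equal_to_region_scores_one(self, fixtures):
        # C2's complement is exactly R3's union in the CRUK0056 tree
        fx = fixtures["CRUK0056"]
        assert clone_druggability(fx.arch, "R3", "C2", fx.kb) == 1.0

    def test_clone_without_druggable_genes_scores_zero(self):
        arch = ClonalArchitecture(
            [Clone("A", None, frozenset({"x"})), Clone("B", "A", frozenset({"y"}))],
            [SampleComposition("S", {"A": 0.5, "B": 0.5})])
        kb = EvidenceKB([EvidenceEntry("Y", "d", 0.5, 0.8, "sensitivity",
                                       "biomarker", "approved")])
        # A carries only X which has no KB entry
        assert clone_druggability(arch, "S", "A", kb) == 0.0

    def test_no_druggable_region_warns_and_returns_zero(self):
        arch = ClonalArchitecture([Clone("A", None, frozenset({"x"}))],
                                  [SampleComposition("S", {"A": 1.0})])
        with pytest.warns(UserWarning, match="no druggable"):
            assert clone_druggability(arch, "S", "A", EvidenceKB([])) == 0.0

    def test_matches_set_ratio_oracle_and_bounded(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            arch = random_architecture(rng, n_clones=5, n_samples=2)
            kb = random_kb(rng, n_genes=40, n_entries=40)
            for sid in arch.sample_ids:
                region = {g for g in region_union_genes(arch, sid)
                          if kb.entries_for_gene(g)}
                if not region:
                    continue
                for cid in arch.clone_ids:
                    frac = clone_druggability(arch, sid, cid, kb)
                    clone = {g for g in full_complement(arch, cid)
                             if kb.entries_for_gene(g)}
                    assert frac == pytest.approx(len(clone & region) / len(region))
                    assert 0.0 <= frac <= 1.0

    def test_cruk0056_c3_carries_all_region_targets(self, fixtures):
        """In R2 the minority clone C3 holds all 31 targetable genes while
        the predominant C4 holds 25 of them."""
        fx = fixtures["CRUK0056"]
        assert clone_druggability(fx.arch, "R2", "C3", fx.kb) == pytest.approx(1.0)
        assert clone_druggability(fx.arch, "R2", "C4", fx.kb) == pytest.approx(25 / 31)


class TestBulkVsIth:
    def test_cruk0056_r2_counts(self, fixtures):
        fx = fixtures["CRUK0056"]
        cmp = bulk_vs_ith(fx.arch, "R2", fx.kb)
        assert (cmp.bulk_gene_count, cmp.ith_gene_count) == (119, 130)
        assert (len(cmp.bulk_druggable_genes), len(cmp.ith_druggable_genes)) == (25, 31)
        assert cmp.bulk_clone == "C4"

    def test_single_clone_sample_bulk_equals_ith(self):
        arch = ClonalArchitecture([Clone("A", None, frozenset({"x", "y"}))],
                                  [SampleComposition("S", {"A": 1.0})])
        kb = EvidenceKB([EvidenceEntry("X", "d", 0.5, 0.8, "sensitivity",
                                       "biomarker", "approved")])
        cmp = bulk_vs_ith(arch, "S", kb)
        assert cmp.bulk_gene_count == cmp.ith_gene_count
        assert cmp.bulk_druggable_genes == cmp.ith_druggable_genes
        assert [r.drug for r in cmp.bulk_drugs] == [r.drug for r in cmp.ith_drugs]

    def test_bulk_subset_of_ith_over_random_instances(self):
        """Set-inclusion property: bulk never reveals more than ITH.

        Drug lists nest when evidence is sensitivity-only; with resistance
        entries in play a drug can drop out of the ITH ranking because the
        wider profile triggers the veto, so only gene-level inclusion is
        universal.
        """
        rng = np.random.default_rng(29)
        for _ in range(30):
            arch = random_architecture(rng, n_clones=6, n_samples=2)
            kb = random_kb(rng, n_genes=40, n_entries=50, sensitivity_prob=1.0)
            for sid in arch.sample_ids:
                cmp = bulk_vs_ith(arch, sid, kb, Thresholds(0.2, 0.0))
                assert cmp.bulk_gene_count <= cmp.ith_gene_count
                assert cmp.bulk_druggable_genes <= cmp.ith_druggable_genes
                assert {r.drug for r in cmp.bulk_drugs} <= {r.drug for r in cmp.ith_drugs}

    def test_counts_equal_component_oracles(self):
        rng = np.random.default_rng(37)
        arch = random_architecture(rng, n_clones=5)
        kb = random_kb(rng, n_genes=40, n_entries=40)
        sid = arch.sample_ids[0]
        cmp = bulk_vs_ith(arch, sid, kb)
        assert cmp.bulk_gene_count == len(full_complement(arch, predominant_clone(arch, sid)))
        assert cmp.ith_gene_count == len(region_union_genes(arch, sid))


class TestClassifyResponse:
    KB = EvidenceKB([
        EvidenceEntry("SENS", "cetuximab", 0.9, 0.9, "sensitivity", "biomarker", "approved"),
        EvidenceEntry("RES", "cetuximab", 0.9, -0.9, "resistance", "biomarker", "approved"),
        EvidenceEntry("OFF", "otherdrug", 0.9, 0.9, "sensitivity", "biomarker", "approved"),
    ])
    CLASS = {"cetuximab", "panitumumab"}

    def test_sensitivity_only_is_responder(self):
        lab = classify_response("p", {"SENS", "BG"}, self.CLASS, self.KB)
        assert (lab.label, lab.reason) == ("responder", "sensitivity_only")

    def test_resistance_beats_sensitivity(self):
        lab = classify_response("p", {"SENS", "RES"}, self.CLASS, self.KB)
        assert (lab.label, lab.reason) == ("non_responder", "resistance_present")

    def test_off_class_evidence_does_not_count(self):
        lab = classify_response("p", {"OFF"}, self.CLASS, self.KB)
        assert (lab.label, lab.reason) == ("non_responder", "no_evidence")

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            classify_response("p", {"SENS"}, set(), self.KB)

    def test_random_profiles_match_three_way_oracle(self):
        rng = np.random.default_rng(41)
        kb = random_kb(rng, n_genes=20, n_entries=60)
        drugs = sorted(kb.drugs)
        drug_class = set(drugs[: max(1, len(drugs) // 3)])
        reasons = set()
        for i in range(500):
            genes = {f"G{j}" for j in rng.choice(20, size=rng.integers(1, 8),
                                                 replace=False)}
            lab = classify_response(f"p{i}", genes, drug_class, kb)
            relevant = [e for e in kb.entries
                        if e.gene in genes and e.drug in drug_class]
            if any(e.response == "resistance" for e in relevant):
                expected = ("non_responder", "resistance_present")
            elif any(e.response == "sensitivity" for e in relevant):
                expected = ("responder", "sensitivity_only")
            else:
                expected = ("non_responder", "no_evidence")
            assert (lab.label, lab.reason) == expected
            reasons.add(lab.reason)
        # over 500 random profiles all three exclusive categories occur
        assert reasons == {"sensitivity_only", "resistance_present", "no_evidence"}


class TestAlternativeTherapies:
    def test_only_candidates_excluded_gives_empty(self):
        kb = EvidenceKB([EvidenceEntry("A", "onlydrug", 0.9, 0.9, "sensitivity",
                                       "biomarker", "approved")])
        assert alternative_therapies({"A"}, {"onlydrug"}, kb) == []

    def test_empty_exclusion_is_identity(self, small_kb):
        genes = {"BRAF", "EGFR", "TP53"}
        assert alternative_therapies(genes, set(), small_kb) == \
            prescribe_profile(genes, small_kb)

    def test_matches_prescribe_then_remove_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            kb = random_kb(rng, n_genes=15, n_entries=40)
            genes = {f"G{i}" for i in rng.choice(15, size=6, replace=False)}
            drugs = sorted(kb.drugs)
            excl = set(drugs[::2])
            got = alternative_therapies(genes, excl, kb, Thresholds(0.2, 0.0))
            oracle = [r for r in prescribe_profile(genes, kb, Thresholds(0.2, 0.0))
                      if r.drug not in excl]
            assert got == oracle

    def test_records_retain_drug_status(self, small_kb):
        recs = alternative_therapies({"MET"}, {"erlotinib"}, small_kb)
        assert recs and recs[0].drug_status == "clinical_trials"


def test_druggable_genes_strict_mode(small_kb):
    genes = {"EGFR", "KRAS", "NOSUCH"}
    assert druggable_genes(genes, small_kb) == {"EGFR", "KRAS"}
    # strict: only sensitivity entries above the DScore rule count
    assert druggable_genes(genes, small_kb, strict=True) == {"EGFR"}
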