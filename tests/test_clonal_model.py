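"""Clonal architecture: complements, trunk, region unions, predominant
clone, temporal selection and event bookkeeping."""

import numpy as np
import pytest

from clonotherapy.clonal_model import (
    Clone,
    ClonalArchitecture,
    SampleComposition,
    TemporalVafProfile,
    full_complement,
    load_vaf_table,
    partition_events,
    predominant_clone,
    region_union_genes,
    select_temporal_genes,
    trunk_genes,
)

from conftest import random_architecture


def _oracle_complement(arch, cid):
    genes = set()
    while cid is not None:
        genes |= arch.clones[cid].novel_genes
        cid = arch.clones[cid].parent
    return genes


class TestArchitectureValidation:
    def test_exactly_one_root_required(self):
        with pytest.raises(ValueError, match="root"):
            ClonalArchitecture([Clone("A", "B", frozenset()), Clone("B", "A", frozenset())], [])
        with pytest.raises(ValueError, match="root"):
            ClonalArchitecture(
                [Clone("A", None, frozenset()), Clone("B", None, frozenset())], [])

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="unknown parent"):
            ClonalArchitecture([Clone("A", None, frozenset()),
                                Clone("B", "X", frozenset())], [])

    def test_prevalence_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SampleComposition("S", {"A": 0.5, "B": 0.4})

    def test_prevalence_keys_must_be_declared(self):
        with pytest.raises(ValueError, match="unknown clones"):
            ClonalArchitecture([Clone("A", None, frozenset())],
                               [SampleComposition("S", {"B": 1.0})])

    def test_json_roundtrip(self, tmp_path):
        arch = random_architecture(np.random.default_rng(0))
        arch.to_json(tmp_path / "a.json")
        again = ClonalArchitecture.from_json(tmp_path / "a.json")
        assert arch.to_dict() == again.to_dict()

    def test_full_complement_file_converted_to_novel_sets(self):
        d = {
            "clones": [
                {"id": "A", "parent": None, "novel_genes": ["x"]},
                {"id": "B", "parent": "A", "novel_genes": ["x", "y"]},
            ],
            "samples": [],
        }
        arch = ClonalArchitecture.from_dict(d, full_complements=True)
        assert arch.clones["B"].novel_genes == {"Y"}
        assert full_complement(arch, "B") == {"X", "Y"}


class TestComplementAndTrunk:
    def test_root_complement_is_its_novel_set(self):
        arch = ClonalArchitecture([Clone("R", None, frozenset({"a", "b"}))], [])
        assert full_complement(arch, "R") == {"A", "B"}

    def test_chain_unions_novel_sets(self):
        arch = ClonalArchitecture([
            Clone("A", None, frozenset({"x"})), Clone("B", "A", frozenset({"y"})),
        ], [])
        assert full_complement(arch, "B") == {"X", "Y"}

    def test_unknown_clone_raises(self):
        arch = ClonalArchitecture([Clone("A", None, frozenset())], [])
        with pytest.raises(KeyError):
            full_complement(arch, "Z")

    def test_random_trees_match_path_walk_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            arch = random_architecture(rng, n_clones=8)
            for cid in arch.clone_ids:
                assert full_complement(arch, cid) == _oracle_complement(arch, cid)

    def test_complement_monotone_along_paths(self):
        rng = np.random.default_rng(4)
        arch = random_architecture(rng, n_clones=8)
        for c in arch.clones.values():
            if c.parent is not None:
                assert full_complement(arch, c.parent) <= full_complement(arch, c.id)

    def test_single_clone_trunk_is_complement(self):
        arch = ClonalArchitecture([Clone("A", None, frozenset({"x", "y"}))], [])
        assert trunk_genes(arch) == {"X", "Y"}

    def test_trunk_matches_brute_force_intersection(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            arch = random_architecture(rng, n_clones=6)
            oracle = set.intersection(
                *(_oracle_complement(arch, c) for c in arch.clone_ids))
            assert trunk_genes(arch) == oracle
            for cid in arch.clone_ids:
                assert trunk_genes(arch) <= full_complement(arch, cid)

    def test_cruk0056_trunk_is_116_genes(self, fixtures):
        assert len(trunk_genes(fixtures["CRUK0056"].arch)) == 116


class TestRegionAndPredominant:
    def test_one_clone_sample(self):
        arch = ClonalArchitecture(
            [Clone("A", None, frozenset({"x"}))],
            [SampleComposition("S", {"A": 1.0})])
        assert region_union_genes(arch, "S") == {"X"}
        assert predominant_clone(arch, "S") == "A"

    def test_cruk0056_r2_reveals_130_genes(self, fixtures):
        arch = fixtures["CRUK0056"].arch
        assert len(region_union_genes(arch, "R2")) == 130

    def test_cruk0056_r2_predominant_is_c4(self, fixtures):
        arch = fixtures["CRUK0056"].arch
        assert predominant_clone(arch, "R2") == "C4"
        assert arch.samples["R2"].prevalence["C4"] == pytest.approx(0.88)

    def test_unknown_sample_raises(self, fixtures):
        with pytest.raises(KeyError):
            region_union_genes(fixtures["CRUK0056"].arch, "R9")

    def test_random_architectures_match_union_and_argmax_oracles(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            arch = random_architecture(rng, n_clones=6, n_samples=3)
            for sid in arch.sample_ids:
                prev = arch.samples[sid].prevalence
                present = [c for c, p in prev.items() if p > 0]
                union = set().union(*(_oracle_complement(arch, c) for c in present))
                assert region_union_genes(arch, sid) == union
                argmax = max(sorted(present), key=lambda c: prev[c])
                assert predominant_clone(arch, sid) == argmax
                # ITH never reveals fewer genes than the bulk approximation
                assert union >= full_complement(arch, predominant_clone(arch, sid))

    def test_tie_warns_and_picks_lexicographically_smallest(self):
        arch = ClonalArchitecture(
            [Clone("A", None, frozenset({"x"})), Clone("B", "A", frozenset({"y"}))],
            [SampleComposition("S", {"B": 0.5, "A": 0.5})])
        with pytest.warns(UserWarning, match="tie"):
            assert predominant_clone(arch, "S") == "A"


class TestTemporalSelection:
    def test_upn933124_selects_20_genes(self, fixtures):
        fx = fixtures["UPN933124"]
        sel = select_temporal_genes(fx.vaf_profiles, "diagnosis", "relapse")
        assert len(sel.genes) == 20
        assert sel.relapse_specific == {"ETV6", "TMEM117"}
        assert {"ERBB4", "FLT4"} <= sel.pre_existing

    def test_gene_high_at_both_timepoints_excluded(self):
        p = TemporalVafProfile("X", {"t0": 0.4, "t1": 0.4})
        sel = select_temporal_genes([p], "t0", "t1")
        assert sel.genes == set()

    def test_thresholds_validated(self):
        p = [TemporalVafProfile("X", {"t0": 0.001, "t1": 0.4})]
        with pytest.raises(ValueError):
            select_temporal_genes(p, "t0", "t1", low_vaf=0.5, rise_min=0.1)
        with pytest.raises(KeyError):
            select_temporal_genes(p, "t0", "t9")

    def test_random_profiles_match_predicate_scan_oracle(self):
        rng = np.random.default_rng(31)
        profiles = []
        for i in range(100):
            vafs = {}
            if rng.random() < 0.8:
                vafs["t0"] = float(rng.uniform(0, 0.5) ** 2)
            if rng.random() < 0.9:
                vafs["t1"] = float(rng.uniform(0, 0.5))
            if not vafs:
                vafs["t0"] = 0.2
            profiles.append(TemporalVafProfile(f"G{i}", vafs))
        sel = select_temporal_genes(profiles, "t0", "t1", low_vaf=0.01, rise_min=0.10)
        pre, rel = set(), set()
        for p in profiles:
            v0, v1 = p.vaf_by_timepoint.get("t0"), p.vaf_by_timepoint.get("t1")
            if v1 is not None and v1 >= 0.10:
                if v0 is None:
                    rel.add(p.gene)
                elif v0 < 0.01:
                    pre.add(p.gene)
        assert (sel.pre_existing, sel.relapse_specific) == (pre, rel)


class TestPartitionEvents:
    @pytest.mark.parametrize("a,b,expected", [
        ({"1", "2"}, {"3", "4", "5"}, (0, 2, 3)),
        ({"1", "2", "3", "4", "5"}, {"1", "2", "3", "4", "5"}, (5, 0, 0)),
        (set(), set(), (0, 0, 0)),
    ])
    def test_set_partition(self, a, b, expected):
        assert partition_events(a, b) == expected

    def test_counts_sum_to_union_cardinality(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = {f"e{i}" for i in rng.choice(100, size=40, replace=False)}
            b = {f"e{i}" for i in rng.choice(100, size=40, replace=False)}
            sh, ao, bo = partition_events(a, b)
            assert sh + ao + bo == len(a | b)

    def test_upn933124_event_bookkeeping(self, fixtures):
        fx = fixtures["UPN933124"]
        assert partition_events(fx.primary_events, fx.relapse_events) == (330, 5, 78)
        assert len(fx.primary_events | fx.relapse_events) == 413


def test_load_vaf_table(tmp_path):
    p = tmp_path / "vaf.tsv"
    p.write_text("gene\ttimepoint\tvaf\nerbb4\tdiagnosis\t0.005\nERBB4\trelapse\t0.35\n")
    profiles = load_vaf_table(p)
    assert len(profiles) == 1
    assert profiles[0].gene == "ERBB4"
    assert profiles[0].vaf_by_timepoint == {"diagnosis": 0.005, "relapse": 0.35}
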