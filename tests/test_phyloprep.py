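"""Concatenation, circular-permutation normalization, clustering, dataset rules."""

import random

import pytest

from lipomap import phyloprep
from lipomap.model import (
    DomainHit,
    DomainOrder,
    FunctionalAnnotation,
    GeneCluster,
    GeneRecord,
    Label,
    PhyloRecord,
    Provenance,
)
from lipomap.profiles import build_profile

TAX = "d__Bacteria;p__P;c__C;o__O;f__F;g__G;s__G s"


def rec(seq, rid="r1", provenance=Provenance.NATIVE, label=Label.LPL):
    return PhyloRecord(rid, seq, ((label.value, 1, len(seq)),), provenance, label)


class TestCpNormalize:
    def test_rotation_example(self):
        out = phyloprep.cp_normalize(rec("BBBBAAAA"), boundary=4)
        assert out.sequence == "AAAABBBB"
        assert out.provenance is Provenance.CP_NORMALIZED
        assert out.partitions == (("LplA", 1, 4), ("LplB", 5, 8))

    def test_already_canonical_record_unchanged(self):
        r = rec("AAAABBBB")
        out = phyloprep.cp_normalize(r, boundary=4, domain_order=DomainOrder.A_THEN_B)
        assert out is r and out.provenance is Provenance.NATIVE

    def test_complementary_boundaries_invert(self):
        rng = random.Random(1)
        for _ in range(25):
            n = rng.randrange(2, 60)
            s = "".join(rng.choice("ACDEFGHIK") for _ in range(n))
            b = rng.randrange(1, n)
            once = phyloprep.cp_normalize(rec(s), b)
            twice = phyloprep.cp_normalize(once, n - b)
            assert twice.sequence == s  # rotation inverse
            assert len(once) == n  # bijection preserves length

    @pytest.mark.parametrize("bad", [0, 8, -3, 100])
    def test_boundary_outside_sequence_is_hard_error(self, bad):
        with pytest.raises(ValueError):
            phyloprep.cp_normalize(rec("BBBBAAAA"), bad)

    def test_boundary_from_envelopes_is_gap_midpoint(self):
        b_hit = DomainHit("p", "PF10437", 60, 25, 4, 95)
        a_hit = DomainHit("p", "TIGR00545", 200, 100, 107, 330)
        assert phyloprep.cp_boundary_from_envelopes(b_hit, a_hit) == 101
        with pytest.raises(ValueError):
            phyloprep.cp_boundary_from_envelopes(a_hit, b_hit)


def syntenic_setup(seq_a, seq_b, syntenic=True):
    anns = {
        "pa": FunctionalAnnotation("pa", Label.LPL, DomainHit("pa", "T", 100, 50, 1, 50)),
        "pb": FunctionalAnnotation("pb", Label.LPLB, DomainHit("pb", "P", 100, 50, 1, 50)),
    }
    sequences = {"pa": seq_a, "pb": seq_b}
    if syntenic:
        genes = [
            GeneRecord("G1", "c1", 0, 1, 90, "+", "pa"),
            GeneRecord("G1", "c1", 1, 101, 190, "+", "pb"),
        ]
        clusters = [GeneCluster("G1", "c1", [(genes[0], anns["pa"]), (genes[1], anns["pb"])])]
    else:
        clusters = [
            GeneCluster("G1", "c1", [(GeneRecord("G1", "c1", 0, 1, 90, "+", "pa"), anns["pa"])]),
            GeneCluster("G1", "c2", [(GeneRecord("G1", "c2", 0, 1, 90, "+", "pb"), anns["pb"])]),
        ]
    return anns, clusters, sequences


class TestConcatSyntenicPair:
    def test_syntenic_pair_concatenated_with_partitions(self):
        anns, clusters, seqs = syntenic_setup("A" * 230, "B" * 90)
        out = phyloprep.concat_syntenic_pair("G1", anns, clusters, seqs)
        assert out is not None and len(out) == 320
        assert out.partitions == (("LplA", 1, 230), ("LplB", 231, 320))
        assert out.provenance is Provenance.CONCAT_SYNTENIC

    def test_non_syntenic_pair_absent(self):
        anns, clusters, seqs = syntenic_setup("A" * 230, "B" * 90, syntenic=False)
        assert phyloprep.concat_syntenic_pair("G1", anns, clusters, seqs) is None

    def test_whitelisted_genome_included_despite_separated_genes(self):
        anns, clusters, seqs = syntenic_setup("A" * 230, "B" * 90, syntenic=False)
        out = phyloprep.concat_syntenic_pair("G1", anns, clusters, seqs, whitelist={"G1"})
        assert out is not None and len(out) == 320


def lipS1S2_setup(n_s1=1, n_s2=1, s1_len=320, s2_len=330):
    anns, seqs = {}, {}
    for i in range(n_s1):
        pid = f"s1_{i}"
        anns[pid] = FunctionalAnnotation(pid, Label.LIPS1, DomainHit(pid, "X", 150, 100, 1, 50))
        seqs[pid] = "S" * s1_len
    for i in range(n_s2):
        pid = f"s2_{i}"
        anns[pid] = FunctionalAnnotation(pid, Label.LIPS2, DomainHit(pid, "Y", 150, 100, 1, 50))
        seqs[pid] = "T" * s2_len
    profile = build_profile("G1", anns, TAX)
    return profile, anns, seqs


class TestConcatLipS1S2:
    def test_single_copies_concatenated_in_order(self):
        profile, anns, seqs = lipS1S2_setup()
        out = phyloprep.concat_lipS1S2(profile, anns, seqs)
        assert out is not None and len(out) == 650
        assert out.partitions[0][0] == "LipS1" and out.partitions[1][0] == "LipS2"

    def test_paralogous_copies_excluded(self):
        profile, anns, seqs = lipS1S2_setup(n_s1=2)
        assert phyloprep.concat_lipS1S2(profile, anns, seqs) is None

    def test_missing_partner_excluded(self):
        profile, anns, seqs = lipS1S2_setup(n_s2=0)
        assert phyloprep.concat_lipS1S2(profile, anns, seqs) is None

    def test_incomplete_subunit_filtered_against_cohort_median(self):
        profile, anns, seqs = lipS1S2_setup(s1_len=100)
        medians = {Label.LIPS1: 320.0, Label.LIPS2: 330.0}
        assert phyloprep.concat_lipS1S2(profile, anns, seqs, medians) is None
        profile2, anns2, seqs2 = lipS1S2_setup()
        assert phyloprep.concat_lipS1S2(profile2, anns2, seqs2, medians) is not None

    def test_concatenation_length_additivity_random(self):
        rng = random.Random(8)
        for _ in range(20):
            a, b = rng.randrange(60, 400), rng.randrange(60, 400)
            profile, anns, seqs = lipS1S2_setup(s1_len=a, s2_len=b)
            out = phyloprep.concat_lipS1S2(profile, anns, seqs)
            assert len(out) == a + b
            assert out.partitions == (("LipS1", 1, a), ("LipS2", a + 1, a + b))


class TestClusterBySimilarity:
    def seqs(self, rng, base, n, mut=0.02):
        out = []
        for i in range(n):
            s = list(base)
            for j in range(len(s)):
                if rng.random() < mut:
                    s[j] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
            out.append(rec("".join(s), rid=f"r{base[:3]}{i}"))
        return out

    def test_identical_sequences_merge_to_one(self):
        records = [rec("M" * 100, "a"), rec("M" * 100, "b")]
        assert len(phyloprep.cluster_by_similarity(records, 0.7)) == 1

    def test_distinct_sequences_below_threshold_all_retained(self):
        rng = random.Random(2)
        records = [
            rec("".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(150)), rid=f"r{i}")
            for i in range(8)
        ]
        assert len(phyloprep.cluster_by_similarity(records, 0.7)) == 8

    def test_threshold_zero_collapses_to_one_representative(self):
        rng = random.Random(2)
        records = [
            rec("".join(rng.choice("ACDEFGHIK") for _ in range(100)), rid=f"r{i}")
            for i in range(5)
        ]
        assert len(phyloprep.cluster_by_similarity(records, 0.0)) == 1

    def test_threshold_one_merges_only_exact_duplicates(self):
        near = rec("M" * 99 + "A", "near")
        records = [rec("M" * 100, "a"), rec("M" * 100, "b"), near]
        reps = phyloprep.cluster_by_similarity(records, 1.0)
        assert len(reps) == 2 and any(r.record_id == "near" for r in reps)

    def test_planted_identity_groups_recovered(self):
        rng = random.Random(77)
        records = []
        for g in range(5):
            base = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(200))
            records.extend(self.seqs(rng, base, 10))
        reps = phyloprep.cluster_by_similarity(records, 0.5)
        assert len(reps) == 5

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            phyloprep.cluster_by_similarity([], 0.7)


def example_pool():
    pool = phyloprep.RecordPool()
    pool.ligases = [
        rec("A" * 300, "lig_native"),
        rec("C" * 320, "lig_concat", Provenance.CONCAT_SYNTENIC),
        rec("D" * 310, "lig_cp", Provenance.CP_NORMALIZED),
    ]
    pool.lipB = [rec("E" * 220, "lipB1", label=Label.LIPB)]
    pool.lipM = [rec("F" * 270, "lipM1", label=Label.LIPM)]
    pool.lipS1S2 = [rec("G" * 650, "s12", Provenance.CONCAT_LIPS1S2, Label.LIPS1)]
    pool.lipS1 = [rec("H" * 320, "s1", label=Label.LIPS1)]
    pool.lipS2 = [rec("I" * 330, "s2", label=Label.LIPS2)]
    pool.outgroups = {
        "BirA": [rec("K" * 320, "birA", Provenance.OUTGROUP, Label.BIRA)],
        "BioB": [rec("L" * 330, "bioB", Provenance.OUTGROUP, Label.BIOB)],
        "clade2": [rec("M" * 330, "clade2_lpl", Provenance.OUTGROUP)],
    }
    return pool


class TestBuildDataset:
    def test_full_superset_contains_transferases_and_bira_root(self):
        records, manifest = phyloprep.build_dataset("full_ligase_transferase", example_pool())
        ids = [r.record_id for r in records]
        assert {"lig_native", "lig_concat", "lig_cp", "lipB1", "lipM1", "birA"} <= set(ids)
        assert manifest.n_included == len(records)

    def test_strict_clade3_variant_excludes_permuted_and_lipm(self):
        records, manifest = phyloprep.build_dataset("clade3_no_LipM_no_cp", example_pool())
        assert all(r.provenance is not Provenance.CP_NORMALIZED for r in records)
        assert all(r.label is not Label.LIPM for r in records)
        excluded = {rid for rid, inc, _ in manifest.entries if not inc}
        assert excluded == {"lig_cp", "lipM1"}

    def test_cp_variant_keeps_permuted_but_not_lipm(self):
        records, _ = phyloprep.build_dataset("clade3_with_cp", example_pool())
        ids = {r.record_id for r in records}
        assert "lig_cp" in ids and "lipM1" not in ids

    def test_rooted_synthase_sets_carry_biob_outgroup(self):
        for name in ("lipS1_rooted", "lipS2_rooted"):
            records, _ = phyloprep.build_dataset(name, example_pool())
            assert any(r.label is Label.BIOB for r in records)

    def test_manifest_accounts_for_every_candidate_exactly_once(self):
        pool = example_pool()
        for name in phyloprep.DATASET_NAMES:
            records, manifest = phyloprep.build_dataset(name, pool)
            seen = [rid for rid, _, _ in manifest.entries]
            assert len(seen) == len(set(seen))
            included = {rid for rid, inc, _ in manifest.entries if inc}
            assert included == {r.record_id for r in records}

    def test_empty_selection_is_hard_error(self):
        with pytest.raises(ValueError):
            phyloprep.build_dataset("lipS1S2_concat", phyloprep.RecordPool(ligases=[rec("A" * 10)]))

    def test_unknown_dataset_name_rejected(self):
        with pytest.raises(ValueError):
            phyloprep.build_dataset("not_a_dataset", example_pool())


class TestToolManifest:
    def test_trimmer_and_tree_lines_carry_configured_parameters(self):
        records = [rec("A" * 300), rec("C" * 310, "r2")]
        cmds = phyloprep.emit_tool_manifest("demo", records)
        text = "\n".join(cmds)
        assert "-m BLOSUM30" in text and "-h 0.95" in text and "-b 1" in text
        assert "-alrt 2000" in text and "-bb 2000" in text and "-abayes" in text
        assert not any(c.startswith("mafft --add-fragments") for c in cmds)

    def test_short_records_trigger_two_stage_alignment(self):
        records = [rec("A" * 300), rec("B" * 100, "short")]
        cmds = phyloprep.emit_tool_manifest("demo", records)
        assert any("--add-fragments" in c and "--keeplength" in c for c in cmds)
        assert cmds[0].startswith("mafft")

    def test_partition_tiling_invariant_enforced_by_record_type(self):
        with pytest.raises(ValueError):
            PhyloRecord("bad", "AAAA", (("x", 1, 2), ("y", 4, 4)))
        with pytest.raises(ValueError):
            PhyloRecord("bad", "AAAA", (("x", 1, 5),))
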