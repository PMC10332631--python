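"""Genome profiles, pathway-system calling, ligase subtype classification."""

import itertools

import pytest

from lipomap import profiles
from lipomap.model import (
    DomainHit,
    DomainOrder,
    FunctionalAnnotation,
    GeneRecord,
    GenomeProfile,
    Label,
    LigaseSubtype,
    PathwaySystem,
)

TAX_B = "d__Bacteria;p__Proteobacteria;c__Gamma;o__O;f__F;g__G;s__G s"
TAX_A = "d__Archaea;p__Thermoproteota;c__C;o__O;f__F;g__G;s__G s"


def ann(pid, label, order=DomainOrder.NOT_APPLICABLE, lplb=False):
    if label is Label.NONE:
        return FunctionalAnnotation(pid)
    return FunctionalAnnotation(
        pid, label, DomainHit(pid, "X", 100, 50, 1, 50), lplb, order
    )


def profile_from_labels(labels, taxonomy=TAX_B, gid="G1"):
    anns = {f"p{i}": ann(f"p{i}", lab) for i, lab in enumerate(labels)}
    return profiles.build_profile(gid, anns, taxonomy)


class TestTaxonomyParsing:
    def test_parses_all_ranks(self):
        tax = profiles.parse_gtdb_taxonomy(TAX_B)
        assert tax["domain"] == "Bacteria" and tax["phylum"] == "Proteobacteria"
        assert tax["species"] == "G s"

    @pytest.mark.parametrize(
        "bad",
        [
            "d__Bacteria;p__X",  # wrong rank count
            "x__Bacteria;p__;c__;o__;f__;g__;s__",  # wrong prefix
            "d__Eukaryota;p__;c__;o__;f__;g__;s__",  # unknown domain
        ],
    )
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            profiles.parse_gtdb_taxonomy(bad)

    def test_cohort_builder_excludes_bad_taxonomy_with_warning(self, caplog):
        anns = {"G1": {"p0": ann("p0", Label.LIPA)}, "G2": {"p0": ann("p0", Label.LIPA)}}
        tax = {"G1": TAX_B, "G2": "not a taxonomy"}
        with caplog.at_level("WARNING"):
            out = profiles.build_profiles(anns, tax)
        assert [p.genome_id for p in out] == ["G1"]
        assert "excluded" in caplog.text


class TestBuildProfile:
    def test_flags_follow_labels(self):
        p = profile_from_labels([Label.LIPB, Label.LIPA, Label.GCVH])
        assert p.flag("LipB") and p.flag("LipA") and p.flag("LD")
        assert not any(p.flag(f) for f in ("Lpl", "LipM", "LipS1", "LipS2", "LipS1S2", "sHdr"))

    def test_both_synthase_subunits_required_for_pair_flag(self):
        p = profile_from_labels([Label.LIPS1])
        assert p.flag("LipS1") and not p.flag("LipS1S2")
        p2 = profile_from_labels([Label.LIPS1, Label.LIPS2])
        assert p2.flag("LipS1S2")

    def test_copy_counts_consistent_with_flags(self):
        p = profile_from_labels([Label.LPL, Label.LPL, Label.LIPA])
        assert p.count(Label.LPL) == 2 and p.flag("Lpl")
        assert p.count(Label.LIPB) == 0 and not p.flag("LipB")

    def test_domain_read_from_taxonomy(self):
        assert profile_from_labels([], TAX_A).domain == "Archaea"

    def test_synthetic_profiles_match_generator_manifest(
        self, small_cohort, annotated_small_cohort
    ):
        for g in small_cohort.genomes:
            _, _, _, profile = annotated_small_cohort[g.genome_id]
            truth_counts = {}
            for lab in g.truth.labels.values():
                truth_counts[lab] = truth_counts.get(lab, 0) + 1
            got = {l.value: n for l, n in profile.counts.items()}
            assert got == truth_counts


def oracle_systems(flags):
    """Independent restatement of the pathway rules for exhaustive checking."""
    lpl, lipb, lipm, lipa, s1, s2 = flags
    s12 = s1 and s2
    out = set()
    if lipb and lipa:
        out.add("LipB_LipA")
    if lipm and lipa:
        out.add("LipM_LipA")
    if lpl and lipa:
        out.add("Lpl_LipA")
    if lpl and s12:
        out.add("sLpl_LipS1S2")
    if lipm and s12 and not lpl:
        out.add("LipM_LipS1S2")
    if lpl and not lipa and not s12:
        out.add("Lpl_scavenging_only")
    return out or {"none"}


class TestCallPathways:
    LABELS = (Label.LPL, Label.LIPB, Label.LIPM, Label.LIPA, Label.LIPS1, Label.LIPS2)

    def test_exhaustive_flag_combinations_match_rule_oracle(self):
        for flags in itertools.product([False, True], repeat=6):
            labels = [lab for lab, f in zip(self.LABELS, flags) if f]
            call = profiles.call_pathways(profile_from_labels(labels))
            assert {s.value for s in call.systems} == oracle_systems(flags), flags

    def test_stated_implications_hold_for_all_combinations(self):
        for flags in itertools.product([False, True], repeat=6):
            labels = [lab for lab, f in zip(self.LABELS, flags) if f]
            p = profile_from_labels(labels)
            systems = profiles.call_pathways(p).systems
            if PathwaySystem.SLPL_LIPS1S2 in systems:
                assert p.flag("LipS1S2")
            if PathwaySystem.LPL_LIPA in systems:
                assert p.flag("Lpl") and p.flag("LipA")
            if PathwaySystem.LIPM_LIPS1S2 in systems:
                assert p.flag("LipM") and p.flag("LipS1S2") and not p.flag("Lpl")

    def test_removing_ligase_never_creates_lpl_lipa(self):
        """Monotone consistency: dropping the ligase from an sLpl-LipS1/S2 genome
        yields a synthase-without-ligase category, never Lpl/LipA."""
        with_lig = profile_from_labels([Label.LPL, Label.LIPS1, Label.LIPS2])
        assert PathwaySystem.SLPL_LIPS1S2 in profiles.call_pathways(with_lig).systems
        without = profile_from_labels([Label.LIPS1, Label.LIPS2])
        systems = profiles.call_pathways(without).systems
        assert PathwaySystem.LPL_LIPA not in systems
        assert PathwaySystem.SLPL_LIPS1S2 not in systems

    def test_all_flags_false_gives_none(self):
        call = profiles.call_pathways(profile_from_labels([]))
        assert call.systems == frozenset({PathwaySystem.NONE})


def genome_with_cluster(tokens, extra_labels=(), gid="G1"):
    """Build genes+annotations: `tokens` contiguous, extras far away."""
    genes, anns = [], {}
    for i, (pid_suffix, label, order, lplb) in enumerate(tokens):
        pid = f"{gid}_{pid_suffix}"
        genes.append(GeneRecord(gid, "c1", i, 100 * i + 1, 100 * i + 90, "+", pid))
        anns[pid] = ann(pid, label, order, lplb)
    base = len(tokens) + 10
    for j, label in enumerate(extra_labels):
        pid = f"{gid}_x{j}"
        genes.append(
            GeneRecord(gid, "c1", base + 6 * j, 1000 + 600 * j, 1090 + 600 * j, "+", pid)
        )
        anns[pid] = ann(pid, label)
    return genes, anns


class TestClassifyLigases:
    def classify(self, genes, anns, taxonomy=TAX_B):
        from lipomap import context

        profile = profiles.build_profile("G1", anns, taxonomy)
        clusters = context.find_clusters(genes, anns)
        return profiles.classify_ligases(profile, clusters, anns, genes)

    def test_fused_ligase_in_synthase_cluster_is_sulfur_subtype(self):
        genes, anns = genome_with_cluster(
            [
                ("s1", Label.LIPS1, DomainOrder.NOT_APPLICABLE, False),
                ("lig", Label.LPL, DomainOrder.A_THEN_B, True),
                ("t", Label.LIPT, DomainOrder.NOT_APPLICABLE, False),
                ("s2", Label.LIPS2, DomainOrder.NOT_APPLICABLE, False),
            ]
        )
        (call,) = self.classify(genes, anns)
        assert call.subtype is LigaseSubtype.SLPL_AB
        assert "context_with_lipS1S2" in call.rationale

    def test_fused_ligase_with_lipa_and_no_pair_synthase_is_classical(self):
        genes, anns = genome_with_cluster(
            [("lig", Label.LPL, DomainOrder.A_THEN_B, True)], extra_labels=[Label.LIPA]
        )
        (call,) = self.classify(genes, anns)
        assert call.subtype is LigaseSubtype.CLASSICAL_LPL
        assert "cooccurring_synthase_LipA" in call.rationale

    def test_unfused_catalytic_with_adjacent_accessory_gene_is_bipartite(self):
        genes, anns = genome_with_cluster(
            [
                ("a", Label.LPL, DomainOrder.NOT_APPLICABLE, False),
                ("b", Label.LPLB, DomainOrder.NOT_APPLICABLE, False),
            ],
            extra_labels=[Label.LIPS1, Label.LIPS2],
        )
        (call,) = self.classify(genes, anns)
        assert call.subtype is LigaseSubtype.BIPARTITE_LPLAB
        assert "syntenic_pair" in call.rationale

    def test_permuted_fusion_is_flagged_cp(self):
        genes, anns = genome_with_cluster(
            [("lig", Label.LPL, DomainOrder.B_THEN_A, True)], extra_labels=[Label.LIPA]
        )
        (call,) = self.classify(genes, anns)
        assert call.subtype is LigaseSubtype.CPLPL_BA
        assert "permuted" in call.rationale

    def test_sole_ligase_with_pair_synthase_elsewhere_is_sulfur_subtype(self):
        genes, anns = genome_with_cluster(
            [("lig", Label.LPL, DomainOrder.A_THEN_B, True)],
            extra_labels=[Label.LIPS1, Label.LIPS2],
        )
        (call,) = self.classify(genes, anns)
        assert call.subtype is LigaseSubtype.SLPL_AB
        assert "cooccurring_synthase_LipS1S2" in call.rationale

    def test_ligase_without_context_is_undetermined(self):
        genes, anns = genome_with_cluster(
            [("lig", Label.LPL, DomainOrder.A_THEN_B, True)]
        )
        (call,) = self.classify(genes, anns)
        assert call.subtype is LigaseSubtype.UNDETERMINED

    def test_planted_subtypes_recovered_from_simulated_genomes(
        self, small_cohort, catalog, annotated_small_cohort
    ):
        for g in small_cohort.genomes:
            if g.truth.ligase_subtype is None:
                continue
            anns, genes, clusters, profile = annotated_small_cohort[g.genome_id]
            calls = profiles.classify_ligases(profile, clusters, anns, genes)
            assert g.truth.ligase_subtype in {c.subtype.value for c in calls}


class TestGtdbMetadata:
    def test_species_representative_manifest(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "accession\tgtdb_taxonomy\tgtdb_representative\n"
            "GCA_1\td__Bacteria;p__P;c__C;o__O;f__F;g__G;s__G a\tt\n"
            "GCA_2\td__Bacteria;p__P;c__C;o__O;f__F;g__G;s__G a\tf\n"
            "GCA_3\td__Archaea;p__Q;c__C;o__O;f__F;g__G;s__G b\tt\n"
        )
        meta = profiles.read_gtdb_metadata(path)
        assert profiles.species_representatives(meta) == ["GCA_1", "GCA_3"]

    def test_fallback_one_per_species_without_representative_column(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "accession\tgtdb_taxonomy\n"
            "GCA_1\td__Bacteria;p__P;c__C;o__O;f__F;g__G;s__G a\n"
            "GCA_2\td__Bacteria;p__P;c__C;o__O;f__F;g__G;s__G a\n"
            "GCA_3\td__Bacteria;p__P;c__C;o__O;f__F;g__G;s__G b\n"
        )
        meta = profiles.read_gtdb_metadata(path)
        assert profiles.species_representatives(meta) == ["GCA_1", "GCA_3"]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("accession\tfoo\nGCA_1\tx\n")
        with pytest.raises(ValueError, match="gtdb_taxonomy"):
            profiles.read_gtdb_metadata(path)
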