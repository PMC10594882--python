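import dataclasses
import random

import pytest

from cardiacg2p import (
    apply_repertoire_constraints,
    check_allelic_requirement,
    passes_frequency,
    run_pipeline1,
    run_pipeline2,
    run_pipeline3_g2p,
)
from cardiacg2p.consequence import assign_variant_class, classify_nmd
from cardiacg2p.filtering import (
    FLAG_ALLELIC_REQUIREMENT_UNMET,
    FLAG_OUTSIDE_HOTSPOT,
    FLAG_UNCLASSIFIED,
    PipelineConfig,
)
from cardiacg2p.knowledge_base import KnowledgeBase, records_for_gene
from cardiacg2p.vocab import GenotypeCall, Panel, VariantClass
from tests._oracles import flat_pipeline3
from tests.conftest import make_variant

P1 = PipelineConfig(pipeline="generic_pav")
P2 = PipelineConfig(pipeline="lof_or_clinvar")
P3 = PipelineConfig(pipeline="g2p")


def tx_pos(toy_transcripts, gene, exon=0, offset=10):
    tm = toy_transcripts[f"TX_{gene}"]
    return tm.exons[exon][0] + offset


def panel_variant(toy_transcripts, gene, terms, **kw):
    kw.setdefault("pos", tx_pos(toy_transcripts, gene))
    return make_variant(gene=gene, transcript_id=f"TX_{gene}", so_terms=terms, **kw)


class TestFrequency:
    def test_below_threshold_passes(self):
        assert passes_frequency(make_variant(population_af=0.00009), P3)

    def test_at_threshold_fails_strictly(self):
        assert not passes_frequency(make_variant(population_af=0.0001), P3)

    def test_missing_af_follows_policy(self):
        absent = make_variant(population_af=None)
        assert passes_frequency(absent, P3)
        drop_cfg = dataclasses.replace(P3, missing_af_policy="drop")
        assert not passes_frequency(absent, drop_cfg)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(af_threshold=0.0)


class TestPipeline1:
    def test_rare_frameshift_retained(self, toy_transcripts):
        v = panel_variant(toy_transcripts, "MYH7", {"frameshift_variant"})
        result = run_pipeline1([v], {"MYH7"}, P1)
        assert result.decisions[0].retained

    def test_synonymous_dropped(self, toy_transcripts):
        v = panel_variant(toy_transcripts, "MYH7", {"synonymous_variant"})
        assert not run_pipeline1([v], {"MYH7"}, P1).decisions[0].retained

    def test_common_missense_dropped(self, toy_transcripts):
        v = panel_variant(toy_transcripts, "MYH7", {"missense_variant"}, population_af=0.01)
        decision = run_pipeline1([v], {"MYH7"}, P1).decisions[0]
        assert not decision.retained
        assert ("frequency", "fail", "allele frequency above threshold") in decision.stages

    def test_gene_outside_set_dropped(self, toy_transcripts):
        v = panel_variant(toy_transcripts, "MYH7", {"missense_variant"})
        assert not run_pipeline1([v], {"TTN"}, P1).decisions[0].retained


class TestPipeline2:
    def test_hc_lof_retained(self, toy_transcripts):
        v = panel_variant(toy_transcripts, "MYH7", {"frameshift_variant"}, lof_confidence="HC")
        assert run_pipeline2([v], {"MYH7"}, P2).decisions[0].retained

    def test_lc_lof_dropped(self, toy_transcripts):
        v = panel_variant(toy_transcripts, "MYH7", {"frameshift_variant"}, lof_confidence="LC")
        assert not run_pipeline2([v], {"MYH7"}, P2).decisions[0].retained

    def test_clinvar_likely_pathogenic_retained(self, toy_transcripts):
        v = panel_variant(
            toy_transcripts, "MYH7", {"missense_variant"},
            clinical_significance=("likely_pathogenic",),
        )
        assert run_pipeline2([v], {"MYH7"}, P2).decisions[0].retained

    def test_plain_missense_dropped(self, toy_transcripts):
        v = panel_variant(toy_transcripts, "MYH7", {"missense_variant"})
        assert not run_pipeline2([v], {"MYH7"}, P2).decisions[0].retained

    def test_conflicting_interpretation_does_not_count(self, toy_transcripts):
        v = panel_variant(
            toy_transcripts, "MYH7", {"missense_variant"},
            clinical_significance=("conflicting_interpretations_of_pathogenicity",),
        )
        assert not run_pipeline2([v], {"MYH7"}, P2).decisions[0].retained


class TestPipeline3:
    """Spec-level behaviour of the mechanism-aware filter."""

    def run_one(self, kb, toy_transcripts, variant, cfg=P3):
        result = run_pipeline3_g2p([variant], kb, cfg, transcripts=toy_transcripts)
        return result.decisions[0]

    def test_myh7_truncating_dropped(self, kb, toy_transcripts):
        # NMD-triggering truncation is not a disease-associated class for MYH7
        v = panel_variant(toy_transcripts, "MYH7", {"frameshift_variant"})
        decision = self.run_one(kb, toy_transcripts, v)
        assert not decision.retained
        assert decision.variant_class == "nmd_truncating"

    def test_mybpc3_truncating_retained(self, kb, toy_transcripts):
        v = panel_variant(toy_transcripts, "MYBPC3", {"frameshift_variant"})
        decision = self.run_one(kb, toy_transcripts, v)
        assert decision.retained
        assert ("MYBPC3", "hypertrophic cardiomyopathy") in decision.matched_records

    def test_ttn_missense_off_allowlist_dropped(self, kb, toy_transcripts):
        v = panel_variant(toy_transcripts, "TTN", {"missense_variant"})
        assert not self.run_one(kb, toy_transcripts, v).retained

    def test_ttn_missense_on_allowlist_retained(self, kb, toy_transcripts):
        v = panel_variant(
            toy_transcripts, "TTN", {"missense_variant"}, hgvs_p="p.Trp976Arg"
        )
        assert self.run_one(kb, toy_transcripts, v).retained

    def test_mybpc3_intronic_retained(self, kb, toy_transcripts):
        tm = toy_transcripts["TX_MYBPC3"]
        v = make_variant(
            gene="MYBPC3", transcript_id="TX_MYBPC3", pos=tm.exons[0][1] + 50,
            so_terms={"intron_variant"},
        )
        assert self.run_one(kb, toy_transcripts, v).retained

    def test_other_gene_intronic_dropped_and_flagged(self, kb, toy_transcripts):
        tm = toy_transcripts["TX_LMNA"]
        v = make_variant(
            gene="LMNA", transcript_id="TX_LMNA", pos=tm.exons[0][1] + 50,
            so_terms={"intron_variant"},
        )
        decision = self.run_one(kb, toy_transcripts, v)
        assert not decision.retained
        assert FLAG_UNCLASSIFIED in decision.flags

    def test_tmem43_allowlist(self, kb, toy_transcripts):
        hit = panel_variant(
            toy_transcripts, "TMEM43", {"missense_variant"}, hgvs_p="p.Ser358Leu"
        )
        miss = panel_variant(toy_transcripts, "TMEM43", {"missense_variant"}, hgvs_p="p.Arg28Trp")
        assert self.run_one(kb, toy_transcripts, hit).retained
        assert not self.run_one(kb, toy_transcripts, miss).retained

    def test_tmem43_one_letter_hgvs_also_matches(self, kb, toy_transcripts):
        v = panel_variant(toy_transcripts, "TMEM43", {"missense_variant"}, hgvs_p="p.S358L")
        assert self.run_one(kb, toy_transcripts, v).retained

    def test_ttn_exon_mask_drops_low_inclusion_exon(self, kb, toy_transcripts):
        tm = toy_transcripts["TX_TTN"]
        low = make_variant(
            gene="TTN", transcript_id="TX_TTN", pos=tm.exons[3][0] + 5,
            so_terms={"stop_gained"}, exon_rank=4,  # inclusion 0.5
        )
        high = make_variant(
            gene="TTN", transcript_id="TX_TTN", pos=tm.exons[2][0] + 5,
            so_terms={"stop_gained"}, exon_rank=3,  # inclusion 0.95
        )
        assert not self.run_one(kb, toy_transcripts, low).retained
        assert self.run_one(kb, toy_transcripts, high).retained

    def test_rbm20_hotspot_region_flags_but_does_not_drop(self, kb, toy_transcripts):
        inside = panel_variant(
            toy_transcripts, "RBM20", {"missense_variant"}, protein_pos=636
        )
        outside = panel_variant(
            toy_transcripts, "RBM20", {"missense_variant"}, protein_pos=100
        )
        d_in = self.run_one(kb, toy_transcripts, inside)
        d_out = self.run_one(kb, toy_transcripts, outside)
        assert d_in.retained and FLAG_OUTSIDE_HOTSPOT not in d_in.flags
        assert d_out.retained and FLAG_OUTSIDE_HOTSPOT in d_out.flags

    def test_panel_restriction(self, kb, toy_transcripts):
        v = panel_variant(toy_transcripts, "KCNQ1", {"missense_variant"})
        lqts_cfg = dataclasses.replace(P3, panels=frozenset({Panel.LQTS}))
        sqts_cfg = dataclasses.replace(P3, panels=frozenset({Panel.SQTS}))
        assert self.run_one(kb, toy_transcripts, v, lqts_cfg).retained
        # SQTS-only interrogation enforces the p.Val141Met allowlist
        assert not self.run_one(kb, toy_transcripts, v, sqts_cfg).retained


class TestRepertoireConstraintEdgeCases:
    def test_region_without_protein_pos_flags_annotation_incomplete(self, kb):
        (rbm20,) = records_for_gene(kb, "RBM20")
        v = make_variant(gene="RBM20", transcript_id="TX_RBM20", protein_pos=None)
        verdict, flags = apply_repertoire_constraints(
            v, rbm20, P3, variant_class=VariantClass.MISSENSE
        )
        assert verdict == "flag_only"
        assert "annotation_incomplete" in flags

    def test_constraint_mode_override_turns_allowlist_into_flag(self, kb, toy_transcripts):
        (tmem43,) = records_for_gene(kb, "TMEM43")
        v = make_variant(gene="TMEM43", transcript_id="TX_TMEM43", hgvs_p="p.Arg28Trp")
        flag_cfg = dataclasses.replace(P3, constraint_mode="flag")
        verdict, flags = apply_repertoire_constraints(
            v, tmem43, flag_cfg, variant_class=VariantClass.MISSENSE
        )
        assert verdict == "flag_only"
        assert "restricted_repertoire_mismatch" in flags


class TestAllelicRequirement:
    @pytest.fixture
    def biallelic_record(self, kb):
        return records_for_gene(kb, "TRDN", Panel.CPVT)[0]

    @pytest.fixture
    def monoallelic_record(self, kb):
        return records_for_gene(kb, "MYH7", Panel.HCM)[0]

    def test_single_het_cannot_satisfy_biallelic(self, biallelic_record):
        v = make_variant(gene="TRDN", genotypes={"S1": GenotypeCall.HET})
        assert not check_allelic_requirement([v], biallelic_record, "S1")

    def test_hom_alt_satisfies_biallelic(self, biallelic_record):
        v = make_variant(gene="TRDN", genotypes={"S1": GenotypeCall.HOM_ALT})
        assert check_allelic_requirement([v], biallelic_record, "S1")

    def test_two_hets_satisfy_biallelic(self, biallelic_record):
        # derived by enumerating genotype configurations: without phase, two
        # distinct het variants are the minimal non-hom_alt satisfying state
        v1 = make_variant(gene="TRDN", pos=100, genotypes={"S1": GenotypeCall.HET})
        v2 = make_variant(gene="TRDN", pos=200, genotypes={"S1": GenotypeCall.HET})
        for group in ([v1], [v2]):
            assert not check_allelic_requirement(group, biallelic_record, "S1")
        assert check_allelic_requirement([v1, v2], biallelic_record, "S1")

    def test_missing_genotypes_fail(self, biallelic_record):
        v = make_variant(gene="TRDN", genotypes=None)
        assert not check_allelic_requirement([v], biallelic_record, "S1")

    def test_single_het_satisfies_monoallelic(self, monoallelic_record):
        v = make_variant(genotypes={"S1": GenotypeCall.HET})
        assert check_allelic_requirement([v], monoallelic_record, "S1")

    def test_zygosity_mode_integration(self, kb, toy_transcripts):
        cfg = dataclasses.replace(P3, zygosity_mode="per_sample")
        base = dict(gene="TRDN", transcript_id="TX_TRDN", so_terms={"missense_variant"})
        tm = toy_transcripts["TX_TRDN"]
        single = make_variant(
            pos=tm.exons[0][0] + 1, genotypes={"S1": GenotypeCall.HET}, **base
        )
        result = run_pipeline3_g2p([single], kb, cfg, transcripts=toy_transcripts)
        assert not result.decisions[0].retained
        assert FLAG_ALLELIC_REQUIREMENT_UNMET in result.decisions[0].flags

        hom = make_variant(
            pos=tm.exons[0][0] + 2, genotypes={"S1": GenotypeCall.HOM_ALT}, **base
        )
        result = run_pipeline3_g2p([hom], kb, cfg, transcripts=toy_transcripts)
        assert result.decisions[0].retained

        pair = [
            make_variant(pos=tm.exons[0][0] + 3, genotypes={"S1": GenotypeCall.HET}, **base),
            make_variant(pos=tm.exons[0][0] + 4, genotypes={"S1": GenotypeCall.HET}, **base),
        ]
        result = run_pipeline3_g2p(pair, kb, cfg, transcripts=toy_transcripts)
        assert all(d.retained for d in result.decisions)


# ---------------------------------------------------------------------------
# Randomised invariants
# ---------------------------------------------------------------------------

_TERM_POOL = (
    "missense_variant", "synonymous_variant", "intron_variant", "stop_gained",
    "frameshift_variant", "splice_donor_variant", "splice_acceptor_variant",
    "inframe_deletion", "exon_loss_variant", "transcript_ablation", "duplication",
)
_AF_POOL = (None, 5e-5, 9.9e-5, 1e-4, 2e-4, 0.01)
_HGVS_POOL = (None, "p.Ser358Leu", "p.Val141Met", "p.Trp976Arg", "p.Gly10Arg")


def random_variants(n, toy_transcripts, seed=17):
    rng = random.Random(seed)
    genes = sorted({tm.gene for tm in toy_transcripts.values()})
    out = []
    for i in range(n):
        gene = rng.choice(genes)
        tm = toy_transcripts[f"TX_{gene}"]
        pos = rng.randint(tm.exons[0][0], tm.exons[-1][1])
        out.append(
            make_variant(
                chrom="chrT",
                pos=pos,
                ref="A",
                alt="GCT"[i % 3],
                gene=gene,
                transcript_id=tm.transcript_id,
                so_terms={rng.choice(_TERM_POOL)},
                population_af=rng.choice(_AF_POOL),
                hgvs_p=rng.choice(_HGVS_POOL),
                protein_pos=rng.choice((None, rng.randint(1, 700))),
                exon_rank=rng.choice((None, rng.randint(1, tm.n_exons))),
                splice_evidence=rng.random() < 0.2,
                lof_confidence=rng.choice((None, "HC", "LC")),
            )
        )
    return out


def assigned_class(variant, toy_transcripts):
    tm = toy_transcripts.get(variant.transcript_id)
    try:
        return assign_variant_class(variant, classify_nmd(tm, variant))
    except ValueError:
        return None


class TestEngineInvariants:
    def test_retained_subset_of_frequency_passing_subset_of_input(
        self, kb, toy_transcripts
    ):
        variants = random_variants(1000, toy_transcripts)
        freq_pass = {v.key for v in variants if passes_frequency(v, P3)}
        all_keys = {v.key for v in variants}
        gene_set = kb.genes()
        for result in (
            run_pipeline1(variants, gene_set, P1),
            run_pipeline2(variants, gene_set, P2),
            run_pipeline3_g2p(variants, kb, P3, transcripts=toy_transcripts),
        ):
            retained = {d.variant_key for d in result.decisions if d.retained}
            assert retained <= freq_pass <= all_keys

    def test_flat_oracle_agrees_with_staged_engine_on_1000_variants(
        self, kb, toy_transcripts
    ):
        variants = random_variants(1000, toy_transcripts)
        result = run_pipeline3_g2p(variants, kb, P3, transcripts=toy_transcripts)
        for variant, decision in zip(variants, result.decisions):
            vc = assigned_class(variant, toy_transcripts)
            expected = flat_pipeline3(
                variant, vc, kb, P3.panels, toy_transcripts
            )
            assert decision.retained == expected, (variant, decision.stages)

    def test_adding_a_class_never_shrinks_retained_set(self, kb, toy_transcripts):
        variants = random_variants(300, toy_transcripts, seed=23)
        baseline = {
            d.variant_key
            for d in run_pipeline3_g2p(variants, kb, P3, transcripts=toy_transcripts).decisions
            if d.retained
        }
        widened_records = [
            dataclasses.replace(
                r, variant_classes=r.variant_classes | {VariantClass.NMD_TRUNCATING}
            )
            if r.gene == "MYH7"
            else r
            for r in kb.records
        ]
        widened = {
            d.variant_key
            for d in run_pipeline3_g2p(
                variants, KnowledgeBase(widened_records), P3, transcripts=toy_transcripts
            ).decisions
            if d.retained
        }
        assert baseline <= widened

    def test_removing_a_restrict_constraint_never_shrinks_retained_set(
        self, kb, toy_transcripts
    ):
        variants = random_variants(300, toy_transcripts, seed=29)
        baseline = {
            d.variant_key
            for d in run_pipeline3_g2p(variants, kb, P3, transcripts=toy_transcripts).decisions
            if d.retained
        }
        relaxed_records = [
            dataclasses.replace(r, constraints=())
            if r.gene in ("TTN", "TMEM43", "KCNQ1")
            else r
            for r in kb.records
        ]
        relaxed = {
            d.variant_key
            for d in run_pipeline3_g2p(
                variants, KnowledgeBase(relaxed_records), P3, transcripts=toy_transcripts
            ).decisions
            if d.retained
        }
        assert baseline <= relaxed
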