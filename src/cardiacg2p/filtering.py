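"""The three variant-prioritisation pipelines.

* ``generic_pav``     - gene list, rarity, any protein-altering consequence.
* ``lof_or_clinvar``  - gene list, rarity, then high-confidence LoF truncating
                        variants or variants with an unambiguous P/LP assertion.
* ``g2p``             - gene list, rarity, then disease-associated variant
                        class and restricted-repertoire constraints from the
                        curated panel, optionally with per-sample allelic
                        requirement (zygosity) logic.

Every verdict carries an ordered stage trace so a decision can be audited.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .consequence import (
    AnnotatedVariant,
    NmdStatus,
    TranscriptModel,
    UnclassifiableVariantError,
    assign_variant_class,
    classify_nmd,
)
from .knowledge_base import GeneDiseaseRecord, KnowledgeBase, RepertoireConstraint
from .vocab import ALL_PANELS, ConstraintKind, GenotypeCall, VariantClass

PIPELINE_GENERIC_PAV = "generic_pav"
PIPELINE_LOF_OR_CLINVAR = "lof_or_clinvar"
PIPELINE_G2P = "g2p"

#: SO terms counted as protein-altering by the generic pipeline.
PROTEIN_ALTERING_TERMS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
        "stop_lost",
        "protein_altering_variant",
        "transcript_ablation",
        "exon_loss_variant",
    }
)

#: High-impact truncating terms eligible for the LOFTEE high-confidence arm.
HIGH_IMPACT_TRUNCATING_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "transcript_ablation",
    }
)

#: Unambiguous clinical-significance tokens (case-insensitive exact match);
#: conflicting-interpretation strings deliberately do not qualify.
PATHOGENIC_CLINVAR_TOKENS = frozenset({"pathogenic", "likely_pathogenic"})

FLAG_UNCLASSIFIED = "unclassified"
FLAG_REPERTOIRE_MISMATCH = "restricted_repertoire_mismatch"
FLAG_OUTSIDE_HOTSPOT = "outside_hotspot_region"
FLAG_ANNOTATION_INCOMPLETE = "annotation_incomplete"
FLAG_LOW_INCLUSION_EXON = "low_inclusion_exon"
FLAG_ALLELIC_REQUIREMENT_UNMET = "allelic_requirement_unmet"
FLAG_GENOTYPES_MISSING = "genotypes_missing"
FLAG_NMD_DEFAULTED = "nmd_defaulted"


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    pipeline: str = PIPELINE_G2P
    af_threshold: float = 1e-4
    panels: frozenset = ALL_PANELS
    missing_af_policy: str = "retain"
    constraint_mode: Optional[str] = None  # None = per-constraint mode
    zygosity_mode: str = "off"

    def __post_init__(self) -> None:
        if not 0.0 < self.af_threshold <= 1.0:
            raise ValueError("af_threshold must lie in (0, 1]")
        if self.missing_af_policy not in ("retain", "drop"):
            raise ValueError("missing_af_policy must be 'retain' or 'drop'")
        if self.zygosity_mode not in ("off", "per_sample"):
            raise ValueError("zygosity_mode must be 'off' or 'per_sample'")
        if self.constraint_mode not in (None, "restrict", "flag"):
            raise ValueError("constraint_mode must be None, 'restrict' or 'flag'")


Stage = Tuple[str, str, str]  # (name, outcome, reason)


@dataclasses.dataclass
class FilterDecision:
    variant_key: str
    gene: str
    transcript_id: str
    variant_class: Optional[str]
    pipeline: str
    retained: bool
    stages: List[Stage]
    matched_records: List[Tuple[str, str]]
    flags: Set[str]


@dataclasses.dataclass
class CohortResult:
    decisions: List[FilterDecision]
    unique_variants_considered: int
    unique_variants_retained: int

    @classmethod
    def from_decisions(cls, decisions: List[FilterDecision]) -> "CohortResult":
        considered = {d.variant_key for d in decisions}
        retained = {d.variant_key for d in decisions if d.retained}
        return cls(decisions, len(considered), len(retained))


def passes_frequency(variant: AnnotatedVariant, cfg: PipelineConfig) -> bool:
    """Strict rarity test: AF < threshold; missing AF follows the policy."""
    if variant.population_af is None:
        return cfg.missing_af_policy == "retain"
    return variant.population_af < cfg.af_threshold


# ---------------------------------------------------------------------------
# Allele matching for restricted repertoires
# ---------------------------------------------------------------------------

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}


def _normalise_hgvs_p(token: str) -> str:
    """Canonicalise a protein HGVS descriptor for comparison.

    Strips prefixes and parentheses and converts three-letter amino acid
    codes to one-letter, so ``p.(Ser358Leu)`` and ``p.S358L`` compare equal.
    """
    t = token.strip()
    if ":" in t:
        t = t.rsplit(":", 1)[1]
    t = t.removeprefix("p.").strip("()")
    for three, one in _AA3TO1.items():
        t = t.replace(three, one)
    return t.upper()


def allele_matches(variant: AnnotatedVariant, alleles: Sequence[str]) -> bool:
    candidates = {variant.key}
    if variant.hgvs_p:
        candidates.add(_normalise_hgvs_p(variant.hgvs_p))
    if variant.hgvs_c:
        candidates.add(variant.hgvs_c.rsplit(":", 1)[-1])
    for allele in alleles:
        if allele in candidates or _normalise_hgvs_p(allele) in candidates:
            return True
    return False


# ---------------------------------------------------------------------------
# Restricted-repertoire constraints
# ---------------------------------------------------------------------------

def _effective_mode(constraint: RepertoireConstraint, cfg: PipelineConfig) -> str:
    # CLI-level override applies to the dual-mode kinds only; allowlist drops
    # for class_drop_except_allowlist and exon-mask drops are always enforced.
    if cfg.constraint_mode is not None and constraint.kind in (
        ConstraintKind.VARIANT_ALLOWLIST,
        ConstraintKind.REGION_FLAG,
    ):
        return cfg.constraint_mode
    return constraint.mode


def apply_repertoire_constraints(
    variant: AnnotatedVariant,
    record: GeneDiseaseRecord,
    cfg: PipelineConfig,
    variant_class: Optional[VariantClass] = None,
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
) -> Tuple[str, Set[str]]:
    """Evaluate all of a record's constraints against one variant.

    Returns ``(verdict, flags)`` with verdict in ``retain`` / ``drop`` /
    ``flag_only`` (retained, but only because a required annotation was
    missing or a flag-mode constraint fired).
    """
    flags: Set[str] = set()
    verdict = "retain"
    for constraint in record.constraints:
        mode = _effective_mode(constraint, cfg)
        kind = constraint.kind
        if kind is ConstraintKind.CLASS_FORCE_RETAIN:
            forced = variant_class is not None and variant_class == constraint.target_class
            if constraint.target_class is VariantClass.INTRONIC_SPLICE_AFFECTING:
                forced = forced or "intron_variant" in variant.so_terms
            if forced:
                return "retain", flags
        elif kind is ConstraintKind.CLASS_DROP_EXCEPT_ALLOWLIST:
            if variant_class == constraint.target_class and not allele_matches(
                variant, constraint.alleles
            ):
                flags.add(FLAG_REPERTOIRE_MISMATCH)
                verdict = "drop"
        elif kind is ConstraintKind.VARIANT_ALLOWLIST:
            applies = constraint.target_class is None or variant_class == constraint.target_class
            if applies and not allele_matches(variant, constraint.alleles):
                flags.add(FLAG_REPERTOIRE_MISMATCH)
                if mode == "restrict":
                    verdict = "drop"
                elif verdict == "retain":
                    verdict = "flag_only"
        elif kind is ConstraintKind.REGION_FLAG:
            if variant.protein_pos is None:
                flags.add(FLAG_ANNOTATION_INCOMPLETE)
                if verdict == "retain":
                    verdict = "flag_only"
            else:
                lo, hi = constraint.region  # type: ignore[misc]
                if not lo <= variant.protein_pos <= hi:
                    if mode == "restrict":
                        flags.add(FLAG_OUTSIDE_HOTSPOT)
                        verdict = "drop"
                    else:
                        flags.add(FLAG_OUTSIDE_HOTSPOT)
        elif kind is ConstraintKind.EXON_MASK:
            target = constraint.target_class or VariantClass.NMD_TRUNCATING
            if variant_class != target:
                continue
            fraction = _exon_inclusion_for(variant, transcripts)
            if fraction is None:
                flags.add(FLAG_ANNOTATION_INCOMPLETE)
                if verdict == "retain":
                    verdict = "flag_only"
            elif fraction <= constraint.threshold:  # strictly-greater-than survives
                flags.add(FLAG_LOW_INCLUSION_EXON)
                verdict = "drop"
    return verdict, flags


def _exon_inclusion_for(
    variant: AnnotatedVariant, transcripts: Optional[Mapping[str, TranscriptModel]]
) -> Optional[float]:
    if transcripts is None:
        return None
    tm = transcripts.get(variant.transcript_id)
    if tm is None:
        return None
    rank = variant.exon_rank if variant.exon_rank is not None else tm.exon_rank_of(variant.pos)
    if rank is None:
        return None
    return tm.inclusion_fraction(rank)


# ---------------------------------------------------------------------------
# Generic pipelines
# ---------------------------------------------------------------------------

def _base_stages(
    variant: AnnotatedVariant, gene_ok: bool, cfg: PipelineConfig
) -> Tuple[List[Stage], bool]:
    stages: List[Stage] = []
    stages.append(
        ("gene", "pass" if gene_ok else "fail", "" if gene_ok else "gene not in panel gene set")
    )
    freq_ok = passes_frequency(variant, cfg)
    reason = "" if freq_ok else (
        "allele frequency missing" if variant.population_af is None else "allele frequency above threshold"
    )
    stages.append(("frequency", "pass" if freq_ok else "fail", reason))
    return stages, gene_ok and freq_ok


def run_pipeline1(
    variants: Iterable[AnnotatedVariant], gene_set: Iterable[str], cfg: PipelineConfig
) -> CohortResult:
    """Generic pipeline: gene list, rarity, protein-altering consequence."""
    if cfg.pipeline != PIPELINE_GENERIC_PAV:
        raise ValueError(f"config pipeline must be {PIPELINE_GENERIC_PAV!r}")
    genes = frozenset(gene_set)
    decisions = []
    for v in variants:
        stages, ok = _base_stages(v, v.gene in genes, cfg)
        pav = bool(v.so_terms & PROTEIN_ALTERING_TERMS)
        stages.append(
            ("consequence", "pass" if pav else "fail", "" if pav else "not protein-altering")
        )
        decisions.append(
            FilterDecision(
                variant_key=v.key,
                gene=v.gene,
                transcript_id=v.transcript_id,
                variant_class=None,
                pipeline=PIPELINE_GENERIC_PAV,
                retained=ok and pav,
                stages=stages,
                matched_records=[],
                flags=set(),
            )
        )
    return CohortResult.from_decisions(decisions)


def _has_pathogenic_assertion(variant: AnnotatedVariant) -> bool:
    return any(
        token.lower() in PATHOGENIC_CLINVAR_TOKENS for token in variant.clinical_significance
    )


def run_pipeline2(
    variants: Iterable[AnnotatedVariant], gene_set: Iterable[str], cfg: PipelineConfig
) -> CohortResult:
    """Generic pipeline: gene list, rarity, then HC LoF or P/LP assertion."""
    if cfg.pipeline != PIPELINE_LOF_OR_CLINVAR:
        raise ValueError(f"config pipeline must be {PIPELINE_LOF_OR_CLINVAR!r}")
    genes = frozenset(gene_set)
    decisions = []
    for v in variants:
        stages, ok = _base_stages(v, v.gene in genes, cfg)
        hc_lof = bool(v.so_terms & HIGH_IMPACT_TRUNCATING_TERMS) and v.lof_confidence == "HC"
        plp = _has_pathogenic_assertion(v)
        impact_ok = hc_lof or plp
        reason = "" if impact_ok else "neither high-confidence LoF nor P/LP assertion"
        stages.append(("impact", "pass" if impact_ok else "fail", reason))
        decisions.append(
            FilterDecision(
                variant_key=v.key,
                gene=v.gene,
                transcript_id=v.transcript_id,
                variant_class=None,
                pipeline=PIPELINE_LOF_OR_CLINVAR,
                retained=ok and impact_ok,
                stages=stages,
                matched_records=[],
                flags=set(),
            )
        )
    return CohortResult.from_decisions(decisions)


# ---------------------------------------------------------------------------
# Mechanism-aware pipeline
# ---------------------------------------------------------------------------

def _classify(
    variant: AnnotatedVariant, transcripts: Optional[Mapping[str, TranscriptModel]]
) -> Tuple[Optional[VariantClass], Set[str]]:
    flags: Set[str] = set()
    tm = transcripts.get(variant.transcript_id) if transcripts else None
    nmd = classify_nmd(tm, variant)
    if (
        nmd is NmdStatus.TRIGGERING
        and tm is None
        and variant.nmd_hint is None
        and (variant.so_terms & HIGH_IMPACT_TRUNCATING_TERMS)
    ):
        flags.add(FLAG_NMD_DEFAULTED)
    try:
        return assign_variant_class(variant, nmd), flags
    except UnclassifiableVariantError:
        return None, flags


def _class_matches_record(vc: VariantClass, record: GeneDiseaseRecord) -> bool:
    if vc in record.variant_classes:
        return True
    # Proven splice-affecting intronic variants belong to the truncating
    # repertoire of records that accept NMD-triggering variants.
    return (
        vc is VariantClass.INTRONIC_SPLICE_AFFECTING
        and VariantClass.NMD_TRUNCATING in record.variant_classes
    )


def check_allelic_requirement(
    variant_group: Sequence[AnnotatedVariant],
    record: GeneDiseaseRecord,
    sample: str,
) -> bool:
    """Does ``sample`` satisfy the record's allelic requirement in this gene?

    Monoallelic-capable records need one non-reference genotype; exclusively
    biallelic records need a homozygous-alternate call or at least two
    distinct heterozygous variants in the gene (phase unknown accepted).
    Missing genotypes never satisfy the requirement.
    """
    calls = []
    for v in variant_group:
        if v.genotypes is None:
            continue
        call = v.genotypes.get(sample, GenotypeCall.MISSING)
        if call in (GenotypeCall.HET, GenotypeCall.HOM_ALT):
            calls.append(call)
    if not calls:
        return False
    if record.exclusively_biallelic:
        return GenotypeCall.HOM_ALT in calls or len(calls) >= 2
    return True


def _force_retain_intronic(variant: AnnotatedVariant, record: GeneDiseaseRecord) -> bool:
    return "intron_variant" in variant.so_terms and any(
        c.kind is ConstraintKind.CLASS_FORCE_RETAIN
        and c.target_class is VariantClass.INTRONIC_SPLICE_AFFECTING
        for c in record.constraints
    )


def run_pipeline3_g2p(
    variants: Iterable[AnnotatedVariant],
    kb: KnowledgeBase,
    cfg: PipelineConfig,
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
) -> CohortResult:
    """Panel-aware filtering on variant class, repertoire and zygosity."""
    if cfg.pipeline != PIPELINE_G2P:
        raise ValueError(f"config pipeline must be {PIPELINE_G2P!r}")
    variants = list(variants)
    candidate_records = [r for r in kb.curated_records if r.panel in cfg.panels]
    by_gene: Dict[str, List[GeneDiseaseRecord]] = {}
    for r in candidate_records:
        by_gene.setdefault(r.gene, []).append(r)

    prelim = []
    for v in variants:
        records = by_gene.get(v.gene, [])
        stages, ok = _base_stages(v, bool(records), cfg)
        vc: Optional[VariantClass] = None
        flags: Set[str] = set()
        matched: List[GeneDiseaseRecord] = []
        if ok:
            vc, flags = _classify(v, transcripts)
            if vc is None:
                forced = [r for r in records if _force_retain_intronic(v, r)]
                if forced:
                    stages.append(("classification", "pass", "forced retain for intronic class"))
                    stages.append(("repertoire", "pass", ""))
                    matched = forced
                else:
                    flags.add(FLAG_UNCLASSIFIED)
                    stages.append(("classification", "fail", "unclassified"))
            else:
                stages.append(("classification", "pass", vc.value))
                class_hits = [r for r in records if _class_matches_record(vc, r)]
                forced = [
                    r
                    for r in records
                    if r not in class_hits and _force_retain_intronic(v, r)
                ]
                for r in class_hits:
                    verdict, cflags = apply_repertoire_constraints(
                        v, r, cfg, variant_class=vc, transcripts=transcripts
                    )
                    flags |= cflags
                    if verdict != "drop":
                        matched.append(r)
                matched.extend(forced)
                if not class_hits and not forced:
                    stages.append(
                        ("repertoire", "fail", "variant class not disease-associated for gene")
                    )
                elif not matched:
                    stages.append(("repertoire", "fail", "restricted repertoire mismatch"))
                else:
                    stages.append(("repertoire", "pass", ""))
        prelim.append((v, stages, vc, flags, matched, ok and bool(matched)))

    if cfg.zygosity_mode == "per_sample":
        # Variants eligible per record, for the biallelic second-hit search.
        eligible_by_record: Dict[Tuple[str, str], List[AnnotatedVariant]] = {}
        samples: Set[str] = set()
        for v, _stages, _vc, _flags, matched, retained in prelim:
            if not retained:
                continue
            if v.genotypes:
                samples.update(v.genotypes)
            for r in matched:
                eligible_by_record.setdefault((r.gene, r.disease_label), []).append(v)
        for i, (v, stages, vc, flags, matched, retained) in enumerate(prelim):
            if not retained:
                continue
            if not v.genotypes:
                flags.add(FLAG_GENOTYPES_MISSING)
                stages.append(("allelic_requirement", "fail", "genotypes missing"))
                prelim[i] = (v, stages, vc, flags, matched, False)
                continue
            satisfied = False
            for r in matched:
                group = eligible_by_record.get((r.gene, r.disease_label), [v])
                for sample in sorted(samples):
                    call = v.genotypes.get(sample, GenotypeCall.MISSING)
                    if call not in (GenotypeCall.HET, GenotypeCall.HOM_ALT):
                        continue
                    if check_allelic_requirement(group, r, sample):
                        satisfied = True
                        break
                if satisfied:
                    break
            if satisfied:
                stages.append(("allelic_requirement", "pass", ""))
            else:
                flags.add(FLAG_ALLELIC_REQUIREMENT_UNMET)
                stages.append(("allelic_requirement", "fail", "no sample satisfies requirement"))
                prelim[i] = (v, stages, vc, flags, matched, False)

    decisions = [
        FilterDecision(
            variant_key=v.key,
            gene=v.gene,
            transcript_id=v.transcript_id,
            variant_class=vc.value if vc else None,
            pipeline=PIPELINE_G2P,
            retained=retained,
            stages=stages,
            matched_records=[(r.gene, r.disease_label) for r in matched],
            flags=flags,
        )
        for v, stages, vc, flags, matched, retained in prelim
    ]
    return CohortResult.from_decisions(decisions)


def run_pipeline(
    variants: Iterable[AnnotatedVariant],
    cfg: PipelineConfig,
    kb: Optional[KnowledgeBase] = None,
    gene_set: Optional[Iterable[str]] = None,
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
) -> CohortResult:
    """Dispatch on ``cfg.pipeline``; generic pipelines default their gene set
    to the curated genes of the configured panels."""
    if cfg.pipeline == PIPELINE_G2P:
        if kb is None:
            raise ValueError("the g2p pipeline requires a knowledge base")
        return run_pipeline3_g2p(variants, kb, cfg, transcripts=transcripts)
    if gene_set is None:
        if kb is None:
            raise ValueError("generic pipelines need a gene set or a knowledge base")
        gene_set = kb.genes(cfg.panels)
    if cfg.pipeline == PIPELINE_GENERIC_PAV:
        return run_pipeline1(variants, gene_set, cfg)
    if cfg.pipeline == PIPELINE_LOF_OR_CLINVAR:
        return run_pipeline2(variants, gene_set, cfg)
    raise ValueError(f"unknown pipeline {cfg.pipeline!r}")
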