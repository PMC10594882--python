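"""Reading VEP-annotated VCFs and writing decision tables.

The reader consumes VCF 4.2 with a header-declared, pipe-separated
per-transcript annotation INFO field (``CSQ`` by default) and yields one
:class:`~cardiacg2p.consequence.AnnotatedVariant` per variant-transcript
annotation, decomposing multi-allelic records per alternate allele.
Positions stay 1-based as in the VCF.  Field-name dialects vary between
annotator versions, so both ``SYMBOL``/``Gene`` and ``Feature``/``Feature_id``
spellings are accepted and the population-AF field name is configurable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

from cyvcf2 import VCF

from .consequence import AnnotatedVariant
from .filtering import CohortResult, FilterDecision
from .knowledge_base import KnowledgeBase
from .vocab import GenotypeCall


class VcfFormatError(ValueError):
    """Raised when the VCF lacks the annotation key or a mandatory field."""


_GENE_FIELDS = ("SYMBOL", "Gene")
_TRANSCRIPT_FIELDS = ("Feature", "Feature_id")


@dataclasses.dataclass(frozen=True)
class CsqSchema:
    """Ordered annotation field names, parsed from the VCF header."""

    fields: Tuple[str, ...]

    def __post_init__(self) -> None:
        if "Consequence" not in self.fields:
            raise VcfFormatError("annotation schema is missing the 'Consequence' field")
        if not any(f in self.fields for f in _GENE_FIELDS):
            raise VcfFormatError("annotation schema is missing a gene symbol field (SYMBOL/Gene)")
        if not any(f in self.fields for f in _TRANSCRIPT_FIELDS):
            raise VcfFormatError(
                "annotation schema is missing a transcript field (Feature/Feature_id)"
            )

    def index_of(self, *names: str) -> Optional[int]:
        for name in names:
            if name in self.fields:
                return self.fields.index(name)
        return None

    @classmethod
    def from_description(cls, description: str) -> "CsqSchema":
        # VEP writes: Description="Consequence annotations ... Format: A|B|C"
        if "Format:" not in description:
            raise VcfFormatError("annotation INFO description lacks a 'Format:' declaration")
        payload = description.split("Format:", 1)[1].strip().strip('"')
        return cls(tuple(f.strip() for f in payload.split("|")))


def _parse_int(token: str) -> Optional[int]:
    try:
        return int(token)
    except (TypeError, ValueError):
        return None


def _genotype_calls(
    record, samples: Sequence[str], alt_index: int
) -> Optional[Dict[str, GenotypeCall]]:
    if not samples:
        return None
    calls: Dict[str, GenotypeCall] = {}
    for sample, gt in zip(samples, record.genotypes):
        alleles = [a for a in gt[:-1] if a is not None and a >= 0]
        if len(alleles) < 1 or len(gt) < 2 or any(a is None or a < 0 for a in gt[:-1]):
            calls[sample] = GenotypeCall.MISSING
            continue
        n_alt = sum(1 for a in alleles if a == alt_index)
        if n_alt == 0:
            calls[sample] = GenotypeCall.HOM_REF
        elif n_alt >= 2:
            calls[sample] = GenotypeCall.HOM_ALT
        else:
            calls[sample] = GenotypeCall.HET
    return calls


def read_annotated_vcf(
    path: Union[str, Path],
    csq_key: str = "CSQ",
    af_field: str = "gnomAD_AF",
    schema_hint: Optional[CsqSchema] = None,
) -> Iterator[AnnotatedVariant]:
    """Stream annotations from an annotated VCF in input order."""
    vcf = VCF(str(path))
    if schema_hint is not None:
        schema = schema_hint
    else:
        try:
            header = vcf.get_header_type(csq_key)
        except KeyError:
            raise VcfFormatError(f"VCF has no {csq_key!r} INFO declaration") from None
        schema = CsqSchema.from_description(header.get("Description", ""))

    idx_cons = schema.index_of("Consequence")
    idx_allele = schema.index_of("Allele")
    idx_gene = schema.index_of(*_GENE_FIELDS)
    idx_tx = schema.index_of(*_TRANSCRIPT_FIELDS)
    idx_hgvsc = schema.index_of("HGVSc")
    idx_hgvsp = schema.index_of("HGVSp")
    idx_ppos = schema.index_of("Protein_position")
    idx_exon = schema.index_of("EXON")
    idx_af = schema.index_of(af_field)
    idx_lof = schema.index_of("LoF")
    idx_clin = schema.index_of("CLIN_SIG")
    idx_splice = schema.index_of("SpliceEvidence")
    idx_nmd = schema.index_of("NMD")
    idx_canon = schema.index_of("CANONICAL")

    samples = list(vcf.samples)
    for record in vcf:
        raw = record.INFO.get(csq_key)
        if raw is None:
            raise VcfFormatError(
                f"record {record.CHROM}:{record.POS} has no {csq_key} annotation"
            )
        entries = [e.split("|") for e in raw.split(",")]
        for alt_index, alt in enumerate(record.ALT, start=1):
            genotypes = _genotype_calls(record, samples, alt_index)
            for fields in entries:
                if len(fields) != len(schema.fields):
                    raise VcfFormatError(
                        f"record {record.CHROM}:{record.POS}: annotation entry has "
                        f"{len(fields)} fields, schema declares {len(schema.fields)}"
                    )

                def get(idx: Optional[int]) -> str:
                    return fields[idx] if idx is not None and fields[idx] else ""

                if len(record.ALT) > 1 and idx_allele is not None and get(idx_allele) != alt:
                    continue
                exon_token = get(idx_exon).split("/")[0]
                ppos_token = get(idx_ppos).split("-")[0]
                af_token = get(idx_af)
                clin = tuple(t for t in get(idx_clin).split("&") if t)
                nmd_token = get(idx_nmd)
                nmd_hint = None
                if nmd_token:
                    nmd_hint = "escaping" if "escaping" in nmd_token.lower() else "triggering"
                yield AnnotatedVariant(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    gene=get(idx_gene),
                    transcript_id=get(idx_tx),
                    so_terms=frozenset(t for t in get(idx_cons).split("&") if t),
                    hgvs_c=get(idx_hgvsc) or None,
                    hgvs_p=get(idx_hgvsp) or None,
                    protein_pos=_parse_int(ppos_token),
                    exon_rank=_parse_int(exon_token),
                    population_af=float(af_token) if af_token else None,
                    lof_confidence=get(idx_lof) or None,
                    clinical_significance=clin,
                    genotypes=genotypes,
                    splice_evidence=get(idx_splice) == "1",
                    nmd_hint=nmd_hint,
                    canonical=get(idx_canon) == "YES",
                )


# Consequence severity used for transcript selection (most severe first).
_SEVERITY = (
    "transcript_ablation",
    "exon_loss_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
    "synonymous_variant",
    "intron_variant",
)


def _severity_rank(variant: AnnotatedVariant) -> int:
    ranks = [_SEVERITY.index(t) for t in variant.so_terms if t in _SEVERITY]
    return min(ranks) if ranks else len(_SEVERITY)


def designated_transcripts(kb: KnowledgeBase) -> Dict[str, str]:
    """Gene -> transcript map from ``[transcript:ID]`` tags in record narratives."""
    out: Dict[str, str] = {}
    for record in kb.curated_records:
        tx = record.designated_transcript
        if tx:
            out[record.gene] = tx
    return out


def select_transcript(
    annotations: Sequence[AnnotatedVariant],
    kb: Optional[KnowledgeBase] = None,
    designated: Optional[Mapping[str, str]] = None,
) -> AnnotatedVariant:
    """Choose the analysis annotation for one variant.

    Preference order: the panel-designated transcript for the gene, then the
    annotation flagged canonical, then the most severe consequence; ties break
    on the lexicographically smallest transcript id.
    """
    if not annotations:
        raise ValueError("select_transcript requires at least one annotation")
    table = dict(designated or {})
    if kb is not None:
        for gene, tx in designated_transcripts(kb).items():
            table.setdefault(gene, tx)
    for ann in sorted(annotations, key=lambda a: a.transcript_id):
        if table.get(ann.gene) == ann.transcript_id:
            return ann
    return sorted(
        annotations,
        key=lambda a: (not a.canonical, _severity_rank(a), a.transcript_id),
    )[0]


def select_analysis_annotations(
    annotations: Sequence[AnnotatedVariant],
    kb: Optional[KnowledgeBase] = None,
    designated: Optional[Mapping[str, str]] = None,
) -> List[AnnotatedVariant]:
    """One annotation per (variant key, gene), chosen by :func:`select_transcript`.

    A variant hitting two panel genes is evaluated once per gene, so it can be
    retained if any gene-record matches.
    """
    grouped: Dict[Tuple[str, str], List[AnnotatedVariant]] = {}
    order: List[Tuple[str, str]] = []
    for ann in annotations:
        group = (ann.key, ann.gene)
        if group not in grouped:
            order.append(group)
        grouped.setdefault(group, []).append(ann)
    return [select_transcript(grouped[g], kb=kb, designated=designated) for g in order]


# ---------------------------------------------------------------------------
# Decision tables
# ---------------------------------------------------------------------------

_DECISION_COLUMNS = (
    "variant_key",
    "gene",
    "transcript",
    "class",
    "pipeline",
    "retained",
    "matched_records",
    "flags",
    "stage_trace",
)


def write_decisions(
    decisions: Union[CohortResult, Sequence[FilterDecision]], path: Union[str, Path]
) -> None:
    """Write decisions as TSV (JSON-encoded cells for the structured columns)."""
    if isinstance(decisions, CohortResult):
        decisions = decisions.decisions
    lines = ["\t".join(_DECISION_COLUMNS)]
    for d in decisions:
        lines.append(
            "\t".join(
                (
                    d.variant_key,
                    d.gene,
                    d.transcript_id,
                    d.variant_class or "",
                    d.pipeline,
                    "true" if d.retained else "false",
                    json.dumps([list(m) for m in d.matched_records]),
                    json.dumps(sorted(d.flags)),
                    json.dumps([list(s) for s in d.stages]),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


def read_decisions(path: Union[str, Path]) -> List[FilterDecision]:
    lines = Path(path).read_text("utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != _DECISION_COLUMNS:
        raise VcfFormatError(f"{path}: not a decision table")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        out.append(
            FilterDecision(
                variant_key=cells[0],
                gene=cells[1],
                transcript_id=cells[2],
                variant_class=cells[3] or None,
                pipeline=cells[4],
                retained=cells[5] == "true",
                stages=[tuple(s) for s in json.loads(cells[8])],
                matched_records=[tuple(m) for m in json.loads(cells[6])],
                flags=set(json.loads(cells[7])),
            )
        )
    return out
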