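"""Deterministic synthetic fixtures: toy transcripts, annotated variant sets
with known per-pipeline truth labels, and multi-sample cohorts.

Coordinates live on a miniature contig (``chrT``) while gene symbols are real
panel symbols, because every filtering rule depends on annotations rather
than sequence.  Truth labels are computed here from flat rule statements,
deliberately not by calling the filter engine, so that engine and generator
check each other.
"""

from __future__ import annotations

import dataclasses
import json
import random
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .consequence import TranscriptModel, write_transcripts
from .knowledge_base import KnowledgeBase, load_knowledge_base
from .vocab import ALL_PANELS, ConstraintKind, GenotypeCall, VariantClass

CONTIG = "chrT"

CSQ_FIELDS = (
    "Allele",
    "Consequence",
    "SYMBOL",
    "Gene",
    "Feature",
    "CANONICAL",
    "EXON",
    "HGVSc",
    "HGVSp",
    "Protein_position",
    "gnomAD_AF",
    "LoF",
    "CLIN_SIG",
    "SpliceEvidence",
    "NMD",
)

#: Allele-frequency strata; ``borderline`` pins the strict < 1e-4 inequality.
AF_STRATA: Dict[str, Optional[float]] = {
    "absent": None,
    "rare": 5e-5,
    "borderline": 1e-4,
    "common": 1e-2,
}

PIPELINES = ("generic_pav", "lof_or_clinvar", "g2p")

# Kinds understood by the generator.  ``gap_*`` kinds emulate variants whose
# real (splice-affecting) consequence is missing from the annotation.
_PTC_KINDS = {
    "nmd_truncating": "stop_gained",
    "nmd_truncating_frameshift": "frameshift_variant",
    "nmd_truncating_splice_donor": "splice_donor_variant",
    "nmd_truncating_splice_acceptor": "splice_acceptor_variant",
    "stop_gained_nmd_escaping": "stop_gained",
    "frameshift_nmd_escaping": "frameshift_variant",
    "splice_donor_nmd_escaping": "splice_donor_variant",
    "splice_acceptor_nmd_escaping": "splice_acceptor_variant",
}

_KIND_CLASS: Dict[str, Optional[VariantClass]] = {
    "missense": VariantClass.MISSENSE,
    "inframe_indel": VariantClass.INFRAME_INDEL,
    "nmd_truncating": VariantClass.NMD_TRUNCATING,
    "nmd_truncating_frameshift": VariantClass.NMD_TRUNCATING,
    "nmd_truncating_splice_donor": VariantClass.NMD_TRUNCATING,
    "nmd_truncating_splice_acceptor": VariantClass.NMD_TRUNCATING,
    "stop_gained_nmd_escaping": VariantClass.STOP_GAINED_NMD_ESCAPING,
    "frameshift_nmd_escaping": VariantClass.FRAMESHIFT_NMD_ESCAPING,
    "splice_donor_nmd_escaping": VariantClass.SPLICE_DONOR_NMD_ESCAPING,
    "splice_acceptor_nmd_escaping": VariantClass.SPLICE_ACCEPTOR_NMD_ESCAPING,
    "structural_exon_deletion": VariantClass.STRUCTURAL_EXON_DELETION,
    "whole_gene_deletion": VariantClass.WHOLE_GENE_DELETION,
    "structural_duplication": VariantClass.STRUCTURAL_DUPLICATION,
    "complex_rearrangement": VariantClass.COMPLEX_REARRANGEMENT,
    "intronic_splice_affecting": VariantClass.INTRONIC_SPLICE_AFFECTING,
    "synonymous": None,
    "intronic": None,
    "gap_intronic": None,
    "gap_synonymous": None,
}

# Flat copies of the generic-pipeline term lists (kept separate from the
# engine's constants on purpose; the closed-loop tests compare the two).
_FLAT_PAV = {
    "missense_variant", "stop_gained", "frameshift_variant", "inframe_insertion",
    "inframe_deletion", "splice_acceptor_variant", "splice_donor_variant",
    "start_lost", "stop_lost", "protein_altering_variant", "transcript_ablation",
    "exon_loss_variant",
}
_FLAT_TRUNCATING = {
    "stop_gained", "frameshift_variant", "splice_acceptor_variant",
    "splice_donor_variant", "transcript_ablation",
}


@dataclasses.dataclass(frozen=True)
class VariantRequest:
    """One requested synthetic variant (or ``count`` replicates of it)."""

    gene: str
    kind: str
    af: Union[str, float, None] = "rare"
    count: int = 1
    lof_confidence: Optional[str] = None
    clin_sig: Tuple[str, ...] = ()
    hgvs_p: Optional[str] = None
    protein_pos: Optional[int] = None
    exon_rank: Optional[int] = None
    genotype_plan: Optional[Tuple[str, ...]] = None

    def resolved_af(self) -> Optional[float]:
        if isinstance(self.af, str):
            if self.af not in AF_STRATA:
                raise ValueError(f"unknown AF stratum {self.af!r}")
            return AF_STRATA[self.af]
        return self.af


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    requests: Tuple[VariantRequest, ...]
    n_samples: int = 0
    seed: int = 0
    panels: frozenset = ALL_PANELS

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        for r in self.requests:
            if r.count < 0:
                raise ValueError("request counts must be non-negative")
            if r.kind not in _KIND_CLASS:
                raise ValueError(f"unknown variant kind {r.kind!r}")


@dataclasses.dataclass
class TruthLabel:
    variant_key: str
    gene: str
    kind: str
    expected: Dict[str, bool]
    reason: Dict[str, str]


@dataclasses.dataclass
class TruthSet:
    vcf_text: str
    labels: List[TruthLabel]
    transcripts: Dict[str, TranscriptModel]
    samples: List[str]

    def gold_positive_keys(self, pipeline: str = "g2p") -> set:
        return {t.variant_key for t in self.labels if t.expected[pipeline]}


# ---------------------------------------------------------------------------
# Toy transcripts
# ---------------------------------------------------------------------------

_DEFAULT_GENES = (
    "MYH7", "MYBPC3", "TTN", "LMNA", "RBM20", "TMEM43", "SCN5A", "TNNC1",
    "TNNT2", "JUP", "DSP", "FLNC", "KCNQ1", "TRDN", "GENEX",
)


def build_toy_transcripts(seed: int = 0) -> Dict[str, TranscriptModel]:
    """Deterministic toy transcript set (``seed`` kept for API symmetry).

    Contains a multi-exon model with inclusion fractions straddling 0.9
    (TTN-like), a two-exon model for NMD boundary tests, a single-exon model
    (TNNC1) and a minus-strand mirror (TNNT2).
    """
    del seed  # geometry is fixed by construction
    models: Dict[str, TranscriptModel] = {}
    for index, gene in enumerate(_DEFAULT_GENES):
        base = 100_000 * (index + 1)
        tid = f"TX_{gene}"
        if gene == "TTN":
            exons = tuple(
                (base + 1 + i * 1000, base + 300 + i * 1000) for i in range(8)
            )
            models[tid] = TranscriptModel(
                tid, gene, "+", exons, exons[0][0], exons[-1][1],
                exon_inclusion=(1.0, 1.0, 0.95, 0.5, 1.0, 0.95, 1.0, 1.0),
            )
        elif gene == "MYH7":
            exons = ((base + 1001, base + 1600), (base + 2001, base + 2600))
            models[tid] = TranscriptModel(tid, gene, "+", exons, base + 1001, base + 2600)
        elif gene == "TNNT2":
            # minus-strand mirror of the MYH7 two-exon geometry
            exons = ((base + 1001, base + 1600), (base + 2001, base + 2600))
            models[tid] = TranscriptModel(tid, gene, "-", exons, base + 1001, base + 2600)
        elif gene == "TNNC1":
            exons = ((base + 1001, base + 1900),)
            models[tid] = TranscriptModel(tid, gene, "+", exons, base + 1001, base + 1900)
        else:
            exons = tuple((base + 1 + i * 1000, base + 300 + i * 1000) for i in range(3))
            models[tid] = TranscriptModel(tid, gene, "+", exons, exons[0][0], exons[-1][1])
    return models


def genomic_pos_at_coding_offset(tm: TranscriptModel, offset: int) -> int:
    """Inverse of :meth:`TranscriptModel.coding_offset` (1-based offsets)."""
    remaining = offset
    for start, end in tm.exons_tx_order:
        s, e = max(start, tm.cds_start), min(end, tm.cds_end)
        if s > e:
            continue
        length = e - s + 1
        if remaining <= length:
            return s + remaining - 1 if tm.strand == "+" else e - remaining + 1
        remaining -= length
    raise ValueError(f"coding offset {offset} beyond transcript {tm.transcript_id}")


# ---------------------------------------------------------------------------
# Variant realisation
# ---------------------------------------------------------------------------

class _PositionAllocator:
    """Hands out unique positions within named transcript regions.

    Ascending and descending take different ends of a region, so two counters
    on the same interval stay collision-free while allocations are sparse.
    """

    def __init__(self) -> None:
        self._next: Dict[Tuple[str, str], int] = {}

    def take(
        self, region_key: str, tm: TranscriptModel, lo: int, hi: int, descending: bool = False
    ) -> int:
        key = (tm.transcript_id, region_key)
        offset = self._next.get(key, 0)
        pos = hi - offset if descending else lo + offset
        if not lo <= pos <= hi:
            raise ValueError(f"region {region_key} of {tm.transcript_id} exhausted")
        self._next[key] = offset + 1
        return pos


def _exon_interval(tm: TranscriptModel, rank: int) -> Tuple[int, int]:
    return tm.exons_tx_order[rank - 1]


def _realise(
    req: VariantRequest,
    tm: TranscriptModel,
    alloc: _PositionAllocator,
    rng: random.Random,
) -> dict:
    """Turn one request into a concrete VCF row payload."""
    kind = req.kind
    so_term = None
    splice_evidence = False
    exon_rank: Optional[int] = req.exon_rank
    n = tm.n_exons
    # Coding-exon kinds share two per-exon counters: PTC kinds take the
    # transcript-5' side of the exon (safely upstream of the NMD-escape
    # window), everything else takes the transcript-3' side.
    if kind in ("missense", "inframe_indel", "synonymous", "gap_synonymous"):
        rank = exon_rank or 1
        lo, hi = _exon_interval(tm, rank)
        pos = alloc.take(f"exon{rank}_b", tm, lo, hi, descending=tm.strand == "+")
        so_term = {
            "missense": "missense_variant",
            "inframe_indel": "inframe_deletion",
            "synonymous": "synonymous_variant",
            "gap_synonymous": "synonymous_variant",
        }[kind]
        exon_rank = rank
    elif kind in ("nmd_truncating", "nmd_truncating_frameshift"):
        rank = exon_rank or 1
        lo, hi = _exon_interval(tm, rank)
        pos = alloc.take(f"exon{rank}_a", tm, lo, hi, descending=tm.strand == "-")
        so_term = _PTC_KINDS[kind]
        exon_rank = rank
    elif kind in ("stop_gained_nmd_escaping", "frameshift_nmd_escaping"):
        rank = n
        lo, hi = _exon_interval(tm, rank)
        pos = alloc.take(f"exon{rank}_a", tm, lo, hi, descending=tm.strand == "-")
        so_term = _PTC_KINDS[kind]
        exon_rank = rank
    elif kind == "nmd_truncating_splice_donor":
        # donor side of intron 1 (transcript order); needs >= 3 exons so the
        # disrupted junction is not also the last one
        if n < 3:
            raise ValueError(f"{kind} needs a transcript with >=3 exons ({tm.transcript_id})")
        first = _exon_interval(tm, 1)
        step = alloc.take("donor1", tm, 0, 7)
        pos = first[1] + 1 + step if tm.strand == "+" else first[0] - 1 - step
        so_term = "splice_donor_variant"
    elif kind == "nmd_truncating_splice_acceptor":
        if n < 3:
            raise ValueError(f"{kind} needs a transcript with >=3 exons ({tm.transcript_id})")
        second = _exon_interval(tm, 2)
        step = alloc.take("acceptor2", tm, 0, 7)
        pos = second[0] - 1 - step if tm.strand == "+" else second[1] + 1 + step
        so_term = "splice_acceptor_variant"
    elif kind == "splice_donor_nmd_escaping":
        penult = _exon_interval(tm, n - 1)
        step = alloc.take("donor_last", tm, 0, 7)
        pos = penult[1] + 1 + step if tm.strand == "+" else penult[0] - 1 - step
        so_term = "splice_donor_variant"
    elif kind == "splice_acceptor_nmd_escaping":
        last = _exon_interval(tm, n)
        step = alloc.take("acceptor_last", tm, 0, 7)
        pos = last[0] - 1 - step if tm.strand == "+" else last[1] + 1 + step
        so_term = "splice_acceptor_variant"
    elif kind in ("intronic", "gap_intronic", "intronic_splice_affecting"):
        first = _exon_interval(tm, 1)
        second = _exon_interval(tm, 2)
        intron_lo = min(first[1], second[1]) + 10
        intron_hi = max(first[0], second[0]) - 10
        pos = alloc.take("intron1", tm, intron_lo, intron_hi)
        so_term = "intron_variant"
        splice_evidence = kind == "intronic_splice_affecting"
    elif kind == "structural_exon_deletion":
        rank = (exon_rank or 2) if n > 1 else 1
        lo, hi = _exon_interval(tm, rank)
        pos = alloc.take(f"exon{rank}_b", tm, lo, hi, descending=tm.strand == "+")
        so_term = "exon_loss_variant"
        exon_rank = rank
    elif kind == "whole_gene_deletion":
        pos = alloc.take("exon1_b", tm, *tm.exons_tx_order[0], descending=tm.strand == "+")
        so_term = "transcript_ablation"
    elif kind == "structural_duplication":
        rank = exon_rank or 1
        lo, hi = _exon_interval(tm, rank)
        pos = alloc.take(f"exon{rank}_b", tm, lo, hi, descending=tm.strand == "+")
        so_term = "duplication"
        exon_rank = rank
    elif kind == "complex_rearrangement":
        pos = alloc.take("exon1_b", tm, *tm.exons_tx_order[0], descending=tm.strand == "+")
        so_term = "complex_structural_alteration"
    else:  # pragma: no cover - guarded by FixtureSpec validation
        raise ValueError(kind)

    ref = rng.choice("ACGT")
    alt = rng.choice([b for b in "ACGT" if b != ref])
    if "frameshift" in kind:
        ref, alt = ref + alt, ref
    protein_pos = req.protein_pos
    if protein_pos is None and exon_rank is not None and kind in (
        "missense", "inframe_indel", "synonymous", "gap_synonymous",
    ):
        protein_pos = max(1, (tm.coding_offset(pos) + 2) // 3)
    return {
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "so_term": so_term,
        "exon_rank": exon_rank,
        "protein_pos": protein_pos,
        "splice_evidence": splice_evidence,
    }


# ---------------------------------------------------------------------------
# Flat truth rules (independent of the filter engine)
# ---------------------------------------------------------------------------

def _flat_allele_ok(req: VariantRequest, alleles: Sequence[str]) -> bool:
    return req.hgvs_p is not None and req.hgvs_p in alleles


def _flat_p3_record_ok(
    req: VariantRequest,
    record,
    transcripts: Mapping[str, TranscriptModel],
    so_term: str,
    exon_rank: Optional[int],
) -> bool:
    vc = _KIND_CLASS[req.kind]
    force_intronic = any(
        c.kind is ConstraintKind.CLASS_FORCE_RETAIN
        and c.target_class is VariantClass.INTRONIC_SPLICE_AFFECTING
        for c in record.constraints
    )
    if vc is None or req.kind.startswith("gap_"):
        return force_intronic and so_term == "intron_variant"
    class_ok = vc in record.variant_classes or (
        vc is VariantClass.INTRONIC_SPLICE_AFFECTING
        and VariantClass.NMD_TRUNCATING in record.variant_classes
    )
    if not class_ok:
        return force_intronic and so_term == "intron_variant"
    for c in record.constraints:
        if c.kind is ConstraintKind.CLASS_DROP_EXCEPT_ALLOWLIST:
            if vc == c.target_class and not _flat_allele_ok(req, c.alleles):
                return False
        elif c.kind is ConstraintKind.VARIANT_ALLOWLIST and c.mode == "restrict":
            if (c.target_class is None or vc == c.target_class) and not _flat_allele_ok(
                req, c.alleles
            ):
                return False
        elif c.kind is ConstraintKind.EXON_MASK:
            target = c.target_class or VariantClass.NMD_TRUNCATING
            if vc == target:
                tm = transcripts.get(f"TX_{record.gene}")
                if tm is not None and tm.exon_inclusion is not None and exon_rank:
                    if tm.exon_inclusion[exon_rank - 1] <= c.threshold:
                        return False
    return True


def _flat_truth(
    req: VariantRequest,
    realised: dict,
    kb: KnowledgeBase,
    gene_set: frozenset,
    records_by_gene: Mapping[str, list],
    transcripts: Mapping[str, TranscriptModel],
    af_threshold: float = 1e-4,
) -> Tuple[Dict[str, bool], Dict[str, str]]:
    af = req.resolved_af()
    af_ok = af is None or af < af_threshold
    gene_ok = req.gene in gene_set
    so_term = realised["so_term"]

    expected: Dict[str, bool] = {}
    reason: Dict[str, str] = {}

    p1 = gene_ok and af_ok and so_term in _FLAT_PAV
    expected["generic_pav"] = p1
    reason["generic_pav"] = (
        "retain" if p1 else
        "gene_not_in_panel" if not gene_ok else
        "af_common" if not af_ok else "not_protein_altering"
    )

    hc_lof = so_term in _FLAT_TRUNCATING and req.lof_confidence == "HC"
    plp = any(t.lower() in ("pathogenic", "likely_pathogenic") for t in req.clin_sig)
    p2 = gene_ok and af_ok and (hc_lof or plp)
    expected["lof_or_clinvar"] = p2
    reason["lof_or_clinvar"] = (
        "retain" if p2 else
        "gene_not_in_panel" if not gene_ok else
        "af_common" if not af_ok else "no_lof_or_clinvar"
    )

    record_hits = [
        r
        for r in records_by_gene.get(req.gene, [])
        if _flat_p3_record_ok(req, r, transcripts, so_term, realised["exon_rank"])
    ]
    p3 = gene_ok and af_ok and bool(record_hits)
    expected["g2p"] = p3
    if p3:
        reason["g2p"] = "retain"
    elif req.kind.startswith("gap_"):
        reason["g2p"] = "annotation_gap"
    elif not gene_ok:
        reason["g2p"] = "gene_not_in_panel"
    elif not af_ok:
        reason["g2p"] = "af_common"
    else:
        reason["g2p"] = "class_or_repertoire_mismatch"
    return expected, reason


# ---------------------------------------------------------------------------
# VCF assembly
# ---------------------------------------------------------------------------

def _csq_entry(req: VariantRequest, realised: dict, tm: TranscriptModel) -> str:
    values = {
        "Allele": realised["alt"],
        "Consequence": realised["so_term"],
        "SYMBOL": req.gene,
        "Gene": req.gene,
        "Feature": tm.transcript_id,
        "CANONICAL": "YES",
        "EXON": f"{realised['exon_rank']}/{tm.n_exons}" if realised["exon_rank"] else "",
        "HGVSc": "",
        "HGVSp": req.hgvs_p or "",
        "Protein_position": str(realised["protein_pos"] or ""),
        "gnomAD_AF": "" if req.resolved_af() is None else f"{req.resolved_af():g}",
        "LoF": req.lof_confidence or "",
        "CLIN_SIG": "&".join(req.clin_sig),
        "SpliceEvidence": "1" if realised["splice_evidence"] else "",
        "NMD": "",
    }
    return "|".join(values[f] for f in CSQ_FIELDS)


_GT_STRING = {
    GenotypeCall.HOM_REF: "0/0",
    GenotypeCall.HET: "0/1",
    GenotypeCall.HOM_ALT: "1/1",
    GenotypeCall.MISSING: "./.",
}


def _sample_calls(
    req: VariantRequest, n_samples: int, rng: random.Random
) -> List[GenotypeCall]:
    if n_samples == 0:
        return []
    if req.genotype_plan is not None:
        plan = list(req.genotype_plan) + [GenotypeCall.HOM_REF.value] * n_samples
        return [GenotypeCall(tok) for tok in plan[:n_samples]]
    calls = [
        GenotypeCall.HET if rng.random() < 0.3 else GenotypeCall.HOM_REF
        for _ in range(n_samples)
    ]
    if all(c is GenotypeCall.HOM_REF for c in calls):
        calls[rng.randrange(n_samples)] = GenotypeCall.HET
    return calls


def generate_truth_set(
    spec: FixtureSpec, out_dir: Optional[Union[str, Path]] = None
) -> TruthSet:
    """Generate a VCF (text) plus one truth label per variant per pipeline."""
    rng = random.Random(spec.seed)
    transcripts = build_toy_transcripts(spec.seed)
    by_gene_tx = {tm.gene: tm for tm in transcripts.values()}
    kb = load_knowledge_base()
    gene_set = kb.genes(spec.panels)
    records_by_gene: Dict[str, list] = {}
    for r in kb.curated_records:
        if r.panel in spec.panels:
            records_by_gene.setdefault(r.gene, []).append(r)

    alloc = _PositionAllocator()
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    rows = []
    labels: List[TruthLabel] = []
    for req in spec.requests:
        tm = by_gene_tx.get(req.gene)
        if tm is None:
            raise ValueError(f"no toy transcript for gene {req.gene!r}")
        for _ in range(req.count):
            realised = _realise(req, tm, alloc, rng)
            calls = _sample_calls(req, spec.n_samples, rng)
            key = f"{CONTIG}:{realised['pos']}:{realised['ref']}:{realised['alt']}"
            expected, reason = _flat_truth(
                req, realised, kb, gene_set, records_by_gene, transcripts
            )
            rows.append((realised["pos"], realised, req, tm, calls))
            labels.append(TruthLabel(key, req.gene, req.kind, expected, reason))

    rows.sort(key=lambda r: r[0])
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CONTIG},length=100000000>",
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        f'Format: {"|".join(CSQ_FIELDS)}">',
    ]
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        columns += ["FORMAT"] + samples
    body = []
    for pos, realised, req, tm, calls in rows:
        cells = [
            CONTIG,
            str(pos),
            ".",
            realised["ref"],
            realised["alt"],
            ".",
            "PASS",
            f"CSQ={_csq_entry(req, realised, tm)}",
        ]
        if samples:
            cells += ["GT"] + [_GT_STRING[c] for c in calls]
        body.append("\t".join(cells))
    vcf_text = "\n".join(header + ["\t".join(columns)] + body) + "\n"

    truth = TruthSet(vcf_text, labels, transcripts, samples)
    if out_dir is not None:
        write_truth_set(truth, out_dir)
    return truth


def generate_cohort_vcf(
    spec: FixtureSpec, out_dir: Optional[Union[str, Path]] = None
) -> TruthSet:
    """Multi-sample variant of :func:`generate_truth_set`."""
    if spec.n_samples < 1:
        raise ValueError("generate_cohort_vcf requires n_samples >= 1")
    return generate_truth_set(spec, out_dir)


def write_truth_set(truth: TruthSet, out_dir: Union[str, Path]) -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "truth.vcf",
        "labels": out / "truth_labels.tsv",
        "transcripts": out / "transcripts.tsv",
    }
    paths["vcf"].write_text(truth.vcf_text, "utf-8")
    lines = ["\t".join(("variant_key", "gene", "kind", "expected", "reason"))]
    for t in truth.labels:
        lines.append(
            "\t".join(
                (t.variant_key, t.gene, t.kind, json.dumps(t.expected), json.dumps(t.reason))
            )
        )
    paths["labels"].write_text("\n".join(lines) + "\n", "utf-8")
    write_transcripts(truth.transcripts, paths["transcripts"])
    return paths


def load_truth_labels(path: Union[str, Path]) -> List[TruthLabel]:
    lines = Path(path).read_text("utf-8").splitlines()
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        key, gene, kind, expected, reason = line.split("\t")
        out.append(TruthLabel(key, gene, kind, json.loads(expected), json.loads(reason)))
    return out


# ---------------------------------------------------------------------------
# Canned compositions
# ---------------------------------------------------------------------------

_GRID_GENES = (
    "MYH7", "MYBPC3", "TTN", "LMNA", "RBM20", "TMEM43", "SCN5A", "TNNT2",
    "JUP", "DSP", "FLNC", "KCNQ1",
)
_GRID_KINDS = (
    "missense",
    "inframe_indel",
    "nmd_truncating",
    "nmd_truncating_frameshift",
    "nmd_truncating_splice_donor",
    "nmd_truncating_splice_acceptor",
    "stop_gained_nmd_escaping",
    "frameshift_nmd_escaping",
    "splice_donor_nmd_escaping",
    "splice_acceptor_nmd_escaping",
    "synonymous",
    "intronic",
    "intronic_splice_affecting",
    "structural_exon_deletion",
    "whole_gene_deletion",
)


def make_grid_spec(n_samples: int = 0, seed: int = 1) -> FixtureSpec:
    """Every feasible gene x variant-class x AF-stratum combination, plus the
    targeted repertoire, annotation-gap, LoF-confidence and ClinVar cases."""
    two_exon = {"MYH7", "TNNT2"}
    requests: List[VariantRequest] = []
    for gene in _GRID_GENES:
        for kind in _GRID_KINDS:
            if gene in two_exon and kind in (
                "nmd_truncating_splice_donor", "nmd_truncating_splice_acceptor"
            ):
                continue  # the only junction is also the last one
            for stratum in AF_STRATA:
                requests.append(VariantRequest(gene, kind, stratum))
    # single-exon gene: no introns/junctions, PTCs always escape NMD
    for kind in ("missense", "inframe_indel", "stop_gained_nmd_escaping",
                 "synonymous", "structural_exon_deletion", "whole_gene_deletion"):
        for stratum in AF_STRATA:
            requests.append(VariantRequest("TNNC1", kind, stratum))
    # non-panel gene: everything fails the gene stage
    for kind in ("missense", "nmd_truncating"):
        requests.append(VariantRequest("GENEX", kind, "rare"))
    requests += [
        # restricted repertoires
        VariantRequest("TTN", "missense", "rare", hgvs_p="p.Trp976Arg"),
        VariantRequest("TTN", "missense", "rare", hgvs_p="p.Val54Met"),
        VariantRequest("TTN", "missense", "rare", hgvs_p="p.Ala178Asp"),
        VariantRequest("TTN", "nmd_truncating", "rare", exon_rank=3),  # PSI 0.95
        VariantRequest("TTN", "nmd_truncating", "rare", exon_rank=4),  # PSI 0.50
        VariantRequest("TMEM43", "missense", "rare", hgvs_p="p.Ser358Leu"),
        VariantRequest("KCNQ1", "missense", "rare", hgvs_p="p.Val141Met"),
        VariantRequest("RBM20", "missense", "rare", protein_pos=636),
        VariantRequest("RBM20", "missense", "rare", protein_pos=100),
        # annotation gaps (splice-affecting variants annotated as benign-looking)
        VariantRequest("LMNA", "gap_intronic", "rare", count=2),
        VariantRequest("LMNA", "gap_synonymous", "rare"),
        VariantRequest("TTN", "gap_intronic", "rare"),
        # MYBPC3 deep-intronic force-retain
        VariantRequest("MYBPC3", "intronic", "rare", count=2),
        # LOFTEE / ClinVar arms for the generic LoF pipeline
        VariantRequest("MYH7", "nmd_truncating", "rare", lof_confidence="HC"),
        VariantRequest("MYH7", "nmd_truncating", "rare", lof_confidence="LC"),
        VariantRequest("MYH7", "missense", "rare", clin_sig=("likely_pathogenic",)),
        VariantRequest("MYBPC3", "missense", "rare", clin_sig=("pathogenic",)),
        VariantRequest("MYBPC3", "missense", "rare",
                       clin_sig=("conflicting_interpretations_of_pathogenicity",)),
    ]
    return FixtureSpec(tuple(requests), n_samples=n_samples, seed=seed)


def load_fixture_spec(path: Union[str, Path]) -> FixtureSpec:
    """Read a YAML fixture spec: ``{seed, n_samples, requests: [...]}``."""
    payload = yaml.safe_load(Path(path).read_text("utf-8"))
    if payload.get("grid"):
        return make_grid_spec(
            n_samples=int(payload.get("n_samples", 0)), seed=int(payload["seed"])
        )
    requests = tuple(
        VariantRequest(
            gene=item["gene"],
            kind=item["kind"],
            af=item.get("af", "rare"),
            count=int(item.get("count", 1)),
            lof_confidence=item.get("lof_confidence"),
            clin_sig=tuple(item.get("clin_sig", ())),
            hgvs_p=item.get("hgvs_p"),
            protein_pos=item.get("protein_pos"),
            exon_rank=item.get("exon_rank"),
            genotype_plan=tuple(item["genotype_plan"]) if item.get("genotype_plan") else None,
        )
        for item in payload.get("requests", ())
    )
    return FixtureSpec(
        requests,
        n_samples=int(payload.get("n_samples", 0)),
        seed=int(payload["seed"]),
    )
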