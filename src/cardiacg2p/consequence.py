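"""Variant-class assignment, including NMD-triggering vs NMD-escaping calls.

The NMD rule is the canonical clinical convention: a premature termination
codon escapes nonsense-mediated decay when it falls in the last exon, within
the final 50 coding nucleotides upstream of the last exon-exon junction, or
when the transcript has a single exon.  The 50-nt window is exposed as a
parameter.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple, Union

from .vocab import GenotypeCall, Mechanism, VariantClass

#: Length of the NMD-escape window upstream of the last exon-exon junction.
NMD_ESCAPE_WINDOW = 50

#: SO terms that introduce (or are treated as introducing) a premature stop.
PTC_TERMS = frozenset(
    {"stop_gained", "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant"}
)

_ESCAPING_LABEL = {
    "stop_gained": VariantClass.STOP_GAINED_NMD_ESCAPING,
    "frameshift_variant": VariantClass.FRAMESHIFT_NMD_ESCAPING,
    "splice_donor_variant": VariantClass.SPLICE_DONOR_NMD_ESCAPING,
    "splice_acceptor_variant": VariantClass.SPLICE_ACCEPTOR_NMD_ESCAPING,
}


class NmdStatus(enum.Enum):
    TRIGGERING = "triggering"
    ESCAPING = "escaping"
    NOT_APPLICABLE = "not_applicable"


class OutsideTranscriptError(ValueError):
    """The variant does not fall within the transcript span."""


class UnclassifiableVariantError(ValueError):
    """No SO term maps into the variant-class vocabulary."""


@dataclasses.dataclass(frozen=True)
class TranscriptModel:
    """Minimal exon/CDS geometry for one transcript.

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order; ``exon_inclusion`` (when present) is aligned to *transcript* order,
    i.e. index 0 is the 5'-most exon.
    """

    transcript_id: str
    gene: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int
    exon_inclusion: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end or start <= prev_end:
                raise ValueError(f"exons must be ordered and non-overlapping: {self.exons}")
            prev_end = end
        if not (self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]):
            raise ValueError("CDS must lie within the exon span")
        if self.exon_inclusion is not None and len(self.exon_inclusion) != len(self.exons):
            raise ValueError("exon_inclusion must have one fraction per exon")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exons_tx_order(self) -> Tuple[Tuple[int, int], ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def contains(self, pos: int) -> bool:
        return self.exons[0][0] <= pos <= self.exons[-1][1]

    def exon_rank_of(self, pos: int) -> Optional[int]:
        """1-based transcript-order rank of the exon containing ``pos``."""
        for rank, (start, end) in enumerate(self.exons_tx_order, start=1):
            if start <= pos <= end:
                return rank
        return None

    def inclusion_fraction(self, rank: int) -> Optional[float]:
        if self.exon_inclusion is None or not 1 <= rank <= self.n_exons:
            return None
        return self.exon_inclusion[rank - 1]

    def _coding_segments(self) -> List[Tuple[int, int]]:
        segs = []
        for start, end in self.exons_tx_order:
            s, e = max(start, self.cds_start), min(end, self.cds_end)
            if s <= e:
                segs.append((s, e))
        return segs

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self._coding_segments())

    def coding_offset(self, pos: int) -> int:
        """1-based coding coordinate of the coding base at-or-5'-of ``pos``.

        Intronic and UTR positions are clamped to the nearest upstream coding
        base (minimum 1), which places splice-site variants at the junction
        they disrupt.
        """
        segs = self._coding_segments()
        offset = 0
        for s, e in segs:
            if self.strand == "+":
                if pos > e:
                    offset += e - s + 1
                elif pos >= s:
                    return offset + (pos - s + 1)
                else:
                    break
            else:
                if pos < s:
                    offset += e - s + 1
                elif pos <= e:
                    return offset + (e - pos + 1)
                else:
                    break
        return max(offset, 1)

    def last_junction_coding_offset(self) -> int:
        """Coding coordinate of the last exon-exon junction (transcript order)."""
        segs = self._coding_segments()
        if len(segs) <= 1:
            return self.coding_length
        last_exon = self.exons_tx_order[-1]
        total = self.coding_length
        s, e = segs[-1]
        if last_exon[0] <= s and e <= last_exon[1]:
            total -= e - s + 1
        return total


@dataclasses.dataclass(frozen=True)
class AnnotatedVariant:
    """One variant-transcript annotation (a single VEP-style CSQ entry)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript_id: str
    so_terms: FrozenSet[str]
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    protein_pos: Optional[int] = None
    exon_rank: Optional[int] = None
    population_af: Optional[float] = None
    lof_confidence: Optional[str] = None
    clinical_significance: Tuple[str, ...] = ()
    genotypes: Optional[Mapping[str, GenotypeCall]] = None
    splice_evidence: bool = False
    nmd_hint: Optional[str] = None
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based and positive")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population_af must lie in [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def classify_nmd(
    tm: Optional[TranscriptModel],
    variant: AnnotatedVariant,
    escape_window: int = NMD_ESCAPE_WINDOW,
) -> NmdStatus:
    """Adjudicate NMD for a PTC-introducing variant.

    An explicit annotation hint (``variant.nmd_hint``) overrides the geometry
    computation, since upstream annotators may apply richer models.  With
    neither hint nor transcript the call defaults to triggering (the
    conservative assumption for a PTC of unknown position).
    """
    if not (variant.so_terms & PTC_TERMS):
        return NmdStatus.NOT_APPLICABLE
    if variant.nmd_hint is not None:
        return NmdStatus.ESCAPING if variant.nmd_hint == "escaping" else NmdStatus.TRIGGERING
    if tm is None:
        return NmdStatus.TRIGGERING
    if not tm.contains(variant.pos):
        raise OutsideTranscriptError(
            f"{variant.key} lies outside transcript {tm.transcript_id}"
        )
    if tm.n_exons == 1 or len(tm._coding_segments()) == 1:
        return NmdStatus.ESCAPING
    offset = tm.coding_offset(variant.pos)
    junction = tm.last_junction_coding_offset()
    return NmdStatus.ESCAPING if offset > junction - escape_window else NmdStatus.TRIGGERING


# Most-severe-first tie-break order for class assignment.  PTC terms follow
# the usual annotation severity ranking (acceptor > donor > stop > frameshift).
_SEVERITY_ORDER: Tuple[Tuple[str, Optional[VariantClass]], ...] = (
    ("transcript_ablation", VariantClass.WHOLE_GENE_DELETION),
    ("whole_gene_deletion", VariantClass.WHOLE_GENE_DELETION),
    ("exon_loss_variant", VariantClass.STRUCTURAL_EXON_DELETION),
    ("feature_truncation", VariantClass.STRUCTURAL_EXON_DELETION),
    ("duplication", VariantClass.STRUCTURAL_DUPLICATION),
    ("feature_elongation", VariantClass.STRUCTURAL_DUPLICATION),
    ("complex_structural_alteration", VariantClass.COMPLEX_REARRANGEMENT),
    ("splice_acceptor_variant", None),
    ("splice_donor_variant", None),
    ("stop_gained", None),
    ("frameshift_variant", None),
    ("inframe_insertion", VariantClass.INFRAME_INDEL),
    ("inframe_deletion", VariantClass.INFRAME_INDEL),
    ("missense_variant", VariantClass.MISSENSE),
)

_SPLICE_EVIDENCE_TERMS = frozenset({"intron_variant", "splice_region_variant", "synonymous_variant"})


def assign_variant_class(variant: AnnotatedVariant, nmd: NmdStatus) -> VariantClass:
    """Map SO terms (plus an NMD call) onto the variant-class vocabulary.

    Raises :class:`UnclassifiableVariantError` when no term maps; bare
    intronic/synonymous terms only map when the annotation carries explicit
    splice evidence.
    """
    if not variant.so_terms:
        raise UnclassifiableVariantError("variant carries no SO terms")
    for term, label in _SEVERITY_ORDER:
        if term not in variant.so_terms:
            continue
        if label is not None:
            return label
        # PTC term: adjudicated by the NMD status.
        if nmd is NmdStatus.NOT_APPLICABLE:
            raise UnclassifiableVariantError(
                f"PTC term {term!r} with a not_applicable NMD status"
            )
        if nmd is NmdStatus.TRIGGERING:
            return VariantClass.NMD_TRUNCATING
        return _ESCAPING_LABEL[term]
    if variant.splice_evidence and (variant.so_terms & _SPLICE_EVIDENCE_TERMS):
        return VariantClass.INTRONIC_SPLICE_AFFECTING
    raise UnclassifiableVariantError(
        f"no recognised consequence term among {sorted(variant.so_terms)}"
    )


_MECHANISM_MAP: Dict[VariantClass, FrozenSet[Mechanism]] = {
    VariantClass.NMD_TRUNCATING: frozenset({Mechanism.DECREASED_LEVEL}),
    VariantClass.STRUCTURAL_EXON_DELETION: frozenset({Mechanism.DECREASED_LEVEL}),
    VariantClass.WHOLE_GENE_DELETION: frozenset({Mechanism.DECREASED_LEVEL}),
    VariantClass.STRUCTURAL_DUPLICATION: frozenset({Mechanism.DECREASED_LEVEL}),
    VariantClass.COMPLEX_REARRANGEMENT: frozenset({Mechanism.DECREASED_LEVEL}),
    VariantClass.MISSENSE: frozenset({Mechanism.ALTERED_SEQUENCE}),
    VariantClass.INFRAME_INDEL: frozenset({Mechanism.ALTERED_SEQUENCE}),
    VariantClass.STOP_GAINED_NMD_ESCAPING: frozenset({Mechanism.ALTERED_SEQUENCE}),
    VariantClass.FRAMESHIFT_NMD_ESCAPING: frozenset({Mechanism.ALTERED_SEQUENCE}),
    VariantClass.SPLICE_DONOR_NMD_ESCAPING: frozenset({Mechanism.ALTERED_SEQUENCE}),
    VariantClass.SPLICE_ACCEPTOR_NMD_ESCAPING: frozenset({Mechanism.ALTERED_SEQUENCE}),
    # In-frame effect unknown for proven splice-affecting intronic variants.
    VariantClass.INTRONIC_SPLICE_AFFECTING: frozenset({Mechanism.ALTERED_SEQUENCE}),
}


def class_to_mechanism(vc: VariantClass) -> FrozenSet[Mechanism]:
    """Total mapping from variant class to implied mechanism terms."""
    return _MECHANISM_MAP[vc]


# ---------------------------------------------------------------------------
# Toy-transcript table IO (fixture format; see synthetic fixtures module)
# ---------------------------------------------------------------------------

_TX_COLUMNS = (
    "transcript_id",
    "gene",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_start",
    "cds_end",
    "exon_inclusion",
)


def write_transcripts(models: Mapping[str, TranscriptModel], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TX_COLUMNS)
        for tid in sorted(models):
            tm = models[tid]
            writer.writerow(
                [
                    tm.transcript_id,
                    tm.gene,
                    tm.strand,
                    ",".join(str(s) for s, _ in tm.exons),
                    ",".join(str(e) for _, e in tm.exons),
                    tm.cds_start,
                    tm.cds_end,
                    ",".join(f"{f:g}" for f in tm.exon_inclusion) if tm.exon_inclusion else ".",
                ]
            )


def load_transcripts(path: Union[str, Path]) -> Dict[str, TranscriptModel]:
    models: Dict[str, TranscriptModel] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TX_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"transcript table missing columns: {sorted(missing)}")
        for row in reader:
            starts = [int(x) for x in row["exon_starts"].split(",")]
            ends = [int(x) for x in row["exon_ends"].split(",")]
            inclusion = (
                tuple(float(x) for x in row["exon_inclusion"].split(","))
                if row["exon_inclusion"] not in (".", "")
                else None
            )
            models[row["transcript_id"]] = TranscriptModel(
                transcript_id=row["transcript_id"],
                gene=row["gene"],
                strand=row["strand"],
                exons=tuple(zip(starts, ends)),
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
                exon_inclusion=inclusion,
            )
    return models
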