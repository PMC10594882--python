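"""Loader, validator and query engine for the curated gene-disease panel.

The panel is a UTF-8 TSV, one gene-disease pair per row (see
``data/cardiac_panel.tsv`` for the bundled dataset).  Rows graded below
Moderate validity, or without adjudicated mechanism terms, are carried for
completeness but excluded from statistics and filtering ("curated" below
always means validity >= Moderate with a non-empty mechanism set).
"""

from __future__ import annotations

import dataclasses
import json
import re
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .vocab import (
    ALL_PANELS,
    CARDIOMYOPATHY_PANELS,
    CHANNELOPATHY_PANELS,
    CURATED_VALIDITIES,
    LEVEL_LOSS_MECHANISMS,
    AllelicRequirement,
    ConstraintKind,
    InheritanceMode,
    InheritanceQualifier,
    Mechanism,
    Panel,
    Validity,
    VariantClass,
    VocabularyError,
    parse_token,
)

BUNDLED = "bundled"

_COLUMNS = (
    "gene",
    "disease_label",
    "panel",
    "validity",
    "inheritance_modes",
    "inheritance_qualifiers",
    "allelic_requirement",
    "mechanisms",
    "variant_classes",
    "constraints",
    "narrative",
    "references",
)

_TRANSCRIPT_TAG = re.compile(r"\[transcript:([A-Za-z0-9_.]+)\]")


class KnowledgeBaseError(ValueError):
    """Raised for malformed panel files."""


@dataclasses.dataclass(frozen=True)
class RepertoireConstraint:
    """A gene-specific restriction on the pathogenic repertoire.

    ``mode`` decides whether a mismatch drops the variant (``restrict``) or
    merely annotates it (``flag``).  ``threshold`` is only meaningful for
    ``exon_mask`` constraints (minimum per-exon inclusion fraction).
    """

    kind: ConstraintKind
    target_class: Optional[VariantClass] = None
    alleles: Tuple[str, ...] = ()
    region: Optional[Union[Tuple[int, int], str]] = None
    threshold: Optional[float] = None
    mode: str = "restrict"

    def __post_init__(self) -> None:
        if self.mode not in ("restrict", "flag"):
            raise KnowledgeBaseError(f"invalid constraint mode {self.mode!r}")
        if self.kind in (
            ConstraintKind.VARIANT_ALLOWLIST,
            ConstraintKind.CLASS_DROP_EXCEPT_ALLOWLIST,
        ) and not self.alleles:
            raise KnowledgeBaseError(f"{self.kind.value} requires a non-empty allele list")
        if self.kind is ConstraintKind.REGION_FLAG and self.region is None:
            raise KnowledgeBaseError("region_flag requires a region")
        if self.kind is ConstraintKind.EXON_MASK and self.threshold is None:
            raise KnowledgeBaseError("exon_mask requires an inclusion-fraction threshold")

    def to_json_dict(self) -> dict:
        out: dict = {"kind": self.kind.value, "mode": self.mode}
        if self.target_class is not None:
            out["target_class"] = self.target_class.value
        if self.alleles:
            out["alleles"] = list(self.alleles)
        if self.region is not None:
            out["region"] = list(self.region) if isinstance(self.region, tuple) else self.region
        if self.threshold is not None:
            out["threshold"] = self.threshold
        return out

    @classmethod
    def from_json_dict(cls, obj: Mapping) -> "RepertoireConstraint":
        region = obj.get("region")
        if isinstance(region, (list, tuple)):
            region = (int(region[0]), int(region[1]))
        target = obj.get("target_class")
        return cls(
            kind=parse_token(ConstraintKind, obj["kind"]),
            target_class=parse_token(VariantClass, target) if target else None,
            alleles=tuple(obj.get("alleles", ())),
            region=region,
            threshold=obj.get("threshold"),
            mode=obj.get("mode", "restrict"),
        )


@dataclasses.dataclass(frozen=True)
class GeneDiseaseRecord:
    """One curated gene-disease pair."""

    gene: str
    disease_label: str
    panel: Panel
    validity: Validity
    inheritance_modes: FrozenSet[InheritanceMode] = frozenset()
    inheritance_qualifiers: FrozenSet[InheritanceQualifier] = frozenset()
    allelic_requirement: FrozenSet[AllelicRequirement] = frozenset()
    mechanisms: FrozenSet[Mechanism] = frozenset()
    variant_classes: FrozenSet[VariantClass] = frozenset()
    constraints: Tuple[RepertoireConstraint, ...] = ()
    narrative: str = ""
    references: Tuple[str, ...] = ()

    @property
    def is_curated(self) -> bool:
        return self.validity in CURATED_VALIDITIES and bool(self.mechanisms)

    @property
    def exclusively_biallelic(self) -> bool:
        return self.allelic_requirement == frozenset({AllelicRequirement.BIALLELIC_AUTOSOMAL})

    @property
    def designated_transcript(self) -> Optional[str]:
        """Transcript named in the narrative via a ``[transcript:ID]`` tag."""
        m = _TRANSCRIPT_TAG.search(self.narrative)
        return m.group(1) if m else None

    @property
    def key(self) -> Tuple[str, str, FrozenSet[AllelicRequirement]]:
        return (self.gene, self.disease_label, self.allelic_requirement)


@dataclasses.dataclass(frozen=True)
class KbStats:
    pairs_total: int
    pairs_by_panel: Mapping[Panel, int]
    unique_genes_by_group: Mapping[str, int]
    pairs_without_level_decrease: int
    pairs_exclusively_biallelic: int
    pairs_with_dual_ad_ar: int


class KnowledgeBase:
    """An in-memory panel with gene and panel indexes."""

    def __init__(self, records: Sequence[GeneDiseaseRecord], version: str = "") -> None:
        self.records: List[GeneDiseaseRecord] = list(records)
        self.version = version
        seen = set()
        for r in self.records:
            if r.key in seen:
                raise KnowledgeBaseError(
                    f"duplicate record for {r.gene} / {r.disease_label} / "
                    f"{sorted(a.value for a in r.allelic_requirement)}"
                )
            seen.add(r.key)
        self.by_gene: Dict[str, List[GeneDiseaseRecord]] = {}
        self.by_panel: Dict[Panel, List[GeneDiseaseRecord]] = {p: [] for p in Panel}
        for r in self.records:
            self.by_gene.setdefault(r.gene, []).append(r)
            self.by_panel[r.panel].append(r)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def curated_records(self) -> List[GeneDiseaseRecord]:
        return [r for r in self.records if r.is_curated]

    def curated_in_panels(self, panels: Optional[Iterable[Panel]] = None) -> List[GeneDiseaseRecord]:
        wanted = frozenset(panels) if panels is not None else ALL_PANELS
        for p in wanted:
            if not isinstance(p, Panel):
                raise VocabularyError(f"unknown panel {p!r}")
        return [r for r in self.curated_records if r.panel in wanted]

    def genes(self, panels: Optional[Iterable[Panel]] = None) -> FrozenSet[str]:
        return frozenset(r.gene for r in self.curated_in_panels(panels))


def _split(cell: str) -> List[str]:
    return [tok for tok in (t.strip() for t in cell.split(";")) if tok]


def _parse_row(fields: Sequence[str], row_num: int) -> GeneDiseaseRecord:
    cells = dict(zip(_COLUMNS, fields))

    def toks(column: str, cls):
        try:
            return frozenset(parse_token(cls, t) for t in _split(cells[column]))
        except VocabularyError as exc:
            raise KnowledgeBaseError(f"row {row_num}, column {column!r}: {exc}") from exc

    try:
        constraints = tuple(
            RepertoireConstraint.from_json_dict(obj)
            for obj in json.loads(cells["constraints"] or "[]")
        )
    except (json.JSONDecodeError, KeyError, VocabularyError) as exc:
        raise KnowledgeBaseError(f"row {row_num}, column 'constraints': {exc}") from exc
    try:
        validity = parse_token(Validity, cells["validity"])
        panel = parse_token(Panel, cells["panel"])
    except VocabularyError as exc:
        raise KnowledgeBaseError(f"row {row_num}: {exc}") from exc
    return GeneDiseaseRecord(
        gene=cells["gene"],
        disease_label=cells["disease_label"],
        panel=panel,
        validity=validity,
        inheritance_modes=toks("inheritance_modes", InheritanceMode),
        inheritance_qualifiers=toks("inheritance_qualifiers", InheritanceQualifier),
        allelic_requirement=toks("allelic_requirement", AllelicRequirement),
        mechanisms=toks("mechanisms", Mechanism),
        variant_classes=toks("variant_classes", VariantClass),
        constraints=constraints,
        narrative=cells["narrative"],
        references=tuple(_split(cells["references"])),
    )


def load_knowledge_base(source: Union[str, Path] = BUNDLED) -> KnowledgeBase:
    """Load a panel TSV; ``source='bundled'`` loads the packaged dataset."""
    if source == BUNDLED:
        text = (resources.files("cardiacg2p") / "data" / "cardiac_panel.tsv").read_text("utf-8")
    else:
        text = Path(source).read_text("utf-8")
    lines = text.splitlines()
    version = ""
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        if lines[i].startswith("#version="):
            version = lines[i].split("=", 1)[1]
        i += 1
    if i >= len(lines):
        raise KnowledgeBaseError("panel file has no header row")
    header = tuple(lines[i].rstrip("\n").split("\t"))
    if header != _COLUMNS:
        missing = set(_COLUMNS) - set(header)
        raise KnowledgeBaseError(f"unexpected header; missing columns: {sorted(missing)}")
    records = []
    for row_num, line in enumerate(lines[i + 1 :], start=i + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_COLUMNS):
            raise KnowledgeBaseError(
                f"row {row_num}: expected {len(_COLUMNS)} columns, got {len(fields)}"
            )
        record = _parse_row(fields, row_num)
        issues = validate_record(record)
        if issues:
            raise KnowledgeBaseError(f"row {row_num} ({record.gene}): " + "; ".join(issues))
        records.append(record)
    return KnowledgeBase(records, version=version)


def write_knowledge_base(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    """Serialize ``kb`` to the panel TSV dialect (round-trips with the loader)."""
    out = []
    if kb.version:
        out.append(f"#version={kb.version}")
    out.append("\t".join(_COLUMNS))
    for r in kb.records:
        out.append(
            "\t".join(
                (
                    r.gene,
                    r.disease_label,
                    r.panel.value,
                    r.validity.value,
                    ";".join(sorted(m.value for m in r.inheritance_modes)),
                    ";".join(sorted(q.value for q in r.inheritance_qualifiers)),
                    ";".join(sorted(a.value for a in r.allelic_requirement)),
                    ";".join(sorted(m.value for m in r.mechanisms)),
                    ";".join(sorted(c.value for c in r.variant_classes)),
                    json.dumps([c.to_json_dict() for c in r.constraints]),
                    r.narrative,
                    ";".join(r.references),
                )
            )
        )
    Path(path).write_text("\n".join(out) + "\n", "utf-8")


def validate_record(record: GeneDiseaseRecord) -> List[str]:
    """Return a list of invariant violations (empty list = valid).

    Mechanism implication treats ``decreased_gene_product_level`` as satisfied
    by ``absent_gene_product_level`` too: complete loss subsumes partial loss
    for biallelic null genotypes.
    """
    from .consequence import class_to_mechanism  # local import: avoid cycle at import time

    issues: List[str] = []
    if record.is_curated:
        if not record.inheritance_modes:
            issues.append("curated record has no inheritance modes")
        if not record.allelic_requirement:
            issues.append("curated record has no allelic requirement")
    else:
        if record.mechanisms and record.validity not in CURATED_VALIDITIES:
            issues.append(
                f"record with {record.validity.value} validity must not carry mechanism terms"
            )
    modes, req = record.inheritance_modes, record.allelic_requirement
    if InheritanceMode.AUTOSOMAL_DOMINANT in modes and AllelicRequirement.MONOALLELIC_AUTOSOMAL not in req:
        issues.append("autosomal dominant inheritance without monoallelic_autosomal requirement")
    if InheritanceMode.AUTOSOMAL_RECESSIVE in modes and AllelicRequirement.BIALLELIC_AUTOSOMAL not in req:
        issues.append("autosomal recessive inheritance without biallelic_autosomal requirement")
    if InheritanceMode.X_LINKED in modes and AllelicRequirement.MONOALLELIC_X_LINKED not in req:
        issues.append("x_linked inheritance without monoallelic_x_linked requirement")
    implied: set = set()
    for vc in record.variant_classes:
        implied |= class_to_mechanism(vc)
    for term in implied:
        satisfied = term in record.mechanisms or (
            term is Mechanism.DECREASED_LEVEL and Mechanism.ABSENT_LEVEL in record.mechanisms
        )
        if not satisfied:
            issues.append(
                f"variant classes imply mechanism {term.value!r} absent from the mechanism set"
            )
    return issues


def _resolve_panels(kb: KnowledgeBase, panel_filter: Optional[Iterable[Panel]]) -> List[GeneDiseaseRecord]:
    return kb.curated_in_panels(panel_filter)


def count_pairs_without_level_decrease(
    kb: KnowledgeBase, panel_filter: Optional[Iterable[Panel]] = None
) -> int:
    """Curated pairs whose mechanisms exclude decreased AND absent product level."""
    return sum(
        1
        for r in _resolve_panels(kb, panel_filter)
        if not (r.mechanisms & LEVEL_LOSS_MECHANISMS)
    )


def kb_stats(kb: KnowledgeBase, panel_filter: Optional[Iterable[Panel]] = None) -> KbStats:
    records = _resolve_panels(kb, panel_filter)
    by_panel: Dict[Panel, int] = {}
    for r in records:
        by_panel[r.panel] = by_panel.get(r.panel, 0) + 1
    groups = {
        "cardiomyopathy": len({r.gene for r in records if r.panel in CARDIOMYOPATHY_PANELS}),
        "channelopathy": len({r.gene for r in records if r.panel in CHANNELOPATHY_PANELS}),
    }
    dual = frozenset({InheritanceMode.AUTOSOMAL_DOMINANT, InheritanceMode.AUTOSOMAL_RECESSIVE})
    return KbStats(
        pairs_total=len(records),
        pairs_by_panel=by_panel,
        unique_genes_by_group=groups,
        pairs_without_level_decrease=sum(
            1 for r in records if not (r.mechanisms & LEVEL_LOSS_MECHANISMS)
        ),
        pairs_exclusively_biallelic=sum(1 for r in records if r.exclusively_biallelic),
        pairs_with_dual_ad_ar=sum(1 for r in records if dual <= r.inheritance_modes),
    )


def records_for_gene(
    kb: KnowledgeBase, gene: str, panel: Optional[Panel] = None
) -> List[GeneDiseaseRecord]:
    """Curated records for ``gene`` (optionally restricted to one panel)."""
    hits = [r for r in kb.by_gene.get(gene, []) if r.is_curated]
    if panel is not None:
        hits = [r for r in hits if r.panel == panel]
    return sorted(hits, key=lambda r: (r.panel.value, r.disease_label))
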