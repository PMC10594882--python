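"""Closed vocabularies shared across the package.

Every token that appears in the bundled panel file or in a decision trace is
drawn from one of the enumerations below; loaders reject anything else.
"""

from __future__ import annotations

import enum
from typing import FrozenSet, Type, TypeVar


class VocabularyError(ValueError):
    """Raised when a token is not part of a closed vocabulary."""


class Mechanism(str, enum.Enum):
    """Disease-associated variant consequence (proxy for disease mechanism)."""

    DECREASED_LEVEL = "decreased_gene_product_level"
    ALTERED_SEQUENCE = "altered_gene_product_sequence"
    ABSENT_LEVEL = "absent_gene_product_level"


#: Mechanism terms that describe loss of gene product (partial or complete).
LEVEL_LOSS_MECHANISMS: FrozenSet[Mechanism] = frozenset(
    {Mechanism.DECREASED_LEVEL, Mechanism.ABSENT_LEVEL}
)


class VariantClass(str, enum.Enum):
    """Variant classes reported with evidence of pathogenicity.

    ``NMD_TRUNCATING`` subsumes frameshift, stop-gained and splice
    acceptor/donor variants that trigger nonsense-mediated decay; PTCs that
    escape NMD keep a per-term label because they leave an altered, rather
    than reduced, gene product.
    """

    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    NMD_TRUNCATING = "nmd_truncating"
    STOP_GAINED_NMD_ESCAPING = "stop_gained_nmd_escaping"
    FRAMESHIFT_NMD_ESCAPING = "frameshift_nmd_escaping"
    SPLICE_DONOR_NMD_ESCAPING = "splice_donor_nmd_escaping"
    SPLICE_ACCEPTOR_NMD_ESCAPING = "splice_acceptor_nmd_escaping"
    STRUCTURAL_EXON_DELETION = "structural_exon_deletion"
    WHOLE_GENE_DELETION = "whole_gene_deletion"
    STRUCTURAL_DUPLICATION = "structural_duplication"
    COMPLEX_REARRANGEMENT = "complex_rearrangement"
    INTRONIC_SPLICE_AFFECTING = "intronic_splice_affecting"


class InheritanceMode(str, enum.Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED = "x_linked"


class InheritanceQualifier(str, enum.Enum):
    INCOMPLETE_PENETRANCE = "incomplete_penetrance"
    AGE_RELATED_ONSET = "age_related_onset"
    TYPICALLY_DE_NOVO = "typically_de_novo"


class AllelicRequirement(str, enum.Enum):
    MONOALLELIC_AUTOSOMAL = "monoallelic_autosomal"
    BIALLELIC_AUTOSOMAL = "biallelic_autosomal"
    MONOALLELIC_X_LINKED = "monoallelic_x_linked"


class Panel(str, enum.Enum):
    HCM = "HCM"
    HCM_SYNDROMIC = "HCM_syndromic"
    DCM = "DCM"
    ARVC = "ARVC"
    LQTS = "LQTS"
    BRS = "BrS"
    CPVT = "CPVT"
    SQTS = "SQTS"


CARDIOMYOPATHY_PANELS: FrozenSet[Panel] = frozenset(
    {Panel.HCM, Panel.HCM_SYNDROMIC, Panel.DCM, Panel.ARVC}
)
CHANNELOPATHY_PANELS: FrozenSet[Panel] = frozenset(
    {Panel.LQTS, Panel.BRS, Panel.CPVT, Panel.SQTS}
)
ALL_PANELS: FrozenSet[Panel] = CARDIOMYOPATHY_PANELS | CHANNELOPATHY_PANELS


class Validity(str, enum.Enum):
    """Gene-disease validity grade (stored as metadata; assigned upstream)."""

    DEFINITIVE = "Definitive"
    STRONG = "Strong"
    MODERATE = "Moderate"
    LIMITED = "Limited"
    DISPUTED = "Disputed"


#: Grades for which inheritance / mechanism terms are adjudicated.
CURATED_VALIDITIES: FrozenSet[Validity] = frozenset(
    {Validity.DEFINITIVE, Validity.STRONG, Validity.MODERATE}
)


class ConstraintKind(str, enum.Enum):
    """Kinds of gene-specific restricted-repertoire constraints."""

    VARIANT_ALLOWLIST = "variant_allowlist"
    CLASS_DROP_EXCEPT_ALLOWLIST = "class_drop_except_allowlist"
    REGION_FLAG = "region_flag"
    EXON_MASK = "exon_mask"
    CLASS_FORCE_RETAIN = "class_force_retain"


class GenotypeCall(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


_E = TypeVar("_E", bound=enum.Enum)


def parse_token(cls: Type[_E], token: str) -> _E:
    """Parse ``token`` into a member of ``cls``, or raise :class:`VocabularyError`."""
    try:
        return cls(token)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise VocabularyError(
            f"{token!r} is not a valid {cls.__name__} token (expected one of: {valid})"
        ) from None
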