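"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (exact rational
hypergeometric enumeration; a flat boolean re-statement of the mechanism-aware
pipeline) and must stay independent of the code paths they check.
"""

from fractions import Fraction
from math import comb

from cardiacg2p.vocab import ConstraintKind, VariantClass


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact rationals."""
    n = a + b + c + d
    r, k = a + b, a + c
    if r in (0, n) or k in (0, n):
        return 1.0

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r, x) * comb(n - r, k - x), comb(n, k))

    p_obs = pmf(a)
    cutoff = p_obs * (1 + Fraction(1, 10**7))
    total = Fraction(0)
    for x in range(max(0, r + k - n), min(r, k) + 1):
        px = pmf(x)
        if px <= cutoff:
            total += px
    return min(1.0, float(total))


def _allele_hit(variant, alleles) -> bool:
    return variant.hgvs_p is not None and variant.hgvs_p in alleles


def flat_pipeline3(variant, variant_class, kb, panels, transcripts, af_threshold=1e-4):
    """Single boolean expression over (gene, class, AF, constraints).

    ``variant_class`` is the pre-assigned class label (or None).  Mirrors the
    published filter logic without any staging machinery.
    """
    af_ok = variant.population_af is None or variant.population_af < af_threshold
    if not af_ok:
        return False
    for record in kb.curated_records:
        if record.panel not in panels or record.gene != variant.gene:
            continue
        force_intronic = any(
            c.kind is ConstraintKind.CLASS_FORCE_RETAIN
            and c.target_class is VariantClass.INTRONIC_SPLICE_AFFECTING
            for c in record.constraints
        )
        if force_intronic and "intron_variant" in variant.so_terms:
            return True
        if variant_class is None:
            continue
        in_classes = variant_class in record.variant_classes or (
            variant_class is VariantClass.INTRONIC_SPLICE_AFFECTING
            and VariantClass.NMD_TRUNCATING in record.variant_classes
        )
        if not in_classes:
            continue
        dropped = False
        for c in record.constraints:
            if c.kind is ConstraintKind.CLASS_DROP_EXCEPT_ALLOWLIST:
                if variant_class == c.target_class and not _allele_hit(variant, c.alleles):
                    dropped = True
            elif c.kind is ConstraintKind.VARIANT_ALLOWLIST and c.mode == "restrict":
                if (c.target_class is None or variant_class == c.target_class) and not _allele_hit(
                    variant, c.alleles
                ):
                    dropped = True
            elif c.kind is ConstraintKind.EXON_MASK:
                target = c.target_class or VariantClass.NMD_TRUNCATING
                if variant_class == target:
                    tm = transcripts.get(variant.transcript_id) if transcripts else None
                    if tm is None or tm.exon_inclusion is None:
                        continue
                    rank = (
                        variant.exon_rank
                        if variant.exon_rank is not None
                        else tm.exon_rank_of(variant.pos)
                    )
                    if rank is None:
                        continue
                    if tm.exon_inclusion[rank - 1] <= c.threshold:
                        dropped = True
        if not dropped:
            return True
    return False
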