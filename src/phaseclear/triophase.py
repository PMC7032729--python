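"""Pedigree-based phasing of heterozygous variants in a child.

A single heterozygous variant is assigned to the maternal or paternal
chromosome by enumerating which parental transmissions are consistent
with the trio genotypes.  An assignment forced by Mendelian inheritance
carries confidence 1.0.  A de novo alternate allele cannot be assigned
by transmission; if the inherited allele is present in both parents with
one parent heterozygous and the other homozygous for it, the inherited
allele is probabilistically assigned to the homozygous parent and the de
novo allele to the other, with confidence 0.66.

Pairs can further be labeled *innocuous* — excluded as causing a
recessive disease under the assumption of healthy parents — when a
parent is homozygous for one of the alternate alleles, or when child,
mother and father all share the same heterozygous genotype at one site.
"""

from __future__ import annotations

from typing import Optional

from phaseclear.datamodel import ParentalOrigin, PhaseEdge, TrioGenotypes

#: Confidence of the probabilistic de novo origin assignment.
DE_NOVO_CONFIDENCE = 0.66


def assign_parental_origin(tg: TrioGenotypes, alt: str) -> Optional[ParentalOrigin]:
    """Parental origin of the child's ``alt`` allele, or None.

    Mendelian case: enumerate all four parental transmission choices;
    if every choice consistent with the child genotype hands ``alt`` to
    the same parent, that parent is the origin with confidence 1.0; if
    consistent choices disagree, no call.  De novo case (``alt`` in
    neither parent): the inherited allele goes to the parent homozygous
    for it when the other parent is heterozygous for it, so ``alt``
    originates from the heterozygous parent with confidence 0.66.  Any
    missing parental genotype yields no call.
    """
    if not tg.child_is_het:
        raise ValueError("parental origin is defined only for a heterozygous child")
    if alt not in tg.child:
        raise ValueError(f"child genotype {tg.child} does not carry alt {alt!r}")
    if tg.mother is None or tg.father is None:
        return None

    child_ms = sorted(tg.child)
    origins = set()
    for m in tg.mother:
        for f in tg.father:
            if sorted((m, f)) == child_ms:
                if m == alt and f == alt:
                    origins.update(("maternal", "paternal"))
                elif m == alt:
                    origins.add("maternal")
                elif f == alt:
                    origins.add("paternal")
    if len(origins) == 1:
        return ParentalOrigin(origins.pop(), 1.0)
    if origins:
        return None  # consistent transmissions disagree

    # no consistent transmission hands alt to a parent: de novo branch
    if alt in tg.mother or alt in tg.father:
        return None  # Mendelian violation other than de novo; abstain
    inherited = tg.child[0] if tg.child[1] == alt else tg.child[1]
    mother_has = inherited in tg.mother
    father_has = inherited in tg.father
    if not (mother_has and father_has):
        return None
    mother_hom = tg.mother == (inherited, inherited)
    father_hom = tg.father == (inherited, inherited)
    if mother_hom and not father_hom:
        # inherited allele assigned maternal, so the de novo alt is paternal
        return ParentalOrigin("paternal", DE_NOVO_CONFIDENCE)
    if father_hom and not mother_hom:
        return ParentalOrigin("maternal", DE_NOVO_CONFIDENCE)
    return None  # both homozygous or both heterozygous for the inherited allele


def trio_pair_edge(o1: ParentalOrigin, o2: ParentalOrigin) -> PhaseEdge:
    """Combine two per-variant origins into a pairwise phase relation.

    Same origin means cis, opposite means trans; the pair confidence is
    the product of the per-variant confidences (1.0, 0.66 or 0.4356).
    """
    return PhaseEdge(
        endpoints=frozenset(),
        orientation="cis" if o1.origin == o2.origin else "trans",
        confidence=round(o1.confidence * o2.confidence, 10),
        source="trio",
    )


def is_innocuous_pair(
    tg1: TrioGenotypes, alt1: str, tg2: TrioGenotypes, alt2: str
) -> bool:
    """Whether a het/het candidate pair can be excluded as innocuous.

    True iff, at either site, a parent is homozygous for that site's
    alternate allele, or child, mother and father all possess the same
    heterozygous genotype.  A missing parental genotype cannot satisfy
    either condition at its site; the pair may still qualify through the
    other site.
    """
    for tg, alt in ((tg1, alt1), (tg2, alt2)):
        if not tg.child_is_het:
            raise ValueError("innocuous labeling is defined for het/het pairs")
        hom_alt = (alt, alt)
        for parent in (tg.mother, tg.father):
            if parent == hom_alt:
                return True
        if (
            tg.mother is not None
            and tg.father is not None
            and sorted(tg.mother) == sorted(tg.child)
            and sorted(tg.father) == sorted(tg.child)
        ):
            return True
    return False
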