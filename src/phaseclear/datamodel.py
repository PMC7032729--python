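"""Core domain types shared by all modules, and the bitflag pair encoding.

Genotypes are kept as tuples of *allele strings* (not indices) so that
records produced by splitting multi-allelic VCF lines stay comparable
across files.  A missing genotype is ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

ALLELE_CHARS = set("ACGTN")

#: Bit values of the pair-outcome flag.
FLAG_CIS = 1
FLAG_TRANS = 2
FLAG_INNOCUOUS = 4
FLAG_NOT_FOUND = 8
FLAG_PHYSICAL = 16

Genotype = Optional[tuple[str, str]]  # unordered pair of allele strings


@dataclass(frozen=True)
class VariantSite:
    """One normalized biallelic variant with per-sample genotypes.

    Positions follow the VCF convention (1-based).  Multi-allelic records
    must be split into one ``VariantSite`` per alternate allele before
    construction; each record carries a single ``alt``.

    ``phase_set_id``/``phase_set_gt`` hold a caller's physical-phasing
    annotation (GATK HaplotypeCaller PID/PGT dialect): variants sharing a
    ``phase_set_id`` were phased together locally during realignment-based
    calling, and ``phase_set_gt`` is the ordered (pipe-separated) genotype
    giving the within-block phase.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    phase_set_id: Optional[str] = None
    phase_set_gt: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - ALLELE_CHARS or set(self.alt) - ALLELE_CHARS:
            raise ValueError(f"alleles must be over ACGTN: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.phase_set_gt is not None and self.phase_set_id is None:
            raise ValueError("phase_set_gt requires phase_set_id")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the site: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype(self, sample: str) -> Genotype:
        return self.genotypes.get(sample)

    def is_het(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        return gt is not None and gt[0] != gt[1]

    def is_het_for_alt(self, sample: str) -> bool:
        """Het genotype carrying exactly one copy of this record's alt
        (the other allele may be the reference or a third allele)."""
        gt = self.genotypes.get(sample)
        return gt is not None and gt[0] != gt[1] and self.alt in gt

    def carries_alt(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        return gt is not None and self.alt in gt

    def is_hom_alt(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        return gt is not None and gt[0] == self.alt and gt[1] == self.alt

    def __str__(self) -> str:  # used in output rows
        return f"{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class TrioGenotypes:
    """Child/mother/father genotypes at one site, as allele-string pairs.

    The child must be heterozygous for any phasing operation consuming
    this type; parents may be missing (``None``).
    """

    child: Genotype
    mother: Genotype
    father: Genotype

    @property
    def child_is_het(self) -> bool:
        return self.child is not None and self.child[0] != self.child[1]


@dataclass(frozen=True)
class ParentalOrigin:
    """Parental-chromosome assignment of a single heterozygous variant.

    Only two confidence levels exist: 1.0 for a Mendelian-forced
    assignment and 0.66 for the probabilistic de novo rule.
    """

    origin: Literal["maternal", "paternal"]
    confidence: float

    def __post_init__(self) -> None:
        if self.origin not in ("maternal", "paternal"):
            raise ValueError(f"bad origin {self.origin!r}")
        if self.confidence not in (1.0, 0.66):
            raise ValueError("trio confidence must be exactly 1.0 or 0.66")


@dataclass(frozen=True)
class FragmentEvidence:
    """One sequencing fragment's observation of a variant pair.

    ``kind`` is ``cis`` when the fragment shows the alternate allele at
    both sites, ``trans`` when it shows exactly one alternate with the
    other site reference-matching, and ``neither`` when both sites are
    covered but reference-matching.  ``corrected_v1``/``corrected_v2``
    are the mean per-base error probabilities (``mean(10^(-q/10))``) of
    the allele bases this fragment used at each site.
    """

    kind: Literal["cis", "trans", "neither"]
    corrected_v1: float
    corrected_v2: float

    def __post_init__(self) -> None:
        if self.kind not in ("cis", "trans", "neither"):
            raise ValueError(f"bad kind {self.kind!r}")
        for v in (self.corrected_v1, self.corrected_v2):
            if not (0.0 <= v <= 1.0):
                raise ValueError("corrected error probabilities must be in [0, 1]")


@dataclass(frozen=True)
class EvidenceSummary:
    """All fragment observations collected for one variant pair."""

    fragments: tuple[FragmentEvidence, ...]

    @property
    def n(self) -> int:
        """Total fragments overlapping both variant positions."""
        return len(self.fragments)

    @property
    def n_cis(self) -> int:
        return sum(1 for f in self.fragments if f.kind == "cis")

    @property
    def n_trans(self) -> int:
        return sum(1 for f in self.fragments if f.kind == "trans")


@dataclass(frozen=True)
class PhaseEdge:
    """A pairwise phase relation between two sites (or a site and the
    parental-origin anchor), with its confidence and provenance."""

    endpoints: frozenset
    orientation: Literal["cis", "trans"]
    confidence: float
    source: Literal["read", "trio", "physical"]

    def __post_init__(self) -> None:
        if self.orientation not in ("cis", "trans"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.source == "trio":
            if self.confidence not in (1.0, 0.66, 0.4356):
                raise ValueError("trio edge confidence must be 1.0, 0.66 or 0.4356")
        elif self.source == "physical":
            if self.confidence != 1.0:
                raise ValueError("physical edge confidence must be 1.0")
        elif self.source == "read":
            if not (0.0 <= self.confidence < 1.0):
                raise ValueError("read edge confidence must be in [0, 1)")
        else:
            raise ValueError(f"bad source {self.source!r}")


@dataclass(frozen=True)
class PairResult:
    """Final record for a candidate pair: bitflag, confidence, provenance."""

    v1: VariantSite
    v2: VariantSite
    flag: int
    confidence: float
    source: str  # "read", "trio", "physical", "path", "none"

    @property
    def phase(self) -> Optional[str]:
        return decode_flags(self.flag)["phase"]

    @property
    def innocuous(self) -> bool:
        return decode_flags(self.flag)["innocuous"]


def encode_flags(
    phase: Optional[str],
    innocuous: bool = False,
    not_found: bool = False,
    physical: bool = False,
) -> int:
    """Encode a pair outcome as a single integer bitflag.

    Bits: 1 = cis, 2 = trans, 4 = innocuous, 8 = variant not found in the
    alignments, 16 = phase adopted from caller physical phasing.  ``phase``
    is ``"cis"``, ``"trans"`` or ``None`` (unphased); cis and trans are
    mutually exclusive by construction, and a not-found pair carries no
    phase unless it was rescued physically (in which case ``not_found``
    must be cleared by the caller).
    """
    if phase not in ("cis", "trans", None):
        raise ValueError(f"bad phase {phase!r}")
    if not_found and phase is not None:
        raise ValueError("a not-found pair cannot carry a phase")
    flag = 0
    if phase == "cis":
        flag |= FLAG_CIS
    elif phase == "trans":
        flag |= FLAG_TRANS
    if innocuous:
        flag |= FLAG_INNOCUOUS
    if not_found:
        flag |= FLAG_NOT_FOUND
    if physical:
        flag |= FLAG_PHYSICAL
    return flag


def decode_flags(flag: int) -> dict:
    """Invert :func:`encode_flags`.

    Returns ``{"phase", "innocuous", "not_found", "physical"}``; raises on
    flags with both the cis and the trans bit set, which no legal encoding
    produces.
    """
    if flag & FLAG_CIS and flag & FLAG_TRANS:
        raise ValueError(f"flag {flag} has both cis and trans bits set")
    if flag & ~(FLAG_CIS | FLAG_TRANS | FLAG_INNOCUOUS | FLAG_NOT_FOUND | FLAG_PHYSICAL):
        raise ValueError(f"flag {flag} has unknown bits set")
    phase = "cis" if flag & FLAG_CIS else ("trans" if flag & FLAG_TRANS else None)
    not_found = bool(flag & FLAG_NOT_FOUND)
    if not_found and phase is not None:
        raise ValueError(f"flag {flag} is not-found but carries a phase")
    return {
        "phase": phase,
        "innocuous": bool(flag & FLAG_INNOCUOUS),
        "not_found": not_found,
        "physical": bool(flag & FLAG_PHYSICAL),
    }
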