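"""Per-fragment allele observations for variant pairs from BAM/CRAM.

A fragment (all primary reads sharing a query name) is the unit of
evidence: both mates of a proper pair come from the same haplotype, so a
fragment connects two variant sites whenever its reads jointly cover
both, regardless of the physical gap between mates or of splicing.

Read filters follow the standard hygiene for haplotype evidence: only
mapped, primary, non-duplicate reads that are proper pairs when paired,
optionally above a mapping-quality floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import pysam

from phaseclear.datamodel import EvidenceSummary, FragmentEvidence, VariantSite

log = logging.getLogger(__name__)

# CIGAR operation codes (pysam)
_MATCH_OPS = {0, 7, 8}  # M, =, X consume both query and reference
_BAM_CINS = 1
_BAM_CDEL = 2
_BAM_CREF_SKIP = 3
_BAM_CSOFT = 4


@dataclass(frozen=True)
class AlleleObservation:
    """What one read says about one variant site."""

    call: Literal["alt", "ref", "other", "not_covered"]
    qualities: tuple[int, ...] = ()

    @property
    def mean_error(self) -> float:
        if not self.qualities:
            return 1.0
        return sum(10 ** (-q / 10) for q in self.qualities) / len(self.qualities)


def passes_filters(read: pysam.AlignedSegment, mapq_min: int = 0) -> bool:
    """True iff the read is usable as phasing evidence.

    Requires: mapped, primary (neither secondary nor supplementary), not
    a duplicate, a proper pair when paired, and MAPQ >= ``mapq_min``.
    """
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.is_duplicate:
        return False
    if read.is_paired and not read.is_proper_pair:
        return False
    return read.mapping_quality >= mapq_min


def _alignment_maps(read: pysam.AlignedSegment):
    """Walk the CIGAR once, returning
    ``(ref2query, skipped_refpos, insertions)`` where ``ref2query`` maps
    each aligned reference position (0-based) to its query index,
    ``skipped_refpos`` holds reference positions consumed by D or N ops
    (D positions map to None in ref2query, N positions are absent), and
    ``insertions`` maps the 0-based reference position *preceding* an
    insertion to the (query_start, length) of the inserted bases."""
    ref2query: dict[int, Optional[int]] = {}
    spliced: set[int] = set()
    deleted: set[int] = set()
    insertions: dict[int, tuple[int, int]] = {}
    rpos = read.reference_start
    qpos = 0
    for op, length in read.cigartuples or ():
        if op in _MATCH_OPS:
            for i in range(length):
                ref2query[rpos + i] = qpos + i
            rpos += length
            qpos += length
        elif op == _BAM_CINS:
            insertions[rpos - 1] = (qpos, length)
            qpos += length
        elif op == _BAM_CDEL:
            for i in range(length):
                deleted.add(rpos + i)
            rpos += length
        elif op == _BAM_CREF_SKIP:
            for i in range(length):
                spliced.add(rpos + i)
            rpos += length
        elif op == _BAM_CSOFT:
            qpos += length
        # hard clip / pad consume nothing we track
    return ref2query, spliced, deleted, insertions


def observe_allele(read: pysam.AlignedSegment, site: VariantSite) -> AlleleObservation:
    """Determine which allele of ``site`` a read shows, with the Phred
    qualities of the bases used.

    The CIGAR is walked to map reference positions to read offsets:

    * substitution (|ref| == |alt|): the read bases across the span must
      equal the alternate (-> alt) or reference (-> ref) allele; any
      third sequence is ``other``.  Qualities are those of the l allele
      bases.
    * insertion: ``alt`` iff the inserted bases are present immediately
      after the anchor base (qualities of the inserted bases, l =
      |alt|-1); ``ref`` iff the read aligns straight through the anchor
      and the following base with no insertion (qualities of those two
      junction bases).
    * deletion: ``alt`` iff the CIGAR deletes exactly the deleted span
      (qualities of the two flanking read bases, l = 2); ``ref`` iff the
      read aligns across the whole span with reference-matching bases.

    A span that is clipped, spliced out (N) or outside the read is
    ``not_covered``; any ambiguity maps to ``other``.
    """
    ref2query, spliced, deleted, insertions = _alignment_maps(read)
    seq = read.query_sequence or ""
    quals = read.query_qualities
    if quals is None:
        quals = [30] * len(seq)  # unstored qualities: neutral default
    pos0 = site.pos - 1
    ref_span = range(pos0, pos0 + len(site.ref))

    if any(p in spliced for p in ref_span):
        return AlleleObservation("not_covered")
    covered = [p for p in ref_span if p in ref2query or p in deleted]
    if len(covered) < len(site.ref):
        return AlleleObservation("not_covered")

    if len(site.ref) == len(site.alt):  # SNV / MNV
        qidx = [ref2query.get(p) for p in ref_span]
        if any(q is None for q in qidx):
            return AlleleObservation("other")  # partial deletion across the span
        bases = "".join(seq[q] for q in qidx)
        qs = tuple(int(quals[q]) for q in qidx)
        if bases == site.alt:
            return AlleleObservation("alt", qs)
        if bases == site.ref:
            return AlleleObservation("ref", qs)
        return AlleleObservation("other", qs)

    if len(site.ref) < len(site.alt):  # insertion (anchored, VCF-style)
        anchor_q = ref2query.get(pos0)
        if anchor_q is None:
            return AlleleObservation("other")
        ins = insertions.get(pos0)
        inserted = site.alt[len(site.ref):]
        if ins is not None:
            qstart, length = ins
            if seq[qstart:qstart + length] == inserted and seq[anchor_q] == site.alt[0]:
                qs = tuple(int(quals[qstart + i]) for i in range(length))
                return AlleleObservation("alt", qs)
            return AlleleObservation("other")
        # no insertion here: reference observation needs the next base aligned too
        next_q = ref2query.get(pos0 + 1)
        if next_q is None:
            if pos0 + 1 in deleted or pos0 + 1 in spliced:
                return AlleleObservation("other")
            return AlleleObservation("not_covered")
        if seq[anchor_q] == site.ref[0]:
            qs = (int(quals[anchor_q]), int(quals[next_q]))
            return AlleleObservation("ref", qs)
        return AlleleObservation("other")

    # deletion (|ref| > |alt|, anchored)
    anchor_q = ref2query.get(pos0)
    if anchor_q is None:
        return AlleleObservation("other")
    del_span = range(pos0 + 1, pos0 + len(site.ref))
    if all(p in deleted for p in del_span):
        # flanking read bases: anchor and first base after the deletion
        after_q = ref2query.get(pos0 + len(site.ref))
        qs = [int(quals[anchor_q])]
        if after_q is not None:
            qs.append(int(quals[after_q]))
        else:
            qs.append(int(quals[anchor_q]))
        if seq[anchor_q] == site.alt[0]:
            return AlleleObservation("alt", tuple(qs))
        return AlleleObservation("other")
    if all(p in ref2query for p in del_span):
        bases = seq[anchor_q] + "".join(seq[ref2query[p]] for p in del_span)
        if bases == site.ref:
            after_q = ref2query.get(pos0 + len(site.ref))
            qs = (int(quals[anchor_q]),
                  int(quals[after_q]) if after_q is not None else int(quals[ref2query[del_span[-1]]]))
            return AlleleObservation("ref", qs)
        return AlleleObservation("other")
    return AlleleObservation("other")


def _fetch_site_reads(
    readers: Sequence[pysam.AlignmentFile], site: VariantSite, mapq_min: int
) -> Iterable[pysam.AlignedSegment]:
    start = site.pos - 1
    end = site.pos - 1 + len(site.ref)
    for rd in readers:
        try:
            it = rd.fetch(site.chrom, start, end)
        except ValueError as exc:
            raise ValueError(f"cannot fetch {site.chrom}:{site.pos} from {rd.filename!r}: {exc}")
        for read in it:
            if passes_filters(read, mapq_min):
                yield read


def _best_observation(obs: list[AlleleObservation]) -> Optional[AlleleObservation]:
    """Reconcile a fragment's (possibly multiple) observations at one site.

    Concordant duplicates keep the higher-quality one (lower mean error);
    any disagreement or an ``other`` call poisons the fragment (None)."""
    calls = {o.call for o in obs}
    if "other" in calls:
        return "discard"  # type: ignore[return-value]
    calls.discard("not_covered")
    if not calls:
        return None
    if len(calls) > 1:
        return "discard"  # type: ignore[return-value]
    usable = [o for o in obs if o.call != "not_covered"]
    return min(usable, key=lambda o: o.mean_error)


def collect_evidence(
    readers: Sequence[pysam.AlignmentFile],
    v1: VariantSite,
    v2: VariantSite,
    mapq_min: int = 0,
) -> EvidenceSummary:
    """Collect fragment-level cis/trans/neither evidence for a pair.

    Reads from all alignment files are pooled and grouped by query name;
    a fragment contributes iff its reads jointly cover both sites (either
    mate may cover either site, including one mate covering both).  A
    fragment showing the alternate allele at both sites is cis evidence;
    exactly one alternate with the other site reference-matching is trans;
    reference at both is ``neither`` (it still enters n).  Fragments with
    any third-allele observation or intra-fragment disagreement at a site
    are discarded entirely.
    """
    if v1.chrom != v2.chrom:
        raise ValueError("pair must be on one chromosome")
    if v1.pos > v2.pos:
        swapped = collect_evidence(readers, v2, v1, mapq_min)
        return EvidenceSummary(tuple(
            FragmentEvidence(f.kind, f.corrected_v2, f.corrected_v1)
            for f in swapped.fragments
        ))

    per_fragment: dict[str, tuple[list, list]] = {}
    for site_idx, site in enumerate((v1, v2)):
        seen: set[tuple[str, int, bool]] = set()
        for read in _fetch_site_reads(readers, site, mapq_min):
            rid = (read.query_name, read.reference_start, read.is_read2)
            if rid in seen:
                continue
            seen.add(rid)
            obs = observe_allele(read, site)
            per_fragment.setdefault(read.query_name, ([], []))[site_idx].append(obs)

    fragments = []
    for name, (obs1, obs2) in sorted(per_fragment.items()):
        b1 = _best_observation(obs1) if obs1 else None
        b2 = _best_observation(obs2) if obs2 else None
        if b1 == "discard" or b2 == "discard":
            continue
        if b1 is None or b2 is None:
            continue  # fragment does not cover both sites
        kinds = (b1.call, b2.call)
        if kinds == ("alt", "alt"):
            kind = "cis"
        elif "alt" in kinds:  # exactly one alt, the other ref
            kind = "trans"
        else:
            kind = "neither"
        fragments.append(FragmentEvidence(kind, b1.mean_error, b2.mean_error))
    return EvidenceSummary(tuple(fragments))


def variant_found(
    readers: Sequence[pysam.AlignmentFile], v: VariantSite, mapq_min: int = 0
) -> bool:
    """True iff at least one filtered read shows the alternate allele.

    A variant with zero alt-supporting raw reads was most likely called
    through the caller's internal read realignment; it is designated
    "not found" and becomes eligible for the physical-phasing fallback.
    """
    for read in _fetch_site_reads(readers, v, mapq_min):
        if observe_allele(read, v).call == "alt":
            return True
    return False
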