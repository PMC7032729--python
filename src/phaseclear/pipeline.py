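"""Per-patient orchestration: intervals -> evidence -> graph -> results.

For every target interval the child's heterozygous variants are loaded
from the all-variants file, candidate pairs are enumerated (restricted
to the filtered-variants file when one is given — non-candidate variants
still bridge the haplotype graph), read evidence is collected per pair,
parental origins and innocuous labels are derived from the trio
genotypes, caller physical phasing is adopted for variants that are
neither visible in the reads nor trio-phaseable, and each candidate pair
is answered from the resolved phase graph.

The pipeline is fully deterministic: identical inputs give identical
output.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pysam

from phaseclear.datamodel import PairResult, TrioGenotypes, VariantSite, decode_flags
from phaseclear.evidence import collect_evidence, variant_found
from phaseclear.format_io import (
    GenomicInterval,
    PedigreeTrio,
    generate_intervals,
    read_bed,
    read_pedigree,
    read_variants,
)
from phaseclear.hapgraph import (
    PhaseGraph,
    build_graph,
    physical_phase_edge,
    query_pair,
    resolve_conflicts,
)
from phaseclear.readphase import LOW_QUALITY_THRESHOLD, call_direct_phase
from phaseclear.triophase import assign_parental_origin, is_innocuous_pair

log = logging.getLogger(__name__)


@dataclass
class PatientConfig:
    """Inputs and tunables for one patient run."""

    all_variants: str
    filtered_variants: Optional[str] = None
    reads: Sequence[str] = ()
    ped: Optional[str] = None
    patient_id: Optional[str] = None
    intervals_bed: Optional[str] = None
    pad: int = 1000
    mapq_min: int = 0
    threshold: float = LOW_QUALITY_THRESHOLD
    reference: Optional[str] = None  # FASTA, required for CRAM inputs


@dataclass
class SummaryStats:
    """Cohort-style summary over one patient's candidate pairs.

    ``cleared`` pairs are phased or innocuous; ``confidently cleared``
    additionally drops phased calls below the confidence threshold;
    ``non-pathogenic`` pairs are innocuous or confidently cis.  Pairs
    both innocuous and phased count as innocuous only.
    """

    n_pairs: int
    pct_cleared: float
    pct_confidently_cleared: float
    pct_non_pathogenic: float
    counts: dict = field(default_factory=dict)


def _trio_genotypes(v: VariantSite, trio: PedigreeTrio) -> TrioGenotypes:
    return TrioGenotypes(
        child=v.genotype(trio.child_id),
        mother=v.genotype(trio.mother_id) if trio.mother_id else None,
        father=v.genotype(trio.father_id) if trio.father_id else None,
    )


def _resolve_trio(config: PatientConfig, vcf_samples: list[str]) -> PedigreeTrio:
    if config.ped:
        trio = read_pedigree(config.ped, config.patient_id)
    else:
        child = config.patient_id or vcf_samples[0]
        trio = PedigreeTrio(child_id=child)
    if trio.child_id not in vcf_samples:
        raise KeyError(f"child sample {trio.child_id!r} not found in the all-variants VCF")
    # a parent named in the PED but absent from the VCF disables trio logic
    mother = trio.mother_id if trio.mother_id in vcf_samples else None
    father = trio.father_id if trio.father_id in vcf_samples else None
    return PedigreeTrio(trio.child_id, mother, father)


def _phase_interval(
    interval: GenomicInterval,
    config: PatientConfig,
    trio: PedigreeTrio,
    readers: list[pysam.AlignmentFile],
    candidate_keys: Optional[set],
) -> list[PairResult]:
    variants = [
        v for v in read_variants(config.all_variants, [interval])
        if v.is_het_for_alt(trio.child_id)
    ]
    if not variants:
        return []
    trio_enabled = trio.has_mother and trio.has_father

    if candidate_keys is None:
        candidates = list(variants)
    else:
        candidates = [v for v in variants if v.key in candidate_keys]
    if len(candidates) < 2:
        return []

    # which variant alleles are visible in the raw alignments
    found = {v.key: (variant_found(readers, v, config.mapq_min) if readers else False)
             for v in variants}

    trio_origins = []
    trio_phased = set()
    if trio_enabled:
        for v in variants:
            origin = assign_parental_origin(_trio_genotypes(v, trio), v.alt)
            if origin is not None:
                trio_origins.append((v, origin))
                trio_phased.add(v.key)

    # read edges only between variants actually observed in the reads:
    # a variant with no alt-supporting read cannot be read-phased, and
    # its reference-matching fragments must not masquerade as trans
    # evidence — such variants fall through to physical phasing.
    read_edges = []
    if readers:
        for u, w in itertools.combinations(variants, 2):
            if not (found[u.key] and found[w.key]):
                continue
            es = collect_evidence(readers, u, w, config.mapq_min)
            edge = call_direct_phase(es)
            if edge is not None:
                read_edges.append((u, w, edge))

    # caller physical phasing: strictly a fallback for variants that are
    # neither visible in the reads nor pedigree-phased
    def eligible(v: VariantSite) -> bool:
        invisible = not readers or not found[v.key]
        return invisible and v.key not in trio_phased

    physical_edges = []
    for u, w in itertools.combinations(variants, 2):
        if eligible(u) or eligible(w):
            e = physical_phase_edge(u, w)
            if e is not None:
                physical_edges.append((u, w, e))

    graph = resolve_conflicts(
        build_graph(variants, read_edges, trio_origins, physical_edges)
    )

    results = []
    for u, w in itertools.combinations(sorted(candidates, key=lambda v: v.key), 2):
        innocuous = trio_enabled and is_innocuous_pair(
            _trio_genotypes(u, trio), u.alt, _trio_genotypes(w, trio), w.alt
        )
        results.append(query_pair(
            graph, u, w,
            found1=found[u.key] or not readers,
            found2=found[w.key] or not readers,
            innocuous=innocuous,
            threshold=config.threshold,
        ))
    return results


def run_patient(config: PatientConfig) -> tuple[list[PairResult], SummaryStats]:
    """Phase all candidate pairs of one patient and summarize them."""
    with pysam.VariantFile(config.all_variants) as vf:
        vcf_samples = list(vf.header.samples)
    trio = _resolve_trio(config, vcf_samples)

    candidate_keys: Optional[set] = None
    filtered_sites: list[VariantSite] = []
    if config.filtered_variants:
        filtered_sites = [
            v for v in read_variants(config.filtered_variants)
            if trio.child_id not in v.genotypes or v.is_het_for_alt(trio.child_id)
        ]
        candidate_keys = {v.key for v in filtered_sites}

    if config.intervals_bed:
        intervals = read_bed(config.intervals_bed)
    else:
        seed_sites = filtered_sites or [
            v for v in read_variants(config.all_variants)
            if v.is_het_for_alt(trio.child_id)
        ]
        intervals = generate_intervals(seed_sites, pad=config.pad)

    readers = []
    try:
        for path in config.reads:
            readers.append(pysam.AlignmentFile(
                path, reference_filename=config.reference))
        results: list[PairResult] = []
        for interval in intervals:
            log.info("phasing interval %s:%d-%d", interval.chrom,
                     interval.start, interval.end)
            results.extend(
                _phase_interval(interval, config, trio, readers, candidate_keys)
            )
    finally:
        for rd in readers:
            rd.close()

    if not results:
        log.warning("no candidate heterozygous pairs found in any interval")
    return results, summarize(results, config.threshold)


def summarize(
    results: Sequence[PairResult], threshold: float = LOW_QUALITY_THRESHOLD
) -> SummaryStats:
    """Cleared / confidently-cleared / non-pathogenic percentages.

    cleared = phased or innocuous; confidently cleared = innocuous or
    phased with confidence >= threshold; non-pathogenic = innocuous or
    cis with confidence >= threshold.  Percentages are relative to the
    total number of candidate pairs; an empty input gives zeros.
    """
    n = len(results)
    counts = {"innocuous": 0, "cis": 0, "trans": 0, "low_quality": 0,
              "unphased": 0, "not_found": 0}
    cleared = confident = nonpath = 0
    for r in results:
        dec = decode_flags(r.flag)
        phase = dec["phase"]
        phased = phase is not None
        if dec["innocuous"]:
            counts["innocuous"] += 1  # innocuous-and-phased counts as innocuous only
        elif phased:
            counts[phase] += 1
            if r.confidence < threshold:
                counts["low_quality"] += 1
        elif dec["not_found"]:
            counts["not_found"] += 1
        else:
            counts["unphased"] += 1
        if dec["innocuous"] or phased:
            cleared += 1
        if dec["innocuous"] or (phased and r.confidence >= threshold):
            confident += 1
        if dec["innocuous"] or (phase == "cis" and r.confidence >= threshold):
            nonpath += 1
    pct = lambda k: 100.0 * k / n if n else 0.0
    return SummaryStats(
        n_pairs=n,
        pct_cleared=pct(cleared),
        pct_confidently_cleared=pct(confident),
        pct_non_pathogenic=pct(nonpath),
        counts=counts,
    )
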