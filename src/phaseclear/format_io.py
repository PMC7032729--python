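"""Readers and writers for VCF, PED, BED and the pair-result TSV.

Internal interval coordinates are 0-based half-open (BED convention);
VCF positions are converted on ingestion and all user-facing output is
1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

from phaseclear.datamodel import Genotype, PairResult, VariantSite, decode_flags

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval: start 0-based inclusive, end exclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def contains(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass(frozen=True)
class PedigreeTrio:
    """The trio named in a PED file: child plus optional parents.

    Absent parents disable trio operations without being an error; the
    child must have a sample column in the all-variants VCF.
    """

    child_id: str
    mother_id: Optional[str] = None
    father_id: Optional[str] = None

    @property
    def has_mother(self) -> bool:
        return self.mother_id is not None

    @property
    def has_father(self) -> bool:
        return self.father_id is not None

    @property
    def sample_ids(self) -> list[str]:
        return [s for s in (self.child_id, self.mother_id, self.father_id) if s]


def read_pedigree(path: str, child_id: Optional[str] = None) -> PedigreeTrio:
    """Read a 6-column whitespace-delimited PED file and extract the trio.

    Columns: family, individual, father, mother, sex, phenotype; "0"
    marks an absent parent.  If ``child_id`` is given the matching row is
    used, otherwise the first row naming at least one parent (or, failing
    that, the first row).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"PED line has {len(fields)} columns, expected 6: {line!r}")
            rows.append(fields)
    if not rows:
        raise ValueError(f"empty PED file: {path}")
    chosen = None
    if child_id is not None:
        for r in rows:
            if r[1] == child_id:
                chosen = r
                break
        if chosen is None:
            raise ValueError(f"sample {child_id!r} not found in PED {path}")
    else:
        chosen = next((r for r in rows if r[2] != "0" or r[3] != "0"), rows[0])
    father = chosen[2] if chosen[2] != "0" else None
    mother = chosen[3] if chosen[3] != "0" else None
    return PedigreeTrio(child_id=chosen[1], mother_id=mother, father_id=father)


def read_bed(path: str) -> list[GenomicInterval]:
    """Read 3+-column BED intervals (0-based half-open, as on disk)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def _parse_gt_field(
    gt_indices: tuple, alleles: Sequence[str]
) -> Genotype:
    """Map a pysam genotype tuple (allele indices, None for '.') onto
    allele strings; any missing allele makes the whole genotype missing."""
    if gt_indices is None or len(gt_indices) != 2:
        return None
    out = []
    for idx in gt_indices:
        if idx is None or idx < 0 or idx >= len(alleles):
            return None
        out.append(alleles[idx])
    return (out[0], out[1])


def _split_record(
    rec: pysam.VariantRecord, sample_ids: Sequence[str]
) -> Iterable[VariantSite]:
    """Split one VCF record into biallelic VariantSites, one per ALT.

    Genotypes keep allele strings so split records remain comparable;
    symbolic or non-ACGTN alleles are skipped with a warning.  PID/PGT
    caller phase annotations are attached when present for the first
    sample carrying them (the child in practice).
    """
    alleles = rec.alleles
    if alleles is None or len(alleles) < 2:
        return
    ref = alleles[0]
    per_sample: dict[str, Genotype] = {}
    for sid in sample_ids:
        if sid not in rec.samples:
            raise KeyError(f"sample {sid!r} not found in VCF (has {list(rec.samples)})")
        try:
            per_sample[sid] = _parse_gt_field(rec.samples[sid].get("GT"), alleles)
        except Exception:
            log.warning("malformed genotype at %s:%s sample %s; treated as missing",
                        rec.chrom, rec.pos, sid)
            per_sample[sid] = None

    for alt in alleles[1:]:
        if alt is None or set(alt) - set("ACGTN") or alt == ref:
            log.warning("skipping non-sequence ALT %r at %s:%s", alt, rec.chrom, rec.pos)
            continue
        pid = pgt = None
        for sid in sample_ids:
            fmt = rec.samples[sid]
            if "PID" in fmt and fmt.get("PID") is not None:
                raw_pid = fmt.get("PID")
                raw_pgt = fmt.get("PGT")
                pid = raw_pid if isinstance(raw_pid, str) else "".join(raw_pid)
                if raw_pgt is not None:
                    pgt = raw_pgt if isinstance(raw_pgt, str) else "".join(raw_pgt)
                break
        try:
            yield VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=ref,
                alt=alt,
                genotypes=per_sample,
                phase_set_id=pid,
                phase_set_gt=pgt,
            )
        except ValueError as exc:
            log.warning("skipping record at %s:%s: %s", rec.chrom, rec.pos, exc)


def read_variants(
    vcf_path: str,
    intervals: Optional[Sequence[GenomicInterval]] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> list[VariantSite]:
    """Read normalized biallelic VariantSites overlapping ``intervals``.

    Multi-allelic records are split, one site per ALT.  When the VCF is
    tabix-indexed the intervals are fetched randomly; otherwise the file
    is scanned in full and filtered.  ``sample_ids=None`` keeps every
    sample column.
    """
    out: list[VariantSite] = []
    with pysam.VariantFile(vcf_path) as vcf:
        sids = list(sample_ids) if sample_ids else list(vcf.header.samples)
        for sid in sids:
            if sid not in vcf.header.samples:
                raise KeyError(f"sample {sid!r} not found in VCF header of {vcf_path}")
        if intervals:
            try:
                seen = set()
                for iv in intervals:
                    for rec in vcf.fetch(iv.chrom, iv.start, iv.end):
                        if (rec.chrom, rec.pos, rec.alleles) in seen:
                            continue
                        seen.add((rec.chrom, rec.pos, rec.alleles))
                        out.extend(_split_record(rec, sids))
                return sorted(out, key=lambda v: v.key)
            except ValueError:
                vcf.reset()
            # no index: full scan below
            ivs = sorted(intervals, key=lambda i: (i.chrom, i.start))
            for rec in vcf:
                if any(iv.chrom == rec.chrom and iv.start < rec.pos <= iv.end for iv in ivs):
                    out.extend(_split_record(rec, sids))
        else:
            for rec in vcf:
                out.extend(_split_record(rec, sids))
    return sorted(out, key=lambda v: v.key)


def generate_intervals(
    filtered_variants: Sequence[VariantSite], pad: int = 1000
) -> list[GenomicInterval]:
    """Auto-generate target intervals enveloping candidate variant pairs.

    Per chromosome, candidate variants are clustered into maximal runs
    whose padded envelopes ``[pos-1-pad, pos+|ref|-1+pad)`` overlap; each
    cluster yields one merged interval, clipped at 0 on the left.  The
    result is sorted and pairwise disjoint.
    """
    if not filtered_variants:
        return []
    by_chrom: dict[str, list[VariantSite]] = {}
    for v in sorted(filtered_variants, key=lambda v: v.key):
        by_chrom.setdefault(v.chrom, []).append(v)
    out = []
    for chrom in sorted(by_chrom):
        cur_start = cur_end = None
        for v in by_chrom[chrom]:
            s = max(0, v.pos - 1 - pad)
            e = v.pos + len(v.ref) - 1 + pad
            if cur_end is None:
                cur_start, cur_end = s, e
            elif s <= cur_end:
                cur_end = max(cur_end, e)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = s, e
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


RESULT_COLUMNS = [
    "chrom", "var1", "var2", "flag", "phase", "innocuous", "confidence", "source",
]


def write_pair_results(results: Sequence[PairResult], path: str) -> None:
    """Write pair results as a header-bearing TSV, one row per pair.

    Variants print as ``pos:ref>alt`` (1-based); the phase column decodes
    the bitflag; confidence has 6 decimal places; rows are sorted by
    (chrom, pos1, pos2).
    """
    rows = sorted(results, key=lambda r: (r.v1.chrom, r.v1.pos, r.v2.pos))
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            dec = decode_flags(r.flag)
            phase = dec["phase"] or ("not_found" if dec["not_found"] else "unphased")
            fh.write(
                f"{r.v1.chrom}\t{r.v1}\t{r.v2}\t{r.flag}\t{phase}\t"
                f"{'yes' if dec['innocuous'] else 'no'}\t{r.confidence:.6f}\t{r.source}\n"
            )


def read_pair_results(path: str) -> list[dict]:
    """Parse a TSV written by :func:`write_pair_results` (round-trip aid)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = dict(zip(header, line.rstrip("\n").split("\t")))
            fields["flag"] = int(fields["flag"])
            fields["confidence"] = float(fields["confidence"])
            out.append(fields)
    return out
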