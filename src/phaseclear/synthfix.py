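"""Deterministic synthetic trio fixtures with known phase truth.

Generates a small reference chromosome, two child haplotypes with
planted variant pairs in known cis/trans configuration, parental
genotypes chosen per scenario, paired-end reads tiled over both
haplotypes, and a machine-readable truth table — emitted as plain
FASTA + VCF + PED + SAM so every byte is reproducible from the seed.

Scenario types (one candidate pair each):

* ``cis`` / ``trans``: both variants pedigree-informative (exactly one
  parent carries each alternate) and close enough for read evidence.
* ``innocuous-hom-parent``: one parent homozygous for an alternate.
* ``innocuous-all-het``: child, mother and father share the same
  heterozygous genotype at one site.
* ``de-novo``: one alternate absent from both parents, with the
  inherited allele heterozygous in one parent and homozygous in the
  other (the probabilistic 0.66 origin rule), written as a
  multi-allelic record so splitting is exercised.
* ``not-found``: one variant carries caller PID/PGT annotations but its
  alternate is never planted in the haplotypes, so only the
  physical-phasing fallback can resolve the pair.
* ``trio-only``: variants separated beyond the fragment span, so only
  pedigree evidence connects them.
* ``read-only``: heterozygous in all three individuals, so pedigree
  phasing is uninformative and reads must decide.

Scenario windows are spaced so that auto-generated intervals (default
1 kb padding) never merge across scenarios.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

SCENARIO_TYPES = (
    "cis",
    "trans",
    "innocuous-hom-parent",
    "innocuous-all-het",
    "de-novo",
    "not-found",
    "trio-only",
    "read-only",
)

CHROM = "chr1"
WINDOW = 4500  # per-scenario span; keeps padded intervals disjoint
MARGIN = 1200
_BASES = "ACGT"

CHILD, MOTHER, FATHER = "child", "mother", "father"


@dataclass(frozen=True)
class TruthPair:
    """Expected outcome for one planted candidate pair."""

    pair_id: str
    scenario: str
    chrom: str
    pos1: int
    alt1: str
    pos2: int
    alt2: str
    expected_phase: Optional[str]  # cis / trans / None
    expected_innocuous: bool
    expected_source: str  # read / trio / physical / any
    min_confidence: float


@dataclass
class FixtureBundle:
    """Paths of one generated fixture plus its truth table."""

    directory: str
    reference_fasta: str
    all_vcf: str
    filtered_vcf: str
    ped: str
    sam: str
    truth_tsv: str
    truth: list[TruthPair] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.truth)


@dataclass
class ScenarioSpec:
    """Study conditions for one fixture: a deeply covered short-read
    trio with near-perfect base qualities, the regime in which
    read-backed phasing of exonic variant pairs operates."""

    n_pairs: int = 24
    pair_types: Sequence[str] = SCENARIO_TYPES
    coverage: int = 30
    read_len: int = 100
    fragment_len: int = 300
    base_q: int = 40
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.pair_types) - set(SCENARIO_TYPES)
        if unknown:
            raise ValueError(f"unknown pair types: {sorted(unknown)}")
        if not self.pair_types:
            raise ValueError("pair_types must not be empty")
        if self.read_len >= self.fragment_len:
            raise ValueError("fragment_len must exceed read_len")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


def _other_base(base: str, shift: int = 1) -> str:
    return _BASES[(_BASES.index(base) + shift) % 4]


@dataclass
class _Var:
    pos: int  # 1-based
    ref: str
    alts: list[str]
    gts: dict[str, str]  # VCF GT strings per sample
    pid: Optional[str] = None
    pgt: Optional[str] = None
    hap1_alt: Optional[str] = None  # allele planted on haplotype 1 (else ref)
    hap2_alt: Optional[str] = None


def _build_scenario(kind: str, idx: int, base: int, ref: str) -> tuple[list[_Var], TruthPair]:
    """Lay out the two candidate variants of one scenario window."""
    pA, pB = base + 1000, base + 1060  # within single-read span
    if kind == "trio-only":
        pA, pB = base + 500, base + 2000  # beyond fragment span, one interval
    rA, rB = ref[pA - 1], ref[pB - 1]
    aA, aB = _other_base(rA), _other_base(rB)
    paternal = {CHILD: "0/1", FATHER: "0/1", MOTHER: "0/0"}
    maternal = {CHILD: "0/1", MOTHER: "0/1", FATHER: "0/0"}
    all_het = {CHILD: "0/1", MOTHER: "0/1", FATHER: "0/1"}

    pid = f"{pA}_{rA}_{aA}"
    if kind == "cis":
        v1 = _Var(pA, rA, [aA], dict(paternal), hap1_alt=aA)
        v2 = _Var(pB, rB, [aB], dict(paternal), hap1_alt=aB)
        truth = ("cis", False, "any", 0.34)
    elif kind == "trans":
        v1 = _Var(pA, rA, [aA], dict(paternal), hap1_alt=aA)
        v2 = _Var(pB, rB, [aB], dict(maternal), hap2_alt=aB)
        truth = ("trans", False, "any", 0.34)
    elif kind == "innocuous-hom-parent":
        v1 = _Var(pA, rA, [aA], {CHILD: "0/1", MOTHER: "1/1", FATHER: "0/0"},
                  hap2_alt=aA)
        v2 = _Var(pB, rB, [aB], dict(paternal), hap1_alt=aB)
        truth = ("trans", True, "any", 0.34)
    elif kind == "innocuous-all-het":
        v1 = _Var(pA, rA, [aA], dict(all_het), hap1_alt=aA)
        v2 = _Var(pB, rB, [aB], dict(paternal), hap1_alt=aB)
        truth = ("cis", True, "read", 0.34)
    elif kind == "de-novo":
        # alt absent from both parents; inherited ref allele het in the
        # mother (via a second alternate) and hom in the father, so the
        # de novo allele is assigned maternal with confidence 0.66
        v1 = _Var(pA, rA, [aA, _other_base(rA, 2)],
                  {CHILD: "0/1", MOTHER: "0/2", FATHER: "0/0"}, hap2_alt=aA)
        v2 = _Var(pB, rB, [aB], dict(maternal), hap2_alt=aB)
        truth = ("cis", False, "any", 0.4356)
    elif kind == "not-found":
        # v1 is in the VCF (caller realignment artifact) but invisible in
        # the reads; the shared phase set rescues the pair as cis
        v1 = _Var(pA, rA, [aA], {CHILD: "0/1", MOTHER: "./.", FATHER: "./."},
                  pid=pid, pgt="0|1")
        v2 = _Var(pB, rB, [aB], {**paternal}, pid=pid, pgt="0|1", hap1_alt=aB)
        truth = ("cis", False, "physical", 1.0)
    elif kind == "trio-only":
        v1 = _Var(pA, rA, [aA], dict(paternal), hap1_alt=aA)
        v2 = _Var(pB, rB, [aB], dict(maternal), hap2_alt=aB)
        truth = ("trans", False, "trio", 1.0)
    elif kind == "read-only":
        v1 = _Var(pA, rA, [aA], dict(all_het), hap1_alt=aA)
        v2 = _Var(pB, rB, [aB], dict(all_het), hap2_alt=aB)
        truth = ("trans", True, "read", 0.34)
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ValueError(kind)

    phase, innoc, source, conf = truth
    tp = TruthPair(f"pair{idx:03d}", kind, CHROM, v1.pos, v1.alts[0],
                   v2.pos, v2.alts[0], phase, innoc, source, conf)
    return [v1, v2], tp


def _apply_haplotypes(ref: str, variants: Sequence[_Var]) -> tuple[str, str]:
    h1, h2 = list(ref), list(ref)
    for v in variants:
        if v.hap1_alt:
            h1[v.pos - 1] = v.hap1_alt
        if v.hap2_alt:
            h2[v.pos - 1] = v.hap2_alt
    return "".join(h1), "".join(h2)


def _write_fasta(path: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def _vcf_header(samples: Sequence[str], ref_len: int) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CHROM},length={ref_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PID,Number=1,Type=String,Description="Physical phasing ID">',
        '##FORMAT=<ID=PGT,Number=1,Type=String,Description="Physical phasing genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    return "\n".join(lines) + "\n"


def _write_vcf(path: str, variants: Sequence[_Var], samples: Sequence[str],
               ref_len: int) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, ref_len))
        for v in sorted(variants, key=lambda x: x.pos):
            has_ps = v.pid is not None
            fmt = "GT:PID:PGT" if has_ps else "GT"
            cols = []
            for s in samples:
                gt = v.gts.get(s, "./.")
                if has_ps:
                    # phase-set annotation travels on the child column
                    if s == CHILD:
                        cols.append(f"{gt}:{v.pid}:{v.pgt}")
                    else:
                        cols.append(f"{gt}:.:.")
                else:
                    cols.append(gt)
            fh.write(f"{CHROM}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t"
                     f"100\tPASS\t.\t{fmt}\t" + "\t".join(cols) + "\n")


def _write_ped(path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"FAM1 {CHILD} {FATHER} {MOTHER} 1 2\n")
        fh.write(f"FAM1 {FATHER} 0 0 1 1\n")
        fh.write(f"FAM1 {MOTHER} 0 0 2 1\n")


def _sam_records(spec: ScenarioSpec, haplotypes: tuple[str, str],
                 rng: np.random.Generator) -> list[tuple[int, str]]:
    """Tile proper paired-end fragments over both haplotypes.

    Fragment starts advance by a fixed step so the target coverage is
    met deterministically; the RNG only injects base substitutions at
    ``error_rate``.
    """
    rl, fl = spec.read_len, spec.fragment_len
    step = max(1, int(4 * rl / spec.coverage))  # per-haplotype coverage ~ c/2
    qual = chr(min(spec.base_q, 93) + 33) * rl
    records: list[tuple[int, str]] = []

    def seq_with_errors(s: str) -> str:
        if spec.error_rate <= 0:
            return s
        out = list(s)
        hits = np.nonzero(rng.random(len(s)) < spec.error_rate)[0]
        for i in hits:
            out[i] = _other_base(out[i], int(rng.integers(1, 4)))
        return "".join(out)

    for h, hap in enumerate(haplotypes, start=1):
        offset = 0 if h == 1 else step // 2
        k = 0
        for start in range(offset, len(hap) - fl, step):
            name = f"frag_h{h}_{k}"
            k += 1
            s1 = seq_with_errors(hap[start:start + rl])
            s2 = seq_with_errors(hap[start + fl - rl:start + fl])
            p1, p2 = start + 1, start + fl - rl + 1  # SAM is 1-based
            records.append((p1, "\t".join(map(str, (
                name, 99, CHROM, p1, 60, f"{rl}M", "=", p2, fl, s1, qual)))))
            records.append((p2, "\t".join(map(str, (
                name, 147, CHROM, p2, 60, f"{rl}M", "=", p1, -fl, s2, qual)))))
    return records


def _write_sam(path: str, records: list[tuple[int, str]], ref_len: int) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{CHROM}\tLN:{ref_len}\n")
        fh.write("@RG\tID:rg1\tSM:child\n")
        for _, line in sorted(records, key=lambda r: r[0]):
            fh.write(line + "\n")


def _write_truth(path: str, truth: Sequence[TruthPair]) -> None:
    cols = ["pair_id", "scenario", "chrom", "pos1", "alt1", "pos2", "alt2",
            "expected_phase", "expected_innocuous", "expected_source",
            "min_confidence"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write("\t".join(map(str, (
                t.pair_id, t.scenario, t.chrom, t.pos1, t.alt1, t.pos2, t.alt2,
                t.expected_phase or "none", int(t.expected_innocuous),
                t.expected_source, t.min_confidence))) + "\n")


def make_truth_scenario(spec: ScenarioSpec, directory: str) -> FixtureBundle:
    """Generate one fixture bundle under ``directory``.

    The same seed yields a byte-identical bundle.  Returns the bundle
    with file paths and the in-memory truth table.
    """
    os.makedirs(directory, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    kinds = [spec.pair_types[i % len(spec.pair_types)] for i in range(spec.n_pairs)]
    ref_len = MARGIN * 2 + WINDOW * len(kinds)
    ref = "".join(rng.choice(list(_BASES), size=ref_len))

    variants: list[_Var] = []
    truth: list[TruthPair] = []
    for i, kind in enumerate(kinds):
        vs, tp = _build_scenario(kind, i, MARGIN + i * WINDOW, ref)
        variants.extend(vs)
        truth.append(tp)

    hap1, hap2 = _apply_haplotypes(ref, variants)

    paths = {name: os.path.join(directory, fn) for name, fn in (
        ("reference_fasta", "ref.fa"), ("all_vcf", "all.vcf"),
        ("filtered_vcf", "filtered.vcf"), ("ped", "trio.ped"),
        ("sam", "reads.sam"), ("truth_tsv", "truth.tsv"))}

    _write_fasta(paths["reference_fasta"], ref)
    samples = (CHILD, MOTHER, FATHER)
    _write_vcf(paths["all_vcf"], variants, samples, ref_len)
    _write_vcf(paths["filtered_vcf"], variants, samples, ref_len)
    _write_ped(paths["ped"])
    _write_sam(paths["sam"], _sam_records(spec, (hap1, hap2), rng), ref_len)
    _write_truth(paths["truth_tsv"], truth)
    return FixtureBundle(directory=directory, truth=truth, **paths)


def sam_to_indexed_bam(sam_path: str, bam_path: Optional[str] = None) -> str:
    """Convert a text SAM into a coordinate-sorted, indexed BAM."""
    bam_path = bam_path or sam_path.rsplit(".", 1)[0] + ".bam"
    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)
    return bam_path
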