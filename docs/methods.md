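# Methods

## Model and procedure

`phaseclear` decides, per candidate pair of heterozygous variants in a
child, whether the two alternate alleles are in cis (same parental
haplotype) or trans (opposite haplotypes), or whether the pair can be
excluded as clinically innocuous. It works interval by interval: target
intervals come from a BED file or are auto-generated as padded envelopes
around the candidate variants, and all heterozygous variants of the child
inside an interval — candidates or not — participate in haplotype
construction, so non-candidate variants can bridge otherwise unlinked
candidates.

### Pedigree phasing

For each heterozygous child variant, all four parental transmission choices
(which of the mother's two alleles, which of the father's) are enumerated;
choices inconsistent with the child genotype are discarded. If every
consistent choice hands the alternate allele to the same parent, the
variant is assigned that parental origin with confidence 1.0. If consistent
choices disagree (e.g. both parents heterozygous), no assignment is made —
pedigree information is fundamentally uninformative there.

A de novo alternate (absent from both parents) cannot be assigned by
transmission. When the inherited allele is present in both parents,
heterozygous in one and homozygous in the other, it is probabilistically
assigned to the homozygous parent and the de novo allele therefore to the
other parent, with confidence 0.66 (stored exactly as the constant 0.66,
not 2/3). Any missing parental genotype disables both branches for that
site.

### Read-backed phasing

Reads are filtered to mapped, primary, non-duplicate alignments that are
proper pairs when paired, with an optional mapping-quality floor (default
0, i.e. the filter is off — it is presented as a user choice). The unit of
evidence is the *fragment*: all reads sharing a query name. Both mates
derive from one physical molecule, hence one haplotype, so a fragment links
two sites whenever its reads jointly cover both — including distant sites
joined only through the mate gap or through an RNA read's splice junction
(positions under an N CIGAR operation are treated as not covered, while
retained positions still testify).

Allele observation walks the CIGAR. For substitutions, the read bases
across the span must equal the alternate or reference allele; qualities of
those l bases are used. For insertions, the alternate is observed when the
inserted bases are present after the anchor base, with the inserted bases'
qualities; for deletions, when the CIGAR deletes exactly the span, with the
two flanking read bases' qualities (the alignment stores no qualities for
deleted bases; the flanking bases are the nearest evidence). Third alleles
or intra-fragment disagreement at a site discard the whole fragment. When
both mates concordantly cover one site, the observation with the lower mean
error probability is kept — one fragment, one observation.

A fragment showing the alternate at both sites is cis evidence; exactly one
alternate with the other site reference-matching is trans; reference at
both sites is "neither" — such fragments carry no orientation information
but still count toward the total n, reflecting how much of the local
coverage actually supports the call. The pair confidence is

    Confidence(v1, v2) = |TransSubscore − CisSubscore| / (n + 2)

with per-fragment weight `1 − (Corrected_v1 + Corrected_v2)/2`, where
`Corrected_v` is the mean of `10^(−q/10)` over the quality list at that
site; `TransSubscore = Σ weights(trans)`;
`CisSubscore = min(2·Σ weights(cis), n)`. The doubling of the cis subscore
and its cap at n are part of the method's definition and are implemented
verbatim. Consequences worth knowing: a single supporting fragment can
never exceed 1/(n+2) ≤ 1/3 < 0.34, so lone-fragment calls are always
low-quality; n perfect trans fragments score exactly n/(n+2); the score is
always in [0, 1). The orientation follows the larger subscore; an exact tie
yields no call (no tie-break is defined, and abstaining is the safe
clinical choice).

The default low-quality threshold is 0.34. It labels calls; it never
suppresses them — low-quality calls are emitted with their score so
downstream filtering stays explicit.

### Haplotype graph

Per interval, heterozygous sites are nodes and pairwise relations are
edges (orientation cis/trans, confidence, source). Parental origins are
encoded through a virtual anchor node standing for the paternal haplotype:
paternal variants attach with a cis edge, maternal with trans, so any two
same-origin variants resolve cis through the anchor and opposite-origin
variants trans; this also lets pedigree-phased variants bridge disjoint
read-phased blocks. Conflicting parallel edges are resolved by confidence
(an exact tie drops the pair); same-orientation duplicates collapse to the
maximum. Queries prefer a direct edge; otherwise the path with the fewest
edges (ties broken by the larger confidence product) gives orientation by
trans-edge parity and confidence by the product of edge confidences — the
product decays with chain length, representing the growing uncertainty of
long haplotype extensions.

### Not-found variants and caller physical phasing

A variant with zero alternate-supporting reads in the raw alignments was
most likely called through the variant caller's internal realignment; it is
designated *not found*. Read edges are never built to a not-found variant:
its reference-matching fragments would otherwise masquerade as trans
evidence against every neighbour, which is exactly the failure mode the
fallback exists for. Instead, if the variant is also not pedigree-phased
and shares a caller phase set (FORMAT PID, with ordered PGT genotypes, the
GATK HaplotypeCaller dialect) with a neighbour, the caller's local phase is
adopted with confidence 1.0. Physical edges are added strictly under this
fallback condition and never override read or trio evidence. When no
alignment files are supplied at all, nothing can be "not found" (the flag
bit is never set) and physical-phasing eligibility reduces to "not
pedigree-phased".

### Innocuous labeling

Assuming healthy parents, a pair is innocuous when (a) a parent is
homozygous for the alternate allele at either site, or (b) child, mother
and father all share the same heterozygous genotype at a site. "Homozygous
in a parent" is read as homozygous for the *alternate*: a homozygous-
reference parent says nothing against compound heterozygosity, and
clinically filtered variants are rare, so the alternate reading is the
informative one. Unphased genotype identity is used for condition (b).
Innocuous labeling and phasing are computed independently; both appear in
the output flag, and summary counting attributes doubly-labeled pairs to
the innocuous category only.

### Output

One row per candidate pair: bitflag (1 cis, 2 trans, 4 innocuous, 8 not
found, 16 physically adopted — the specific bit values are this package's
own encoding of the category taxonomy), decoded labels, confidence to six
decimals, and evidence source. Summary percentages: *cleared* = phased or
innocuous; *confidently cleared* = innocuous or phased at/above threshold;
*non-pathogenic* = innocuous or confidently cis. These nest:
non-pathogenic ⊆ confidently cleared ⊆ cleared.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pad` | 1000 bp | envelope padding for auto-generated intervals; spans typical short-read fragment lengths so read-linkable neighbours fall in one interval |
| `mapq_min` | 0 | mapping-quality floor for reads (0 = filter off) |
| `threshold` | 0.34 | confidence below which a phased call is labeled low-quality |
| de novo confidence | 0.66 | fixed by the method |
| trio / physical confidence | 1.0 | fixed by the method |

## Synthetic fixtures

`phaseclear.synthfix` generates the study conditions used by the test
suite and the acceptance script: a single-chromosome reference (~110 kb for
24 scenarios), a fully genotyped trio, and deterministic tiled paired-end
reads (default 30× total coverage, 100 bp reads, 300 bp fragments, Phred
40 base quality, substitution error rate 0 — the error-free deep-WES-like
regime in which combined read and pedigree phasing is expected to clear
every pair). Eight scenario types plant, respectively: read+pedigree cis
and trans pairs, both innocuous constellations, a de novo pair (written as
a multi-allelic record so record splitting is exercised), a caller-rescue
pair whose first variant exists only in the VCF (with shared PID/PGT), a
pedigree-only pair separated beyond the fragment span, and a read-only pair
heterozygous in all three individuals. Reads are written as plain SAM with
simple match CIGARs; spliced and indel CIGAR behaviour is exercised by
hand-built alignments in the unit tests instead of by the generator.

What the generator does **not** emulate: exome capture bias, indel/splice
variation in the planted variants, coverage gaps, genotyping errors,
reference bias, multi-gene interval structure. Passing on these fixtures
therefore demonstrates the correctness of the decision logic and score
arithmetic under clean conditions, not robustness to real-data artifacts
such as missing parental genotypes (whose effect — unresolvable pairs — is
handled but not stress-tested at scale).

## Numerical and degenerate-input choices

* Exact subscore ties and equal-confidence orientation conflicts abstain.
* Confidence arithmetic is plain float; the oracle agreement tolerance in
  the tests is 1e−12.
* Multi-allelic records are split into biallelic sites at load time;
  genotypes keep allele strings so split records stay comparable and a
  child heterozygous for two alternates is handled per-alternate.
* A variant record with a missing or malformed genotype is kept with that
  genotype marked missing (warning logged); missing parental genotypes
  disable pedigree phasing and innocuous matching at that site only.
* Shortest path = fewest edges, then maximal confidence product; this is
  deterministic and never reports a higher-confidence long detour in place
  of a short low-confidence chain, except that a direct edge always wins.
* Reads without stored base qualities are assigned Phred 30 (neutral).

## Problem sizes

The bundled fixtures use 24 scenario windows (~110 kb reference, ~1,600
read pairs); a full test-suite run and the acceptance script each complete
in seconds. These sizes were chosen as the smallest at which every scenario
type appears several times with stable read support.

## Known limitations

* Trio-only pedigrees: no siblings, grandparents or X-special-casing.
* No read realignment: the alignments are taken as given, which is exactly
  why the not-found/physical-phasing fallback exists.
* Structural variants and polyploid genotypes are out of scope.
* The 0.34 threshold is adopted as a constant (configurable), not
  re-derived.
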