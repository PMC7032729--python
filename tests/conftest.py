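import pysam
import pytest

from phaseclear.datamodel import VariantSite
from phaseclear.synthfix import ScenarioSpec, make_truth_scenario, sam_to_indexed_bam

SAM_HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1_000_000}]}
)


def make_read(
    seq,
    start,
    cigar=None,
    quals=None,
    name="r1",
    flag=0,
    mapq=60,
):
    """Hand-build one alignment record (0-based start)."""
    a = pysam.AlignedSegment(SAM_HEADER)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{len(seq)}M"
    a.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in (quals or [40] * len(seq)))
    )
    return a


def make_site(pos, ref="A", alt="G", chrom="chr1", **kw):
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def write_bam(tmp_path, reads, name="mini"):
    """Write hand-built reads to a sorted, indexed BAM; returns its path."""
    sam = str(tmp_path / f"{name}.sam")
    with pysam.AlignmentFile(sam, "w", header=SAM_HEADER) as out:
        for r in reads:
            out.write(r)
    return sam_to_indexed_bam(sam)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One error-free full-trio fixture shared across tests."""
    d = tmp_path_factory.mktemp("fixture")
    b = make_truth_scenario(ScenarioSpec(seed=7), str(d))
    b.bam = sam_to_indexed_bam(b.sam)
    return b
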