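import math

import pysam
import pytest

from conftest import make_read, make_site, write_bam
from phaseclear.evidence import (
    collect_evidence,
    observe_allele,
    passes_filters,
    variant_found,
)

# 0-based reference offset used by most hand-built reads
START = 1000


class TestReadFilters:
    def test_clean_single_end_read_passes(self):
        assert passes_filters(make_read("ACGT", START), mapq_min=20)

    @pytest.mark.parametrize(
        "flag",
        [4, 1024, 256, 2048, 1],  # unmapped, duplicate, secondary, suppl, pair-not-proper
    )
    def test_rejected_flags(self, flag):
        assert not passes_filters(make_read("ACGT", START, flag=flag))

    def test_proper_pair_passes(self):
        assert passes_filters(make_read("ACGT", START, flag=99))

    def test_mapq_threshold(self):
        read = make_read("ACGT", START, mapq=10)
        assert not passes_filters(read, mapq_min=20)
        assert passes_filters(read, mapq_min=0)


class TestObserveAllele:
    # reference around the site is irrelevant for SNVs: only read bases count
    def test_snv_alt(self):
        site = make_site(START + 3, "A", "G")  # 1-based: covers 0-based START+2
        read = make_read("CCGCC", START, quals=[20, 20, 37, 20, 20])
        obs = observe_allele(read, site)
        assert (obs.call, obs.qualities) == ("alt", (37,))

    def test_snv_ref_and_other(self):
        site = make_site(START + 3, "A", "G")
        assert observe_allele(make_read("CCACC", START), site).call == "ref"
        assert observe_allele(make_read("CCTCC", START), site).call == "other"

    def test_spliced_over_site_is_not_covered(self):
        site = make_site(START + 11, "A", "G")
        # 10M100N10M: the N gap spans the site
        read = make_read("C" * 20, START, cigar="10M100N10M")
        assert observe_allele(read, site).call == "not_covered"

    def test_spliced_read_keeps_retained_positions(self):
        site = make_site(START + 111, "A", "G")  # inside the second exon block
        seq = "C" * 10 + "G" + "C" * 9
        read = make_read(seq, START, cigar="10M100N10M")
        assert observe_allele(read, site).call == "alt"

    def test_site_outside_read(self):
        site = make_site(START + 500, "A", "G")
        assert observe_allele(make_read("CCCC", START), site).call == "not_covered"

    def test_insertion_alt_uses_inserted_base_qualities(self):
        site = make_site(START + 3, "A", "AGT")
        # read: 3 matched, insertion GT, 2 matched; anchor base A at site
        seq = "CCA" + "GT" + "CC"
        read = make_read(seq, START, cigar="3M2I2M",
                         quals=[20, 20, 25, 30, 32, 20, 20])
        obs = observe_allele(read, site)
        assert (obs.call, obs.qualities) == ("alt", (30, 32))

    def test_insertion_ref(self):
        site = make_site(START + 3, "A", "AGT")
        read = make_read("CCACC", START)
        assert observe_allele(read, site).call == "ref"

    def test_deletion_alt_uses_flanking_qualities(self):
        site = make_site(START + 3, "ATT", "A")
        # read matches 3, deletes TT, matches 2; flanks at read idx 2 and 3
        read = make_read("CCACC", START, cigar="3M2D2M",
                         quals=[20, 20, 31, 33, 20])
        obs = observe_allele(read, site)
        assert (obs.call, obs.qualities) == ("alt", (31, 33))

    def test_deletion_ref(self):
        site = make_site(START + 3, "ATT", "A")
        read = make_read("CCATTCC", START)
        assert observe_allele(read, site).call == "ref"

    def test_mnv_spans_multiple_bases(self):
        site = make_site(START + 2, "AT", "GC")
        obs = observe_allele(make_read("CGCC", START, quals=[20, 30, 31, 20]), site)
        assert (obs.call, obs.qualities) == ("alt", (30, 31))


def _pair_sites():
    return make_site(START + 1, "A", "G"), make_site(START + 61, "C", "T")


def _covering_read(name, b1, b2, q=40, flag=0):
    seq = b1 + "A" * 59 + b2 + "A" * 10
    return make_read(seq, START, name=name, flag=flag, quals=[q] * len(seq))


class TestCollectEvidence:
    def test_single_cis_fragment(self, tmp_path):
        v1, v2 = _pair_sites()
        bam = write_bam(tmp_path, [_covering_read("f1", "G", "T", q=40)])
        with pysam.AlignmentFile(bam) as rd:
            es = collect_evidence([rd], v1, v2)
        assert (es.n, es.n_cis, es.n_trans) == (1, 1, 0)
        frag = es.fragments[0]
        assert frag.corrected_v1 == pytest.approx(1e-4, rel=1e-12)
        assert frag.corrected_v2 == pytest.approx(1e-4, rel=1e-12)

    def test_two_trans_fragments(self, tmp_path):
        v1, v2 = _pair_sites()
        reads = [_covering_read("f1", "G", "C"), _covering_read("f2", "A", "T")]
        bam = write_bam(tmp_path, reads)
        with pysam.AlignmentFile(bam) as rd:
            es = collect_evidence([rd], v1, v2)
        assert (es.n, es.n_cis, es.n_trans) == (2, 0, 2)

    def test_ref_ref_fragment_counts_in_n_only(self, tmp_path):
        v1, v2 = _pair_sites()
        bam = write_bam(tmp_path, [_covering_read("f1", "A", "C")])
        with pysam.AlignmentFile(bam) as rd:
            es = collect_evidence([rd], v1, v2)
        assert (es.n, es.n_cis, es.n_trans) == (1, 0, 0)

    def test_intra_fragment_disagreement_discards_fragment(self, tmp_path):
        v1, v2 = _pair_sites()
        # two mates of one fragment disagree at v1: alt vs ref
        reads = [
            _covering_read("f1", "G", "T", flag=99),
            _covering_read("f1", "A", "T", flag=147),
            _covering_read("f2", "G", "T", flag=99),
            _covering_read("f2", "G", "T", flag=147),
        ]
        bam = write_bam(tmp_path, reads)
        with pysam.AlignmentFile(bam) as rd:
            es = collect_evidence([rd], v1, v2)
        assert es.n == 1  # f1 discarded entirely, f2 counted once

    def test_mates_covering_one_site_each(self, tmp_path):
        """Paired-end evidence: disjoint mates still form one fragment."""
        v1, v2 = _pair_sites()
        m1 = make_read("G" + "A" * 19, START, name="f1", flag=99)
        m2 = make_read("C" + "A" * 19, START + 60, name="f1", flag=147)
        bam = write_bam(tmp_path, [m1, m2])
        with pysam.AlignmentFile(bam) as rd:
            es = collect_evidence([rd], v1, v2)
        assert (es.n, es.n_trans) == (1, 1)

    def test_swap_symmetry(self, tmp_path):
        v1, v2 = _pair_sites()
        reads = [_covering_read("f1", "G", "T", q=30),
                 _covering_read("f2", "A", "T", q=20)]
        bam = write_bam(tmp_path, reads)
        with pysam.AlignmentFile(bam) as rd:
            fwd = collect_evidence([rd], v1, v2)
            rev = collect_evidence([rd], v2, v1)
        assert fwd.n == rev.n and fwd.n_cis == rev.n_cis and fwd.n_trans == rev.n_trans
        assert [f.corrected_v1 for f in fwd.fragments] == [
            f.corrected_v2 for f in rev.fragments]


class TestVariantFound:
    def test_found_with_alt_reads(self, tmp_path):
        v1, _ = _pair_sites()
        bam = write_bam(tmp_path, [_covering_read(f"f{i}", "G" if i < 4 else "A", "C")
                                   for i in range(10)])
        with pysam.AlignmentFile(bam) as rd:
            assert variant_found([rd], v1)

    def test_ref_only_coverage_is_not_found(self, tmp_path):
        v1, _ = _pair_sites()
        bam = write_bam(tmp_path, [_covering_read(f"f{i}", "A", "C")
                                   for i in range(10)])
        with pysam.AlignmentFile(bam) as rd:
            assert not variant_found([rd], v1)
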