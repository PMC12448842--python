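"""Read tagging against constructed alignments and simulated BAMs."""

import pysam
import pytest

from nanofilter.fragments import TaggingConfig, extract_fragment_matrix, tag_read_at_site
from nanofilter.io import VariantSite, read_vcf
from nanofilter.simulate import SimConfig, emit_fixtures, simulate

from conftest import matrix_calls

HEADER = pysam.AlignmentHeader.from_references(["chr1"], [100_000])


def make_alignment(pos0, cigar, seq, baseq=30, mapq=60, flag=0, name="read1"):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos0
    a.mapping_quality = mapq
    a.cigarstring = cigar
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(chr(33 + baseq) * len(seq))
    return a


def snv(pos, ref="A", alt="G", idx=1):
    return VariantSite("chr1", pos, ref, alt, "SNV", "het", 50.0, idx)


CFG = TaggingConfig()


class TestTagSnv:
    # site at 1-based pos 101; reads aligned from 0-based 90
    def test_alt_base_tags_one(self):
        aln = make_alignment(90, "21M", "T" * 10 + "G" + "T" * 10)
        assert tag_read_at_site(aln, snv(101), CFG)[0] == 1

    def test_ref_base_tags_zero(self):
        aln = make_alignment(90, "21M", "T" * 10 + "A" + "T" * 10)
        assert tag_read_at_site(aln, snv(101), CFG)[0] == 0

    def test_third_allele_is_no_call(self):
        aln = make_alignment(90, "21M", "T" * 10 + "C" + "T" * 10)
        assert tag_read_at_site(aln, snv(101), CFG) is None

    def test_low_base_quality_is_no_call(self):
        aln = make_alignment(90, "21M", "T" * 10 + "G" + "T" * 10, baseq=5)
        assert tag_read_at_site(aln, snv(101), CFG) is None

    def test_site_inside_read_deletion_is_no_call(self):
        # deletion spans ref 95..104, removing the site base
        aln = make_alignment(90, "5M10D6M", "T" * 11)
        assert tag_read_at_site(aln, snv(101), CFG) is None


class TestTagIndel:
    # 2-bp deletion: ref ATT -> A at 1-based pos 101 (0-based 100..102)
    DEL = VariantSite("chr1", 101, "ATT", "A", "INDEL", "het", 50.0, 1)
    # 2-bp insertion: A -> ACC at pos 101
    INS = VariantSite("chr1", 101, "A", "ACC", "INDEL", "het", 50.0, 1)

    def test_matching_deletion_tags_one(self):
        # 10M: ref 90..100 (incl. anchor A at 100), 2D: 101..103, 10M after
        aln = make_alignment(90, "11M2D10M", "T" * 10 + "A" + "T" * 10)
        assert tag_read_at_site(aln, self.DEL, CFG)[0] == 1

    def test_reference_path_tags_zero(self):
        aln = make_alignment(90, "23M", "T" * 10 + "ATT" + "T" * 10)
        assert tag_read_at_site(aln, self.DEL, CFG)[0] == 0

    def test_other_deletion_length_is_no_call(self):
        aln = make_alignment(90, "11M1D10M", "T" * 10 + "A" + "T" * 10)
        assert tag_read_at_site(aln, self.DEL, CFG) is None

    def test_matching_insertion_tags_one(self):
        aln = make_alignment(90, "11M2I10M", "T" * 10 + "ACC" + "T" * 10)
        assert tag_read_at_site(aln, self.INS, CFG)[0] == 1

    def test_wrong_inserted_bases_no_call(self):
        aln = make_alignment(90, "11M2I10M", "T" * 10 + "AGG" + "T" * 10)
        assert tag_read_at_site(aln, self.INS, CFG) is None

    def test_insufficient_flank_is_no_call(self):
        # alignment ends 3 bp past the locus end: < require_full_span_bp
        aln = make_alignment(90, "11M2D3M", "T" * 10 + "A" + "T" * 3)
        assert tag_read_at_site(aln, self.DEL, CFG) is None


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    sim = simulate(SimConfig(
        n_true_sites=50, n_fp_sites=10, region_length=25_000,
        coverage=12, read_length_mean=4_000, allele_error_rate=0.0, seed=5,
    ))
    out = tmp_path_factory.mktemp("fixtures")
    paths = emit_fixtures(sim, out)
    return sim, paths


class TestExtraction:
    def test_error_free_extraction_matches_simulated_matrix(self, fixture_dir):
        sim, paths = fixture_dir
        sites = read_vcf(paths["vcf"])
        m = extract_fragment_matrix(paths["bam"], sites)
        assert matrix_calls(m) == matrix_calls(sim.matrix)

    def test_stricter_thresholds_never_add_calls(self, fixture_dir):
        sim, paths = fixture_dir
        sites = read_vcf(paths["vcf"])
        loose = matrix_calls(extract_fragment_matrix(paths["bam"], sites, TaggingConfig(min_mapq=0, min_baseq=0)))
        strict = matrix_calls(extract_fragment_matrix(paths["bam"], sites, TaggingConfig(min_mapq=30, min_baseq=30)))
        for read_id, calls in strict.items():
            assert calls.items() <= loose[read_id].items()

    def test_high_mapq_threshold_drops_everything(self, fixture_dir):
        sim, paths = fixture_dir
        sites = read_vcf(paths["vcf"])
        m = extract_fragment_matrix(paths["bam"], sites, TaggingConfig(min_mapq=61))
        assert m.n_fragments == 0

    def test_missing_index_errors(self, fixture_dir, tmp_path):
        sim, paths = fixture_dir
        sites = read_vcf(paths["vcf"])
        unindexed = tmp_path / "noindex.bam"
        unindexed.write_bytes(paths["bam"].read_bytes())
        with pytest.raises(FileNotFoundError, match="index"):
            extract_fragment_matrix(unindexed, sites)

    def test_contig_mismatch_errors(self, fixture_dir):
        sim, paths = fixture_dir
        bad = [VariantSite("chrX", 100, "A", "G", "SNV", "het", 50.0, 1)]
        with pytest.raises(ValueError, match="chrX"):
            extract_fragment_matrix(paths["bam"], bad)

    def test_deterministic(self, fixture_dir):
        sim, paths = fixture_dir
        sites = read_vcf(paths["vcf"])
        m1 = extract_fragment_matrix(paths["bam"], sites)
        m2 = extract_fragment_matrix(paths["bam"], sites)
        assert [f.calls for f in m1.fragments] == [f.calls for f in m2.fragments]
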