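"""Read tagging: from BAM + VCF to a fragment matrix.

For every primary alignment and every het biallelic site it overlaps,
decide whether the read carries the REF allele (0), the ALT allele (1),
or makes no usable call (None). SNVs are tagged from the aligned base at
the site; INDELs from the CIGAR-implied sequence over the REF span of the
locus (plus any inserted bases at its junctions), compared exactly against
the REF and ALT allele paths. Any ambiguity — third allele, partial
overlap, low base quality, insufficient flanking alignment around an
INDEL — yields no call rather than a guess.

All arithmetic here is 0-based half-open; conversion from VCF's 1-based
positions happens on entry.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .io import (
    FragmentMatrix,
    ReadFragment,
    VariantSite,
    build_fragment_matrix,
)

DEFAULT_SKIP_FLAGS = frozenset({"secondary", "supplementary", "duplicate", "qcfail"})


@dataclass(frozen=True)
class TaggingConfig:
    """Alignment- and base-level thresholds for tagging.

    require_full_span_bp: an alignment must extend at least this many
    reference bases past both ends of an INDEL locus for the read to be
    tagged there — a read ending inside or just at an indel cannot
    distinguish the allele paths.
    """

    min_mapq: int = 20
    min_baseq: int = 7
    skip_flags: frozenset[str] = DEFAULT_SKIP_FLAGS
    require_full_span_bp: int = 5

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.require_full_span_bp < 1:
            raise ValueError("require_full_span_bp must be >= 1")


def _skip_alignment(aln: pysam.AlignedSegment, config: TaggingConfig) -> bool:
    if aln.is_unmapped or aln.mapping_quality < config.min_mapq:
        return True
    flags = config.skip_flags
    return (
        ("secondary" in flags and aln.is_secondary)
        or ("supplementary" in flags and aln.is_supplementary)
        or ("duplicate" in flags and aln.is_duplicate)
        or ("qcfail" in flags and aln.is_qcfail)
    )


class _AlignmentView:
    """Pre-digested aligned-pair maps for one alignment.

    ref2query maps each aligned reference position to its query position;
    insertions maps a reference junction (the aligned position *before*
    the inserted bases) to the (query start, length) of the insertion.
    """

    __slots__ = ("seq", "quals", "ref2query", "insertions", "ref_start", "ref_end")

    def __init__(self, aln: pysam.AlignedSegment) -> None:
        self.seq = aln.query_sequence or ""
        self.quals = aln.query_qualities
        self.ref_start = aln.reference_start
        self.ref_end = aln.reference_end
        self.ref2query: dict[int, int] = {}
        self.insertions: dict[int, tuple[int, int]] = {}
        last_ref: Optional[int] = None
        for qpos, rpos in aln.get_aligned_pairs():
            if qpos is not None and rpos is not None:
                self.ref2query[rpos] = qpos
                last_ref = rpos
            elif qpos is not None:  # insertion relative to reference
                if last_ref is not None:
                    start, length = self.insertions.get(last_ref, (qpos, 0))
                    self.insertions[last_ref] = (start, length + 1)
            else:  # deletion: rpos aligned to gap
                last_ref = rpos


def tag_read_at_site(
    aln: pysam.AlignedSegment,
    site: VariantSite,
    config: TaggingConfig,
    view: Optional[_AlignmentView] = None,
) -> Optional[tuple[int, str]]:
    """Tag one alignment at one het biallelic site.

    Returns (allele, qual_char) with allele in {0, 1}, or None for no call.
    The qual char is the Phred+33 encoding of the supporting base quality
    (the minimum over involved bases for INDELs).
    """
    if view is None:
        view = _AlignmentView(aln)
    pos0 = site.pos - 1
    if site.vtype == "SNV":
        qpos = view.ref2query.get(pos0)
        if qpos is None:
            return None
        baseq = view.quals[qpos] if view.quals is not None else 60
        if baseq < config.min_baseq:
            return None
        base = view.seq[qpos].upper()
        if base == site.ref.upper():
            return 0, chr(33 + min(baseq, 93))
        if base == site.alt.upper():
            return 1, chr(33 + min(baseq, 93))
        return None

    # INDEL: require the alignment to reach past both ends of the locus
    span = config.require_full_span_bp
    locus_end = site.end  # 0-based exclusive end of REF span
    if view.ref_start > pos0 - span or view.ref_end < locus_end + span:
        return None

    observed = []
    qual_min = 93
    for rpos in range(pos0, locus_end):
        qpos = view.ref2query.get(rpos)
        if qpos is not None:
            observed.append(view.seq[qpos].upper())
            if view.quals is not None:
                qual_min = min(qual_min, view.quals[qpos])
        ins = view.insertions.get(rpos)
        if ins is not None:
            qstart, length = ins
            observed.append(view.seq[qstart : qstart + length].upper())
            if view.quals is not None:
                qual_min = min(qual_min, *view.quals[qstart : qstart + length])
    observed_seq = "".join(observed)
    if view.quals is not None and qual_min < config.min_baseq:
        return None
    qual_char = chr(33 + min(qual_min, 93))
    if observed_seq == site.ref.upper():
        return 0, qual_char
    if observed_seq == site.alt.upper():
        return 1, qual_char
    return None


def extract_fragment_matrix(
    bam_path: str | Path,
    sites: Sequence[VariantSite],
    config: TaggingConfig = TaggingConfig(),
) -> FragmentMatrix:
    """Tag every primary alignment at the het biallelic sites it overlaps.

    Requires a coordinate-sorted, indexed BAM. Raises ``FileNotFoundError``
    if the index is missing and ``ValueError`` if the VCF names contigs the
    BAM does not carry. Output is deterministic for identical inputs: one
    ReadFragment per alignment with at least one tagged site, in BAM order.
    """
    bam_path = str(bam_path)
    scorable = [s for s in sites if s.scorable]
    fragments: list[ReadFragment] = []
    with pysam.AlignmentFile(bam_path) as bam:
        if not bam.has_index():
            raise FileNotFoundError(f"{bam_path}: BAM index required (run samtools index)")
        vcf_chroms = {s.chrom for s in scorable}
        missing = sorted(vcf_chroms - set(bam.references))
        if missing:
            raise ValueError(
                f"contigs in VCF but not in BAM: {', '.join(missing)}"
            )
        by_chrom: dict[str, list[VariantSite]] = defaultdict(list)
        for s in scorable:
            by_chrom[s.chrom].append(s)
        for chrom in (c for c in bam.references if c in by_chrom):
            chrom_sites = by_chrom[chrom]
            starts = [s.pos - 1 for s in chrom_sites]
            max_ref = max(len(s.ref) for s in chrom_sites)
            for aln in bam.fetch(chrom):
                if _skip_alignment(aln, config):
                    continue
                # candidate window by start position; tag() rejects non-overlaps
                lo = bisect_left(starts, aln.reference_start - max_ref)
                hi = bisect_left(starts, aln.reference_end)
                if lo >= hi:
                    continue
                view = _AlignmentView(aln)
                calls: list[tuple[int, int, str]] = []
                for s in chrom_sites[lo:hi]:
                    tag = tag_read_at_site(aln, s, config, view)
                    if tag is not None:
                        calls.append((s.vcf_index, tag[0], tag[1]))
                if calls:
                    fragments.append(ReadFragment(aln.query_name, tuple(calls)))
    return build_fragment_matrix(sites, fragments)
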