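"""VCF and HapCUT2 fragment-format I/O.

This module owns the boundary between the on-disk formats the tool touches
(VCF 4.x, the whitespace-delimited HapCUT2 fragment format, and the TSV
report) and the internal data model: :class:`VariantSite`,
:class:`ReadFragment` and :class:`FragmentMatrix`.

Conventions
-----------
* ``pos`` on a :class:`VariantSite` is the 1-based VCF position; all other
  genomic arithmetic in the package is 0-based half-open.
* ``vcf_index`` is the 1-based ordinal of the record within the *whole* VCF
  file — the index space HapCUT2 fragment files use — regardless of whether
  a region restriction is in effect or whether the record is scorable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

PROVENANCE_HEADER = "##nanofilter=consistency-filtered"

#: Phred+33 offset used by fragment-file quality strings.
QUAL_OFFSET = 33


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSite:
    """One VCF record reduced to the fields the filter needs.

    ``vtype`` is "SNV" iff both alleles have length 1, else "INDEL".
    ``genotype`` is "het" for 0/1, 1/0, 0|1, 1|0; "hom" for 1/1 or 0/0;
    "other" for anything else (multi-allelic, missing, haploid...).
    Missing QUAL ('.') is stored as 0.0 so the quality fallback treats
    unverifiable sites conservatively.
    """

    chrom: str
    pos: int                    # 1-based, VCF convention
    ref: str
    alt: str
    vtype: str                  # "SNV" | "INDEL"
    genotype: str               # "het" | "hom" | "other"
    qual: float
    vcf_index: int              # 1-based ordinal in file order

    @property
    def scorable(self) -> bool:
        """Het biallelic sites are the only ones that enter the matrix."""
        return self.genotype == "het"

    @property
    def end(self) -> int:
        """0-based exclusive end of the REF span."""
        return self.pos - 1 + len(self.ref)


@dataclass(frozen=True)
class ReadFragment:
    """The ordered allele calls one read makes at het variant sites.

    ``calls`` is a tuple of ``(vcf_index, allele, qual_char)`` with strictly
    increasing ``vcf_index`` and alleles in {0, 1}.
    """

    read_id: str
    calls: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        idx = [c[0] for c in self.calls]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"fragment {self.read_id}: vcf_index not strictly increasing: {idx}"
            )
        if any(c[1] not in (0, 1) for c in self.calls):
            raise ValueError(f"fragment {self.read_id}: allele outside {{0,1}}")


@dataclass
class FragmentMatrix:
    """Sparse read x site matrix over {0,1}.

    ``sites`` holds only het biallelic sites, in vcf_index order; fragments
    may reference vcf_index values outside ``sites`` (e.g. hom records an
    external extractHAIRS run tagged) — such calls are dropped on
    construction and counted in ``n_ignored_calls``.
    """

    sites: list[VariantSite]
    fragments: list[ReadFragment] = field(default_factory=list)
    n_ignored_calls: int = 0

    def __post_init__(self) -> None:
        self._index_of = {s.vcf_index: i for i, s in enumerate(self.sites)}
        kept: list[ReadFragment] = []
        dropped = 0
        for frag in self.fragments:
            calls = tuple(c for c in frag.calls if c[0] in self._index_of)
            dropped += len(frag.calls) - len(calls)
            if calls:
                kept.append(ReadFragment(frag.read_id, calls))
        self.fragments = kept
        self.n_ignored_calls += dropped
        # per-site {fragment row -> allele} maps: the substrate of pair counting
        self._site_calls: list[dict[int, int]] = [dict() for _ in self.sites]
        for row, frag in enumerate(self.fragments):
            for vidx, allele, _q in frag.calls:
                self._site_calls[self._index_of[vidx]][row] = allele

    # -- lookups ------------------------------------------------------------

    def site_position(self, vcf_index: int) -> int:
        """Row of ``sites`` for a vcf_index (KeyError if not scorable)."""
        return self._index_of[vcf_index]

    def calls_at(self, site_row: int) -> Mapping[int, int]:
        """{fragment row -> allele} at one site."""
        return self._site_calls[site_row]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _classify_genotype(gt: Optional[tuple]) -> str:
    if gt is None:
        return "other"
    alleles = tuple(a for a in gt if a is not None)
    if len(alleles) != 2 or any(a not in (0, 1) for a in alleles):
        return "other"
    if sorted(alleles) == [0, 1]:
        return "het"
    return "hom"


def read_vcf(path: str | Path, region: Optional[str] = None) -> list[VariantSite]:
    """Read a VCF into :class:`VariantSite` records in file order.

    ``vcf_index`` is assigned from 1 over the *full* file even when
    ``region`` ("chrom" or "chrom:start-end") restricts the returned
    records, so indices in companion fragment files stay valid.

    Raises ``ValueError`` on a record without GT or on an unsorted file.
    """
    path = str(path)
    wanted_chrom: Optional[str] = None
    wanted_span: Optional[tuple[int, int]] = None  # 1-based inclusive
    if region:
        if ":" in region:
            chrom_part, span = region.split(":", 1)
            lo, hi = span.replace(",", "").split("-")
            wanted_chrom, wanted_span = chrom_part, (int(lo), int(hi))
        else:
            wanted_chrom = region

    sites: list[VariantSite] = []
    last_key: Optional[tuple[str, int]] = None
    seen_chroms: dict[str, int] = {}
    with pysam.VariantFile(path) as vcf:
        if "GT" not in vcf.header.formats:
            raise ValueError(f"{path}: VCF header declares no GT FORMAT field")
        for vcf_index, rec in enumerate(vcf, start=1):
            if rec.chrom not in seen_chroms:
                seen_chroms[rec.chrom] = len(seen_chroms)
            if last_key is not None:
                prev_chrom, prev_pos = last_key
                if rec.chrom == prev_chrom and rec.pos < prev_pos:
                    raise ValueError(
                        f"{path}: unsorted VCF at {rec.chrom}:{rec.pos} "
                        f"(previous position {prev_pos})"
                    )
                if rec.chrom != prev_chrom and seen_chroms[rec.chrom] < seen_chroms[prev_chrom]:
                    raise ValueError(f"{path}: unsorted VCF, contig {rec.chrom} reappears")
            last_key = (rec.chrom, rec.pos)

            if not rec.samples:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} has no sample/GT")
            sample = rec.samples[0]
            if "GT" not in sample:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks GT")
            gt = sample["GT"]

            alts = rec.alts or ()
            multiallelic = len(alts) != 1
            alt = ",".join(a or "." for a in alts) if alts else "."
            genotype = "other" if multiallelic else _classify_genotype(gt)
            ref = rec.ref or "."
            vtype = "SNV" if (not multiallelic and len(ref) == 1 and len(alt) == 1) else "INDEL"
            # htslib stores QUAL as float32; round off its representation noise
            qual = round(float(rec.qual), 4) if rec.qual is not None else 0.0

            if wanted_chrom is not None and rec.chrom != wanted_chrom:
                continue
            if wanted_span is not None and not (wanted_span[0] <= rec.pos <= wanted_span[1]):
                continue
            sites.append(
                VariantSite(rec.chrom, rec.pos, ref, alt, vtype, genotype, qual, vcf_index)
            )
    return sites


# ---------------------------------------------------------------------------
# Fragment file reading / writing
# ---------------------------------------------------------------------------

def read_fragment_file(path: str | Path) -> list[ReadFragment]:
    """Parse a HapCUT2-style fragment file.

    Line format: ``nblocks read_id  s1 alleles1  s2 alleles2 ... qualstring``
    where each block starts at 1-based vcf_index ``s`` and its allele string
    covers consecutive indices; the trailing quality string (Phred+33) has
    one character per allele call across all blocks.
    """
    fragments: list[ReadFragment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split()
            try:
                nblocks = int(tokens[0])
            except (ValueError, IndexError):
                raise ValueError(f"{path}:{lineno}: cannot parse block count") from None
            if len(tokens) != 2 + 2 * nblocks + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {2 + 2 * nblocks + 1} fields for "
                    f"{nblocks} blocks, got {len(tokens)}"
                )
            read_id = tokens[1]
            quals = tokens[-1]
            calls: list[tuple[int, int, str]] = []
            for b in range(nblocks):
                start = int(tokens[2 + 2 * b])
                alleles = tokens[3 + 2 * b]
                for k, ch in enumerate(alleles):
                    if ch not in "01":
                        raise ValueError(
                            f"{path}:{lineno}: allele char {ch!r} outside {{0,1}}"
                        )
                    calls.append((start + k, int(ch), ""))
            if len(quals) != len(calls):
                raise ValueError(
                    f"{path}:{lineno}: quality string length {len(quals)} != "
                    f"{len(calls)} allele calls"
                )
            calls = [(idx, a, q) for (idx, a, _), q in zip(calls, quals)]
            fragments.append(ReadFragment(read_id, tuple(calls)))
    return fragments


def write_fragment_file(fragments: Iterable[ReadFragment], path: str | Path) -> None:
    """Write fragments in the HapCUT2 format read by :func:`read_fragment_file`.

    Consecutive vcf_index runs within a fragment are emitted as one block.
    """
    with open(path, "w") as fh:
        for frag in fragments:
            blocks: list[tuple[int, list[int]]] = []
            quals: list[str] = []
            for idx, allele, q in frag.calls:
                if blocks and idx == blocks[-1][0] + len(blocks[-1][1]):
                    blocks[-1][1].append(allele)
                else:
                    blocks.append((idx, [allele]))
                quals.append(q if q else "I")
            fields = [str(len(blocks)), frag.read_id]
            for start, alleles in blocks:
                fields.append(str(start))
                fields.append("".join(str(a) for a in alleles))
            fields.append("".join(quals))
            fh.write(" ".join(fields) + "\n")


def build_fragment_matrix(
    sites: Sequence[VariantSite], fragments: Iterable[ReadFragment]
) -> FragmentMatrix:
    """Assemble the matrix over het biallelic sites, dropping sub-informative
    fragments (< 2 calls carry no pairwise information)."""
    scorable = [s for s in sites if s.scorable]
    first = FragmentMatrix(scorable, list(fragments))
    informative = [f for f in first.fragments if len(f.calls) >= 2]
    return FragmentMatrix(scorable, informative, first.n_ignored_calls)


# ---------------------------------------------------------------------------
# Filtered VCF + report writing
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def write_filtered_vcf(
    decisions: Mapping[int, "object"],
    in_path: str | Path,
    out_path: str | Path,
) -> None:
    """Copy the input VCF to ``out_path`` minus the removed records.

    ``decisions`` maps vcf_index -> object with a boolean ``kept`` attribute
    and must cover every record. Header lines are preserved verbatim with one
    provenance line added; kept record lines are byte-identical to the input.
    """
    out_lines: list[str] = []
    vcf_index = 0
    with _open_text(in_path) as fh:
        for line in fh:
            if line.startswith("##"):
                out_lines.append(line)
            elif line.startswith("#"):
                out_lines.append(PROVENANCE_HEADER + "\n")
                out_lines.append(line)
            else:
                if not line.strip():
                    continue
                vcf_index += 1
                if vcf_index not in decisions:
                    raise ValueError(
                        f"no filtering decision for VCF record #{vcf_index}"
                    )
                if decisions[vcf_index].kept:
                    out_lines.append(line)
    with open(out_path, "w") as out:
        out.writelines(out_lines)


REPORT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vtype", "n_pairs",
    "max_consistency", "mean_consistency", "qual", "decision", "reason",
]


def write_report(
    sites: Sequence[VariantSite],
    summaries: Mapping[int, "object"],
    decisions: Mapping[int, "object"],
    out_path: str | Path,
) -> None:
    """TSV report: one row per het biallelic site.

    ``summaries``/``decisions`` are keyed by vcf_index; summary objects carry
    n_pairs/max_score/mean_score, decision objects carry kept/reason.
    Sites without a final summary (removed early, or coverage-insufficient)
    report 'NA' scores.
    """
    with open(out_path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for site in sites:
            if not site.scorable:
                continue
            dec = decisions[site.vcf_index]
            summ = summaries.get(site.vcf_index)
            if summ is not None and summ.n_pairs > 0:
                n_pairs = summ.n_pairs
                max_s = f"{summ.max_score:.4f}"
                mean_s = f"{summ.mean_score:.4f}"
            else:
                n_pairs = 0
                max_s = mean_s = "NA"
            fh.write(
                "\t".join(
                    [
                        site.chrom, str(site.pos), site.ref, site.alt, site.vtype,
                        str(n_pairs), max_s, mean_s, f"{site.qual:.2f}",
                        "kept" if dec.kept else "removed", dec.reason,
                    ]
                )
                + "\n"
            )
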