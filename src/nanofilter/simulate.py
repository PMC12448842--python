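"""Synthetic diploid data with known truth.

The generator emulates the statistical structure consistency filtering
relies on, not nanopore signal: a diploid individual with true het
variants phased onto two haplotypes, long reads drawn from one haplotype
each, a per-read allele error rate in the nanopore regime, and injected
false-positive variant sites whose alleles are Bernoulli draws independent
of read haplotype — the linkage-free pattern a miscalled site produces.

Everything is derived from one numpy Generator seeded by ``SimConfig.seed``;
identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .io import (
    FragmentMatrix,
    ReadFragment,
    VariantSite,
    build_fragment_matrix,
    write_fragment_file,
)

CHROM = "chr1"
BASES = "ACGT"

#: flanking alignment an INDEL call needs; mirrors TaggingConfig's default
#: so simulated truth calls match what tagging can recover from the BAM.
INDEL_FLANK = 5

#: minimum gap between simulated sites so allele paths never overlap
MIN_SITE_SPACING = 12

TRUE_VARIANT = "true_variant"
FALSE_POSITIVE = "false_positive"
FALSE_HOMLIKE = "false_homlike"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation.

    Defaults follow the regime the filter targets: a few hundred het sites
    over a 100 kb region, ~10 kb nanopore-length reads at 30x, a 5% allele
    error rate, and false sites showing ALT on half the reads regardless of
    haplotype. ``n_homlike_fp_sites`` injects the second false class —
    sites where essentially every read shows ALT (a het call at a
    homozygous or systematically miscalled locus); these look perfectly
    consistent and are a documented blind spot of the method.
    """

    n_true_sites: int = 200
    n_fp_sites: int = 40
    n_homlike_fp_sites: int = 0
    indel_fraction: float = 0.3
    region_length: int = 100_000
    coverage: float = 30.0
    read_length_mean: int = 10_000
    allele_error_rate: float = 0.05
    fp_alt_prob: float = 0.5
    qual_true_mean: float = 40.0
    qual_true_sd: float = 10.0
    qual_fp_mean: float = 8.0
    qual_fp_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("indel_fraction", "allele_error_rate", "fp_alt_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass(frozen=True)
class SimRead:
    """One simulated read: haplotype of origin and its (pre/post error)
    allele calls keyed by vcf_index."""

    read_id: str
    hap: int                    # 0 or 1
    start: int                  # 0-based ref window
    end: int
    truth_calls: dict[int, int]
    observed_calls: dict[int, int]


@dataclass
class SimTruth:
    """Ground truth for evaluation: per-site labels and phase, plus the
    error-free fragment matrix."""

    labels: dict[int, str]              # vcf_index -> TRUE_VARIANT / FALSE_*
    phase: dict[int, Optional[int]]     # vcf_index -> hap carrying ALT (true sites)
    truth_matrix: FragmentMatrix
    read_haps: dict[str, int]           # read_id -> haplotype


@dataclass
class SimResult:
    config: SimConfig
    reference: str
    sites: list[VariantSite]
    matrix: FragmentMatrix              # observed (post-error) calls
    truth: SimTruth
    reads: list[SimRead]


def _place_sites(rng: np.random.Generator, config: SimConfig) -> list[int]:
    """Uniform random 0-based positions, no two closer than MIN_SITE_SPACING."""
    n = config.n_true_sites + config.n_fp_sites + config.n_homlike_fp_sites
    margin = 2 * INDEL_FLANK
    usable = config.region_length - 2 * margin
    if usable < n * MIN_SITE_SPACING * 2:
        raise ValueError(
            f"region of {config.region_length} bp too small for {n} sites"
        )
    positions: list[int] = []
    taken = np.zeros(config.region_length, dtype=bool)
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("could not place sites without collision")
        p = int(rng.integers(margin, config.region_length - margin))
        lo, hi = max(0, p - MIN_SITE_SPACING), p + MIN_SITE_SPACING + 1
        if taken[lo:hi].any():
            continue
        taken[p] = True
        positions.append(p)
    return sorted(positions)


def _draw_alleles(
    rng: np.random.Generator, reference: str, pos0: int, is_indel: bool
) -> tuple[str, str]:
    refbase = reference[pos0]
    if not is_indel:
        alt = BASES[(BASES.index(refbase) + int(rng.integers(1, 4))) % 4]
        return refbase, alt
    k = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # deletion: REF carries the deleted bases
        return reference[pos0 : pos0 + 1 + k], refbase
    inserted = "".join(BASES[i] for i in rng.integers(0, 4, size=k))
    return refbase, refbase + inserted


def simulate(config: SimConfig) -> SimResult:
    """Generate sites, reads and both (truth / observed) fragment matrices."""
    rng = np.random.default_rng(config.seed)
    reference = "".join(BASES[i] for i in rng.integers(0, 4, size=config.region_length))

    positions = _place_sites(rng, config)
    n_sites = len(positions)
    labels_arr = (
        [TRUE_VARIANT] * config.n_true_sites
        + [FALSE_POSITIVE] * config.n_fp_sites
        + [FALSE_HOMLIKE] * config.n_homlike_fp_sites
    )
    rng.shuffle(labels_arr)

    sites: list[VariantSite] = []
    labels: dict[int, str] = {}
    phase: dict[int, Optional[int]] = {}
    for vcf_index, (pos0, label) in enumerate(zip(positions, labels_arr), start=1):
        is_indel = rng.random() < config.indel_fraction
        ref, alt = _draw_alleles(rng, reference, pos0, is_indel)
        vtype = "SNV" if len(ref) == len(alt) == 1 else "INDEL"
        if label == TRUE_VARIANT:
            mu, sd = config.qual_true_mean, config.qual_true_sd
        else:
            mu, sd = config.qual_fp_mean, config.qual_fp_sd
        qual = float(max(0.0, rng.normal(mu, sd)))
        sites.append(
            VariantSite(CHROM, pos0 + 1, ref, alt, vtype, "het", round(qual, 2), vcf_index)
        )
        labels[vcf_index] = label
        phase[vcf_index] = int(rng.integers(0, 2)) if label == TRUE_VARIANT else None

    n_reads = max(1, round(config.coverage * config.region_length / config.read_length_mean))
    reads: list[SimRead] = []
    read_haps: dict[str, int] = {}
    site_starts = np.array([s.pos - 1 for s in sites])
    for r in range(n_reads):
        length = max(50, int(rng.normal(config.read_length_mean, 0.1 * config.read_length_mean)))
        length = min(length, config.region_length)
        start = int(rng.integers(0, config.region_length - length + 1))
        end = start + length
        hap = int(rng.integers(0, 2))
        read_id = f"read_{r:05d}"
        truth_calls: dict[int, int] = {}
        observed_calls: dict[int, int] = {}
        lo = int(np.searchsorted(site_starts, start))
        hi = int(np.searchsorted(site_starts, end))
        for site in sites[lo:hi]:
            pos0 = site.pos - 1
            if site.vtype == "INDEL":
                if pos0 - INDEL_FLANK < start or site.end + INDEL_FLANK > end:
                    continue  # cannot be tagged there; emit reference in fixtures
            label = labels[site.vcf_index]
            if label == TRUE_VARIANT:
                allele = 1 if hap == phase[site.vcf_index] else 0
            elif label == FALSE_POSITIVE:
                allele = int(rng.random() < config.fp_alt_prob)
            else:  # hom-as-het false call: ALT on (nearly) every read
                allele = int(rng.random() < 0.95)
            truth_calls[site.vcf_index] = allele
            observed = allele
            if label == TRUE_VARIANT and rng.random() < config.allele_error_rate:
                observed = 1 - allele
            observed_calls[site.vcf_index] = observed
        reads.append(SimRead(read_id, hap, start, end, truth_calls, observed_calls))
        read_haps[read_id] = hap

    def to_fragments(attr: str) -> list[ReadFragment]:
        frags = []
        for rd in reads:
            calls = getattr(rd, attr)
            if calls:
                frags.append(
                    ReadFragment(
                        rd.read_id,
                        tuple((idx, calls[idx], "I") for idx in sorted(calls)),
                    )
                )
        return frags

    matrix = build_fragment_matrix(sites, to_fragments("observed_calls"))
    truth_matrix = build_fragment_matrix(sites, to_fragments("truth_calls"))
    truth = SimTruth(labels, phase, truth_matrix, read_haps)
    return SimResult(config, reference, sites, matrix, truth, reads)


# ---------------------------------------------------------------------------
# Fixture emission (FASTA / SAM+BAM / VCF / fragment file / truth TSV)
# ---------------------------------------------------------------------------

def _read_to_sam_fields(
    rd: SimRead, sites_by_index: dict[int, VariantSite], reference: str
) -> tuple[int, str, str]:
    """(1-based POS, CIGAR, SEQ) encoding the read's observed alleles."""
    seq_parts: list[str] = []
    cigar: list[tuple[int, str]] = []

    def emit(n: int, op: str, segment: str = "") -> None:
        if n <= 0:
            return
        if segment:
            seq_parts.append(segment)
        if cigar and cigar[-1][1] == op:
            cigar[-1] = (cigar[-1][0] + n, op)
        else:
            cigar.append((n, op))

    pos = rd.start
    for vcf_index in sorted(rd.observed_calls):
        site = sites_by_index[vcf_index]
        s0, s1 = site.pos - 1, site.end
        emit(s0 - pos, "M", reference[pos:s0])
        allele = site.alt if rd.observed_calls[vcf_index] == 1 else site.ref
        if len(site.ref) == len(allele) == 1:           # SNV path
            emit(1, "M", allele)
        elif allele == site.ref:                        # REF path of an indel
            emit(len(site.ref), "M", site.ref)
        elif len(site.ref) > len(allele):               # deletion allele
            emit(len(allele), "M", allele)
            emit(len(site.ref) - len(allele), "D")
        else:                                           # insertion allele
            emit(1, "M", allele[0])
            emit(len(allele) - 1, "I", allele[1:])
        pos = s1
    emit(rd.end - pos, "M", reference[pos : rd.end])
    cigar_str = "".join(f"{n}{op}" for n, op in cigar)
    return rd.start + 1, cigar_str, "".join(seq_parts)


def emit_fixtures(sim: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture set for one simulation.

    Produces reference FASTA (+ .fai), coordinate-sorted indexed BAM whose
    CIGARs/sequences encode the observed alleles, a VCF with GT 0/1 and the
    simulated QUALs, a HapCUT2 fragment file of the observed matrix, and a
    truth TSV. Extracting fragments from the BAM reproduces ``sim.matrix``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "ref.fa",
        "sam": out_dir / "reads.sam",
        "bam": out_dir / "reads.bam",
        "vcf": out_dir / "variants.vcf",
        "fragments": out_dir / "fragments.txt",
        "truth": out_dir / "truth.tsv",
    }

    with open(paths["fasta"], "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(sim.reference), 70):
            fh.write(sim.reference[i : i + 70] + "\n")
    pysam.faidx(str(paths["fasta"]))

    sites_by_index = {s.vcf_index: s for s in sim.sites}
    with open(paths["sam"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{CHROM}\tLN:{len(sim.reference)}\n")
        for rd in sorted(sim.reads, key=lambda r: r.start):
            pos, cigar, seq = _read_to_sam_fields(rd, sites_by_index, sim.reference)
            fh.write(
                f"{rd.read_id}\t0\t{CHROM}\t{pos}\t60\t{cigar}\t*\t0\t0\t"
                f"{seq}\t{'I' * len(seq)}\n"
            )
    pysam.sort("-o", str(paths["bam"]), str(paths["sam"]))
    pysam.index(str(paths["bam"]))

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={CHROM},length={len(sim.reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for s in sim.sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{s.qual:g}\t.\t.\tGT\t0/1\n"
            )

    write_fragment_file(sim.matrix.fragments, paths["fragments"])

    with open(paths["truth"], "w") as fh:
        fh.write("vcf_index\tchrom\tpos\tref\talt\tvtype\tlabel\tphase\tqual\n")
        for s in sim.sites:
            ph = sim.truth.phase[s.vcf_index]
            fh.write(
                f"{s.vcf_index}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.vtype}\t"
                f"{sim.truth.labels[s.vcf_index]}\t{'NA' if ph is None else ph}\t{s.qual:g}\n"
            )
    return paths


def read_truth_tsv(path: str | Path) -> tuple[dict[int, str], dict[int, Optional[int]]]:
    """Re-load (labels, phase) written by :func:`emit_fixtures`."""
    labels: dict[int, str] = {}
    phase: dict[int, Optional[int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            vcf_index = int(row[idx["vcf_index"]])
            labels[vcf_index] = row[idx["label"]]
            ph = row[idx["phase"]]
            phase[vcf_index] = None if ph == "NA" else int(ph)
    return labels, phase
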