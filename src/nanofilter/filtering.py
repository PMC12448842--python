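"""Three-step consistency filtering with a quality fallback.

The filter removes het biallelic sites whose allele calls do not
co-segregate with their neighbors, in three passes of increasing
stringency over thresholds (p1, p2, p3), default (0.7, 0.8, 0.9):

  step 1  remove sites with no neighbor pair score above p1 (max <= p1);
  step 2  remove sites whose mean neighbor score is below p2;
  step 3  remove sites whose mean neighbor score is below p3.

Summaries are recomputed against the surviving active set between steps:
removing one unreliable site lets the means of its neighbors rise, so a
reliable site dragged down by a bad neighbor is not lost with it.

Sites for which no reliable score exists (zero qualifying pairs at the
step where they would be judged) fall back to the VCF QUAL field: kept
iff QUAL >= min_qual (default 15). A quality-rescued site stays in the
active pairing set and is not re-tested at later steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .consistency import ConsistencyConfig, SiteSummary, summarize_sites
from .io import FragmentMatrix, VariantSite

REASON_KEPT = "kept"
REASON_STEP1 = "step1_max_le_p1"
REASON_STEP2 = "step2_mean_lt_p2"
REASON_STEP3_MAX = "step3_max_le_p3"
REASON_STEP3_MEAN = "step3_mean_lt_p3"
REASON_QUAL = "qual_fallback_removed"
REASON_PASSTHROUGH = "unscored_passthrough"
REASON_MULTIALLELIC = "unscored_multiallelic"


@dataclass(frozen=True)
class FilterConfig:
    p1: float = 0.7
    p2: float = 0.8
    p3: float = 0.9
    min_qual: float = 15.0
    mode: str = "indels_only"           # or "all_variants"
    step3_statistic: str = "max"        # or "mean"
    consistency: ConsistencyConfig = field(default_factory=ConsistencyConfig)

    def __post_init__(self) -> None:
        if not (0.5 <= self.p1 < self.p2 < self.p3 <= 1.0):
            raise ValueError(
                f"thresholds must satisfy 0.5 <= p1 < p2 < p3 <= 1.0, "
                f"got ({self.p1}, {self.p2}, {self.p3})"
            )
        if self.mode not in ("indels_only", "all_variants"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.step3_statistic not in ("max", "mean"):
            raise ValueError(f"unknown step3_statistic {self.step3_statistic!r}")


@dataclass(frozen=True)
class FilterDecision:
    vcf_index: int
    kept: bool
    reason: str


def apply_mode_mask(sites: Sequence[VariantSite], mode: str) -> list[bool]:
    """Which sites may be *removed*. indels_only restricts removal to INDELs
    (SNVs still pair); all_variants makes every het biallelic site filterable."""
    if mode == "indels_only":
        return [s.scorable and s.vtype == "INDEL" for s in sites]
    if mode == "all_variants":
        return [s.scorable for s in sites]
    raise ValueError(f"unknown mode {mode!r}")


def filter_variants(
    matrix: FragmentMatrix,
    sites: Sequence[VariantSite],
    config: FilterConfig,
) -> tuple[dict[int, FilterDecision], dict[int, SiteSummary]]:
    """Run the three-step filter.

    Parameters
    ----------
    matrix : fragment matrix over the het biallelic subset of ``sites``.
    sites : every VCF record (so the decision table covers the whole file).
    config : thresholds, fallback quality, mode and pairing rules.

    Returns
    -------
    decisions : {vcf_index -> FilterDecision} covering every record.
    final_summaries : {vcf_index -> SiteSummary} over surviving active sites,
        recomputed once after the last step (what the report shows).
    """
    decisions: dict[int, FilterDecision] = {}

    # records that never enter the matrix pass through unscored
    for site in sites:
        if not site.scorable:
            reason = (
                REASON_MULTIALLELIC if site.genotype == "other" and "," in site.alt
                else REASON_PASSTHROUGH
            )
            decisions[site.vcf_index] = FilterDecision(site.vcf_index, True, reason)

    filterable_rows = {
        matrix.site_position(s.vcf_index)
        for s, flag in zip(sites, apply_mode_mask(sites, config.mode))
        if flag and s.scorable
    }

    active = set(range(matrix.n_sites))
    rescued: set[int] = set()
    use_mean3 = config.step3_statistic == "mean"
    steps = (
        (config.p1, "max", REASON_STEP1),
        (config.p2, "mean", REASON_STEP2),
        (config.p3, config.step3_statistic,
         REASON_STEP3_MEAN if use_mean3 else REASON_STEP3_MAX),
    )

    for p, statistic, reason in steps:
        summaries = summarize_sites(matrix, config.consistency, active)
        removed: set[int] = set()
        for row in sorted(active & filterable_rows - rescued):
            summ = summaries[row]
            site = matrix.sites[row]
            if not summ.sufficient_coverage:
                # no reliable score: judge by VCF QUAL instead, once
                if site.qual >= config.min_qual:
                    rescued.add(row)
                else:
                    removed.add(row)
                    decisions[site.vcf_index] = FilterDecision(
                        site.vcf_index, False, REASON_QUAL
                    )
                continue
            # "no neighbor score above p" for max; "average below p" for mean
            fails = summ.max_score <= p if statistic == "max" else summ.mean_score < p
            if fails:
                removed.add(row)
                decisions[site.vcf_index] = FilterDecision(
                    site.vcf_index, False, reason
                )
        active -= removed

    final_summaries_by_row = summarize_sites(matrix, config.consistency, active)

    for row in range(matrix.n_sites):
        site = matrix.sites[row]
        if site.vcf_index not in decisions:
            reason = REASON_KEPT if row in filterable_rows else REASON_PASSTHROUGH
            decisions[site.vcf_index] = FilterDecision(site.vcf_index, True, reason)

    final_summaries = {
        matrix.sites[row].vcf_index: summ
        for row, summ in final_summaries_by_row.items()
    }
    return decisions, final_summaries
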