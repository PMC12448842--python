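"""Evaluation against simulation truth.

Filtering quality is scored as precision/recall over the filterable sites
(kept true sites are TP, kept false sites FP, removed true sites FN). The
downstream phasing effect is demonstrated with a deliberately simple
greedy read-backed phaser — chain consecutive sites linked by enough
co-covering reads, orient each link by the majority allele pattern — plus
a switch-error counter and block-span N50. The phaser is a toy stand-in
for production phasers; it exists so the end-to-end claim (adding filtered
INDELs to SNVs lengthens blocks without adding switch errors) is testable
on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Optional, Sequence

import pandas as pd

from .consistency import pair_counts
from .filtering import FilterConfig, FilterDecision, filter_variants
from .io import FragmentMatrix, VariantSite
from .simulate import TRUE_VARIANT

#: threshold ranges explored by the parameter grid (each admissible
#: combination must satisfy p1 < p2 < p3)
P1_GRID = (0.6, 0.65, 0.7, 0.75)
P2_GRID = (0.7, 0.75, 0.8, 0.85)
P3_GRID = (0.8, 0.85, 0.9, 0.95)


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    tn: int
    switch_errors: Optional[int] = None
    n50_block: Optional[int] = None

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


def precision_recall(
    decisions: Mapping[int, FilterDecision],
    truth_labels: Mapping[int, str],
    sites: Sequence[VariantSite],
    filterable: Sequence[bool],
) -> EvalResult:
    """Count TP/FP/FN/TN over the filterable sites.

    ``truth_labels`` maps vcf_index to a label; TRUE_VARIANT counts as a
    real variant, anything else as a false call. Raises ``KeyError`` if a
    filterable site has no truth label.
    """
    tp = fp = fn = tn = 0
    for site, flag in zip(sites, filterable):
        if not flag:
            continue
        label = truth_labels[site.vcf_index]
        kept = decisions[site.vcf_index].kept
        is_true = label == TRUE_VARIANT
        if kept and is_true:
            tp += 1
        elif kept:
            fp += 1
        elif is_true:
            fn += 1
        else:
            tn += 1
    return EvalResult(tp, fp, fn, tn)


@dataclass
class PhaseResult:
    """Per-site haplotype assignment (relative within each block)."""

    assignment: dict[int, int]          # site row -> 0/1
    blocks: list[list[int]]             # site rows, position order


def greedy_phase(
    matrix: FragmentMatrix,
    site_rows: Sequence[int],
    min_link_support: int = 3,
) -> PhaseResult:
    """Chain-link consecutive sites sharing >= min_link_support reads.

    Links are oriented by the majority pattern: concordant (00/11) majority
    keeps the phase, discordant (01/10) majority flips it; ties keep it.
    A missing or under-supported link starts a new block. Deterministic.
    """
    rows = sorted(site_rows, key=lambda r: matrix.sites[r].pos)
    assignment: dict[int, int] = {}
    blocks: list[list[int]] = []
    for row in rows:
        if blocks:
            prev = blocks[-1][-1]
            x, y = pair_counts(matrix, prev, row)
            if x + y >= min_link_support:
                flip = 1 if x > y else 0
                assignment[row] = assignment[prev] ^ flip
                blocks[-1].append(row)
                continue
        blocks.append([row])
        assignment[row] = 0
    return PhaseResult(assignment, blocks)


def switch_errors(
    phase: PhaseResult,
    truth_phase: Mapping[int, Optional[int]],
    matrix: FragmentMatrix,
) -> int:
    """Count switch errors of a phasing against the truth haplotypes.

    Within each block, only sites with a defined truth phase are compared;
    an error is a consecutive such pair whose predicted relative
    orientation differs from the truth's. Counting relative orientations
    makes the tally invariant under flipping all labels of a block (or of
    the truth), so no explicit minimization is needed.
    """
    errors = 0
    for block in phase.blocks:
        phased = [
            r for r in block
            if truth_phase.get(matrix.sites[r].vcf_index) is not None
        ]
        for a, b in zip(phased, phased[1:]):
            pred_rel = phase.assignment[a] ^ phase.assignment[b]
            ta = truth_phase[matrix.sites[a].vcf_index]
            tb = truth_phase[matrix.sites[b].vcf_index]
            if pred_rel != (ta ^ tb):
                errors += 1
    return errors


def block_n50(phase: PhaseResult, matrix: FragmentMatrix) -> int:
    """N50 of block genomic spans (last site pos - first site pos + 1)."""
    spans = sorted(
        (matrix.sites[b[-1]].pos - matrix.sites[b[0]].pos + 1 for b in phase.blocks),
        reverse=True,
    )
    if not spans:
        return 0
    half = sum(spans) / 2
    acc = 0
    for s in spans:
        acc += s
        if acc >= half:
            return s
    return spans[-1]


def grid_search(
    matrix: FragmentMatrix,
    sites: Sequence[VariantSite],
    truth_labels: Mapping[int, str],
    truth_phase: Mapping[int, Optional[int]],
    base_config: FilterConfig = FilterConfig(),
    p1_grid: Sequence[float] = P1_GRID,
    p2_grid: Sequence[float] = P2_GRID,
    p3_grid: Sequence[float] = P3_GRID,
) -> pd.DataFrame:
    """Evaluate every admissible (p1, p2, p3) with p1 < p2 < p3.

    Each triple is run once: filter, phase the kept scorable sites, count
    switch errors and block N50 against truth. Returns one row per triple.
    """
    from dataclasses import replace
    from .filtering import apply_mode_mask

    filterable = apply_mode_mask(sites, base_config.mode)
    rows = []
    for p1, p2, p3 in product(p1_grid, p2_grid, p3_grid):
        if not p1 < p2 < p3:
            continue
        config = replace(base_config, p1=p1, p2=p2, p3=p3)
        decisions, _ = filter_variants(matrix, sites, config)
        pr = precision_recall(decisions, truth_labels, sites, filterable)
        kept_rows = [
            matrix.site_position(s.vcf_index)
            for s in sites
            if s.scorable and decisions[s.vcf_index].kept
        ]
        phase = greedy_phase(
            matrix, kept_rows, base_config.consistency.min_pair_support
        )
        rows.append(
            {
                "p1": p1, "p2": p2, "p3": p3,
                "precision": pr.precision, "recall": pr.recall,
                "switch_errors": switch_errors(phase, truth_phase, matrix),
                "n50_block": block_n50(phase, matrix),
            }
        )
    return pd.DataFrame(rows, columns=[
        "p1", "p2", "p3", "precision", "recall", "switch_errors", "n50_block",
    ])
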