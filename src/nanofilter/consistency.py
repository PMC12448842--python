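"""Pairwise allele co-segregation consistency scores.

For a pair of het sites co-covered by N reads, let x be the number of reads
showing discordant allele patterns (01 or 10) and y the concordant ones
(00 or 11), x + y = N. The consistency score is

    score = max(x, y) / (x + y)

which is 1.0 when the pair segregates perfectly with the two haplotypes
(all reads concordant, or all discordant) and 0.5 when the alleles are
independent. True het variants on the same pair of haplotypes score near 1;
a site whose alleles are random with respect to haplotype — a typical
false-positive call — drags every pair it enters toward 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io import FragmentMatrix


@dataclass(frozen=True)
class ConsistencyConfig:
    """Pairing rules.

    min_pair_support: minimum co-covering reads (n = x + y) for a pair to
        count toward a site's summary.
    neighbor_window: each site is paired with at most this many *active*
        scored sites on each side, in vcf_index order. Read length bounds
        co-coverage naturally; the window bounds cost.
    """

    min_pair_support: int = 3
    neighbor_window: int = 20

    def __post_init__(self) -> None:
        if self.min_pair_support < 1:
            raise ValueError("min_pair_support must be >= 1")
        if self.neighbor_window < 1:
            raise ValueError("neighbor_window must be >= 1")


@dataclass(frozen=True)
class PairConsistency:
    site_a: int                 # row in matrix.sites
    site_b: int
    x: int                      # discordant reads (01 / 10)
    y: int                      # concordant reads (00 / 11)

    @property
    def n(self) -> int:
        return self.x + self.y

    @property
    def score(self) -> float:
        return consistency_score(self.x, self.y)


@dataclass
class SiteSummary:
    """Per-site aggregation over its qualifying neighbor pairs."""

    site: int
    pair_scores: list[tuple[int, PairConsistency]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_scores)

    @property
    def sufficient_coverage(self) -> bool:
        return self.n_pairs >= 1

    @property
    def max_score(self) -> Optional[float]:
        if not self.pair_scores:
            return None
        return max(p.score for _, p in self.pair_scores)

    @property
    def mean_score(self) -> Optional[float]:
        if not self.pair_scores:
            return None
        return sum(p.score for _, p in self.pair_scores) / len(self.pair_scores)


def consistency_score(x: int, y: int) -> float:
    """max(x, y) / (x + y); requires at least one co-covering read."""
    n = x + y
    if n < 1:
        raise ValueError("consistency score undefined for x + y = 0")
    return max(x, y) / n


def pair_counts(matrix: FragmentMatrix, site_a: int, site_b: int) -> tuple[int, int]:
    """(x, y) over exactly the fragments calling both sites.

    x counts 01/10 patterns, y counts 00/11; symmetric in its arguments.
    """
    calls_a = matrix.calls_at(site_a)
    calls_b = matrix.calls_at(site_b)
    if len(calls_b) < len(calls_a):
        calls_a, calls_b = calls_b, calls_a
    x = y = 0
    for row, allele_a in calls_a.items():
        allele_b = calls_b.get(row)
        if allele_b is None:
            continue
        if allele_a == allele_b:
            y += 1
        else:
            x += 1
    return x, y


def summarize_sites(
    matrix: FragmentMatrix,
    config: ConsistencyConfig,
    active_set: Optional[Iterable[int]] = None,
) -> dict[int, SiteSummary]:
    """Neighbor-pair summaries for every active site.

    Pairs are formed only between active sites within ``neighbor_window``
    positions of each other in active-site order, and only kept when their
    co-coverage n reaches ``min_pair_support``. Returns {site row ->
    SiteSummary}; a site whose every candidate pair is under-supported gets
    an empty summary (sufficient_coverage False).
    """
    if active_set is None:
        active = list(range(matrix.n_sites))
    else:
        active = sorted(set(active_set))
    summaries = {s: SiteSummary(s) for s in active}
    w = config.neighbor_window
    for i, a in enumerate(active):
        for b in active[i + 1 : i + 1 + w]:
            x, y = pair_counts(matrix, a, b)
            if x + y < config.min_pair_support:
                continue
            pc = PairConsistency(a, b, x, y)
            summaries[a].pair_scores.append((b, pc))
            summaries[b].pair_scores.append((a, pc))
    return summaries


def dump_pairs_tsv(
    matrix: FragmentMatrix, summaries: dict[int, SiteSummary], path
) -> None:
    """Debug dump of every materialized pair (each written once)."""
    seen: set[tuple[int, int]] = set()
    with open(path, "w") as fh:
        fh.write("site_a_pos\tsite_b_pos\tx\ty\tn\tscore\n")
        for summ in summaries.values():
            for _, pc in summ.pair_scores:
                key = (pc.site_a, pc.site_b)
                if key in seen:
                    continue
                seen.add(key)
                fh.write(
                    f"{matrix.sites[pc.site_a].pos}\t{matrix.sites[pc.site_b].pos}"
                    f"\t{pc.x}\t{pc.y}\t{pc.n}\t{pc.score:.4f}\n"
                )
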