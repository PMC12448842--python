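"""Shared fixtures and independent oracles.

``brute_force_summaries`` re-derives pair counts and site summaries by
exhaustive enumeration over every read x site-pair combination, sharing no
code with the package's counting path; tests use it as the reference.
"""

from __future__ import annotations

import numpy as np
import pytest

from nanofilter.io import FragmentMatrix, ReadFragment, VariantSite


def make_sites(n: int, vtypes: str | None = None, quals=None) -> list[VariantSite]:
    """n het biallelic sites 100 bp apart; vtypes is a string of 'S'/'I'."""
    sites = []
    for i in range(n):
        vt = "INDEL" if (vtypes and vtypes[i] == "I") else "SNV"
        ref, alt = ("AT", "A") if vt == "INDEL" else ("A", "G")
        q = quals[i] if quals is not None else 50.0
        sites.append(
            VariantSite("chr1", 100 * (i + 1), ref, alt, vt, "het", q, i + 1)
        )
    return sites


def matrix_from_patterns(
    patterns: list[str], vtypes: str | None = None, quals=None
) -> FragmentMatrix:
    """Build a matrix from per-read allele strings over sites.

    Each pattern string has one char per site: '0', '1', or '.' (no call).
    """
    n_sites = len(patterns[0])
    sites = make_sites(n_sites, vtypes, quals)
    fragments = []
    for r, pat in enumerate(patterns):
        calls = tuple(
            (i + 1, int(ch), "I") for i, ch in enumerate(pat) if ch != "."
        )
        if calls:
            fragments.append(ReadFragment(f"read_{r}", calls))
    return FragmentMatrix(sites, fragments)


def random_patterns(rng: np.random.Generator, n_sites: int, n_reads: int) -> list[str]:
    """Random call patterns with ~20% missingness."""
    out = []
    for _ in range(n_reads):
        chars = []
        for _ in range(n_sites):
            u = rng.random()
            chars.append("." if u < 0.2 else ("1" if u < 0.6 else "0"))
        out.append("".join(chars))
    return out


def brute_force_summaries(
    patterns: list[str], min_pair_support: int, neighbor_window: int,
    active: list[int] | None = None,
):
    """Independent reimplementation of pair counting and summarising.

    Returns {site -> {"pairs": {other: (x, y)}, "max": float|None,
    "mean": float|None}} using plain loops over the pattern strings.
    """
    n_sites = len(patterns[0])
    if active is None:
        active = list(range(n_sites))
    active = sorted(active)
    rank = {s: i for i, s in enumerate(active)}
    result = {s: {"pairs": {}} for s in active}
    for a in active:
        for b in active:
            if b <= a or abs(rank[b] - rank[a]) > neighbor_window:
                continue
            x = y = 0
            for pat in patterns:
                if pat[a] == "." or pat[b] == ".":
                    continue
                if pat[a] == pat[b]:
                    y += 1
                else:
                    x += 1
            if x + y >= min_pair_support:
                result[a]["pairs"][b] = (x, y)
                result[b]["pairs"][a] = (x, y)
    for s in active:
        scores = [
            max(x, y) / (x + y) for x, y in result[s]["pairs"].values()
        ]
        result[s]["max"] = max(scores) if scores else None
        result[s]["mean"] = sum(scores) / len(scores) if scores else None
    return result


@pytest.fixture(scope="session")
def small_sim():
    """One modest error-free simulation reused across tests."""
    from nanofilter.simulate import SimConfig, simulate

    return simulate(
        SimConfig(
            n_true_sites=60, n_fp_sites=0, region_length=30_000,
            coverage=15, read_length_mean=4_000, allele_error_rate=0.0,
            seed=11,
        )
    )


def matrix_calls(matrix: FragmentMatrix) -> dict[str, dict[int, int]]:
    """Order-independent view of a matrix for equality checks."""
    return {
        f.read_id: {idx: allele for idx, allele, _ in f.calls}
        for f in matrix.fragments
    }
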