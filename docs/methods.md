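# Methods

## Model

`nanofilter` treats a het biallelic variant site as trustworthy when its
alleles co-segregate with those of neighboring het sites across long
reads. Reads are reduced to fragments — ordered 0/1 allele calls at the
het sites they cover, in the HapCUT2 representation — and every pair of
nearby sites is scored by

    score = max(x, y) / (x + y),

where x counts reads with discordant patterns (01/10) and y concordant
ones (00/11) among the reads calling both sites. Under a diploid model
with per-call allele error rate e, a true pair's expected score is about
1 − 2e(1 − e) (≈ 0.905 at e = 0.05), while a site whose alleles are
independent of haplotype yields pair scores concentrated near
E[max(X, n − X)]/n with X ~ Binomial(n, ½) — close to 0.5 for large n.
The score cannot distinguish a *consistently wrong* site: a het call at a
homozygous-ALT or systematically miscalled locus shows ALT on every read,
co-segregates perfectly, and passes the filter. That failure mode is
deliberately constructible in the simulator (`n_homlike_fp_sites`) and is
a known limitation of the approach.

## Pairing rules

The neighborhood of a site is its `neighbor_window` (default 20) nearest
*active* scored sites on each side in VCF order, with no genomic-distance
cap: read length bounds co-coverage naturally, and the window bounds
cost. A pair only counts toward a site's summary when at least
`min_pair_support` (default 3) reads call both sites. Per-site summaries
are the unweighted max and mean over qualifying pair scores; an
n-weighted mean was considered and rejected as a default because it
over-weights near neighbors, but the statistic choice is confined to one
function and easy to revisit.

## Filtering procedure

Three passes over thresholds p1 < p2 < p3 (defaults 0.7, 0.8, 0.9):

1. remove sites with **no** neighbor pair scoring above p1 (max ≤ p1);
2. remove sites with mean score below p2;
3. a stricter cleanup at p3.

Summaries are recomputed against the surviving active set between
passes, so removing one unreliable site lets the means of its neighbors
recover — a reliable site dragged down by a bad neighbor is not lost
with it.

Two statistics are defensible for pass 3, and the package exposes both
(`FilterConfig.step3_statistic`). The default is **max** (remove iff no
neighbor pair exceeds p3, symmetric with pass 1). The mean reading was
rejected as a default on first principles: at realistic nanopore allele
error (e ≥ 0.05) the *expected* true-pair score is ≈ 0.905, so a
mean < 0.9 rule sits on top of the true-site distribution and removes a
third or more of genuine variants — incompatible with a filter whose
purpose is to retain informative sites. With the max statistic a true
site needs only one well-supported faithful neighbor to survive pass 3,
while haplotype-random sites (max pair score ≈ 0.8 at typical
co-coverage) still fail it.

Filterable scope is set by `mode`: `indels_only` (the intended
production use — SNVs still serve as pairing partners but are never
removed) or `all_variants`. Sites with zero qualifying pairs at the pass
where they would be judged fall back to the VCF QUAL field: kept iff
QUAL ≥ `min_qual` (default 15), with missing QUAL treated as 0 so
unverifiable sites in dead zones are removed. A quality-rescued site
stays in the active pairing set and is not re-tested at later passes;
rescue timing is evaluated per pass because a site can lose its last
qualifying pair mid-procedure. Hom, multi-allelic and otherwise
unscorable records pass through unfiltered and are flagged in the
report — phasing consumes 0/1 het sites only, and removing records the
filter cannot assess would be overreach.

## Read tagging

The BAM route re-derives fragments directly (an extractHAIRS
equivalent). SNVs: the aligned base at the site, subject to
`min_baseq` (default 7); third alleles and deleted bases yield no call.
INDELs: the CIGAR-implied read sequence over the REF span of the locus,
including inserted bases at its junctions, compared exactly against the
REF and ALT allele paths; anything else is no call. An alignment must
extend `require_full_span_bp` (default 5) reference bases past both ends
of an INDEL locus to be tagged there. Alignments below `min_mapq`
(default 20) or flagged secondary/supplementary/duplicate/qcfail are
skipped. These defaults are documented package choices, not values
inferred from any external tool's configuration. A pre-computed
HapCUT2 fragment file can substitute for the BAM entirely; both routes
produce identical downstream output on equivalent inputs.

Internal coordinates are 0-based half-open; conversion to VCF's 1-based
convention happens only at I/O boundaries. Fragment files index sites by
their 1-based ordinal over *all* VCF records, so externally produced
fragment files remain valid; calls at non-scorable records are dropped
with a counted warning.

## Simulator

The generator emulates exactly the structure the method assumes: one
chromosome with a random reference; het sites placed uniformly at random
(with a 12 bp minimum spacing so INDEL allele paths never overlap — a
constraint of unambiguous SAM encoding, not of the method); per-site
truth labels; true sites phased onto one of two haplotypes by a fair
coin; reads of Normal(mean, 0.1·mean) length from a uniformly chosen
start and a fair-coin haplotype. A read's call at a true site is the
haplotype allele, flipped with probability `allele_error_rate`; at a
false site it is an independent Bernoulli(`fp_alt_prob`) draw. Defaults
(200 true + 40 false sites over 100 kb, 30× coverage, 10 kb reads, 5%
allele error, fp_alt_prob 0.5, QUAL ~ N(40, 10) for true and N(8, 4) for
false sites) define the package's reference regime: site density
(~2.4/kb) and read length give each site ~40 scorable neighbor pairs,
and the 5% flip rate sits at the bottom of the raw nanopore error range,
appropriate for allele-level calls after alignment.

What the simulator does *not* model: alignment ambiguity, homopolymer
and strand-biased error profiles, clustered calling errors, mapping
noise, coverage heterogeneity beyond region-edge ramp-down (read starts
are uniform inside the region, so the first/last read-length of the toy
region is under-covered — which usefully exercises the quality
fallback). Passing tests therefore demonstrate correctness of the
counting, filtering and evaluation machinery and the method's behavior
under its own assumptions, not performance on real nanopore data.

## Evaluation

Precision/recall are counted over filterable sites only (kept true = TP,
kept false = FP, removed true = FN). The bundled phaser is deliberately
minimal — chain consecutive sites sharing ≥ `min_pair_support` reads,
orient each link by majority pattern, ties toward same-phase — and is a
toy stand-in for production phasers, present so the downstream claim
(filtered INDELs added to SNVs lengthen blocks without adding switch
errors) is testable end to end. Switch errors are counted as consecutive
truth-phased site pairs within a block whose predicted relative
orientation disagrees with the truth; counting relative orientation makes
the tally invariant to global block flips. Block N50 is computed over
genomic spans (last site position − first + 1). The threshold grid
enumerates p1 ∈ {0.6, 0.65, 0.7, 0.75}, p2 ∈ {0.7, 0.75, 0.8, 0.85},
p3 ∈ {0.8, 0.85, 0.9, 0.95} under p1 < p2 < p3 (40 admissible triples),
each evaluated once.

## Numerical and procedural choices

- Pass-1 and pass-3(max) comparators are "max ≤ p" (strictly above p
  survives); pass-2 and pass-3(mean) are "mean < p". Scores are exact
  rational arithmetic in floating point (max(x,y)/n), so threshold
  comparisons at e.g. exactly 0.7 are well defined for small counts.
- Pairs with zero co-covering reads are never materialized; the score is
  undefined (an error) at n = 0 by construction.
- QUAL is parsed to 4 decimal places to absorb htslib's float32
  representation of the VCF QUAL column.
- Problem sizes in the test suite and acceptance script (10 simulations
  of 240 sites × ~300 reads; grids on one simulation) were chosen so the
  full pipeline's statistical claims are measurable with stable margins
  while the whole suite runs in seconds.

## Known limitations

- Consistently-wrong sites (hom-as-het calls) pass the filter; see above.
- Multi-sample VCFs are read through their first sample only.
- The mode `indels_only` never removes SNVs even when they are plainly
  inconsistent; run `all_variants` for symmetric filtering.
- No local realignment: an INDEL represented differently by the aligner
  than by the VCF (unnormalized alleles) yields no call rather than a
  match, which lowers coverage at such sites and can push them to the
  quality fallback.
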