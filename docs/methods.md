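# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults and the numerical choices made where the design was open.

## Methylation calling

Bisulfite chemistry deaminates unmethylated cytosine to uracil (read T);
methylated cytosines resist conversion, so a retained C marks methylation.
Reads descend from either the original-top (OT) or original-bottom (OB)
strand of a fragment. In reference (plus-strand) orientation an OT read
reports methylation as C vs T at reference C positions; an OB read as G vs
A at reference G positions (the bottom-strand C). Any other base at such a
position — a sequencing error or variant — is ignored rather than counted.
Calls are indexed by the position of the C **on its own strand** (an OB
call sits at the plus-strand coordinate of the G); the two strands of a
symmetric CpG are not pooled by default, because the consensus
meta-profiles are per-C, but `pool_cpg_strands` merges them on request.
Context (CpG / CHG / CHH) is assigned from the reference. No base-quality
filtering is applied, so repeat alignments are retained.

**Multi-mapper weighting.** Reads with k placements, 1 < k ≤ 7 (the
genomic cap), contribute one record per placement at weight 1/k, so each
read adds exactly one unit of evidence regardless of ambiguity; reads
exceeding the cap are dropped and counted. The cap of 7 mirrors the
repeat-rescue realignment convention for Alu reads; the weighting itself
is a design choice (the alternative — weight 1 per placement — is
available behind a flag for sensitivity analysis, and conserves nothing).

**Conversion control.** All cytosines of the spike-in contig are
unmethylated by construction, so the conversion rate is estimated as
(converted observations)/(total observations) over *all* contexts on that
contig. Zero spike-in coverage is a hard error: without the control the
methylation calls are uninterpretable.

## Occupancy calling

Each alignment is reduced to a single point at `start + shift/2` (plus
strand) or `end − shift/2` (minus strand), with shift = 116 bp by default
— an externally determined fragment-length offset, accepted as a
parameter, not re-estimated. Windows of 300 bp tiled every 150 bp
(half-window steps; the tiling density is our choice) are tested for ChIP
enrichment with a **one-sided binomial test**: chip_sum successes in
chip_sum + input_sum trials against p₀ = N_chip/(N_chip + N_input), the
ChIP share of the combined library size. Weighted sums are rounded
half-up for the exact test; log₂ ratios add a 0.5 pseudocount to both sums
before library-size normalization. The binomial statistic is a documented,
swappable choice — it is exact, calibrated under label exchange, and
library-size-aware; windows with zero combined count are omitted.

Two false-discovery statistics are attached, both phred-scaled
(−10·log₁₀, capped at 100, so printed thresholds 20/70 mean FDR
10⁻²/10⁻⁷): a Benjamini–Hochberg adjusted p over all tested windows
("Q-value"), and an **empirical FDR** obtained by re-scanning with the
ChIP and input labels swapped — at a window with p-value p,
eFDR = max(1, #swapped ≤ p)/#real ≤ p, the numerator floored at 1 to avoid
zero estimates. Windows passing Q ≥ 20, eFDR ≥ 13 and log₂ ≥ 1 merge into
regions when overlapping or adjacent; each region keeps its best (lowest-p)
window. Elements are additionally scored over their own spans with the
same statistic, BH-adjusted across elements, with Q ≥ 70 marking
high-confidence targets; an element is "enriched" when any region overlaps
it by ≥ 1 bp.

## Differential methylation

Windows are defined in **CpG-index space**: 10 consecutive CpG sites
covered in both libraries, sliding one site at a time, so each window
carries comparable information even where CpGs are sparse. Windows where
either library has fewer than 10 observations are skipped. Each window is
tested with a two-sided Fisher exact test on (methylated, unmethylated) ×
(ChIP, input), using the classic tie rule — sum of hypergeometric
probabilities ≤ that of the observed table, ties included (relative
tolerance 10⁻⁷ for float pmf comparison; sums within 10⁻¹² of 1 snap to
1). BH adjustment runs across tested windows; a window is reported at
phred FDR ≥ 13 with |log₂ methylation ratio| ≥ 0 (i.e. no ratio floor by
default). The same Fisher test on per-element aggregate counts, followed
by per-class tallies of significantly ChIP-enriched elements, produces the
"percent of Alu SINEs with significant methylation enrichment" figure; on
methylation-independent sampling this is ~0%.

The exact test is conservative on discrete counts: under a simulated null
the fraction of windows with raw p < 0.05 is *below* 0.05 (≈ 0.03 at 30×
coverage), and overlapping windows are positively correlated. The test
suite therefore asserts one-sided type-I control rather than two-sided
agreement with the nominal level.

## Consensus meta-profiles

Reads with ≥ 1 bp overlap with an annotated SINE are realigned, ungapped,
against every family consensus in collapsed bisulfite space: C→T collapse
for top-strand chemistry, G→A (after reverse complement) for bottom-strand
chemistry; both chemistries × both orientations are always tried, so input
orientation is irrelevant. A placement is valid at ≤ 20% collapsed-space
mismatches; all placements within **one mismatch of the read's best** are
reported up to a cap of 14, weight 1/k — emulating all-alignments
reporting without full aligner score semantics. Reads compete across all
family consensi simultaneously. Ungapped alignment suffices at Alu length
scales with substitution-only divergence; indels are a known limitation.
Profiles accumulate weighted retained/converted counts at every consensus
C (top) or G (bottom-strand C); fractions are undefined (NaN) without
coverage. The concatenated consensus index with 100 N spacers exists as a
construction mirror; output coordinates are always per-family.

## Family statistics

Kruskal–Wallis uses pooled mid-ranks with the standard tie correction
C = 1 − Σ(t³−t)/(n³−n) and a chi-square p on g − 1 df. Dunn's pairwise
z statistics use the tie-corrected rank variance
n(n+1)/12 − Σ(t³−t)/(12(n−1)), two-sided normal p-values, Bonferroni
adjustment by default (Holm and none selectable). The chi-square
approximation is accurate to ≈ MC error of a 10⁵-rep permutation test for
group sizes ≳ 60; at very small n the implementation is instead validated
against an independent rank-statistic computation. The
occupancy-vs-methylation curve sorts covered elements by methylation and
averages both axes over 25-element blocks sliding by one; the occupancy
axis is the element log₂ occupancy score (the published y-axis quantity is
not fully specified; this is our documented choice, and a comparison
restricted to high-confidence occupied elements is available via
`enriched_only`).

## Synthetic-data model

The generator emulates the statistical structure of a HeLa pol III
ChIP-BS-Seq experiment at desk scale:

- **Genome**: one contig (default 200 kb) carrying n families of repeat
  copies (default 3 × 60 at 300 bp — AluY/S/J-like with CpG densities
  9/7/5 per 100 bp and methylation 0.6/0.35/0.13, spanning the observed
  young-to-old Alu B-block methylation contrast) plus tRNA-like loci
  (18 × 80 bp, CpG-poor, methylation 0.05) and low-CpG background
  (1/100 bp at methylation 0.7). Copies are substitution-mutated at 5%
  divergence; copies 0 and 1 of each family are exact duplicates, forcing
  multi-mapping. Mutations never *create* CpGs (repeats erode CpGs as they
  age; this also keeps every element CpG mapped to a consensus position).
  Gaps between elements carry a fixed T…A frame so no CpG spans an
  element boundary. A second, fully unmethylated contig models the lambda
  spike-in.
- **Methylation truth**: per-consensus-CpG probabilities drawn once per
  family from a Beta with the family mean and concentration 15 (giving
  realistic position-to-position variation; set the concentration to none
  for exact constant levels), shared by all copies and recorded per site
  in the truth table.
- **Libraries**: single-end reads (75 bp) from truncated-normal fragments
  (mean 160 bp ≥ read length, sd 30 — the real libraries' small-insert,
  non-size-selected fragmentation is not quantified anywhere, so the mean
  is a free parameter). Input fragments are sampled uniformly; ChIP
  fragment midpoints carry weight `occupancy_fold` (default 8) over the
  occupied loci. Each fragment is OT or OB with probability ½; on the
  converted strand an unmethylated C reads T with probability
  `conversion_rate` (default 0.9987) and a methylated C with probability
  `conversion_failure_rate` (default 0.005), the CpG methylation state
  drawn per molecule; sequencing errors (10⁻³/base) follow conversion.
  Spike-in reads are 2% of the library.
- **Truth alignments**: the external aligner is *not* simulated — the
  truth SAM records each read's true placement, and for reads wholly
  inside a duplicate pair, both equally valid placements (NH tag = k);
  an `alignment_noise` mode instead keeps one random placement. This lets
  downstream multi-mapper handling be tested without a genomic aligner.

What the generator does **not** emulate: indels and structural divergence,
PCR duplicates, coverage and quality biases, CHG/CHH methylation (always
unmethylated, as only CpG methylation is analyzed), paired-end insert
dialects, or coincidental multi-mapping outside the constructed duplicate
pairs. Passing tests therefore demonstrate correctness of the statistical
machinery under clean single-end substitution-only data, not robustness to
every artifact of real libraries.

## Numerical and convention choices

- Coordinates are 0-based half-open everywhere internally; SAM POS and
  bedGraph conversion happens exactly once at the file boundary. Touching
  intervals do not overlap; region merging *does* join adjacent windows.
- Phred caps at 100; pseudocount 0.5 for all log-ratios; weighted counts
  round half-up before exact tests.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration + seed gives
  byte-identical outputs, including across full pipeline runs (tables are
  written with fixed column order, sorted rows and `%.6g` floats).
- Problem sizes in the test and acceptance runs (genomes of 100–450 kb,
  45k–64k reads per library, 10⁵ permutation replicates) were chosen so
  each recovery check has comfortable statistical resolution (≥ 3 SE
  margins) while a full run stays in the minutes range on one CPU.

## Known limitations

- Duplicate reads are not removed before methylation calling (whether the
  original analysis deduplicated is unstated); a deduplication flag is the
  natural extension point.
- The window statistic (binomial) and the Q-value estimator (BH) stand in
  for an unspecified upstream implementation; both are documented and
  isolated behind the module surface so alternatives can be swapped in.
- Consensus realignment is ungapped with a fixed near-best window of one
  mismatch; highly diverged or indel-bearing copies lose reads to the
  unplaced counter rather than being force-placed.
- Percent-methylation scores weight every CpG observation equally within
  an element; no per-CpG beta-binomial dispersion model is attempted.
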