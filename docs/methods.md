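# Methods

## Model and procedure

The caller assumes a reciprocal-cross F1 design: four samples with fixed
roles — (forward, replicate 1), (forward, 2), (reverse, 1), (reverse, 2) —
where in the forward cross the mother is strain1. Under this design the
maternal allele is allele1 in forward samples and allele2 in reverse
samples, which is the only fact the method needs to separate parental from
strain effects.

The pipeline runs in discrete stages:

1. **Intersection.** SNPs are attached to every locus whose merged
   intervals contain them (0-based half-open throughout; a SNP inside two
   overlapping loci serves both; SNP-free loci are kept and become NS).
2. **Counting.** Per sample, fragments overlapping a locus are filtered
   (primary alignments only; QC-fail and duplicate-marked reads excluded;
   optional strandedness and base-quality filters) and each fragment is
   counted at exactly one SNP: every mate is logically trimmed to the
   leftmost SNP its aligned bases cover, mates covering the same SNP are
   deduplicated (mate 1's base wins; disagreeing mates count as "other"),
   and a fragment whose mates resolve to different SNPs counts only at the
   leftmost. Bases other than the two strain alleles are tallied separately
   and never enter allele counts.
3. **minread.** Within each sample a SNP's counts enter the locus sums only
   if n1 + n2 ≥ minread *in that sample*, so a SNP may be informative in
   one replicate and excluded in another. This per-sample reading maximizes
   use of unevenly covered replicates; the alternative (pooled-depth
   inclusion) would couple the samples before scoring.
4. **Scoring.** The allelic score of counts (a, b) is the exact two-sided
   binomial p-value against 1:1, p = min(1, 2·P(X ≥ max(a,b))), reported
   as −log10 p and signed by the favored side. Both one- and two-sided
   variants exist; two-sided is the default because the deviation being
   tested is directionless under the symmetric null. Equal counts score
   exactly 0, and a zero score breaks sign consistency.
5. **Summary.** Per locus, the four parental scores summarize to `i_score`
   and the four strain scores to `s_score`: the minimum-magnitude score if
   all four are strictly positive or all strictly negative, else 0. Because
   per-sample parental and strain scores differ only by sign flips on the
   reverse samples, at most one summary is nonzero per locus.
6. **Mock analysis and FDR.** The same summaries are recomputed after
   negating the scores of replicate 2 of each cross (a fixed, deterministic
   inversion set). This destroys genuine biases and measures the rate of
   chance sign-consistency. Pooling strictly positive |i_score| and
   |s_score| values over loci for both analyses, the empirical FDR at
   cutoff c is 100 · #{mock > c}/#{reciprocal > c}. Exceedance is strict,
   and the cutoff grid is the union of observed reciprocal *and* mock
   values: both exceedance counts are step functions whose breakpoints lie
   at values of either pool, and the largest mock value is the smallest
   cutoff with zero mock exceedances. Restricting the grid to reciprocal
   values can badly overshoot on small annotations: if the mock maximum
   happens to top the reciprocal null values, the next admissible
   reciprocal cutoff may sit far up in the true-bias score range, emptying
   the biallelic category. The run uses the smallest cutoff whose FDR is at
   or below the target (default 1%); if none qualifies, an infinite
   sentinel is propagated and the run completes with zero biased calls and
   a warning.
7. **Categorization.** First match wins: NS if the locus has no SNP;
   MAT/PAT if |i_score| exceeds the cutoff and the pooled parental ratio
   exceeds the ratio cutoff (default 0.7, strict); STRAIN1/2 likewise for
   s_score and the strain ratio; else BAE if the locus *could* have been
   called — i.e. for every sample, hypothetical counts at exactly the ratio
   cutoff, (ceil(r·n), n − ceil(r·n)), would have exceeded the score
   cutoff; else NI.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `fdr_target_percent` | 1.0 | target empirical FDR for the score cutoff (percent) |
| `ratio_cutoff` | 0.7 | pooled favored-allele fraction a biased call must exceed |
| `minread` | 1 | minimum reads over a SNP per sample for inclusion |
| `strandedness` | unstranded | `forward` or `reverse` (dUTP) restrict fragments to the locus strand |
| `min_base_quality` | 0 | Phred floor for the base at the SNP |
| `min_locus_length` | 0 | drop annotation rows shorter than this before merging |
| `one_sided` | off | use the one-sided binomial tail |

The allelic ratio is computed from counts pooled over the four samples
(weighting samples by evidence), oriented by the sign of the nonzero
summary score; unbiased loci report the larger side of the strain pooling,
which unlike the parental pooling is invariant under cross direction. A
ratio cutoff of 0.5 disables the filter (useful for cutoff sweeps) and is
accepted by the categorizer, though a run configuration requires a cutoff
strictly above 0.5.

## Numerical choices

Binomial p-values are computed in log space via the scipy survival
function; where that underflows (tails beyond ~1e-308, reachable at high
depth) a term-wise log-space summation over lgamma takes over, so scores
stay finite for totals up to at least 1e7. Agreement with exact
integer-arithmetic enumeration is at the 1e-15 relative level for totals
up to 30 (see `tests/test_scoring.py` and the acceptance script). The
browser BED caps its score field at 1000 as the format requires; the
results TSV reports uncapped values. All outputs are deterministically
ordered by (chrom, start, name), so identical inputs and configuration
yield byte-identical tables.

## What the simulator emulates — and what it does not

`simulate_cross` lays loci left-to-right on a toy contig, spaces SNPs one
read-length apart (each read covers exactly one SNP), draws the read total
per SNP/sample from Poisson(depth), the allele per read from
Bernoulli(true ratio) mapped through the cross direction for parental
truth, and substitutes uniformly random bases at the configured per-base
error rate. Reads are emitted as pre-aligned, coordinate-sorted, indexed
BAMs (alignment is upstream of this tool); a FASTQ emitter exists for
end-to-end demos with an external aligner. Generation is deterministic per
seed, one RNG stream per sample file, with the seed recorded in the truth
TSV header.

Default study conditions: depth 30 reads/SNP/sample, 8 SNPs per locus, 1%
base-error rate, read length 50. The recovery mix is 20 maternal loci at
ratio 0.95, 20 strain1-biased at 0.85, 200 biallelic, 20 zero-depth
(expected NI) and 10 SNP-free (expected NS). The mixing preset emulates
combining equal aliquots of pure-strain reads into four identical mock
"crosses": all loci biallelic by construction plus a 5% strain-biased
subset at ratio 0.8, because real mixed-strain data contains genuine
strain biases and without any true signal the reciprocal pool cannot
dominate the mock pool — the 1% FDR target is then unreachable and every
locus is non-informative, leaving the imprinted-FDR estimate undefined.

The simulator does not model transcript structure (splicing, UTRs),
mappability or reference bias, overdispersed depth beyond Poisson
(a negative-binomial knob exists in design but is out of scope here),
quality-score variation, or correlated errors. Passing tests on simulated
data therefore demonstrate the correctness of counting, scoring,
calibration and categorization logic — not robustness to alignment
artefacts, which real data and aligner choice dominate.

## Problem sizes

The test suite and acceptance script use 2,000-locus null and mixing
simulations (~1.9 M reads per dataset across four samples) and the
270-locus recovery mix; together they complete in a couple of minutes on
one CPU. These sizes put ~500 values in each FDR pool, enough to resolve a
1% target while staying desk-scale; genome-scale annotations (~20k loci)
behave strictly better because the pools are larger.

## Known limitations

- The 2+2 reciprocal design is structural: the mock-inversion scheme does
  not generalize to other replicate counts in this version.
- The empirical FDR needs true biased loci in the data to anchor the
  reciprocal pool; on data with no real signal the cutoff is the +inf
  sentinel and nothing is called (by design).
- Sex chromosomes receive no special handling; X-inactivation skew appears
  as strain bias, as it should.
- Overlapping or antisense genes can bleed counts into each other;
  raising `minread` is the mitigation, as reflected in the minread
  monotonicity test.
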