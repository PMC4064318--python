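# Methods

## Reference model

Typing operates on *sub-transcripts*, not full mRNAs. The
peptide-binding domains — exons 2+3 for class I, exon 2 for class II —
carry nearly all allele-distinguishing polymorphism, so each allele's
reference sequence is that region plus short flanks to catch reads
spanning the exon boundaries:

* class I (A, B, C): exon 1 (73 nt in the canonical annotation) + exon 2
  + exon 3 + the first 75 nt of exon 4;
* class II (DQA1, DQB1, DRB1): the last 75 nt of exon 1 + exon 2 + the
  first 75 nt of exon 3.

With canonical exon sizes the class I sub-transcript is 694 nt and the
class II ones 400 nt (DQA1) and 421 nt (DQB1, DRB1); these lengths are
also the RPKM denominators. Entries whose flanking exon is missing or
shorter than 75 nt keep whatever flank exists and are flagged
`short_flank` rather than rejected — truncated database entries are
common and the flanks are not load-bearing for calling. Only the
peptide-binding exons are required (class I additionally requires exon
1, which is included in full). Alleles are grouped at two-digit
resolution (the first name field, e.g. `A*02`); suffix letters and
deeper fields are parsed but ignored for grouping. Four-digit calling is
out of scope.

## Alignment model

Reads are placed ungapped, end to end, on both strands, anywhere the
full-length Hamming distance is ≤ v (default v = 1 for 37-nt reads at
~1–2 % sequencing error; v ∈ {0,1,2} supported). All qualifying
placements are reported by default; the `unique` policy keeps a read
only when all its placements fall on a single allele, and exists mainly
to demonstrate why it should not be used (nearly every HLA read is
shared between sibling alleles, so unique-only mapping starves the
counts). A mate pair aligns to an allele when both mates place on it in
opposite orientation; no insert-size constraint is imposed (the
reference is only ~0.4–0.7 kb, so a length gate would add nothing). One
fragment contributes one count. `N` matches nothing, including another
`N`.

The bulk mapper splits each read into v+1 contiguous pieces and looks
the pieces up exactly in a reference substring index; any placement with
≤ v mismatches must contain at least one exact piece, so verification of
the candidate set by direct mismatch counting reproduces the brute-force
hit set exactly. This is an implementation detail with a correctness
proof, and the test suite checks the equivalence against exhaustive
enumeration.

## Calling statistics

Counts are tallied per allele; every allele of the locus (zeros
included) participates. The calling statistics operate at two different
resolutions, deliberately:

* **Confidence p-values** use the distribution of reads over *groups*,
  each group represented by its best-supported allele's count. Counts of
  alleles within one group are near-duplicates of each other, not
  independent background observations; treating them as such would make
  a heterozygote's first call look insignificant simply because the
  winner's siblings track its own count.
* **The zygosity threshold** is the median over the *allele* counts of
  iteration 1, which deliberately sits at the typical cross-group
  ambiguity level.

Given the winning count `a` and background counts `R` with `x = |R|`:
`tail = P(X ≥ a)` for `X ~ Normal(mean(R), sd(R))` (sample sd, n−1
denominator), and `p = 1 − (1 − tail)^x`, the probability that at least
one background value reaches `a`. In iteration 1 the winner is removed
from `R` before estimating the background; in iteration 2 it is kept,
which inflates the background mean and sd and makes the second call
strictly harder — the appropriate direction, since the second iteration
is run on a reduced read set. A compatibility flag returns the
lower-tail form `(1 − tail)^x` instead (the probability of *zero*
background exceedances), for consumers that expect that orientation.

Degenerate cases: sd = 0 uses the limiting tail (0 above the mean, 0.5
at it, 1 below); an empty background yields p = 1; all-zero counts yield
a no-call, distinct from an error. Ties anywhere (maximal counts,
even-length medians) resolve deterministically: lexicographic
group/allele order; the median of an even list is the mean of the two
central values.

## Zygosity

Threshold: `median(R_L^1)` for class I, `median(R_L^1)/2` for class II —
class II loci cross-map heavily enough that the unhalved median
overshoots the real second allele. Second-round winner above the
threshold ⇒ heterozygous; below ⇒ homozygous, scored by the outlier
statistic of its count against the iteration-2 group counts with the
iteration-1 median appended (include-top convention). This
*homozygosity p-value* is the probability that background reaches the
second winner, so its confident direction is **large**: ~1 when nothing
group-shaped survives iteration 1, smaller as the second winner
approaches the threshold. It is reported for homozygous and ambiguous
calls only and is not comparable to the call cutoff.

The ambiguous status ("likely homozygous or single allele expressed")
was genuinely open design space. The implemented rule: a locus is
ambiguous when the second winner ties the threshold exactly, or when it
is below the threshold yet behaves like a real, weakly expressed group —
its own outlier p-value beats the call cutoff *and* its count exceeds
half the threshold, while the homozygosity p-value stays above the
cutoff. The half-threshold guard exists because the iteration-2
background at a cleanly homozygous locus is nearly empty, and one or two
stray fragments over seven zeros are "significant" under a normal model
while obviously not being a lowly expressed allele; a genuine
single-expressed second allele shows tens of percent of the expected
read mass, not single fragments.

Loci are processed independently over the full read set; iteration-2
removal is scoped per locus, so cross-locus ambiguous reads always count
toward every locus's background.

## Expression

Only fragments mapping to at least one *determined* group (the called
genotype; both groups for heterozygous loci, the first for
homozygous/ambiguous) contribute, each split 1/k over the k determined
groups it hits, so read mass is conserved exactly. RPKM uses the mean
sub-transcript length of the called groups' alleles and, by default, the
number of input fragments as the per-million denominator — the mapper
only ever sees HLA reads, so a library-wide mapped-read total, when
available, can be supplied explicitly and simply rescales all loci. Both
denominators are supported; neither is asserted to be the "true"
normalization, and ratios between loci are invariant to the choice.

## Diversity analytics

* Per-column variability of an allele alignment: Shannon entropy
  −Σ f_b log2 f_b over observed A/C/G/T frequencies (gaps and N
  excluded), 0 = invariant column, 2 = all four bases equally likely.
  Plain frequencies, no small-sample correction.
* Intra-/inter-group mean Hamming distances over the peptide-binding
  exons; single-member groups report no intra-group distance (absent,
  not 0). Sequence sets of unequal length are right-trimmed to the
  common minimum with a warning.
* Unique f-mer fraction: an allele is distinguishable at read length f
  and mismatch tolerance v if at least one of its f-mers occurs, within
  ≤ v mismatches on either strand, in no other allele in scope. The
  fraction is non-decreasing in f and non-increasing in v; the absolute
  values depend strongly on the allele set and are not comparable across
  databases.

## Synthetic data

The generator emulates the features that make this problem hard: one
ancestral sequence per gene family, per-locus ancestors (cross-locus
substitution rate 8 %), per-group founders (3 %), per-allele leaves
(0.5 %). Two siblings produced at rate r differ at ~2r − (4/3)r² of
positions, so pairwise intra-group divergence is ~1 %, inter-group ~6 %,
cross-locus ~15 % — qualitatively the "highly similar alleles, conserved
paralogues" regime of the real loci. Reads are 37-nt mate pairs (one
fragment end each, opposite strands, fragment length ~N(150, 30²)
clamped to the sub-transcript), uniform fragment starts, i.i.d. 1 %
substitution errors, constant placeholder qualities.

Deliberately not modelled: indels (the aligner contract is ungapped),
quality-score structure, positional/GC bias, splice noise, intronic or
whole-transcriptome background reads, and the long tail of rare alleles
in a real database (thousands per locus rather than 40). The last point
matters for interpreting the statistics: with 8 groups per locus the
background for the confidence p-value has only 7 free values, so even a
perfect heterozygous call bottoms out near p ≈ 0.08 when both true
groups carry equal mass — passing the default 0.1 cutoff, but without
the orders-of-magnitude margin a 1,600-allele database provides.
Recovery results on synthetic cohorts therefore demonstrate the
machinery and its failure directions, not clinical-grade sensitivity on
real data.

Default study conditions used across the test suite: 6 loci, 8 groups ×
5 alleles, the divergence rates above, 2,000 fragments per locus per
individual, 20 individuals per cohort, 25 % group-level homozygosity per
locus, all seeds fixed. These sizes keep the full suite around a minute
on one CPU while leaving every count distribution well away from
small-number noise.

## Known limitations

* Two-digit resolution only; phasing beyond group calls and four-digit
  typing are out of scope.
* The normal background model is a rough fit for low, discrete counts;
  the half-threshold guard in the ambiguity rule papers over the worst
  of it, but homozygosity p-values should be read qualitatively.
* Expression estimates are locus-level; allele-specific expression would
  require assignment below group resolution, which short single-locus
  reads cannot support reliably.
* The unique-mapping policy is provided for completeness and parameter
  studies; it is not a recommended operating mode.
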