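# Methods

## Problem setting

Somatic mosaicism in vascular skin lesions (the Sturge–Weber
syndrome / port-wine birthmark setting) presents as a pathogenic SNV in
only a subset of cells, so bulk tissue carries the variant at well below
the 50% of a germline heterozygote — from tens of percent in purified
endothelium down to fractions of a percent in bulk biopsies.  Detection
therefore relies on ultra-deep amplicon sequencing (10^4–10^5 reads over
a short PCR product spanning the locus) with per-sample barcodes, and on
deciding, per sample, whether the mutant-read fraction is signal or
sequencing error.  `ampmosaic` implements that analysis chain end to
end, plus the exome-style paired affected/unaffected filtration used to
discover a novel candidate when the recurrent hotspot is absent, and a
small structural stage that makes the "charge-reversal at a subunit
interface" argument computable.

## Pipeline model and assumptions

**Demultiplexing.** Barcodes are fixed-length read prefixes and must
match a sample exactly (0 mismatches by default; a `max_mismatch`
option exists but is off).  Exactness is the conservative choice: with
6-bp barcodes pairwise distinct, one substitution error in the barcode
sends a read to the unassigned bin rather than to a wrong sample, and
it makes the partition property (bins sum to input) crisp.

**Alignment.** Reads come from PCR of a known short template, so the
aligner evaluates *every* gapless placement of the read and of its
reverse complement on the amplicon and keeps the minimum-mismatch one.
No indel alignment is attempted: the interrogated variants are SNVs and
the pileup counts substitutions only; a read that cannot be placed
within `max_mismatch_frac` (default 0.2) of its length is dropped as
unalignable, the gapless analogue of an aberrant-CIGAR read.
Tie-breaks are deterministic (smallest start, then + strand) and a
non-unique best placement gets mapping quality 0, so repeat-mediated
ambiguity is removed by the same cleaning rule as in the exome stage.
Coordinates are 1-based and amplicon-local throughout; genomic/HGVS
coordinates are configuration metadata.

**Read cleaning.** PCR duplicates, reads without a proper pair flag and
reads under a mapping-quality cutoff (default `min_mapq=1`, i.e. only
ambiguous placements are dropped; configurable) are removed by
predicates on the alignment record.  The cutoff for the original
exome cleaning is not knowable from the inputs; 1 is the weakest
non-trivial choice.

**Pileup.** Raw integer tallies of A/C/G/T per reference position, with
reverse-strand bases complemented back to reference orientation.  No
base-quality or strand filtering is applied: the published depths equal
the sum of the four base columns in every printed row, which is only
true of unfiltered tallies.  N bases are tallied separately and counted
in depth; simulated data contain no Ns, so this policy only matters for
real reads.

## The positivity rule

For a pileup row at the target locus with mutant count *k* and depth
*n*:

* **VAF** = *k*/*n*, kept as an exact rational; report tables print
  100·VAF rounded half-up to 2 decimals (this reproduces all 18
  published rows, e.g. 3265/91041 → 3.59 and 206/133486 → 0.15).
* **Background error.** The two bases that are neither reference nor
  alternative can only arise from error.  Under a uniform substitution
  model an error lands on each of the three non-template bases with
  probability e/3, so the pooled off-target count over 2·*n* estimates
  the *per-substitution* rate — directly the rate at which error feeds
  the alternative base.  `vaf_corrected = max(0, vaf − error_rate_hat)`
  removes the resulting upward bias of the raw VAF (≈ e/3, i.e.
  ~3×10⁻⁴ at e = 10⁻³).
* **Call.** Positive iff the one-sided binomial tail
  P[X ≥ *k* | *n*, p = max(error_rate_hat, 10⁻⁴)] < α (default 0.01,
  Bonferroni-divided across loci when a sample is tested at more than
  one locus) **and** VAF ≥ `min_vaf` = 0.002.

The 0.2% reporting floor is the substantive choice here.  At depths of
10⁵ the binomial test alone is overwhelmingly significant for any trace
above ~0.05%, yet the published calls treat a 0.15% signal in matched
unaffected dermis as negative while the positive range starts at 0.2%.
A pure significance rule cannot reproduce that; a measured-VAF floor at
the bottom of the reported positive range does, for every stated call
(down to the 0.24% positive culture).  The floor, α and the error floor
are all parameters of `classify_mosaic`.  One published sample (a
second endothelial culture at 0.13%) is never stated positive or
negative; the default rule calls it negative and the tests leave it
unasserted.

A sample whose *true* VAF sits exactly at the floor is intrinsically a
boundary case: at depth 2×10⁴ its measured VAF straddles 0.2%, so its
call tracks the measured value.  The validation study asserts strict
all-positive only above the floor and checks the boundary sample for
consistency with its measured frequency; separating 0.15% from 0.2%
reliably would need several-fold greater depth.

## Exome filtration cascade

Candidate discovery on paired ~400× exome base counts: call a variant
wherever ≥ 3 reads support the same non-reference base; keep candidates
from affected tissue with alt count ≥ 15 (inclusive), population allele
frequency < 1% (strict; absent from the database counts as 0) and
conservation score > 5 (strict; an unscorable site fails); then remove
any candidate whose key also occurs in the unaffected tissue with alt
count > 5 (strict).  Filtration precedes subtraction, matching the
described order; reversing them only matters for variants that would be
annotated differently per tissue, which the data model excludes.  The
historical candidate list itself is not reproducible (the raw exomes
are not public), so correctness is established against the simulator's
independently computed row-by-row truth plus threshold-monotonicity
properties.

## Synthetic data generators

**Amplicon reads.** Per sample×amplicon block, templates carry the alt
base with probability `true_vaf`; every base of the barcoded read is
then substituted independently with probability `error_rate`, uniformly
to one of the three other bases; about half the reads (configurable)
are emitted as the reverse complement of the template.  Errors hit the
barcode bases as well — that is what makes demultiplexing lossy at
realistic error rates and exercises the unassigned path.  Quality
strings are constant Q30 placeholders since no stage consumes
qualities.  Draw order per block is documented in the module docstring
so the realized mutant-template count can be replayed independently;
identical configs reproduce byte-identical FASTQ.  Default study
conditions: depths 2×10⁴ (desk-scale stand-in for the 10⁴–10⁵ of the
real screens), error 10⁻³ (mid-range of typical amplicon MiSeq
substitution noise), 50 bp single-end reads, and a 12-sample VAF ladder
{0, 0, 0.001, 0.002, 0.03, 0.03, 0.09, 0.09, 0.21, 0.21, 0.30, 0.30}
mirroring the unaffected / trace / bulk dermis / endothelial culture /
microdissected endothelium tiers.

What the generator does *not* emulate: PCR-cycle errors and chimeras
(errors are i.i.d. per base, not jackpotted), quality-score profiles,
indels and strand bias.  Passing the recovery study therefore shows the
pipeline arithmetic and rule behave correctly under the stated error
model — not that the 0.2% floor is safe against real-world jackpot
artefacts, which is exactly why the floor (and not the binomial test
alone) carries the published negative calls.

**Variant tables.** Sites are drawn from a mixture of survivors
(constructed to pass every rule), germline heterozygotes, common
polymorphisms, weakly conserved or under-supported somatic sites and
bare noise, at ~400× Poisson depth; the ground-truth survivor list is
recomputed row by row with literal thresholds, independent of the
cascade implementation.

## Structural stage

Fixed-column PDB ATOM parsing (HETATM/ANISOU ignored, altLoc other than
blank/'A' skipped); inter-chain salt bridges as cation side-chain N
(Lys NZ, Arg NH1/NH2/NE, His ND1/NE2) to carboxylate O (Asp OD1/OD2,
Glu OE1/OE2) pairs within 4.0 Å — the conventional Barlow–Thornton
criterion; the cutoff is a parameter.  Histidine protonation is
unknown, so His-mediated contacts are flagged rather than excluded.
The charge-reversal report recomputes each involved contact's character
(attractive/repulsive/neutral) from formal side-chain charges before
and after a substitution such as K78E.  The chain mapping of a real
heterotrimer structure (which letters are Gα/Gβ) is configuration; the
integration check against the 2.0 Å transducin structure (1GOT) runs
only when a local copy of the coordinates exists, since no binary data
ships with the package.

## Numerical and engineering choices

* All count arithmetic is integer; VAFs are `fractions.Fraction`;
  percent display uses decimal half-up rounding.  The binomial tail is
  `scipy.stats.binom.sf(k−1, n, p)`.
* Randomness: `numpy.random.default_rng` seeded with
  `[seed, sample_index, amplicon_index]` per block; every CLI artifact
  header records the seed.
* The aligner's batched implementation (one array pass per offset and
  strand) and the single-read path are tested for equality; both are
  checked against an exhaustive pure-Python placement oracle.
* Zero-depth pileups raise on VAF computation rather than returning a
  sentinel; empty inputs otherwise produce empty outputs.
* Validation problem sizes (12 samples × 2×10⁴ reads × 20 replicates;
  1000-site variant tables; ≥100 randomized instances per stage oracle)
  were chosen so the whole study re-runs in a couple of minutes on one
  CPU while keeping ≥ 3σ statistical margins.

## Known limitations

* Gapless alignment cannot place reads spanning indels; such reads are
  dropped, which would bias VAF at loci adjacent to true indels.
* The error model is locus-local and symmetric; context-specific error
  (e.g. oxidative damage G>T) would inflate the per-substitution
  estimate only if it hits the two off-target bases, and escape it if
  it feeds the alt base specifically.
* The 0.2% positivity floor is calibrated to ultra-deep (≥ 5×10⁴)
  data; at lower depth the binomial test dominates and the floor is
  conservative.
* The exome stage consumes pre-annotated tables; no annotation sources
  are bundled.
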