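# Methods

## Problem setting

Plasma cell-free DNA from a cancer patient contains a small fraction of
tumor-derived fragments.  Deep sequencing of PCR amplicons spanning the EGFR
hotspots (exons 19–21) can detect and quantify these mutant alleles, but
only if the decision rule separates true mutant reads from read errors
introduced by PCR and the sequencer.  Read error is strongly position- and
pattern-specific: at most positions one alternate base dominates the error
mass, insertion/deletion error far exceeds substitution error, and error
intensities fluctuate between runs.  `plasmut` treats mutation calling as
anomaly detection against per-type null models of this error.

## Null models and thresholds

For each substitution type (position × alternate base; 169 positions × 3
patterns = 507 types across the three default amplicons, plus one pooled
indel pseudo-type per position and one exon-19 deletion channel), event
counts are normalized to events per 100,000 reads and summarized across a
panel of normal samples by the method of moments: mean *m*, variance *v*
(population variance, *n* denominator; `ddof=1` available as a switch).
Model selection is three-way:

| condition              | null model        | parameters                    |
|------------------------|-------------------|-------------------------------|
| *m* < 1                | Poisson (floor)   | λ = 1                         |
| *m* ≥ 1, *v*/*m* ≤ 1.2 | Poisson           | λ = ⌈*m*⌉                     |
| *m* ≥ 1, *v*/*m* > 1.2 | negative binomial | r = ⌈*m*²/(*v*−*m*)⌉, p = r/(r+*m*) |

The λ = 1 floor guards the many types whose panel error is essentially zero:
their true intensity is not identifiable at panel size 48, and λ = 1 is a
deliberately conservative null.  The negative binomial arises as a
gamma-mixed Poisson, the natural model when the error intensity itself
fluctuates between samples (overdispersion).  λ and r are rounded **up** to
integers; after rounding r, p is re-solved as r/(r+*m*) so the fitted
distribution preserves the empirical mean — the mean is the better-estimated
moment, and preserving it keeps thresholds anchored to the observed error
level.  A variance/mean ratio exactly at 1.2 goes to the Poisson (ties favor
the simpler model).  If *v*−*m* is positive but so small that r would exceed
10⁶, the NB is numerically indistinguishable from a Poisson and a Poisson
fit is returned with a warning.

The calling threshold is T = min{k ≥ 0 : P(X > k) ≤ α} with α = 2×10⁻⁵ per
test and no multiplicity correction (a Bonferroni switch exists, off by
default).  Tail probabilities are evaluated exactly through survival
functions, never by normal approximation.  Two conventions deserve note:

* **Threshold convention.**  T is defined through P(X > k) ≤ α, while the
  calling rule is "events ≥ T".  The realized per-test size P(X ≥ T) can
  therefore exceed α slightly (8.3×10⁻⁵ at the λ = 1 floor).  This pairing
  is the one that yields T = 7 for the floor model at α = 2×10⁻⁵; defining T
  through P(X ≥ k) ≤ α would give 8.  Reports carry both T and the realized
  size so the gap is visible.
* **No rounding at call time.**  Observed events per 100,000 reads are
  compared to T as real numbers.  Rounding direction at depths ≠ 100,000 is
  not specified by any convention we consider authoritative; the raw
  comparison is monotone in depth and exact at the reference depth.

The **detection limit** at depth *d* rescales the fitted intensity
real-valued (λ_d = λ·d/100 000; an NB keeps r and rescales its mean),
recomputes the threshold T_d, and reports 100·T_d/*d* percent — the smallest
mutant fraction whose events alone reach the threshold.  For the λ = 1 loci
at depth 100,000 this is 0.007%, i.e. below 0.01% (one mutant allele in
10,000).  For overdispersed loci an alternative reading subtracts the
expected background first (100·(T_d − mean_d)/*d*); both are computable
(`mean_adjusted=True`) because the definition is genuinely ambiguous for NB
loci.

## Counting

Reads carry a 5-nt inline index; demultiplexing requires an exact prefix
match and strips the index.  Reads shorter than 70 bases after stripping are
discarded (the filter protects alignment quality of the biological insert,
so it applies post-strip).  Alignment is glocal — read global, reference
local — with affine gap scores (match +1, mismatch −3, gap open −5, extend
−2), via Biopython's `PairwiseAligner`; references are ≤ ~250 bp so no
banding is needed.  A read whose best score falls below 0.25× its length is
unaligned; the reverse complement is tried and a reverse hit is used but
logged, since the amplicon protocol produces forward reads.  `N` bases never
count as matches and are excluded from depth.  Pileups tally A/C/G/T,
deletions, and insertions per window position; insertions and deletions are
pooled into one indel channel when error rates are summarized, because
aligners do not reliably distinguish them.  Pre-aligned SAM is accepted as
an alternative entry point (`import_sam`), with unknown reference names
rejected.

Exon-19 deletions: each exon-19 read is assigned to the best-scoring
sequence among the intact reference and eight deletion templates (cDNA
intervals 2233-2247, 2235-2246, 2235-2249, 2236-2250, 2236-2256, 2238-2252,
2239-2247, 2239-2256; the derived sequences drop the interval from the
intact reference).  Score ties for a read favor the intact reference;
deletions absent from the list still land on their best-matching template.
The deletion event count and fraction use the template with the most reads
(count ties break to the smallest template id); the fraction denominator is
all exon-19-aligned reads.  Whether the numerator should instead sum over
all templates is a genuinely open reading; `numerator="sum"` provides it.

Coordinates are 1-based inclusive internally (cDNA NM_005228 and GRCh37
chr7); conversion to 0-based half-open happens only at the SAM/VCF/BED
boundaries.  VCF deletion records use a one-base left anchor.  Temporal
reports scale to events per 10,000 reads; all internal math is per 100,000.

## Synthetic references

The paper-scale coordinate frame is real — target loci L858R c.2573T>G,
L861Q c.2582T>A, T790M c.2369C>T, the frequent SNP (G>A at cDNA 2361,
excluded from fitting by default), the eight deletion intervals, and the
cDNA↔genomic offsets — but the amplicon base content between those pinned
loci is synthetic, generated deterministically in code.  Windows span
57+56+56 = 169 positions.  Exact amplicon boundaries are configurable; no
conclusions depend on the filler sequence.

## Simulator

`simulate_normal_panel` draws, per sample and amplicon, a read depth uniform
on [44 400, 373 000] (mean ≈ 162 000), and per type an intensity that is
either fixed (pure Poisson) or gamma-distributed with variance/mean ratio ρ
at the reference depth (shape *m*/(ρ−1), scale ρ−1); the count is Poisson at
that intensity scaled to depth.  The default landscape draws each position's
substitution error mass log-uniformly from [1, 120] per 100,000 reads, gives
the dominant alternate base 80% of it (10%/10% to the others), and makes
each type pure Poisson with probability 0.05, otherwise overdispersed with
ρ ~ U(1.5, 4).  These defaults put ~1/3 of types under mean 1 (the floor
category) and ~82% under 10 per 100k (RER < 0.01%), with a few percent of
the mean ≥ 1 types Poisson — the qualitative composition the method was
built for.  Indel pseudo-types draw mass from [0.5, 300] with ρ ~ U(2, 6),
so roughly half the positions exceed 0.01% indel error.  The four target
loci are pinned: near-zero error for the exon-19 deletion channel (the
template screen eliminates deletion read errors in normals) and for L858R;
Poisson mean 2.6 for L861Q (fitting to λ = 3, threshold 12); gamma-mixed
mean 20, ρ = 3 for T790M (typical fit r ≈ 13, threshold near 60).  The
T790M and L861Q values were chosen analytically so the fitted thresholds
land at the magnitudes the assay design expects for those categories.

`simulate_assay` performs two-stage sampling: mutant input molecules ~
Binomial(5 000, fraction) — the pre-PCR template bottleneck — then
sequencing reads allocated binomially at the realized molecule fraction,
with per-position errors added under the error processes.  PCR amplification
noise beyond the bottleneck is not modeled; the bottleneck alone reproduces
the ~0.3% quantitation floor (15 expected mutant molecules at 0.3% give a
~26% replicate CV, and replicate variance relative to the mean is ~10×
larger at 0.3% than at 3%).  `simulate_reads` emits indexed FASTQ with
planted substitutions or deletion-template reads and a ground-truth
manifest.

**What the simulator does not emulate:** flow-space/homopolymer error
physics, emulsion-PCR bead statistics, quality scores, sample-quality
differences between plasma and cell-line DNA, and correlated errors across
positions.  Passing tests therefore demonstrate the statistical machinery —
model selection, thresholds, quantitation, the counting path — under the
assumed error structure, not sequencer-specific behavior on real data.

## Numerical and testing choices

* Threshold search is a linear scan of the exact survival function from
  k = 0; fitted thresholds are a few hundred at most.
* ⌈·⌉ is applied after rounding to 9 decimals, so a mean that is exactly an
  integer up to float noise is not pushed to the next integer.
* Fraction estimates at depth *d* have binomial noise; tests compare at
  3–4 σ tolerances with fixed seeds, and Monte-Carlo checks of the per-test
  size use 10⁶ replicates.
* Ceiling-recovery of planted Poisson means is only identifiable when the
  mean sits a couple of standard errors (√(m/48)) inside its ceiling
  interval; the recovery test plants such means (0.4, 1.3, 2.5, 3.5).
  Means near integer boundaries cannot be recovered by any estimator at
  panel size 48.
* Problem sizes in the test suite (panel fits at 48 samples, read-level
  runs at 600–3 000 reads, dilution series at counts level) were chosen as
  the smallest sizes at which each property is statistically decidable.

## Known limitations

* The whole-region scan inherits the per-test α without multiplicity
  correction; across ~503 scanned types, panel-estimation error makes some
  false positives expected in practice, as the region-scan false-positive
  test quantifies.  Parameter estimation from larger panels or Bayesian
  shrinkage (not implemented) would be the remedy.
* Single-end, forward-orientation reads only; no quality-aware calling; no
  paired-end merging.
* The internal aligner is exact but not optimized for long references; for
  production-scale alignment, import SAM from a dedicated aligner.
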