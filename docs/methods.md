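# Methods

## Scope and model of the problem

The package treats a multi-center sequencing comparison as a set of
replicate observations of one cohort: the same ten genomes (8 cases, one of
whom is the child of 2 sequenced healthy parents) sequenced independently by
several centers. Agreement between replicates is measured at three levels —
raw reads (k-mer spectrum QC), genotypes (concordance, Mendel transmission,
allele spectra), and derived calls (segmental duplications, long indels) —
and the replicate structure is then exploited for variant prioritization:
genotyping errors rarely replicate across independent pipelines, so
requiring near-perfect cross-replicate genotype agreement is a powerful
error filter for rare-variant candidates.

## Raw-read QC

All read-level QC derives from the canonical 23-mer multiplicity spectrum
(lexicographic min of each k-mer and its reverse complement; windows
containing N are skipped). The estimator proceeds:

* **error boundary** *m*: the first local minimum of distinct-k-mer counts
  scanning multiplicity upward (missing multiplicities count 0, the left
  neighbor of multiplicity 1 is treated as infinite). K-mer instances at
  multiplicity ≤ *m* are attributed to sequencing error; their fraction of
  all instances is the *fraction of k-mers with errors*. A monotone
  decreasing spectrum has no coverage peak and is rejected as
  uninterpretable.
* **peak** *M*: argmax of counts above *m*. The *non-repetitive window* is
  (*m*, 2*M* − *m*], symmetric about the peak, excluding the repeat tail.
* **coverage conversion**: a read of length *L* yields *L* − *k* + 1
  k-mers, so k-mer coverage understates base coverage by (*L* − *k* + 1)/*L*;
  all coverage figures are multiplied by *L*/(*L* − *k* + 1).
* **mean coverage**: the weighted mean multiplicity over the window is
  additionally divided by (1 − error fraction). Erroneous k-mers originate
  from genuinely sequenced bases, so the error-free peak mean tracks only
  the error-free share of coverage; the correction restores total coverage
  and makes the estimate accurate (within ~1% in the tests) even at 1–2%
  per-base error, where the uncorrected peak would be ~20% low.
* **variance coefficient**: window sd / window mean, scale-free, so no
  conversion or correction applies.
* **mode of coverage**: the raw converted peak *M* · *L*/(*L* − *k* + 1),
  deliberately uncorrected — it is the quantity the inclusion gate
  (C ≥ 27) historically thresholds. Note that for a sample at exactly 30x
  nominal coverage with ~0.3% base error the expected mode is ≈ 28, so the
  gate is intrinsically marginal there: the discrete peak falls on 23 or 24
  in k-mer space and the gate outcome can flip between seeds. That is a
  property of the study conditions, not an estimator artifact; real
  passing runs had realized coverages of ~32–36x.

Adapter scanning flags a pair when either mate contains a full adapter
(default TruSeq read-through sequence) anywhere, or an adapter prefix of
≥ 12 bp at its 3′ end, or any N. Adapters are detected, never trimmed.
Quality filtering retains reads with mean Phred ≥ 20 (inclusive) and counts
a pair only when both mates survive.

## Center statistics

Kruskal–Wallis (scipy, standard tie correction) compares a metric across
centers over all sequenced samples. For the shared-sample complete block,
a balanced randomized-block two-way ANOVA is computed by direct sums of
squares; for a balanced design its center-effect F test coincides with the
mixed-model (sample-as-random-factor) F test, so no REML machinery is
needed. Pairwise center comparisons use the paired t on per-sample
differences with a t-based 95% CI, with the paired Wilcoxon p alongside
since it is ambiguous which of the two any given published pairwise p-value
came from. Zero-variance differences are flagged degenerate rather than
tested. Both tests hold their nominal 5% type-I error within [0.03, 0.07]
over 2,000 null simulations of a 6-sample × 3-center table (tested).

## Genome masks

Coordinates are 0-based half-open internally; BED at the boundary; VCF
positions convert at the mask lookup.

*Mappability*: "uniquely mapped" is operationalized as exact canonical
sequence uniqueness — a 151-mer is unique iff its canonical form occurs
exactly once in the canonical 151-mer multiset of the whole reference. A
position is masked when < 0.5 of its covering 151-mers are unique (fewer
k-mers cover positions near sequence ends; the denominator shrinks
accordingly). This is stricter than aligner-based uniqueness, which
tolerates mismatches; it is deterministic and verifiable against a
brute-force per-position substring-count oracle, which the tests do on
random references with planted exact duplications.

*Low complexity*: the union of (a) maximal homopolymer runs ≥ 7 bp, (b)
windows (64 bp, step 32) whose DUST-style trinucleotide score
Σ c(c−1)/2 / (n−1) exceeds 2.0, and (c) an optional external repeat
annotation BED (full repeat annotation is an external tool's job and is
consumed, not recomputed). Every interval gets 10 bp flanks, clipped to
sequence bounds, then merged.

## Variant handling

Genotypes are unphased allele-index pairs; the legacy clinical-table coding
(1 = reference, 2 = alternative) is translated at I/O by
`parse_genotype(..., allele_offset=1)`. Normalization splits multiallelic
records (other alternatives collapse to the reference index), verifies the
reference allele (mismatches are dropped and reported), and left-aligns to
the minimal leftmost representation. The SNV hard filter applies strict
inequalities exactly as stated (QUAL > 40, GQ > 20, DP > 10, SP < 20); the
per-sample FORMAT thresholds default to every-non-missing-sample-must-pass
(the call sets are jointly genotyped), with an "any" mode exposed. A site
with a FORMAT field missing in all samples fails that criterion. The
long-indel chain takes |len(ref) − len(alt)| ∈ [20, 100] inclusive and
requires the minimum over non-missing per-sample GQ to exceed 20. Every
chain emits a ledger whose adjacent steps must agree on counts (asserted).

## Copy number and segmental duplications

Window copy number is 2 · depth / mean(control depth), which pins the
control mean at exactly 2. The "correction for dispersion" in the
duplication definition is operationalized as the threshold
mean + k·sd over control windows, k = 3 by default. Above-threshold
windows merge when genomically consecutive; a missing (masked) gap of up to
one window is bridged, but an evaluated below-threshold window always
breaks the run. Merged runs must span ≥ 10 kb (the stated definition; a
1 kb variant of the rule appears elsewhere, so the span is a parameter with
10 kb as default). Case-specific duplications are regions duplicated in at
least `min_cases` (default 2) case samples and in no healthy sample, where
any shared base counts as overlap.

## Prioritization

The filter chain and its defaults: high-confidence LoF; every present
population frequency ≤ 0.01 with absence counting as rare (a causal variant
may be absent from databases precisely because it is rare); ≥ 2 alternative
alleles over cases *or* any homozygous case (a homozygous case carries two
alleles, so the bypass only matters if the count threshold is raised);
parental alternative alleles = 0, relaxed to ≤ 2 only when the trio child
carries the variant (a transmitted allele must sit in a parent); replicate
concordance ≥ 0.98, where concordance is the fraction of concordant
unordered replicate-pair genotype comparisons pooled over individuals —
pooled, because a single individual contributes at most
C(replicates, 2) pairs, too few for a per-individual rate. Exclusion
reasons use first-failing-step attribution, making the ledger conservative:
retained + excluded = input, always.

## The synthetic cohort

The generator's defaults are the study conditions: 150 bp pairs at 30x with
400 ± 30 bp inserts on a 100 kb (configurable) reference; 0.3% per-base
error (chosen to reproduce the observed ~7% erroneous-23-mer fraction);
0.5% adapter read-through and 0.1% N pairs (≈ 99.4% clean pairs); 0.55%
low-quality reads (≈ 98.9% retained pairs); a 10-sample cohort (8 cases,
2 healthy parents, one trio); 0.3% Mendel-error rate (the observed range
was 0.27–0.58%); 1% per-center genotype discordance — a free parameter, as
no inter-center error model was published. Qualities are two-state (Q35 /
Q12) because only the mean-Q ≥ 20 gate consumes them. Allele frequencies
are Beta(0.5, 2), skewed rare. The trio child's genotypes follow Mendel
transmission except at planted violations; a planted "violation" is always
a genuinely inconsistent genotype (sites where all genotypes are consistent
with the parents are left untouched), so the independent Mendel check
reconciles exactly with the plant log.

Two deliberate structural choices make the prioritization recovery test
sharp. First, the planted causal site is never corrupted when replicates
are built — it models a real variant that replicates perfectly across
platforms. Second, rare database frequencies are assigned only to
background variants carried by a parent *and not by the trio child*; all
other background variants receive a common (≥ 0.02) frequency. Under the
filter chain this guarantees every background variant fails at least one
step, so the planted causal is the unique prioritizable signal and any
additional retained variant is a genuine false positive of the
implementation. Corruption of a background variant in one replicate drops
its pooled concordance to ≈ 0.93 (2 broken pairs of 30), comfortably below
the 0.98 gate.

CNV window noise is drawn at a fixed magnitude relative to the diploid
depth (coefficient `cn_dispersion`, default 0.15 → control copy-number sd
0.3) and the expected depth is scaled by cn/2 — modelling technical
window effects (GC, residual mappability) that do not grow with copy
number. With proportional noise instead, a single sub-threshold window
inside a true duplication would split it below the 10 kb span and recovery
would be luck; the additive model keeps the probability of such a break
below 10⁻³ per window at CN 4.

What the generator does **not** emulate: haplotype structure and linkage
disequilibrium, per-cycle quality decay, indel-specific error profiles,
alignment artefacts, and real repeat families (the reference is i.i.d.
random plus planted features). Passing tests therefore demonstrate the
correctness of the computations and the recoverability of planted signals
under controlled noise — not performance on real genomes, where masks,
discordance rates and LoF annotation quality are all harder.

## Problem sizes

Tests and the acceptance script run on 20–120 kb references, ~5,000 read
pairs, 1,000–5,000 variant sites, 10-seed grids and 1,000–2,000-simulation
calibrations — sizes chosen so the full suite completes in well under a
minute of compute per stage while every statistical check retains enough
resolution to fail loudly (binomial and 3·SE bounds are asserted where
rates are recovered).

## Known limitations

* Exact-match mappability is stricter than mismatch-tolerant aligner
  uniqueness; masks on real genomes would be smaller than an aligner-based
  track.
* The microarray is simulated as an error-free truth subset by default;
  real arrays have their own error mode.
* Replicate concordance treats a record absent from one replicate as
  missing genotypes (no pairs) rather than homozygous reference; the
  alternative convention is reasonable and would penalize dropped records
  harder.
* `min_span`, `k_sigma`, `min_cases` and the per-sample FORMAT pass mode
  are exposed because the published procedure leaves them ambiguous; the
  defaults follow the stated definitions.
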