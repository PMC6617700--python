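# Methods

This note documents the statistical procedures, their assumptions, the
tunable parameters, and the design choices made where the procedure was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Composition conventions

A coding sequence is read as non-overlapping frame-0 triplets. Three
denominators coexist and are kept strictly apart:

* the **61-entry percentage profile** divides each sense codon's count by
  the number of *sense* codons, so the profile sums to 100;
* **GC3% and AU3%** divide by the *total* codon count (stop included) with
  stop codons excluded from both numerators, so
  GC3% + AU3% + stop-fraction = 100. This is the unique convention under
  which a 117-codon transcript with 85 G/C-ending and 31 A/T-ending sense
  codons reads 72.65% / 26.50% — the VAMP2 anchor the test suite pins.
  The sense-only variant is available as an option; for typical lengths
  the two differ by well under one percentage point.
* ATG and TGG count toward the GC3 numerator (they end in G); they are
  excluded from the *correlation* codon set (below) because their
  per-amino-acid fraction is identically 1.

The bundled `data/vamp2_synthetic.fa` is a synthetic stand-in: it encodes
the human VAMP2 protein with synonymous codons chosen deterministically to
reproduce exactly that 85/31/117 wobble composition. It anchors the
counting convention, not the nucleotide-level sequence.

**FWHM.** The GC3 histogram spans [0, 100] at a configurable bin width
(default 1 point), optionally smoothed by a 3-bin moving average; the full
width at half maximum interpolates the half-maximum crossings linearly on
both sides of the global mode. A point-mass distribution has no width and
reports FWHM as undefined rather than one bin.

**Codon–codon correlations** use per-amino-acid synonymous fractions
(Ala's GCC as a fraction of all Ala codons, etc.) over the 59 codons of
degenerate families, Pearson across genes with pairwise-complete handling
of genes lacking an amino acid; zero-variance codons give NaN rows, never
silent zeros. The split-half control halves each sequence by codon index
(stop stripped, extra codon to the first half) and correlates codon *i* of
first halves against codon *j* of second halves.

## CEC, employment shift, CorrCEC

The codon employment coefficient of codon *c* in one sample is the Pearson
correlation, across genes, between the 61-codon percentage of *c* and the
transcript abundance. Abundances are log2(1+x)-transformed by default
(`--transform raw` disables this): expression spans orders of magnitude
and raw-scale Pearson is dominated by a handful of transcripts. Cohorts
aggregate per-sample CEC vectors (mean ± SEM, undefined entries excluded
pairwise); computing one CEC on the cohort-mean abundance is an option.

The employment shift is the per-codon relative change
100·(CEC_dis − CEC_ctrl)/|CEC_ctrl| averaged separately over AU3 and GC3
sense codons. The absolute-value denominator preserves the direction
semantics (positive AU3 shift = employment moved toward AU3) regardless of
the control coefficient's sign; codons with |CEC_ctrl| < ε (default
ε = 0.01) are excluded and reported. Because control CECs are small
numbers, relative shifts of ±100–200% are normal on strong-effect cohorts.

CorrCEC correlates each transcript's 61-codon composition with the control
and disease cohort CEC vectors; the scalar score is
r_disease − r_control (the alternative — correlating against the CEC
difference vector — is available as `scalar="delta_corr"`). Swapping the
cohorts negates every score exactly.

## Pre-ranked enrichment

Genes are ranked by log2(GC3 / mean GC3) over the analysed set, ties
broken lexicographically, zero-GC3 genes excluded. For each set a weighted
running sum is computed over the ranking: hits increment by
|score|^w / Σ_hits |score|^w (default w = 1), misses decrement uniformly
by 1/(N−k); the enrichment score is the extremum of the running sum
(∈ [−1, 1]), its leading edge the member genes at or before (after, for
negative ES) the extremum. The null permutes gene labels — equivalently,
draws random k-subsets — and is shared between sets of equal effective
size; p-values are two-sided against the signed null with numerical ties
counted as extreme, and BH controls the FDR across sets. Sets with fewer
than 5 or more than 500 members present in the list are skipped. NES
divides ES by the mean |null ES| of same-sign permutations.

GP1 is the union of (leading-edge, by default) genes of significant
negative-ES sets at the FDR cut (default 0.01), GP2 the positive side;
genes landing in both are excluded from both. Note a structural limit of
leading-edge derivation: when a set's members are statistically
exchangeable with equally extreme non-members — exactly the situation the
synthetic generator creates — a rank-based leading edge cannot separate
members below the running-sum extremum from the rest, so full-membership
derivation (`use_leading_edge=False`) is the mode to use when the goal is
recovering planted or curated group lists, and is what the recovery tests
use; leading-edge remains the default for exploratory work on real gene
sets, where members are not exchangeable with non-members.

The robustness protocol adds, per replicate, independent uniform noise of
±δ percentage points to every gene's GC3% (clipped to (0, 100];
multiplicative mode behind a flag), re-ranks, re-runs the enrichment, and
counts sets significant in at least `min_hits` of `n_reps` replicates
(defaults 5 of 5). At δ = 0 all replicates are the same analysis, so one
run suffices and the count equals the unperturbed significant count.

## Scenario models

Both scenarios start from a measured (or generated) control cohort.
*Causal*: each gene's abundance is multiplied by 2^(β·(AU3−mean AU3)/100)
— composition drives expression, with graded magnitude everywhere.
*Effect*: GP1 genes are multiplied by a uniform fold (default 2),
everything else is untouched. Multiplicative log-normal noise (log2-scale
SD `noise_sd`) is applied per gene and sample in both. The two models are
made comparable by calibrating β so the causal model's all-genes AU3 shift
matches the effect model's (bisection on the noise-free shift) — the only
fair contrast, since the all-genes shift is the statistic they share.

The discriminating measurement recomputes the employment shift three
times, with CECs restricted to all genes, GP1 only, and the complement.
Under the effect model a uniform fold cancels inside GP1, so the GP1-only
shift is statistically a null draw; under the causal model the
composition gradient survives restriction to any subset. "Null draw" is
made precise by generating β = 0 cohorts over seeds and using the
empirical 97.5% envelope of the |GP1-only shift|; the paired comparison
(causal GP1-only shift exceeds the effect model's, over seeds) is the
sharpest version of the contrast and is what the acceptance suite counts.

## Diagnostics

Per-sample CEC vectors are computed once on the scoring subset (GP1 by
default). On each training split the model is (i) the unit-normalised
disease-mean minus control-mean CEC vector (the reference direction) and
(ii) a scalar cutoff on the score axis, where a sample's score is the
Pearson correlation of its CEC vector with the reference direction.
Cutoff rule: midpoint of the training class score means (default) or
Youden's J maximiser. Splits are stratified 80/20 and repeated (1000 in
the reference protocol; the test suite uses 200 and states so); test
samples never enter direction or cutoff fitting, which the suite asserts
structurally by poisoning held-out rows. A per-patient mean-CorrCEC score
is available as an alternative scalarisation.

Cross-study transfer fits once on the full training cohort and evaluates
once on the test cohort. Noise robustness multiplies every abundance
value by a factor drawn log-uniformly from [1/f, f] (symmetric "up or
down" on the fold scale), recomputes the CECs and re-runs the resampled
evaluation; f = 1 reproduces the clean run exactly because split seeds
reuse the caller's seed.

## The synthetic generator

`GenomeSpec` draws per-gene GC3 targets from a two-component normal
mixture (35 ± 6 and 70 ± 6 percent, weights 0.4/0.6 — the two peaks of the
human GC3 histogram), gene lengths log-normal (median 300 codons, log-SD
0.35, floor 60), amino acids from a bundled human-like frequency table,
ATG first and a uniform stop last. Each synonymous codon's wobble class is
G/C-ending with a probability corrected for the forced-GC positions (Met,
Trp have no A/T-ending codon), so realized composition matches the target
on average. GP1 (10% of genes) is planted from the low-GC3 component, GP2
(10%) from the high one.

`CohortSpec` generates log2 abundances
`base_g + c_s·(GC3_g − mean)/100 [+ b_s·(AU3_g − mean)/100] + noise` with
per-gene baselines N(5, 1.5), per-sample couplings c_s ~ N(5, 1) — normal
tissue prefers GC3 codons — and per-sample disease shifts b_s ~ N(β, 1),
β = 9 in the strong-effect preset and 3 in the weak one (presets
calibrated once to the near-perfect and the ~85% diagnostic regimes,
respectively). Two noise features beyond the iid per-gene/per-sample term
(SD 0.5 inside GP1/GP2) make the cohorts behave like real studies rather
than idealised ones:

* genes outside GP1/GP2 get 3× the iid noise — their expression is
  dominated by programs unrelated to codon composition;
* non-group genes are partitioned into 10 blocks, contiguous in GC3 rank,
  each receiving an independent N(0, 2.5) per-sample offset. Real
  co-regulated programs are composition-coherent (that is the central
  phenomenon), so pathway-activity and tissue-composition variability
  perturbs the whole-transcriptome CEC in a way that does not average out
  with gene count. Without these two features every scoring subset
  separates cohorts perfectly and whole-transcriptome scoring would
  always dominate subset scoring — i.e. the generator would not emulate
  the regime in which restricting to GP1 is worth doing.

An optional `base_seed` shares the per-gene baselines between two
generated cohorts, emulating cross-study transfer in which the biology is
common but scale, patients and noise differ.

`recover_generator_coefficients` re-estimates β and the control coupling
by single-covariate least squares (the centred GC3 and AU3 fractions are
near-perfectly anti-correlated, so a joint fit is ill-conditioned);
standard errors combine the regression SE with the between-patient spread
of per-sample slopes, which is what makes the 2-SE recovery checks
honest under the random-slope model.

**What passing tests show, and what they do not.** The generator emulates
composition-coupled expression, graded per-patient effects and structured
non-compositional variability; it does not simulate read-level counts,
platform-specific normalisation artefacts, tRNA pools, or the correlation
of codon composition with gene function beyond the planted groups.
Green tests demonstrate the machinery is correct and that the analysis
recovers the structure it assumes when that structure is present — not
that any particular real cohort contains it.

## Numerical choices and degenerate inputs

Pearson helpers flag exactly-constant vectors as undefined explicitly
(float summation of identical values need not centre to zero). Undefined
CEC entries propagate as NaN and are excluded pairwise, never imputed.
Permutation p-values use the add-one estimator (1 + #extreme)/(n + 1).
All 61-entry vectors and file columns use the fixed alphabetical codon
order (AAA … TTT, stops excluded); TSV output prints 6 significant digits
so byte-identical rerun checks are meaningful. Single master seeds derive
all per-replicate seeds; identical seeds give identical outputs, including
byte-identical FASTA and pipeline artifacts.

Problem sizes used by the test and acceptance suites — 1200-gene genomes,
25 + 25-sample cohorts, 100-seed scenario batteries, 200-repetition
diagnostics, 500–1000-permutation enrichments — are the package's chosen
reference conditions; every routine accepts larger inputs unchanged.

## Known limitations

* The enrichment engine is a standard weighted running-sum implementation;
  it stands in for whichever engine a user may prefer, and the ranking,
  robustness protocol and group derivation are the parts this package is
  opinionated about.
* The employment shift's relative scale is sensitive to the ε floor when
  control CECs sit near zero; the per-codon table reports exclusions so
  users can judge.
* Leading-edge group derivation under-recovers planted groups whose
  members are exchangeable with non-members (see above).
* The diagnostics report sensitivity/specificity at the trained cutoff
  only; ROC/AUC summaries are an easy extension left out deliberately.
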