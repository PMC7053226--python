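# Methods

This note documents the statistical models behind `ccpevolve`, the design
of the bundled simulator, and the numerical choices made where the
procedure was genuinely open. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## The inference problem

Four populations descend from one pooled founding population and evolve
independently for ~10 generations in a predominantly selfing crop. The
questions are (i) whether the locations diverged (differential selection),
(ii) whether allele frequencies moved further from the founder than drift
alone allows (shared selection), and (iii) whether those movements are
explained by the alleles' phenotypic effects, especially on plant height.
Answering (ii) requires the founder frequencies and the effective
population size; neither is observed directly, so both are reconstructed.

## Virtual founding population

The founder is rebuilt from the crossing scheme: each cross of homozygous
parents i and j contributes n_ij = round(s_ij / Σs_ij · N_virtual) copies
of its F1 heterozygote (default N_virtual = 10,000, rounding half-to-even,
no re-normalization — the total may miss N_virtual by at most
n_crosses/2). Holding F1 heterozygotes rather than segregating F2s leaves
expected allele frequencies identical, which is all downstream stages use.
Heterozygous parental calls are rejected by default (parents are fixed
lines); an override uses the first-listed allele. A parent-proportional
mixing variant is provided and agrees exactly when every parent
contributes equally to its crosses (tested).

Marker recoding: alleles absent from the parental set are removed
record-wise (the individual's other loci are kept) — with no mutation or
migration these are genotyping artifacts or pollen contamination, assumed
unbiased. Each SSR locus is then collapsed to {most frequent allele in
FND, OTHER}; ties are broken lexicographically and logged. The same
recoding map applies to every population and generation, so "frequency"
always means the frequency of the frequent-in-FND allele.

## Gene diversity and differentiation

Gene diversity is Nei's H_e = 1 − Σp_k², computed on the multi-allelic
allele set (before collapsing — pooling alleles necessarily deflates H_e),
averaged over loci, with 95% percentile intervals from resampling loci
with replacement (default 5,000 draws). The small-sample correction
2n/(2n−1) is available behind `corrected=True`; the uncorrected form is
the default because it is the quantity whose Hardy–Weinberg-heterozygosity
identity motivates the statistic.

Differentiation is the Weir–Cockerham estimator for diploid biallelic
data: per-locus variance components a (among populations), b (among
individuals within populations), c (within individuals), computed from
sample sizes, allele frequencies and *observed* heterozygote proportions —
important here, because selfing populations are far from Hardy–Weinberg
and estimators that assume HWE would misattribute variance. The multilocus
value is the ratio of sums Σa/Σ(a+b+c), never the mean of per-locus
ratios; negative per-locus values are retained. CIs again come from the
locus bootstrap (ratio-of-sums statistic). The estimator is verified in
the tests against an independent gene-copy nested-ANOVA implementation to
1e-12, and against its drift expectation θ ≈ 1 − (1 − 1/(2Ne))^t on
island simulations.

## Outlier scan

The neutral null for "is this locus more differentiated than drift
allows?" is simulated forward under a finite island model: d demes
(default 100) of N diploids (default 100), migration toward the
metapopulation mean at rate m, binomial drift of 2N gene copies, ancestral
frequency uniform on (0.02, 0.98), 50 warm-up generations. m is calibrated
analytically from the recursion F' = (1−m)²(1−1/(2N))F + 1/(2N) so the
quasi-equilibrium differentiation equals the observed neutral multilocus θ
(a target below the m = 0.5 drift floor 1/(2N)/(1 − 0.25(1−1/(2N))) is a
parameter error). With 20,000 simulated loci the realized mean θ lands
within 0.002 of the target (tested at 0.009). Samples of the same size and
deme count as the data are then scored with the *same* Weir–Cockerham
estimator.

Per observed locus, the empirical p-value is the share of null loci with
heterozygosity within ±0.05 of the observed pooled H_e whose θ is at least
as large, with the (r+1)/(n+1) convention (never exactly zero); windows
with fewer than 100 null points widen stepwise and are logged. A locus is
flagged only when p < 0.05 **and** its θ exceeds the multilocus value —
the high tail only. On neutral data the pooled p-values are uniform (KS
below the 1% critical value) and flag counts stay inside the binomial
alpha = 0.05 envelope (tested over 100 simulated 28-locus panels).

## Effective population size

Two routes, deliberately different in their drift clocks:

**Pair-sampled F_ST.** For populations that split t generations ago,
Ne = t / (4·ln(1/(1 − F_ST))). This inversion is exact when F_ST is the
*pair-sampling moment estimator*: per pair of populations, the among-pair
variance with divisor 2, (p1 − p2)²/4, over the pooled heterozygosity
p̄(1 − p̄), summed over loci (ratio of sums) and averaged over pairs. Its
drift expectation is ≈ t/(4Ne), matching the formula's denominator. The
Weir–Cockerham θ has drift expectation ≈ t/(2Ne) — twice as large — so
feeding it through the same formula would halve the estimate; that is why
the package computes F_ST *for Ne estimation* with the pair-sampling
moment estimator while keeping Weir–Cockerham θ as the differentiation
measure everywhere else. On neutral simulations with a known drift target
of Ne = 200 (t = 8, four populations) the median estimate over 50
replicates falls within the expected recovery band (tested); the residual
downward bias comes from finite-sample noise in (p1 − p2)², which is not
corrected.

**Temporal method.** Nei–Tajima Fc = (x − y)²/((x + y)/2 − xy) per locus
between two sampled generations, averaged over loci (loci identically
fixed at both time points are 0/0 and drop out), with the sampling-plan-II
correction: Ne = t / (2·(Fc − 1/(2S_early) − 1/(2S_late))). A corrected
denominator ≤ 0 means the drift signal is below sampling noise and is an
error, not an estimate. Caveat stated plainly: the 1/(2S) corrections
assume outbred samples; in a selfing population the two gene copies of an
individual are nearly duplicates, the effective number of independent
copies is closer to S than 2S, and the estimator under-corrects —
temporal estimates therefore run low relative to the F_ST route on
selfing data (visible in the worked example). On realized census
frequencies (no sampling), the estimator recovers the simulator's drift
target within ~2%.

## Drift bands and selection flags

The drift-null band for a locus with founder frequency p after t
generations at effective size Ne is p ± z·sqrt(p(1 − p)·[1 − (1 −
1/(2Ne))^t]), clipped to [0, 1], with z the normal quantile of the
confidence level. The bracketed term is the variance of the allele
frequency under pure drift; the square root is essential — adding a
variance to a frequency would mix units. Bands are evaluated at a grid of
effective sizes (default {150, 250}) so the conclusion's sensitivity to Ne
is visible, with t equal to each sample's own generation count.
Wright–Fisher simulation (10,000 binomial trajectories, 2Ne = 300,
p0 = 0.5, t = 10) puts the empirical coverage of the 95% band at ~95.2%
(the acceptance script recomputes this). Loci outside the band in the
same direction in every population enter the consistency summary, with a
toward/away-from-wild-type annotation at functional loci.

## Marker–trait association

Mixed stand (single plants): per locus and trait, only homozygotes at the
tested locus enter (heterozygotes are excluded at that locus only), and
y = μ + allele-class + trial + allele×trial + ε is fit by REML with the
class effect fixed and the rest random. The additive allele effect is half
the frequent-homozygote minus other-homozygote difference; significance is
an F test with Satterthwaite denominator df. The REML engine profiles the
variance ratios through the Woodbury identity (all solves are q×q in the
number of random levels), takes the gradient of Var(c'β) and the REML
Hessian numerically for the Satterthwaite df, and on a fitted variance
collapsing to zero drops the term and refits (logged) — the singular-fit
fallback. It reproduces lme4/lmerTest estimates, standard errors,
Satterthwaite df and p-values on fixed fixtures to ≤0.1% (frozen-oracle
tests). With a single trial the model reduces to the fixed two-class fit,
where the balanced case returns exactly half the class-mean difference.

Pure stand (parent varieties in plot trials): variety LS-means first, from
y = μ + block-in-trial + variety + trial + variety×trial + ε (variety
fixed; equal trial weights, i.e. the cell-means GLS coefficients —
verified against emmeans), then a fixed one-way regression of the LS-means
on allele class; all varieties in one class is an error. Correlations
between per-locus Δp (FND to final generation; "overall" = the
across-location mean of final-generation frequencies) and additive
effects, and between effect vectors, are Pearson r with the two-sided
t-test on df = L − 2 and stars at 0.05/0.01/0.001.

Sign convention: every effect and every Δp refers to the frequent-in-FND
allele. Re-designating the reference at one locus flips that locus's
effect and Δp exactly and leaves its p-value unchanged; re-designating the
whole panel leaves every correlation exactly invariant. (Flipping a single
locus does *not* leave a Pearson correlation exactly invariant — the
joint negation of one data point moves both means — so the invariance is
stated, and tested, in these two exact forms.)

## The simulator

`synthetic_ccp` emulates the study system: 20 homozygous parents, 93
crosses with Beta-distributed seed counts on [37, 2,569] targeting a mean
of 957, a 28-locus panel (20 SSR loci from 18 markers — two markers
amplify two loci — at 4 alleles each, plus 8 biallelic functional loci
whose first allele is wild-type), the pooled F2 shared by all locations
(generation 2), then independent per-location evolution to generation 10
at selfing rate 0.98 with census 32,000 and drift target Ne = 200, samples
of 150/250/500 individuals at generations 3/6/10, and phenotypes: mixed-
stand single-plant values y = genetic value + trial + residual at the two
"organic" locations in generations 6 and 10, and pure-stand plot values
per variety × 12 trials × 3 blocks. Default additive architecture: height
gains ~5–6 cm per wild-type Rht allele copy (residual sd 10 cm, trial sd
5 cm), heading delayed ~3 d per photoperiod-sensitive Ppd-D1 copy.
Selection enters as fecundity weights ∝ exp(Σ s·dosage) on named loci;
`height_selection()` gives the shared height-mediated regime.

Drift is imposed, not emergent: each generation samples m =
round(target_Ne·(1 + F̂)) parent slots with replacement (fecundity-
weighted) and gives each slot an equal share of the census offspring,
where F̂ is the census inbreeding coefficient (1 − observed/expected
heterozygosity, pooled over loci). Sampling whole individuals from an
inbred population inflates allele-frequency variance by (1 + F); the
correction keeps the per-generation drift variance at p(1 − p)/(2·
target_Ne) for any selfing rate, so every parameter-recovery test has a
known truth. Realized temporal F on census frequencies recovers the
target within ~2%; replicate-population Var(p_t) matches the
Wright–Fisher formula within 10% (tested at 500 replicates). Offspring
are produced by selfing with probability `selfing_rate`, otherwise by
uniform outcrossing among the parent slots; loci are unlinked; there is
no mutation and no migration, so novel alleles never arise — matching the
analysis's filtering assumption.

What the simulator does *not* emulate: linkage (SSR/gene loci on shared
chromosomes), explicit plant-to-plant competition (selection is reduced to
per-locus coefficients), spatial structure within a field, genotyping
error, and year-to-year environmental trends beyond i.i.d. trial effects.
Passing tests therefore demonstrate the statistical machinery under the
stated drift/selection model, not robustness to those realities.

## Problem sizes and determinism

Defaults follow the study scale (5,000 bootstrap draws, 20,000 null
simulations with 100 demes, census 32,000, virtual founder 10,000). The
test suite and the worked example run the same code at reduced sizes
(census 2,000–3,000, 300–2,000 bootstrap draws, 2,000–20,000 null
simulations, 25–60 replicate datasets), chosen so each stochastic check
retains a comfortable margin over its Monte-Carlo noise. All randomness
descends from a single root seed (`RunConfig.rng_seed`) split per stage
via `numpy` seed sequences; a fixed seed makes every pipeline output
byte-identical across runs (tested).
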