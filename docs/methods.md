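# Methods

## Data model

An SSR genotype table holds, per sample and locus, a multiset of up to
`ploidy` integer allele calls (fragment sizes in bp).  Allele identity
is the exact integer size; no binning is applied.  The missing sentinel
is `0` in an allele slot; a genotype is MISSING at a locus iff all its
slots are `0` (the GenAlEx convention).  Because allele dosage in
autotetraploids cannot be read from peak data, the canonical downstream
encoding is **allele presence**: one 0/1 column per observed
(locus, allele) pair, with cells of MISSING genotypes masked.  This
choice is what makes the haploid/binary gene-flow transform
`Nm = (1 − Φ)/(2Φ)` the appropriate companion to PhiPT — it is the only
transform consistent with every PhiPT→Nm pair in the reference report's
tables (the diploid transform `(1/Φ − 1)/4` is available behind a
flag).

## Diversity indices

* `H` (Shannon–Wiener) is computed over **genotype-class** proportions,
  where a class is the unordered multiset of calls; `GD` (Nei) over
  **allele** frequencies.  The split follows the index definitions'
  own symbols: `pᵢ` is a genotype proportion in H and an allele
  frequency in h.
* H is reported in nats.  A log-2 variant is available via the
  `base` argument, but the evenness formula
  `E5 = (1/λ − 1)/(e^H − 1)` pairs H with `e^H` (Stoddart–Taylor form),
  which forces natural log for internal consistency.
* Nei's correction `n/(n−1)` uses `n` = observed gene copies at the
  locus.  The alternative literal reading (`n` = distinct alleles) is
  exposed via `n_convention="distinct"`; the gene-copy convention is the
  standard small-sample correction and the default.
* Missing genotypes are excluded from both genotype-class and allele
  proportions; no imputation enters the diversity statistics.
* Group summaries report Na and Ng as mean ± sd (sample sd, n−1) over
  loci; groups of fewer than 2 samples are flagged with undefined GD.

## Distance AMOVA

Squared Euclidean distances between allele-presence rows (equal to
allele mismatch counts when nothing is missing).  Masked cells are
mean-imputed per column before distances (the "interpolate" behaviour
of the standard implementation); columns masked everywhere are dropped
with a warning.  The one-way partition uses

    SS_total  = (1/N)·Σ_{i<j} d²,   SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²,
    n0 = (N − Σ n_g²/N)/(k−1),      Va = max(0, (MS_among − MS_within)/n0).

Negative Va estimates are truncated to zero, keeping PhiPT in [0, 1];
in the fully degenerate case (all samples identical) PhiPT is 0 by
convention.  On one-dimensional data these sums of squares coincide
exactly with textbook one-way ANOVA (verified against a brute-force
oracle in the tests).

Significance: whole-sample label permutation with group sizes fixed,
`p = (#{Φ_perm ≥ Φ_obs} + 1)/(n_perm + 1)`, one shared seeded RNG
stream.  Type-I error at α = 0.05 is calibrated to 0.05 ± 0.02 over 500
null panels in the test suite.  Stars follow the usual thresholds
(*** p < 0.001); note that with 999 permutations the smallest
achievable p is exactly 0.001, which prints as **.

Pairwise PhiPT/Nm matrices re-run the one-way analysis on each group
pair's sample subset, with distances (and imputation) recomputed within
the subset.

## Admixture model

The sampler operates on the binary allele-presence matrix: sample i has
admixture proportions q_i over K clusters; cluster k has a Bernoulli
presence frequency f_kj per column; each observed cell draws its
cluster of origin z_ij ~ Cat(q_i) and then x_ij ~ Bern(f_{z_ij},j).
Priors q_i ~ Dir(α·1), f_kj ~ Beta(β, β); all updates are conjugate.
Masked cells are skipped.  This is a deliberate simplification of the
classical Bayesian clustering programs — one binary observation per
allele column, no diploid phase, no correlated-frequencies model, no α
inference — chosen because dosage-free polyploid SSR data reduce
naturally to allele presence and because a desk-scale, fully testable
sampler is worth more here than an untestable replica.

**Choice of α.**  The default is α = 0.1.  A flat α = 1 prior shrinks
the admixture proportions of genuinely unadmixed individuals toward the
simplex interior by a margin that no amount of sampling removes (on
separated two-population panels the posterior-mean q plateaus ~0.13
away from the one-hot truth).  The classical programs avoid this by
inferring α from the data, where it typically converges well below 1 on
structured collections; a small fixed α emulates that behaviour while
keeping the sampler simple.

Label switching within a chain is resolved by matching each recorded
draw's frequency matrix f to the first post-burn-in draw (Hungarian
assignment on row-wise L2 distance) before averaging.  The recorded
log-likelihood is the mixture form `Σ ln Σ_k q_ik f^x (1−f)^(1−x)`.

`L(K) = mean(lnL) − var(lnL)/2` (variance with n−1 denominator);
Evanno's ΔK is the mean over runs of `|L(K+1) − 2L(K) + L(K−1)|`
divided by sd(L(K)), defined for interior K only, NaN where the sd is
zero.  Membership: label = argmax q (ties to the lowest index);
admixed iff max q ≤ 0.8 (the threshold itself counts as admixed).

Reference chain lengths for real panels are 50,000 burn-in + 500,000
iterations; the package defaults (1,000 + 10,000, thin 10) and the test
suite's shorter chains (≈200 + 800) are desk-scale settings at which
the separable-recovery and ΔK checks are already stable.

## DAPC

PCA by SVD of the column-centred (optionally scaled) matrix; masked
cells mean-imputed.  Cluster detection runs k-means (squared Euclidean,
10 restarts, deterministic per-K seeds, empty-cluster repair as
implemented by scikit-learn) on the retained PC scores and scores each
K by `BIC(K) = N·ln(W_K/N) + K·ln(N)`, taking the minimum.  The penalty
is isolated so an alternative is a one-line change; note it is
calibrated for PC-score matrices of moderate dimensionality — in very
low dimension k-means reduces noise WSS fast enough to over-split.

Discriminant axes solve the generalized eigenproblem `Sb a = λ Sw a`
with a ridge term `1e−8·tr(Sw)/p·I` on the within-group scatter (also
covering single-member groups, with a warning); axes are
Sw-orthonormal, at most `min(K−1, n_pcs)` of them.  Prediction is
nearest centroid in LD space with Gaussian posterior weights.
Cross-validation uses repeated stratified holdout (default 30 × 10%,
held-out size raised to the number of groups when necessary) and
recommends the PC count with the highest mean success, ties going to
fewer PCs.

## Synthetic panels

The generator emulates a genebank collection: 482 accessions from seven
origins (sizes 29, 42, 48, 122, 60, 41, 140), 24 SSR loci with 4–20
alleles each, tetraploid genotypes as four independent allele draws,
2% of genotypes missing completely at random.  Divergence is
Balding–Nichols: ancestral per-locus frequencies from a symmetric
Dirichlet; each latent subpopulation from `Dir(p·(1−F)/F)` with
F = 0.025; each origin from its subpopulation with a smaller
within-subpopulation F (0.005–0.008).  One origin (PER) carries the
second, wild-relative-like subpopulation; 5% of samples are admixed
with q ~ Dir(1).  These defaults were calibrated once so that a one-way
AMOVA by origin attributes a few percent (~3%) of variance to
among-origin differences — the weak structure such collections show —
and are not test-tuning knobs.

What the generator does **not** emulate: stepwise mutation (allele
sizes are an arbitrary ladder), linkage between loci, dosage-dependent
scoring error, null alleles (except in the dedicated diploid test
construction), and pedigree relatedness.  Passing recovery tests
therefore demonstrate correctness of the estimators under the F-model,
not robustness to these real-data features.

## Pedigree counting

Cross strings split on a standalone `x`/`×` at parenthesis depth 0;
parenthesised sub-crosses stay opaque single parents.  Names are
whitespace-collapsed but never fuzzy-matched (curated passport typos
are preserved, not corrected).  Every mention counts; co-usage edges
are undirected, weighted by the number of shared crosses, with no
self-edges.

## Numerical conventions and limitations

* Report rounding: SS/MS/Va/PhiPT/Nm to 3 decimals, percentages to
  whole numbers, diversity tables to 2 decimals; full precision kept
  internally.
* The Brookfield estimator-1 null-allele frequency
  `r = (He − Ho)/(1 + He)` (diploid coding only) is a moment estimator
  with a known downward bias that grows with the true null frequency;
  it is accurate for moderate r (the test exercises r = 0.1).
* The permutation statistic is the truncated PhiPT; ties at zero make
  the test conservative only when the observed statistic is itself
  zero.
* Hierarchical (multi-stratum) AMOVA, rarefaction, bootstrap CIs,
  a-score optimization and image rendering are out of scope.
* All stochastic components take explicit seeds; identical seeds give
  bit-identical outputs (files included).
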