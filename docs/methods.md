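# Methods

`restogen` re-implements, as a tested library, the population-genomic
analysis used to evaluate large-mammal translocation programs: admixture
inference from genotype likelihoods, diversity and differentiation
statistics from posterior genotype dosages, spatial isolation-by-distance
tests, and a translocation-history simulator that provides ground truth for
all of it. This note documents the models, the defaults and why they were
chosen, and the limits of what the tests demonstrate.

## The admixture model

The core model is the structure-style correlated allele-frequency admixture
model extended to genotype uncertainty (the entropy approach). Each
individual i carries a simplex ancestry vector q_i over k clusters with a
Dirichlet(α) prior (α = 1 by default). Each gene copy at biallelic locus l
draws a latent cluster z ~ q_i and an allele Bernoulli(p_{z,l}). Cluster
frequencies are tied to a shared ancestral frequency π_l through
per-cluster drift F_k in Balding–Nichols form:

    p_{k,l} ~ Beta(π_l (1−F_k)/F_k, (1−π_l) (1−F_k)/F_k)

Read data never become hard genotype calls: the likelihood of the
observations at (i, l) enters as the triple P(reads | g) for g ∈ {0, 1, 2},
taken from VCF PL/GL fields or generated by the simulator's binomial
read-count model. Posterior mean genotypes ("genotype probabilities" on the
0–2 dosage scale; a perfectly known heterozygote is exactly 1) are a direct
by-product of the sampler and feed every downstream statistic.

### Sampling scheme

A Gibbs sweep updates, in order: latent genotypes g (discrete conditional
combining the likelihood triple with the Hardy–Weinberg prior at the
individual's mixture frequency θ_il = Σ_k q_ik p_kl), gene-copy ancestries
z given the alleles implied by g, q rows from their Dirichlet conditional,
then the hyperparameters, then p from its conjugate beta.

π_l and F_k are updated by random-walk Metropolis against the *collapsed*
model in which p is analytically integrated out (a beta-binomial marginal of
the current cluster allele counts), after which p is redrawn from its full
conditional — a partially collapsed Gibbs step. This is deliberate: a
Metropolis step evaluated on the Balding–Nichols *density* at the sampled p
is numerically treacherous, because the beta density is unbounded at the
frequency boundaries whenever the prior pseudo-counts (1−F)/F drop below
one. With a rare-allele-heavy spectrum the density-based chain ratchets F
upward by chasing those boundary spikes, which in turn washes out ancestry
resolution. The collapsed marginal is a probability and therefore bounded,
and numerical integration over p on fixture data confirms it concentrates
where the true posterior does.

Priors: π_l uniform on (0, 1) by default, with an optional empirical-Bayes
beta prior moment-matched to the cohort's frequency spectrum (shapes capped
at one, so on MAF-filtered input it effectively reduces to uniform). F_k
carries a weakly informative gamma prior (shape 0.04, rate 4.0 — mean 0.01,
sd 0.05), the conventional small-drift prior for this model family; a flat
prior is available via `f_prior=None`. These choices anchor the scale of
cluster divergence, which is what keeps ancestry coefficients identifiable
when differentiation among herds is weak (F_ST ≈ 0.06–0.08): the likelihood
alone has a ridge trading sharper q against more dispersed p.

### Initialization, schedules, model choice

Chains start from PCA of the covariance of likelihood-weighted mean
genotypes, k-means on the principal components (a distinct seed per chain),
and a linear-discriminant fit on all PCs converted to membership
probabilities, softened by 5% toward uniform so no chain starts on a
simplex boundary. The production schedule is 100,000 iterations, 30,000
burn-in, thinning 10; the desk schedule used throughout the tests is
20,000 / 5,000 / 10. π and F are refreshed on every 5th sweep (their
conditionals are tight and the collapsed evaluations dominate sweep cost);
this fixed cycling schedule is still a valid MCMC. Model choice across k
uses DIC = mean posterior deviance + half the variance of the deviance
trace, smaller being better. Replicate chains are combined after aligning
cluster labels by optimal one-to-one column matching (Hungarian algorithm
on L1 distances between q columns); within-chain label switching is
monitored via a split-chain potential-scale-reduction factor on the
deviance (warn at 1.1, never auto-fail).

Degenerate inputs: k = 1 collapses to the conjugate single-population
model; depth-0 observations carry flat likelihood triples; beta draws for p
are clipped to [1e-9, 1 − 1e-9] for numerical safety (the clip no longer
interacts with any density evaluation).

## Diversity and differentiation

All statistics operate on dosages. Unit allele frequencies are half the
mean dosage over non-missing individuals. H_E is the mean over loci of
2p̂(1−p̂) (an n/(n−1) small-sample correction is available but off by
default, since the convention in the source analyses is the uncorrected
expectation). H_O scores an entry as heterozygous when its dosage lies in
[0.9, 1.1], endpoints inclusive. F_IS = 1 − H_O/H_E, undefined (reported
missing) when H_E = 0. Units enter summaries only with ≥ 5 genotyped
individuals.

Hudson's F_ST uses the per-locus estimator

    N_l = (p̂₁−p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1)
    D_l = p̂₁(1−p̂₂) + p̂₂(1−p̂₁)

with n the number of sampled allele copies (2 × non-missing individuals),
combined across loci as the ratio of sums Σ N_l / Σ D_l — the standard
recommendation for this estimator; mean-of-ratios is exposed as an option.
Negative per-locus numerators are retained so the estimator stays unbiased;
loci with zero denominator are skipped. Under the simulator's generative
dual this estimator recovers the configured drift F directly (for two herds
with equal drift F, E[N]/E[D] = F), which the tests verify at L = 5,000,
n = 30 diploids, within ±0.015.

## Spatial analysis

Haversine great-circle distances on a 6,371-km sphere between hunt-unit
midpoints. MRM regresses the lower-triangle vectorization (diagonal
excluded) of one distance matrix on others by OLS; significance comes from
jointly permuting rows and columns of the response matrix (Mantel-style,
the formulation matching the cited MRM method; the permutation count
defaults to 999 and the paper-side convention of a one-tailed positive
slope test is used for isolation by distance, both declared in the output).
P-values use the add-one rule (x + 1)/(m + 1). Type-I error at α = 0.05 is
verified to be calibrated within ±0.02 over 500 null replicates.

## Cohort statistics

PCA of the individual-by-individual covariance of the column-centered
dosage matrix (covariance, not correlation — no scaling), with percent
variance per component and missing entries mean-imputed per locus before
centering. The paired t test (H_E vs H_O across units), Welch's t with
Satterthwaite df (remnant vs reintroduced herds, unweighted unit means),
and simple OLS of diversity on translocation source count (F with 1, n−2
df) are thin, typed wrappers over scipy with explicit error handling for
degenerate inputs; all default to two-tailed.

## The simulator

The simulator is the exact generative dual of the inference model on the
source side, and deliberately harder than it on the founded side.

* Source herds: ancestral frequencies π_l ~ Beta(0.3, 0.3) (clipped to
  [0.01, 0.99]) — a rare-allele-heavy SNP spectrum whose post-MAF-filter
  expected heterozygosity sits near 0.19, typical of GBS panels in this
  system; herd frequencies Balding–Nichols at per-herd F (default 0.07,
  the middle of the observed source-herd differentiation band); individuals
  drawn in Hardy–Weinberg proportions.
* Founded herds: founders sampled from each source per a translocation
  ledger, then explicit Wright–Fisher generations (default 10) at a census
  default of 200, with Bernoulli(0.5) sex and a skewed subset of sires
  (default: 30% of rams eligible per generation) emulating polygynous
  reproductive skew. True ancestry is tracked by pedigree expectation, so
  founded-herd truth includes real drift the admixture model must absorb.
* Reads: depth per entry negative-binomial (dispersion 3.0) around a mean
  of 4.34 reads — the realized coverage scale of the motivating survey —
  with per-read miscall probability 0.005; likelihood triples follow the
  binomial read-count model; depth 0 is a flat triple.

One seed determines all three stages through spawned substreams.

What the simulator does not emulate: linkage (loci are independent),
selection and local adaptation, spatially explicit dispersal or gene flow
between herds after founding, allele-dropout/PCR artifacts of GBS beyond
symmetric miscalls, and reference-alignment bias. Passing recovery tests
therefore demonstrates statistical correctness of the estimators under the
model's own assumptions, not robustness to these real-data complications.

## Known limitations

* At desk scale (2,000 loci, ~12 individuals per source herd, mean depth
  8) the ancestry posteriors of pure-herd individuals are genuinely soft
  (posterior max-q ≈ 0.8) once founded herds with real post-founding drift
  are in the cohort: the drift inflates the cluster-level F estimates,
  which weakens the frequency anchoring for everyone. Admixed individuals'
  ancestry is recovered almost exactly, and DIC still identifies the true
  number of source clusters, but mean absolute ancestry error sits near
  0.10 rather than the few-percent regime reached at full survey scale
  (hundreds of individuals, ~17k loci). This is a property of the
  posterior, verified against fixed-truth and short-window diagnostics,
  not a sampler artifact.
* MAF filtering before admixture is not optional in practice: on
  unfiltered rare-allele-heavy data the per-locus uniform prior on π
  systematically pulls near-fixed loci inward and the unabsorbed
  dispersion inflates drift estimates.
* DIC with the variance-based penalty is a pragmatic model-choice score;
  it inherits the usual caveats for mixture-like posteriors and is
  reported per chain alongside convergence summaries rather than treated
  as decisive.

## Problem sizes used in the test suite

Unit tests run seconds-scale chains (hundreds to thousands of sweeps on
cohorts of ~20–40 individuals × a few hundred loci). The end-to-end
recovery scenario uses 60 individuals × 2,000 MAF-filtered loci with the
desk MCMC schedule over k ∈ {2, 3, 4} (~4–5 minutes per k on one core);
differentiation recovery uses 5,000 loci × 30 diploids; the MRM
calibration uses 500 null replicates of a 10-unit system at 99
permutations each. These sizes were chosen so the full suite and the
reproduction script each complete comfortably on a single core while
keeping every statistical check at meaningful resolution.
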