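# Methods

This note documents the models, the numerical choices and the simulation
design behind `gsel`, and what the test suite does and does not establish.

## Genotype model and quality control

Dosages count copies of the A1 allele of the `.bim` allele pair, coded
0/1/2 with a sentinel for missing.  Per-marker quantities are computed over
non-missing calls only: the allele frequency p, the heterozygote and
alt-homozygote frequencies p1 and p2 (so p = 0.5·p1 + p2 identically), and
the call rate.  Quality control removes animals with > 10% missing calls
first, then recomputes frequencies on the survivors before applying the
marker filters (MAF < 0.05, call rate < 0.9, non-autosomes) — the order
PLINK uses.  Remaining missing cells are replaced by the marker mean 2p;
mean imputation preserves column means and is the de-facto standard before
GRM construction.  The filter is idempotent by construction.

## Relationship matrices

Two centerings and two variance conventions produce four GRMs:

| method | centering      | per-marker variance        | divisor    |
|--------|----------------|----------------------------|------------|
| SP     | 2p (HWE mean)  | 2p(1−p)                    | pooled sum |
| IP     | 2p             | 2p(1−p)                    | per marker |
| SV     | p1 + 2p2       | Var* = p1 + 4p2 − (p1+2p2)² | pooled sum |
| IV     | p1 + 2p2       | Var*                        | per marker |

Var* is a population (divide-by-n) variance by construction from genotype
frequencies, so the per-marker standardization in IV makes
trace(G)/n = 1 an exact algebraic identity — used as an invariant test.
Each method centers by its own mean: the HWE-variance methods use the HWE
mean 2p, the empirical-variance methods the empirical mean.  At exact HWE
genotype counts the two families coincide element-wise.  Markers that are
monomorphic under the requested convention are rejected (pointing at QC)
rather than silently skipped, keeping the marker count m consistent across
methods.  The per-marker family is implemented symmetrically as Z*D Z*′.

The pedigree numerator matrix A uses the tabular method (O(n²)); founders
have diagonal 1 and unknown parents are treated as unrelated founders.
Before inversion in the mixed-model equations any kernel can be shrunk as
(1−ε)G + εI (default ε = 0.01), which bounds the smallest eigenvalue away
from zero when m < n or when markers are heavily correlated.

## REML and BLUP

The univariate animal model is fitted by average-information REML.  The
observations' covariance ZKZ′ is eigendecomposed once; in the eigenbasis
every likelihood, score and AI evaluation is O(n), so the iteration cost
is dominated by the single decomposition.  Updates are projected AI steps
with step-halving against the restricted likelihood and an EM-style step
as a fallback; components are bounded below at 1e−8 of the phenotypic
variance.  Convergence requires both a relative log-likelihood change
below 1e−8 and a scale-free gradient statistic |∂ℓ/∂θ·θ| below 1e−3
(components pinned at the bound are exempt); if no direction improves the
likelihood, the iterate is accepted as the numerical optimum.  Standard
errors come from the inverse AI matrix, and the h² SE by the delta method
on that 2×2 covariance.  A caveat documented by the equivariance test: the
(σ²ₐ, σ²ₑ) profile is nearly flat along a trade-off ridge when the GRM
diagonal is close to 1, so individual components are reproducible only to
~1%, while their sum and the likelihood are much stiffer.

The bivariate fit parameterizes the 2×2 genetic and residual covariance
matrices by their Cholesky factors (log-diagonal), which keeps both
positive semi-definite without any post-hoc bending, and maximizes the
restricted likelihood (evaluated per eigencomponent in O(n)) by
Nelder–Mead restarts.  The 6×6 covariance of the natural parameters is
obtained from a finite-difference Hessian at the optimum; the SE of the
genetic correlation r_g = σ_a12/√(σ²_a1 σ²_a2) follows by the delta
method.  A duplicated trait drives the residual covariance to the
singular boundary; a small diagonal floor (1e−8 of the larger variance)
keeps the likelihood finite and r_g converges to 1.

Henderson's mixed-model equations are solved densely with λ = σ²ₑ/σ²ₐ.
All animals present in the kernel stay in the equations, so animals
without records (the masked cross-validation fold) receive predictions
through their relationships — this is how CV prediction works throughout.
Fixed effects are treatment-coded with the first observed level as
reference; predicted genetic values are invariant to that choice.

## Bayesian whole-genome regression

All five models share y = Xβ + Wα + e with W centered at the training
2p, flat priors on β, and scaled-inverse-χ² priors (df 4) on variances.
Prior scales split the phenotypic variance half-and-half between the
genetic and residual sides; the marker-variance scale divides the genetic
share by the expected number of non-zero effects times the mean
heterozygosity.  Updates are single-site with residual adjustment, O(n)
per marker, in one numba kernel; a chain is bit-reproducible from its
seed.

Model-specific conditionals:

* **BayesCπ** — common slab variance σ²; π from Beta(1+m_in, 1+m_out).
* **BayesB** — per-marker variance with an inverse-χ² prior (the
  hierarchical form of the scaled-t slab); excluded markers redraw their
  variance from the prior; π fixed (default 0.05).
* **BayesN** — markers sit in non-overlapping 0.2 Mb windows restarting
  at chromosome boundaries.  The window indicator is sampled from the
  product of per-marker spike/slab marginal likelihoods (exact when
  within-window genotypes are orthogonal, an approximation otherwise);
  open windows then run BayesCπ updates inside, with window- and
  marker-level inclusion probabilities each getting Beta updates.
* **BayesS** — slab variance [2p(1−p)]^S σ²; S gets a N(0,1) prior and a
  random-walk Metropolis update whose step adapts toward ~0.30 acceptance
  during burn-in.  Fixing S = 0 reproduces the BayesCπ chain exactly
  (verified bit-for-bit in the tests).
* **BayesR** — component membership sampled from the four marginal
  likelihoods with variances (0, 0.01, 0.1, 1)·σ²; mixture weights from a
  Dirichlet(1+counts).  Forcing all weight onto the γ = 1 component turns
  the model into ridge regression, and its GEBVs then match GBLUP.

Default chain settings (20,000 iterations, 5,000 burn-in, thinning 10)
are deliberately long for production use; the tests and the acceptance
script run 400–600 iterations with 150–200 burn-in, which is sufficient
for posterior-mean GEBVs on the simulated architectures used there.

## Cross-validation and the density study

Reliability is the raw Pearson correlation between adjusted phenotypes
(y − Xβ̂) and predicted genetic values of the masked fold, averaged over
k = 5 folds.  β̂ and the variance components are re-estimated inside every
training fold (the leakage-safe reading; a single global adjustment is
available as an option).  One fold assignment is shared across models per
trait and seed, so model comparisons are paired.  The density study draws
uniform random marker subsets without replacement, rebuilds the GRM and
reruns the CV per replicate, also recording the between-replicate
correlation of GRM entries; predictive capability divides each density's
mean reliability by the best density's.

## Simulation design

The generator mirrors the study population the toolkit targets: ~1,000
animals from an F2 cross, sex/reciprocal-cross/feed-room fixed effects,
and heritabilities spanning roughly 0.1–0.7.

* `independent_loci` draws each marker independently with genotype
  frequencies p² + Fp(1−p) / 2p(1−p)(1−F) / (1−p)² + Fp(1−p); F is a
  single knob for Hardy–Weinberg departure (F = 0 exact HWE sampling,
  F = 1 no heterozygotes).  Allele frequencies are uniform on
  [0.05, 0.5].
* `f2_cross` fixes two founder lines for alternate alleles, crosses to a
  uniformly heterozygous F1 and gene-drops two recombinant F1 gametes per
  F2 animal.  Crossovers are Poisson at 1 cM/Mb on 5 chromosomes of
  80 Mb (defaults), giving allele frequencies near 0.5 and LD decaying
  with map distance.
* `simulate_pedigree` gene-drops founder haplotypes through random-mating
  discrete generations, recording sire/dam, so pedigree-BLUP comparisons
  have a consistent A matrix.

Traits place n_qtl effects (normal or a BayesR-like mixture) on random
markers and scale the residual variance so the realized h² equals the
target exactly; fixed-effect contrasts default to 0.5 phenotypic SD per
level step.  What the generator does **not** emulate: genotyping error,
minor-allele-frequency spectra from real site-frequency spectra,
selection over generations, dominance/epistasis, and maternal or
permanent-environment effects — so passing tests demonstrate internal
consistency and statistical calibration of the methods, not their field
performance on real data.

## Problem sizes in the test suite

The acceptance-style tests use n = 1,000/m = 2,000 for REML recovery
(20 replicates per generating h²), n = 1,000/m = 3,000 with 20 QTL for
the model-ordering comparison (10 replicates), n = 500/m = 4,000 for the
density study (10 replicates over five densities) and n = 300 for the
null calibration (10 seeds) — sizes chosen so the whole suite completes
in a few minutes on one CPU while keeping the sampling error of each
check well below the effect it measures.

## Known limitations

* The per-marker (IP/IV) GRMs up-weight rare alleles; with very small MAF
  after lax QC the per-marker divisor is noisy.
* BayesN's window conditional is the orthogonal approximation described
  above; strongly correlated markers within a window mix more slowly.
* The bivariate REML handles exactly two traits; no missing-by-trait
  patterns (records missing either trait are dropped).
* Single-chain inference only; the log-likelihood trace is exported for
  eyeballing convergence, but no formal multi-chain diagnostics.
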