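# Methods

## Data model and filtering

The unit of input is one ultra-rare variant: gene symbol, functional
annotation, MPC pathogenicity score for missense variants, and the
minor-allele counts in cases and controls.  Filtering keeps variants
with cohort minor-allele count (cases + controls combined) between 1
and `mac_max` (default 5, the customary ultra-rare cutoff).  Variant
classes are assigned as: protein-truncating variants and missense with
MPC ≥ 3 → class I; missense with 2 ≤ MPC < 3 → class II; missense
below MPC 2 is excluded.  MPC exactly 3 is placed in class I so the
two intervals [2, 3) and [3, ∞) partition the retained missense range
cleanly.  Analyses are usually restricted to a constraint-gene list
(pLI > 0.9); the list is consumed as plain text and no attempt is made
to resolve gene-symbol aliases beyond upper-casing.

Genes with no retained variants stay in the model with a neutral
Bayes factor of 1, so the risk-gene proportion δ refers to the whole
gene universe supplied, not just to genes that happen to carry
variants.

## Per-variant Bayes factor

Conditioning on a variant's total carrier count *T* (a retrospective
view that matches how such meta-analytic counts arise), the case count
is Binomial(*T*, p₀) under the null and Binomial(*T*, γp₀/(γp₀+1−p₀))
for relative risk γ.  The effect-size prior is Gamma with shape γ̄σ and
rate σ, i.e. mean γ̄ for every σ and variance γ̄/σ.  γ̄ is the
class-level hyperparameter (defaults 3 and 1 for classes I and II; the
class-II value reflects the weak burden expected of moderate-MPC
missense).  σ defaults to 1 and is exposed in the prior configuration;
only the prior mean is well-identified by this kind of data, and fits
are insensitive to γ̄ choices of similar magnitude (3–5), which the
test suite checks for the Bayes-factor layer.

The binomial coefficients cancel in the Bayes factor, leaving
BF(k,T) = E<sub>γ</sub>[γ^k (p₀γ + 1 − p₀)^(−T)].  This is integrated
by adaptive quadrature on the u = log γ axis with the integrand
assembled fully in log space, target relative accuracy 1e−8 and a
raised `QuadratureError` when the reported error estimate exceeds
100× the target.  Because ultra-rare counts admit at most 21 distinct
(k, T) pairs per class, Bayes factors are computed once per distinct
combination and broadcast.

## EM estimation

The latent structure is Z_i ~ Bernoulli(δ) per gene and U_ij ~
Bernoulli(η_c Z_i) per variant.  The E-step computes the posterior
gene-risk probability T_i = δLR_i/((1−δ)+δLR_i) and variant-risk
probability U_ij = η_c BF_ij/((1−η_c)+η_c BF_ij); the M-step sets δ to
the mean of T_i over the universe (variant-free genes contribute
T_i = δ) and η_c to Σ T_i U_ij / Σ T_i over class-c variants.
Iterations stop when the relative log-likelihood change falls below
`tol` (default 1e−8) or at `max_iter` (default 5000).  The
log-likelihood trace is recorded and is non-decreasing up to 1e−10.

η = 0 is an absorbing fixed point of EM, so `fit()` uses multi-start:
the first start is (δ, η) = 0.1 everywhere, the remaining
`n_restarts − 1` (default total 5) draw all parameters uniformly on
(0.02, 0.98) from the fit seed; the best final likelihood wins.
Estimates are invariant to gene and variant ordering.

With ultra-rare counts the likelihood carries a mildly flat ridge
trading δ against η, so single-replicate estimates of η₁ scatter with
a standard deviation near 0.05 at 2000 genes; averaged over replicates
the estimator is unbiased to well under that (mean absolute error
≈ 0.035 in the acceptance suite).

## Likelihood-ratio test at the boundary

`lrt_eta(c)` refits with η_c pinned at 0 (everything else
re-optimised, same multi-start policy).  Because the null value sits
on the parameter boundary, Λ = 2(ℓ_full − ℓ_0) is referred to the
50:50 mixture of a point mass at zero and χ²₁: p = ½P(χ²₁ > Λ).  The
full fit is additionally polished by an EM run started from the
constrained optimum with η_c nudged to 1e−3, which guarantees
ℓ_full ≥ ℓ_0 up to convergence noise; residual negative statistics
(|Λ| < 1e−3, produced by EM's geometric creep toward a boundary
optimum when the class truly carries no signal) are clipped to 0,
i.e. p = 0.5.  Larger shortfalls raise an error rather than being
silently absorbed.

## Bayesian FDR selection

Genes are sorted by descending posterior (ties broken by gene symbol
so output is byte-reproducible).  The Bayesian FDR of the top-k prefix
is the running mean of (1 − posterior); the nominated set is the
largest prefix with FDR strictly below the level, matching a
"FDR < 5%" convention.  Because the ranked (1 − posterior) sequence is
non-decreasing, its running mean is too, and selection is always a
prefix.  Level 0 is legal and selects nothing.

## Enrichment statistics

Overlap of two gene lists reports the exact intersection and the
percentage with the *reference* list size as denominator.  Fisher
exact tests build on scipy's hypergeometric distribution; the
two-sided p-value sums all tables whose point probability is no larger
than the observed one, with a 1e−9 relative slack so exact rational
ties survive floating point (p-values within 1e−9 of 1 are snapped to
exactly 1 — the closest attainable non-unit value for any table of
realistic size is farther away).  The sample odds ratio (ad)/(bc) is
reported.  Term enrichment is database-agnostic: given any gene→term
map it reports fold change (k/n)/(K/N), the hypergeometric upper tail
and a Bonferroni correction over all terms with at least one reference
hit.  The enrichment universe should normally be the constraint-gene
list used for the association analysis.

## Synthetic data generator

`simulate_dataset` draws, per gene, Z ~ Bernoulli(δ); per class a
Poisson number of variants; per variant U ~ Bernoulli(η_c Z), γ from
the class prior when U = 1 (else 1), a carrier total uniform on
{1..5}, and a case count Binomial(T, γp₀/(γp₀+1−p₀)).  Defaults match
the analysis conditions: 3000 genes, 24,248 cases / 97,322 controls,
δ = 0.451, η₁ = 0.6766, η₂ = 0.081, γ̄ = (3, 1), σ = 1.  Mean variant
counts per gene (class I: 6, class II: 4) are of the order expected
for ultra-rare variants in constraint genes in a cohort of this size;
the totals distribution is uniform on 1..5 because the analysis
conditions on totals, so this choice affects power only.  Class I
variants are emitted as PTVs and class II as missense with MPC in
[2, 3), so simulated tables round-trip through the I/O and
classification layer.

The generator mirrors the fitted likelihood exactly, which is what
makes parameter-recovery and FDR-calibration tests well-posed.  It
deliberately does not emulate population structure, linkage, calling
artifacts, per-gene mutability differences or mis-annotation; passing
tests therefore validate the inference machinery, not robustness to
those real-data features.

## Problem sizes used by the test and acceptance suites

Quadrature is verified against a dense-grid trapezoid oracle over
every count split with total ≤ 5 crossed with p₀ ∈ {0.1, 0.2, 0.5},
γ̄ ∈ {1, 3, 4, 5}, σ ∈ {0.5, 1, 2} (for Gamma shapes below 2 the
oracle integrates on the √γ axis, where the integrand is smooth down
to 0).  EM is checked against an exhaustive 1e−3 grid search on small
single-class-per-gene instances, where the likelihood separates per
class and the full-grid argmax can be computed without materialising
the (δ, η₁, η₂) cube.  Parameter recovery uses 20 replicates of 2000
genes; FDR calibration 100 replicates of 1000 genes fitted end to end;
the LRT type-I error 200 null replicates of 500 genes.  The Fisher
test is compared with exact integer enumeration on all 46,376 tables
with N ≤ 30.

## Known limitations

* De novo variants are out of scope; the model handles inherited
  case–control counts only.
* p₀ is a single cohort-wide split; unmodelled case/control imbalance
  per site (e.g. differential coverage) would bias Bayes factors.
* No uncertainty intervals on (δ, η): point estimates plus LRTs only.
* The dispersion σ of the effect-size prior is essentially
  unidentified from ultra-rare counts and is treated as a fixed
  configuration value.
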