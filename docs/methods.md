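# Methods

This note documents the statistical model behind `opvardec`, the choices
made where the method was genuinely open, and what the synthetic-data tests
do and do not establish.

## Trial structure and phenotype model

The unit of analysis is a multi-site open-pollinated (OP) progeny trial:
maternal families of nominal half-sibs, each tree planted at exactly one
site in one block (single-tree plots), one measurement per tree. Phenotypes
are standardized to zero mean and unit variance *within site* before any
modeling; this is the remedy adopted for heterogeneous variances across
environments (rather than fitting per-site residual variances), and all
downstream quantities — variance components, heritabilities, breeding
values, selection differentials — live on that standardized scale.

The general model is

    y = Xb + sum_k Z_k u_k + e,   u_k ~ N(0, K_k s2_k),   e ~ N(0, I s2_e)

with fixed intercept and site effects. Blocks are random, nested within
site, with identity covariance. The four named specifications (ABLUP,
GBLUP-A, GBLUP-AD, GBLUP-ADE) differ only in which kernels enter: the
pedigree numerator matrix A versus the genomic additive matrix, the
dominance matrix, and the three first-order epistatic Hadamard products.

### Kernels

* **A** — OP pedigree with unknown, assumed-unrelated sires: diagonal 1,
  0.25 within maternal family, 0 elsewhere. Mothers are assumed unrelated
  and non-inbred; with a two-generation structure no recursion is needed.
* **G_add** = `Z Z' / (2 Σ p_i q_i)`, `Z = M − 2p`, with allele
  frequencies estimated from the current (imputed) sample, which therefore
  acts as the base population: the matrix is centered in-sample, its mean
  off-diagonal is ≈ −r̄/(1−r̄) below the pedigree expectation (r̄ = mean
  relatedness over all pairs), a shift of order 1/n_families here.
* **G_dom** = `W W' / Σ (2 p_i q_i)²`, W coding the reference homozygote,
  heterozygote and alternative homozygote as −2p², 2pq, −2q². The
  per-marker-summed denominator Σ(2pq)² is used (the orthogonal
  parameterization), since a pooled alternative would change only the
  overall scale. The coding is defined for discrete genotypes, so
  fractional imputed codes are rounded to the nearest integer genotype when
  building W; G_add uses the fractional values directly.
* **Epistatic kernels** — element-wise (Hadamard) products G_add#G_add,
  G_dom#G_dom, G_add#G_dom, used unrescaled; an optional trace
  normalization is deliberately not applied by default.

All marker kernels are bent before model fitting: if the smallest
eigenvalue falls below ε (default 1e-6 × mean diagonal) a constant is added
to the diagonal to lift it to ε, and the shift is recorded on the matrix.
With ~1000 individuals on a few thousand effective marker dimensions this
is routinely needed.

### Genotype-by-environment terms

Each tree occupies one site, so a G×E effect with identity covariance over
trees would contribute s2 · I to the phenotypic covariance — exactly the
residual's footprint — and the two variances would be unidentifiable (the
likelihood flat along their sum). The axe/dxe terms therefore carry the
covariance **K ∘ S**: the genetic kernel restricted to pairs of trees at
the same site (equivalently I_sites ⊗ K on the observed layout). Two
same-site relatives then share both their main genetic effect and their
site-specific deviation, while cross-site relatives share only the former;
that contrast is what makes s2_axe estimable. A `RandomTerm` with
`kernel=None` still yields the literal identity covariance for users who
want it, with the identifiability caveat above.

The generator mirrors this exactly: site-specific deviations are built from
*independent draws of marker effects per site*, giving interaction values
whose covariance is the genomic kernel within site and zero across sites.

## Genotype quality control and imputation

The QC pipeline is: keep the `keep_n` individuals with the lowest missing
rate (stable ties), drop markers whose missing rate is not strictly below
the threshold (default 30%), then impute. Imputation is a full
multivariate-normal EM over markers: individuals are i.i.d. rows of
N(mu, Sigma) with the marker-by-marker covariance re-estimated each
iteration, so missing calls borrow strength from correlated (linked)
markers; observed calls are never altered, imputed values are clamped to
[0, 2] on output, and the observed-data log-likelihood is tracked (it is
monotone for the exact EM; a sticky diagonal stabilizer is added only if
Sigma turns singular, e.g. under perfect collinearity, at the cost of exact
monotonicity). Convergence is declared when the largest change in an
imputed value drops below `tol` (default 1e-4 genotype units, `max_iter`
100); non-convergence is a logged warning, not an error. The E-step costs
O(p³) per missingness pattern, so the EM is meant for filtered desk-scale
panels (≲ a few thousand markers); a per-marker mean-imputation fallback is
provided for degenerate or very large inputs. Allele frequencies for the
kernels are computed *after* imputation from the completed matrix, and no
MAF floor is applied (monomorphic markers are dropped with a warning, since
they contribute nothing to either numerator or denominator).

## REML estimation and boundary convention

Variance components are estimated by average-information (AI) REML:
score and AI matrix from the projection matrix P, Newton-like updates with
deep step halving (the AI matrix is nearly singular along kernel ridges),
and an EM-flavoured gradient fallback whose quadratic factor is bounded
below so parameters at the boundary can re-enter when the score is
positive. Components are floored at 1e-8 × var(y); convergence requires
|Δ log L| < 1e-8 and a maximum parameter change < 1e-6 on the var(y) scale,
with `max_iter` 200. Components that finish at the floor are *reported* as
0 with SE 0 — the convention of standard REML software, where boundary
components print as "0.00 (0.00)". SEs for interior components come from
the inverse AI matrix at convergence; the SE of h² (and H²) is obtained by
the delta method from that covariance. Fits with a constant response
short-circuit to an all-floor result. The optimizer has been checked to
land on the same maximum as a derivative-free simplex search of the same
likelihood.

Two consequences of boundary truncation are worth knowing when reading
simulation results at moderate size (hundreds of trees, thousands of
markers). First, the dominance-type kernels (G_dom, its within-site
restriction, D#D, A#D) are nearly diagonal, so the likelihood has flat
ridges between them and the residual; a correct constrained optimum can sit
at e = 0 with the dominance-by-site term absorbing the residual, and
equally-likely parameter splits can wander along the ridge. Second, a
component whose true value is small relative to its SE pins at the floor in
a large fraction of replicates (roughly the probability mass the estimator
would put below zero), and a truly null component remains *positive* in
roughly half of them — exact zeros in an output table are a statement about
the boundary, not a hypothesis test. Recovery is sharp for the
well-identified components (additive, dominance main effect,
additive-by-site, block, h²).

BLUPs are solved at the REML estimates as u_k = s2_k K_k Z_k' P y, with
prediction error variance s2_k K_k − s2_k² K_k Z_k' P Z_k K_k; SEP_i is the
root of its diagonal. Individuals without phenotypes receive predictions
through the kernel — under the pedigree matrix a whole held-out family has
zero relatedness to training and its predictions are exactly the model mean
(zero on the standardized scale), whereas genomic kernels propagate
realized relatedness and marker LD. Missing phenotypes are handled by row
deletion, never by imputation.

## Cross-validation

k-fold (default 10) with `replicates` (default 5) under two schemes:
`random` partitions individuals, `family` partitions whole maternal
families (shuffled, dealt round-robin to folds). Variance components are
re-estimated within each training fold by default; a switch reuses the
full-data estimates and only re-solves the BLUP system (orders of magnitude
faster, and the difference is small in practice). Predictability correlates
the cross-validated predictions with the standardized phenotype (the
model's working response; a flag exposes the raw scale), accuracy with the
full-data breeding values computed once. Metric SEs are the SD of replicate
means over √replicates. A constant prediction vector (ABLUP under family
folding) makes the metrics undefined and is reported as such with the
reason, never as a number. In the pairwise table, cell (i, j) is
cor(PBV-CV of model i, EBV-all of model j), averaged over replicates.

## Selection analysis

Trees are ranked on additive BLUPs (ties broken by id), top-k persistence
between two models is |intersection|/k, and response to selection follows
R = h² S. The operational definition of S is open in the literature this
implements; the default takes the mean standardized phenotype of the
BV-selected group (the classical breeder's-equation reading), and
`basis="bv"` uses the mean breeding value instead — the latter makes the
pedigree model's gain inflation more visible, since its BVs are inflated
along with its h². k defaults to 5% of the population.

## The synthetic trial generator

`simdata` generates: founder mothers and a finite pollen pool with
Hardy-Weinberg genotypes at frequencies uniform on `maf_range`; offspring
by gamete sampling with a per-sib probability `full_sib_excess` of reusing
the previous sib's sire (hidden full-sib structure — the half-sib
violation, made a dial because no field estimate of it exists); a field
layout spreading every family round-robin over all site × block cells; and
a trait summing site means, block effects, additive values (centered causal
codes × effects), dominance values (orthogonal W coding), additive×additive
values (products of centered codes over random causal pairs), per-site
independent additive and dominance deviations, and Gaussian residual. Every
component is centered and rescaled so its *realized* sample variance equals
the requested value exactly, which makes recovery tests sharp at desk
scale. Defaults describe the emulated trial: 25 families × 40 offspring,
30,000 markers with 30% missing calls, 3 sites × 4 blocks, and variance
fractions (block 0.021, additive 0.244, dominance 0.195, axe 0.281, dxe
0.045, residual 0.214) taken from the full height-model decomposition of a
published multi-site interior-spruce OP trial, normalized to total 1.
Unanchored choices, made once: `maf_range = (0.05, 0.5)` (post-QC GBS
panels are depleted of rare alleles), `pollen_pool_size = 100` (many but
finitely many effective fathers), `full_sib_excess = 0.25` (a moderate
violation; 1.0 turns families fully full-sib), `n_causal = 300`
(oligogenic-to-polygenic architecture at desk marker counts).

What the generator does **not** emulate: linkage and LD between markers
(marker genotypes are independent given founders — so imputation gains from
LD and the LD component of genomic prediction are understated), genotyping
error, unequal family sizes, selection or structure in the pollen cloud,
spatial field trends, and multi-trait correlations. A green recovery test
therefore establishes that the estimation machinery recovers the generating
process of this stated world, not that field data of the same size would
behave as well.

## Numerical details at a glance

| quantity | default | notes |
|---|---|---|
| marker missingness threshold | < 0.30 strict | counts compared exactly |
| EM imputation | tol 1e-4, max_iter 100 | warning on non-convergence |
| kernel bending ε | 1e-6 × mean diag | shift recorded |
| variance floor | 1e-8 × var(y) | floored ⇒ reported 0 (SE 0) |
| REML convergence | |Δll| < 1e-8, Δθ < 1e-6 | max_iter 200 |
| CV | k=10, 5 replicates | per-fold re-estimation on by default |
| selection intensity | top 5% | k overridable |
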