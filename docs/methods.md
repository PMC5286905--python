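# Methods

## Model

The package fits the T-trait individual-level mixed model

    y = (1ₙ ⊗ I_T) μ + g + ε,    g ~ N(0, K ⊗ Q),    ε ~ N(0, Iₙ ⊗ R)

with y stacked individual-major (T consecutive entries per individual).
Every trait is observed on every individual; the Kronecker residual
structure relies on this and missing phenotype cells are rejected rather
than imputed. All fixed effects other than per-trait intercepts are removed
upstream by pre-correction, which keeps the GBLUP stage's fixed-effect
design at a single intercept per trait.

The kinship kernel K is a convex combination λG + (1−λ)A of the pedigree
numerator relationship matrix and a genomic relationship matrix. A is built
by the tabular (recursive) method — at the population sizes targeted here
(order 10³) a dense O(n²) construction is simplest and feeds the blend
directly; unknown parents are treated as unrelated, non-inbred base
founders. G comes in the VanRaden (WW′/2Σpᵢqᵢ) and Forni (WW′/(tr(WW′)/m))
normalizations, with allele frequencies computed from the current sample
(there is no meaningful base population to take frequencies from).

### Map-minmax rescaling

An unscaled G is not on A's scale, so a rescaled variant maps all entries
affinely onto [s_min, s_max] = [0, 2]:

    Gs_ij = (s_max − s_min)(G_ij − G_min)/(G_max − G_min) + s_min

using the global entrywise extrema, diagonal included (the transform is
defined entrywise with no diagonal exemption). The extreme entries map onto
the bounds exactly in floating point, which the tests assert with equality.
Scaling is applied to G **before** blending. Because the affine map can
push a PSD matrix slightly indefinite, every interior blend is
eigenvalue-checked: a smallest eigenvalue in (−1e−6, 0) is repaired by
logged diagonal jitter, anything lower is an error. Blends at λ = 0 and
λ = 1 return the source matrix bit-identically (no check, no jitter), so
endpoint results are exactly the single-source analyses.

## REML estimation

With K = UDU′, rotating the n×T phenotype matrix by U′ turns the nT-variate
Gaussian into n independent T-variate blocks with covariance Σᵢ = dᵢQ + R.
The restricted log-likelihood

    ℓ_R = −½ [ (n−1)T log 2π + Σᵢ log|Σᵢ| + log|X′V⁻¹X| + y′Py ]

is evaluated blockwise in O(nT³) per call; a singular block yields −∞
rather than an exception so the optimizer simply retreats. The
eigendecomposition is computed once per fit and cached on the model spec.

Maximization is quasi-Newton (L-BFGS-B) over the stacked lower-triangular
Cholesky factors of Q and R, which enforces positive semidefiniteness by
construction and allows boundary solutions (rank-deficient Q̂) without
barriers. Gradients are analytic, via the standard REML identity
∂ℓ/∂θ = −½[tr(P ∂V) − y′P ∂V P y] evaluated blockwise and chained through
the Cholesky parametrization. Three starting points split the sample
phenotypic covariance 50/50, 10/90 and 90/10 between Q and R; the best
optimum wins and must weakly dominate every start. Stopping tolerances are
ftol = 1e−13 and projected-gradient 1e−8; the reported convergence flag
additionally requires the final gradient norm to be below 1e−5 of the
objective magnitude (the likelihood grows like n, so an absolute gradient
threshold would be meaningless across problem sizes). An estimate is
flagged `boundary` when the smallest eigenvalue of Q̂ falls below 1e−6 of
its trace; this is informational, not fatal — e.g. duplicated traits
legitimately drive the genetic and residual correlations to 1.

Phenotypes are standardized per trait internally and all estimates mapped
back (Q̂ and R̂ by the scale outer product, the restricted likelihood by its
(n−1)Σlog s Jacobian term). This makes results equivariant under rescaling
any trait — multiplying a trait by c scales its variance components by c²
and leaves heritabilities and all correlations unchanged to optimizer
precision (~1e−12 in practice) — and conditions the search well regardless
of trait units.

Standard errors come from the inverse numerical Hessian of the negative
restricted likelihood in the unconstrained parametrization (statsmodels
finite differences, pseudo-inverted to tolerate boundary singularity),
delta-method mapped to heritabilities, correlations, and covariance
entries. Derived parameters: h²_t = Q_tt/(Q_tt+R_tt), r_G = Q_xy/√(Q_xx
Q_yy), r_e analogously from R, r_P from Q + R; zero variances yield NaN
correlations with a log message rather than errors.

Identifiability: Q and R are separable only through the spread of K's
eigenvalues, so a kernel numerically proportional to I is rejected. With
T = 1 and K = I the likelihood would depend on Q + R only — the degenerate
ridge case this guard excludes.

## Prediction

Breeding values of target individuals are the conditional mean given the
training phenotypes and the variance components estimated on training data
only:

    ĝ_target = (K_target,train ⊗ Q̂) V̂_train⁻¹ (y_train − Xμ̂),

computed through the eigendecomposition of the training block of K plus one
cross-block multiplication. K spans train ∪ target but target phenotypes
never enter (the spanning-K conditional-mean reading of test-set
prediction; re-fitting on the full data would leak). Individuals with zero
kinship to every training individual get exactly ĝ = 0.

## Cross-validation and genetic regressions

The evaluation stage repeats R = 20 random 60/40 train/test partitions
(train size round(0.6n)). Splits are drawn once per replicate and shared
across all (G-variant, λ) cells, making comparisons along the grid paired —
the statistically stronger design when the question is the *shape* of the
predictive-ability curve in λ. Variance components are re-estimated per
cell on the training subset; predictive correlation pairs the held-out
pre-corrected phenotype (used as-is, not re-standardized) with the
predicted breeding value, and MSE is the mean squared difference.
Convergence failures are recorded per cell and skipped, never fatal; a cell
family with >50% failures is flagged in the log.

Expected genetic regressions b(x,y) = r̂_G(x,y)·√Q̂_xx/√Q̂_yy are compared
with realized slopes from intercept-included OLS of test phenotypes of x on
predicted breeding values of y (the intercept is the safe default since
phenotype and DGV means differ); a predictor with zero variance yields NaN.
By construction b(x,y)·b(y,x) = r̂_G², so the two slopes of a pair always
share a sign.

## Synthetic data

The generator emulates the structure of a commercial broiler dataset: a
founder cohort and non-overlapping offspring generations with dams nested
within sires (half-sib families composed of full-sib groups), unlinked
biallelic SNPs gene-dropped through the pedigree with founder frequencies
uniform on (0.05, 0.5), and three traits. Default sizes — 120 founders,
three generations of 25 sires × 75 dams × 5 offspring (1245 individuals,
225 full-sib groups), 1000 SNPs — give pedigrees of the same shape and
order as that study system. Default trait parameters are unit phenotypic
variances with heritabilities (0.2, 0.25, 0.3), genetic correlations
(0.5, −0.2, −0.2) and residual correlations (0.5, −0.05, −0.05): a
growth/growth/reproduction trio with a strong positive growth correlation
and weak antagonism against reproduction. Nuisance contamination is purely
additive categorical shifts (sex 2 × hatch week 6 × pen 8 levels by
default, effect SD half a phenotypic SD), so fixed-effect residualization
can remove it exactly and the pre-correction stage is testable for exact
recovery.

Two architectures:

* **infinitesimal** — founder breeding values ~ N(0, Q); offspring =
  mid-parent + Mendelian-sampling deviation with covariance
  ½(1 − (F_s+F_d)/2)·Q (¾ − ¼F with a single known parent, full Q with
  none). The pedigree model is exactly true; markers carry only family
  structure.
* **pleiotropic_qtl** — per-QTL effect T-vectors drawn with correlation
  `qtl_effect_corr`; breeding values are centered-genotype-weighted sums
  over a random QTL subset, rescaled by one scalar so the realized genetic
  covariance matches the targeted share of trace(Q). Setting
  `qtl_variance_frac` < 1 adds an infinitesimal polygenic background with
  its own correlation matrix (`polygenic_corr`) carrying the remaining
  trace share. When the QTL and polygenic correlations differ, the
  marker-based kernel leans toward the QTL-component correlation and the
  pedigree kernel toward the polygenic one, implanting a *directional*
  divergence between r̂_G at λ = 1 and λ = 0 — the controllable analogue of
  missing/excessive/spurious marker-based correlations.

Loci are unlinked (no recombination map or marker–QTL LD beyond family
structure and shared causal loci); there is no selection across
generations, and residuals are Gaussian. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
model, not robustness to LD patterns, selection history, or non-Gaussian
noise in real populations. One master seed is split into per-stage
substreams (pedigree, genotypes, traits), so identical configurations
reproduce bit-identical datasets and each stage is reproducible in
isolation.

## Phenotype pre-correction

Raw phenotypes are residualized per trait on intercept + reference-coded
dummies of the named categorical factors; output is centered. All factors
are treated as **fixed** even where a random-hatch treatment would be
conventional for a lowly heritable reproduction trait: with the balanced
synthetic designs used here the difference is a shrinkage detail, and the
fixed-effect formulation keeps this stage free of a second mixed-model
solver while being exactly invertible on simulated truth. A rank-deficient
design (confounded factors) is an error naming the factors involved. The
operation is idempotent and leaves residuals orthogonal to every dummy
column.

## Numerical choices

* Symmetry of all kinship constructions enforced/validated at 1e−10.
* Eigenvalues of K floored at 0 after `eigh` (roundoff guard).
* `_safe_chol` adds 1e−8 ridge when a start covariance is near-singular.
* SNP QC thresholds: MAF < 0.01 and call rate < 0.95, the conventional
  chip-data defaults for this kind of analysis.
* Naive imputation replaces missing calls by the 2p mean dosage — plumbing
  for completeness; haplotype-based imputation is deliberately out of
  scope.
* Matrix TSV round-trips use %.17g printing and round-trip float parsing.
* CV split sizes use round(train_frac·n); ties in min-max scaling are
  irrelevant because only the global extrema enter.

## Problem sizes in tests and the acceptance script

The test suite exercises parameter recovery on 20 replicate 1500-member
pedigrees (T = 3), the kernel-divergence sign test on 20 replicates of
420-member two-trait populations per architecture, and a 20-replicate
six-λ cross-validation on a 300-individual population — sizes chosen so
the full suite runs in about a minute on one CPU while keeping Monte-Carlo
error well below the effects being asserted. `scripts/acceptance.py` uses
the same scales.

## Limitations

* No single-step H-matrix, no weighted-SNP or LD-adjusted G variants.
* No Bayesian treatment of λ; the grid-plus-CV choice is the design.
* Missing phenotype cells unsupported (by model structure, not oversight).
* Standard errors are asymptotic; near boundaries they should be read as
  diagnostics, not as the basis of formal tests.
* The simulator's realized QTL-component covariance is trace-matched to
  its target, so individual entries of the realized genetic covariance
  fluctuate around Q at finite QTL counts — intentional, as this sampling
  noise is itself one source of "spurious" marker-based correlation.
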