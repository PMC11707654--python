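# Methods

## Model

Each trait is analysed separately with the linear mixed model

    y_ijk = mu + E_j + R_k(j) + G_i + GE_ij + e_ijk,

where `E_j` (environment, here planting spacing) and `R_k(j)` (complete
block within environment) are fixed, and genotype `G_i ~ N(0, sigma2_g)`,
interaction `GE_ij ~ N(0, sigma2_ge)` and residual `e ~ N(0, sigma2_e)`
are independent random effects. Traits are never fitted jointly; the
multi-trait structure enters only downstream, through the correlations of
the per-trait BLUP predictions.

Variance components are estimated by REML with the EM algorithm on
Henderson's mixed-model equations (MME). The GEI block is absorbed
analytically — each observation carries exactly one genotype×environment
cell, so that block of Z'Z is diagonal and its Schur complement costs
O(q·(p+g)²) to form — leaving a dense system of order p+g (fixed effects
plus genotypes). One EM step therefore costs O((p+g)³) independent of the
number of observations; at the largest analysis unit shipped here (573
genotypes) a step takes ~50 ms.

EM updates are the standard ones: for each random factor,
`sigma2_u <- (u'u + sigma2_e * tr(C_uu)) / q_u` with `C_uu` the
corresponding block of the inverted MME coefficient matrix, and
`sigma2_e <- (y'y - b'X'y - u'Z'y) / (n - rank X)`. The restricted
log-likelihood is evaluated at every iterate from the same factorisation
(`log|V|` and `log|X'V⁻¹X|` via the block-determinant identities), and its
monotone increase is asserted in the test suite.

### Initialisation, convergence, boundaries

Fits start at the balanced-ANOVA moment estimators
(`sigma2_e = MSE`, `sigma2_ge = (MS_GE − MSE)/b`,
`sigma2_g = (MS_G − MS_GE)/(be)`), truncated at zero. On balanced data
these are the REML optimum and a fixed point of EM, so the balanced case
converges immediately and exactly reproduces the classical estimators; on
unbalanced data the same sums (with observed cell means) give a warm start
only.

Convergence is declared when the relative change of the restricted
log-likelihood **and** of every variance component falls below `tol`
(default 1e-8, max 500 iterations). Two boundary behaviours need care:

* components are floored at `1e-10 × var(y)` (REML boundary behaviour);
* a component collapsing to the boundary, or sitting in a nearly flat
  likelihood direction, shrinks by a near-constant factor every iteration
  and would never satisfy a pure relative-change rule. A fit is therefore
  also accepted once the relative likelihood change has stayed below
  `10 × tol` for ten consecutive iterations. In that regime the likelihood
  is flat to ~1e-7 and any further movement of the crawling component is
  statistically meaningless.

A truly constant response (every variance zero) makes the restricted
likelihood unbounded; the fit short-circuits to the exact least-squares
fixed effects with all variances zero and a `degenerate_constant_response`
flag.

With a single environment the interaction is inestimable: the reduced
model (genotype only) is fitted and flagged.

### Tests of random effects and the joint ANOVA

Each random term is dropped in turn and the LR statistic
`2(l_full − l_reduced)` referred to chi-square with 1 df, as is customary
in this literature even though the boundary argument suggests the
`0.5·chi2(0) + 0.5·chi2(1)` mixture; `mixture=True` switches to the
halved p-values.

The combined ANOVA uses sequential (Type I) sums of squares in the order
ENV → REP(ENV) → GEN → GEN×ENV, computed by incremental least squares on
sparse indicator matrices (degrees of freedom from level/cell counts, so
empty genotype×environment cells reduce the interaction df). On balanced
data GEN is tested against the GEN×ENV mean square and everything else
against the residual; unbalanced data fall back to residual denominators
for every term, with a warning, since no exact denominator exists there.
Stars follow the P ≤ 0.05 / 0.01 / 0.001 convention.

## Genetic parameters

From `(sigma2_g, sigma2_ge, sigma2_e)` with `e` environments and `b`
blocks: h², r²i, h²mg, accuracy √h²mg, CVg, CVr and their ratio, using the
fitted fixed-effect surface averaged over the environment×block grid as
the grand mean μ (identical to the raw mean on balanced data).

Two definitions of the genotype–environment correlation `rge` circulate:
`sigma2_g/(sigma2_g + sigma2_ge)` and `sigma2_ge/(sigma2_ge + sigma2_e)`.
Published parameter tables for this trial type are numerically consistent
only with the second (which is also what the upstream R tooling prints),
so it is the default; the first is available as `definition="genotypic"`.
Both are exposed rather than silently resolved.

## The selection index

1. **Rescaling.** Affine map of each trait column to [0, 100] with the
   desirable extreme at 100. All eight default traits are treated as
   "increase"; the direction is configurable per trait. Affine maps leave
   the trait correlation matrix unchanged (up to sign for "decrease"
   columns), which the tests assert to 1e-10.
2. **Factor analysis.** Eigen-decomposition of the correlation matrix of
   rescaled values; factors with eigenvalue > 1 retained (at least one,
   with a warning when the Kaiser rule would retain none); initial
   loadings `eigvec·√eigval`; varimax rotation. Varimax uses the classic
   Kaiser-normalised SVD iteration, but with stopping tolerance 1e-8
   rather than the customary 1e-5: with two factors of nearly equal
   variance the iteration passes very slowly through a saddle, and the
   loose tolerance stops it there, short of simple structure (the
   iteration cap is raised accordingly). Eigenvalue ties are broken by
   original index; after rotation each factor's loading vector is
   sign-fixed so its largest-magnitude loading is positive — eigenvector
   sign is arbitrary and distances are invariant, this only makes the
   reported tables deterministic.
3. **Scores and ideotype.** Regression scores `F = Z R⁻¹ A` with Z the
   column-standardised (ddof = 1) rescaled matrix; a singular R gets a
   1e-8 ridge, with a warning. The ideotype row [100, …, 100] is
   standardised with the genotype-derived column statistics and projected
   through the same operator — the natural reading of "scored by the same
   formula", and it makes a genotype whose rescaled row is all 100 land
   exactly on the ideotype.
4. **Distance, selection, gains.** Euclidean distance in score space;
   `round(intensity·n)` lowest-distance genotypes selected (round half
   away from zero — this reproduces counts of 26/25/35/86 from family
   sizes 172/169/232/573 at 15%), distance ties broken by genotype label.
   ω rows are reported uniform (1/f, flagged) for a genotype exactly at
   the ideotype. Gains are computed on the *original* two-way table, each
   trait annotated with the factor holding its largest absolute loading.

The index consumes across-environment genotype predictions (μ̂ + û_g) by
default; a per-environment table can be supplied instead, but gains tables
are conventionally reported once per family, not per environment.

## Correlation reports

Pearson r/p per trait pair on complete pairs, on phenotypic genotype means
and on BLUPs (the latter attenuated by shrinkage — the tests check sign
agreement for pairs with substantial true correlation, not magnitudes).
Trait clustering uses distance 1 − r with average linkage by default; the
literature rarely states its clustering parameters, so both are
configurable.

## Synthetic data

The generator inverts the analysis model exactly: fixed environment and
block shifts plus Gaussian G, GE and residual draws, with the cross-trait
genetic correlation applied to G only — interaction and residual effects
are trait-independent, since published correlations for this design are
reported at the genotype level and no GE cross-trait structure is given.
Whether stomatal and growth traits share genotype-level correlation is
left to the caller; the default matrix encodes the reported sign
structure (leaf-morphology block positively intercorrelated, height
mildly positive with everything, stomatal density and length mutually
negative and weakly negative against leaf traits) with magnitudes chosen
to be comfortably positive definite.

Presets encode the published per-trait variance partitions (phenotypic
variance, h², r²i) and genotypic CVs of the three families and the joint
set; trait means are recovered from the CVs as `mu = 100·√sigma2_g / CVg`,
which lands on the published population means (e.g. ~8.1 for height,
~48 for petiole length in the joint set). Default fixed environment shifts
are ±¼ phenotypic SD with signs matching the reported spacing response
(denser spacing raises stomatal density and depresses the rest); block
shifts are Gaussian with 0.4 phenotypic SD, reflecting the large
replicate-within-environment mean squares of such trials.

Attrition is per-record Bernoulli thinning (default rate 0.15) with a
floor of one observation per genotype×environment cell per trait — the
simplest mechanism producing the reported unbalancedness, where each
genotype survives with roughly 2–6 of its 6 plants. It does not emulate
whole-plot loss, spatial field trends, or non-Gaussian traits; passing
tests therefore demonstrate correctness of the estimators and index under
the stated Gaussian model, not robustness to field artefacts the model
does not describe.

## Problem sizes used in validation

The oracle-equivalence checks run at 200 genotypes × 2 environments × 3
blocks; heritability recovery uses 200 replicate simulations per preset in
the test suite (50 in the acceptance script) at the same size; the
acceptance pipeline runs the three families at their published sizes
(172/169/232, joint 573). These sizes keep the full validation cycle at a
few minutes on a single CPU while leaving Monte-Carlo error an order of
magnitude below the tolerance bands.

## Known limitations

* No pedigree/kinship covariance, spatial or autoregressive residual
  structures, or multi-trait REML.
* LRT p-values use the published chi-square(1) reference by default even
  though it is conservative at the boundary.
* The EM fitter reports flat-likelihood boundary crawls as converged (see
  above); the affected component is then determined only up to a
  likelihood plateau of ~1e-7.
* The Shapiro–Wilk statistic tests residual normality; it is sometimes
  described in this literature as a check of residual-variance
  homogeneity, which it is not. The named test is implemented as such.
* Stomatal trait labels in source tables are occasionally inconsistent
  (a "stomatal number" trait appears in prose but not in the measured
  trait list); the eight measured traits are used throughout.
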