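# Methods

This note documents the statistical models, conventions and numerical
choices behind `semvar`, and what the synthetic-data-backed tests do and do
not establish.

## Structural model and estimation

The structural equation model over a pathway's variables is the linear
system `[y η]ᵀ = B [y η]ᵀ + Γ x + ζ` with measurement equations
`z = Λ η + δ`. Assumptions: errors Gaussian and mutually uncorrelated with
regressors; `I − B` nonsingular; structural and measurement error
covariances diagonal; pairwise covariances between exogenous pathway
variables fixed to zero; latent variables scaled by the reference-group
convention — variance 1 and mean 0 for exogenous latents, disturbance
variance 1 for endogenous latents (the total variance of an endogenous
latent is derived, so the constraint is placed on its disturbance).

Internally the implementation does not keep four separate LISREL blocks.
Every variable — observed gene, latent, covariate — is one row of a single
path matrix `A` and error covariance `Ω`; the implied covariance of the full
vector is `(I−A)⁻¹ Ω (I−A)⁻ᵀ` and the observed block is selected from it.
This is algebraically identical to the B/Γ/Λ assembly and much simpler to
differentiate. The public grammar (`SemModel.pattern_B/Gamma/Lambda`) still
exposes the classical patterns.

Estimation minimizes `F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p` with `S`
the unbiased (n−1 denominator) sample covariance. Multigroup fits minimize
`Σ_g (n_g−1) F_g` jointly; the model χ² is this value at the optimum, the
dominant convention in SEM software.

### Covariates and the mean structure

Each observed gene receives a linear covariate equation (age, sex, batch,
two expression PCs) whose slopes are constrained equal across groups, while
all structural parameters stay group-specific. Covariates enter as observed
exogenous variables under a fixed-x convention: their variance/covariance
block is fixed at the group sample moments and therefore contributes no
misfit. With per-variable intercepts left free the mean structure is
saturated in every group and profiles out of the likelihood, so the fit is
covariance-only; intercept equality across groups is deliberately *not*
imposed (the covariate adjustment is a residualization, not a mean model).
The zero-covariance constraint on exogenous pairs applies to exogenous
pathway variables, not to the fixed-x covariate block — fixing empirically
correlated covariates to zero covariance would leak sampling noise into χ².

Degrees of freedom: `G·[p(p+1)/2 − q(q+1)/2] − k` with `p` observed
variables including the `q` covariates and `k` the optimized parameters
(shared slopes counted once).

### Optimization and standard errors

Quasi-Newton (L-BFGS-B) on unconstrained parameters with error variances
log-transformed; the objective is normalized by `Σ_g (n_g−1)` so its scale
is O(1) regardless of sample size. Starting values: structural paths 0.1,
loadings 1.0, slopes 0, error variances half the observed variance.
Convergence: relative function tolerance 1e-13, projected-gradient
tolerance 1e-9, 500 iterations maximum; a fit is also accepted as converged
when the final normalized gradient is below 1e-6 (the line search can stall
one step short of the tolerance at machine precision). The analytic
gradient uses `dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) dΣ]` with exact derivatives of the
all-variable assembly; it is verified against finite differences in the
test suite.

Standard errors come from the observed information of the
`Σ_g ((n_g−1)/2) F_g` objective — the Hessian is computed by central
differences of the analytic gradient (relative step 1e-5) in the natural
(untransformed) parameterization. The `(n_g−1)` factor keeps the
information consistent with the χ² convention; the alternative `n_g`
scaling differs by O(1/n). Simulation places 95% CI coverage at 0.95
(±0.01) at n = 1000.

### Identifiability

A fit is declared empirically non-identifiable when any of the following
holds, each reported by name: the optimizer failed to converge; the sample
covariance of a group is singular (constant or collinear variables); the
observed information matrix has a relative eigenvalue below 1e-8; the
inverse information places negative variance on a parameter; any standard
error exceeds 20× the estimate and 10 in absolute value. Non-identifiable
alternatives are discarded by the model search, never fatal.

### Fit indices

`RMSEA = √G · √(max(χ²−df, 0) / (df·(N−G)))` with `G` groups and `N` total
samples; reported as 0 with a warning when df = 0. `CFI = 1 − max(χ²−df,0) /
max(χ²_b−df_b, χ²−df, 0)`, clamped to [0, 1], against an independence
baseline with free variances *and* free covariate slopes — keeping the
baseline nested within the target model under covariate adjustment, so CFI
stays in range. Per-group `AIC_g = −2 lnL_g + 2k_g` and
`BIC_g = −2 lnL_g + k_g ln n_g`, where `lnL_g` uses the same (n−1)-scaled
convention as χ² and `k_g` counts the group's own parameters plus an equal
share of the shared covariate slopes; only between-group comparisons of
these values are meaningful.

### Between-group tests and model selection

Per-edge Wald difference: `z = (θ̂₁−θ̂₂)/√(SE₁²+SE₂²)`, two-sided normal p.
The group estimates come from independent samples; the slight correlation
induced through shared slope parameters is ignored, and simulation shows
the resulting null p-values are uniform (KS test) with 5% size at α = 0.05.
"Non-significant path" in the search filter means control-group Wald
p ≥ 0.05 (α configurable). Selection: among identifiable fits with at most
3 non-significant control paths and RMSEA < 0.2, the highest CFI wins; CFI
ties within 1e-6 break by lower RMSEA, then by enumeration order, which is
fixed lexicographically (nodes in declaration order, members in declared
order) so results are reproducible. Networks are capped at 14 nodes for
the SEM stage and 10,000 alternatives by default for enumeration.

## Variance stage

Variances are unbiased per gene per group; exact ties give an undefined
indicator and are excluded from the sign-test n (the count is reported).
The sign test is the exact binomial tail `P(X ≥ k | n, ½)`.
Residualization is per-gene pooled OLS on the supplied normalized values
(intercept + numeric covariates + dummy-coded categoricals) — the package
consumes an already-normalized matrix, so no count-model machinery is
involved; this keeps the stage self-contained and exactly testable.
Levene's test uses mean-centered absolute deviations (the classic form;
median-centering is a flag away in scipy for comparison) and, for two
groups, the pooled t-form of the statistic — identical in square to the
ANOVA F form — so the one-sided alternative var(test) > var(reference) is
well defined. Swapping the group labels maps p to exactly 1 − p. Type-I
error at α = 0.05 is 0.050 ± 0.01 in 10,000-replicate Gaussian null
simulations.

## Enrichment stage

* **EASE ORA** subtracts one hit from the overlap cell (floored at zero)
  before the one-tailed Fisher exact tail, so single-gene overlaps are never
  significant.
* **Node-based ORA** counts nodes with ≥ 1 flagged member. The null permutes
  the flags across the analysis universe; for the member genes this is a
  multivariate hypergeometric law, which is sampled directly (exactly
  equivalent, far cheaper than permuting 20k+ flags per trial). "More
  extreme" means ≥ the observed score, and the p-value uses add-one
  smoothing `(1 + #extreme)/(1 + trials)` so p > 0 always — a deliberate,
  documented deviation from the raw trial proportion. Default 10⁶ trials.
* **Preranked GSEA** is the classic running-sum statistic with weight
  exponent 1, genes ranked by ascending Levene p (scores −log₁₀ p). The
  permutation p compares the observed ES against the same-sign half of the
  gene-label permutation null — the standard signed convention; comparing
  against the full null would bound p by ~0.5 and destroy uniformity. The
  multilevel speedup of modern implementations is out of scope (a speed
  optimization, not a definitional component).
* **Node-based Fisher GSA** aggregates in two stages — member p-values to a
  node p by `−2Σ ln p ~ χ²(2m)`, node p-values to a pathway p the same way —
  matching the node-centric design of the ORA; zero p-values are clamped to
  the smallest positive float with a warning. A single-stage pooled-gene
  variant would be a trivial modification but is not what "node-based"
  implies, so it is not the default.
* **Selection**: pathways at FDR < 0.01 under either node-based method are
  merged into the selected set. The enrichment universe is all analyzed
  genes in the supplied indicator (configurable and logged), not the genome.

## Classifier stage

PCA on centered, unscaled residuals (residual scales are already comparable
after covariate adjustment; scaling would equalize genuinely informative
variance differences). Components with individual explained-variance
fraction ≥ 1% enter a maximum-likelihood logistic regression with status as
the outcome — status is the response and components the predictors, the
only consistent reading of the design. The C-index is the rank
(Mann–Whitney) estimate with ties counted ½, identical to the trapezoidal
AUROC to machine precision. Pseudo-R² is Nagelkerke by default (McFadden is
reported alongside) since the variant behind a bare "R²" in logistic
reporting is ambiguous. Perfect separation is flagged, the coefficients
reported with a warning.

## Synthetic-data generator

The generator is the sampling inverse of the fitted model: per group, draw
covariates (age ~ uniform integers 18–65, sex and batch ~ Bernoulli(½),
two PCs ~ standard normal), Gaussian structural/measurement errors, and
solve the linear system for the observed variables. Covariate effects are
shared across groups by construction; latents have unit variance. Unchosen
members of complex nodes are generated as independent Gaussian decoys so
that every alternative model can be fitted. The background block is
independent Gaussian genes with a configurable fraction variance-inflated
in one group. Defaults mirror the emulated study design: 144 case and 111
control samples, 23,920 background genes; the inflation regime
(fraction 0.3, factor 2.0, base variance 1) is a package choice of a
realistic moderate-signal setting, fixed once. Seeds derive from one
master seed via `SeedSequence.spawn`, so every output is bit-reproducible.

What the generator does **not** emulate: count noise and mean-variance
coupling of RNA-seq (all downstream stages consume normalized, residualized
values, so errors are Gaussian by design; an optional count layer was
considered and rejected as out of scope), gene-gene correlation in the
background, batch structure beyond a two-level effect, and missing data.
Passing tests therefore demonstrate correctness of the estimators and
procedures under their stated assumptions — not robustness to RNA-seq
artifacts.

## Problem sizes in the test suite

The simulation-backed validation uses sizes chosen to make the Monte-Carlo
error small relative to the tested tolerances while keeping the default
suite quick: 500 single-group fits at n = 1000 for CI coverage; 200
replicates for Wald null calibration and 100 for power at n = 500/group;
10⁶ trials against the exhaustive node-ORA oracle; n = 200,000 draws for
the implied-covariance oracle; 50 replicates of the 8-alternative
model-selection study at n = 1000/group; 10,000 replicates for Levene
type-I error. The end-to-end demo uses 255 samples, 405 genes, 20,000
node-ORA trials.

## Known limitations

* Covariance-only ML assumes multivariate normality; no robust (Satorra-
  Bentler) corrections are provided.
* The Wald difference test ignores cross-group parameter covariance from
  shared slopes (empirically negligible; see calibration tests).
* Bundled pathway edge topologies are reconstructions; node partitions and
  gene lists are exact, so alternative-model counts are too, but edge-level
  conclusions on real data should use user-verified topologies.
* Endogenous latent scaling fixes the disturbance, not the total variance.
* No missing-data support; samples with incomplete covariates must be
  dropped upstream.
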