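# Methods

## The models

`holowas` tests single-SNP associations with a quantitative trait while
accounting for host genetic and gut-microbial similarity between animals.
All four scans are linear mixed models of the form

    y = X beta + Z gamma + (random effects) + e,       e ~ N(0, sigma_e^2 I)

where `y` is the trait, `X` the fixed covariates (intercept, optional
genotype principal components, any user columns), and `Z gamma` a single
SNP effect tested at a time with the Wald statistic
`W = gamma_hat^2 / var(gamma_hat)` referred to chi-squared with 1 df.
The models differ only in the random-effect kernels:

* **GWAS** — one polygenic effect `g ~ N(0, sigma_g^2 G)` with
  `G = X_s X_s' / (q - 1)` the genomic relationship matrix from
  column-standardized dosages `X_s` (VanRaden standardization
  `(x - 2p) / sqrt(2p(1-p))` with observed allele frequencies).
* **M-GWAS** — one microbial effect `m ~ N(0, sigma_m^2 M)` with
  `M = R R' / p` built from the log-transformed OTU relative-abundance
  matrix `R` (p = OTU count).
* **HWAS-CG** — `g + m + h_c`, where `h_c = L_M L_G' + (L_M L_G')'` is
  built from the Cholesky factors of `M` and `G`. `h_c` is in general
  indefinite; its coefficient `sigma_hc` is interpreted as the
  *covariance* between the genomic and microbial effects and is left
  unconstrained in sign.
* **HWAS-H** — `g + m + h_hp` with `h_hp = G ∘ M` (Hadamard product),
  positive semidefinite by the Schur product theorem; its coefficient is
  constrained non-negative like a variance.

## Estimation and testing

Variance components are estimated once per trait and model, without any
candidate SNP, by restricted maximum likelihood: average-information
(AI-REML) updates with step-halving and an EM-REML fallback whenever an
AI step does not improve the restricted likelihood. Convergence is
`|delta log-lik| < 1e-6`, at most 100 iterations; parameters start at
equal shares of the phenotypic variance (the covariance coefficient at
0). Non-negative parameters are projected to the boundary; if the
unconstrained HRM-CG coefficient drives the fitted `V` indefinite it is
halved toward zero until a Cholesky factorization succeeds.

The fitted covariance `V = sum_k sigma_k^2 K_k + sigma_e^2 I` is
eigendecomposed once (`V = U D U'`); `y`, `X` and every SNP column are
rotated through `D^(-1/2) U'`, after which each per-SNP test is ordinary
least squares in whitened coordinates. `var(gamma_hat)` is taken from
the GLS information under the fitted `V` (equivalently, unit error
variance after whitening), the convention of EMMAX-type mixed-model
scans. The alternative — scaling by a per-SNP residual variance, which
turns `W` into a squared t statistic — is *not* used: at n = 300 it
shifts the pooled null rejection rate at alpha = 0.05 to about 0.051
because a t-squared tail is compared against chi-squared(1), whereas the
fixed-V form with REML components is nearly exactly calibrated.

Holding the null-fitted components fixed across SNPs (the P3D/EMMAX
approximation) is the default; `run_model(..., exact_per_snp=True)`
re-estimates components with each SNP in the fixed effects. The two
paths agree closely in the bulk (median |delta log10 p| ~ 0.003 at
n = 80, q = 50) but can differ visibly at strongly associated SNPs,
where the exact path absorbs the SNP's own variance into the components;
this is the documented cost of the approximation, not a defect of either
path (both are verified against explicit-inverse GLS).

Missing dosages are kept as missing in storage and mean-imputed (to
`2p`) only at standardization/testing time. SNPs whose rotated column is
numerically constant are flagged and emit missing p-values.

## Significance regimes

Per scan: an arbitrary per-test threshold `p <= 0.05`; Benjamini-
Hochberg step-up adjusted p-values (via statsmodels); Bonferroni
`alpha / n_tested` (0.05 over 132,214 tests = 3.78e-7, over 51,970 =
9.62e-7); and a permutation family-wise threshold ("GWST"): whitened
trait residuals are permuted T times (default 1000) with a seeded
generator, each permutation re-runs the fast scan, and the threshold is
the empirical alpha-quantile (k-th smallest, `k = floor(alpha (T+1))`)
of the min-p distribution. The permutation definition is this package's
explicit choice of a genome-wide threshold; a fixed user-supplied
threshold mode is also provided. These regimes nest by construction:
Bonferroni-significant ⊆ BH-significant ⊆ arbitrary-significant at equal
alpha.

The genomic-inflation factor is `lambda = median(W) / 0.4549` (median of
chi-squared(1)); values near 1 indicate calibration.

## Annotation

SNPs are mapped to genes from a GFF3 file by three criteria with a
SNP-centered window (default 100 kb, boundaries inclusive, strand
ignored): inside the gene (`within_gene`, distance 0); gene entirely
inside `[pos - w, pos + w]` (`within_window`); gene partially
intersecting it (`overlaps_window`). `nearest_gene` breaks ties by
distance, then start coordinate, then gene ID.

## Quality control

All comparisons are inclusive on the keep side: SNPs kept when
MAF >= `maf_min` (default 0.05) and call rate >= `cr_min` (default
0.95); OTUs kept when prevalence (fraction of samples with non-zero
abundance) >= `prevalence_min` (default 0.20). The OTU filter can
alternatively use mean relative abundance (`mode="abundance"`), since
"abundance rate" filters in the literature are ambiguous between the
two. The OTU log-transform uses a pseudocount (default: half the
smallest non-zero relative abundance, because the transform is undefined
at zero) and mean-centers each OTU column by default so that `R R' / p`
plays a covariance-like role next to the GRM rather than being dominated
by the compositional mean.

## The synthetic generator

`simulate` emulates a post-QC livestock panel, not raw data:

* genotypes: per-SNP MAF ~ Uniform(0.05, 0.5), dosages Binomial(2, MAF)
  i.i.d. across samples — HWE, no LD, no relatedness or population
  structure;
* microbiome: logistic-normal OTU table. Latent log-abundances are
  `sqrt(f) * (X_s B)_unit + sqrt(1-f) * E` with `f = otu_heritable_frac`
  (default 0.3, in the range reported for heritable rumen/gut taxa),
  plus per-OTU baseline offsets with sd 2.0 that reproduce the uneven
  abundance profile of 16S surveys; a row-wise softmax yields
  compositions summing to exactly 1;
* phenotype: `y = 1·beta + sum_causal z_j gamma_j + u`,
  `u ~ N(0, V_true)` drawn by Cholesky from the exact kernel mixture
  implied by the configured variance fractions. A genome-microbiome
  effect covariance is injected through the `h_c` kernel term
  (`rho_gm`), which equals the marginal covariance contribution of
  jointly drawn `(g, m)` effects with cross-covariance
  `rho L_G L_M'` — always samplable even though `h_c` alone is
  indefinite; `rho_gm` is halved automatically (and recorded) if it
  would break positive definiteness. Causal SNP effects are scaled so
  each explains a configured fraction of trait variance (default 0.05).

Because samples are unrelated and SNPs are independent, the off-diagonal
structure of `G` (and hence of the hologenome kernels) is weak at the
default sizes; the interaction variance is therefore only weakly
identified per replicate — estimates of the HRM-H fraction scatter
widely and truncate at zero — and recovery claims are about means over
replicates, not single fits. Passing tests on these data demonstrate
the estimator's correctness and calibration under the stated
architecture; they do not demonstrate performance under LD, family
structure, compositional zero-inflation beyond the logistic-normal, or
phylogenetically structured communities.

Default experiment sizes (n = 300–500, q = 2000, p = 200, 50–100
replicates) were chosen so that full calibration and recovery suites
complete in minutes on one CPU; larger runs are configuration changes
only.

## Numerical choices

* Kernels are symmetrized exactly (`(K + K') / 2`) on construction;
  serialization keeps 15 significant digits.
* Cholesky jitter escalates ×10 from `1e-8 · mean(diag)` to `1e-2`;
  eigenvalue clipping floors at a configurable tolerance.
* Whitening requires the fitted `V` to be positive definite; the REML
  fit guarantees this by the shrink-to-PD rule for the covariance
  coefficient and by flooring the residual variance at `1e-6` of the
  phenotypic variance (a GCTA-style boundary constraint) so that `V`
  never becomes numerically singular when the residual estimate hits
  zero.
* A SNP is reported untestable ("degenerate") when its raw dosage
  column is constant; the whitened-norm check is only a numerical
  guard, because a near-null direction of `V` can inflate rotated norms
  by orders of magnitude without making a SNP untestable.
* Permutation thresholds, simulations and experiment grids are pure
  functions of their integer seeds (per-stream keys derive from CRC32 of
  the stream name, so results are stable across processes).
* Degenerate inputs (monomorphic SNPs at standardization, empty QC
  results, all-zero OTU tables, non-PD covariances) raise errors naming
  the offending object rather than propagating NaNs.

## Known limitations

* The exact per-SNP path is O(q) REML fits and is intended for
  verification, not production scans.
* HRM-CG's indefinite kernel means the "variance explained" bookkeeping
  for that model is a covariance decomposition; fractions can be
  negative.
* The annotation module treats SNPs as points and ignores strand; no
  regulatory-region or consequence annotation is attempted.
* No LD-aware or set-based tests; one SNP at a time only.
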