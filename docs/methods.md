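# Methods

`comorbigen` dissects the shared genetic architecture of comorbid complex
traits — the motivating case is depression co-occurring with atherosclerotic
cardiovascular disease — from GWAS summary statistics alone. Every method
operates on per-variant z-statistics and an LD reference; no individual-level
genotypes are required. This note records the models implemented, the
defaults and why, and what the synthetic validation does and does not show.

## The summary-statistic model

All modules share one generative model for a trait's marginal z-statistics
within an LD block with correlation matrix `R`:

    z = sqrt(n) R beta + eps,     eps ~ N(0, R)

where `beta` are joint effects on the standardized-genotype scale and `n` is
the GWAS sample size. When two studies share samples, the errors are
correlated across traits: `cov(eps_1j, eps_2j) = c R`, with `c` the product
of overlap fraction and phenotypic correlation. Binary traits enter as
z-statistics like any others; liability-scale conversion of heritability is
out of scope.

## Synthetic data (`simulate`)

The generator draws sparse causal sets and effect sizes under either

* a **latent-factor architecture**: `beta_t = loading_t * gamma + delta_t`,
  with a shared factor component `gamma` (causal proportion `pi_shared`) and
  trait-specific residual components `delta_t` (proportion `pi`). The
  component vectors are orthonormalized so realized per-trait heritability
  and pairwise genetic covariance equal their configured values *exactly* —
  recovery tests then measure estimator error only, not simulation
  wobble; or
* a **pair-mixture architecture** for exactly two traits: unique and shared
  causal sets with an effect correlation `rho12` inside the shared set.
  Effects here are left un-normalized so each causal effect stays exactly
  Gaussian, the distribution the mixture likelihood models.

LD is block-diagonal with AR(1) correlation profiles. The default decay
varies linearly from 0 to 0.9 across blocks: heterogeneous LD strength is
what makes LD scores vary, and with a common profile the LD-score regression
slope and intercept are barely identified. Defaults are M = 20,000 variants
in 100 blocks, `pi = 0.1`, `pi_shared = 0.05` — proportionally denser than a
real genome, deliberately: at desk scale this keeps several causal variants
per jackknife block, the polygenic regime in which LD score regression's
block jackknife is calibrated. Under very sparse desk-scale architectures
(a couple of causal variants per block) the jackknife understates the
causal-placement component of variance and 2-SE coverage drops to roughly
80%; the same caveat applies to real traits of very low polygenicity.

What the generator does *not* emulate: allele-frequency-dependent effect
sizes, case-control ascertainment, population stratification, and
genuinely long-range LD. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data complications.

## LD score regression (`ldsc`)

Heritability: weighted regression of chi-square on LD scores,
`E[chi2_j] = intercept + n h2 l_j / M`. Genetic covariance: regression of
`z1 z2` on LD scores with a free intercept absorbing sample overlap.
Estimation is strict two-step WLS — an unweighted pass sets the
heteroskedasticity weights (`1/(2 v_j^2)` for chi-square,
`1/(v1_j v2_j + m_j^2)` for the cross product) — rather than full IRLS. The
weight forms are chosen so the cross-trait machinery applied to one trait
against itself reduces *exactly* to the heritability machinery: the
self-correlation is 1 to machine precision by construction. Standard errors
come from a delete-one block jackknife over contiguous variant spans
(default 200 blocks, config-exposed); the multivariable wrapper shares one
block partition across all trait pairs so the sampling covariance `V` of all
unique elements of `S` is estimated jointly (PSD-projected with a flag when
numerical noise intrudes). Confidence intervals are reported on the raw
scale without a Fisher transform, giving symmetric intervals.

Partitioned enrichment regresses chi-square on per-annotation LD scores
(baseline always includes the all-ones annotation), tests the target
coefficient one-sided, and applies Benjamini–Hochberg across the targets of
one call. Expression-specificity annotations follow the top-decile
expression proportion construction: specificity is each gene's share of its
total expression across categories, the top decile per category forms the
gene set, and variants within the gene intervals extended by 100 kb (default
flank) are annotated.

## Local genetic correlation (`localrg`)

Within a block, eigendecomposing `R` and projecting z onto the components
explaining 99% of LD variance (default `pc_var`, config-exposed) whitens the
noise: the squared norm of the projection is chi-square distributed with `q`
degrees of freedom under no local signal, giving the local-heritability
estimate `(delta'delta - q)/n` and its gate p-value. Local correlation is
computed and tested only where *both* traits pass the marginal gate
(p < 0.05), mirroring standard practice; the gate is what keeps the
downstream FDR honest, and removing it demonstrably inflates significant
counts on null data.

Empirical two-sided p-values come from Monte-Carlo simulation of the null
cross product (10,000 draws by default) conditional on the estimated local
heritabilities. One subtlety matters for calibration: local signal
concentrates on high-eigenvalue LD components for *both* traits even when
their effects are uncorrelated, so the null draws give component `i`
variance `1 + n h2_loc lambda_i / m` rather than a flat variance — a flat
null is anticonservative. This Monte-Carlo scheme replaces the
partial-integration analytic null of the reference methodology; it is
validated by calibration (uniform null p, FDR held at its level) rather
than claimed numerically identical.

## Causal-mixture overlap (`mixture`)

The univariate model is a two-component Gaussian mixture for pruned
z-statistics; the bivariate model a four-component mixture over causal-set
membership (neither / trait 1 only / trait 2 only / shared) with an effect
correlation inside the shared component and a residual correlation for
sample overlap. The central simplification, stated in all outputs: LD is
handled by greedy pruning to pairwise r² < 0.1 before fitting, instead of a
convolution of the likelihood over LD. The cost is that `M_ref`, the
effective variant count the pruned panel represents, must be supplied; the
benefit is a likelihood that is exactly what the data were generated from
under the pruning approximation, validated end-to-end by parameter recovery
on synthetic architectures.

Estimation is profiled: univariate parameters are fixed while the three
overlap parameters (`pi12`, `rho12`, `rho0`) are optimized by bounded
quasi-Newton from a deterministic multi-start grid. Correlations are bounded
at |rho| ≤ 0.99 because the mixture density is singular at rho0 = 1 for
duplicated inputs. Two constrained fits bracket the overlap for AIC
comparison: minimal (|rho12| = 1, i.e. the smallest shared set able to
explain the covariance) and maximal (`pi12` at the less polygenic trait's
total polygenicity); a free fit beaten by both flags the overlap as not
identified, the analogue of excluding a trait pair on performance checks.

`n90` — the number of causal variants explaining 90% of heritability — uses
the chi-square tail-expectation identity `E[X 1{X>t}] = P(chi2_3 > t)` for
squared standard-normal effects, solving for the tail mass 0.9; for
equal-effect (point-mass) architectures it is simply `ceil(0.9 pi M)`. Venn
displays use n90-scaled counts by default, with raw `pi M` also emitted.
Sign concordance inside the shared component is the bivariate-normal orthant
probability `1/2 + arcsin(rho12)/pi`.

## Genomic SEM (`sem`)

Models are specified in RAM form (directed paths `A`, exogenous covariances
`S2`), so higher-order factors and mediation paths need no special cases.
Fitting is diagonally weighted least squares on the unique elements of the
LDSC genetic covariance matrix, with diag(V) weights, three deterministically
jittered starts, and sandwich standard errors using the full sampling
covariance V. The implied-moment Jacobian is computed by forward differences;
local identifiability is checked by its rank at the start values. Model
chi-square uses the V-metric GLS discrepancy, CFI compares against the
independence model, and SRMR is computed on the correlation-scale residual
matrix. Standardized loadings divide each path by the ratio of child to
parent implied SDs (the genetic-variance metric).

The bundled two-level comorbidity design puts a first-order factor over the
four atherosclerotic traits (first loading fixed to 1) and a second-order
factor over the depression trait plus that factor, with the depression
loading fixed to 1 and the first-order factor's residual variance fixed to 0
so that all of its variance is carried by the comorbidity factor.

**Factor GWAS and the Q heterogeneity test.** Adding a variant to the model
only changes the k SNP–trait covariance moments, and the independent-pathway
model (SNP → every indicator) saturates exactly those moments. The contrast
therefore reduces to a weighted projection: the SNP's trait-effect vector is
regressed onto the traits' model-implied total loadings on the factor, the
residual weighted sum of squares is the common-pathway chi-square, and

    Q = chi2_common - chi2_independent ~ chi2_{k-1}

under homogeneity (chi2_independent = 0 by saturation). This two-stage
formulation is algebraically the nested-model chi-square difference and
vectorizes over the whole genome. Cross-trait sampling covariance of the
per-variant effects (sample overlap) is approximated as zero in the
per-SNP weighting — a stated limitation; the null-calibration test is run
without overlap accordingly. Variants with `p_Q < 0.05` are flagged
heterogeneous and excluded from the filtered factor GWAS, and the flagged
share among genome-wide-significant variants is reported.

**Adjustment and mediation.** Covariate-adjusted genetic correlation is the
partial covariance `S_xy - S_xc S_cc^-1 S_cy` standardized by the analogously
partialled variances, with a delta-method SE over V and ridge regularization
(flagged) for ill-conditioned covariate blocks. The mediation model fits
x → m → y with a direct path; the covariate model is the partialled
correlation. These are different estimands — the partial correlation removes
the mediator from both sides — and their comparison is the point: following
the practice the design mirrors, attenuation of the mediator-model direct
effect to the point that its 95% CI no longer overlaps the covariate-model
CI is reported as tentative support for mediation. Both intervals and the
indirect effect (path product, delta-method SE) are emitted; the rule relies
on untestable assumptions and is labelled accordingly.

## Mendelian randomization (`mr`)

Instruments are clump leads at p < 5e-8, r² < 0.001, 5 Mb window, with a
fallback to p < 1e-5 capped at the 10 best leads when fewer than 10 survive;
the threshold actually used is always reported. Steiger filtering removes
variants whose outcome r² significantly exceeds their exposure r²
(one-sided Fisher-transform z test at 0.05). The battery: IVW with
multiplicative random effects by default (fixed-effects behind a flag),
MR-Egger with the I²_GX ≥ 0.9 no-measurement-error guard (slope reported
but flagged suppressed below it), weighted median and weighted mode with
parametric-bootstrap SEs (1,000 draws, mandatory seed). The sensitivity
verdict marks a pair robust only when IVW is significant, the Egger
intercept is not, and the sensitivity estimators agree in sign; a
significant intercept instructs non-interpretation of the causal estimate.

Multivariable MR unions the per-exposure clump leads, re-clumps the union
with the same parameters, aligns all effects to the primary exposure's
increasing allele, and fits a weighted multi-exposure regression without
intercept. A caveat discovered in validation and worth knowing: Steiger
filtering on the primary exposure–outcome pair systematically removes
mediator-specific instruments when mediation is strong — they legitimately
explain more outcome than exposure variance — which destroys the variation
identifying the conditional model. `steiger_alpha=None` disables the filter
for such mediation analyses; the default keeps it, matching common practice
for confounder adjustment. Conditional instrument strength is reported as a
mean F on each exposure residualized on the others (an approximation to the
conditional F statistic).

## Pipeline (`pipeline`, `cli`)

One YAML config drives simulate → clean → genome-wide correlation → local
correlation → mixture → factor GWAS → enrichment → adjusted/mediation → MR.
A single global seed is fanned out per stage by fixed offsets; every output
file is hashed into a manifest, and a rerun with the same config is
bit-identical. Problem sizes in the bundled config (10,000 variants, six
traits, n = 100,000) were chosen so a full run takes well under a minute on
one CPU while every stage still has power to detect its target signal.

## Numerical choices and degenerate inputs

* LD blocks are floored at eigenvalue -1e-8 (PSD tolerance); Cholesky
  factorizations add 1e-10 jitter.
* rg is clipped to [-1, 1] with a flag, and |rg| > 1.25 pre-clipping marks
  the estimate unstable.
* Mixture polygenicity is bounded below at 1e-6; estimates at the bound are
  flagged (null-data behavior).
* Negative SEM residual variances are permitted but flagged (Heywood);
  collinear mediator sets and duplicated traits raise explicit errors.
* BH adjustment is delegated to statsmodels throughout.

## Known limitations

* All effects live on the standardized-genotype scale; allele frequencies
  are bookkeeping only.
* The per-SNP factor GWAS ignores cross-trait error covariance in its
  weighting; with heavy sample overlap the Q test will be mildly
  miscalibrated.
* The mixture module's pruning approximation trades MiXeR-style LD
  convolution for tractability; absolute polygenicity estimates inherit the
  quality of the supplied `M_ref`.
* Local correlation handles one trait pair at a time; conditional
  multi-trait local models are not implemented.
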