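# Methods

`survfdr` implements two complementary significance-threshold estimators for
genome-wide association scans of a quantitative trait, together with the
supporting quality control, kinship, scan and simulation machinery needed to
run and validate them end to end.

## The two-groups local FDR

Per-SNP test statistics are taken to the z scale (two-sided by default:
z = Φ⁻¹(1 − p/2)·sign(β̂); p-values are clamped to [1e−15, 1 − 1e−16] before
inversion). The observed z follow the mixture

    f(z) = π₀ f₀(z) + (1 − π₀) f₁(z),

and the local false discovery rate of SNP i is the posterior null
probability locfdr(zᵢ) = π₀ f₀(zᵢ)/f(zᵢ), truncated to [0, 1].

**Marginal density.** f is estimated by Poisson regression of histogram
counts (120 fixed-width bins over the padded z range) on a cubic B-spline
basis. The spline degrees of freedom default to
max(5, ⌈1.5·log₁₀(m)⌉ + 4) so the basis grows slowly with the number of
tests m; boundary knots sit at the padded range ends and interior knots are
equally spaced. Per-observation locfdr values evaluate the fitted
log-density at each z (clipped into the knot span).

**Empirical null.** Genomic scans are rarely exactly N(0,1)-null (residual
structure, correlated markers, model misspecification), so the null is
fitted as N(δ, σ²) by truncated-normal maximum likelihood on a central
window, with π₀ recovered by count matching:
π₀ = (N_window/m) / P_{δ,σ}(window). The window is
median(z) ± 4.3·exp(−0.26·log₁₀ m) robust-scale units (half-IQR/Φ⁻¹(0.75)),
covering roughly 90% of the null mass. A narrower window (for example the
interquartile range) leaves σ weakly identified — its MLE then has sampling
standard deviation near 0.2 at m = 5000, which is useless for ranking
competing scan models — while the wide window brings that down to about
0.02. Optimization is Nelder–Mead on (δ, log σ) with 1e−8 tolerances.
`null_method="theoretical"` fixes (δ, σ) = (0, 1) exactly. π₀ is reported
raw (capped at 1.5) and truncated at 1 for use in locfdr.

**Model-comparison metrics.** The fit emits Delta (δ), Sigma (σ) and
Proportion-H₀. The null proportion is reported under two readings — the
mixture weight π₀ and the σ/δ ratio — because both summaries circulate in
practice for ranking scan models; they are separate keys in the metrics
dict and agree on nothing by construction.

**Selection.** `locfdr_select` returns indices with locfdr ≤ t (default
0.05) plus the realized Bayesian FDR of the selection, the mean locfdr over
the selected set, which is bounded by t by construction.

Fitting requires at least 200 finite z values; constant z is rejected.

## Bayesian survival FDR

The survival construction converts the trait ranking into pseudo-time:
individuals are ranked ascending by trait value (ties broken by sample id,
so the ordering is a deterministic permutation of 1..n). At a SNP the
sample partitions into allele classes — major homozygote (dosage 0),
heterozygote (1), minor homozygote (2), missing. Carriers of the minor
allele are events at their own pseudo-time; major homozygotes and missing
calls are censored there. Intuition: a minor allele confined to low-yield
genotypes "dies out" early along the ranking, one spread evenly persists.

**Survival curves.** The cumulative hazard is the Nelson–Aalen estimator
H(t) = Σ_{tᵢ≤t} dᵢ/nᵢ with S = exp(−H). Per-class curves treat every class
member as an event at its own pseudo-time, so a class's mean S over its
event grid measures how long the class persists along the ranking; a class
is "survived" when it has ≥ 3 members (`min_count`) and mean S ≥ 0.05
(`floor`). Class survival summaries (mean S, SE) together with AIC/BIC of
the hazard fits provide the model-comparison report.

**Hazard model.** Exposure times follow an exponential proportional-hazards
model λ(x) = λ₀·exp(β·x) with dosage covariate x. The fit is Newton on
(log λ₀, β), tolerance 1e−8, at most 100 damped steps. Because events are
structurally confined to minor-allele carriers, the reference group has
zero observed hazard and the unpenalized β diverges by complete separation;
a weakly informative N(0, 4) prior on β (sd 2 on the log hazard-ratio
scale) keeps the estimate finite without materially shrinking identified
fits. Reported logL, AIC = 2k − 2·logL and BIC = k·ln(d) − 2·logL (d =
event count) use the unpenalized likelihood at the optimum. The null model
(no covariate) has the closed-form MLE rate = d/Σt.

**Bayes survived factor.** λ_SNP = λ₀·exp(β_GY) carries the hazard
information into the prior. β_GY admits two readings: one genome-wide
coefficient from the pooled event table over all SNPs (`lambda_mode=
"global"`, the default — a flat prior across SNPs, matching the flat-prior
operating point λ₀ = 1, exp(β_GY) = 0.001 of a routine run), or each SNP's
own coefficient (`lambda_mode="per_snp"`). Per-SNP coefficients are
estimated and reported in either mode. At desk scale the per-SNP hazard
coefficient is dominated by the structural carrier-fraction effect rather
than association (its marginal ranking power is indistinguishable from
noise), which is why the flat prior is the default.

**Posterior inclusion.** A binary-indicator Gibbs sampler runs over the
two-group model z|γ=0 ~ N(0, 1), z|γ=1 ~ N(0, 1 + τ²) with τ² = 4 by
default. Prior odds for SNP j are (π₁/(1−π₁))·λⱼ/mean(λ), so the survival
factors tilt the prior without changing its average level; π₁ defaults to
0.05, and the pipeline passes 1 − π₀ from the local FDR fit. With fixed
prior odds the full conditional of each indicator is an independent
Bernoulli; the sweep draws all indicators per iteration (chunked to bound
memory at ~80 MB) and P_j is the post-burn-in mean. The documented default
is 150,000 iterations with 2,000 burn-in; tests and the acceptance script
use 10,000/1,000, at which the Monte-Carlo error of P is below 0.02
(verified against the closed-form posterior). Identical seeds give
identical P vectors.

**Decision rule and summaries.** SNP j is significant when
P_j > 1 − MAF_j: rare alleles must clear a higher evidence bar. MAF = 0
yields an unreachable threshold and a warning. Two set-level summaries are
reported: the ratio Σ P / Σ (λ·|z|) ("bsfdr_score", emitted verbatim — it
is not confined to [0, 1]) and the conventional Bayesian FDR mean(1 − P)
over the flagged set.

## Supporting machinery

**SNP QC.** MAF = min(q, 1−q) with q the alt-allele frequency over
non-missing calls; sites with MAF ≤ 0.05 are removed (strictly-greater
survives), call rate ≥ 0.9 required, and a 1-df HWE chi-square
(no continuity correction) is available but off by default
(`hwe_alpha = 0`): in a selfing organism the heterozygote deficit is
biology, not genotyping error. Monomorphic sites carry no HWE evidence and
get p = 1. All-missing SNPs fail with reason "callrate". Multiallelic VCF
records are rejected at read time.

**Phenotype QC.** Classical bootstrap of the trait mean (B = 2000 default;
boot SE = sd of replicate means, percentile 95% CI) and a Bayesian
bootstrap with flat-Dirichlet weights. The "Bayesian bootstrap p-value" is
pinned as the median Shapiro–Wilk p over weighted resamples of size n, one
per replicate — no standard definition exists, and this one is reproducible
and monotone in non-normality. Outlier detection uses Tukey fences
(k = 1.5) and is report-only; removal is the caller's decision.

**Kinship.** VanRaden method 1: K = WWᵀ / Σ 2p_k(1−p_k) with W the dosage
matrix centered at 2p per SNP. Missing dosages are mean-imputed (centered
value 0) inside this module only. `gblup_ebv` solves the single-trait mixed
model in closed form, u = K(K + λI)⁻¹(y − ȳ) with λ = (1−h²)/h², profiling
h² by grid REML (0.05..0.95 step 0.05) when not supplied, and reports the
correlation of the breeding values with the centered trait as a phenotype
quality summary.

**Association scan.** EMMAX-style exact two-step: the variance ratio is
estimated once under the null by grid REML on h² (0.01..0.99, 99 points,
ties toward lower h²) in the eigenbasis of K, then each SNP is tested by
GLS in the rotated basis with a two-sided t reference on n − rank(X) − 1
degrees of freedom and per-SNP residual variance, so with K = I (or
σ_g² = 0) the scan reduces exactly to OLS. Missing dosages are mean-imputed
in the regression design only; monomorphic SNPs get NaN effect and p = 1.

## Synthetic data

The generator emulates a selfing-crop association panel: ancestral allele
frequencies uniform on [0.05, 0.95], subpopulation frequencies from the
Balding–Nichols model (3 subpopulations, Fst = 0.1 by default), genotypes
drawn with inbreeding coefficient 0.95 (wheat-like selfing; mean GRM
diagonal ≈ 1.95). The trait mixes n_qtl = 10 standard-normal QTL effects on
centered dosages with a dense polygenic background (variance split 0.7/0.3)
standardized so the genetic fraction of trait variance equals h² = 0.3 by
default; defaults n = 221 individuals, m = 2000 SNPs. Optional balanced
LN/HN treatment labels with a mean shift, and symmetric ±5-sd outlier
injection. Everything is reproducible from (config, seed).

What the generator does **not** emulate: linkage disequilibrium (adjacent
markers are independent), chromosome-scale recombination maps, genotype ×
environment interaction, and real wheat allele-frequency spectra. Passing
tests therefore demonstrate statistical correctness of the estimators under
a clean population-genetic null and signal model, not performance on any
particular real panel.

A consequence of drawing QTL effects from N(0, 1) is that per-QTL variance
shares are χ²₁-skewed: in a typical draw 3–4 of 10 QTLs carry under 2% of
the genetic variance and are statistically invisible at n = 221, so
rank-recovery summaries (AUC of the posterior ranking) plateau around
0.75–0.85 depending on the draw — a ceiling set by the simulated genetics,
not by the estimators; the mixed-model scan matches or beats plain
regression and leave-one-chromosome-out variants on the same panels.

## Numerical choices and degenerate inputs

- p-value clamps: [1e−15, 1 − 1e−16] before normal inversion.
- Spline density floor 1e−10 before division; locfdr truncated to [0, 1].
- Eigenvalues of K clipped at 0 in the rotated likelihood.
- Pseudo-time ties broken lexicographically by sample id.
- Monomorphic SNPs: skipped by the hazard model (β = 0, identifiability
  flag), null scan record, removed by default QC.
- Zero events: survival S ≡ 1; exponential fit refuses (no information).
- Empty QC survivor set, constant z, all-monomorphic GRM: hard errors, not
  silent empty results.
- Problem sizes in tests and the acceptance script (m = 2000–10,000 SNPs,
  10,000 MCMC iterations, 20 null replicates) are chosen so the whole
  validation battery completes in a few minutes on one core while keeping
  Monte-Carlo error well inside each tolerance.

## Known limitations

- The bsfdr_score ratio has no [0, 1] interpretation; treat it as a
  comparative index between runs, and use mean(1 − P) for calibrated error
  rates.
- The empirical-null MLE assumes the central window is signal-poor; very
  dense signal (π₀ well below 0.9) inflates σ̂ and makes locfdr
  conservative.
- The exponential hazard on rank pseudo-time is a working model; its
  absolute AIC/BIC values are only meaningful for comparisons on the same
  event tables.
- With `lambda_mode="per_snp"` the prior tilt reflects hazard-scale
  structure (carrier fraction) more than association at realistic effect
  sizes; it is provided for completeness and experimentation.
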