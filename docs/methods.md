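# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, the numerical conventions, and the known limits
of what the test suite demonstrates.

## Enrichment scoring

For variant i the 2×2 allele table is (ALT_study, REF_study) vs
(ALT_ref, REF_ref), where the reference row comes from the eligible
reference population with the highest ALT frequency. Eligibility requires
the per-population coverage flag to pass (coverage is supplied as input
metadata, e.g. "≥20× depth in ≥80% of samples") and reference frequency
≥ 1e-4; ties on frequency break to the larger allele number (more
informative), then lexicographic label. The estimator adds 0.5 to every
cell (Haldane–Anscombe), which keeps both the log-OR and its Woolf SE
finite for any non-negative counts; the test is the one-sided ("greater")
Fisher exact upper hypergeometric tail, delegated to
`scipy.stats.fisher_exact` and verified in the suite against an
exact-rational enumeration oracle on all tables with total ≤ 30.

Classification uses the study-AF window [0.002, 0.1) — below it single-
digit allele counts cannot reach convincing significance, above it alleles
are largely shared between populations — and a Bonferroni threshold
α/n_tests with α = 0.05. `n_tests` defaults to the number of in-window
variants that have an eligible reference (the rule is data-size dependent);
an external constant can be passed to reproduce a published analysis.
Variants with no eligible reference are reported unclassifiable and never
enriched. The per-class summary compares each functional class to
synonymous variants with a pooled two-proportion z test. The
recessive-risk translation is simply the square of the fold enrichment:
homozygote frequencies scale as f² under HWE.

A practical note on reconstructing published odds ratios from printed
frequencies: a frequency printed as 0.0002 constrains the true value only
to [0.00015, 0.00025), which alone moves the reconstructed OR by up to
±25%. Reconstruction therefore agrees tightly on the log-odds scale but
only approximately on the OR scale, and the acceptance script reports both
agreement fractions.

## Firth logistic regression

The association fit maximizes ℓ(β) + ½ log det I(β) (Jeffreys prior
penalty) by Newton iterations on the modified score
U*(β) = Xᵀ(y − p + h(½ − p)), with h the hat diagonals of
W^½X(XᵀWX)⁻¹XᵀW^½, step-halving to guarantee ascent, convergence at
modified-score sup-norm below 1e-8·n (the score scales with sample size),
and at most 50 iterations. Standard errors come from the penalized
information matrix and the per-variant p-value is the Wald tail. On a
saturated 2×2 design this estimator coincides with adding 0.5 to every
cell, which the suite uses as a closed-form check alongside a brute-force
grid+simplex maximization oracle. Variants are filtered at minor allele
count ≥ 1 and call rate ≥ 0.8 before fitting; association drops to
per-variant complete cases (missing dosages are never imputed here).

## Bayesian meta-analysis

Each study contributes (β̂_k, SE_k), treated as β̂ ~ N(θ_k, SE_k²). The
effect prior is θ ~ N(0, 0.2²): on the odds-ratio scale roughly
(0.67, 1.48) at 2 s.d., a deliberately modest prior for complex-disease
log-ORs. Under the correlated-effects model all θ_k equal one shared draw
(marginal covariance diag(SE²) + W·J, with the inter-study correlation ρ
configurable and 1 by default); under the independent-effects model each
study draws its own θ_k (diag(SE²) + W·I). Bayes factors against the point
null (covariance diag(SE²)) are Gaussian density ratios evaluated with
`scipy.stats.multivariate_normal`; for K = 1 both reduce analytically to
the Wakefield ABF, and K identical studies collapse to one study at
SE/√K — both identities are asserted to 1e-10 or better. Heterogeneity is
flagged at log₁₀(BF_indep/BF_corr) > 2.

The reported p-value is the two-sided normal tail of the inverse-variance
combined z. With fixed per-study SEs this is a monotone transform of the
correlated-model BF, so rankings agree; it is an approximation, and the BF
itself is always reported alongside. Its null uniformity is checked by
Kolmogorov–Smirnov over 2,000 simulated null summary triplets.

The false-discovery annotation threshold for a Q-Q panel of n p-values is
t = 1/n (expected false discoveries n·t = 1). GWAS-locus stratification
consumes precomputed credible-set intervals and labels a variant "gwas"
when it lies within a 50 kb flank of any interval on its chromosome.

## Non-additivity

Hit classes count risk alleles across a gene's variant set: total dosage,
rounded, capped at "2+". A homozygote for one variant counts as two hits
(the compound-heterozygote and homozygote genotypes are biologically
comparable here); `carriers_only=True` caps each variant's contribution at
one for sensitivity analysis. Class odds ratios against the 0-hit class
use plain 2×2 arithmetic with Woolf 95% intervals and a flagged Haldane
correction on zero cells. The additive prediction for the 2-hit OR is the
square of the 1-hit OR.

The deviation-from-additivity test is a likelihood-ratio test on the
logistic scale: free model with separate 1-hit and 2-hit terms versus the
constraint β₂ = 2β₁ (within-gene), or main effects ± interaction
(between-gene), df = 1. The default fit is plain maximum likelihood, which
is chi-square calibrated (measured type-I rate 0.03–0.07 at nominal 0.05
over hundreds of null replicates). A `firth=True` variant compares
Jeffreys-penalized likelihoods instead; it is useful when a class is
nearly empty and ML separates, but it is **not** chi-square calibrated at
large n — the penalty contributes about ½·log n per extra parameter — so
the calibrated ML test is the default. Power at n = 20,000 against a
1-hit OR of 2.17 with a 2-hit OR of 9.93 (far above the additive
prediction 4.71) exceeds 80%.

## Polygenic risk scores

Scores are Σβ̂·dosage with effect alleles fixed to the ALT allele of the
variant key (tables keyed by effect/other allele must be flipped upstream,
changing the sign of β). Missing dosages are imputed at 2f — the expected
dosage under HWE — using a caller-specified population's frequency; this
is the one place missingness is imputed rather than dropped. The closed-
form expectation Σ2β̂f, its between-population decomposition 2β̂(f_a−f_b)
per variant (ranked, highlighted at |contribution| ≥ 0.01), and the
genotype-specific expectation Σ[2f(1−f)β_het + f²β_hom] are exact sums;
the latter reduces algebraically to the additive form at β_hom = 2β_het,
asserted to 1e-12. Standardization maps all scores through the reference
subset's mean and (ddof = 1) standard deviation, so the reference ends at
exactly mean 0, variance 1, and a non-reference group's post-transform
mean is its shift in reference-s.d. units. Variant exclusion lists (e.g.
removing large-effect genes to isolate the polygenic background) are a
config input, not hard-coded.

## Liability model

With additive log-odds effects the population risk score is approximately
normal: μ = logit(p₀) + Σ2fβ and σ² = 2Σf(1−f)β², the HWE mean and
variance of the PRS (σ² is checked against empirical score variance in the
suite). Expected prevalence is E[g(η)] for η ~ N(μ, σ²), computed by
Gauss–Hermite quadrature — exact for the normal weight — starting at 64
nodes and doubling until successive estimates agree to 1e-10 relative; the
σ = 0 limit short-circuits to g(μ) exactly. The implied density of p
itself, f(p) = φ((logit p − μ)/σ)/(σ·p(1−p)) under the logit link, is
provided for plotting and integrates to 1 (checked to 1e-8).

The baseline score β₀ is calibrated by Brent root-finding so a designated
population's expected prevalence hits a target (unique by monotonicity of
E[p] in μ; bracket ±60 logits, tolerance 1e-10). The prevalence-ratio
curve recalibrates β₀ for each baseline on the default grid 0.001–0.01 in
steps of 0.001 and tabulates both populations' expected prevalences; for a
fixed score shift the ratio varies only mildly across that sweep because
the small-p logistic is nearly exponential.

The probit comparison maps scores through equal probability,
η_probit = Φ⁻¹(expit(η_logit)), pushes the logit-score normal through that
map by quadrature to get (μ_probit, σ²_probit), and uses the closed form
E[Φ(η)] = Φ(μ/√(1+σ²)) for the probit prevalence. The reported slope is
the no-intercept least-squares fit of η_probit on η_logit over a 201-point
uniform grid on [−1, 1] — a declared convention; the relation is linear to
r² > 0.9999 there with slope ≈ 0.622, and deviates outside that range.

The attributable-prevalence ("without the risk factors") calculation
divides observed prevalence by the genotype-frequency-weighted mean
relative risk: per variant (1 + f(GRR − 1))² in the additive (per-allele)
mode, or (1−f)² + 2f(1−f)GRR_het + f²GRR_hom — equivalently
1 + 2f(1−f)(GRR_het−1) + f²(GRR_hom−1) — in the genotype-specific mode.
The HWE weight 2f(1−f) on the heterozygote term is what makes the
genotype-specific factor collapse exactly to the additive one at
GRR_hom = GRR_het²; a version without the (1−f) (which sometimes appears
in print) breaks that identity by 2f²(GRR_het−1). The two-population
attributable fraction ((p₂−p₁) − (i₂−i₁))/(p₂−p₁) is reported as
undefined when p₂ = p₁.

## QC and ancestry

Defaults follow standard exome-cohort practice: samples excluded for
het/hom ratio < 1 (contamination signature), > 2000 singletons, del/ins
ratio > 1.5, mean GQ < 40; variants for call rate < 0.8 or heterozygote
allele balance outside [0.3, 0.7] (boundaries pass) in > 40% of
heterozygous samples once at least 7 heterozygotes are seen. Genotype-
level GQ < 20 masking is applied at matrix construction, before any
sample-level summary — the ordering of the genotype-level and sample-level
GQ filters is a package convention. Relatedness pruning above 0.35 is
greedy: repeatedly drop the sample in the most above-cutoff pairs, ties
broken by lower call rate then sample id. Greedy is deterministic and
near-minimal but not guaranteed minimal (it can exceed the optimal
exclusion count by one even on small graphs); exactness was not worth a
vertex-cover solver here. Ancestry calls require a single Q-matrix
fraction ≥ 0.4 with all others strictly below ("admixed" otherwise), and
the high-ancestry flag for frequency estimation requires a fraction
strictly > 0.9.

## Synthetic data

The generators reproduce the statistical structure the pipeline assumes,
not the biology of any cohort. Ancestral allele frequencies follow a 1/x
spectrum truncated to [1e-4, 0.5] (the neutral site-frequency shape over
the range where enrichment testing operates). The founder event is a
single-generation binomial resample of 500 chromosomes by default — a
strong bottleneck of a few hundred effective founders — rather than a
multi-generation Wright–Fisher trajectory; one generation suffices to
produce the qualitative outcome the enrichment module needs (a heavy
right tail of boosted alleles plus outright loss), though it understates
the drift accumulated over ~30 generations of modest population size.
Study samples (2,000 diploids) are drawn binomially from the founder
frequency, reference samples (30,000) from the ancestral frequency.
Case-control genotypes are HWE draws with logistic phenotypes; covariate
confounding is available as normal covariates entering the linear
predictor. No LD, haplotype structure, genotyping error, or ascertainment
is modelled — so passing tests demonstrate estimator correctness under the
generating model, not robustness to real-data artifacts such as population
stratification or differential missingness.

All generators are pure functions of (config, seed).

## Problem sizes in the checks

The suite and the acceptance script use: 10,000 variants for bottleneck
runs; Fisher enumeration over all tables with total ≤ 30 (46,375 tables);
2,000 null meta-analysis replicates; 200 cohorts of 8,000 for Firth
recovery; 200 null and 40–100 alternative replicates for the additivity
test at n = 10,000–20,000; 50 replicates of 3,000 samples × 100 variants
for PRS shift recovery; and 10⁷ Monte-Carlo draws per liability grid
point. These sizes keep Monte-Carlo error comfortably inside the asserted
tolerances.

## Known limitations

- Strand/allele harmonization across studies, LD-aware PRS construction,
  variant normalization, and annotation are upstream concerns; inputs are
  assumed biallelic, normalized, annotated, and ALT-effect-coded.
- The meta-analysis p-value is a BF-monotone approximation, not a
  posterior quantity.
- The liability normal approximation for the score distribution is
  asymptotic in the number of variants; with few, large-effect variants
  the true score distribution is discrete.
- Greedy relatedness pruning is near-minimal, not minimal.
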