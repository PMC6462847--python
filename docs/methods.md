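# Methods

## The question and the four causal models

A SNP that is both an mQTL (associated with methylation at a CpG) and a
disease risk variant admits four explanations: the methylation mediates
the genetic effect (vertical path G → M → L → D, with L the latent
liability); the causality is reversed (G → L → M: liability itself, being
heritable, perturbs methylation); two distinct causal variants sit in LD
(G₁ → M, G₂ → L); or one variant acts on both through separate pathways
(horizontal pleiotropy). The pipeline scores each locus against these
models by combining forward MR, reverse MR and colocalization. Because
most CpGs are instrumented by a single variant, mediation and horizontal
pleiotropy are empirically indistinguishable here; the classifier's
strongest positive label is therefore `putative_mediation_or_pleiotropy`,
never plain mediation.

## Synthetic data

**Genotypes.** Haplotypes come from a latent-Gaussian threshold model: for
each LD block, standard normal variables with exchangeable correlation are
dichotomized at the Φ⁻¹(MAF) quantile, so the coded allele has exactly the
target frequency and within-block LD is controlled by one parameter.
Individuals are sums of two haplotypes drawn with replacement from a pool
(default 4000 individuals' worth), which reproduces Hardy–Weinberg
genotype frequencies. Block tightness is parameterized on the genotype-r²
scale and converted to the latent scale by solving the tetrachoric
equation (bivariate-normal orthant probability), because the downstream
colocalization method is defined in terms of genotype r²: the focal blocks
default to within-block r² ≈ 0.9, above the r² = 0.8 resolution limit, so
a shared causal variant is in principle resolvable. Cross-block coupling
is zero by default; the linkage scenario opts into a calibrated
cross-block correlation so the mQTL SNP and the disease SNP reach a target
r² (default 0.5).

**Scenario layout.** Each study has three focal blocks of 8 SNPs (A: mQTL
SNP; B: disease SNP for linkage; C: moderate LD, r² ≈ 0.3) spanning
~300 kb, plus six independent "background" disease SNPs placed megabases
away. The background SNPs give disease a polygenic component in every
non-null model; they are what the reverse MR instruments, mirroring the
practice of instrumenting overall genetic liability with independent
genome-wide-significant SNPs. Without them a reverse-causation model would
have no instrumentable liability at all.

**Methylation.** Latent methylation is
`intercept + β_mQTL·dosage + covariate terms + N(0, σ)` and beta-values
are its logistic transform — bounded in (0,1) while making the rank-based
inverse-normal transform downstream an exact inverse on ranks. The
methylation cohort (default n = 900, matching the scale of cord-blood
mQTL cohorts) carries sex, ten ancestry PCs, a three-level bisulfite batch
and four Dirichlet cell proportions with nonzero effects, so the
residualization step is exercised against real structure. The disease
cohort's methylation is the latent biological trait only; assay covariates
are a property of the measurement study, not of the biology that drives
liability.

**Disease.** Liability = model-specific predictor + N(0,1); disease is
liability above Φ⁻¹(1 − prevalence) (default prevalence 0.05). All genetic
liability terms are centered (per-allele effects are unchanged; centering
keeps the realized prevalence at its nominal value — uncentered scores
inflate it badly). Under mediation the predictor uses standardized latent
methylation, so `methylation_to_liability` is in liability units per
population SD of methylation. The GWAS cohort is ascertained case-control
(default 500 cases / 1500 controls, a scaled-down version of a
consortium-size meta-analysis), sampled by quota from the population
model.

**Trios.** Parents are pool draws; each transmits one uniformly chosen
haplotype; the child's disease follows the scenario's liability model and
families are resampled until the child is affected (cap 10⁶ candidate
families). A configurable fraction of families is stored with the father
masked (duos). **Duos contribute nothing to the TDT.** We measured why the
naive rule ("count transmissions from the observed heterozygous parent
when the child genotype determines them") is biased: for a heterozygous
parent, a homozygous-alt child (which forces "transmitted") has null
probability p/2 while a homozygous-ref child (forces "not transmitted")
has q/2, so the determinable subset is tilted toward the major allele —
observed null transmission fraction 0.494 instead of 0.500 across ~20,000
counts. The unbiased single-parent test is the 1-TDT correction, which is
out of scope; full trios alone give exact calibration.

## Summary statistics

The TDT uses the classic genotype bookkeeping (double-heterozygote
families contribute through the child genotype); the record carries both
the McNemar chi-square `(b−c)²/(b+c)` with its χ²₁ p-value and a
meta-analysis-compatible effect `ln(b/c)` with SE `√(1/b + 1/c)` (Haldane
+0.5 when a cell is empty) whose p-value is two-sided normal — the record
is self-consistent under the `p = 2Φ(−|β/se|)` convention used everywhere.
The two conventions differ slightly (the chi-square is the standard TDT
test; the log-ratio exists for inverse-variance pooling), and both are
reported rather than conflated. Note the trio log-ratio and the
case-control log-OR are similar but not identical estimands under a
liability-threshold ascertained design; the fixed-effects meta-analysis
treats them as exchangeable the way a consortium meta-analysis of mixed
designs does.

Case-control association is per-SNP logistic regression (statsmodels) of
disease on dosage plus optional covariates; monomorphic SNPs and perfect
separation produce flagged records with an infinite-SE sentinel, excluded
downstream. Meta-analysis is fixed-effects inverse-variance after allele
harmonization (match / swap with sign flip / strand flip via complement;
palindromic SNPs dropped when the reference EAF is missing or in
[0.42, 0.58]). Clumping is greedy by ascending p (ties broken by snp_id
for determinism): r² < 0.001 within 250 kb by default.

## cis-mQTL scan

Per CpG: rank-based inverse normal transform Φ⁻¹((rank − 0.5)/n) with
average ranks for ties, OLS residualization on the covariate design (one
batch level and one compositional cell column dropped; rank deficiency is
an error naming the collinear columns), then simple regression of the
residuals on every SNP dosage within 1 Mb (boundary inclusive), emitting
records at p < 1e-7. Residualize-then-regress is used, not joint
adjustment; on simulated data the two differ by well under the estimation
noise (tested). Flagged-probe exclusion is a set difference on CpG ids.

## Mendelian randomization

First-order (delta-method) SEs without an exposure-uncertainty term,
fixed-effect variances, two-sided normal p-values. IVW is algebraically a
zero-intercept weighted regression of outcome betas on exposure betas with
weights 1/se²_outcome; the correlated-instrument re-test is the GLS
closed form of the multivariate-normal instrument likelihood with signed
LD (signed r is required — r² would destroy the covariance structure) and
a 1e-6 diagonal ridge. The reverse MR instruments are
genome-wide-significant (p < 5e-8), LD-clumped disease SNPs further than
1 Mb from the CpG under test, so a cis mQTL can never instrument its own
reverse test. Multiple testing across CpGs uses Bonferroni (α = 0.05 over
the number of CpGs tested).

## Colocalization

Window z-scores are modeled as z ~ MVN(λ·R[:,j], R) with a single causal
placement j and λ profiled in closed form. The statistic contrasts the
best methylation-trait placement inside the disease lead SNP's shared
support S = {j : r²(j, lead) ≥ 0.8} with the best placement in the
distinct support D (r² below 0.75; the 0.05-wide buffer below the
resolution limit belongs to neither support, so near-threshold LD neither
helps nor hurts). Λ > 0 favors one shared variant. Significance: permute
the methylation residuals across individuals, regenerate the full z
vector, recompute Λ; p = (1 + #{Λ_perm ≥ Λ_obs})/(1 + n_perm). The
observed z is recomputed through the identical code path for
exchangeability. A max over the support is the default score; a
log-sum-exp variant is exposed (`score="sum"`) for sensitivity. When
either support is empty the result is an explicit undefined-statistic
sentinel (e.g. windows too sparse in LD terms), which the classifier maps
to `indeterminate`. Phenotype (residual) permutation rather than genotype
permutation was chosen because it preserves the LD geometry exactly; both
conventions appear in practice.

## The decision table

Gates in order: forward MR not Bonferroni-significant → `no_signal`;
reverse MR p < 0.05 → `reverse_causation` (flagged: this gate is
power-limited, a nominal threshold is the conservative direction for
mediation claims); colocalization sentinel → `indeterminate`;
colocalization p ≥ 0.05 → `linkage`; otherwise
`putative_mediation_or_pleiotropy`. Checking reverse causation before
colocalization is deliberate: under a true reverse model the methylation
and disease signals genuinely colocalize, so a coloc-first ordering would
misread reverse causation as mediation.

## Measured scale factor (liability → log-odds)

The forward-MR estimand is not `methylation_to_liability` itself: the
outcome arm is a logistic fit to a probit-generated ascertained trait, and
the exposure arm is an INT-residualized slope. Rather than assert a closed
form for the combined attenuation, the package computes the outcome side
exactly (binomial mixture over the background polygenic score, probit cell
risks, two-parameter logistic MLE on the ascertained cell probabilities by
Newton iteration — verified against large simulations) and measures the
exposure side asymptotically (INT slope at n = 100,000, averaged over
pools). At the default settings the measured liability→log-odds factor is
≈ 1.7, i.e. the estimand is ≈ 1.7 × the liability-scale effect per SD
methylation; the recovery experiment then checks the median Wald estimate
over 200 studies at n = 2000 against this reference within ±10%.

## Experiment sizes

Monte-Carlo sizes used by the test suite and the acceptance script (chosen
as the smallest sizes whose binomial error bands are informative): null
calibration 800 replicates for TDT (100 trios each) and case-control
(n = 300), 1000 for ANOVA, 500 for reverse MR and for colocalization
specificity (200 permutations per replicate, cohorts scaled to 1200 GWAS /
600 methylation); recovery 200 replicates at full cohort sizes;
classification 50 loci per causal model at full sizes with 200
permutations. Deeper runs (e.g. 1000 permutations, as in the analysis
drivers) sharpen the permutation p floor but do not change any
calibration conclusion.

## What the generator does and does not emulate

It reproduces: block LD with controllable r², Hardy–Weinberg genotypes,
covariate/batch/cell structure in measured methylation, liability-threshold
disease with case-control ascertainment, affected-offspring trio
ascertainment with transmission distortion at risk loci, and all four
causal architectures with a polygenic background. It does not emulate:
realistic recombination maps or LD decay, imputation error, population
stratification, X chromosome, probe-level measurement artifacts
(cross-hybridization is represented only as an id-list filter), or
trans-mQTL networks. Passing tests therefore demonstrate statistical
correctness and calibration of the machinery under a faithful but stylized
genetic architecture — not robustness to every artifact of real array
data.

## Known limitations

The reverse-MR gate is genuinely power-limited at realistic sizes (the
classifier flags it); the forward/reverse asymmetry means a weak reverse
path can be missed and the locus called mediation/pleiotropy. The
colocalization model assumes a single causal variant per trait in the
window. The TDT ignores duos entirely (see above). Fixed-effect SEs are
used throughout; under effect heterogeneity across instruments the IVW SE
is anti-conservative. The trio and case-control arms estimate slightly
different quantities under ascertainment; their meta-analysis follows
field practice rather than a formal identical-estimand argument.
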