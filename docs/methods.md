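# Methods

## Problem setting

Non-targeted LC–MS metabolomics quantifies drug metabolites only in the
subset of participants who recently took the drug and whose plasma
levels exceed the assay's limit of detection (LOD). For such panels the
missingness is informative (missing-not-at-random), the relative
quantification drifts across run-day batches, and within-person factors
(dose, time since ingestion) add large variation shared by every
metabolite of a sample. Ratios of biochemically related metabolites
cancel shared multiplicative factors and proxy the substrate/product
balance of single enzymatic steps, which makes them unusually powerful
GWAS phenotypes in this regime. This package implements that analysis
end to end and ships a generative simulator so every stage is testable
without restricted cohort data.

## Trait construction

Samples enter the analysis if at least `min_detected` (default 5) of the
panel's metabolites were detected. For M metabolites the trait set is
the M natural-log abundances plus all M(M−1)/2 pairwise log-ratios
(difference of logs), T = M + M(M−1)/2 in total; for the canonical
nine-metabolite panel T = 45. Ratio orientation is canonicalized by
panel column order; p-values are orientation-invariant and betas flip
sign. Non-detections are never imputed: each trait carries its own
complete-case mask (a ratio is defined iff both components were
detected), which is the only treatment of LOD missingness that does not
fabricate values below the detection limit. A rank-based inverse-normal
transform is available (`rank_inverse_normal`) but off by default so
betas remain per-allele log-fold changes.

T counts singles and ratios together. The Bonferroni denominator and the
p-gain multiplier (below) use this same T; with nine metabolites the
count of ratios alone is 36 and the count including singles is 45, and
the thresholds here are anchored to 45.

## Variant QC

* Per-variant statistics on called genotypes only: MAF = min(f, 1−f),
  call rate, and the exact conditional Hardy–Weinberg test (probability
  of the observed heterozygote count given the allele counts, summing
  all configurations no more probable than observed; no mid-p
  correction). The conditional weights are computed in exact integer
  arithmetic, so equal-probability configurations are genuine ties
  rather than floating-point accidents; monomorphic variants get p = 1.
* Filters remove strict violations — MAF < 5%, call rate < 90%, HWE
  p < 10⁻⁶, non-autosomal — so boundary values survive. Filtering is
  idempotent and reports per-criterion removal counts.
* LD pruning is greedy over a sliding window (defaults 50 variants,
  step 5, r² > 0.5 removes the later-positioned variant of a pair). r²
  is the squared Pearson correlation of dosages over pairwise-complete
  samples (composite r², not haplotype-EM); undefined-variance pairs are
  treated as unlinked. The window geometry is a conventional default;
  only the r² threshold is protocol-anchored.
* PCs are the top singular vectors of the column-standardized dosage
  matrix after per-variant mean imputation of missing calls, with the
  sign fixed so each component's largest-magnitude loading is positive.
* The GRM entry (j,k) averages (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))
  over variants jointly called in both samples (pairwise-complete
  averaging; monomorphic variants excluded). Indels are dropped before
  pruning, and PCs/GRM are computed on the pruned set, with the QC
  filter applied first.

## Association

The default engine is OLS of the trait on additive dosage, an intercept,
and covariates (age, sex, 10 PCs), with a two-sided t test on the dosage
coefficient at the full-model residual degrees of freedom. The scan is
vectorized per trait via the Frisch–Waugh–Lovell decomposition
(residualize trait and dosages on the covariate block once, then simple
regressions), with a per-variant complete-case fallback for variants
that have missing dosages inside the trait's analysis subset; the two
paths are algebraically identical and tested against each other.
Genotypes are unstandardized, so betas are per-allele effects on the log
scale. P-values are floored at the smallest positive double.

The mixed-model engine fits y = Xb + g + ε with g ~ N(0, σ_g² A) for a
GRM A, per trait: REML on the covariate-only model in the eigenbasis of
A (a bounded scalar optimization over the heritability ratio, total
variance profiled in closed form, σ_g² allowed to hit the zero
boundary), then per-variant GLS under the fitted covariance — the
standard MLMA factorization that avoids re-fitting variance components
per variant. With A = I this collapses exactly to OLS (tested to 1e-6
relative tolerance). No leave-one-chromosome-out GRM is used. In the
mixed path, samples with missing dosage are mean-imputed within the
analysis subset rather than dropped, because dropping would invalidate
the shared eigendecomposition; the OLS path never imputes. Non-converged
REML falls back to OLS with a status flag.

## p-gain inference

p-gain = min(p_num, p_den) / p_ratio, with all p-values in (0, 1].
Component p-values are computed on each single trait's own complete-case
samples (a strict mode restricting all three tests to the ratio's sample
set can be composed from the library but is not the default; the
field's convention uses each trait's own cases). Thresholds for T
traits: p_Bonf = 5 × 10⁻⁸ / T, p-gain_Bonf = 10 × T, suggestive
p < 10⁻⁵; all comparisons strict. The package reports p_Bonf at full
precision (1.11… × 10⁻⁹ at T = 45; 1.1 × 10⁻⁹ is its 2-significant-
figure rendering).

`null_calibration` measures the empirical single-test type-I error of
the p-gain criterion: replicates of one HWE SNP and two independent
log-normal metabolites with no genetic effect, covariate-free
regressions, exceedance fraction of p-gain ≥ critical value with a
Clopper–Pearson interval. At critical value 10 the criterion calibrates
to alpha = 0.05 for a single test; for independent metabolites it is
conservative (measured exceedance is well below 0.05), because
min(p_num, p_den)/p_ratio rarely exceeds 10 when all three tests are
null and the ratio test is positively coupled to its components.

## Loci

Suggestive associations are clumped per trait by the greedy index-SNP
rule: take the smallest-p unassigned variant (ties broken by chromosome,
position), absorb all unassigned variants with r² ≥ 0.1 to it, repeat.
Index variants are therefore mutually independent at r² < 0.1, and every
suggestive variant belongs to exactly one locus. A variant suggestive
for two traits contributes two association records; reported
*independent locus* counts union the index variants across traits.
Nearest-gene annotation is local and strand-agnostic: distance from the
index variant (1-based) to the nearest interval edge of each gene (BED
0-based half-open, converted internally; GFF3 accepted for `gene`
features), distance 0 inside, both genes reported on an exact tie.
Candidate-gene cross-referencing is case-insensitive exact name matching
against a user-supplied list; the shipped default is a representative
acetaminophen-pathway list (UGT/SULT/CYP/GST families plus COMT).

## The synthetic cohort generator

`simulate` emulates the statistical footprint of the study design —
not the chemistry. The generative model per sample i, metabolite j:

log m_ij = μ_j + Σ effects(dosage_i) + d_i + b_{batch(i), j} + ε_ij

* Genotypes: two Bernoulli(maf) alleles per variant (HWE exact in
  expectation), uniformly spaced positions on one synthetic autosome.
  Optional LD blocks: within a block each variant copies the previous
  variant's alleles, re-drawing each with the mutation rate (default
  0.1), preserving marginal frequency while giving adjacent r² ≈ 0.8 —
  enough structure to exercise pruning and clumping.
* Effect archetypes (per alternate allele, natural-log scale): *direct*
  (+β one metabolite), *branch* (+β/−β on a pair, so the log-ratio moves
  by 2β — a shifted partition between two conjugation routes),
  *conversion* (−β substrate, +β product), *dilution* (+β to all
  metabolites, cancelling exactly in every ratio).
* d_i ~ N(0, dilution_sd²) is the shared per-sample factor absorbing
  dose and time-since-ingestion variability (default sd 1.0 — drug
  levels legitimately span orders of magnitude across a population
  sampled at arbitrary times after intake). b is a per-(run-day,
  metabolite) batch factor (default sd 0.5, emulating between-batch
  drift); ε is i.i.d. noise (default sd 0.5). These nuisance scales are
  deliberately generous; they make single-metabolite tests weak and the
  ratio's cancellation property visible, which is the regime the method
  targets.
* Detection and normalization: the lowest `lod_quantile` fraction of
  each metabolite's latent abundances is censored (MNAR; defaults set to
  the panel's printed detection fractions, 363–514 of 520), then each
  run-day block of detected values is divided by its per-metabolite
  median (median ≡ 1 exactly on non-missing values). Censoring precedes
  normalization because detection happens at measurement while median
  registration is applied to the detected values — and because only this
  order makes the median-one property exact. An MCAR mode supports null
  calibration experiments.
* Covariates: age uniform over 18–76, sex Bernoulli(0.592), matching
  the cohort demographics the panel metadata describes.

Everything is deterministic given the config seed (independent
generator streams for genotypes, metabolites, covariates).

What the simulator does **not** model: pharmacokinetic dynamics,
LC–MS spectra, correlated measurement error between co-eluting peaks,
population structure / admixture in genotypes (two-population tests
construct their own frequency-shifted cohorts), and real LD patterns.
Passing recovery tests on these cohorts therefore demonstrates the
statistical machinery (estimator correctness, calibration, cancellation
properties) — not robustness to every failure mode of real platform
data.

## Problem sizes used in validation

The shipped validation uses desk-scale problems chosen to give the
relevant estimators clear resolution: null calibration at 10,000
replicates of n = 500; branch-effect recovery at n = 2000, MAF 0.3, 200
replicates (mean ratio beta within 3 per-study SEs of 2β = 0.30 — under
MNAR censoring a small attenuation is expected and observed, roughly
1–2 SE at these settings); heritability recovery at n = 400 in block
families over 30 replicates; the HWE exact test checked exhaustively
against an exact-fraction enumeration oracle for all genotype
configurations with n ≤ 50. The demonstration cohort is 520 samples ×
200 variants, mirroring the panel's cohort size.

## Known limitations

* The mixed model supports a single variance component; no LOCO scheme.
* Clumping and LD use composite genotype r²; no haplotype phasing.
* The critical p-gain value is the fixed 10 × T rule; correlation-
  adjusted critical values for dependent ratios are out of scope.
* With heavy MNAR censoring, complete-case ratio betas are mildly
  attenuated (selection on both components); the package reports
  complete-case estimates and does not attempt censoring-aware
  likelihoods (e.g. Tobit) — a deliberate scope boundary.
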