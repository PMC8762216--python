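# Methods

## The model

The unit of analysis is the *feature*: either one tissue-specific eQTL
association (SNP s, eGene g, tissue t) or one SNP without eQTL annotation.
For individual i the eQTL feature value is `x_{i,f} = g_{i,s} · NES_f`,
where `g_{i,s}` counts copies of the eQTL effect allele and `NES_f` is the
signed normalized effect size of the association; raw-SNP features use
`g_{i,s}` directly. Disease status is modelled as

    P(y_i = 1 | x_i) = sigmoid(β₀ + Σ_f β_f z_{i,f}),

with `z` the z-scored features and an elastic-net penalty on β. The
quantity of interest is not the prediction itself but the decomposition of
the fitted coefficient vector into per-tissue contributions
`W_t = Σ_{f∈t} |β_f|`, reported as fractions `W_t / Σ_u W_u` and ranked.
The intercept is excluded from the total: it is not attributable to any
tissue. A feature's SNP may drive several tissues; each (SNP, gene, tissue)
coefficient counts only toward its own tissue, with no de-duplication by
SNP — that is the feature definition, and collapsing by SNP would erase
exactly the tissue resolution the method exists to provide.

Assumptions worth stating: dosages are complete (or mean-imputed) and
harmonized to the eQTL effect allele; NES values are taken as fixed, known
weights; tissue attribution follows the reference table, so an eQTL wrongly
assigned to a tissue there is wrongly credited here too.

## Pipeline order and leakage

The univariate Mann-Whitney/Benjamini-Yekutieli screen runs once on the full
training cohort *before* cross-validation, and the CV folds are used for
hyperparameter selection and ensemble stability on the screened matrix.
This reproduces the standard order of operations for this kind of analysis;
it leaks a little information into the fold AUCs. `cv_ensemble` accepts
`filter_alpha` to re-run the screen inside each training fold for a
leakage-free estimate; this is reported separately, never silently
substituted.

Standardization is ON by default. Absolute model weights are only
comparable across features of very different natural scales (dosage × NES
vs raw dosage) after unit-variance scaling, and the contribution sums add
coefficient magnitudes across such features. The z-scoring statistics
(population-sd convention, so replays are bit-stable) are recorded in the
matrix sidecar and in every fitted model, and validation cohorts are always
transformed with the *training* statistics. Passing `standardize(…)` by and
fitting raw features reproduces the literal unscaled reading.

## Univariate screen

Per feature, a two-sided Mann-Whitney U test of case vs control values:
U counts case>control pairs plus half the ties. The p-value is exact (null
permutation distribution) when min(n₁, n₂) ≤ 8 with no ties, otherwise a
tie-corrected normal approximation with continuity correction — exactness
where it is cheap, the standard approximation elsewhere. Two-sided because
the direction of a feature's effect is unknown a priori. Constant pooled
values define p = 1.

Multiplicity is controlled with Benjamini-Yekutieli rather than
Benjamini-Hochberg: features sharing a SNP are perfectly correlated
(proportional columns), and BY's harmonic-factor inflation
`c(m) = Σ_{k≤m} 1/k` is valid under arbitrary dependence. Features with
`q < α` (default α = 0.05) are kept; `α ≥ 1` saturates the threshold and
keeps everything. The rank-based test makes the screen invariant to
standardization.

## Risk model

Penalty family: elastic net, grid `l1_ratio ∈ {0.25, 0.5, 0.75, 1.0}` ×
13 log-spaced strengths `C ∈ [1e-4, 1e2]` (`default_grid`). The sparsity
of reported models of this kind implies an l1 component; pure l1 and l2
remain available. A 10-point `fast_grid` (2 ratios × 5 strengths) is the
pipeline default at desk scale — tuning cost grows as grid × repeats ×
folds fits, and on the cohort sizes used here the reduced grid selects the
same region of the path. Solvers: lbfgs for pure l2, saga otherwise;
tolerance 1e-8, max 10,000 iterations, fixed seed. Non-convergence is an
error for the final fit and a logged warning inside CV (extreme grid points
may legitimately not converge and simply lose the tuning comparison).
No class weighting by default: the case/control imbalances modelled here
are mild. Ties in mean out-of-fold AUC break toward stronger
regularization (smaller C, then larger l1_ratio).

Folds are stratified and derived from a single seed; every grid point is
evaluated on the same fold assignment, and the winning point's 50 fold
models (5 repeats × 10 folds) are the ensemble used for stability analysis.
The fully-shrunk limit is well-defined: as C → 0 all coefficients vanish
and the intercept tends to log(n_case/n_control).

AUC is computed by the rank identity `AUC = U/(n₁n₀)` with tie-halves, so
constant scores give exactly 0.5. The 95% CI uses a seeded stratified
bootstrap (2,000 replicates) rather than DeLong — simpler to make
deterministic; expect small divergences from analytic CIs.

The PRS comparison is the textbook score `Σ_s β̂_s g_{i,s}` with externally
supplied (or marginally estimated) GWAS log-odds, no shrinkage and no
p-value thresholding, alleles harmonized the same way as the feature
matrix.

## Synthetic cohorts

The generator emulates what the analysis structurally assumes about its
inputs, with known ground truth:

* **Reference table** — `round(frac_eqtl · n_snps)` SNPs receive
  `1 + Poisson(mean−1)` (gene, tissue) records; tissues uniform; NES drawn
  zero-symmetric with scale `nes_scale` (default 0.35, a typical eQTL
  effect-size spread) and floored at |NES| ≥ 0.05; association FDR uniform
  below the 0.05 retention threshold. Remaining SNPs carry no records.
* **Genotypes** — independent biallelic SNPs, dosage ~ Binomial(2, MAF),
  MAF ~ U(0.05, 0.5). No LD by default; the real SNP sets this emulates do
  contain tightly linked pairs, which the independent-SNP default does not
  exercise.
* **Labels** — liability `η_i = β₀ + Σ_f γ_f z_{i,f}` over the planted
  features (γ = ±effect_size, random signs, on the standardized scale so
  signal is comparable across MAF/NES combinations), with retrospective
  sampling: individuals are drawn until the case and control quotas fill.
  β₀ = −1 keeps sampling efficient for case-enriched designs.
* **Calibration** — with k independent causal features the score is
  approximately N(0, σ²), σ = γ√k. The population AUC of that score under
  the logistic label model is computed by 1-D numerical integration of the
  case/control score densities (no probit shortcut), and `effect_size` is
  solved (brentq) so this AUC hits the target, default 0.70. Causal eQTL
  features are drawn one-per-SNP so the σ bookkeeping stays exact under
  HWE independence. `SimTruth` records γ, σ, β₀, the analytic AUC, and the
  realized in-sample score AUC.
* **Seeding** — population-level randomness (MAFs, causal choice, signs,
  alleles) is keyed by the config seed alone; individual draws use a
  separate `sampling_seed`. A validation cohort from the *same* process is
  therefore one config with a different sampling seed. All outputs are
  byte-deterministic in (config, seeds).
* **Negative control** — a disjoint set of control-trait SNPs (default:
  same size as the study set) with their own eQTL records and
  label-independent genotypes is appended to an existing cohort, for
  depletion testing of the screen.

Default `SimConfig` sizes mirror a realistic large case/control study
(1,698/2,668 samples, 281 SNPs, 49 tissues, ~78 records per eQTL SNP,
missingness 0 as for fully imputed data). Tests and the acceptance script
use the `recovery_config` preset — 2,000/2,000 samples, 200 SNPs, 10
tissues, 12 causal features in one tissue, population AUC 0.70 — and a
`null_config` preset (1,000/1,000, ~2,100 features, no signal), sizes
chosen so the full battery (20-seed recovery/null/negative-control loops)
runs in minutes on one CPU.

What passing on these cohorts does *not* show: robustness to LD between
causal and non-causal SNPs, population stratification, covariate
confounding, dosage uncertainty, or misassigned tissues in the reference
table — none of which the generator produces.

## Numerical and format choices

* Dosage TSV dialect: tab-separated, header `sample_id` + SNP columns,
  optional `counted_allele` / `other_allele` metadata rows, `NA` missing.
  VCF 4.2 also accepted (ALT-allele dosage; multi-allelic sites skipped).
* Allele harmonization: flip `d → 2−d` when the cohort counts the
  non-effect allele; strand-ambiguous pairs (A/T, C/G) are never flipped —
  flagged by default, dropped in strict mode — because a flip cannot be
  distinguished from a strand swap. Every SNP gets one audit-report row.
* Missing dosages are mean-imputed per SNP at matrix build time (neutral,
  deterministic); the screen and model stages therefore always see complete
  data.
* Matrix store: values TSV written with `%.17g` and read with pandas'
  round-trip parser, plus a JSON sidecar (descriptors, labels, column
  stats, sha256) — lossless and corruption-detecting.
* Contribution ties break alphabetically by group label; an all-zero model
  yields an explicit empty report, not an error.
* Feature ids: `<snp>_<allele>` for raw-SNP features, `<snp>|<gene>|<tissue>`
  for eQTL features (the triple must be encoded uniquely).

## Known limitations

Tissue contributions are attribution of penalized regression weights, not
causal estimates; correlated features (shared SNPs, LD) split weight in
ways the penalty — not biology — decides, which is why the ensemble
stability summary accompanies every ranking. The screen-before-CV default
inflates fold AUCs slightly (see above). The generator's independence
assumptions make recovery easier than on real genotypes with LD.
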