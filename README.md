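# eqtlrank

Rank tissue-specific eQTL contributions to polygenic disease risk from
case/control genotypes.

Most disease-associated GWAS variants are non-coding, and many act as
expression quantitative trait loci (eQTLs): their genotype shifts a gene's
expression in particular tissues. `eqtlrank` asks *which tissues' regulatory
effects carry the genetic risk* by integrating a tissue-specific eQTL
reference table with individual-level genotypes:

1. **Feature matrix.** Every (SNP, eGene, tissue) eQTL association becomes
   one feature per individual, valued `g × NES` — the allele count
   `g ∈ {0,1,2}` of the eQTL effect allele times the signed normalized
   effect size. SNPs without eQTL annotation enter as raw allele counts.
   Columns are z-scored so coefficient magnitudes are comparable.
2. **Univariate screen.** Each feature is tested case-vs-control with a
   two-sided Mann-Whitney U test; p-values are adjusted with the
   Benjamini-Yekutieli step-up procedure (valid under the strong dependence
   between features sharing a SNP), and features with q ≥ 0.05 are dropped.
3. **Risk model.** An elastic-net logistic regression
   `P(case | x) = σ(β₀ + Σ_f β_f x_f)` is tuned by 5-repeat 10-fold
   stratified cross-validation maximizing out-of-fold AUC; the 50 fold
   models of the winning grid point form an ensemble, and a final model is
   fit on the full cohort.
4. **Tissue contributions.** The model is decomposed into per-tissue risk
   contributions `W_t = Σ_{f ∈ t} |β_f|`, reported as fractions of the total
   coefficient mass and ranked; raw-SNP features form their own
   `no_eqtl_snps` group. Ranking stability is summarized over the 50-model
   ensemble.

Individual-level disease genotypes are access-controlled, so the package
ships a synthetic cohort generator with known ground truth: Hardy-Weinberg
dosages, a many-to-many SNP→(eGene, tissue) map with signed NES values, and
labels drawn retrospectively from a logistic liability over a planted set of
features in one causal tissue, calibrated to a target population AUC.
Every stage is tested against that ground truth and against brute-force
oracles. A conventional PRS (`Σ_s β̂_s g_s` with marginal GWAS log-odds) is
included for comparison, and a subsampled-validation routine checks that a
fitted model scores an independent cohort inside its training fold-AUC
range.

## Worked example

`examples/` contains one narrative script per capability. The core run
(`examples/03_fit_and_contributions.py`) simulates a 2,000-case /
2,000-control cohort with 12 causal features planted in `tissue_01`
(population AUC 0.70), filters 508 features down to 39, and fits the model:

```
ensemble : 50 models, out-of-fold AUC 0.707 +- 0.022 (range 0.659-0.772)
final model: train AUC 0.711, 39 features selected
top tissue contributions (fraction of total |coefficient| mass):
  rank 1: tissue_01     37.1% (12 features)
  rank 2: tissue_09     13.3% (5 features)
  rank 3: tissue_06      9.6% (4 features)
  rank 4: tissue_04      8.0% (2 features)
consensus rank of the planted tissue (tissue_01) across the 50 fold models: 1
```

The out-of-fold AUC matches the generator's 0.70 calibration, the planted
tissue dominates the contribution ranking (the residual weight in other
tissues comes from features that share SNPs with the causal ones), and the
ranking is stable across all 50 cross-validation models.
`examples/04_validate_and_prs.py` scores an independent cohort (mean subset
AUC 0.707, inside the 0.669–0.747 training fold range; PRS baseline 0.684),
and `examples/05_negative_control.py` shows that features built from
unrelated-trait SNPs are removed by the filter (0 of 498 kept).

A thin CLI mirrors the library: `eqtlrank simulate | build-matrix | filter |
tune | fit | contributions | prs | validate | run-all` (see `--help`).
`run-all` executes the whole pipeline from one YAML config and writes a
manifest of content-hashed artifacts; identical config + seed reproduces
byte-identical outputs.

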