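"""Synthetic case/control cohorts and eQTL reference tables with ground truth.

The generator emulates the statistical structure of a GWAS-SNP + GTEx-style
eQTL analysis: biallelic SNP dosages under Hardy-Weinberg equilibrium at
uniform-random minor allele frequencies, a many-to-many SNP -> (eGene,
tissue) map with signed normalized effect sizes across a configurable number
of tissue labels, a fraction of SNPs with no eQTL annotation, and binary
disease labels drawn retrospectively from a logistic liability over a planted
subset of features.  Planted effects act on the *standardized* feature scale
so that signal strength is comparable across MAF/NES combinations, and the
per-feature effect size can be calibrated to a target population AUC.

Default :class:`SimConfig` values mirror a large genotyped case/control
study: 1,698 cases /
2,668 controls, 281 SNPs of which ~81% carry eQTL records, 49 tissues, and
~78 (gene, tissue) records per eQTL SNP.  :func:`recovery_config` is a
smaller preset (2,000/2,000 samples, 200 SNPs, 10 tissues, 12 causal
features in one tissue, population AUC 0.70) used for recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .data_io import EqtlRecord, EqtlReferenceTable, GenotypeMatrix
from .errors import PipelineError, ValidationError
from .feature_matrix import eqtl_feature_id, snp_feature_id
from .risk_model import auc as _auc

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Generator settings; defaults emulate a large case/control study.

    ``effect_size`` is the per-feature log-odds on the standardized feature
    scale; when ``None`` it is calibrated so the total genetic score attains
    ``target_population_auc``.  ``beta0`` is the liability intercept used for
    retrospective case/control sampling.
    """

    n_cases: int = 1698
    n_controls: int = 2668
    n_snps: int = 281
    frac_eqtl_snps: float = 0.81
    n_tissues: int = 49
    triples_per_snp: float = 78.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    nes_scale: float = 0.35
    causal_tissue: str = "tissue_01"
    n_causal_features: int = 12
    n_causal_snp_only: int = 2
    effect_size: float | None = None
    target_population_auc: float = 0.70
    missing_rate: float = 0.0
    beta0: float = -1.0
    n_control_snps: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps, self.n_tissues) < 1:
            raise ValidationError("cohort/SNP/tissue counts must be positive")
        if not (0.0 < self.frac_eqtl_snps <= 1.0):
            raise ValidationError("frac_eqtl_snps must be in (0, 1]")
        if self.triples_per_snp < 1.0:
            raise ValidationError("triples_per_snp must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.effect_size is not None and self.effect_size <= 0:
            raise ValidationError("effect_size must be positive")
        if min(self.n_causal_features, self.n_causal_snp_only) < 0:
            raise ValidationError("causal feature counts must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``population_auc`` is the analytic AUC of the total genetic score under
    the generator's Gaussian bookkeeping (score ~ N(0, sigma^2), logistic
    label model with intercept ``beta0``); ``realized_score_auc`` is the
    in-sample AUC of the true score in the generated cohort.
    """

    causal_feature_ids: list[str]
    generative_coefficients: dict[str, float]
    population_auc: float
    sigma: float
    beta0: float
    effect_size: float
    realized_score_auc: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "causal_feature_ids": self.causal_feature_ids,
            "generative_coefficients": self.generative_coefficients,
            "population_auc": self.population_auc,
            "sigma": self.sigma,
            "beta0": self.beta0,
            "effect_size": self.effect_size,
            "realized_score_auc": self.realized_score_auc,
            "seed": self.seed,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Analytic AUC bookkeeping
# ---------------------------------------------------------------------------

def analytic_population_auc(sigma: float, beta0: float) -> float:
    """AUC of a Gaussian score S ~ N(0, sigma^2) under P(case|S) = expit(beta0+S).

    Computed by numerical integration of the case/control score densities
    (Bayes-tilted Gaussians); tie mass is zero for a continuous score.
    """
    if sigma <= 0:
        return 0.5
    s = np.linspace(-10 * sigma, 10 * sigma, 4001)
    base = norm.pdf(s, scale=sigma)
    w1 = base * expit(beta0 + s)
    w0 = base * (1.0 - expit(beta0 + s))
    w1 /= trapezoid(w1, s)
    w0 /= trapezoid(w0, s)
    cdf0 = cumulative_trapezoid(w0, s, initial=0.0)
    return float(trapezoid(w1 * cdf0, s))


def calibrate_effect_size(
    n_causal: int,
    beta0: float,
    target_auc: float,
) -> float:
    """Per-feature effect size so the total score reaches ``target_auc``.

    With k independent standardized causal features of effect +-gamma the
    score has sigma = gamma * sqrt(k); solves the analytic AUC for sigma.
    """
    if n_causal < 1:
        raise ValidationError("calibration needs at least one causal feature")
    if not (0.5 < target_auc < 1.0):
        raise ValidationError("target population AUC must be in (0.5, 1)")
    sigma = brentq(lambda s: analytic_population_auc(s, beta0) - target_auc,
                   1e-6, 50.0, xtol=1e-10)
    return float(sigma / np.sqrt(n_causal))


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

def _draw_records(
    rng: np.random.Generator,
    snp_ids: list[str],
    n_eqtl: int,
    n_tissues: int,
    triples_per_snp: float,
    nes_scale: float,
    gene_prefix: str,
) -> tuple[list[EqtlRecord], set[str], dict[str, str]]:
    tissues = [f"tissue_{t + 1:02d}" for t in range(n_tissues)]
    n_genes = max(20, round(4.6 * len(snp_ids)))
    genes = [f"{gene_prefix}{g + 1:05d}" for g in range(n_genes)]
    eqtl_snps = sorted(rng.choice(snp_ids, size=n_eqtl, replace=False))
    effect_allele = {s: str(rng.choice(_BASES)) for s in snp_ids}
    records: list[EqtlRecord] = []
    for snp in eqtl_snps:
        k = 1 + int(rng.poisson(triples_per_snp - 1.0))
        pairs: set[tuple[str, str]] = set()
        guard = 0
        while len(pairs) < k and guard < 50 * k:
            pairs.add((genes[int(rng.integers(n_genes))],
                       tissues[int(rng.integers(n_tissues))]))
            guard += 1
        for gene, tissue in sorted(pairs):
            raw = rng.normal(0.0, nes_scale)
            nes = float(np.sign(raw) if raw != 0 else 1.0) * max(abs(raw), 0.05)
            records.append(EqtlRecord(
                snp_id=snp, effect_allele=effect_allele[snp], egene_id=gene,
                tissue=tissue, nes=nes, assoc_fdr=float(rng.uniform(0.0, 0.05)),
            ))
    no_eqtl = set(snp_ids) - set(eqtl_snps)
    return records, no_eqtl, effect_allele


def simulate_reference(cfg: SimConfig) -> EqtlReferenceTable:
    """Simulate the eQTL reference table for ``cfg`` (deterministic in seed).

    ``round(frac_eqtl_snps * n_snps)`` SNPs get ``1 + Poisson(mean - 1)``
    (gene, tissue) records with uniform tissue labels and zero-symmetric NES
    (|NES| >= 0.05); the rest become no-eQTL SNPs.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    snp_ids = [f"rs{100001 + i}" for i in range(cfg.n_snps)]
    n_eqtl = int(round(cfg.frac_eqtl_snps * cfg.n_snps))
    records, no_eqtl, _ = _draw_records(
        rng, snp_ids, n_eqtl, cfg.n_tissues, cfg.triples_per_snp,
        cfg.nes_scale, "gene_",
    )
    return EqtlReferenceTable(records=records, no_eqtl_snps=no_eqtl)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _pick_causal(
    rng: np.random.Generator,
    cfg: SimConfig,
    table: EqtlReferenceTable,
) -> list[tuple[str, str, float]]:
    """(feature_id, snp_id, nes-or-nan) for the planted features.

    Causal eQTL features are drawn from the causal tissue, at most one per
    SNP so the score variance bookkeeping stays exact under HWE independence.
    """
    by_snp: dict[str, EqtlRecord] = {}
    for rec in sorted(table.records, key=lambda r: (r.snp_id, r.egene_id)):
        if rec.tissue == cfg.causal_tissue and rec.snp_id not in by_snp:
            by_snp[rec.snp_id] = rec
    candidates = sorted(by_snp)
    if len(candidates) < cfg.n_causal_features:
        raise ValidationError(
            f"causal tissue {cfg.causal_tissue} has only {len(candidates)} "
            f"distinct-SNP features; {cfg.n_causal_features} requested"
        )
    chosen: list[tuple[str, str, float]] = []
    if cfg.n_causal_features:
        for snp in sorted(rng.choice(candidates, cfg.n_causal_features,
                                     replace=False)):
            rec = by_snp[snp]
            chosen.append((eqtl_feature_id(snp, rec.egene_id, rec.tissue),
                           snp, rec.nes))
    pool = sorted(table.no_eqtl_snps)
    if len(pool) < cfg.n_causal_snp_only:
        raise ValidationError(
            f"only {len(pool)} no-eQTL SNPs available; "
            f"{cfg.n_causal_snp_only} causal raw-SNP features requested"
        )
    if cfg.n_causal_snp_only:
        for snp in sorted(rng.choice(pool, cfg.n_causal_snp_only, replace=False)):
            chosen.append((snp, snp, np.nan))  # feature id fixed up later
    return chosen


def simulate_cohort(
    cfg: SimConfig,
    table: EqtlReferenceTable,
    sampling_seed: int | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a case/control cohort under the planted liability model.

    Dosages are Binomial(2, MAF_s) per SNP with MAF_s ~ U(maf_range) (HWE, no
    LD); the liability is ``beta0 + sum_f gamma_f z_f`` over the planted
    features, where z is the population-standardized feature value and
    ``gamma_f = +-effect_size`` with random sign; labels come from
    retrospective sampling (individuals are drawn until the case and control
    quotas fill).  Missing entries are masked at ``missing_rate``.

    Population-level randomness (MAFs, causal feature choice, effect signs,
    allele assignments) is keyed by ``cfg.seed`` alone; ``sampling_seed``
    (default ``cfg.seed``) keys only the individual draws, so a validation
    cohort from the *same* generative process is obtained by passing a
    different ``sampling_seed`` with an unchanged config.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    rng_ind = np.random.default_rng(
        [cfg.seed if sampling_seed is None else sampling_seed, 4])
    snp_ids = sorted(table.all_snps)
    n_snps = len(snp_ids)
    col_of = {s: j for j, s in enumerate(snp_ids)}
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_snps)
    sd_dos = np.sqrt(2.0 * maf * (1.0 - maf))

    causal = _pick_causal(rng, cfg, table)
    n_causal = len(causal)
    if n_causal and cfg.effect_size is None:
        effect = calibrate_effect_size(n_causal, cfg.beta0,
                                       cfg.target_population_auc)
    else:
        effect = cfg.effect_size or 0.0
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    gamma = signs * effect

    causal_cols = np.array([col_of[snp] for _, snp, _ in causal], dtype=int)
    # standardized eqtl feature = sign(NES) * standardized dosage
    nes_sign = np.array([1.0 if np.isnan(nes) else np.sign(nes)
                         for _, _, nes in causal])

    need = {1: cfg.n_cases, 0: cfg.n_controls}
    rows = {1: [], 0: []}
    batch = 2048
    for _ in range(2000):
        if need[1] <= len(rows[1]) and need[0] <= len(rows[0]):
            break
        d = rng_ind.binomial(2, maf, size=(batch, n_snps)).astype(float)
        if n_causal:
            z = (d[:, causal_cols] - 2.0 * maf[causal_cols]) / sd_dos[causal_cols]
            eta = cfg.beta0 + (z * nes_sign) @ gamma
        else:
            eta = np.full(batch, cfg.beta0)
        y = (rng_ind.random(batch) < expit(eta)).astype(int)
        for cls in (1, 0):
            want = need[cls] - len(rows[cls])
            if want > 0:
                take = np.flatnonzero(y == cls)[:want]
                rows[cls].extend(d[take])
    if len(rows[1]) < need[1] or len(rows[0]) < need[0]:
        raise PipelineError("simulate_cohort: sampling did not terminate "
                            "(extreme beta0?)")

    dosages = np.vstack([np.array(rows[1]), np.array(rows[0])])
    labels = np.concatenate([np.ones(cfg.n_cases, int),
                             np.zeros(cfg.n_controls, int)])
    sample_ids = [f"case_{i + 1:05d}" for i in range(cfg.n_cases)] + \
                 [f"ctrl_{i + 1:05d}" for i in range(cfg.n_controls)]

    # alleles: eQTL SNPs count the table's effect allele (pre-harmonized);
    # non-complementary second allele avoids strand-ambiguous pairs
    counted: dict[str, str] = {}
    other: dict[str, str | None] = {}
    for snp in snp_ids:
        if snp in table.snp_index:
            counted[snp] = table.effect_allele(snp)
        else:
            counted[snp] = str(rng.choice(_BASES))
        options = [b for b in "ACGT"
                   if b != counted[snp] and b != _COMPLEMENT[counted[snp]]]
        other[snp] = str(options[int(rng.integers(len(options)))])

    # ground-truth score of the generated cohort, for the realized AUC
    if n_causal:
        z_all = (dosages[:, causal_cols] - 2.0 * maf[causal_cols]) / sd_dos[causal_cols]
        score = (z_all * nes_sign) @ gamma
        realized = _auc(score, labels)
    else:
        realized = 0.5

    if cfg.missing_rate > 0.0:
        mask = rng_ind.random(dosages.shape) < cfg.missing_rate
        dosages = np.where(mask, np.nan, dosages)

    feature_ids = [
        fid if not np.isnan(nes) else snp_feature_id(snp, counted[snp])
        for fid, snp, nes in causal
    ]
    sigma = float(effect * np.sqrt(n_causal)) if n_causal else 0.0
    truth = SimTruth(
        causal_feature_ids=feature_ids,
        generative_coefficients={f: float(g) for f, g in zip(feature_ids, gamma)},
        population_auc=analytic_population_auc(sigma, cfg.beta0),
        sigma=sigma,
        beta0=cfg.beta0,
        effect_size=float(effect),
        realized_score_auc=float(realized),
        seed=cfg.seed,
    )
    gm = GenotypeMatrix(sample_ids, snp_ids, dosages, counted, other, labels)
    return gm, truth


def make_negative_control(
    cfg: SimConfig,
    table: EqtlReferenceTable,
    gm: GenotypeMatrix,
) -> tuple[EqtlReferenceTable, GenotypeMatrix, set[str]]:
    """Append control-trait SNPs with eQTL records but no effect on labels.

    Emulates mixing a second trait's SNP set into the reference: the added
    SNPs get their own (gene, tissue) records and HWE dosages for the same
    samples, independent of disease status.  Returns the augmented table and
    genotypes plus the control SNP id set for depletion testing.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    n_ctrl = cfg.n_control_snps or cfg.n_snps
    ctrl_ids = [f"ctrlrs{200001 + i}" for i in range(n_ctrl)]
    if set(ctrl_ids) & set(gm.snp_ids):
        raise ValidationError("control SNP ids collide with cohort SNP ids")
    n_eqtl = int(round(cfg.frac_eqtl_snps * n_ctrl))
    records, no_eqtl, _ = _draw_records(
        rng, ctrl_ids, n_eqtl, cfg.n_tissues, cfg.triples_per_snp,
        cfg.nes_scale, "ctrlgene_",
    )
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_ctrl)
    d = rng.binomial(2, maf, size=(gm.n_samples, n_ctrl)).astype(float)
    if cfg.missing_rate > 0.0:
        mask = rng.random(d.shape) < cfg.missing_rate
        d = np.where(mask, np.nan, d)

    counted = dict(gm.counted_allele)
    other = dict(gm.other_allele)
    allele_of = {r.snp_id: r.effect_allele for r in records}
    for snp in ctrl_ids:
        counted[snp] = allele_of.get(snp, str(rng.choice(_BASES)))
        options = [b for b in "ACGT"
                   if b != counted[snp] and b != _COMPLEMENT[counted[snp]]]
        other[snp] = str(options[int(rng.integers(len(options)))])

    table_aug = EqtlReferenceTable(
        records=list(table.records) + records,
        no_eqtl_snps=set(table.no_eqtl_snps) | no_eqtl,
    )
    gm_aug = GenotypeMatrix(
        list(gm.sample_ids), list(gm.snp_ids) + ctrl_ids,
        np.hstack([gm.dosages, d]), counted, other, gm.labels.copy(),
    )
    return table_aug, gm_aug, set(ctrl_ids)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def recovery_config(seed: int = 0, **overrides) -> SimConfig:
    """Recovery preset: one causal tissue, population AUC 0.70, 2000/2000."""
    base = dict(
        n_cases=2000, n_controls=2000, n_snps=200, frac_eqtl_snps=0.8,
        n_tissues=10, triples_per_snp=3.0, nes_scale=0.35,
        causal_tissue="tissue_01", n_causal_features=12, n_causal_snp_only=0,
        target_population_auc=0.70, missing_rate=0.0, seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Global-null preset: >= 2,000 features, no planted effect, 1000/1000."""
    base = dict(
        n_cases=1000, n_controls=1000, n_snps=700, frac_eqtl_snps=0.8,
        n_tissues=10, triples_per_snp=3.5, nes_scale=0.35,
        n_causal_features=0, n_causal_snp_only=0, effect_size=None,
        missing_rate=0.0, seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
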