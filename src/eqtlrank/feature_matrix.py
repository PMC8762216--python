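"""Weighted genotype x eQTL-effect feature matrix.

Each eQTL association (SNP, eGene, tissue) becomes one feature column valued
``dosage x NES``; each study SNP without any eQTL record becomes one raw
allele-count column.  This is the matrix the filter and the regularized
logistic model operate on.  Columns are standardized (z-scored with the
population-sd convention) before model fitting so that absolute model weights
are comparable across dosage-scaled and NES-scaled features; the per-column
statistics are stored so the identical transform can be replayed on
validation cohorts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import EqtlReferenceTable, GenotypeMatrix
from .errors import DataError, FormatError, PipelineError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column.

    ``kind`` is ``"eqtl"`` (dosage x NES for one SNP/eGene/tissue triple) or
    ``"snp_only"`` (raw allele count for a SNP without eQTL records).
    Feature ids follow ``<snp>|<gene>|<tissue>`` for eQTL features and
    ``<snp>_<allele>`` for raw-SNP features.
    """

    feature_id: str
    kind: str
    snp_id: str
    egene_id: str = ""
    tissue: str = ""
    nes: float | None = None
    allele: str = ""

    def __post_init__(self) -> None:
        if self.kind == "eqtl":
            if not (self.egene_id and self.tissue and self.nes is not None):
                raise ValidationError(
                    f"eqtl feature {self.feature_id} needs egene, tissue, nes"
                )
        elif self.kind == "snp_only":
            if self.egene_id or self.tissue or self.nes is not None:
                raise ValidationError(
                    f"snp_only feature {self.feature_id} must not carry "
                    "egene/tissue/nes"
                )
        else:
            raise ValidationError(f"unknown feature kind {self.kind!r}")


def eqtl_feature_id(snp: str, gene: str, tissue: str) -> str:
    return f"{snp}|{gene}|{tissue}"


def snp_feature_id(snp: str, allele: str) -> str:
    return f"{snp}_{allele}"


@dataclass
class FeatureMatrix:
    """Samples x features matrix with labels and (optional) column stats.

    ``column_stats`` is ``None`` until :func:`standardize` runs; afterwards it
    holds the per-column mean/sd (population convention) and a zero-variance
    flag, so the same transform can be replayed on a new cohort.
    """

    sample_ids: list[str]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray
    labels: np.ndarray
    column_stats: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.descriptors):
            raise ValidationError("feature matrix shape inconsistent with ids")
        ids = [d.feature_id for d in self.descriptors]
        if len(set(ids)) != len(ids):
            raise ValidationError("feature ids are not unique")
        if np.isnan(self.values).any():
            raise ValidationError("feature matrix must not contain missing values")

    @property
    def feature_ids(self) -> list[str]:
        return [d.feature_id for d in self.descriptors]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def select_columns(self, idx: np.ndarray) -> "FeatureMatrix":
        """Restrict to a subset of columns (used by the feature filter)."""
        idx = np.asarray(idx)
        stats = None
        if self.column_stats is not None:
            stats = {
                "mean": [self.column_stats["mean"][j] for j in idx],
                "sd": [self.column_stats["sd"][j] for j in idx],
                "zero_variance": [self.column_stats["zero_variance"][j] for j in idx],
            }
        return FeatureMatrix(
            list(self.sample_ids),
            [self.descriptors[j] for j in idx],
            self.values[:, idx].copy(),
            self.labels.copy(),
            stats,
        )


def build_feature_matrix(
    gm: GenotypeMatrix,
    table: EqtlReferenceTable,
) -> tuple[FeatureMatrix, dict]:
    """Assemble the weighted genotype-eQTL effect matrix.

    One column per eQTL record whose SNP is genotyped, valued
    ``dosage x NES`` (after per-SNP mean imputation of missing dosages); one
    column per genotyped no-eQTL SNP, valued raw dosage.  Column order: eQTL
    features sorted by (snp, gene, tissue), then raw-SNP features sorted by
    snp.  Returns the matrix and a build report (counts of features created,
    SNPs skipped, entries imputed, samples dropped).
    """
    dosages = gm.dosages.copy()
    # a sample with every dosage missing carries no information at all
    all_missing = np.isnan(dosages).all(axis=1) if dosages.size else np.zeros(
        len(gm.sample_ids), bool)
    if all_missing.any():
        logger.warning("build_feature_matrix: dropping %d samples with all "
                       "dosages missing", int(all_missing.sum()))
    keep = ~all_missing
    dosages = dosages[keep]
    sample_ids = [s for s, k in zip(gm.sample_ids, keep) if k]
    labels = gm.labels[keep]

    n_imputed = int(np.isnan(dosages).sum())
    if n_imputed:
        col_mean = np.nanmean(dosages, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dosages))
        dosages[nan_r, nan_c] = col_mean[nan_c]

    col_of = {s: j for j, s in enumerate(gm.snp_ids)}
    skipped: set[str] = set()

    eqtl_feats: list[tuple[FeatureDescriptor, int, float]] = []
    for rec in sorted(table.records, key=lambda r: (r.snp_id, r.egene_id, r.tissue)):
        j = col_of.get(rec.snp_id)
        if j is None:
            skipped.add(rec.snp_id)
            continue
        desc = FeatureDescriptor(
            feature_id=eqtl_feature_id(rec.snp_id, rec.egene_id, rec.tissue),
            kind="eqtl", snp_id=rec.snp_id, egene_id=rec.egene_id,
            tissue=rec.tissue, nes=rec.nes, allele=rec.effect_allele,
        )
        eqtl_feats.append((desc, j, rec.nes))

    snp_feats: list[tuple[FeatureDescriptor, int]] = []
    for snp in sorted(table.no_eqtl_snps):
        j = col_of.get(snp)
        if j is None:
            skipped.add(snp)
            continue
        allele = gm.counted_allele.get(snp, "N")
        desc = FeatureDescriptor(
            feature_id=snp_feature_id(snp, allele), kind="snp_only",
            snp_id=snp, allele=allele,
        )
        snp_feats.append((desc, j))

    n_feat = len(eqtl_feats) + len(snp_feats)
    if n_feat == 0:
        raise PipelineError("build_feature_matrix: zero features created")

    values = np.empty((len(sample_ids), n_feat), dtype=float)
    descriptors: list[FeatureDescriptor] = []
    for k, (desc, j, nes) in enumerate(eqtl_feats):
        values[:, k] = dosages[:, j] * nes
        descriptors.append(desc)
    off = len(eqtl_feats)
    for k, (desc, j) in enumerate(snp_feats):
        values[:, off + k] = dosages[:, j]
        descriptors.append(desc)

    report = {
        "n_eqtl_features": len(eqtl_feats),
        "n_snp_only_features": len(snp_feats),
        "n_snps_skipped": len(skipped),
        "skipped_snps": sorted(skipped),
        "n_entries_imputed": n_imputed,
        "n_samples_dropped": int(all_missing.sum()),
    }
    if skipped:
        logger.info("build_feature_matrix: skipped %d SNPs absent from "
                    "genotypes", len(skipped))
    fm = FeatureMatrix(sample_ids, descriptors, values, labels)
    return fm, report


def standardize(fm: FeatureMatrix, stats: dict | None = None) -> FeatureMatrix:
    """Z-score columns; population (divide-by-n) sd convention.

    With ``stats`` given (a ``column_stats`` dict recorded at training time)
    the stored transform is replayed — the new cohort's own statistics are
    never used.  Zero-variance columns become all-zero and are flagged.
    Standardizing an already standardized matrix is an error.
    """
    if fm.column_stats is not None:
        raise ValidationError("matrix is already standardized")
    if stats is None:
        mean = fm.values.mean(axis=0)
        sd = fm.values.std(axis=0)  # population convention
        zero = sd == 0.0
    else:
        mean = np.asarray(stats["mean"], dtype=float)
        sd = np.asarray(stats["sd"], dtype=float)
        zero = np.asarray(stats["zero_variance"], dtype=bool)
        if mean.shape[0] != fm.n_features:
            raise ValidationError("replay stats do not match feature count")
    safe_sd = np.where(zero | (sd == 0.0), 1.0, sd)
    out = (fm.values - mean) / safe_sd
    out[:, zero | (sd == 0.0)] = 0.0
    if stats is None and zero.any():
        logger.info("standardize: %d zero-variance columns set to zero",
                    int(zero.sum()))
    column_stats = {
        "mean": [float(x) for x in mean],
        "sd": [float(x) for x in sd],
        "zero_variance": [bool(z) for z in zero],
    }
    return FeatureMatrix(list(fm.sample_ids), list(fm.descriptors), out,
                         fm.labels.copy(), column_stats)


# ---------------------------------------------------------------------------
# On-disk store: values TSV + JSON sidecar
# ---------------------------------------------------------------------------

def _descriptor_dict(d: FeatureDescriptor) -> dict:
    return {
        "feature_id": d.feature_id, "kind": d.kind, "snp_id": d.snp_id,
        "egene_id": d.egene_id, "tissue": d.tissue, "nes": d.nes,
        "allele": d.allele,
    }


def write_matrix(fm: FeatureMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.values.tsv`` + ``<prefix>.meta.json`` (lossless)."""
    prefix = Path(prefix)
    values_path = prefix.with_name(prefix.name + ".values.tsv")
    meta_path = prefix.with_name(prefix.name + ".meta.json")
    df = pd.DataFrame(fm.values, columns=fm.feature_ids)
    df.insert(0, "sample_id", fm.sample_ids)
    # %.17g round-trips float64 exactly
    df.to_csv(values_path, sep="\t", index=False, float_format="%.17g")
    digest = hashlib.sha256(values_path.read_bytes()).hexdigest()
    meta = {
        "shape": [fm.n_samples, fm.n_features],
        "sha256_values": digest,
        "descriptors": [_descriptor_dict(d) for d in fm.descriptors],
        "labels": [int(y) for y in fm.labels],
        "column_stats": fm.column_stats,
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return values_path, meta_path


def read_matrix(prefix: str | Path) -> FeatureMatrix:
    """Read a matrix written by :func:`write_matrix`; verifies checksum/shape."""
    prefix = Path(prefix)
    values_path = prefix.with_name(prefix.name + ".values.tsv")
    meta_path = prefix.with_name(prefix.name + ".meta.json")
    try:
        meta = json.loads(meta_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read matrix sidecar {meta_path}: {exc}") from exc
    digest = hashlib.sha256(values_path.read_bytes()).hexdigest()
    if digest != meta["sha256_values"]:
        raise DataError(f"corrupt matrix store: checksum mismatch for {values_path}")
    df = pd.read_csv(values_path, sep="\t", float_precision="round_trip")
    values = df.drop(columns=["sample_id"]).to_numpy(dtype=float)
    if list(values.shape) != meta["shape"]:
        raise DataError(f"corrupt matrix store: shape mismatch for {values_path}")
    descriptors = [
        FeatureDescriptor(
            feature_id=d["feature_id"], kind=d["kind"], snp_id=d["snp_id"],
            egene_id=d["egene_id"], tissue=d["tissue"], nes=d["nes"],
            allele=d["allele"],
        )
        for d in meta["descriptors"]
    ]
    if [d.feature_id for d in descriptors] != list(df.columns[1:]):
        raise DataError("corrupt matrix store: descriptor/header mismatch")
    return FeatureMatrix(
        list(df["sample_id"].astype(str)), descriptors, values,
        np.asarray(meta["labels"], dtype=int), meta["column_stats"],
    )
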