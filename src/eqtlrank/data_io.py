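"""Input readers and allele harmonization.

The analysis consumes three kinds of input:

* an eQTL reference table mapping SNPs to (eGene, tissue) pairs with a signed
  normalized effect size (NES) relative to a declared effect allele, in the
  style of a GTEx-derived export;
* case/control genotypes, either a VCF or a simple dosage TSV, together with
  a sample -> {case, control} phenotype table;
* optionally, GWAS effect sizes for a conventional polygenic risk score.

Dosages are counts (0/1/2) of a declared "counted" allele.  Because the NES
is signed relative to the eQTL effect allele, genotypes must be harmonized so
that the counted allele IS the effect allele before any feature is built;
:func:`harmonize_alleles` does that and emits an audit report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: Strand-ambiguous allele pairs: a flip cannot be distinguished from a
#: strand swap, so these are flagged (or dropped in strict mode).
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))

EQTL_TABLE_COLUMNS = ["snp", "effect_allele", "gene", "tissue", "nes", "fdr"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EqtlRecord:
    """One SNP -> (eGene, tissue) eQTL association.

    Attributes
    ----------
    snp_id : str
        Variant identifier (rsID or ``chrom:pos:ref:alt``).
    effect_allele : str
        The allele the NES is signed relative to; one of A/C/G/T.
    egene_id : str
        The gene whose expression the eQTL modulates.
    tissue : str
        Tissue label, e.g. ``Heart_Atrial_Appendage``.
    nes : float
        Signed normalized effect size (expression slope per effect allele).
    assoc_fdr : float
        FDR of the eQTL association, in [0, 1].
    """

    snp_id: str
    effect_allele: str
    egene_id: str
    tissue: str
    nes: float
    assoc_fdr: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValidationError(
                f"effect allele {self.effect_allele!r} for {self.snp_id} "
                "is not one of A/C/G/T"
            )
        if not np.isfinite(self.nes) or self.nes == 0.0:
            raise ValidationError(
                f"NES for ({self.snp_id}, {self.egene_id}, {self.tissue}) "
                f"must be finite and non-zero, got {self.nes!r}"
            )
        if not (0.0 <= self.assoc_fdr <= 1.0):
            raise ValidationError(
                f"association FDR {self.assoc_fdr!r} for {self.snp_id} "
                "outside [0, 1]"
            )


@dataclass
class EqtlReferenceTable:
    """The set of eQTL records plus the study SNPs that have none.

    ``snp_index`` maps each SNP id to its records; ``no_eqtl_snps`` holds
    study SNPs with no retained eQTL record (these become raw allele-count
    features downstream).
    """

    records: list[EqtlRecord]
    no_eqtl_snps: set[str] = field(default_factory=set)
    snp_index: dict[str, list[EqtlRecord]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        index: dict[str, list[EqtlRecord]] = {}
        allele: dict[str, str] = {}
        for rec in self.records:
            key = (rec.snp_id, rec.egene_id, rec.tissue)
            if key in seen:
                raise ValidationError(f"duplicate (snp, gene, tissue) triple {key}")
            seen.add(key)
            prev = allele.setdefault(rec.snp_id, rec.effect_allele)
            if prev != rec.effect_allele:
                raise ValidationError(
                    f"conflicting effect alleles for {rec.snp_id}: {prev} vs "
                    f"{rec.effect_allele}"
                )
            index.setdefault(rec.snp_id, []).append(rec)
        overlap = self.no_eqtl_snps & index.keys()
        if overlap:
            raise ValidationError(
                f"no_eqtl_snps overlaps SNPs with records: {sorted(overlap)[:5]}"
            )
        self.snp_index = index

    def effect_allele(self, snp_id: str) -> str:
        return self.snp_index[snp_id][0].effect_allele

    @property
    def all_snps(self) -> set[str]:
        return set(self.snp_index) | self.no_eqtl_snps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.snp_id, r.effect_allele, r.egene_id, r.tissue, r.nes, r.assoc_fdr)
                for r in self.records
            ],
            columns=EQTL_TABLE_COLUMNS,
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write the retained records back out in the input TSV dialect."""
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-count matrix with case/control labels.

    ``dosages`` is a float array with entries in {0, 1, 2} or NaN for
    missing.  ``counted_allele[snp]`` is the allele whose copies the dosage
    counts; ``other_allele[snp]`` is the second declared allele (may be None
    for a bare dosage TSV without allele rows).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    counted_allele: dict[str, str]
    other_allele: dict[str, str | None]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValidationError("dosage matrix shape inconsistent with id lists")
        if self.labels.shape != (n,):
            raise ValidationError("labels length inconsistent with sample_ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosage entries must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.snp_ids),
            self.dosages.copy(),
            dict(self.counted_allele),
            dict(self.other_allele),
            self.labels.copy(),
        )


# ---------------------------------------------------------------------------
# eQTL reference table
# ---------------------------------------------------------------------------

def load_eqtl_table(
    path: str | Path,
    study_snps: Iterable[str] | None = None,
    fdr_max: float = 0.05,
) -> EqtlReferenceTable:
    """Load an eQTL reference TSV, keeping associations with FDR < ``fdr_max``.

    Parameters
    ----------
    path
        TSV with header columns ``snp, effect_allele, gene, tissue, nes, fdr``.
    study_snps
        Optional full study SNP list; SNPs with no retained record become
        ``no_eqtl_snps`` (they are modelled as raw allele-count features).
    fdr_max
        Association-FDR threshold; default 0.05.

    Raises
    ------
    FormatError, ParseError, ValidationError
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EQTL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"eQTL table {path} missing columns {missing}")

    for col in ("nes", "fdr"):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() | raw.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric {col}={raw.iloc[row]!r} in {path} data row {row + 1}"
            )
        df[col] = num

    dup = df.duplicated(subset=["snp", "gene", "tissue"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        trip = tuple(df.loc[row, ["snp", "gene", "tissue"]])
        raise ValidationError(f"duplicate (snp, gene, tissue) row {trip} in {path}")

    kept = df[df["fdr"] < fdr_max]
    n_dropped = len(df) - len(kept)
    if n_dropped:
        logger.info("load_eqtl_table: dropped %d records with fdr >= %g",
                    n_dropped, fdr_max)
    records = [
        EqtlRecord(r.snp, r.effect_allele, r.gene, r.tissue, float(r.nes), float(r.fdr))
        for r in kept.itertuples(index=False)
    ]
    with_records = {rec.snp_id for rec in records}
    no_eqtl = set(study_snps) - with_records if study_snps is not None else set()
    return EqtlReferenceTable(records=records, no_eqtl_snps=no_eqtl)


# ---------------------------------------------------------------------------
# Genotypes + phenotypes
# ---------------------------------------------------------------------------

def _load_phenotypes(path: str | Path) -> dict[str, int]:
    ph = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "status"}.issubset(ph.columns):
        raise FormatError(f"phenotype table {path} needs columns sample_id, status")
    bad = ~ph["status"].isin(["case", "control"])
    if bad.any():
        raise ValidationError(
            f"phenotype status values outside {{case, control}}: "
            f"{sorted(ph.loc[bad, 'status'].unique())}"
        )
    return {s: int(st == "case") for s, st in zip(ph["sample_id"], ph["status"])}


def _read_dosage_tsv(path: str | Path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise FormatError(f"dosage TSV {path} must start with a sample_id column")
    snp_ids = list(df.columns[1:])
    counted: dict[str, str] = {}
    other: dict[str, str | None] = {s: None for s in snp_ids}
    is_meta = df["sample_id"].isin(["counted_allele", "other_allele"])
    for _, row in df[is_meta].iterrows():
        target = counted if row["sample_id"] == "counted_allele" else other
        for s in snp_ids:
            target[s] = row[s]
    body = df[~is_meta]
    dos = body[snp_ids].replace("NA", np.nan).astype(float).to_numpy()
    if counted == {}:
        counted = {s: "N" for s in snp_ids}  # unknown; harmonization will drop
    return list(body["sample_id"]), snp_ids, dos, counted, other


def _read_vcf(path: str | Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    counted: dict[str, str] = {}
    other: dict[str, str | None] = {}
    cols: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        sid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        # dosage counts the ALT allele
        gt = np.asarray(var.gt_types)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0,
                       np.where(gt == 3, 2.0, np.nan)))
        snp_ids.append(sid)
        counted[sid] = var.ALT[0]
        other[sid] = var.REF
        cols.append(dos)
    vcf.close()
    if n_multi:
        logger.warning("load_genotypes: skipped %d multi-allelic VCF sites", n_multi)
    dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return sample_ids, snp_ids, dosages, counted, other


def load_genotypes(
    path: str | Path,
    format: str,
    phenotype_path: str | Path,
) -> GenotypeMatrix:
    """Load genotypes (VCF or dosage TSV) joined with a phenotype table.

    Samples without a phenotype are dropped (count logged); VCF dosages
    count the ALT allele; multi-allelic VCF sites are skipped with a warning.
    """
    if format == "tsv":
        sample_ids, snp_ids, dosages, counted, other = _read_dosage_tsv(path)
    elif format == "vcf":
        sample_ids, snp_ids, dosages, counted, other = _read_vcf(path)
    else:
        raise FormatError(f"unknown genotype format {format!r}")

    phenos = _load_phenotypes(phenotype_path)
    keep = [i for i, s in enumerate(sample_ids) if s in phenos]
    if not keep:
        raise DataError("no overlapping samples between genotypes and phenotypes")
    n_dropped = len(sample_ids) - len(keep)
    if n_dropped:
        logger.info("load_genotypes: dropped %d samples with no phenotype", n_dropped)
    sample_ids = [sample_ids[i] for i in keep]
    dosages = dosages[keep]
    labels = np.array([phenos[s] for s in sample_ids], dtype=int)
    return GenotypeMatrix(sample_ids, snp_ids, dosages, counted, other, labels)


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

HARMONIZE_ACTIONS = (
    "kept", "flipped", "dropped_unmatched", "flagged_ambiguous",
    "dropped_ambiguous", "dropped_not_in_table",
)


def harmonize_alleles(
    gm: GenotypeMatrix,
    table: EqtlReferenceTable,
    strict_ambiguous: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Align genotype counted alleles with the table's eQTL effect alleles.

    For each genotyped SNP with eQTL records: if the counted allele already is
    the effect allele the column is kept; if the *other* declared allele is
    the effect allele the dosage is flipped ``d -> 2 - d`` (missing stays
    missing); otherwise the SNP is dropped.  Strand-ambiguous pairs (A/T and
    C/G) are never flipped — they are flagged, or dropped when
    ``strict_ambiguous`` is set.  SNPs absent from the reference table
    entirely are dropped.  Returns the harmonized matrix and a report with
    one (snp, action) row per input SNP.
    """
    actions: list[tuple[str, str]] = []
    keep_idx: list[int] = []
    new_counted = dict(gm.counted_allele)
    new_other = dict(gm.other_allele)
    dosages = gm.dosages.copy()

    for j, snp in enumerate(gm.snp_ids):
        counted = gm.counted_allele.get(snp)
        other = gm.other_allele.get(snp)
        if snp in table.no_eqtl_snps:
            actions.append((snp, "kept"))
            keep_idx.append(j)
            continue
        if snp not in table.snp_index:
            actions.append((snp, "dropped_not_in_table"))
            continue
        effect = table.effect_allele(snp)
        pair = frozenset(a for a in (counted, other) if a)
        if other is not None and pair in AMBIGUOUS_PAIRS:
            if strict_ambiguous:
                actions.append((snp, "dropped_ambiguous"))
                continue
            actions.append((snp, "flagged_ambiguous"))
            keep_idx.append(j)
        elif counted == effect:
            actions.append((snp, "kept"))
            keep_idx.append(j)
        elif other == effect:
            col = dosages[:, j]
            dosages[:, j] = np.where(np.isnan(col), np.nan, 2.0 - col)
            new_counted[snp], new_other[snp] = other, counted
            actions.append((snp, "flipped"))
            keep_idx.append(j)
        else:
            actions.append((snp, "dropped_unmatched"))

    report = pd.DataFrame(actions, columns=["snp", "action"])
    dropped = report[report["action"].str.startswith("dropped")]
    if len(dropped):
        logger.info("harmonize_alleles: dropped %d SNPs (%s)", len(dropped),
                    dropped["action"].value_counts().to_dict())

    kept_snps = [gm.snp_ids[j] for j in keep_idx]
    out = GenotypeMatrix(
        list(gm.sample_ids),
        kept_snps,
        dosages[:, keep_idx],
        {s: new_counted[s] for s in kept_snps},
        {s: new_other.get(s) for s in kept_snps},
        gm.labels.copy(),
    )
    return out, report


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes in the dosage-TSV dialect read by :func:`load_genotypes`."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(gm.snp_ids) + "\n")
        fh.write("counted_allele\t"
                 + "\t".join(gm.counted_allele[s] for s in gm.snp_ids) + "\n")
        if all(gm.other_allele.get(s) for s in gm.snp_ids):
            fh.write("other_allele\t"
                     + "\t".join(gm.other_allele[s] for s in gm.snp_ids) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            row = ["NA" if np.isnan(d) else str(int(d)) for d in gm.dosages[i]]
            fh.write(sid + "\t" + "\t".join(row) + "\n")


def write_phenotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, y in zip(gm.sample_ids, gm.labels):
            fh.write(f"{sid}\t{'case' if y == 1 else 'control'}\n")
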