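"""Genotype, covariate and cohort file I/O.

Genotypes are handled as *risk-allele dosages*: 0 if the risk allele is
absent, 1 for heterozygotes, 2 for risk-allele homozygotes, NaN for a
missing call.  Supported on-disk formats are a plain dosage TSV (samples x
SNPs), VCF 4.x with GT fields (oriented to the panel's risk allele on
read), and a covariate/outcome CSV.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .panel import SnpPanel
from .simulate import Cohort, BINARY_TCRFS, OBESITY_BMI_THRESHOLD

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "read_dosage_table",
    "write_dosage_table",
    "read_vcf",
    "write_vcf",
    "read_covariates",
    "write_covariates",
    "complete_case_filter",
    "impute_mean_dosage",
]

REQUIRED_COVARIATE_COLUMNS = (
    "sample_id",
    "age",
    "sex",
    "hypertension",
    "diabetes",
    "hypercholesterolemia",
    "smoking",
    "chd",
)


@dataclass(frozen=True)
class GenotypeTable:
    """Sample-by-SNP risk-allele dosage matrix ({0,1,2}, NaN missing)."""

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid dosage {vals[i, j]!r} at sample "
                f"{self.dosages.index[i]!r}, SNP {self.dosages.columns[j]!r}; "
                "dosages must be 0, 1, 2 or missing"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_missing(self) -> int:
        return int(self.dosages.isna().to_numpy().sum())


def _align_to_panel(df: pd.DataFrame, panel: SnpPanel | None) -> pd.DataFrame:
    if panel is None:
        return df
    unknown = [c for c in df.columns if c not in panel.rsids]
    if unknown:
        logger.warning("dropping %d column(s) not in panel: %s", len(unknown), unknown)
        df = df.drop(columns=unknown)
    absent = [r for r in panel.rsids if r not in df.columns]
    for r in absent:
        df[r] = np.nan
    if absent:
        logger.warning("panel SNP(s) absent from input, set all-missing: %s", absent)
    return df[panel.rsids]


def read_dosage_table(path: str | Path, panel: SnpPanel | None = None) -> GenotypeTable:
    """Read a dosage TSV (first column sample id, one column per SNP).

    Entries must be 0, 1, 2 or NA.  When a panel is given, columns are
    reordered to panel order; unknown columns are dropped with a warning and
    panel SNPs absent from the file become all-missing columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"{path}: invalid dosage {vals[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return GenotypeTable(_align_to_panel(df.astype(float), panel))


def write_dosage_table(table: GenotypeTable | pd.DataFrame, path: str | Path) -> None:
    """Write dosages as TSV; missing entries serialize as NA (lossless round-trip)."""
    df = table.dosages if isinstance(table, GenotypeTable) else table
    out = df.copy()
    out.index.name = out.index.name or "sample_id"
    # integers where called, NA where missing
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_vcf(path: str | Path, panel: SnpPanel) -> GenotypeTable:
    """Read GT fields from a VCF and orient them to panel risk alleles.

    Sites are matched to the panel by ID (rsid).  The dosage counts copies
    of the panel risk allele, whichever of REF/ALT carries it; genotypes
    with any missing allele are treated as missing.  Multi-allelic records
    overlapping a panel SNP are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for rec in vcf:
        rsid = rec.ID
        if rsid is None or rsid not in panel.rsids:
            continue
        if len(rec.ALT) > 1:
            raise ValueError(
                f"{path}: multi-allelic site {rsid} overlaps the panel; unsupported"
            )
        snp = panel[rsid]
        alt = rec.ALT[0] if rec.ALT else None
        if snp.risk_allele == rec.REF:
            risk_is_alt = False
        elif alt is not None and snp.risk_allele == alt:
            risk_is_alt = True
        else:
            raise ValueError(
                f"{path}: {rsid} alleles REF={rec.REF} ALT={alt} do not include "
                f"panel risk allele {snp.risk_allele}"
            )
        # gt_types unreliable for half-calls; use the genotype tuples
        dosages = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is phasing flag
            if any(a < 0 for a in alleles) or len(alleles) != 2:
                continue  # half-call or missing -> NaN
            alt_count = sum(1 for a in alleles if a == 1)
            dosages[i] = alt_count if risk_is_alt else 2 - alt_count
        data[rsid] = dosages
    df = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    return GenotypeTable(_align_to_panel(df, panel))


def write_vcf(table: GenotypeTable, panel: SnpPanel, path: str | Path) -> None:
    """Write dosages as a minimal VCFv4.2 (GT only, risk allele as ALT).

    Chromosome labels come from the panel; positions are synthetic ordinals
    (the panel carries no build coordinates).  Readable back via
    :func:`read_vcf` for a lossless dosage round-trip.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=cardiogrs",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = []
    for s in panel.snps:
        c = s.chromosome.split("q")[0].split("p")[0]
        if c not in chroms:
            chroms.append(c)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [str(s) for s in table.sample_ids]
    lines.append("\t".join(header))
    for pos, snp in enumerate(panel.snps, start=1):
        if snp.rsid not in table.snp_ids:
            continue
        col = table.dosages[snp.rsid]
        chrom = snp.chromosome.split("q")[0].split("p")[0]
        row = [chrom, str(pos), snp.rsid, snp.reference_allele, snp.risk_allele,
               ".", "PASS", ".", "GT"]
        row += [gt_map.get(float(v), "./.") if pd.notna(v) else "./." for v in col]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate/outcome CSV.

    Required columns: sample_id, age, sex, hypertension, diabetes,
    hypercholesterolemia, smoking, chd; optional bmi (from which an
    obesity flag is derived at BMI >= 30 kg/m^2).  Binary columns must be
    coded 0/1 - labels like "M"/"F" are rejected with a recoding hint.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df.set_index("sample_id")
    binary_cols = ["sex", *BINARY_TCRFS, "chd"]
    for col in binary_cols:
        vals = df[col].dropna()
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any() or not numeric.isin([0, 1]).all():
            bad = vals[numeric.isna() | ~numeric.isin([0, 1])].unique()[:5]
            raise ValueError(
                f"{path}: column {col!r} must be coded 0/1, found {list(bad)}; "
                "recode (e.g. M/F -> 1/0) before loading"
            )
        df[col] = pd.to_numeric(df[col])
    if "bmi" in df.columns and "obesity" not in df.columns:
        df["obesity"] = (df["bmi"] >= OBESITY_BMI_THRESHOLD).astype("Int64").astype(float)
    return df


def write_covariates(cohort: Cohort, path: str | Path) -> None:
    out = cohort.covariates.copy()
    out["chd"] = cohort.outcome
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.6g")


def load_cohort(
    genotype_path: str | Path,
    covariate_path: str | Path,
    panel: SnpPanel,
    population: str = "cohort",
    fmt: str = "tsv",
) -> Cohort:
    """Join a genotype file and a covariate CSV into a Cohort on sample id."""
    if fmt == "vcf":
        table = read_vcf(genotype_path, panel)
    elif fmt == "tsv":
        table = read_dosage_table(genotype_path, panel)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}; use 'tsv' or 'vcf'")
    cov = read_covariates(covariate_path)
    geno_ids = set(map(str, table.sample_ids))
    cov_ids = set(map(str, cov.index))
    unmatched = sorted(geno_ids ^ cov_ids)
    if unmatched:
        raise ValueError(
            f"sample ids do not match between genotype and covariate files: {unmatched[:10]}"
            + ("..." if len(unmatched) > 10 else "")
        )
    cov = cov.loc[table.dosages.index]
    return Cohort(
        population=population,
        genotypes=table.dosages,
        covariates=cov.drop(columns=["chd"]),
        outcome=cov["chd"].astype(int),
    )


def complete_case_filter(cohort: Cohort) -> Cohort:
    """Drop every individual with any missing genotype or missing TCRF.

    Mirrors a complete-case analysis: only participants with full genotype
    and risk-factor data enter the models.  Raises if nobody survives.
    """
    geno_ok = ~cohort.genotypes.isna().any(axis=1)
    tcrf_cols = ["age", "sex", *BINARY_TCRFS]
    cov_ok = ~cohort.covariates[tcrf_cols].isna().any(axis=1)
    keep = geno_ok & cov_ok
    n_drop = int((~keep).sum())
    logger.info(
        "complete-case filter: dropped %d of %d individuals (%d genotype-missing, "
        "%d TCRF-missing)",
        n_drop, len(keep), int((~geno_ok).sum()), int((~cov_ok).sum()),
    )
    if not keep.any():
        raise ValueError("complete-case filter removed every individual")
    return cohort.subset(keep)


def impute_mean_dosage(table: GenotypeTable) -> pd.DataFrame:
    """Per-SNP mean imputation of missing dosages (sensitivity analyses only)."""
    df = table.dosages.copy()
    return df.fillna(df.mean())
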