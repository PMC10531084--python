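"""Genotype/phenotype ingestion and per-SNP quality control.

Filters follow the usual GWAS panel-cleaning recipe for a selfing crop:
minor-allele-frequency floor (sites with MAF <= 0.05 are treated as effectively
monomorphic and removed), call-rate floor, and an optional Hardy-Weinberg
goodness-of-fit screen.  HWE filtering is OFF by default because a
self-pollinating organism shows a genuine heterozygote deficit, so departures
from (p^2, 2pq, q^2) are expected rather than diagnostic of genotyping error.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix, PhenotypeVector

__all__ = [
    "SnpQcReport",
    "snp_qc_metrics",
    "filter_snps",
    "read_genotype_csv",
    "read_plink_raw",
    "read_vcf",
    "read_phenotype_table",
    "write_genotype_csv",
]


@dataclass
class SnpQcReport:
    """Per-SNP QC metrics with pass/fail verdicts.

    ``table`` columns: snp, maf, call_rate, hwe_chi2, hwe_p, pass, reason.
    ``reason`` is one of {"kept", "maf", "hwe", "callrate"} (first failing
    filter in priority order callrate > maf > hwe).
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def _per_snp_counts(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype counts (n0, n1, n2) per SNP over non-missing calls."""
    n0 = (dosage == 0).sum(axis=0)
    n1 = (dosage == 1).sum(axis=0)
    n2 = (dosage == 2).sum(axis=0)
    return n0, n1, n2


def snp_qc_metrics(G: GenotypeMatrix) -> SnpQcReport:
    """Compute MAF, call rate and a 1-df HWE chi-square per SNP.

    MAF and the HWE test use non-missing calls only; ``q`` is the alt-allele
    frequency and MAF = min(q, 1 - q).  The chi-square compares observed
    genotype counts with (p^2, 2pq, q^2) expectations without continuity
    correction.  All-missing SNPs get NaN metrics and fail with reason
    "callrate".
    """
    dosage = G.dosage
    n = G.n_samples
    n0, n1, n2 = _per_snp_counts(dosage)
    called = n0 + n1 + n2
    call_rate = called / n

    with np.errstate(invalid="ignore", divide="ignore"):
        q = (n1 + 2.0 * n2) / (2.0 * called)
    maf = np.minimum(q, 1.0 - q)
    maf[called == 0] = np.nan

    # HWE 1-df goodness of fit; monomorphic sites carry no evidence -> p = 1
    p_allele = 1.0 - q
    exp0 = called * p_allele**2
    exp1 = called * 2.0 * p_allele * q
    exp2 = called * q**2
    chi2 = np.full(G.n_snps, np.nan)
    hwe_p = np.full(G.n_snps, np.nan)
    poly = (called > 0) & (q > 0) & (q < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2_poly = (
            (n0 - exp0) ** 2 / exp0 + (n1 - exp1) ** 2 / exp1 + (n2 - exp2) ** 2 / exp2
        )
    chi2[poly] = chi2_poly[poly]
    hwe_p[poly] = stats.chi2.sf(chi2_poly[poly], df=1)
    mono = (called > 0) & ~poly
    chi2[mono] = 0.0
    hwe_p[mono] = 1.0

    return SnpQcReport(
        table=pd.DataFrame(
            {
                "snp": G.snp_ids,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_chi2": chi2,
                "hwe_p": hwe_p,
            }
        )
    )


def filter_snps(
    G: GenotypeMatrix,
    report: SnpQcReport,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.0,
    callrate_min: float = 0.9,
) -> tuple[GenotypeMatrix, SnpQcReport]:
    """Drop SNPs failing MAF (strictly > ``maf_min`` kept), HWE and call rate.

    Returns the filtered matrix and the report annotated with pass/reason.
    ``hwe_alpha=0`` disables the HWE screen (the default for selfers).

    Raises
    ------
    ValueError
        If no SNP survives — an empty panel is an explicit failure, not a
        silently empty result.
    """
    tab = report.table
    if len(tab) != G.n_snps or list(tab["snp"]) != G.snp_ids:
        raise ValueError("QC report is not aligned to the genotype matrix")

    maf = tab["maf"].to_numpy(float)
    cr = tab["call_rate"].to_numpy(float)
    hwe = tab["hwe_p"].to_numpy(float)

    fail_cr = ~(cr >= callrate_min)
    fail_maf = ~(maf > maf_min)  # NaN MAF fails too
    fail_hwe = ~(np.nan_to_num(hwe, nan=-1.0) >= hwe_alpha)

    reason = np.full(G.n_snps, "kept", dtype=object)
    reason[fail_hwe] = "hwe"
    reason[fail_maf] = "maf"
    reason[fail_cr] = "callrate"
    keep = ~(fail_cr | fail_maf | fail_hwe)

    annotated = tab.copy()
    annotated["pass"] = keep
    annotated["reason"] = reason
    annotated_report = SnpQcReport(table=annotated)

    if not keep.any():
        raise ValueError("no SNP passed QC filters")
    return G.take_snps(np.flatnonzero(keep)), annotated_report


# ---------------------------------------------------------------------------
# Readers / writers


def _finish_matrix(dosage: np.ndarray, meta: pd.DataFrame, samples: list[str]) -> GenotypeMatrix:
    return GenotypeMatrix(dosage=dosage, snp_meta=meta, sample_ids=samples)


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read a dosage CSV: rows = samples (first column = id), columns = SNP ids.

    Cells are 0/1/2 or empty/NA for missing.  SNP metadata defaults to
    chromosome "0", positions 1..m and N/N alleles when no sidecar is given.
    """
    df = pd.read_csv(path, index_col=0)
    dosage = df.to_numpy(float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    meta = pd.DataFrame(
        {
            "id": df.columns.astype(str),
            "chrom": "0",
            "pos": np.arange(1, df.shape[1] + 1),
            "ref": "N",
            "alt": "N",
        }
    )
    return _finish_matrix(dosage, meta, [str(s) for s in df.index])


def read_plink_raw(path: str | Path) -> GenotypeMatrix:
    """Read PLINK ``--recode A`` additive dosage output (.raw, whitespace TSV)."""
    df = pd.read_csv(path, sep=r"\s+")
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f".raw file lacks header columns {missing}")
    snp_cols = [c for c in df.columns if c not in fixed]
    dosage = df[snp_cols].to_numpy(float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    ids = [c.rsplit("_", 1)[0] for c in snp_cols]
    alts = [c.rsplit("_", 1)[1] if "_" in c else "N" for c in snp_cols]
    meta = pd.DataFrame(
        {"id": ids, "chrom": "0", "pos": np.arange(1, len(ids) + 1), "ref": "N", "alt": alts}
    )
    return _finish_matrix(dosage, meta, df["IID"].astype(str).tolist())


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF via cyvcf2 (GT field -> 0/1/2 dosage).

    Multiallelic records are rejected with a clear error: the analysis is
    defined for biallelic SNPs only.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading VCF requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multiallelic site at {variant.CHROM}:{variant.POS}; biallelic SNPs only"
            )
        gt = np.asarray(variant.gt_types)  # 0 hom-ref, 1 het, 2 missing, 3 hom-alt
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dosage.astype(np.int8))
        meta_rows.append(
            {
                "id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
    if not meta_rows:
        raise ValueError("VCF contains no variants")
    return _finish_matrix(np.stack(rows, axis=1), pd.DataFrame(meta_rows), samples)


def read_phenotype_table(path: str | Path) -> PhenotypeVector:
    """Read a phenotype TSV/CSV with columns sample_id, value[, treatment]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("sample_id", "value"):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks column '{col}'")
    df = df.dropna(subset=["value"])
    return PhenotypeVector(
        sample_ids=df["sample_id"].astype(str).tolist(),
        values=df["value"].to_numpy(float),
        treatment=df["treatment"].astype(str).tolist() if "treatment" in df.columns else None,
    )


def write_genotype_csv(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as CSV (samples x SNPs); missing cells left empty."""
    df = pd.DataFrame(G.dosage.astype(float), index=G.sample_ids, columns=G.snp_ids)
    df = df.where(df != MISSING, other=np.nan)
    df.to_csv(path, index_label="sample_id")
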