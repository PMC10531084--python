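"""Core in-memory containers shared across the package.

Genotypes are biallelic SNP dosages coded 0/1/2 (count of the alt allele),
with ``MISSING`` (−1) marking no-calls.  All downstream modules consume these
containers rather than raw files.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

SNP_META_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """n individuals × m SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosage : (n, m) int8 array with entries in {0, 1, 2, MISSING}.
    snp_meta : DataFrame with columns id, chrom, pos, ref, alt (one row per SNP).
    sample_ids : length-n list of unique sample identifiers.
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D (individuals x SNPs) array")
        n, m = self.dosage.shape
        if n < 2 or m < 1:
            raise ValueError(f"need at least 2 individuals and 1 SNP, got {n} x {m}")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"invalid dosage codes {bad.tolist()}; expected 0/1/2 or {MISSING}")
        self.snp_meta = pd.DataFrame(self.snp_meta).reset_index(drop=True)
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise ValueError(f"snp_meta lacks columns {missing_cols}")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta row count does not match dosage columns")
        if self.snp_meta["id"].duplicated().any():
            raise ValueError("SNP ids must be unique")
        if (pd.to_numeric(self.snp_meta["pos"]) < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["id"].astype(str).tolist()

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the SNP columns in ``index`` (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            snp_meta=self.snp_meta.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class PhenotypeVector:
    """Trait values aligned to genotype sample ids.

    ``treatment`` carries the nitrogen-level style grouping label (e.g. LN/HN);
    a single shared label is allowed.
    """

    sample_ids: list[str]
    values: np.ndarray
    treatment: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("values must be 1-D and aligned to sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("trait values must be finite")
        if np.isfinite(self.values).sum() < 3:
            raise ValueError("need at least 3 trait values")
        if self.treatment is not None:
            self.treatment = [str(t) for t in self.treatment]
            if len(self.treatment) != len(self.sample_ids):
                raise ValueError("treatment labels must align to sample_ids")

    def __len__(self) -> int:
        return len(self.values)

    def align_to(self, sample_ids: list[str]) -> "PhenotypeVector":
        """Reorder/subset to ``sample_ids`` (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[str(s)] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"phenotype lacks sample {exc}") from exc
        return PhenotypeVector(
            sample_ids=[str(s) for s in sample_ids],
            values=self.values[idx],
            treatment=None if self.treatment is None else [self.treatment[i] for i in idx],
        )


@dataclass
class SummaryStats:
    """Per-SNP association summary records (one row per SNP).

    ``table`` columns: snp, chr, pos, effect, se, p, z, maf, model_tag.
    ``z`` may be NaN until :func:`survfdr.assoc_scan.p_to_z` fills it.
    """

    table: pd.DataFrame

    REQUIRED = ["snp", "chr", "pos", "effect", "se", "p", "maf"]

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table).reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary stats lack columns {missing}")
        if "z" not in self.table.columns:
            self.table["z"] = np.nan
        if "model_tag" not in self.table.columns:
            self.table["model_tag"] = "unknown"
        if self.table["snp"].duplicated().any():
            raise ValueError("one record per SNP id required")
        p = self.table["p"].to_numpy(float)
        ok = np.isnan(p) | ((p > 0) & (p <= 1))
        if not ok.all():
            raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)
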