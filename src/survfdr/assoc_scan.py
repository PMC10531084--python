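"""Single-locus mixed-model association scan and p-to-z conversion.

The scan fits y = X b + g + e with g ~ N(0, K sigma_g^2) once under the null
(no SNP), holding the fitted variance ratio fixed thereafter, and then tests
each SNP by generalized least squares in the eigenbasis of K — the standard
"exact two-step" approximation (EMMAX-style).  Summary statistics from any
external GWAS tool can enter the downstream FDR machinery through
:func:`read_summary_stats` instead.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._mixed import eigen_rotate, profile_h2
from .datatypes import MISSING, GenotypeMatrix, PhenotypeVector, SummaryStats
from .grm import KinshipMatrix
from .io_qc import snp_qc_metrics

__all__ = ["single_locus_scan", "p_to_z", "read_summary_stats", "write_summary_stats"]

P_CLAMP = 1e-15


def single_locus_scan(
    y: PhenotypeVector,
    G: GenotypeMatrix,
    K: KinshipMatrix | None = None,
    covariates: np.ndarray | None = None,
    model_tag: str = "single_locus_mm",
) -> SummaryStats:
    """Per-SNP effect, SE and two-sided Wald p under the kinship mixed model.

    Parameters
    ----------
    covariates : optional (n, c) design appended to the intercept (e.g.
        principal components).  Must have full column rank.
    K : kinship; ``None`` means an identity relationship (plain regression).

    Notes
    -----
    Missing dosages are mean-imputed for the regression design only.
    Monomorphic SNPs yield a record with NaN effect and p = 1.  The Wald test
    uses a t reference with n - rank(X) - 1 degrees of freedom, so with K = I
    and sigma_g^2 = 0 the scan reduces exactly to ordinary least squares.
    """
    ph = y.align_to(G.sample_ids)
    yv = ph.values.astype(float)
    n, m = G.dosage.shape
    if n < 3:
        raise ValueError("scan needs at least 3 individuals")

    X = np.ones((n, 1))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            raise ValueError("covariates must align to samples")
        X = np.hstack([X, covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    p_fixed = X.shape[1]
    if n - p_fixed - 1 <= 0:
        raise ValueError("insufficient degrees of freedom for the scan")

    if K is None:
        d = np.zeros(n)
        U = np.eye(n)
        h2 = 0.0
    else:
        d, U = eigen_rotate(K.values)
        h2, _, _ = profile_h2(yv, X, K.values)

    v = h2 * d + (1.0 - h2)
    sw = 1.0 / np.sqrt(v)  # whitening weights in the rotated basis
    yr = (U.T @ yv) * sw
    Xr = (U.T @ X) * sw[:, None]

    dosage = G.dosage.astype(float)
    dosage[dosage == MISSING] = np.nan
    col_mean = np.nanmean(dosage, axis=0)
    filled = np.where(np.isnan(dosage), col_mean, dosage)
    mono = np.nanstd(dosage, axis=0) == 0
    Gr = (U.T @ filled) * sw[:, None]

    df = n - p_fixed - 1
    effects = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    pvals = np.ones(m)

    # project out fixed effects once, then each SNP is a 1-dof addition
    Q, _ = np.linalg.qr(Xr)
    y_res = yr - Q @ (Q.T @ yr)
    G_res = Gr - Q @ (Q.T @ Gr)
    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gg
        rss = y_res @ y_res - beta * gy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    ok = ~mono & (gg > 1e-12) & np.isfinite(tstat)
    effects[ok] = beta[ok]
    ses[ok] = se[ok]
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df=df)
    pvals = np.clip(pvals, P_CLAMP, 1.0)

    qc = snp_qc_metrics(G).table
    table = pd.DataFrame(
        {
            "snp": G.snp_ids,
            "chr": G.snp_meta["chrom"].astype(str),
            "pos": G.snp_meta["pos"].to_numpy(),
            "effect": effects,
            "se": ses,
            "p": pvals,
            "maf": qc["maf"].to_numpy(),
            "model_tag": model_tag,
        }
    )
    return p_to_z(SummaryStats(table=table))


def p_to_z(summary: SummaryStats, one_sided: bool = False) -> SummaryStats:
    """Fill the z column from p-values (and effect signs when present).

    Default two-sided convention: z = Phi^{-1}(1 - p/2) * sign(effect), with
    the magnitude left unsigned for records lacking an effect estimate (so
    p = 1 maps to z = 0).  ``one_sided=True`` uses z = Phi^{-1}(1 - p)
    instead.  p-values are clamped away from 0 and 1 before inversion so z
    stays finite.
    """
    tab = summary.table.copy()
    p = tab["p"].to_numpy(float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.clip(p, P_CLAMP, 1.0 - 1e-16)
    if one_sided:
        z = stats.norm.isf(p)
    else:
        effect = tab["effect"].to_numpy(float)
        sign = np.where(np.isfinite(effect) & (effect < 0), -1.0, 1.0)
        z = stats.norm.isf(p / 2.0) * sign
        z[tab["p"].to_numpy(float) >= 1.0] = 0.0
    tab["z"] = z
    return SummaryStats(table=tab)


STATS_COLUMNS = ["snp", "chr", "pos", "effect", "se", "p", "maf"]


def read_summary_stats(path: str | Path, model_tag: str | None = None) -> SummaryStats:
    """Read an external scan's summary TSV (columns snp, chr, pos, effect, se, p, maf)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats file lacks columns {missing}")
    if model_tag is not None:
        df["model_tag"] = model_tag
    out = SummaryStats(table=df)
    if out.table["z"].isna().all():
        out = p_to_z(out)
    return out


def write_summary_stats(summary: SummaryStats, path: str | Path) -> None:
    summary.table.to_csv(path, sep="\t", index=False)
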