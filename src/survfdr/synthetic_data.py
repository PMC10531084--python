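"""Synthetic GWAS panels with the structure the estimators assume.

Emulates a selfing-crop association panel: a few subpopulations diverged
under a Balding–Nichols model, strong excess homozygosity, a minor-allele
frequency spectrum bounded away from zero, and a quantitative trait driven by
a handful of moderate QTLs on top of a polygenic background, optionally with
a treatment-level shift (low vs high nitrogen style) and injected outliers.

Defaults mirror the study conditions the package is designed around:
221 individuals in 3 subpopulations, MAF floor 0.05, 10 QTLs at
heritability 0.3.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PhenotypeVector

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_zvalues",
    "PhenotypeSimulation",
]


@dataclass
class SimulationConfig:
    seed: int
    n: int = 221
    m: int = 2000
    n_subpops: int = 3
    fst: float = 0.1
    selfing: float = 0.95
    maf_floor: float = 0.05
    n_qtl: int = 10
    h2: float = 0.3
    qtl_var_share: float = 0.7  # fraction of genetic variance from the QTLs
    treatment_shift: float = 0.0
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 individuals and m >= 1 SNPs")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if not 0.0 <= self.selfing <= 1.0:
            raise ValueError("selfing must lie in [0, 1]")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0 <= self.n_qtl <= self.m:
            raise ValueError("n_qtl must lie in [0, m]")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if not 0.0 <= self.qtl_var_share <= 1.0:
            raise ValueError("qtl_var_share must lie in [0, 1]")


@dataclass
class PhenotypeSimulation:
    phenotype: PhenotypeVector
    qtl_ids: list[str]
    qtl_effects: np.ndarray
    genetic_values: np.ndarray
    outlier_flags: np.ndarray


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Structured genotypes; returns the matrix and per-sample subpop labels.

    Ancestral frequencies are uniform on [maf_floor, 1 - maf_floor];
    subpopulation frequencies follow Balding–Nichols
    Beta(p(1-fst)/fst, (1-p)(1-fst)/fst); genotypes are drawn with
    inbreeding coefficient equal to ``selfing``:
    P(het) = 2pq(1-F), P(hom) = p^2 + Fpq / q^2 + Fpq.
    """
    rng = np.random.default_rng(cfg.seed)
    p_anc = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.m)

    subpop = np.repeat(np.arange(cfg.n_subpops), int(np.ceil(cfg.n / cfg.n_subpops)))[
        : cfg.n
    ]
    if cfg.fst > 0:
        a = p_anc * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst
        p_sub = rng.beta(a, b, size=(cfg.n_subpops, cfg.m))
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))

    q = p_sub[subpop]  # per-individual alt frequency, (n, m)
    F = cfg.selfing
    prob_het = 2.0 * q * (1.0 - q) * (1.0 - F)
    prob_hom_alt = q**2 + F * q * (1.0 - q)
    u = rng.random((cfg.n, cfg.m))
    dosage = np.where(
        u < prob_hom_alt, 2, np.where(u < prob_hom_alt + prob_het, 1, 0)
    ).astype(np.int8)

    meta = pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(cfg.m)],
            "chrom": (np.arange(cfg.m) % 21 + 1).astype(str),
            "pos": np.arange(1, cfg.m + 1) * 1000,
            "ref": "A",
            "alt": "T",
        }
    )
    G = GenotypeMatrix(
        dosage=dosage,
        snp_meta=meta,
        sample_ids=[f"geno{i:04d}" for i in range(cfg.n)],
    )
    return G, subpop


def simulate_phenotype(G: GenotypeMatrix, cfg: SimulationConfig) -> PhenotypeSimulation:
    """Quantitative trait: QTL effects + polygenic background + noise.

    The genetic value mixes ``n_qtl`` standard-normal QTL effects on centered
    dosages with a polygenic contribution from all remaining SNPs (tiny
    effects), split ``qtl_var_share`` : 1 - ``qtl_var_share``; the total is
    standardized and combined with N(0, 1) noise so the genetic variance
    fraction equals h2.  Treatment labels (LN/HN, balanced at random) shift
    the HN group by ``treatment_shift``; outliers are +/- 5 sd injections at
    ``outlier_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n, m = G.dosage.shape
    X = G.dosage.astype(float)
    X = np.where(X < 0, np.nan, X)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    X = X - X.mean(axis=0)

    qtl_idx = rng.choice(m, size=cfg.n_qtl, replace=False) if cfg.n_qtl else np.array([], int)
    qtl_effects = rng.normal(size=cfg.n_qtl)
    g_qtl = X[:, qtl_idx] @ qtl_effects if cfg.n_qtl else np.zeros(n)
    poly_effects = rng.normal(size=m) / np.sqrt(m)
    g_poly = X @ poly_effects

    def standardize(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return v / s if s > 0 else v

    g = np.sqrt(cfg.qtl_var_share) * standardize(g_qtl) + np.sqrt(
        1.0 - cfg.qtl_var_share
    ) * standardize(g_poly)
    g = standardize(g)

    noise = rng.normal(size=n)
    y = np.sqrt(cfg.h2) * g + np.sqrt(1.0 - cfg.h2) * noise

    treatment = np.array(["LN", "HN"])[rng.permutation(n) % 2]
    if cfg.treatment_shift:
        y = y + np.where(treatment == "HN", cfg.treatment_shift, 0.0)

    outliers = np.zeros(n, dtype=bool)
    if cfg.outlier_rate > 0:
        n_out = int(round(cfg.outlier_rate * n))
        if n_out:
            idx = rng.choice(n, size=n_out, replace=False)
            outliers[idx] = True
            y[idx] += rng.choice([-1.0, 1.0], size=n_out) * 5.0 * y.std()

    pheno = PhenotypeVector(
        sample_ids=list(G.sample_ids), values=y, treatment=treatment.tolist()
    )
    return PhenotypeSimulation(
        phenotype=pheno,
        qtl_ids=[G.snp_ids[j] for j in qtl_idx],
        qtl_effects=qtl_effects,
        genetic_values=np.sqrt(cfg.h2) * g,
        outlier_flags=outliers,
    )


def simulate_zvalues(
    m: int, pi0: float, mu1: float = 3.0, sd1: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group z mixture: null N(0,1) w.p. pi0, else N(mu1, sd1^2).

    Returns (z, is_null) with truth labels for calibration tests.
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    is_null = rng.random(m) < pi0
    z = np.where(
        is_null,
        rng.normal(size=m),
        rng.normal(loc=mu1, scale=sd1, size=m),
    )
    return z, is_null
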