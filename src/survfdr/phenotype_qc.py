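"""Bootstrap and Bayesian-bootstrap quality control of the trait vector.

A grain-yield style trait vector carries a single realized mean; resampling
gives an honest picture of its sampling variability before the vector is used
in association scans.  Two flavours are provided:

* classical bootstrap — multinomial resampling with replacement, B = 2000 by
  default;
* Bayesian bootstrap — flat-Dirichlet observation weights per replicate, which
  never drops an observation entirely and therefore damps the influence of
  isolated outliers on the replicate means.

The "Bayesian bootstrap p-value" summary is defined here as the median
Shapiro–Wilk p-value over weighted resamples of size n, one per replicate: a
reproducible scalar that is monotone in the non-normality of the vector.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import PhenotypeVector

__all__ = [
    "BootstrapSummary",
    "bootstrap_mean",
    "bayesian_bootstrap",
    "normality_test",
    "detect_outliers",
]


@dataclass
class BootstrapSummary:
    B: int
    replicate_means: np.ndarray
    boot_se: float
    ci95: tuple[float, float]
    replicate_normality_p: np.ndarray
    bayes_boot_p: float | None
    seed: int
    method: str = "classical"


def _check_input(y: PhenotypeVector, B: int) -> np.ndarray:
    values = np.asarray(y.values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("trait values must be finite")
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    return values


def _shapiro_p(x: np.ndarray) -> float:
    # Shapiro-Wilk is undefined for constant input; a constant vector is
    # trivially "not rejectable", report p = 1.
    if np.ptp(x) == 0:
        return 1.0
    return float(stats.shapiro(x).pvalue)


def bootstrap_mean(y: PhenotypeVector, B: int = 2000, seed: int = 0) -> BootstrapSummary:
    """Classical bootstrap of the trait mean.

    ``boot_se`` is the standard deviation of the B replicate means and the
    95% CI is the percentile interval.  Per-replicate Shapiro–Wilk p-values
    are recorded so normality can be judged across resamples rather than from
    the single observed vector.
    """
    values = _check_input(y, B)
    rng = np.random.default_rng(seed)
    n = len(values)
    idx = rng.integers(0, n, size=(B, n))
    samples = values[idx]
    means = samples.mean(axis=1)
    norm_p = np.array([_shapiro_p(row) for row in samples])
    return BootstrapSummary(
        B=B,
        replicate_means=means,
        boot_se=float(means.std(ddof=1)),
        ci95=(float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))),
        replicate_normality_p=norm_p,
        bayes_boot_p=None,
        seed=seed,
        method="classical",
    )


def bayesian_bootstrap(y: PhenotypeVector, B: int = 2000, seed: int = 0) -> BootstrapSummary:
    """Bayesian bootstrap of the trait mean with flat-Dirichlet weights.

    Each replicate draws w ~ Dirichlet(1, ..., 1) and records the weighted
    mean.  ``bayes_boot_p`` is the median Shapiro–Wilk p-value over weighted
    resamples of size n (one per replicate).
    """
    values = _check_input(y, B)
    rng = np.random.default_rng(seed)
    n = len(values)
    weights = rng.dirichlet(np.ones(n), size=B)
    means = weights @ values
    norm_p = np.empty(B)
    for b in range(B):
        resample = rng.choice(values, size=n, replace=True, p=weights[b])
        norm_p[b] = _shapiro_p(resample)
    return BootstrapSummary(
        B=B,
        replicate_means=means,
        boot_se=float(means.std(ddof=1)),
        ci95=(float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))),
        replicate_normality_p=norm_p,
        bayes_boot_p=float(np.median(norm_p)),
        seed=seed,
        method="bayesian",
    )


def normality_test(y: PhenotypeVector) -> tuple[float, float]:
    """Shapiro–Wilk test of the trait vector; returns (W, p)."""
    values = np.asarray(y.values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if len(values) > 5000:
        raise ValueError("Shapiro-Wilk p-value unreliable beyond n = 5000")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def detect_outliers(y: PhenotypeVector, k: float = 1.5) -> np.ndarray:
    """Tukey fence outlier flags: outside [Q1 - k*IQR, Q3 + k*IQR].

    Report-only: callers decide whether flagged observations are removed
    (field phenotypes often keep genuine extreme yields).
    """
    values = np.asarray(y.values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 observations for quartile fences")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    if not np.isfinite(k):
        return np.zeros(len(values), dtype=bool)
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)
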