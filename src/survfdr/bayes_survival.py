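"""Bayesian survival FDR for GWAS significance thresholds.

The idea: order the individuals by trait value and treat that ranking as a
pseudo-time axis.  At each SNP the sample splits into allele classes (major
homozygote, heterozygote, minor homozygote, missing).  Carriers of the minor
allele are "events" at their own pseudo-time; major homozygotes are censored.
A SNP whose minor-allele carriers cluster at one end of the trait ranking
produces allele-class survival curves that separate, and the exponential
proportional-hazards coefficient of the dosage covariate quantifies that
separation on the log-hazard scale.

That hazard information enters a spike-and-slab posterior as a per-SNP prior
weight, the Bayes survived factor lambda_SNP = lambda0 * exp(beta_GY).  A
binary-indicator Gibbs sampler over the two-group model for z-scores then
yields per-SNP posterior inclusion probabilities P(association | data), and
the decision rule flags SNP j when P_j > 1 - MAF_j — rare alleles must clear
a higher evidence bar.  Two set-level summaries are reported: the
survival-weighted ratio sum(P) / sum(lambda * |z|) ("bsfdr_score") and the
standard Bayesian FDR mean(1 - P) over the selected set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix, PhenotypeVector, SummaryStats

__all__ = [
    "AlleleEventTable",
    "SurvivalCurve",
    "SurvivalFit",
    "PosteriorTable",
    "build_event_table",
    "nelson_aalen",
    "class_survival_curves",
    "summarize_survival",
    "fit_exponential_ph",
    "bayes_survived_factor",
    "mcmc_posterior_inclusion",
    "bsfdr_score",
    "significance_decision",
    "bsfdr_analysis",
]

CLASS_NAMES = {0: "major_hom", 1: "het", 2: "minor_hom", MISSING: "missing"}


@dataclass
class AlleleEventTable:
    """Per-individual pseudo-time, allele class and event/censor flags."""

    table: pd.DataFrame  # columns: sample_id, time, allele_class, event
    monomorphic: bool = False

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())


@dataclass
class SurvivalCurve:
    times: np.ndarray       # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    cum_hazard: np.ndarray  # H(t) at each event time
    n_members: int

    @property
    def survival(self) -> np.ndarray:
        return np.exp(-self.cum_hazard)


@dataclass
class SurvivalFit:
    """Exponential proportional-hazards fit for one SNP (or the pooled panel)."""

    rate: float              # baseline hazard lambda0
    beta: float              # log hazard ratio per dosage unit
    log_lik: float
    aic: float
    bic: float
    n_events: int
    identifiable: bool = True


@dataclass
class PosteriorTable:
    """Per-SNP posterior inclusion probabilities and the MAF-indexed decision."""

    table: pd.DataFrame  # columns: snp, P, lambda, alpha, significant
    bsfdr: float
    bayes_fdr_selected: float
    iterations: int
    burn_in: int
    seed: int
    settings: dict = field(default_factory=dict)


def build_event_table(
    snp_dosage: np.ndarray, y: PhenotypeVector
) -> AlleleEventTable:
    """Pseudo-time event table for one SNP.

    Pseudo-time is the ascending rank (1..n) of the trait value, ties broken
    by sample id so the ordering is a deterministic permutation.  Minor-allele
    carriers (het and minor hom) are events at their own pseudo-time; major
    homozygotes (and missing calls) are censored there.
    """
    dosage = np.asarray(snp_dosage)
    if dosage.ndim != 1 or len(dosage) != len(y):
        raise ValueError("dosage column must align to the phenotype")
    if len(y) < 4:
        raise ValueError("need at least 4 individuals")

    order = sorted(range(len(y)), key=lambda i: (y.values[i], y.sample_ids[i]))
    time = np.empty(len(y), dtype=int)
    time[order] = np.arange(1, len(y) + 1)

    allele_class = np.array([CLASS_NAMES.get(int(d), "missing") for d in dosage])
    event = np.isin(allele_class, ("het", "minor_hom"))
    tab = pd.DataFrame(
        {
            "sample_id": y.sample_ids,
            "time": time,
            "allele_class": allele_class,
            "event": event,
        }
    )
    observed = dosage[dosage != MISSING]
    monomorphic = len(np.unique(observed)) <= 1
    return AlleleEventTable(table=tab, monomorphic=monomorphic)


def nelson_aalen(tab: AlleleEventTable) -> SurvivalCurve:
    """Nelson–Aalen cumulative hazard H(t) = sum_{t_i <= t} d_i / n_i.

    Censored individuals leave the risk set at their time without
    contributing an event; S(t) = exp(-H(t)).
    """
    df = tab.table
    n = len(df)
    event_times = np.unique(df.loc[df["event"], "time"].to_numpy())
    at_risk = np.empty(len(event_times))
    d = np.empty(len(event_times))
    times_all = df["time"].to_numpy()
    ev = df["event"].to_numpy()
    for j, t in enumerate(event_times):
        at_risk[j] = (times_all >= t).sum()
        d[j] = (ev & (times_all == t)).sum()
    hazard = np.cumsum(d / at_risk) if len(event_times) else np.array([])
    return SurvivalCurve(
        times=event_times.astype(float),
        at_risk=at_risk,
        events=d,
        cum_hazard=hazard,
        n_members=n,
    )


def class_survival_curves(tab: AlleleEventTable) -> dict[str, SurvivalCurve]:
    """Per-allele-class survival along the trait ranking.

    Within a class every member is an event at its own pseudo-time: the curve
    measures how long the class persists along the yield ranking, which is
    what separates, say, a minor allele confined to low-yield genotypes from
    one spread across the panel.
    """
    out: dict[str, SurvivalCurve] = {}
    for name, sub in tab.table.groupby("allele_class", sort=True):
        sub_tab = AlleleEventTable(
            table=sub.assign(event=True).reset_index(drop=True)
        )
        out[str(name)] = nelson_aalen(sub_tab)
    return out


def summarize_survival(
    curves: dict[str, SurvivalCurve], min_count: int = 3, floor: float = 0.05
) -> pd.DataFrame:
    """Mean and SE of S over each class's event grid, with survived flags.

    A class "survives" when it has at least ``min_count`` members and its
    mean survival stays at or above ``floor``.  Classes with an empty grid
    (no events, S identically 1) get mean 1 and SE 0.
    """
    rows = []
    for name, curve in curves.items():
        s = curve.survival
        if len(s) == 0:
            mean_s, se_s = 1.0, 0.0
        else:
            mean_s = float(s.mean())
            se_s = float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0
        rows.append(
            {
                "allele_class": name,
                "n_members": curve.n_members,
                "mean_S": mean_s,
                "se_S": se_s,
                "survived": curve.n_members >= min_count and mean_s >= floor,
            }
        )
    if not rows:
        raise ValueError("no allele classes present")
    return pd.DataFrame(rows)


def fit_exponential_ph(
    tab: AlleleEventTable, dosage: np.ndarray | None = None, beta_prior_var: float = 4.0
) -> SurvivalFit:
    """Exponential hazard fit lambda(x) = lambda0 * exp(beta * x).

    With no covariate (or a constant one) the null MLE is rate = events /
    total exposure time, beta = 0.  AIC = 2k - 2 logL; BIC = k ln(d) - 2 logL
    with d the event count.  Newton iterations on (log lambda0, beta),
    tolerance 1e-8, at most 100 steps.

    Because events are by construction confined to minor-allele carriers, a
    clean SNP has a zero-hazard reference group and the unpenalized beta MLE
    diverges (complete separation).  A weakly informative N(0, beta_prior_var)
    prior on beta (default sd 2 on the log hazard ratio) keeps the estimate
    finite without materially shrinking identified fits; the reported logL,
    AIC and BIC are the unpenalized likelihood at the penalized optimum.
    """
    df = tab.table
    t = df["time"].to_numpy(float)
    delta = df["event"].to_numpy(float)
    d = delta.sum()
    if d == 0:
        raise ValueError("no events: exponential hazard unidentifiable")

    def null_fit(identifiable: bool) -> SurvivalFit:
        rate = d / t.sum()
        ll = d * np.log(rate) - rate * t.sum()
        return SurvivalFit(
            rate=float(rate),
            beta=0.0,
            log_lik=float(ll),
            aic=float(2 * 1 - 2 * ll),
            bic=float(1 * np.log(d) - 2 * ll),
            n_events=int(d),
            identifiable=identifiable,
        )

    if dosage is None:
        return null_fit(True)

    x = np.asarray(dosage, float)
    x = np.where(x == MISSING, np.nan, x)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    if np.ptp(x) == 0:
        return null_fit(False)

    # Newton on theta = (log lambda0, beta) with ridge on beta
    inv_v = 1.0 / beta_prior_var
    theta = np.array([np.log(d / t.sum()), 0.0])
    for _ in range(100):
        eta = np.clip(theta[0] + theta[1] * x, -500, 50)
        mu = np.exp(eta) * t  # expected events per subject
        grad = np.array(
            [np.sum(delta - mu), np.sum(x * (delta - mu)) - theta[1] * inv_v]
        )
        hess = -np.array(
            [
                [np.sum(mu), np.sum(x * mu)],
                [np.sum(x * mu), np.sum(x * x * mu) + inv_v],
            ]
        )
        step = np.linalg.solve(hess, grad)
        # damp large steps so separated configurations stay on track
        step = np.clip(step, -2.0, 2.0)
        theta = theta - step
        if np.max(np.abs(step)) < 1e-8:
            break
    lam0 = float(np.exp(theta[0]))
    beta = float(theta[1])
    eta = theta[0] + theta[1] * x
    ll = float(np.sum(delta * eta) - np.sum(np.exp(eta) * t))
    k = 2
    return SurvivalFit(
        rate=lam0,
        beta=beta,
        log_lik=ll,
        aic=float(2 * k - 2 * ll),
        bic=float(k * np.log(d) - 2 * ll),
        n_events=int(d),
        identifiable=True,
    )


def bayes_survived_factor(lam0: float, beta_gy: float) -> float:
    """Bayes survived factor lambda_SNP = lambda0 * exp(beta_GY)."""
    if lam0 <= 0:
        raise ValueError("baseline rate must be positive")
    return float(lam0 * np.exp(beta_gy))


def mcmc_posterior_inclusion(
    z: np.ndarray,
    lam: np.ndarray,
    pi1_base: float = 0.05,
    iterations: int = 150_000,
    burn_in: int = 2_000,
    seed: int = 0,
    tau2: float = 4.0,
) -> np.ndarray:
    """Posterior inclusion probabilities by binary-indicator Gibbs sampling.

    Two-group model: z_j | gamma_j = 0 ~ N(0, 1); z_j | gamma_j = 1 ~
    N(0, 1 + tau2).  Prior odds for SNP j are
    (pi1_base / (1 - pi1_base)) * lam_j / mean(lam), so the survival factors
    tilt the prior without changing its average level.  Returns the
    post-burn-in mean of the sampled indicators.
    """
    z = np.asarray(z, float)
    lam = np.asarray(lam, float)
    if z.shape != lam.shape:
        raise ValueError("z and lambda must align")
    if not np.isfinite(z).all():
        raise ValueError("z must be finite")
    if np.any(lam <= 0):
        raise ValueError("lambda factors must be positive")
    if not 0.0 < pi1_base < 1.0:
        raise ValueError("pi1_base must lie in (0, 1)")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")

    prior_odds = (pi1_base / (1.0 - pi1_base)) * lam / lam.mean()
    # Bayes factor of slab vs spike at each z (log scale for stability)
    log_bf = stats.norm.logpdf(z, scale=np.sqrt(1.0 + tau2)) - stats.norm.logpdf(z)
    odds = prior_odds * np.exp(log_bf)
    p_cond = odds / (1.0 + odds)  # full conditional is an independent Bernoulli

    rng = np.random.default_rng(seed)
    m = len(z)
    kept = iterations - burn_in
    acc = np.zeros(m, dtype=np.int64)
    # bound the per-chunk uniform draw at ~1e7 entries (~80 MB)
    chunk = max(1, min(iterations, int(1e7 // max(m, 1)) or 1))
    done = 0
    while done < iterations:
        size = min(chunk, iterations - done)
        draws = rng.random((size, m)) < p_cond
        lo = max(burn_in - done, 0)
        if lo < size:
            acc += draws[lo:].sum(axis=0)
        done += size
    return acc / kept


def bsfdr_score(
    P: np.ndarray, lam: np.ndarray, theta_hat: np.ndarray
) -> tuple[float, float]:
    """Survival-weighted FDR ratio sum(P) / sum(lam * theta_hat).

    ``theta_hat`` is the per-SNP standardized effect magnitude |z|.  Returns
    (bsfdr, bayes_fdr) where bayes_fdr = mean(1 - P) over all SNPs — the
    conventional set-level Bayesian FDR companion.  The ratio itself is not
    confined to [0, 1]; it is reported verbatim.
    """
    P = np.asarray(P, float)
    lam = np.asarray(lam, float)
    theta_hat = np.asarray(theta_hat, float)
    if not (P.shape == lam.shape == theta_hat.shape):
        raise ValueError("P, lambda and theta_hat must align")
    denom = float(np.sum(lam * theta_hat))
    if denom <= 0:
        raise ValueError("sum(lambda * theta_hat) must be positive")
    return float(P.sum() / denom), float(np.mean(1.0 - P))


def significance_decision(P: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """MAF-indexed decision rule: flag SNP j when P_j > 1 - MAF_j.

    A SNP with MAF 0 can never be flagged (threshold 1); a warning is issued
    since such sites should have been removed by QC.
    """
    P = np.asarray(P, float)
    maf = np.asarray(maf, float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("MAF must lie in [0, 0.5]")
    if np.any(maf == 0):
        warnings.warn(
            "MAF of 0 encountered: threshold is 1, the SNP can never be significant",
            stacklevel=2,
        )
    return P > (1.0 - maf)


def bsfdr_analysis(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    summary: SummaryStats,
    pi1_base: float | None = None,
    lam0: float = 1.0,
    iterations: int = 150_000,
    burn_in: int = 2_000,
    seed: int = 0,
    tau2: float = 4.0,
    lambda_mode: str = "global",
) -> PosteriorTable:
    """End-to-end Bayesian survival FDR over a genotype panel.

    For each SNP: build the allele-event table on the trait ranking, fit the
    exponential proportional-hazards model to obtain beta, form the Bayes
    survived factor lambda_SNP = lam0 * exp(beta_GY), then run the
    spike-and-slab Gibbs sampler on the z-scores with survival-tilted prior
    odds and apply the P > 1 - MAF rule.

    ``lambda_mode`` picks the beta_GY entering the prior: "global" (default)
    uses one genome-wide coefficient from the pooled event table — a flat
    prior across SNPs, the operating choice for a routine run — while
    "per_snp" tilts each SNP by its own hazard coefficient.  Per-SNP betas
    are estimated and reported in either mode.  ``pi1_base`` defaults to 0.05
    when not supplied (callers typically pass 1 - pi0 from a local FDR fit).
    SNPs whose hazard model is unidentifiable (monomorphic) keep beta = 0.
    """
    if lambda_mode not in ("global", "per_snp"):
        raise ValueError("lambda_mode must be 'global' or 'per_snp'")
    stats_tab = summary.table.set_index("snp")
    snp_ids = G.snp_ids
    missing = [s for s in snp_ids if s not in stats_tab.index]
    if missing:
        raise ValueError(f"summary stats lack {len(missing)} SNPs (e.g. {missing[:3]})")
    z = stats_tab.loc[snp_ids, "z"].to_numpy(float)
    maf = stats_tab.loc[snp_ids, "maf"].to_numpy(float)
    if pi1_base is None:
        pi1_base = 0.05

    betas = np.zeros(G.n_snps)
    pooled_t, pooled_e, pooled_x = [], [], []
    for j in range(G.n_snps):
        tab = build_event_table(G.dosage[:, j], y)
        if tab.monomorphic or tab.n_events == 0:
            continue
        fit = fit_exponential_ph(tab, G.dosage[:, j])
        if fit.identifiable:
            betas[j] = fit.beta
        pooled_t.append(tab.table["time"].to_numpy())
        pooled_e.append(tab.table["event"].to_numpy())
        pooled_x.append(G.dosage[:, j])

    if lambda_mode == "global":
        # one genome-wide coefficient from the pooled event table
        if pooled_t:
            n_rows = sum(len(t) for t in pooled_t)
            pooled = AlleleEventTable(
                table=pd.DataFrame(
                    {
                        "sample_id": np.arange(n_rows).astype(str),
                        "time": np.concatenate(pooled_t),
                        "allele_class": "pooled",
                        "event": np.concatenate(pooled_e),
                    }
                )
            )
            beta_gy = fit_exponential_ph(
                pooled, np.concatenate(pooled_x).astype(float)
            ).beta
        else:
            beta_gy = 0.0
        lam = np.full(G.n_snps, bayes_survived_factor(lam0, beta_gy))
    else:
        lam = lam0 * np.exp(betas)

    P = mcmc_posterior_inclusion(
        z, lam, pi1_base=pi1_base, iterations=iterations, burn_in=burn_in,
        seed=seed, tau2=tau2,
    )
    flags = significance_decision(P, np.nan_to_num(maf, nan=0.0))
    score, _ = bsfdr_score(P, lam, np.abs(z))
    sel_fdr = float(np.mean(1.0 - P[flags])) if flags.any() else float("nan")
    table = pd.DataFrame(
        {
            "snp": snp_ids,
            "P": P,
            "lambda": lam,
            "beta": betas,
            "alpha": maf,
            "significant": flags,
        }
    )
    return PosteriorTable(
        table=table,
        bsfdr=score,
        bayes_fdr_selected=sel_fdr,
        iterations=iterations,
        burn_in=burn_in,
        seed=seed,
        settings={"pi1_base": pi1_base, "lam0": lam0, "tau2": tau2},
    )
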