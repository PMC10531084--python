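import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survfdr.bayes_survival import (
    AlleleEventTable,
    bayes_survived_factor,
    bsfdr_score,
    build_event_table,
    class_survival_curves,
    fit_exponential_ph,
    mcmc_posterior_inclusion,
    nelson_aalen,
    significance_decision,
    summarize_survival,
)
from survfdr.datatypes import MISSING, PhenotypeVector


def phenotype(values, ids=None):
    ids = ids or [f"g{i}" for i in range(len(values))]
    return PhenotypeVector(sample_ids=ids, values=values)


def all_event_table(times):
    return AlleleEventTable(
        table=pd.DataFrame(
            {
                "sample_id": [f"g{i}" for i in range(len(times))],
                "time": times,
                "allele_class": "het",
                "event": True,
            }
        )
    )


def brute_force_cum_hazard(times, events):
    """Risk-set enumeration oracle for the Nelson-Aalen estimator."""
    event_times = sorted(set(t for t, e in zip(times, events) if e))
    H, out = 0.0, []
    for t in event_times:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, e in zip(times, events) if e and ti == t)
        H += d / at_risk
        out.append(H)
    return np.array(event_times, float), np.array(out)


class TestBuildEventTable:
    def test_direct_construction(self):
        tab = build_event_table(np.array([0, 0, 1, 2]), phenotype([10.0, 20.0, 30.0, 40.0]))
        df = tab.table
        assert list(df["time"]) == [1, 2, 3, 4]
        assert list(df["event"]) == [False, False, True, True]
        assert list(df["allele_class"]) == ["major_hom", "major_hom", "het", "minor_hom"]

    def test_monomorphic_has_zero_events_and_flag(self):
        tab = build_event_table(np.zeros(5, dtype=int), phenotype([1.0, 2, 3, 4, 5]))
        assert tab.n_events == 0
        assert tab.monomorphic

    def test_tie_break_is_deterministic_by_sample_id(self):
        y = phenotype([1.0, 1.0, 1.0, 2.0], ids=["d", "b", "a", "c"])
        tab = build_event_table(np.array([0, 1, 2, 0]), y)
        by_id = tab.table.set_index("sample_id")["time"]
        assert by_id["a"] < by_id["b"] < by_id["d"] < by_id["c"]
        # same data presented in another order gives the same times
        perm = [2, 0, 3, 1]
        y2 = phenotype([1.0, 1.0, 2.0, 1.0], ids=["a", "d", "c", "b"])
        tab2 = build_event_table(np.array([2, 0, 0, 1]), y2)
        pd.testing.assert_series_equal(
            tab2.table.set_index("sample_id")["time"].sort_index(), by_id.sort_index()
        )

    def test_missing_dosage_is_censored_class(self):
        tab = build_event_table(
            np.array([0, MISSING, 1, 2]), phenotype([1.0, 2.0, 3.0, 4.0])
        )
        row = tab.table[tab.table["allele_class"] == "missing"].iloc[0]
        assert not row["event"]


class TestNelsonAalen:
    def test_hand_computed_all_events(self):
        curve = nelson_aalen(all_event_table([1, 2, 3, 4]))
        np.testing.assert_allclose(
            curve.cum_hazard, [0.25, 0.5833, 1.0833, 2.0833], atol=1e-4
        )
        np.testing.assert_allclose(
            curve.survival, [0.7788, 0.5580, 0.3385, 0.1245], atol=1e-4
        )

    def test_zero_events_survival_stays_one(self):
        tab = build_event_table(np.zeros(5, dtype=int), phenotype([1.0, 2, 3, 4, 5]))
        curve = nelson_aalen(tab)
        assert len(curve.times) == 0
        assert curve.survival.size == 0  # S identically 1 before any event

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_risk_set_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        times = list(rng.permutation(np.arange(1, n + 1)))
        events = list(rng.random(n) < 0.6)
        if not any(events):
            events[0] = True
        tab = AlleleEventTable(
            table=pd.DataFrame(
                {
                    "sample_id": [f"g{i}" for i in range(n)],
                    "time": times,
                    "allele_class": "het",
                    "event": events,
                }
            )
        )
        curve = nelson_aalen(tab)
        t_or, h_or = brute_force_cum_hazard(times, events)
        np.testing.assert_allclose(curve.times, t_or)
        np.testing.assert_allclose(curve.cum_hazard, h_or, atol=1e-12)

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        times = rng.permutation(np.arange(1, 31))
        events = rng.random(30) < 0.5
        tab = AlleleEventTable(
            table=pd.DataFrame(
                {
                    "sample_id": [f"g{i}" for i in range(30)],
                    "time": times,
                    "allele_class": "het",
                    "event": events,
                }
            )
        )
        curve = nelson_aalen(tab)
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(times, event_observed=events)
        ref = naf.cumulative_hazard_.loc[curve.times].to_numpy().ravel()
        np.testing.assert_allclose(curve.cum_hazard, ref, atol=1e-10)

    def test_survival_is_exp_neg_hazard_and_monotone(self):
        rng = np.random.default_rng(12)
        tab = all_event_table(list(rng.permutation(np.arange(1, 9))))
        curve = nelson_aalen(tab)
        np.testing.assert_allclose(curve.survival, np.exp(-curve.cum_hazard))
        assert (np.diff(curve.survival) <= 0).all()


class TestSummarizeSurvival:
    def test_mean_of_hand_curve(self):
        curves = {"het": nelson_aalen(all_event_table([1, 2, 3, 4]))}
        out = summarize_survival(curves)
        assert out.loc[0, "mean_S"] == pytest.approx(0.4500, abs=1e-4)
        assert out.loc[0, "survived"]

    def test_small_class_not_survived(self):
        curves = {"minor_hom": nelson_aalen(all_event_table([1, 2]))}
        out = summarize_survival(curves, min_count=3)
        assert not out.loc[0, "survived"]

    def test_eventless_class_mean_one(self):
        tab = build_event_table(np.zeros(5, dtype=int), phenotype([1.0, 2, 3, 4, 5]))
        curves = {"major_hom": nelson_aalen(tab)}
        out = summarize_survival(curves)
        assert out.loc[0, "mean_S"] == 1.0
        assert out.loc[0, "survived"]

    def test_class_curves_partition_sample(self):
        y = phenotype(list(np.linspace(0, 1, 12)))
        tab = build_event_table(np.tile([0, 1, 2, MISSING], 3), y)
        curves = class_survival_curves(tab)
        assert sum(c.n_members for c in curves.values()) == 12
        assert set(curves) == {"major_hom", "het", "minor_hom", "missing"}


class TestExponentialPh:
    def test_null_fit_closed_form(self):
        fit = fit_exponential_ph(all_event_table([1, 2, 3, 4]))
        assert fit.rate == pytest.approx(0.4)
        assert fit.log_lik == pytest.approx(-7.6652, abs=1e-4)
        assert fit.aic == pytest.approx(17.3304, abs=1e-3)
        assert fit.bic == pytest.approx(16.7167, abs=1e-3)

    def test_constant_covariate_flagged(self):
        fit = fit_exponential_ph(all_event_table([1, 2, 3, 4]), np.ones(4))
        assert not fit.identifiable
        assert fit.beta == 0.0

    def test_zero_events_rejected(self):
        tab = build_event_table(np.zeros(5, dtype=int), phenotype([1.0, 2, 3, 4, 5]))
        with pytest.raises(ValueError, match="no events"):
            fit_exponential_ph(tab)

    @pytest.mark.parametrize("seed", range(4))
    def test_information_criteria_identities(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        times = rng.permutation(np.arange(1, n + 1))
        tab = AlleleEventTable(
            table=pd.DataFrame(
                {
                    "sample_id": [f"g{i}" for i in range(n)],
                    "time": times,
                    "allele_class": "het",
                    "event": rng.random(n) < 0.7,
                }
            )
        )
        x = rng.integers(0, 3, size=n).astype(float)
        fit = fit_exponential_ph(tab, x)
        k = 2 if fit.identifiable and np.ptp(x) > 0 else 1
        assert fit.aic == pytest.approx(2 * k - 2 * fit.log_lik)
        assert fit.bic == pytest.approx(k * np.log(fit.n_events) - 2 * fit.log_lik)

    def test_recovers_known_hazard_ratio(self):
        # exposure-time likelihood check: simulated exponential times
        rng = np.random.default_rng(42)
        n = 4000
        x = rng.integers(0, 3, size=n).astype(float)
        lam = 0.5 * np.exp(0.7 * x)
        t = rng.exponential(1.0 / lam)
        tab = AlleleEventTable(
            table=pd.DataFrame(
                {
                    "sample_id": [f"g{i}" for i in range(n)],
                    "time": t,
                    "allele_class": "het",
                    "event": True,
                }
            )
        )
        fit = fit_exponential_ph(tab, x)
        assert fit.rate == pytest.approx(0.5, rel=0.1)
        assert fit.beta == pytest.approx(0.7, abs=0.05)


class TestBayesFactorAndDecision:
    def test_flat_prior_value(self):
        assert bayes_survived_factor(1.0, np.log(0.001)) == pytest.approx(0.001)

    def test_identity_and_arithmetic(self):
        assert bayes_survived_factor(2.0, 0.0) == 2.0
        assert bayes_survived_factor(2.0, np.log(2.0)) == pytest.approx(4.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            bayes_survived_factor(0.0, 1.0)

    def test_rare_allele_needs_more_evidence(self):
        P = np.array([0.90, 0.5])
        maf = np.array([0.127, 0.05])
        flags = significance_decision(P, maf)
        assert flags[0]  # 0.90 > 1 - 0.127
        assert not flags[1]  # 0.5 < 0.95

    def test_zero_maf_warns_and_never_flags(self):
        with pytest.warns(UserWarning, match="MAF of 0"):
            flags = significance_decision(np.array([0.9999]), np.array([0.0]))
        assert not flags[0]


class TestMcmcPosterior:
    def test_matches_analytic_two_group_posterior_at_zero(self):
        tau2 = 4.0
        pi1 = 0.3
        z = np.zeros(50)
        lam = np.ones(50)
        P = mcmc_posterior_inclusion(z, lam, pi1, iterations=20_000, burn_in=2_000, seed=0)
        f1 = stats.norm.pdf(0, scale=np.sqrt(1 + tau2))
        f0 = stats.norm.pdf(0)
        expected = pi1 * f1 / ((1 - pi1) * f0 + pi1 * f1)
        np.testing.assert_allclose(P, expected, atol=0.02)

    def test_extreme_z_saturates(self):
        P = mcmc_posterior_inclusion(
            np.array([10.0]), np.array([1.0]), 0.05, iterations=5_000, burn_in=500, seed=1
        )
        assert P[0] > 0.99

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=100)
        lam = np.exp(rng.normal(size=100) * 0.1)
        a = mcmc_posterior_inclusion(z, lam, 0.1, iterations=3_000, burn_in=300, seed=9)
        b = mcmc_posterior_inclusion(z, lam, 0.1, iterations=3_000, burn_in=300, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_burn_in_must_be_shorter(self):
        with pytest.raises(ValueError):
            mcmc_posterior_inclusion(
                np.zeros(3), np.ones(3), 0.1, iterations=100, burn_in=100, seed=0
            )


class TestBsfdrScore:
    def test_single_snp_instantiation(self):
        score, _ = bsfdr_score(np.array([0.8]), np.array([1.0]), np.array([1.0]))
        assert score == pytest.approx(0.8)

    def test_two_snp_ratio(self):
        score, bfdr = bsfdr_score(
            np.array([1.0, 0.0]), np.array([1.0, 1.0]), np.array([1.0, 1.0])
        )
        assert score == pytest.approx(0.5)
        assert bfdr == pytest.approx(0.5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            bsfdr_score(np.array([0.5]), np.array([1.0]), np.array([0.0]))
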