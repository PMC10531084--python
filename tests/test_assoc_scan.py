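import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survfdr.assoc_scan import (
    p_to_z,
    read_summary_stats,
    single_locus_scan,
    write_summary_stats,
)
from survfdr.datatypes import PhenotypeVector, SummaryStats
from survfdr.grm import compute_grm
from survfdr.synthetic_data import SimulationConfig, simulate_genotypes
from tests.conftest import make_genotypes


def phenotype_for(G, values):
    return PhenotypeVector(sample_ids=list(G.sample_ids), values=values)


class TestSingleLocusScan:
    def test_equals_ols_without_kinship(self):
        rng = np.random.default_rng(0)
        G = make_genotypes(rng.integers(0, 3, size=(30, 8)).astype(np.int8))
        y = phenotype_for(G, rng.normal(size=30))
        scan = single_locus_scan(y, G, K=None)
        import statsmodels.api as sm

        for j in range(8):
            x = sm.add_constant(G.dosage[:, j].astype(float))
            ols = sm.OLS(y.values, x).fit()
            assert scan.table.loc[j, "effect"] == pytest.approx(ols.params[1], rel=1e-8)
            assert scan.table.loc[j, "p"] == pytest.approx(ols.pvalues[1], rel=1e-6)

    def test_null_pvalues_uniform(self):
        cfg = SimulationConfig(seed=5, n=221, m=2000, fst=0.0, selfing=0.0)
        G, _ = simulate_genotypes(cfg)
        rng = np.random.default_rng(6)
        y = phenotype_for(G, rng.normal(size=221))
        scan = single_locus_scan(y, G, K=None)
        ks = stats.kstest(scan.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        G = make_genotypes(rng.integers(0, 3, size=(40, 6)).astype(np.int8))
        y1 = phenotype_for(G, rng.normal(size=40))
        y2 = PhenotypeVector(sample_ids=y1.sample_ids, values=2.0 * y1.values)
        s1 = single_locus_scan(y1, G, K=None).table
        s2 = single_locus_scan(y2, G, K=None).table
        np.testing.assert_allclose(s2["effect"], 2.0 * s1["effect"], rtol=1e-10)
        np.testing.assert_allclose(s2["p"], s1["p"], rtol=1e-10)
        np.testing.assert_allclose(s2["z"], s1["z"], rtol=1e-8)

    def test_monomorphic_snp_gets_null_record(self):
        G = make_genotypes(
            np.column_stack([np.zeros(10, dtype=np.int8), np.tile([0, 1], 5)])
        )
        y = phenotype_for(G, np.arange(10.0))
        scan = single_locus_scan(y, G, K=None)
        assert np.isnan(scan.table.loc[0, "effect"])
        assert scan.table.loc[0, "p"] == 1.0

    def test_kinship_scan_runs_and_controls_structure(self):
        cfg = SimulationConfig(seed=8, n=120, m=600, fst=0.15)
        G, subpop = simulate_genotypes(cfg)
        rng = np.random.default_rng(9)
        # structured phenotype: subpop means differ, no SNP effect
        y = phenotype_for(G, subpop * 1.0 + rng.normal(size=120))
        K = compute_grm(G)
        with_k = single_locus_scan(y, G, K)
        no_k = single_locus_scan(y, G, K=None)
        # kinship correction suppresses the structure-driven inflation
        lam_with = np.median(with_k.table["z"] ** 2) / 0.4549
        lam_without = np.median(no_k.table["z"] ** 2) / 0.4549
        assert lam_with < lam_without

    def test_rank_deficient_covariates_rejected(self):
        G = make_genotypes(np.tile([0, 1, 2], (6, 1)).T[:, :1].repeat(2, axis=1))
        y = phenotype_for(G, np.arange(3.0))
        with pytest.raises(ValueError):
            single_locus_scan(y, G, covariates=np.ones((3, 1)))

    def test_too_few_samples_rejected(self):
        G = make_genotypes(np.array([[0, 1], [2, 1], [1, 0]]))
        y = phenotype_for(G, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degrees of freedom"):
            single_locus_scan(y, G, covariates=np.array([[1.0], [0.0], [2.0]]))


class TestPToZ:
    def make_stats(self, p, effect=np.nan):
        return SummaryStats(
            table=pd.DataFrame(
                {
                    "snp": ["a"],
                    "chr": ["1"],
                    "pos": [1],
                    "effect": [effect],
                    "se": [np.nan],
                    "p": [p],
                    "maf": [0.2],
                }
            )
        )

    def test_p_one_maps_to_zero(self):
        out = p_to_z(self.make_stats(1.0))
        assert out.table.loc[0, "z"] == 0.0

    def test_one_sided_quantile(self):
        out = p_to_z(self.make_stats(0.05), one_sided=True)
        assert out.table.loc[0, "z"] == pytest.approx(1.6449, abs=1e-4)

    def test_sign_carried_from_effect(self):
        out = p_to_z(self.make_stats(0.05, effect=-1.0))
        assert out.table.loc[0, "z"] == pytest.approx(-1.9600, abs=1e-4)

    def test_tiny_p_clamped_finite(self):
        out = p_to_z(self.make_stats(1e-300))
        assert np.isfinite(out.table.loc[0, "z"])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(
                table=pd.DataFrame(
                    {"snp": ["a"], "chr": ["1"], "pos": [1], "effect": [1.0],
                     "se": [1.0], "p": [0.0], "maf": [0.1]}
                )
            )


def test_summary_stats_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    G = make_genotypes(rng.integers(0, 3, size=(20, 5)).astype(np.int8))
    y = PhenotypeVector(sample_ids=list(G.sample_ids), values=rng.normal(size=20))
    scan = single_locus_scan(y, G, K=None)
    path = tmp_path / "stats.tsv"
    write_summary_stats(scan, path)
    back = read_summary_stats(path)
    pd.testing.assert_frame_equal(
        back.table[["snp", "p", "z"]], scan.table[["snp", "p", "z"]]
    )
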