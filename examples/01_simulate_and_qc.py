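"""Simulate a selfing-crop GWAS panel and run genotype + phenotype QC.

Builds a 221 x 2000 structured panel (3 subpopulations, strong selfing),
applies the MAF/call-rate filters, and checks the trait vector with the
classical and Bayesian bootstrap.
"""
import numpy as np

from survfdr import (
    SimulationConfig,
    bayesian_bootstrap,
    bootstrap_mean,
    detect_outliers,
    filter_snps,
    normality_test,
    simulate_genotypes,
    simulate_phenotype,
    snp_qc_metrics,
)

cfg = SimulationConfig(seed=7, n=221, m=2000, h2=0.3, n_qtl=10, outlier_rate=0.02)
G, subpop = simulate_genotypes(cfg)
sim = simulate_phenotype(G, cfg)

report = snp_qc_metrics(G)
G_f, annotated = filter_snps(G, report, maf_min=0.05, callrate_min=0.9)
print(f"SNP QC: {G_f.n_snps} of {G.n_snps} SNPs pass (MAF > 0.05, call rate >= 0.9)")
print(f"median MAF among survivors: {annotated.table.loc[annotated.table['pass'], 'maf'].median():.3f}")

y = sim.phenotype
boot = bootstrap_mean(y, B=2000, seed=7)
bayes = bayesian_bootstrap(y, B=2000, seed=7)
W, p = normality_test(y)
flags = detect_outliers(y)
print(f"\ntrait mean {np.mean(y.values):.3f}, bootstrap SE {boot.boot_se:.3f}, "
      f"95% CI ({boot.ci95[0]:.3f}, {boot.ci95[1]:.3f})")
print(f"Shapiro-Wilk p = {p:.4f}; Bayesian-bootstrap median Shapiro p = {bayes.bayes_boot_p:.4f}")
print(f"Tukey-fence outliers flagged: {int(flags.sum())} "
      f"(injected: {int(sim.outlier_flags.sum())})")
print("\nThe injected outliers drive the Shapiro p toward zero, and the")
print("Bayesian-bootstrap summary (median Shapiro p over weighted resamples)")
print("confirms the non-normality is systematic rather than a one-draw fluke.")
print("Flagged outliers are reported, not removed: field phenotypes often")
print("keep genuine extreme yields.")
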