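"""Bayesian survival FDR end to end on a simulated QTL panel.

Simulates a 221 x 2000 panel with 10 QTLs at h2 = 0.3, runs the kinship
mixed-model scan, then the survival-prior spike-and-slab posterior with the
P > 1 - MAF decision rule, and prints the allele-class survival summary of
the top SNP.
"""
import numpy as np

from survfdr import (
    SimulationConfig,
    bsfdr_analysis,
    build_event_table,
    compute_grm,
    simulate_genotypes,
    simulate_phenotype,
    single_locus_scan,
    summarize_survival,
)
from survfdr.bayes_survival import class_survival_curves

cfg = SimulationConfig(seed=2, n=221, m=2000, h2=0.3, n_qtl=10)
G, _ = simulate_genotypes(cfg)
sim = simulate_phenotype(G, cfg)
K = compute_grm(G)
scan = single_locus_scan(sim.phenotype, G, K)

post = bsfdr_analysis(G, sim.phenotype, scan, iterations=10_000, burn_in=1_000, seed=2)
tab = post.table.sort_values("P", ascending=False)
print("top 5 SNPs by posterior inclusion probability:")
print(tab[["snp", "P", "alpha", "significant"]].head(5).to_string(index=False))
print(f"\nflagged significant (P > 1 - MAF): {int(tab['significant'].sum())}")
truth = np.isin(G.snp_ids, sim.qtl_ids)
ranks = tab.reset_index(drop=True).index[np.isin(tab["snp"], sim.qtl_ids)]
pct = 100 * (1 - ranks.to_numpy() / len(tab))
print(f"true QTL rank percentiles by P (100 = top): {np.round(np.sort(pct)[::-1], 1)}")
print(f"bsFDR score (sum P / sum lambda*|z|): {post.bsfdr:.4f}")
print(f"Bayesian FDR over flagged set: {post.bayes_fdr_selected:.4f}")

top_idx = G.snp_ids.index(tab["snp"].iloc[0])
events = build_event_table(G.dosage[:, top_idx], sim.phenotype)
curves = class_survival_curves(events)
print(f"\nallele-class survival along the trait ranking for {tab['snp'].iloc[0]}:")
print(summarize_survival(curves).to_string(index=False))
print("\nMost true QTLs sit in the upper percentiles of the posterior ranking;")
print("with 10 QTLs sharing 30% heritability at n = 221 the weakest are")
print("statistically invisible, so perfect recovery is not expected.")
print("A class whose mean S differs from the others persists differently")
print("along the yield ranking - the survival signature of an associated SNP.")
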