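"""Local FDR with an empirical null on a two-group z mixture.

Draws 10,000 z-scores (95% null, 5% shifted to mean 3), fits the
spline-density two-groups model, and selects SNPs at locfdr <= 0.05.
"""
import numpy as np

from survfdr import fit_local_fdr, locfdr_select, simulate_zvalues

z, is_null = simulate_zvalues(m=10_000, pi0=0.95, mu1=3.0, sd1=1.0, seed=11)
fit = fit_local_fdr(z, null_method="mle")

print("empirical null: delta = %.4f, sigma = %.4f, pi0 = %.4f"
      % (fit.delta, fit.sigma, fit.pi0_raw))
print("model-comparison metrics:", {k: round(v, 4) for k, v in fit.metrics.items()
                                    if k in ("Delta", "Sigma", "ProportionH0")})

selected, realized = locfdr_select(fit, threshold=0.05)
true_pos = (~is_null[selected]).sum()
print(f"\nselected {len(selected)} SNPs at locfdr <= 0.05; "
      f"{true_pos} are truly non-null")
print(f"realized Bayesian FDR of the selection: {realized:.4f}")
print("\ndelta/sigma near (0, 1) and pi0 near 0.95 show the empirical null")
print("recovered the generating mixture; the realized FDR is the expected")
print("fraction of false leads among the selected SNPs.")
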