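"""Solve the heteroscedastic model for one causal locus and verify the
variance decomposition on simulated data.

A locus is configured to explain 5% of trait variance through a mean shift
and 5% through a variance (SD) shift at minor-allele frequency 0.3.  The
closed-form solver returns the per-dose mean shift alpha, per-dose SD shift
phi and baseline SD sigma; simulating a large cohort and decomposing the
phenotypes recovers the configured shares.
"""

import numpy as np

from vgwas_sim import (
    EffectSizes,
    analytic_decomposition,
    empirical_decomposition,
    generate_hwe,
    simulate_study,
    solve_haploid,
)

params = solve_haploid(EffectSizes(c_mu=0.05, c_v=0.05), v_y=1.0, q=0.3)
print(f"alpha = {params.alpha[0]:.4f}   (carrier mean shift)")
print(f"phi   = {params.phi[0]:.4f}   (carrier SD shift)")
print(f"sigma = {params.sigma:.4f}   (baseline residual SD)")

dec = analytic_decomposition(params)
print(f"analytic shares: V_M={dec.v_m[0]:.3f}  V_V={dec.v_v[0]:.3f} "
      f"V_R={dec.v_r:.3f}  (sum={dec.v_y:.3f})")

gm = generate_hwe(n_samples=50_000, maf=[0.3], ploidy=1, seed=1)
res = simulate_study(gm, [0], EffectSizes(0.05, 0.05), "haploid", seed=2)
emp = empirical_decomposition(res.y, res.causal_doses[:, 0])
c_mu_hat, c_v_hat = emp.shares()
print(f"empirical shares at n=50,000: C_mu={c_mu_hat[0]:.3f} "
      f"C_v={c_v_hat[0]:.3f}  Var(Y)={res.y.var(ddof=1):.3f}")
print("-> the moment estimates sit on the configured 5%/5% split and the "
      "total variance stays at V_Y=1.")
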