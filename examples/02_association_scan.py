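"""Recover simulated mean/variance loci with the three association tests.

A diploid cohort carries three causal loci: mean-only (5%), variance-only
(5%), and a combined 3%+3% locus.  The genome is scanned with the linear
and Brown-Forsythe tests; the DGLM runs at the causal loci.  The expected
pattern: the linear test sees only the mean locus, Brown-Forsythe only the
variance locus, and the DGLM joint test is strongest at the combined locus.
"""

import numpy as np

from vgwas_sim import EffectSizes, generate_hwe, scan, simulate_study

rng = np.random.default_rng(0)
gm = generate_hwe(2000, rng.uniform(0.05, 0.5, 2000), ploidy=2, seed=1)

causal = [100, 1000, 1900]
effects = EffectSizes(c_mu=[0.05, 0.0, 0.03], c_v=[0.0, 0.05, 0.03])
res = simulate_study(gm, causal, effects, "diploid_codominant", seed=2)

df = scan(gm, res.y, tests=("linear", "brown_forsythe", "dglm"),
          dglm_loci=causal)
labels = {100: "mean-only", 1000: "variance-only", 1900: "combined"}
for idx, label in labels.items():
    lid = gm.locus_ids[idx]
    sub = df[df.locus_id == lid]
    print(f"{label:13s} locus {lid}:")
    for _, row in sub.iterrows():
        print(f"   {row.test:15s} -log10 p = {-row.log10_p:7.2f}")
print("-> each detector flags exactly the signal type it models; the "
      "2-df DGLM joint test pools both signals at the combined locus.")
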