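"""Replicable study designs built on the simulator.

Four families, mirroring the validation studies the simulator is meant to
support:

* :func:`effect_share_replicates` — simulate a small architecture many times
  and recover the per-locus variance shares by moment-based decomposition.
* :func:`detection_experiment` — three causal loci (mean-only, variance-only,
  combined) on three chromosomes, scanned with the linear, Brown-Forsythe
  and DGLM tests.
* :func:`ld_contrast_experiment` — two variance loci under low- versus
  high-LD genotypes.
* :func:`clustered_variance_experiment` — three small variance loci packed
  into one high-LD block versus one isolated locus of the same size.

Default problem sizes are deliberately modest (thousands of samples, a few
thousand loci) — the phenomena of interest here are qualitative detection
patterns, which are already stable at these scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import brown_forsythe, dglm_association, linear_association, scan
from .genotypes import generate_hwe, generate_ld_blocks
from .model import EffectSizes, Mode, empirical_decomposition
from .pipeline import simulate_study
from .selection import LocusCriteria, select_loci

__all__ = [
    "effect_share_replicates",
    "detection_experiment",
    "ld_contrast_experiment",
    "clustered_variance_experiment",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def effect_share_replicates(
    mode: Mode | str,
    c_mu,
    c_v,
    maf,
    n_samples: int = 2000,
    n_replicates: int = 50,
    seed: int = 0,
    v_y: float = 1.0,
    mu: float = 0.0,
) -> pd.DataFrame:
    """Simulate ``n_replicates`` fresh cohorts and recover variance shares.

    Each replicate draws new Hardy-Weinberg genotypes at the given MAF(s),
    simulates phenotypes for the configured effects, and estimates each
    causal locus's mean-shift and variance-shift share of Var(Y) from
    genotype-group moments.  Returns one row per (replicate, locus) with
    estimated shares plus the replicate's overall sample mean and variance.
    """
    mode = Mode(mode)
    effects = EffectSizes(c_mu, c_v)
    maf = np.broadcast_to(np.atleast_1d(np.asarray(maf, float)),
                          (effects.n_loci,))
    ploidy = 1 if mode is Mode.HAPLOID else 2
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_replicates)):
        gm = generate_hwe(n_samples, maf, ploidy=ploidy, seed=int(s))
        res = simulate_study(gm, range(effects.n_loci), effects, mode,
                             seed=int(s) + 1, mu=mu, v_y=v_y)
        noncarrier = res.causal_doses.sum(axis=1) == 0
        for i in range(effects.n_loci):
            dec = empirical_decomposition(res.y, res.causal_doses[:, i])
            vy_hat = res.y.var(ddof=1)
            rows.append({
                "replicate": rep,
                "locus": i,
                "v_m_share": float(dec.v_m[0] / vy_hat),
                "v_v_share": float(dec.v_v[0] / vy_hat),
                "sample_mean": float(res.y.mean()),
                "sample_var": float(vy_hat),
                # mean of the all-zero-dose group estimates the baseline mu
                "baseline_mean": float(res.y[noncarrier].mean()),
                "n_noncarrier": int(noncarrier.sum()),
            })
    return pd.DataFrame(rows)


def detection_experiment(
    seed: int,
    n_samples: int = 2000,
    n_loci_per_chrom: int = 5000,
    maf_window: tuple = (0.2, 0.5),
) -> dict:
    """Three-chromosome recovery study under co-dominant diploid inheritance.

    One causal locus per chromosome: a 5% mean-effect locus, a 5%
    variance-effect locus, and a 6% locus split equally between mean and
    variance.  A single phenotype carries all three.  Each chromosome is
    scanned with the linear and Brown-Forsythe tests; the DGLM is evaluated
    at the causal loci.

    Returns per-chromosome scan frames plus a summary: the causal locus's
    rank under each test on its own chromosome and the three tests'
    log10 p at each causal locus.
    """
    ss = _child_seeds(seed, 7)
    chroms = []
    causal = []
    for c in range(3):
        gm = generate_hwe(
            n_samples,
            np.random.default_rng(int(ss[c])).uniform(0.05, 0.5,
                                                      n_loci_per_chrom),
            ploidy=2, seed=int(ss[c]) + 1,
        )
        idx = select_loci(gm, LocusCriteria(
            n_loci=1, maf_min=maf_window[0], maf_max=maf_window[1],
            seed=int(ss[c]) + 2,
        ))[0]
        chroms.append(gm)
        causal.append(idx)

    effects = EffectSizes(c_mu=[0.05, 0.0, 0.03], c_v=[0.0, 0.05, 0.03])
    doses = np.column_stack([chroms[c].doses[:, causal[c]] for c in range(3)])
    # stitch the three causal columns into one matrix to share a phenotype
    from .genotypes import GenotypeMatrix

    stitched = GenotypeMatrix(
        doses=doses, positions=np.arange(3, dtype=float), ploidy=2,
        locus_ids=[f"chr{c + 1}_causal" for c in range(3)],
    )
    res = simulate_study(stitched, [0, 1, 2], effects,
                         Mode.DIPLOID_CODOMINANT, seed=int(ss[3]))

    scans, summary = [], {}
    for c, gm in enumerate(chroms):
        df = scan(gm, res.y, tests=("linear", "brown_forsythe"))
        df["chrom"] = c + 1
        scans.append(df)
        cid = gm.locus_ids[causal[c]]
        for test in ("linear", "brown_forsythe"):
            sub = df[df.test == test].reset_index(drop=True)
            ranks = sub.log10_p.rank(method="min")
            at = sub.index[sub.locus_id == cid][0]
            summary[f"chr{c + 1}_{test}_rank"] = int(ranks.iloc[at])
            summary[f"chr{c + 1}_{test}_log10p"] = float(sub.log10_p.iloc[at])
        col = gm.doses[:, causal[c]]
        for r in dglm_association(res.y, col, locus_id=cid):
            summary[f"chr{c + 1}_{r.test_name}_log10p"] = r.log10_p
    return {"scans": pd.concat(scans, ignore_index=True),
            "summary": summary, "causal": causal,
            "metadata": res.metadata}


def _variance_loci_min_bf(gm, causal_idx, c_v_each, seed, window=None):
    """Simulate variance-only loci and return min BF log10 p over a window."""
    effects = EffectSizes(
        c_mu=np.zeros(len(causal_idx)), c_v=np.full(len(causal_idx), c_v_each)
    )
    res = simulate_study(gm, causal_idx, effects, Mode.HAPLOID, seed=seed)
    idx = range(gm.n_loci) if window is None else window
    best = 0.0
    for j in idx:
        col = gm.doses[:, j]
        if np.ptp(col) == 0:
            continue
        best = min(best, brown_forsythe(res.y, col).log10_p)
    return best, res


def ld_contrast_experiment(
    seed: int,
    n_samples: int = 2000,
    n_loci: int = 2000,
    block_size: int = 20,
    low_r2: float = 0.05,
    high_r2: float = 0.8,
    c_v_each: float = 0.07,
) -> pd.DataFrame:
    """Two variance loci scanned under low- versus high-LD genotypes.

    In each regime, two 7% variance-effect loci are placed in different
    blocks and the whole segment is scanned with the Brown-Forsythe test.
    High LD disperses the signal onto non-causal block-mates; low LD
    confines it.  Returns the concatenated scan frames tagged by regime.
    """
    ss = _child_seeds(seed, 4)
    out = []
    for regime, r2, s0, s1 in (("low", low_r2, ss[0], ss[1]),
                               ("high", high_r2, ss[2], ss[3])):
        gm = generate_ld_blocks(n_samples, n_loci, block_size, r2,
                                seed=int(s0), maf=0.3)
        # one causal locus in the middle of each of two well-separated blocks
        causal = [block_size // 2, n_loci // 2 + block_size // 2]
        effects = EffectSizes(c_mu=[0.0, 0.0], c_v=[c_v_each, c_v_each])
        res = simulate_study(gm, causal, effects, Mode.HAPLOID, seed=int(s1))
        df = scan(gm, res.y, tests=("brown_forsythe",))
        df["regime"] = regime
        df["causal"] = df.locus_id.isin([gm.locus_ids[c] for c in causal])
        out.append(df)
    return pd.concat(out, ignore_index=True)


def clustered_variance_experiment(
    seed: int,
    n_samples: int = 2000,
    n_loci: int = 400,
    block_size: int = 10,
    within_block_r2: float = 0.8,
    c_v_each: float = 0.03,
) -> dict:
    """Three clustered 3% variance loci versus one isolated 3% locus.

    Segment A packs three variance-effect loci into a single high-LD block
    (emulating variants of the same gene); segment B carries one such locus
    in an otherwise identical genome.  Both segments are scanned with the
    Brown-Forsythe test over the causal block.  LD pools the variance
    contributions of clustered loci, so the cluster's minimum p is far
    smaller than the single locus's.

    Returns {"log10p_cluster", "log10p_single", ...} (log10 of the minimum
    Brown-Forsythe p over the causal block in each segment).
    """
    ss = _child_seeds(seed, 4)
    gm_a = generate_ld_blocks(n_samples, n_loci, block_size, within_block_r2,
                              seed=int(ss[0]), maf=0.3)
    block0 = list(range(block_size))
    causal_a = [2, block_size // 2, block_size - 3]  # inside the first block
    min_a, res_a = _variance_loci_min_bf(gm_a, causal_a, c_v_each,
                                         int(ss[1]), window=block0)

    gm_b = generate_ld_blocks(n_samples, n_loci, block_size, within_block_r2,
                              seed=int(ss[2]), maf=0.3)
    min_b, res_b = _variance_loci_min_bf(gm_b, [block_size // 2], c_v_each,
                                         int(ss[3]), window=block0)
    return {
        "log10p_cluster": min_a,
        "log10p_single": min_b,
        "realized_variance_cluster": res_a.metadata["realized_variance"],
        "realized_variance_single": res_b.metadata["realized_variance"],
    }
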