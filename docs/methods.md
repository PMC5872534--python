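# Methods

## The phenotype model

Each sample's quantitative trait is conditionally Gaussian given its
genotype at the causal loci:

    y = μ + gᵀα + ε,   ε ~ N(0, (σ + gᵀφ)²)

`g` is the vector of minor-allele doses, `α` the per-dose mean shift, `φ`
the per-dose standard-deviation shift, `σ` the baseline residual SD shared
by all loci, `μ` the baseline mean. The law of total variance splits
Var(Y) into Var(E[Y|G]) + Var(SD(Y|G)) + E[SD(Y|G)]², giving per-locus
mean-shift and variance-shift components

    V_M = k p q α²,   V_V = k p q φ²,   V_R = (σ + k qᵀφ)²

with k = 1 for Bernoulli(q) doses (haploid, or the collapsed complete-
dominance indicator) and k = 2 for Binomial(2, q) Hardy–Weinberg doses.
Users specify effect sizes as variance fractions C_μ = V_M/V_Y and
C_V = V_V/V_Y; the solver inverts them in closed form (non-negative roots):

    α = √(C_μ V_Y / k p q),  φ = √(C_V V_Y / k p q),
    σ = √(V_Y (1 − Σᵢ(C_μ⁽ⁱ⁾ + C_V⁽ⁱ⁾))) − k qᵀφ

### Assumptions and their consequences

* **Additivity across loci.** Multi-locus effects combine linearly in both
  the mean and the SD; epistasis and other nonlinear interactions are out of
  scope.
* **Independent causal loci.** The shared-σ expression assumes uncorrelated
  doses. When causal loci are in LD the realized Var(Y) exceeds (positive
  correlation) or falls below the configured V_Y. No analytic correction
  exists in this framework; the simulator instead records the pairwise dose
  correlations of causal loci and the realized variance in the run metadata
  and logs a notice when |r| > 0.05. The LD scenarios exploit exactly this
  property (clustered variance loci pool their shifts).
* **Feasibility.** σ ≥ 0 requires √(1 − ΣC) ≥ k qᵀφ; large C_V at high q is
  not representable. The solver fails fast with the single-locus bound
  C_V ≤ (1 − C_μ)/(1 + k q/p) in the message rather than clamping — clamping
  would silently distort V_Y. With optional negative φ signs (variance-
  *decreasing* minor alleles, off by default) the constraint tightens to
  keeping every attainable genotype group's SD positive.

### Dominance modes

* *Haploid*: dose 0/1, frequency q.
* *Co-dominant diploid*: dose 0/1/2, Hardy–Weinberg frequencies, k = 2; a
  mean-only locus yields three equidistant group means (0, α, 2α).
* *Complete dominance*: the major allele masks the minor, so only minor-
  allele homozygotes (frequency q_allele²) shift; the haploid formulas apply
  to the 0/1 recessive indicator with q = q_allele². (Descriptions of which
  formula serves which mode vary in the vGWAS simulation literature; this
  assignment is the one consistent with the genotype-class frequency/mean/SD
  tables, and is the one implemented.)

### Parameters that matter

| parameter | units | default | notes |
|---|---|---|---|
| `c_mu`, `c_v` | fraction of V_Y | — | per causal locus; Σ ≤ 1 |
| `v_y` | trait units² | 1.0 | total variance target |
| `mu` | trait units | 0.0 | baseline mean |
| `q` | frequency | estimated from genotypes | per-locus; estimation (default) makes the realized decomposition match the drawn cohort, theoretical q shifts realized effect sizes by the sampling error of the frequency |
| `seed` | — | required | all draws flow through `numpy.random.default_rng(seed)`; identical seed + config is bit-reproducible |

## Moment-based decomposition (the recovery oracle)

`empirical_decomposition` estimates α̂ and φ̂ as count-weighted straight-line
fits of the genotype-group sample means and SDs on dose level (plain group
differences for two groups), reads q̂ off the dose column, and plugs into
the analytic forms. It is deliberately independent of the simulation path
(no likelihood, no model fit) so it can serve as an oracle for the solver.
Two caveats are inherent to the estimator: (i) Ê[α̂²] = α² + Var(α̂)
inflates small shares by O(1/(n k p q)); (ii) with several variance loci,
the per-locus group SDs marginalize over the other loci, and because the SD
of a scale mixture is less than the mean of its component SDs, per-locus
shares are attenuated (measurably ≈0.5 pp for two 7% loci; negligible for
three 3% loci). Both effects are properties of the measurement, not the
generator, and are left uncorrected.

## Synthetic genotypes

`generate_hwe` draws doses i.i.d. Binomial(ploidy, maf) — ideal
Hardy–Weinberg populations with exactly controlled frequencies.
`generate_ld_blocks` adds LD through haplotype copying: within a block,
each haplotype's allele at locus j equals its allele at locus j−1 with
probability ρ = √r², otherwise a fresh Bernoulli(q) draw. This preserves
marginal frequencies (blocks share one q when frequencies are auto-drawn)
and yields adjacent-locus dose correlation ρ decaying geometrically with
distance; blocks are mutually independent. The scheme is chosen because the
LD studies only need a "low" versus "high" LD contrast — it makes no claim
to a calibrated recombination map, coalescent genealogy, demography or
mutation model, and positions are simply uniform over a configurable
segment (default 25 Mb). Real genomes add rare variants, frequency spectra,
haplotype structure and population stratification that these generators do
not emulate — passing tests demonstrate correctness of the phenotype
machinery and the qualitative detection patterns, not realism of any
particular genome. Genotypes from coalescent simulators (Hudson `ms` text)
or real data (VCF) can be substituted via `vgwas_sim.io`.

## Association tests

* **Linear**: OLS of y on dose; t statistic on n−2 df. Equivalent to the
  standard GWAS regression test.
* **Brown–Forsythe**: one-way ANOVA F on absolute deviations from
  genotype-group medians, referred to F(k−1, n−k) — the textbook reference
  distribution (some descriptions cite a chi-square reference; the two are
  asymptotically equivalent at GWAS sample sizes). Groups are the observed
  dose levels; each needs ≥ 2 members.
* **DGLM**: alternating estimation — WLS of y on dose with weights 1/σ̂ᵢ²,
  then a log-link gamma GLM of leverage-deflated squared residuals
  dᵢ = rᵢ²/(1−hᵢ) on dose — iterated until the relative change of the
  heteroscedastic Gaussian log-likelihood is < 1e-8 (max 100 iterations;
  non-convergence warns and reports the last iterate). The gamma dispersion
  is fixed at 2, exact for χ²₁-distributed squared Gaussian residuals, which
  keeps the dispersion Wald test calibrated. Reported p-values: Wald for
  the mean coefficient, Wald for the dispersion coefficient, and a 2-df
  likelihood-ratio test of the full model against the homoscedastic
  no-effect null. The joint LRT is our choice for "combined" detection —
  the natural 2-df pooling of both signals; mean-only and dispersion-only
  p-values are always reported alongside so any other combination rule can
  be applied downstream.

P-values are additionally carried as log10(p) computed from log survival
functions, so genome-wide comparisons survive double-precision underflow.
Genome scans run as vectorized passes (numerically identical to the
per-locus functions, verified in tests) with per-locus failures flagged in
the output rather than aborting; the DGLM, being iterative, is restricted
to a configurable subset of loci.

## Numerical and design choices

* Non-negative roots for α, φ by default; per-locus sign flags expose
  direction of effect (the C's are sign-invariant).
* Allele frequencies default to matrix estimates, folded MAF for selection
  eligibility; monomorphic loci are kept in matrices but excluded from
  causal eligibility and flagged in scans.
* Causal-locus search samples uniformly among eligible loci under the run
  seed (not "first match"), so repeated experiments explore different
  architectures; over-constrained criteria raise with the eligible count
  rather than relaxing bounds.
* Diploid individuals from phased haplotype input are formed by summing
  consecutive haplotype pairs (ms convention).
* Missing VCF genotypes are mean-imputed with a logged count (option to
  refuse); multi-allelic records are skipped with a warning.
* Ties in ms positions are nudged by one ulp to keep coordinates strictly
  increasing.
* p-values that underflow to 0 are clamped to the smallest positive double;
  log10_p carries the true magnitude.

## Validation studies and problem sizes

The packaged experiments run at deliberately modest scale — 2,000–5,000
samples, up to 5,000 loci per chromosome, 20–50 replicates — chosen because
every claim they check (share recovery within 1 pp, detection ranks, LD
pooling) is already stable there; the same designs scale up via function
arguments (`--full-scale` in the CLI reproduction command). The acceptance
script reports recovered variance shares in percent, averaged over 50
fresh replicates per configuration.

## Known limitations

Linear additive effects only (no epistasis, no GxE terms beyond the implied
variance heterogeneity); quantitative traits only (no case/control
thresholding); no population structure or covariates in either the
generator or the tests; the LD generator is a qualitative instrument, not a
population-genetic model; per-locus moment recovery is biased in the ways
described above.
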