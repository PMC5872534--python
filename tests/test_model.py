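"""Closed-form solver, phenotype draws and variance decompositions."""

import numpy as np
import pytest
from scipy import stats

from vgwas_sim import (
    EffectSizes,
    InfeasibleModelError,
    Mode,
    analytic_decomposition,
    empirical_decomposition,
    simulate_phenotypes,
    solve_diploid_codominant,
    solve_diploid_complete_dominance,
    solve_effects,
    solve_haploid,
    solve_multilocus,
)


class TestSingleLocusSolvers:
    # expected values frozen from direct evaluation of the closed forms
    @pytest.mark.parametrize(
        "solver,c_mu,c_v,v_y,q,alpha,phi,sigma",
        [
            (solve_haploid, 0.05, 0.0, 1.0, 0.5, 0.4472135955, 0.0, 0.9746794345),
            (solve_haploid, 0.0, 0.0, 1.0, 0.3, 0.0, 0.0, 1.0),
            (solve_diploid_codominant, 0.05, 0.0, 1.0, 0.5,
             0.3162277660, 0.0, 0.9746794345),
            (solve_diploid_codominant, 0.0, 0.0, 2.0, 0.1,
             0.0, 0.0, 1.4142135624),
            (solve_diploid_codominant, 0.03, 0.03, 1.0, 0.2,
             0.3061862178, 0.3061862178, 0.8470614843),
            (solve_diploid_complete_dominance, 0.05, 0.0, 1.0, 0.5,
             0.5163977795, 0.0, 0.9746794345),
            (solve_diploid_complete_dominance, 0.0, 0.0, 1.0, 0.37,
             0.0, 0.0, 1.0),
        ],
    )
    def test_closed_forms(self, solver, c_mu, c_v, v_y, q, alpha, phi, sigma):
        p = solver(EffectSizes(c_mu, c_v), v_y, q)
        assert p.alpha[0] == pytest.approx(alpha, abs=1e-9)
        assert p.phi[0] == pytest.approx(phi, abs=1e-9)
        assert p.sigma == pytest.approx(sigma, abs=1e-9)

    def test_complete_dominance_squares_the_allele_frequency(self):
        p = solve_diploid_complete_dominance(EffectSizes(0.05, 0.0), 1.0, 0.5)
        assert p.q[0] == pytest.approx(0.25)
        # recessive homozygotes in a large Hardy-Weinberg cohort: ~q_allele^2
        from vgwas_sim import generate_hwe, recessive_indicator

        gm = generate_hwe(100_000, [0.3], ploidy=2, seed=11)
        frac = recessive_indicator(gm.doses).mean()
        assert frac == pytest.approx(0.09, abs=3 * np.sqrt(0.09 * 0.91 / 1e5))

    def test_defining_identities_hold(self):
        for mode, k in ((Mode.HAPLOID, 1), (Mode.DIPLOID_CODOMINANT, 2)):
            e = EffectSizes(0.04, 0.07)
            q = 0.23
            p = solve_effects(e, 1.7, q, mode)
            assert k * (1 - q) * q * p.alpha[0] ** 2 == pytest.approx(0.04 * 1.7)
            assert k * (1 - q) * q * p.phi[0] ** 2 == pytest.approx(0.07 * 1.7)
            assert (p.sigma + k * q * p.phi[0]) ** 2 == pytest.approx(
                (1 - 0.11) * 1.7
            )


class TestFeasibilityAndDomain:
    def test_large_variance_effect_at_high_frequency_is_infeasible(self):
        # phi = sqrt(0.3/0.09) ~ 1.826, q*phi ~ 1.643 > sqrt(0.7) ~ 0.837
        with pytest.raises(InfeasibleModelError, match="maximum feasible"):
            solve_haploid(EffectSizes(0.0, 0.3), 1.0, 0.9)

    def test_three_strong_variance_loci_are_jointly_infeasible(self):
        with pytest.raises(InfeasibleModelError):
            solve_multilocus(
                EffectSizes([0, 0, 0], [0.3, 0.3, 0.3]), 1.0,
                [0.5, 0.5, 0.5], Mode.HAPLOID,
            )

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.3])
    def test_frequency_domain(self, q):
        with pytest.raises(ValueError):
            solve_haploid(EffectSizes(0.05, 0.0), 1.0, q)

    def test_effect_size_invariants(self):
        with pytest.raises(ValueError):
            EffectSizes(-0.01, 0.0)
        with pytest.raises(ValueError):
            EffectSizes([0.5, 0.4], [0.2, 0.0])  # sums to 1.1
        with pytest.raises(ValueError):
            EffectSizes([0.1, 0.1], [0.1])  # length mismatch

    def test_non_positive_total_variance(self):
        with pytest.raises(ValueError):
            solve_haploid(EffectSizes(0.05, 0.0), 0.0, 0.3)

    def test_length_mismatch_between_effects_and_frequencies(self):
        with pytest.raises(ValueError, match="frequencies"):
            solve_multilocus(EffectSizes([0.01, 0.01], [0, 0]), 1.0,
                             [0.3], Mode.HAPLOID)

    def test_negative_phi_sign_flag_tightens_feasibility(self):
        # phi sign flags allow variance-decreasing minor alleles, but the
        # minor-homozygote SD must stay positive
        ok = solve_diploid_codominant(EffectSizes(0.0, 0.02), 1.0, 0.3,
                                      sign_phi=[-1])
        assert ok.phi[0] < 0
        with pytest.raises(InfeasibleModelError):
            solve_diploid_codominant(EffectSizes(0.0, 0.3), 1.0, 0.4,
                                     sign_phi=[-1])


class TestMultilocus:
    def test_reduces_to_single_locus_at_n1(self):
        e = EffectSizes(0.02, 0.06)
        for mode, single in ((Mode.HAPLOID, solve_haploid),
                             (Mode.DIPLOID_CODOMINANT, solve_diploid_codominant)):
            multi = solve_multilocus(e, 1.3, [0.17], mode)
            one = single(e, 1.3, 0.17)
            assert multi.alpha[0] == pytest.approx(one.alpha[0], rel=1e-12)
            assert multi.phi[0] == pytest.approx(one.phi[0], rel=1e-12)
            assert multi.sigma == pytest.approx(one.sigma, rel=1e-12)

    def test_two_variance_loci_closed_form(self):
        # phi_i = sqrt(0.07/0.25) each; sigma = sqrt(0.86) - (0.5+0.5) phi
        p = solve_multilocus(EffectSizes([0, 0], [0.07, 0.07]), 1.0,
                             [0.5, 0.5], Mode.HAPLOID)
        assert p.phi == pytest.approx([0.5291502622, 0.5291502622], abs=1e-9)
        assert p.sigma == pytest.approx(0.3982115873, abs=1e-9)

    def test_decomposition_sums_to_v_y_with_independent_loci(self):
        e = EffectSizes([0.02, 0.0, 0.01], [0.0, 0.05, 0.03])
        p = solve_multilocus(e, 2.5, [0.1, 0.3, 0.45], Mode.DIPLOID_CODOMINANT)
        d = analytic_decomposition(p)
        assert d.v_y == pytest.approx(2.5, rel=1e-12)
        assert d.v_m == pytest.approx(e.c_mu * 2.5, rel=1e-9)
        assert d.v_v == pytest.approx(e.c_v * 2.5, rel=1e-9)


class TestSimulatePhenotypes:
    def test_group_moments_match_the_model(self):
        # carriers and non-carriers should sit at (mu, mu+alpha) with SDs
        # (sigma, sigma+phi), each within 3 standard errors
        n = 400_000
        params = solve_haploid(EffectSizes(0.05, 0.05), 1.0, 0.5, mu=1.0)
        rng = np.random.default_rng(5)
        doses = rng.binomial(1, 0.5, n)
        y = simulate_phenotypes(doses, params, rng_seed=6)
        for dose in (0, 1):
            grp = y[doses == dose]
            m_exp = 1.0 + dose * params.alpha[0]
            s_exp = params.sigma + dose * params.phi[0]
            se_m = s_exp / np.sqrt(grp.size)
            se_s = s_exp / np.sqrt(2 * grp.size)
            assert abs(grp.mean() - m_exp) < 3 * se_m
            assert abs(grp.std(ddof=1) - s_exp) < 3 * se_s

    def test_total_variance_conservation_all_modes(self):
        n = 300_000
        for mode in Mode:
            e = EffectSizes([0.03, 0.02], [0.04, 0.0])
            q = np.array([0.3, 0.4])
            params = solve_effects(e, 1.0, q, mode)
            rng = np.random.default_rng(7)
            doses = rng.binomial(1 if mode is not Mode.DIPLOID_CODOMINANT else 2,
                                 params.q, size=(n, 2))
            y = simulate_phenotypes(doses, params, rng_seed=8)
            se = np.sqrt(2.0 / n)  # MC error of a unit-variance estimate
            assert abs(y.var(ddof=1) - 1.0) < 3 * se * 1.0

    def test_codominant_mean_only_gives_three_equidistant_levels(self):
        params = solve_diploid_codominant(EffectSizes(0.08, 0.0), 1.0, 0.4)
        rng = np.random.default_rng(9)
        doses = rng.binomial(2, 0.4, 100_000)
        y = simulate_phenotypes(doses, params, rng_seed=10)
        means = [y[doses == d].mean() for d in (0, 1, 2)]
        gaps = np.diff(means)
        assert gaps == pytest.approx([params.alpha[0]] * 2, abs=0.02)

    def test_no_carriers_degenerates_to_baseline_noise(self):
        params = solve_haploid(EffectSizes(0.05, 0.05), 1.0, 0.5)
        y = simulate_phenotypes(np.zeros(200_000, dtype=int), params, 12)
        assert abs(y.mean()) < 3 * params.sigma / np.sqrt(y.size)
        assert y.std(ddof=1) == pytest.approx(params.sigma, rel=0.01)

    def test_seed_determinism_is_bit_exact(self):
        params = solve_haploid(EffectSizes(0.02, 0.02), 1.0, 0.25)
        doses = np.random.default_rng(1).binomial(1, 0.25, 1000)
        a = simulate_phenotypes(doses, params, rng_seed=42)
        b = simulate_phenotypes(doses, params, rng_seed=42)
        c = simulate_phenotypes(doses, params, rng_seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_dose_encoding_must_match_mode(self):
        params = solve_haploid(EffectSizes(0.02, 0.0), 1.0, 0.3)
        with pytest.raises(ValueError, match="out of range"):
            simulate_phenotypes(np.array([0, 1, 2]), params, 1)

    def test_mode_consistency_halved_alpha_on_doubled_doses(self):
        # a co-dominant population of only 0/2 doses with alpha and phi
        # halved draws the identical phenotypes as the haploid model
        from vgwas_sim.model import PhenotypeModelParams

        hap = solve_haploid(EffectSizes(0.05, 0.03), 1.0, 0.3)
        dip = PhenotypeModelParams(
            mu=hap.mu, v_y=hap.v_y, alpha=hap.alpha / 2, phi=hap.phi / 2,
            sigma=hap.sigma, q=hap.q, mode=Mode.DIPLOID_CODOMINANT,
        )
        doses = np.random.default_rng(3).binomial(1, 0.3, 5000)
        y_h = simulate_phenotypes(doses, hap, 77)
        y_d = simulate_phenotypes(2 * doses, dip, 77)
        assert np.array_equal(y_h, y_d)

    def test_conditional_normality_within_genotype_groups(self):
        # phenotypes are Gaussian given genotype: Shapiro-Wilk at alpha=0.01
        # should reject in at most ~1% of (seed, group) cases
        params = solve_haploid(EffectSizes(0.04, 0.04), 1.0, 0.4)
        rejections = trials = 0
        for seed in range(40):
            doses = np.random.default_rng(seed).binomial(1, 0.4, 600)
            y = simulate_phenotypes(doses, params, rng_seed=1000 + seed)
            for d in (0, 1):
                trials += 1
                if stats.shapiro(y[doses == d]).pvalue < 0.01:
                    rejections += 1
        assert rejections / trials <= 0.05


class TestEmpiricalDecomposition:
    def test_constant_phenotype_returns_zero_components(self):
        d = empirical_decomposition(np.ones(50), np.r_[np.zeros(25), np.ones(25)])
        assert d.v_m[0] == d.v_v[0] == d.v_r == 0.0

    def test_null_phenotype_has_vanishing_genetic_shares(self):
        rng = np.random.default_rng(21)
        doses = rng.binomial(1, 0.3, 100_000)
        y = rng.standard_normal(100_000)
        d = empirical_decomposition(y, doses)
        c_mu_hat, c_v_hat = d.shares()
        assert c_mu_hat[0] < 1e-3
        assert c_v_hat[0] < 1e-3
        assert d.v_r == pytest.approx(1.0, rel=0.01)

    def test_recovers_configured_shares_in_expectation(self):
        from vgwas_sim.experiments import effect_share_replicates

        df = effect_share_replicates("haploid", [0.05], [0.0], maf=0.3,
                                     n_samples=2000, n_replicates=25, seed=4)
        assert df.v_m_share.mean() == pytest.approx(0.05, abs=0.01)

    def test_matches_analytic_decomposition_at_large_n(self):
        params = solve_diploid_codominant(EffectSizes(0.05, 0.05), 1.0, 0.3)
        rng = np.random.default_rng(31)
        doses = rng.binomial(2, 0.3, 500_000)
        y = simulate_phenotypes(doses, params, 32)
        emp = empirical_decomposition(y, doses)
        ana = analytic_decomposition(params)
        assert emp.v_m[0] == pytest.approx(ana.v_m[0], abs=0.01)
        assert emp.v_v[0] == pytest.approx(ana.v_v[0], abs=0.01)
        assert emp.v_r == pytest.approx(ana.v_r, abs=0.02)

    def test_degenerate_groups_raise(self):
        y = np.arange(5.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            empirical_decomposition(y, np.array([0, 0, 0, 0, 1]))
        with pytest.raises(ValueError, match="monomorphic"):
            empirical_decomposition(y, np.zeros(5, dtype=int))
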