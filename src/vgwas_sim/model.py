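"""Heteroscedastic phenotype model for variance-heterogeneity GWAS simulation.

The quantitative trait of sample *s* is drawn as

    y_s = mu + g_s' alpha + eps_s,     eps_s ~ Normal(0, (sigma + g_s' phi)^2)

where ``g_s`` is the minor-allele dose vector at the causal loci, ``alpha``
shifts the conditional mean per dose unit and ``phi`` shifts the conditional
standard deviation per dose unit.  The user specifies, per causal locus, the
fraction of the total phenotypic variance ``v_y`` contributed by the mean
shift (``c_mu``) and by the variance shift (``c_v``); the solvers in this
module invert those fractions into (alpha, phi, sigma) in closed form for
haploid doses (0/1), co-dominant diploid doses (0/1/2) and complete-dominance
diploid genotypes (collapsed to a 0/1 recessive-homozygote indicator whose
carrier frequency is the squared minor-allele frequency).

The decomposition underlying the inversion is

    V(Y) = V_M + V_V + V_R
    V_M = k p q alpha^2          (variance of the conditional mean)
    V_V = k p q phi^2            (variance of the conditional SD)
    V_R = (sigma + k q phi)^2    (squared mean conditional SD)

with ``k = 1`` for 0/1 doses and ``k = 2`` for Hardy-Weinberg 0/1/2 doses.
Setting V_M = c_mu v_y and V_V = c_v v_y and solving gives the closed forms
implemented by :func:`solve_effects`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mode",
    "EffectSizes",
    "PhenotypeModelParams",
    "VarianceDecomposition",
    "InfeasibleModelError",
    "solve_haploid",
    "solve_diploid_codominant",
    "solve_diploid_complete_dominance",
    "solve_multilocus",
    "solve_effects",
    "simulate_phenotypes",
    "analytic_decomposition",
    "empirical_decomposition",
    "recessive_indicator",
    "max_feasible_c_v",
]


class Mode(str, enum.Enum):
    """Ploidy / dominance mode of the dose encoding."""

    HAPLOID = "haploid"
    DIPLOID_CODOMINANT = "diploid_codominant"
    DIPLOID_COMPLETE_DOMINANCE = "diploid_complete_dominance"

    @property
    def dose_factor(self) -> int:
        """k in V_M = k p q alpha^2: 2 for 0/1/2 doses, 1 for 0/1 doses."""
        return 2 if self is Mode.DIPLOID_CODOMINANT else 1

    @property
    def max_dose(self) -> int:
        return 2 if self is Mode.DIPLOID_CODOMINANT else 1


class InfeasibleModelError(ValueError):
    """Requested effect sizes cannot be represented (baseline SD would be < 0)."""


@dataclass(frozen=True)
class EffectSizes:
    """Per-locus variance fractions: mean-shift share ``c_mu`` and
    variance-shift share ``c_v`` of the total phenotypic variance.

    Scalars describe a single causal locus; equal-length vectors describe an
    additive multi-locus architecture.  Both fractions are dimensionless,
    non-negative, and must jointly leave non-negative residual variance:
    sum(c_mu) + sum(c_v) <= 1.
    """

    c_mu: np.ndarray
    c_v: np.ndarray

    def __init__(self, c_mu, c_v):
        c_mu = np.atleast_1d(np.asarray(c_mu, dtype=float))
        c_v = np.atleast_1d(np.asarray(c_v, dtype=float))
        if c_mu.shape != c_v.shape or c_mu.ndim != 1:
            raise ValueError(
                f"c_mu and c_v must be equal-length vectors, got shapes "
                f"{c_mu.shape} and {c_v.shape}"
            )
        if np.any(c_mu < 0) or np.any(c_v < 0):
            raise ValueError("effect sizes must be non-negative")
        total = c_mu.sum() + c_v.sum()
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"sum of effect sizes is {total:.6g} > 1; residual variance "
                "would be negative"
            )
        object.__setattr__(self, "c_mu", c_mu)
        object.__setattr__(self, "c_v", c_v)

    @property
    def n_loci(self) -> int:
        return self.c_mu.size

    @property
    def total(self) -> float:
        return float(self.c_mu.sum() + self.c_v.sum())


@dataclass(frozen=True)
class PhenotypeModelParams:
    """Solved parameters of the heteroscedastic phenotype model.

    ``alpha``/``phi`` are per-locus mean/SD shifts per minor-allele dose (in
    phenotype units), ``sigma`` the shared baseline residual SD, ``q`` the
    effective per-locus minor frequency used in the solution (for complete
    dominance this is the recessive-genotype frequency, i.e. the squared
    allele frequency).
    """

    mu: float
    v_y: float
    alpha: np.ndarray
    phi: np.ndarray
    sigma: float
    q: np.ndarray
    mode: Mode
    effects: EffectSizes = field(repr=False, default=None)

    @property
    def n_loci(self) -> int:
        return self.alpha.size

    def group_mean(self, dose) -> np.ndarray:
        """Conditional phenotype mean mu + g' alpha for dose vector(s)."""
        return self.mu + np.atleast_2d(dose) @ self.alpha

    def group_sd(self, dose) -> np.ndarray:
        """Conditional phenotype SD sigma + g' phi for dose vector(s)."""
        return self.sigma + np.atleast_2d(dose) @ self.phi


@dataclass(frozen=True)
class VarianceDecomposition:
    """Additive split of total phenotypic variance into mean-shift (v_m),
    variance-shift (v_v) and residual (v_r) components."""

    v_m: np.ndarray
    v_v: np.ndarray
    v_r: float

    @property
    def v_y(self) -> float:
        return float(np.sum(self.v_m) + np.sum(self.v_v) + self.v_r)

    def shares(self):
        """(c_mu_hat, c_v_hat) — components as fractions of their total."""
        vy = self.v_y
        if vy == 0:
            return np.zeros_like(np.atleast_1d(self.v_m)), np.zeros_like(
                np.atleast_1d(self.v_v)
            )
        return np.atleast_1d(self.v_m) / vy, np.atleast_1d(self.v_v) / vy


def _validate_q(q: np.ndarray) -> None:
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError(f"allele frequencies must lie strictly in (0, 1), got {q}")


def max_feasible_c_v(c_mu_total: float, q, mode: Mode = Mode.HAPLOID) -> float:
    """Largest total variance effect representable at frequency vector ``q``.

    Feasibility requires sigma >= 0, i.e.
    sqrt(1 - c_mu_total - c_v_total) >= k sum_i q_i sqrt(c_v_i / (k p_i q_i)).
    For a single locus this solves to
    c_v <= (1 - c_mu) / (1 + k q / p).
    For several loci the bound depends on how c_v is split; the single worst
    locus bound is reported as a guide.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    k = mode.dose_factor
    ratio = np.max(k * q / (1.0 - q))
    return float((1.0 - c_mu_total) / (1.0 + ratio))


def solve_effects(
    effects: EffectSizes,
    v_y: float,
    q,
    mode: Mode | str,
    mu: float = 0.0,
    sign_alpha=None,
    sign_phi=None,
) -> PhenotypeModelParams:
    """Invert variance-fraction effect sizes into model parameters.

    Parameters
    ----------
    effects
        Per-locus mean/variance variance fractions.
    v_y
        Total phenotypic variance (phenotype units squared), > 0.
    q
        Minor-allele frequency per causal locus.  Under complete dominance
        pass the *allele* frequency; it is squared internally to the
        recessive-genotype frequency.
    mode
        Dose encoding (haploid, co-dominant diploid, complete dominance).
    mu
        Baseline phenotype mean.
    sign_alpha, sign_phi
        Optional per-locus signs (+1/-1) for the direction of each shift.
        The closed forms are square roots, hence sign-invariant in the
        effect sizes; the non-negative root is the default.  A negative phi
        tightens the feasibility constraint (every attainable group SD must
        stay positive).

    Raises
    ------
    InfeasibleModelError
        If the implied baseline SD is negative, or any attainable genotype
        group would have non-positive SD.
    """
    mode = Mode(mode)
    if v_y <= 0:
        raise ValueError(f"v_y must be positive, got {v_y}")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if mode is Mode.DIPLOID_COMPLETE_DOMINANCE:
        # the trait is carried by the recessive homozygote only; its
        # Hardy-Weinberg frequency is the squared allele frequency
        q = q**2
    _validate_q(q)
    if q.size != effects.n_loci:
        raise ValueError(
            f"{effects.n_loci} effect pairs but {q.size} allele frequencies"
        )
    p = 1.0 - q
    k = mode.dose_factor

    alpha = np.sqrt(effects.c_mu * v_y / (k * p * q))
    phi = np.sqrt(effects.c_v * v_y / (k * p * q))
    if sign_alpha is not None:
        alpha = alpha * np.sign(np.atleast_1d(sign_alpha))
    if sign_phi is not None:
        phi = phi * np.sign(np.atleast_1d(sign_phi))

    sigma = float(np.sqrt(v_y * (1.0 - effects.total)) - k * (q @ phi))
    if sigma < 0:
        raise InfeasibleModelError(
            f"baseline SD is negative (sigma={sigma:.6g}) for c_mu="
            f"{effects.c_mu}, c_v={effects.c_v} at q={q} ({mode.value}); "
            f"the maximum feasible total variance effect at these "
            f"frequencies is about {max_feasible_c_v(float(effects.c_mu.sum()), q, mode):.4g}"
        )
    # every attainable dose combination must keep sigma + g'phi > 0
    min_sd = sigma + float(np.sum(np.minimum(phi, 0.0)) * mode.max_dose)
    if min_sd <= 0:
        raise InfeasibleModelError(
            f"a genotype group has non-positive SD ({min_sd:.6g}); "
            "negative phi signs are too large for this configuration"
        )
    return PhenotypeModelParams(
        mu=float(mu), v_y=float(v_y), alpha=alpha, phi=phi, sigma=sigma,
        q=q, mode=mode, effects=effects,
    )


def solve_haploid(effects: EffectSizes, v_y: float, q: float, mu: float = 0.0,
                  **kw) -> PhenotypeModelParams:
    """Single- or multi-locus solver for haploid 0/1 doses:
    alpha = sqrt(c_mu v_y / pq), phi = sqrt(c_v v_y / pq),
    sigma = sqrt(v_y (1 - c_mu - c_v)) - q phi."""
    return solve_effects(effects, v_y, q, Mode.HAPLOID, mu, **kw)


def solve_diploid_codominant(effects: EffectSizes, v_y: float, q: float,
                             mu: float = 0.0, **kw) -> PhenotypeModelParams:
    """Solver for additive 0/1/2 doses under Hardy-Weinberg:
    denominators 2pq, sigma = sqrt(v_y (1 - c_mu - c_v)) - 2 q phi."""
    return solve_effects(effects, v_y, q, Mode.DIPLOID_CODOMINANT, mu, **kw)


def solve_diploid_complete_dominance(effects: EffectSizes, v_y: float,
                                     q_allele: float, mu: float = 0.0,
                                     **kw) -> PhenotypeModelParams:
    """Solver for a fully dominant major allele: only the minor-allele
    homozygote (frequency q_allele^2) expresses the shifts, so the haploid
    closed forms apply with q = q_allele^2 and a 0/1 indicator dose."""
    return solve_effects(effects, v_y, q_allele,
                         Mode.DIPLOID_COMPLETE_DOMINANCE, mu, **kw)


def solve_multilocus(effects: EffectSizes, v_y: float, q, mode: Mode | str,
                     mu: float = 0.0, **kw) -> PhenotypeModelParams:
    """Additive multi-locus solver; reduces to the single-locus solvers at
    N=1.  sigma is shared: sqrt(v_y (1 - sum(c_mu + c_v))) - k q'phi."""
    return solve_effects(effects, v_y, q, mode, mu, **kw)


def recessive_indicator(doses: np.ndarray) -> np.ndarray:
    """Collapse 0/1/2 diploid doses to the 0/1 recessive-homozygote
    indicator used by the complete-dominance mode."""
    return (np.asarray(doses) == 2).astype(np.int8)


def simulate_phenotypes(doses: np.ndarray, params: PhenotypeModelParams,
                        rng_seed) -> np.ndarray:
    """Draw one phenotype per sample from the heteroscedastic model.

    ``doses`` is (n_samples, n_causal_loci) — or a 1-D vector for one locus —
    encoded to match ``params.mode``: 0/1 for haploid, 0/1/2 for co-dominant
    diploid, and the 0/1 recessive indicator (see :func:`recessive_indicator`)
    for complete dominance.  Deterministic for a fixed seed.
    """
    doses = np.asarray(doses)
    if doses.ndim == 1:
        doses = doses[:, None]
    if doses.shape[1] != params.n_loci:
        raise ValueError(
            f"dose matrix has {doses.shape[1]} loci, params solve {params.n_loci}"
        )
    if doses.min() < 0 or doses.max() > params.mode.max_dose:
        raise ValueError(
            f"doses out of range for mode {params.mode.value}: "
            f"[{doses.min()}, {doses.max()}]"
        )
    mean = params.mu + doses @ params.alpha
    sd = params.sigma + doses @ params.phi
    if np.any(sd <= 0):
        raise InfeasibleModelError(
            "a sample's conditional SD is non-positive; model infeasible for "
            "the observed dose combinations"
        )
    rng = np.random.default_rng(rng_seed)
    return mean + sd * rng.standard_normal(doses.shape[0])


def analytic_decomposition(params: PhenotypeModelParams) -> VarianceDecomposition:
    """Closed-form variance decomposition of solved parameters.

    Per locus: V_M = k p q alpha^2, V_V = k p q phi^2; shared residual
    V_R = (sigma + k q'phi)^2.  Under independent causal loci the components
    sum to v_y, round-tripping the solver.
    """
    k = params.mode.dose_factor
    p = 1.0 - params.q
    v_m = k * p * params.q * params.alpha**2
    v_v = k * p * params.q * params.phi**2
    v_r = (params.sigma + k * float(params.q @ params.phi)) ** 2
    return VarianceDecomposition(v_m=v_m, v_v=v_v, v_r=float(v_r))


def _group_moment_fit(y: np.ndarray, doses: np.ndarray):
    """Weighted straight-line fits of group means and group SDs on dose level.

    Returns (alpha_hat, mu_hat, phi_hat, sigma_hat, levels, counts).
    """
    levels, inverse = np.unique(doses, return_inverse=True)
    counts = np.bincount(inverse)
    if levels.size < 2:
        raise ValueError("dose column is monomorphic; group moments undefined")
    if np.any(counts < 2):
        lonely = levels[counts < 2]
        raise ValueError(
            f"genotype group(s) {lonely.tolist()} have fewer than 2 samples"
        )
    means = np.bincount(inverse, weights=y) / counts
    sq = np.bincount(inverse, weights=y**2) / counts
    sds = np.sqrt(np.maximum(sq - means**2, 0.0) * counts / (counts - 1))

    w = counts.astype(float)
    x = levels.astype(float)
    xbar = np.average(x, weights=w)
    sxx = np.sum(w * (x - xbar) ** 2)
    alpha_hat = float(np.sum(w * (x - xbar) * means) / sxx)
    mu_hat = float(np.average(means, weights=w) - alpha_hat * xbar)
    phi_hat = float(np.sum(w * (x - xbar) * sds) / sxx)
    sigma_hat = float(np.average(sds, weights=w) - phi_hat * xbar)
    return alpha_hat, mu_hat, phi_hat, sigma_hat, levels, counts


def empirical_decomposition(y: np.ndarray, doses: np.ndarray) -> VarianceDecomposition:
    """Moment-based estimate of the variance decomposition at one locus.

    The mean shift per dose (alpha_hat) and SD shift per dose (phi_hat) are
    count-weighted straight-line fits of the genotype-group sample means and
    SDs against dose level (for two groups these are plain differences); the
    frequency is read off the dose column.  Plugging the estimates into the
    analytic forms gives estimated components whose expectation matches
    :func:`analytic_decomposition` under the model; the reported v_r uses the
    fitted baseline SD and mean dose.

    A constant ``y`` returns the all-zero decomposition.
    """
    y = np.asarray(y, dtype=float)
    doses = np.asarray(doses)
    if doses.ndim != 1:
        raise ValueError("empirical_decomposition works on one dose column")
    if y.shape != doses.shape:
        raise ValueError("y and doses must have the same length")
    if np.ptp(y) == 0:
        return VarianceDecomposition(
            v_m=np.zeros(1), v_v=np.zeros(1), v_r=0.0
        )
    alpha_hat, _, phi_hat, sigma_hat, levels, counts = _group_moment_fit(y, doses)
    k = 2 if levels.max() > 1 else 1
    q_hat = float(doses.mean() / k)
    p_hat = 1.0 - q_hat
    v_m = k * p_hat * q_hat * alpha_hat**2
    v_v = k * p_hat * q_hat * phi_hat**2
    v_r = (sigma_hat + k * q_hat * phi_hat) ** 2
    return VarianceDecomposition(
        v_m=np.atleast_1d(v_m), v_v=np.atleast_1d(v_v), v_r=float(v_r)
    )
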