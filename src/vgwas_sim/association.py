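"""Association tests for mean and variance effects at a locus.

Three detectors:

* :func:`linear_association` — ordinary least-squares regression of the
  phenotype on minor-allele dose; detects mean shifts only.
* :func:`brown_forsythe` — Levene-type test on absolute deviations from
  genotype-group medians; detects variance (SD) shifts only.
* :func:`dglm_association` — double generalized linear model: a weighted
  linear mean submodel and a log-link gamma dispersion submodel fit by
  alternating estimation; yields Wald tests for each submodel coefficient
  and a 2-df joint likelihood-ratio test, detecting mean and variance
  effects simultaneously.

:func:`scan` applies any subset of the tests across all polymorphic loci of
a genotype matrix.  P-values are also reported as log10(p) computed via
log survival functions, so genome-wide comparisons remain meaningful after
double-precision underflow of p itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "DegenerateTestError",
    "linear_association",
    "brown_forsythe",
    "dglm_association",
    "scan",
]

LOG10 = np.log(10.0)


class DegenerateTestError(ValueError):
    """The test is undefined on this dose column (monomorphic or a genotype
    group too small)."""


@dataclass(frozen=True)
class AssociationResult:
    """One (locus, test) record."""

    locus_id: str
    test_name: str  # linear | brown_forsythe | dglm_mean | dglm_disp | dglm_joint
    statistic: float
    df: tuple
    p_value: float
    log10_p: float
    effect_estimate: float | None = None

    def __post_init__(self):
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            # p can underflow to exactly 0 in double precision; clamp to the
            # smallest positive normal so downstream -log10 stays finite via
            # log10_p, and the invariant p in (0, 1] holds
            object.__setattr__(self, "p_value", np.finfo(float).tiny)


def _check_polymorphic(doses: np.ndarray) -> None:
    if np.ptp(doses) == 0:
        raise DegenerateTestError("dose column is monomorphic")


def linear_association(y, doses, locus_id: str = "locus") -> AssociationResult:
    """OLS regression of phenotype on dose: slope, t statistic, two-sided p
    on n-2 degrees of freedom."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(doses, dtype=float)
    if y.size < 3:
        raise DegenerateTestError("need at least 3 samples")
    _check_polymorphic(g)
    n = y.size
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = gc @ gc
    slope = (gc @ yc) / sxx
    resid = yc - slope * gc
    s2 = (resid @ resid) / (n - 2)
    if s2 == 0:
        return AssociationResult(locus_id, "linear", np.inf, (n - 2,),
                                 np.finfo(float).tiny, -np.inf, slope)
    se = np.sqrt(s2 / sxx)
    t = slope / se
    logsf = stats.t.logsf(abs(t), n - 2) + np.log(2.0)
    return AssociationResult(
        locus_id, "linear", float(t), (n - 2,),
        float(min(np.exp(logsf), 1.0)), float(logsf / LOG10), float(slope),
    )


def brown_forsythe(y, doses, locus_id: str = "locus") -> AssociationResult:
    """Brown-Forsythe test: one-way ANOVA F on absolute deviations from the
    genotype-group medians, referred to F(k-1, n-k).

    Genotype groups are the observed dose levels (2 for haploid or dominant
    encodings, up to 3 for co-dominant diploids); every group needs at least
    2 members.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(doses)
    _check_polymorphic(g)
    levels, inverse = np.unique(g, return_inverse=True)
    counts = np.bincount(inverse)
    if np.any(counts < 2):
        raise DegenerateTestError(
            f"genotype group(s) {levels[counts < 2].tolist()} have < 2 members"
        )
    k = levels.size
    n = y.size
    medians = np.empty(k)
    for j in range(k):
        medians[j] = np.median(y[inverse == j])
    z = np.abs(y - medians[inverse])
    group_means = np.bincount(inverse, weights=z) / counts
    grand = z.mean()
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((z - group_means[inverse]) ** 2))
    if ss_within == 0:
        if ss_between == 0:
            return AssociationResult(locus_id, "brown_forsythe", 0.0,
                                     (k - 1, n - k), 1.0, 0.0, 0.0)
        return AssociationResult(locus_id, "brown_forsythe", np.inf,
                                 (k - 1, n - k), np.finfo(float).tiny,
                                 -np.inf, None)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    logsf = stats.f.logsf(f, k - 1, n - k)
    return AssociationResult(
        locus_id, "brown_forsythe", float(f), (k - 1, n - k),
        float(np.exp(logsf)) if np.exp(logsf) > 0 else np.finfo(float).tiny,
        float(logsf / LOG10), None,
    )


def _hetero_loglik(y, mean, var):
    return float(-0.5 * np.sum(np.log(2 * np.pi * var) + (y - mean) ** 2 / var))


def _dglm_fit(y, X, Xd, max_iter, tol):
    """Alternate WLS mean fit and log-link gamma dispersion fit.

    Returns (beta, se_beta, gamma, se_gamma, loglik, n_iter, converged).
    X is the mean design, Xd the dispersion design (both with intercept).
    """
    n = y.size
    var = np.full(n, max(y.var(), np.finfo(float).tiny))
    ll_old = -np.inf
    converged = False
    gamma_fit = None
    for it in range(1, max_iter + 1):
        w = 1.0 / var
        XtW = X.T * w
        xtwx_inv = np.linalg.inv(XtW @ X)
        beta = xtwx_inv @ (XtW @ y)
        mean = X @ beta
        resid = y - mean
        h = w * np.einsum("ij,jk,ik->i", X, xtwx_inv, X)
        h = np.clip(h, 0.0, 1.0 - 1e-8)
        d = resid**2 / (1.0 - h)
        d = np.maximum(d, 1e-300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gamma_fit = sm.GLM(
                d, Xd, family=sm.families.Gamma(link=sm.families.links.Log())
            ).fit(scale=2.0)  # squared normal residuals are sigma^2 * chi2_1
        var = np.maximum(gamma_fit.fittedvalues, np.finfo(float).tiny)
        ll = _hetero_loglik(y, mean, var)
        if abs(ll - ll_old) <= tol * (abs(ll_old) + tol):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    se_beta = np.sqrt(np.diag(xtwx_inv))
    return (beta, se_beta, np.asarray(gamma_fit.params),
            np.asarray(gamma_fit.bse), ll_old, it, converged)


def dglm_association(y, doses, locus_id: str = "locus", max_iter: int = 100,
                     tol: float = 1e-8) -> tuple[AssociationResult, ...]:
    """Double-GLM test of a locus: mean submodel E[y] = b0 + b1 g (weighted
    least squares) and dispersion submodel log Var[eps] = c0 + c1 g (gamma
    GLM on leverage-deflated squared residuals), iterated to convergence.

    Returns three records: Wald test of the mean coefficient (``dglm_mean``),
    Wald test of the dispersion coefficient (``dglm_disp``), and a 2-df
    likelihood-ratio test against the no-effect homoscedastic null
    (``dglm_joint``).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(doses, dtype=float)
    _check_polymorphic(g)
    if y.size < 10:
        raise DegenerateTestError("need at least 10 samples for the DGLM")
    ones = np.ones_like(y)
    X = np.column_stack([ones, g])
    beta, se_b, gam, se_g, ll_full, n_iter, conv = _dglm_fit(
        y, X, X, max_iter, tol
    )
    if not conv:
        warnings.warn(
            f"DGLM did not converge in {max_iter} iterations at {locus_id}; "
            "reporting last iterate", RuntimeWarning,
        )
    X0 = ones[:, None]
    _, _, _, _, ll_null, _, _ = _dglm_fit(y, X0, X0, max_iter, tol)

    z_mean = beta[1] / se_b[1]
    z_disp = gam[1] / se_g[1]
    lr = max(2.0 * (ll_full - ll_null), 0.0)

    def _wald(name, z, est):
        logsf = stats.norm.logsf(abs(z)) + np.log(2.0)
        return AssociationResult(
            locus_id, name, float(z), (1,),
            float(min(np.exp(logsf), 1.0)), float(logsf / LOG10), float(est),
        )

    logsf_lr = stats.chi2.logsf(lr, 2)
    joint = AssociationResult(
        locus_id, "dglm_joint", float(lr), (2,),
        float(np.exp(logsf_lr)) if np.exp(logsf_lr) > 0 else np.finfo(float).tiny,
        float(logsf_lr / LOG10), None,
    )
    return (_wald("dglm_mean", z_mean, beta[1]),
            _wald("dglm_disp", z_disp, gam[1]), joint)


_TESTS = ("linear", "brown_forsythe", "dglm")

_COLUMNS = ["locus_id", "position", "test", "statistic", "df", "p",
            "log10_p", "effect", "note"]


def _tiny_where_zero(p):
    return np.where(p > 0, p, np.finfo(float).tiny)


def _linear_scan(y, doses, ids, pos) -> pd.DataFrame:
    """Vectorized OLS of y on every dose column."""
    n, m = doses.shape
    g = doses.astype(float)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    slope = (yc @ gc) / sxx
    rss = yc @ yc - slope**2 * sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.maximum(rss, 0.0) / (n - 2)
        t = slope / np.sqrt(s2 / sxx)
    t = np.where(np.isfinite(t), t, np.inf)
    logsf = stats.t.logsf(np.abs(t), n - 2) + np.log(2.0)
    p = _tiny_where_zero(np.minimum(np.exp(logsf), 1.0))
    return pd.DataFrame({
        "locus_id": ids, "position": pos, "test": "linear",
        "statistic": t, "df": [(n - 2,)] * m, "p": p,
        "log10_p": logsf / LOG10, "effect": slope, "note": "",
    })


def _bf_scan(y, doses, ids, pos, max_dose) -> pd.DataFrame:
    """Vectorized Brown-Forsythe over every dose column.

    Columns where an observed genotype group is a singleton are flagged
    (NaN statistic) rather than tested.
    """
    n, m = doses.shape
    yv = y[:, None]
    levels = range(int(max_dose) + 1)
    masks = [doses == lev for lev in levels]
    counts = np.array([mk.sum(axis=0) for mk in masks])  # levels x m
    k = (counts > 0).sum(axis=0)
    degenerate = (counts == 1).any(axis=0)

    med_by_sample = np.zeros((n, m))
    for mk in masks:
        if not mk.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN columns (absent level)
            med = np.nanmedian(np.where(mk, yv, np.nan), axis=0)
        med_by_sample += mk * np.nan_to_num(med)
    z = np.abs(yv - med_by_sample)

    grand = z.mean(axis=0)
    ss_between = np.zeros(m)
    gmean_by_sample = np.zeros((n, m))
    for lev, mk in enumerate(masks):
        with np.errstate(invalid="ignore", divide="ignore"):
            gmean = np.where(counts[lev] > 0,
                             (mk * z).sum(axis=0) / counts[lev], 0.0)
        ss_between += counts[lev] * (gmean - grand) ** 2
        gmean_by_sample += mk * gmean
    ss_within = ((z - gmean_by_sample) ** 2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    f = np.where(ss_within > 0, f, np.where(ss_between > 0, np.inf, 0.0))
    logsf = stats.f.logsf(f, k - 1, n - k)
    p = _tiny_where_zero(np.minimum(np.exp(logsf), 1.0))
    df = pd.DataFrame({
        "locus_id": ids, "position": pos, "test": "brown_forsythe",
        "statistic": f, "df": [(int(ki) - 1, n - int(ki)) for ki in k],
        "p": p, "log10_p": logsf / LOG10, "effect": np.nan, "note": "",
    })
    if degenerate.any():
        df.loc[degenerate, ["statistic", "p", "log10_p"]] = np.nan
        df.loc[degenerate, "note"] = "singleton genotype group"
    return df


def scan(gm, y, tests=("linear", "brown_forsythe"), dglm_loci=None,
         bonferroni: bool = False) -> pd.DataFrame:
    """Apply the selected tests to every polymorphic locus.

    The linear and Brown-Forsythe tests run as vectorized genome-wide
    passes (numerically identical to the per-locus functions); per-locus
    failures (degenerate groups) become flagged rows with NaN statistics
    rather than aborting the scan.  The DGLM is markedly slower, so
    ``dglm_loci`` restricts it to a subset of locus indices (default: all
    scanned loci).

    Returns a tidy frame with columns locus_id, position, test, statistic,
    df, p, log10_p, effect [, p_bonferroni] sorted by position.
    """
    unknown = set(tests) - set(_TESTS)
    if unknown:
        raise ValueError(f"unknown tests {sorted(unknown)}; choose from {_TESTS}")
    y = np.asarray(y, dtype=float)
    poly = np.flatnonzero(np.ptp(gm.doses, axis=0) > 0)
    if poly.size == 0:
        warnings.warn("all loci monomorphic; empty scan", RuntimeWarning)
        return pd.DataFrame(columns=_COLUMNS)
    frames = []
    chunk = 4096  # bound the temporaries of the vectorized passes
    for lo in range(0, poly.size, chunk):
        sel = poly[lo:lo + chunk]
        doses = gm.doses[:, sel]
        ids = [gm.locus_ids[j] for j in sel]
        pos = gm.positions[sel]
        if "linear" in tests:
            frames.append(_linear_scan(y, doses, ids, pos))
        if "brown_forsythe" in tests:
            frames.append(_bf_scan(y, doses, ids, pos, gm.doses.max()))
    if "dglm" in tests:
        rows = []
        for j in poly if dglm_loci is None else dglm_loci:
            col = gm.doses[:, j]
            lid, position = gm.locus_ids[j], gm.positions[j]
            try:
                for res in dglm_association(y, col, lid):
                    rows.append((lid, position, res.test_name, res.statistic,
                                 res.df, res.p_value, res.log10_p,
                                 res.effect_estimate, ""))
            except DegenerateTestError as exc:
                rows.append((lid, position, "dglm", np.nan, (), np.nan,
                             np.nan, None, str(exc)))
        frames.append(pd.DataFrame(rows, columns=_COLUMNS))
    df = pd.concat(frames, ignore_index=True)
    if bonferroni:
        mcount = df.groupby("test")["p"].transform("count")
        df["p_bonferroni"] = np.minimum(df["p"] * mcount, 1.0)
    return df.sort_values(["position", "test"], kind="stable").reset_index(drop=True)
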