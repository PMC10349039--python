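"""Cohort-level statistics.

Brain-age-gap arithmetic, multiple regression with standardized betas,
paired t-test, partial correlation, varimax-rotated PCA with KMO/Bartlett
diagnostics, single-mediator mediation with bias-corrected bootstrap
confidence intervals, and LMG relative-importance decomposition of R^2.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


# ---------------------------------------------------------------------------
# brain-age gap
# ---------------------------------------------------------------------------

def brain_age_gap(chronological_age: float, predicted_brain_age: float) -> float:
    """Predicted brain age minus chronological age, in years.

    Positive values indicate a brain that looks older than its chronological
    age (advanced brain aging).
    """
    if not (np.isfinite(chronological_age) and np.isfinite(predicted_brain_age)):
        raise ValueError("ages must be finite")
    if chronological_age <= 0 or predicted_brain_age <= 0:
        raise ValueError("ages must be positive")
    return float(predicted_brain_age - chronological_age)


# ---------------------------------------------------------------------------
# OLS with standardized betas
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    terms: list[str]
    coefficients: dict[str, float]
    standardized_betas: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coefficients": self.coefficients,
            "standardized_betas": self.standardized_betas,
            "standard_errors": self.standard_errors,
            "p_values": self.p_values,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "df": [self.df_model, self.df_resid],
            "n_obs": self.n_obs,
        }


def _design(regressors: pd.DataFrame) -> pd.DataFrame:
    x = sm.add_constant(regressors.astype(float), has_constant="raise")
    return x


def fit_ols(
    outcome: pd.Series | np.ndarray,
    regressors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> RegressionResult:
    """Multiple linear regression with standardized coefficients.

    ``standardized beta_k = b_k * sd(x_k) / sd(y)``; binary indicators are
    standardized by the same rule as continuous terms.
    """
    x = regressors if covariates is None else pd.concat([regressors, covariates], axis=1)
    x = x.astype(float)
    y = np.asarray(outcome, dtype=float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    design = _design(x)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns that fail to grow the rank
        bad, r, cols = [], 0, []
        for c in design.columns:
            cols.append(c)
            new_rank = np.linalg.matrix_rank(design[cols].to_numpy())
            if new_rank == r:
                bad.append(str(c))
            r = new_rank
        raise ValueError(f"rank-deficient design; dependent columns: {bad}")
    fit = sm.OLS(y, design).fit()
    sd_y = float(np.std(y, ddof=1))
    betas = {}
    for c in x.columns:
        sd_x = float(np.std(x[c], ddof=1))
        betas[str(c)] = float(fit.params[c] * sd_x / sd_y) if sd_y > 0 else float("nan")
    return RegressionResult(
        terms=["const"] + [str(c) for c in x.columns],
        coefficients={str(c): float(fit.params[c]) for c in design.columns},
        standardized_betas=betas,
        standard_errors={str(c): float(fit.bse[c]) for c in design.columns},
        p_values={str(c): float(fit.pvalues[c]) for c in design.columns},
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n_obs=int(fit.nobs),
    )


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Classical paired t-test on the elementwise differences.

    Identical vectors give ``(0, n-1, 1)``; a constant nonzero difference has
    an undefined t statistic and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0:
        if float(np.mean(d)) == 0:
            return 0.0, df, 1.0
        raise ValueError("zero-variance nonzero difference: t undefined")
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), df))
    return t, df, p


def partial_correlation(
    a: np.ndarray, b: np.ndarray, controls: pd.DataFrame | np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of the residuals of ``a`` and ``b`` on the controls.

    With no controls this reduces to the ordinary Pearson correlation.  The
    p-value uses the t transform with ``df = n - 2 - n_controls``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    if controls is None:
        z = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(controls, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        k = c.shape[1]
        z = np.column_stack([np.ones(n), c])
    if n <= k + 2:
        raise ValueError(f"need n > n_controls + 2 (n={n}, controls={k})")
    ra = a - z @ np.linalg.lstsq(z, a, rcond=None)[0]
    rb = b - z @ np.linalg.lstsq(z, b, rcond=None)[0]
    na, nb = float(np.linalg.norm(ra)), float(np.linalg.norm(rb))
    tiny_a = na <= 1e-10 * max(float(np.linalg.norm(a - a.mean())), 1e-300)
    tiny_b = nb <= 1e-10 * max(float(np.linalg.norm(b - b.mean())), 1e-300)
    if na == 0 or nb == 0 or tiny_a or tiny_b:
        warnings.warn(
            "a residual is the zero vector (variable collinear with controls); "
            "partial correlation reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    r = float(np.dot(ra, rb) / (na * nb))
    df = n - 2 - k
    r_clamped = min(max(r, -1.0), 1.0)
    if abs(r_clamped) == 1.0:
        return r_clamped, 0.0
    t = r_clamped * math.sqrt(df / (1 - r_clamped**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# PCA with varimax rotation, KMO and Bartlett diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    loadings: pd.DataFrame  # region x factor, varimax-rotated
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    kmo: float
    kmo_per_variable: dict[str, float]
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n_factors_retained: int
    n_rotation_iterations: int

    def to_dict(self) -> dict:
        return {
            "loadings": {
                c: self.loadings[c].to_dict() for c in self.loadings.columns
            },
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "kmo": self.kmo,
            "kmo_per_variable": self.kmo_per_variable,
            "bartlett_chi2": self.bartlett_chi2,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
            "n_factors_retained": self.n_factors_retained,
            "n_rotation_iterations": self.n_rotation_iterations,
        }


def _varimax(loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 100
             ) -> tuple[np.ndarray, int]:
    """Varimax rotation of a loading matrix; returns rotated loadings and
    the number of iterations to convergence of the rotation criterion."""
    n, k = loadings.shape
    if k < 2:
        return loadings.copy(), 0
    rotation = np.eye(k)
    var_old = 0.0
    iters = 0
    for iters in range(1, max_iter + 1):
        lam = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / n)
        )
        rotation = u @ vt
        var_new = float(s.sum())
        if var_old != 0 and (var_new - var_old) < tol * var_old:
            break
        var_old = var_new
    return loadings @ rotation, iters


def kmo_statistic(r: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy (overall, per-variable).

    Computed from the anti-image partial correlations
    ``q_ij = -S_ij / sqrt(S_ii S_jj)`` with ``S = R^{-1}``.
    """
    s = np.linalg.pinv(r)
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    q = -s / d
    np.fill_diagonal(q, 0.0)
    rr = r.copy()
    np.fill_diagonal(rr, 0.0)
    r2 = rr**2
    q2 = q**2
    denom_all = r2.sum() + q2.sum()
    overall = float(r2.sum() / denom_all) if denom_all > 0 else float("nan")
    per_denoms = r2.sum(axis=1) + q2.sum(axis=1)
    per = np.where(per_denoms > 0, r2.sum(axis=1) / per_denoms, np.nan)
    return overall, per


def bartlett_sphericity(r: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity on a correlation matrix.

    ``chi2 = -(n - 1 - (2p + 5)/6) ln det(R)``, ``df = p(p-1)/2``.
    """
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        return float("nan"), p * (p - 1) // 2, float("nan")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(sps.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return float(chi2), df, pval


def pca_varimax(
    table: pd.DataFrame,
    eigenvalue_threshold: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PCAResult:
    """PCA extraction on the correlation matrix with varimax rotation.

    Components with eigenvalue >= ``eigenvalue_threshold`` are retained;
    rotation applies Kaiser row-normalization.  KMO and Bartlett diagnostics
    assess suitability of the data for factoring.
    """
    table = table.astype(float)
    n, p = table.shape
    if p < 3:
        raise ValueError(f"need at least 3 columns, got {p}")
    if n < p + 1:
        raise ValueError(f"need at least p + 1 rows (p={p}, n={n})")
    r = np.corrcoef(table.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    variance_fractions = eigvals / p
    n_keep = int(np.sum(eigvals >= eigenvalue_threshold))
    n_keep = max(n_keep, 1)
    loadings = eigvecs[:, :n_keep] * np.sqrt(np.maximum(eigvals[:n_keep], 0.0))
    # Kaiser normalization: rotate rows scaled to unit communality
    h = np.sqrt((loadings**2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    rotated, iters = _varimax(loadings / h_safe[:, None], tol=tol, max_iter=max_iter)
    rotated = rotated * h_safe[:, None]
    # orient each factor so its largest-magnitude loading is positive
    for j in range(rotated.shape[1]):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] *= -1
    kmo, kmo_per = kmo_statistic(r)
    chi2, df, pval = bartlett_sphericity(r, n)
    cols = [f"factor_{j + 1}" for j in range(n_keep)]
    return PCAResult(
        loadings=pd.DataFrame(rotated, index=table.columns, columns=cols),
        eigenvalues=eigvals,
        variance_fractions=variance_fractions,
        kmo=kmo,
        kmo_per_variable={str(c): float(v) for c, v in zip(table.columns, kmo_per)},
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
        n_factors_retained=n_keep,
        n_rotation_iterations=iters,
    )


# ---------------------------------------------------------------------------
# single-mediator mediation with bias-corrected bootstrap
# ---------------------------------------------------------------------------

@dataclass
class Effect:
    estimate: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    p: float | None = None

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci": list(self.ci) if self.ci is not None else None,
            "p": self.p,
        }


@dataclass
class MediationResult:
    total_effect: Effect
    direct_effect: Effect
    indirect_effect: Effect  # se is the bootstrap SE, ci the bias-corrected CI
    a_path: Effect
    b_path: Effect
    n_boot: int
    seed: int
    significant_indirect: bool
    n_obs: int
    n_excluded: int = 0
    n_boot_dropped: int = 0
    flagged: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total_effect": self.total_effect.to_dict(),
            "direct_effect": self.direct_effect.to_dict(),
            "indirect_effect": self.indirect_effect.to_dict(),
            "a_path": self.a_path.to_dict(),
            "b_path": self.b_path.to_dict(),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "significant_indirect": self.significant_indirect,
            "n_obs": self.n_obs,
            "n_excluded": self.n_excluded,
            "n_boot_dropped": self.n_boot_dropped,
            "flagged": self.flagged,
            "notes": self.notes,
        }


def _ols_effect(y: np.ndarray, design: np.ndarray, col: int) -> Effect:
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int()
    return Effect(
        estimate=float(fit.params[col]),
        se=float(fit.bse[col]),
        ci=(float(ci[col][0]), float(ci[col][1])),
        p=float(fit.pvalues[col]),
    )


def mediate(
    x: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 5000,
    ci: float = 0.95,
    seed: int | None = None,
) -> MediationResult:
    """Single-mediator mediation with bias-corrected bootstrap inference.

    Three least-squares fits share one covariate set: total (y ~ x + cov),
    a path (m ~ x + cov), and direct/b (y ~ x + m + cov).  The indirect effect
    is a*b; its confidence interval comes from case-resampling the rows
    ``n_boot`` times and applying the bias-corrected percentile method
    (no acceleration constant).  The null of no indirect effect is rejected
    when the interval excludes zero.  Rows with any missing value are dropped
    (complete-case analysis) and counted.
    """
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    x = np.asarray(x, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    mask = np.isfinite(x) & np.isfinite(m) & np.isfinite(y) & np.all(
        np.isfinite(cov), axis=1
    )
    n_excluded = int(np.sum(~mask))
    x, m, y, cov = x[mask], m[mask], y[mask], cov[mask]
    n = x.size
    k = cov.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > n_covariates + 3 (n={n}, covariates={k})")

    ones = np.ones((n, 1))
    design_xc = np.column_stack([ones, x[:, None], cov])     # total & a path
    design_xmc = np.column_stack([ones, x[:, None], m[:, None], cov])

    total = _ols_effect(y, design_xc, col=1)
    a_path = _ols_effect(m, design_xc, col=1)
    direct = _ols_effect(y, design_xmc, col=1)
    b_path = _ols_effect(y, design_xmc, col=2)
    indirect_point = a_path.estimate * b_path.estimate

    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        xc = design_xc[idx]
        xmc = design_xmc[idx]
        a_b = np.linalg.lstsq(xc, m[idx], rcond=None)[0][1]
        b_b = np.linalg.lstsq(xmc, y[idx], rcond=None)[0][2]
        draws[i] = a_b * b_b
    finite = np.isfinite(draws)
    n_dropped = int(np.sum(~finite))
    draws = draws[finite]
    flagged = n_dropped > 0.01 * n_boot
    notes = []
    if n_dropped:
        notes.append(f"{n_dropped} degenerate bootstrap draws dropped")

    # bias-corrected percentile interval
    n_eff = draws.size
    prop_below = float(np.mean(draws < indirect_point))
    prop_below = min(max(prop_below, 1.0 / (n_eff + 1)), n_eff / (n_eff + 1.0))
    z0 = float(sps.norm.ppf(prop_below))
    z_crit = float(sps.norm.ppf((1 + ci) / 2))
    lo_q = float(sps.norm.cdf(2 * z0 - z_crit))
    hi_q = float(sps.norm.cdf(2 * z0 + z_crit))
    lo, hi = np.percentile(draws, [100 * lo_q, 100 * hi_q])
    boot_se = float(np.std(draws, ddof=1)) if n_eff > 1 else float("nan")

    indirect = Effect(estimate=float(indirect_point), se=boot_se, ci=(float(lo), float(hi)))
    return MediationResult(
        total_effect=total,
        direct_effect=direct,
        indirect_effect=indirect,
        a_path=a_path,
        b_path=b_path,
        n_boot=n_boot,
        seed=seed,
        significant_indirect=bool(lo > 0 or hi < 0),
        n_obs=n,
        n_excluded=n_excluded,
        n_boot_dropped=n_dropped,
        flagged=flagged,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

@dataclass
class LMGResult:
    shares: dict[str, float]
    total_r_squared: float

    def to_dict(self) -> dict:
        return {"shares": self.shares, "total_r_squared": self.total_r_squared}


def _subset_r2(y: np.ndarray, x: np.ndarray, cols: tuple[int, ...],
               cache: dict[tuple[int, ...], float], tss: float) -> float:
    if cols in cache:
        return cache[cols]
    if not cols:
        r2 = 0.0
    else:
        design = np.column_stack([np.ones(y.size), x[:, cols]])
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    cache[cols] = r2
    return r2


def lmg(outcome: np.ndarray | pd.Series, regressors: pd.DataFrame) -> LMGResult:
    """LMG relative-importance decomposition of R^2.

    Each regressor's share is its average increment to R^2 over all orderings
    of entry, computed exactly by subset enumeration with combinatorial
    weights; the shares sum to the full-model R^2.  Limited to 10 regressors.
    """
    x = regressors.astype(float).to_numpy()
    y = np.asarray(outcome, dtype=float)
    p = x.shape[1]
    if not 1 <= p <= 10:
        raise ValueError(f"LMG supports 1..10 regressors, got {p}")
    tss = float(np.sum((y - y.mean()) ** 2))
    cache: dict[tuple[int, ...], float] = {}
    others = list(range(p))
    shares = {}
    fact = math.factorial
    for k in range(p):
        rest = [j for j in others if j != k]
        share = 0.0
        for s in range(p):
            w = fact(s) * fact(p - s - 1) / fact(p)
            for subset in itertools.combinations(rest, s):
                with_k = tuple(sorted(subset + (k,)))
                share += w * (
                    _subset_r2(y, x, with_k, cache, tss)
                    - _subset_r2(y, x, tuple(sorted(subset)), cache, tss)
                )
        shares[str(regressors.columns[k])] = float(share)
    full = _subset_r2(y, x, tuple(range(p)), cache, tss)
    return LMGResult(shares=shares, total_r_squared=float(full))
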