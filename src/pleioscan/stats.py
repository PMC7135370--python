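"""Cross-cutting statistics tying the scans, eQTLs and network together.

Enrichment with Fisher's exact test and bootstrap percentage CIs;
standardized multiple regressions of diversity and connectivity on
expression features; a label-permutation test for whether outlier
status improves the fit of stat ~ S + outlier beyond chance; and a
smooth-trend summary of connectivity against scan p-values.

All regression tables standardize the response and the continuous
predictors (z-scores), so coefficients are comparable across models;
binary predictors stay on their 0/1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.stats import fisher_exact, ranksums
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .eqtl import fit_logistic


@dataclass
class PermutationTest:
    """Observed fit, permutation distribution, add-one p-value."""

    observed_fit: float
    n_perm: int
    permuted_fits: np.ndarray
    p: float
    seed: int


def fisher_enrichment(set_a: np.ndarray, set_b: np.ndarray) -> dict:
    """Two-sided Fisher exact test on the 2x2 cross of two gene flags.

    Returns the conditional-MLE odds ratio (np.inf when a margin is
    empty on the off-diagonal) and the exact p-value.
    """
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    if a.size == 0:
        raise ValueError("empty gene universe")
    table = np.array([[int((a & b).sum()), int((a & ~b).sum())],
                      [int((~a & b).sum()), int((~a & ~b).sum())]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError("a margin of the 2x2 table is empty")
    _, p = fisher_exact(table, alternative="two-sided")
    try:
        orat = float(_odds_ratio(table, kind="conditional").statistic)
    except Exception:
        orat = float("inf")
    return {"odds_ratio": orat, "p": float(p), "table": table}


def bootstrap_percent_ci(flags: np.ndarray, B: int = 1000,
                         seed: int = 0) -> dict:
    """Percentile bootstrap CI for a flagged percentage over genes."""
    flags = np.asarray(flags, dtype=float)
    n = flags.size
    if n < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(B, n))
    pct = flags[draws].mean(axis=1) * 100.0
    lo, hi = np.percentile(pct, [2.5, 97.5])
    return {"percent": float(flags.mean() * 100.0),
            "lo": float(lo), "hi": float(hi)}


def permutation_fit_test(stat: np.ndarray, S: np.ndarray, labels: np.ndarray,
                         n_perm: int = 10_000, seed: int = 0) -> PermutationTest:
    """Does outlier status improve the fit of stat ~ S + outlier?

    The observed R^2 is compared with R^2 under random reassignment of
    the outlier labels (S kept fixed); p uses the add-one convention
    (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    y = np.asarray(stat, dtype=float)
    S = np.asarray(S, dtype=float)
    lab = np.asarray(labels, dtype=float)
    if y.std() == 0:
        raise ValueError("constant statistic")
    if len(np.unique(lab)) < 2:
        raise ValueError("need both label classes present")
    if min((lab == u).sum() for u in np.unique(lab)) < 2:
        raise ValueError("need at least 2 genes per label class")
    n = len(y)
    base = np.column_stack([np.ones(n), S])
    qb, _ = np.linalg.qr(base)
    yr = y - qb @ (qb.T @ y)
    ss_tot = ((y - y.mean()) ** 2).sum()
    yr_ss = (yr ** 2).sum()

    def _r2(lvec_r):
        l_ss = (lvec_r ** 2).sum(axis=0)
        gain = np.where(l_ss > 0, (yr @ lvec_r) ** 2 / np.where(l_ss > 0, l_ss, 1.0), 0.0)
        return 1.0 - (yr_ss - gain) / ss_tot

    lr = lab - qb @ (qb.T @ lab)
    observed = float(_r2(lr[:, None])[0])
    rng = np.random.default_rng(seed)
    fits = np.empty(n_perm)
    chunk = 512
    for start in range(0, n_perm, chunk):
        b = min(chunk, n_perm - start)
        perms = rng.permuted(np.tile(lab, (b, 1)), axis=1).T  # (n, b)
        perms_r = perms - qb @ (qb.T @ perms)
        fits[start:start + b] = _r2(perms_r)
    p = (1.0 + (fits >= observed).sum()) / (n_perm + 1.0)
    return PermutationTest(observed_fit=observed, n_perm=n_perm,
                           permuted_fits=fits, p=float(p), seed=seed)


# ---------------------------------------------------------------------
# Standardized regressions
# ---------------------------------------------------------------------

def standardized_ols(y: np.ndarray, X: pd.DataFrame,
                     binary: tuple = ()) -> pd.DataFrame:
    """OLS with z-scored response and continuous predictors.

    Binary predictors named in ``binary`` keep their 0/1 coding.
    Returns beta, analytic 95% CI, p per predictor; R^2 and n in
    ``attrs``.  Raises on collinear designs (condition number > 1e8).
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("zero variance in response")
    ys = (y - y.mean()) / y.std()
    Xs = X.copy().astype(float)
    for c in Xs.columns:
        if c in binary:
            continue
        sd = Xs[c].std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero variance in predictor {c!r}")
        Xs[c] = (Xs[c] - Xs[c].mean()) / sd
    Xc = sm.add_constant(Xs)
    if np.linalg.cond(Xc.to_numpy()) > 1e8:
        raise ValueError("collinear predictors")
    fit = sm.OLS(ys, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame({"beta": fit.params, "ci_lo": ci[0], "ci_hi": ci[1],
                        "se": fit.bse, "p": fit.pvalues})
    out.attrs["r_squared"] = float(fit.rsquared)
    out.attrs["n"] = int(len(ys))
    return out


def diversity_connectivity_model(theta, connectivity, expr_level,
                                 expr_variance, subset=None) -> pd.DataFrame:
    """Standardized OLS of per-gene diversity on connectivity plus
    expression level and variance; run on an optional boolean subset
    (outlier or background genes)."""
    df = pd.DataFrame({"theta": theta, "connectivity": connectivity,
                       "level": expr_level, "variance": expr_variance}).dropna()
    if subset is not None:
        df = df[np.asarray(subset)[df.index] if not isinstance(subset, pd.Series)
                else subset.reindex(df.index).fillna(False).astype(bool)]
    if len(df) < 10:
        raise ValueError("need at least 10 genes")
    return standardized_ols(df["theta"].to_numpy(),
                            df[["connectivity", "level", "variance"]])


def connectivity_outlier_model(connectivity, expr_level, expr_variance,
                               outlier) -> pd.DataFrame:
    """Standardized OLS of connectivity on outlier status controlling
    for expression level and variance."""
    df = pd.DataFrame({"k": connectivity, "level": expr_level,
                       "variance": expr_variance,
                       "outlier": np.asarray(outlier, float)}).dropna()
    if len(df) < 10:
        raise ValueError("need at least 10 genes")
    return standardized_ols(df["k"].to_numpy(),
                            df[["level", "variance", "outlier"]],
                            binary=("outlier",))


def eqtl_outlier_logistic(is_eqtl, S, outlier) -> pd.DataFrame:
    """Logistic regression of eQTL status on outlier status with S as
    covariate; Wald CIs, penalized fallback on separation."""
    y = np.asarray(is_eqtl, dtype=float)
    X = pd.DataFrame({"S": np.asarray(S, float),
                      "outlier": np.asarray(outlier, float)})
    return fit_logistic(y, X)


def connectivity_pvalue_trend(connectivity, min_p, edge_frac: float = 0.05) -> dict:
    """Smooth-trend summary of scan p-values against connectivity.

    Fits a cubic smoothing spline of min_p on connectivity; reports the
    overall trend sign (with an OLS slope CI), and whether the fitted
    derivative changes sign in the interior (an intermediate peak or
    dip), excluding ``edge_frac`` of the range at each end.
    """
    k = np.asarray(connectivity, dtype=float)
    y = np.asarray(min_p, dtype=float)
    if len(k) < 50:
        raise ValueError("need at least 50 genes")
    order = np.argsort(k)
    ks, ys = k[order], y[order]
    # collapse ties for the spline
    uk, inv = np.unique(ks, return_inverse=True)
    uy = np.bincount(inv, weights=ys) / np.bincount(inv)
    spl = UnivariateSpline(uk, uy, k=3, s=len(uk) * np.var(uy))
    grid = np.linspace(uk[0], uk[-1], 200)
    deriv = spl.derivative()(grid)
    lo = int(len(grid) * edge_frac)
    core = deriv[lo:len(grid) - lo]
    sign_change = bool(np.any(np.sign(core[:-1]) * np.sign(core[1:]) < 0))

    # simple linear slope with CI for the "flat trend" check
    import statsmodels.api as sm
    fit = sm.OLS((y - y.mean()) / y.std(),
                 sm.add_constant((k - k.mean()) / k.std())).fit()
    ci = np.asarray(fit.conf_int())[1]
    slope = float(np.asarray(fit.params)[1])
    return {"trend_sign": int(np.sign(spl(grid[-1]) - spl(grid[0]))),
            "slope": slope, "slope_ci": (float(ci[0]), float(ci[1])),
            "interior_mode": sign_change}


def wilcoxon_rank_sum(a, b) -> dict:
    """Two-sided rank-sum comparison of two groups (normal approx)."""
    stat, p = ranksums(np.asarray(a, float), np.asarray(b, float))
    return {"stat": float(stat), "p": float(p),
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}
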