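"""The study's statistical layer.

One-way repeated-measures ANOVA with Greenhouse–Geisser correction,
Holm-corrected pairwise paired t-tests, JZS (Cauchy-prior) Bayes factors for
t-tests, nonparametric bootstrap confidence intervals, t_max
permutation-corrected correlation courses, and per-participant OLS
residualization of gamma power on N70 slope and amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class RmAnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float


def _as_wide(table) -> np.ndarray:
    """(n_participants, k_conditions) array from a wide DataFrame or array."""
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a participants × conditions table")
    if np.any(~np.isfinite(arr)):
        raise ValueError("table must be balanced with finite values")
    return arr


def rm_anova_gg(table) -> RmAnovaResult:
    """One-way repeated-measures F with Greenhouse–Geisser corrected dfs.

    Epsilon comes from the double-centered sample covariance of condition
    scores: eps = tr(D)² / ((k−1)·tr(D²)).  The p value uses the F
    distribution at (eps·(k−1), eps·(k−1)(n−1)).
    """
    x = _as_wide(table)
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need at least 2 conditions and 3 participants")
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = x - subj_means[:, None] - cond_means[None, :] + grand
    ss_err = np.sum(resid**2)
    df1, df2 = k - 1.0, (k - 1.0) * (n - 1.0)
    f_stat = (ss_cond / df1) / (ss_err / df2)

    s = np.cov(x, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    d = c @ s @ c
    eps = np.trace(d) ** 2 / ((k - 1) * np.trace(d @ d))
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    p = float(stats.f.sf(f_stat, eps * df1, eps * df2))
    return RmAnovaResult(float(f_stat), eps * df1, eps * df2, p, eps)


def holm_pairwise(table, pairs: list[tuple] | None = None) -> pd.DataFrame:
    """Paired t-tests between condition columns, Holm step-down corrected.

    ``table`` is a wide DataFrame (columns = condition labels); ``pairs``
    defaults to all column pairs.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table, dtype=float))
    cols = list(table.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_rel(table[a], table[b])
        rows.append({"a": a, "b": b, "t": float(t), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def jzs_bayes_factor(t: float, n: int, rscale: float = 1.0) -> float:
    """BF01 of the JZS default Bayes factor for a one-sample/paired t-test.

    The Cauchy(0, rscale) prior on standardized effect size is integrated
    through its inverse-gamma mixture representation:

        BF10 = ∫ (1+N g r²)^{-1/2} (1 + t²/(ν(1+N g r²)))^{-(ν+1)/2}
                 (2π)^{-1/2} g^{-3/2} e^{-1/(2g)} dg
               / (1 + t²/ν)^{-(ν+1)/2},  ν = n − 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1.0
    t2 = float(t) ** 2
    r2 = rscale**2

    def integrand(g):
        a = 1.0 + n * g * r2
        return (
            a ** (-0.5)
            * (1.0 + t2 / (nu * a)) ** (-(nu + 1.0) / 2.0)
            * (2.0 * np.pi) ** (-0.5)
            * g ** (-1.5)
            * np.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(num) or err > 1e-6 * max(num, 1e-12):
        raise RuntimeError("JZS quadrature did not converge")
    den = (1.0 + t2 / nu) ** (-(nu + 1.0) / 2.0)
    return float(den / num)


def bootstrap_ci(
    values,
    stat=np.mean,
    B: int = 10000,
    level: float = 0.95,
    seed=None,
) -> tuple[float, float]:
    """Percentile bootstrap interval of ``stat`` over resampled values."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    if stat is np.mean:
        reps = x[idx].mean(axis=1)
    else:
        reps = np.array([stat(x[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(reps, alpha)), float(np.quantile(reps, 1.0 - alpha))


@dataclass
class CorrelationCourse:
    axis: np.ndarray
    r: np.ndarray  # mean across-participant correlation per bin
    t: np.ndarray  # group-level one-sample t per bin (Fisher-z domain)
    significant: np.ndarray  # per-bin flag after t_max correction
    threshold: float  # 95th percentile of the permutation max-|t|


def _one_sample_t(z: np.ndarray) -> np.ndarray:
    """Columnwise one-sample t against 0 for (n_participants, n_bins)."""
    n = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return mean / (sd / np.sqrt(n))


def tmax_correlation(
    courses,
    n_perm: int = 1000,
    seed=None,
    axis=None,
    fisher_z: bool = True,
    alpha: float = 0.05,
) -> CorrelationCourse:
    """Group test of per-participant correlation courses with t_max FWER control.

    ``courses`` is (n_participants, n_bins) of per-participant correlations.
    Correlations are Fisher-z transformed (config-switchable), tested per bin
    with a one-sample t, and the null is built by random sign-flipping of the
    participants' whole courses; the max |t| over bins per permutation forms
    the reference distribution.  ``n_perm="exact"`` enumerates all 2^n sign
    patterns.
    """
    r = np.asarray(courses, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 bins")
    exact = isinstance(n_perm, str) and n_perm == "exact"
    if not exact and n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n_sub, n_bins = r.shape
    z = np.arctanh(np.clip(r, -0.999999, 0.999999)) if fisher_z else r.copy()
    t_obs = _one_sample_t(z)

    if exact:
        bits = np.arange(2**n_sub)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n_sub)[None, :]) & 1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(int(n_perm) - 1, n_sub))
        signs = np.vstack([np.ones((1, n_sub)), signs])  # include identity
    max_t = np.empty(signs.shape[0])
    for i, s in enumerate(signs):
        max_t[i] = np.abs(_one_sample_t(z * s[:, None])).max()
    # next-higher order statistic: the conservative permutation convention,
    # needed for finite n_perm to keep the familywise error at alpha
    threshold = float(np.quantile(max_t, 1.0 - alpha, method="higher"))
    significant = np.abs(t_obs) > threshold
    if axis is None:
        axis = np.arange(n_bins)
    return CorrelationCourse(
        axis=np.asarray(axis), r=r.mean(axis=0), t=t_obs,
        significant=significant, threshold=threshold,
    )


def residualize_gamma(gamma, n70_slope, n70_amplitude) -> np.ndarray:
    """Residuals of gamma power on [1, N70 slope, N70 amplitude] (per participant).

    All three inputs are per-condition vectors for one participant; at least
    three conditions are required (two regressors plus intercept).
    """
    y = np.asarray(gamma, dtype=float)
    x = np.column_stack(
        [np.ones_like(y), np.asarray(n70_slope, float), np.asarray(n70_amplitude, float)]
    )
    if y.size < 3:
        raise ValueError("need at least 3 conditions")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design: regressors are collinear")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta
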