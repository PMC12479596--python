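"""Group-level inference for microstate studies.

Covers the parametric and nonparametric two-sample tests with their effect
sizes (pooled-variance Student t with Cohen's d; Mann-Whitney U with
Cliff's delta), multiplicity control via the Li-Ji effective number of
independent tests with a Sidak-adjusted alpha, the TANOVA permutation test
on scalp topographies, Benjamini-Hochberg FDR, and bootstrap confidence
intervals for correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidArgumentError, UndefinedCorrelationError

__all__ = [
    "TestResult",
    "MeffResult",
    "student_t_summary",
    "mann_whitney",
    "cliffs_delta_from_u",
    "li_ji_meff",
    "sidak_alpha",
    "tanova",
    "bh_fdr",
    "correlate_bootstrap",
]


@dataclass
class TestResult:
    statistic: float
    statistic_name: str
    p: float
    df: float | None = None
    effect: float | None = None
    ci: tuple[float, float] | None = None


@dataclass
class MeffResult:
    """Li-Ji effective number of independent tests and the Sidak-adjusted
    per-test alpha."""

    eigenvalues: np.ndarray
    m_eff: float
    alpha: float
    alpha_adjusted: float


def student_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample t test from summary statistics.

    t = (mean1 - mean2) / sqrt(s_p^2 (1/n1 + 1/n2)), df = n1 + n2 - 2,
    Cohen's d = (mean1 - mean2) / s_p.  This is the form that yields df = 34
    for two groups of 18.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidArgumentError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    sp = np.sqrt(sp2)
    t = (mean1 - mean2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), statistic_name="t", p=float(p), df=float(df),
                      effect=float((mean1 - mean2) / sp))


def mann_whitney(x, y, alternative: str = "two-sided", method: str = "auto") -> TestResult:
    """Mann-Whitney U with Cliff's delta.

    U is oriented to the first sample (midrank tie handling).  With
    ``method="auto"`` the p-value is exact when n1*n2 <= 400 and there are
    no ties, otherwise a continuity- and tie-corrected normal approximation.
    delta = 2U/(n1*n2) - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("empty sample")
    if method == "auto":
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    u = float(res.statistic)
    delta = 2.0 * u / (x.size * y.size) - 1.0
    return TestResult(statistic=u, statistic_name="U", p=float(res.pvalue), effect=delta)


def cliffs_delta_from_u(u: float, n1: int, n2: int) -> float:
    """delta = 2U/(n1*n2) - 1, with U oriented to the first-listed group."""
    if not 0 <= u <= n1 * n2:
        raise InvalidArgumentError(f"U={u} outside [0, {n1 * n2}]")
    return 2.0 * u / (n1 * n2) - 1.0


def li_ji_meff(variable_matrix: np.ndarray, alpha: float = 0.05) -> MeffResult:
    """Effective number of independent tests from the eigenvalues of the
    variables' correlation matrix (Li & Ji estimator).

    M_eff = sum_i f(|lambda_i|) with f(x) = I(x >= 1) + (x - floor(x));
    the Sidak-adjusted per-test level is 1 - (1 - alpha)^(1/M_eff).
    """
    X = np.asarray(variable_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise InvalidArgumentError("need >= 3 subjects and >= 2 variables")
    if np.any(X.std(axis=0) < 1e-15):
        raise UndefinedCorrelationError("constant variable: correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    lam = np.abs(np.linalg.eigvalsh(corr))
    m_eff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    m_eff = min(max(m_eff, 1.0), float(X.shape[1]))
    return MeffResult(
        eigenvalues=lam[::-1],
        m_eff=m_eff,
        alpha=alpha,
        alpha_adjusted=sidak_alpha(alpha, m_eff),
    )


def sidak_alpha(alpha: float, m_eff: float) -> float:
    """Sidak-corrected per-test alpha for m_eff effective tests."""
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    if m_eff < 1:
        raise InvalidArgumentError("m_eff must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m_eff)


def _unit_gfp(maps: np.ndarray) -> np.ndarray:
    """Average-reference rows and scale each to unit GFP."""
    m = maps - maps.mean(axis=1, keepdims=True)
    g = np.sqrt(np.mean(m**2, axis=1, keepdims=True))
    if np.any(g < 1e-15):
        raise InvalidArgumentError("zero-GFP map")
    return m / g


def _diss(u: np.ndarray, v: np.ndarray) -> float:
    """Global map dissimilarity between two unit-GFP-normalized means."""
    un = _unit_gfp(u[None, :])[0]
    vn = _unit_gfp(v[None, :])[0]
    return float(np.sqrt(np.mean((un - vn) ** 2)))


def tanova(
    group_a_maps: np.ndarray,
    group_b_maps: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence | None = None,
) -> TestResult:
    """Topographic ANOVA: permutation test on global map dissimilarity.

    Subject topographies are average-referenced and scaled to unit GFP; the
    statistic is DISS between the (re-normalized) group-mean maps.  Group
    labels are permuted ``n_perm`` times; the p-value counts replicates with
    DISS >= observed, with the observed statistic included in numerator and
    denominator, so p is never 0.
    """
    a = np.atleast_2d(np.asarray(group_a_maps, dtype=float))
    b = np.atleast_2d(np.asarray(group_b_maps, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise InvalidArgumentError("groups must share the channel count")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 subjects per group")
    pooled = _unit_gfp(np.vstack([a, b]))
    n1 = a.shape[0]
    n = pooled.shape[0]
    observed = _diss(pooled[:n1].mean(axis=0), pooled[n1:].mean(axis=0))
    rng = np.random.default_rng(seed)
    # vectorized label permutations: boolean membership matrix @ pooled maps
    u = rng.random((n_perm, n))
    order = np.argsort(u, axis=1)
    in_a = np.zeros((n_perm, n))
    np.put_along_axis(in_a, order[:, :n1], 1.0, axis=1)
    mean_a = in_a @ pooled / n1
    mean_b = (1.0 - in_a) @ pooled / (n - n1)
    ga = np.sqrt(np.mean(mean_a**2, axis=1, keepdims=True))
    gb = np.sqrt(np.mean(mean_b**2, axis=1, keepdims=True))
    ga[ga < 1e-15] = 1.0
    gb[gb < 1e-15] = 1.0
    diss = np.sqrt(np.mean((mean_a / ga - mean_b / gb) ** 2, axis=1))
    p = (1 + int(np.sum(diss >= observed - 1e-15))) / (n_perm + 1)
    return TestResult(statistic=observed, statistic_name="diss", p=float(p))


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def correlate_bootstrap(
    x,
    y,
    method: str = "pearson",
    n_boot: int = 5000,
    seed: int | np.random.SeedSequence | None = None,
    ci_level: float = 0.95,
) -> TestResult:
    """Correlation with a percentile bootstrap confidence interval.

    Pairs are resampled with replacement ``n_boot`` times; the CI is the
    percentile interval of the resampled coefficients.  Deterministic under
    a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise InvalidArgumentError("need >= 4 paired observations")
    if x.std() < 1e-15 or y.std() < 1e-15:
        raise UndefinedCorrelationError("zero-variance input")
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    if method not in ("pearson", "spearman"):
        raise InvalidArgumentError("method must be 'pearson' or 'spearman'")
    est = fn(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    reps = np.full(n_boot, np.nan)
    for i in range(n_boot):
        xi, yi = x[idx[i]], y[idx[i]]
        if xi.std() < 1e-15 or yi.std() < 1e-15:
            continue
        reps[i] = fn(xi, yi).statistic
    tail = (1 - ci_level) / 2 * 100
    lo, hi = np.nanpercentile(reps, [tail, 100 - tail])
    name = "r" if method == "pearson" else "rho"
    return TestResult(
        statistic=float(est.statistic),
        statistic_name=name,
        p=float(est.pvalue),
        effect=float(est.statistic),
        ci=(float(lo), float(hi)),
    )
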