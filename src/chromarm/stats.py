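"""Statistical kernel: exact contingency tests, rank tests, correlation,
multiple-testing correction, over-representation, and the Box–Cox regression
comparison engine.

Standard distributions and test machinery come from scipy/statsmodels; the
Freeman–Halton exact test for r×c tables is implemented here by direct
enumeration because no installed package provides it.  Two-sided exact
p-values follow the probability-mass convention (sum the probabilities of all
margin-fixed tables at most as probable as the observed one), with a relative
tie tolerance of 1e-7 so that enumeration order cannot change the result.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

#: Relative tolerance when comparing table probabilities for the two-sided
#: probability-mass rule.
TIE_RTOL = 1e-7

#: Default cap on enumerated tables for the exact r×c test.
MAX_EXACT_TABLES = 2_000_000


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    p: float
    statistic: float | None = None
    effect: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = ""
    df: int | None = None
    note: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("contingency table entries must be non-negative integers")
    return arr.astype(np.int64)


# ---------------------------------------------------------------------------
# Exact contingency tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table, or_kind: str = "conditional") -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 table.

    The p-value sums hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's (scipy's
    convention).  With ``or_kind="conditional"`` (default) the effect is the
    conditional maximum-likelihood odds ratio with its 95% CI; ``"sample"``
    reports the cross-product odds ratio without a CI, which is much cheaper
    for large per-gene screens.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got {t.shape}")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2×2 table; association untestable",
                      stacklevel=2)
        return TestResult(p=1.0, method="fisher_exact", note="zero margin")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    if or_kind == "conditional":
        orr = sps.contingency.odds_ratio(t, kind="conditional")
        ci = orr.confidence_interval(0.95)
        return TestResult(p=float(p), effect=float(orr.statistic),
                          ci_low=float(ci.low), ci_high=float(ci.high),
                          method="fisher_exact")
    a, b = t[0]
    c, d = t[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = float(np.divide(a * d, b * c)) if b * c else np.inf
    return TestResult(p=float(p), effect=sample_or, method="fisher_exact")


def _log_table_prob(t: np.ndarray, row_margins, col_margins, n) -> float:
    # log P(table | margins) = Σ log r_i! + Σ log c_j! − log N! − Σ log n_ij!
    return (gammaln(row_margins + 1).sum() + gammaln(col_margins + 1).sum()
            - gammaln(n + 1) - gammaln(t + 1).sum())


def _enumerate_tables(row_margins, col_margins):
    """Yield all non-negative integer tables with the given margins."""
    r = len(row_margins)

    def fill(row_idx, remaining_cols):
        if row_idx == r - 1:
            yield [list(remaining_cols)]
            return
        target = row_margins[row_idx]
        cols = np.asarray(remaining_cols)

        def fill_row(j, left, prefix):
            if j == len(cols) - 1:
                if left <= cols[j]:
                    yield prefix + [left]
                return
            hi = min(cols[j], left)
            lo = max(0, left - cols[j + 1:].sum())
            for v in range(lo, hi + 1):
                yield from fill_row(j + 1, left - v, prefix + [v])

        for row in fill_row(0, target, []):
            for rest in fill(row_idx + 1, cols - np.asarray(row)):
                yield [row] + rest

    yield from fill(0, np.asarray(col_margins))


def exact_rxc(table, max_tables: int = MAX_EXACT_TABLES,
              monte_carlo: bool = False, n_montecarlo: int = 100_000,
              seed: int | None = None) -> TestResult:
    """Freeman–Halton exact test for an r×c contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table.  When
    the enumeration would exceed ``max_tables`` the test either falls back to
    seeded Monte-Carlo sampling of margin-fixed tables (``monte_carlo=True``)
    or raises.
    """
    t = _as_table(table)
    row_m, col_m = t.sum(axis=1), t.sum(axis=0)
    t = t[row_m > 0][:, col_m > 0]
    row_m, col_m = t.sum(axis=1), t.sum(axis=0)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return TestResult(p=1.0, method="exact_rxc",
                          note="fewer than two effective rows/columns")
    n = int(t.sum())
    log_p_obs = _log_table_prob(t, row_m, col_m, n)
    cutoff = log_p_obs + math.log1p(TIE_RTOL)

    # loose upper bound on the enumeration size
    bound = 1.0
    for ri in row_m[:-1]:
        for cj in col_m[:-1]:
            bound *= min(ri, cj) + 1
    if bound > max_tables:
        if not monte_carlo:
            raise ValueError(
                f"exact r×c enumeration bound {bound:.3g} exceeds "
                f"max_tables={max_tables}; pass monte_carlo=True")
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_montecarlo):
            sim = sps.random_table(row_m, col_m, seed=rng).rvs()
            if _log_table_prob(sim, row_m, col_m, n) <= cutoff:
                hits += 1
        return TestResult(p=(hits + 1) / (n_montecarlo + 1),
                          method="exact_rxc_montecarlo",
                          extra={"n_montecarlo": n_montecarlo})
    total = 0.0
    for cand in _enumerate_tables(row_m, col_m):
        lp = _log_table_prob(np.asarray(cand), row_m, col_m, n)
        if lp <= cutoff:
            total += math.exp(lp)
    return TestResult(p=min(1.0, total), method="exact_rxc")


def chi_square_test(table, continuity: bool = False) -> TestResult:
    """Pearson's χ² test of independence on an r×c table."""
    t = _as_table(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: expected cell count of zero")
    stat, p, df, _ = sps.chi2_contingency(t, correction=continuity)
    return TestResult(p=float(p), statistic=float(stat), df=int(df),
                      method="chi_square" + ("_yates" if continuity else ""))


# ---------------------------------------------------------------------------
# Rank tests and correlation
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact by enumeration for combined n ≤ 12 without ties; normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        warnings.warn("all values identical across both groups", stacklevel=2)
        return TestResult(p=1.0, statistic=float(x.size * y.size / 2),
                          method="mann_whitney")
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(p=float(res.pvalue), statistic=float(res.statistic),
                      method=f"mann_whitney_{method}")


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties.

    For n ≤ 9 the p-value is exact, from full enumeration of rank
    permutations; otherwise the t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n ≥ 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero variance: rho undefined")
    rho, p_approx = sps.spearmanr(x, y)
    n = x.size
    if n <= 9:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        p_c = perms - ry.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (p_c ** 2).sum(axis=1))
        rhos = p_c @ rx_c / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return TestResult(p=p, statistic=float(rho), effect=float(rho),
                          method="spearman_exact")
    return TestResult(p=float(p_approx), statistic=float(rho),
                      effect=float(rho), method="spearman_t")


# ---------------------------------------------------------------------------
# Multiple testing and over-representation
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_ora(hits, pathway, universe) -> TestResult:
    """Upper-tail hypergeometric over-representation test.

    p = P(overlap ≥ observed) drawing |hits| genes from a universe containing
    |pathway| pathway members.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    pathway = set(pathway) & universe
    k = len(hits & pathway)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(pathway), len(hits)))
    return TestResult(p=min(1.0, p), statistic=float(k),
                      method="hypergeometric_ora",
                      extra={"overlap": k, "pathway_size": len(pathway),
                             "n_hits": len(hits), "universe_size": len(universe)})


# ---------------------------------------------------------------------------
# Box–Cox + linear regression comparison engine
# ---------------------------------------------------------------------------

def boxcox_regression(y, group, covariates=None, shift_eps: float = 1e-6
                      ) -> TestResult:
    """Compare a positive outcome between two groups on a Box–Cox scale.

    λ is chosen by profile maximum likelihood on the pooled outcome; the
    transformed outcome is regressed on the group indicator (plus optional
    binary covariates) by ordinary least squares, and the group coefficient's
    Wald p-value is reported.  If min(y) ≤ 0 the outcome is first shifted by
    −min(y)+``shift_eps``.  The effect is also reported as the ratio of group
    means on the original scale with a delta-method 95% CI.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    g = np.asarray(group)
    if y.size != g.size:
        raise ValueError("y and group must have equal length")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels")
    if np.unique(y).size == 1:
        raise ValueError("constant outcome")
    shift = 0.0
    if y.min() <= 0:
        shift = -y.min() + shift_eps
    yy = y + shift
    if np.ptp(yy) / yy.max() < 1e-12:
        raise ValueError("outcome nearly constant after shift")
    lam = float(sps.boxcox_normmax(yy, method="mle"))
    yt = sps.boxcox(yy, lam)
    gi = (g == levels[1]).astype(float)
    X = gi.reshape(-1, 1)
    names = ["group"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(-1, 1)
        X = np.column_stack([X, cov])
        names += [f"cov{i}" for i in range(cov.shape[1])]
    X = sm.add_constant(X, prepend=True)
    fit = sm.OLS(yt, X).fit()
    coef = float(fit.params[1])
    p = float(fit.pvalues[1])
    ci_t = fit.conf_int()[1]
    # ratio of group means on the original scale, delta-method CI on log scale
    y0, y1 = y[gi == 0], y[gi == 1]
    m0, m1 = y0.mean(), y1.mean()
    if m0 > 0 and m1 > 0:
        ratio = m1 / m0
        se_log = math.sqrt(y1.var(ddof=1) / (y1.size * m1 ** 2)
                           + y0.var(ddof=1) / (y0.size * m0 ** 2))
        rlo, rhi = ratio * math.exp(-1.96 * se_log), ratio * math.exp(1.96 * se_log)
    else:
        ratio, rlo, rhi = np.nan, np.nan, np.nan
    return TestResult(p=p, statistic=coef, effect=ratio,
                      ci_low=rlo, ci_high=rhi, method="boxcox_ols",
                      extra={"lambda": lam, "shift": shift,
                             "coef_ci": (float(ci_t[0]), float(ci_t[1])),
                             "coef_p": p, "levels": levels.tolist(),
                             "params": dict(zip(["const"] + names,
                                                map(float, fit.params)))})
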