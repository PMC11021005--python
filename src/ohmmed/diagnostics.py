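"""Pre-fit screening, model selection, fit-quality data and track comparison.

Everything here emits plot-ready tables (numpy arrays / pandas frames)
rather than figures: the autocorrelation permutation F-test that should be
run before fitting, adjacent-state significance tests on a fitted
annotation, the log-likelihood-by-K model-selection table, density/QQ and
rootogram data for goodness of fit, and cross-tabulation / Spearman
correlation of two annotations of the same windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_rng

__all__ = [
    "AutocorrReport",
    "autocorrelation_check",
    "neighbor_mean_significance",
    "model_selection_table",
    "fit_density_data",
    "rootogram_data",
    "compare_annotations",
]


@dataclass
class AutocorrReport:
    """Variance-of-differences autocorrelation screen.

    var_observed is the variance of consecutive-window differences on the
    observed ordering; var_permuted the median of the same statistic over
    random permutations.  Autocorrelated tracks change slowly, so
    var_observed is much smaller than var_permuted; the one-sided F-test
    (H1: var_observed < var_permuted) quantifies this with L - 2 degrees
    of freedom on each variance.
    """

    var_observed: float
    var_permuted: float
    f_statistic: float
    p_value: float
    perm_p_value: float
    n_permutations: int
    degenerate: bool = False


def autocorrelation_check(y, n_permutations: int = 25, seed=None) -> AutocorrReport:
    """Screen a track for the autocorrelation the ordered HMM assumes.

    Two p-values are reported.  ``p_value`` is the one-sided F-test of
    var_observed against the median permuted variance with (L-2, L-2)
    degrees of freedom; it resolves the extreme significance levels seen
    on genuinely autocorrelated genome tracks, but it is conservative
    under the null because both variances derive from the same data.
    ``perm_p_value`` is the empirical permutation p-value
    (1 + #{permutations with variance <= observed}) / (n + 1), which is
    exactly calibrated under exchangeability and should be used for
    borderline decisions.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 windows")
    rng = as_rng(seed)
    L = y.size
    var_obs = float(np.var(np.diff(y), ddof=1))
    perm_vars = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_vars[i] = np.var(np.diff(rng.permutation(y)), ddof=1)
    var_perm = float(np.median(perm_vars))
    perm_p = float((1 + np.sum(perm_vars <= var_obs)) / (n_permutations + 1))
    if var_perm == 0.0:
        return AutocorrReport(var_obs, var_perm, np.nan, 0.0, perm_p, n_permutations, degenerate=True)
    f = var_obs / var_perm
    df = L - 2
    p = float(stats.f.cdf(f, df, df))
    return AutocorrReport(var_obs, var_perm, f, p, perm_p, n_permutations)


def neighbor_mean_significance(y, assignment, family: str, level: float = 0.95) -> pd.DataFrame:
    """One-sided tests that each state's mean exceeds its lower neighbour's.

    Normal family: Welch two-sample t-test of mean(state i+1) > mean(state
    i) on the assigned observations.  Count family: exact conditional
    binomial comparison of two Poisson totals with exposures equal to the
    number of windows per state (the classic conditional test: given the
    combined total, the higher-state total is binomial with success
    probability proportional to its exposure).

    Returns K-1 rows: (state_low, state_high, statistic, p_value,
    significant, testable).
    """
    y = np.asarray(y, dtype=float)
    assignment = np.asarray(assignment)
    K = int(assignment.max()) + 1 if assignment.size else 0
    rows = []
    alpha = 1.0 - level
    for i in range(K - 1):
        a = y[assignment == i]
        b = y[assignment == i + 1]
        if a.size < 2 or b.size < 2:
            rows.append(
                {"state_low": i + 1, "state_high": i + 2, "statistic": np.nan,
                 "p_value": np.nan, "significant": False, "testable": False}
            )
            continue
        if family == "normal":
            res = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
            stat, p = float(res.statistic), float(res.pvalue)
        elif family == "gamma-poisson":
            tot_a, tot_b = int(a.sum()), int(b.sum())
            n = tot_a + tot_b
            p_null = b.size / (a.size + b.size)
            if n == 0:
                stat, p = 0.0, 1.0
            else:
                res = stats.binomtest(tot_b, n, p_null, alternative="greater")
                stat, p = float(tot_b), float(res.pvalue)
        else:
            raise ValueError(f"unknown family {family!r}")
        rows.append(
            {"state_low": i + 1, "state_high": i + 2, "statistic": stat,
             "p_value": p, "significant": bool(p < alpha), "testable": True}
        )
    return pd.DataFrame(rows, columns=["state_low", "state_high", "statistic",
                                       "p_value", "significant", "testable"])


def model_selection_table(fits, plateau_fraction: float = 0.1) -> pd.DataFrame:
    """Log-likelihood plateau table across candidate state counts.

    ``fits`` is a list of (K, trace, neighbor_table) or (K, trace) tuples;
    traces supply the retained log-likelihoods.  The table reports mean
    and median loglik per K, their gap (an autocorrelated-trace
    indicator), whether all adjacent-mean tests were significant, and a
    ``suggested`` flag on the smallest K that sits on the plateau
    (incremental mean-loglik gain < ``plateau_fraction`` of the previous
    increment) while remaining fully separated.  The suggestion is
    advisory; nothing is auto-selected.
    """
    rows = []
    seen = set()
    for entry in fits:
        K, trace = entry[0], entry[1]
        nbr = entry[2] if len(entry) > 2 else None
        if K in seen:
            raise ValueError(f"duplicate K={K}")
        seen.add(K)
        ll = np.asarray(trace.logliks if hasattr(trace, "logliks") else trace, dtype=float)
        sep = bool(nbr["significant"].all()) if nbr is not None and len(nbr) else None
        rows.append(
            {"K": K, "mean_loglik": float(np.mean(ll)), "median_loglik": float(np.median(ll)),
             "mean_median_gap": float(np.mean(ll) - np.median(ll)), "all_separated": sep}
        )
    tab = pd.DataFrame(rows).sort_values("K").reset_index(drop=True)
    tab["suggested"] = False
    if len(tab) >= 3:
        gains = np.diff(tab["mean_loglik"].to_numpy())
        for i in range(1, len(gains)):
            plateau = gains[i] < plateau_fraction * max(gains[i - 1], 0.0) or gains[i] <= 0
            sep = tab.loc[i, "all_separated"]
            if plateau and (sep is None or sep):
                tab.loc[i, "suggested"] = True
                break
    return tab


def _mixture_cdf(x, fit):
    params = fit.params()
    w = fit.occupancy
    if fit.family == "normal":
        return np.sum(w[None, :] * stats.norm.cdf(np.atleast_1d(x)[:, None],
                                                  loc=params.means[None, :], scale=params.sd), axis=1)
    n, p = params.nb_n_p()
    return np.sum(w[None, :] * stats.nbinom.cdf(np.atleast_1d(x)[:, None], n, p[None, :]), axis=1)


def _mixture_quantile(q, fit, lo, hi):
    """Numeric inversion of the fitted mixture CDF (monotone bisection)."""
    q = np.atleast_1d(q)
    lo_arr = np.full(q.shape, lo)
    hi_arr = np.full(q.shape, hi)
    for _ in range(200):
        mid = 0.5 * (lo_arr + hi_arr)
        c = _mixture_cdf(mid, fit)
        below = c < q
        lo_arr = np.where(below, mid, lo_arr)
        hi_arr = np.where(below, hi_arr, mid)
    return 0.5 * (lo_arr + hi_arr)


def fit_density_data(y, fit, grid_size: int = 512, n_qq: int = 199) -> dict:
    """Observed vs fitted-mixture density, state bands, and QQ pairs.

    The fitted mixture weights each state's emission density by its
    occupancy.  QQ pairs compare observed quantiles with fitted-mixture
    quantiles at 199 evenly spaced probability points.
    """
    y = np.asarray(y, dtype=float)
    params = fit.params()
    w = fit.occupancy
    lo = float(np.min(y)) - 4.0 * float(np.max(fit.state_sds))
    hi = float(np.max(y)) + 4.0 * float(np.max(fit.state_sds))
    if fit.family == "normal":
        grid = np.linspace(lo, hi, grid_size)
        fitted = np.sum(w[None, :] * stats.norm.pdf(grid[:, None], loc=params.means[None, :],
                                                    scale=params.sd), axis=1)
        observed = stats.gaussian_kde(y)(grid)
    else:
        grid = np.arange(0, int(np.max(y)) + 1, dtype=float)
        n, p = params.nb_n_p()
        fitted = np.sum(w[None, :] * stats.nbinom.pmf(grid[:, None], n, p[None, :]), axis=1)
        observed = np.bincount(y.astype(int), minlength=grid.size) / y.size

    probs = (np.arange(1, n_qq + 1)) / (n_qq + 1)
    obs_q = np.quantile(y, probs)
    fit_q = _mixture_quantile(probs, fit, lo, hi)
    bands = pd.DataFrame(
        {"state": np.arange(1, fit.K + 1), "mean": fit.state_means,
         "lower": fit.state_means - fit.state_sds, "upper": fit.state_means + fit.state_sds}
    )
    return {
        "grid": grid, "observed_density": observed, "fitted_density": fitted,
        "state_bands": bands,
        "qq": pd.DataFrame({"prob": probs, "observed": obs_q, "fitted": fit_q}),
    }


def rootogram_data(y, fit) -> pd.DataFrame:
    """Hanging-rootogram data for a count-family fit.

    For each count value: sqrt observed frequency, sqrt expected frequency
    under the fitted negative-binomial mixture, and the hanging deviation
    sqrt(expected) - sqrt(observed) — the distance of the hanging bar's
    lower end from the axis.
    """
    if fit.family != "gamma-poisson":
        raise ValueError("rootogram requires the count family")
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("rootogram requires non-negative integer counts")
    counts = y.astype(int)
    values = np.arange(0, counts.max() + 1)
    observed = np.bincount(counts, minlength=values.size).astype(float)
    params = fit.params()
    n, p = params.nb_n_p()
    expected = y.size * np.sum(fit.occupancy[None, :] * stats.nbinom.pmf(values[:, None], n, p[None, :]), axis=1)
    return pd.DataFrame(
        {"count": values, "sqrt_observed": np.sqrt(observed), "sqrt_expected": np.sqrt(expected),
         "deviation": np.sqrt(expected) - np.sqrt(observed)}
    )


def compare_annotations(fit_a, fit_b, rolling_width: int = 40) -> dict:
    """Compare two annotations of the same windows.

    Returns the K_A x K_B cross-tabulation of hard states, the Spearman
    correlation (with p-value) of the position-specific posterior means,
    and a rolling Spearman series over blocks of ``rolling_width``
    windows (length L - rolling_width + 1).
    """
    a_hard = np.asarray(fit_a.hard_assignment)
    b_hard = np.asarray(fit_b.hard_assignment)
    if a_hard.shape != b_hard.shape:
        raise ValueError("annotations cover different windows")
    L = a_hard.size
    ka, kb = fit_a.K, fit_b.K
    crosstab = pd.crosstab(
        pd.Series(a_hard + 1, name="state_a"), pd.Series(b_hard + 1, name="state_b")
    ).reindex(index=np.arange(1, ka + 1), columns=np.arange(1, kb + 1), fill_value=0)

    pa = np.asarray(fit_a.posterior_mean_track, dtype=float)
    pb = np.asarray(fit_b.posterior_mean_track, dtype=float)
    if np.array_equal(pa, pb):
        rho, pval = 1.0, 0.0
    else:
        rho, pval = stats.spearmanr(pa, pb)
    rolling = np.full(max(L - rolling_width + 1, 0), np.nan)
    for start in range(rolling.size):
        seg_a = pa[start : start + rolling_width]
        seg_b = pb[start : start + rolling_width]
        if np.ptp(seg_a) == 0 or np.ptp(seg_b) == 0:
            continue
        rolling[start] = stats.spearmanr(seg_a, seg_b)[0]
    return {"crosstab": crosstab, "spearman_rho": float(rho), "spearman_p": float(pval),
            "rolling_rho": rolling}
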