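"""Gibbs samplers for the ordered HMM with normal or gamma-Poisson emissions.

Each sweep draws a full hidden path by forward-filtering backward-sampling
(FFBS), then updates the emission parameters from their conjugate
conditionals (plus a Metropolis step for the shared gamma shape), enforces
the ascending-mean state ordering by a joint relabelling sort, and redraws
the tridiagonal transition rows from Dirichlet conditionals over their
band support.  The recorded per-iteration log-likelihood is the forward
marginal likelihood of the data given the current transition matrix and
emission parameters — marginalised over hidden states, and over the
latent Poisson intensities (negative-binomial marginal) for counts — so
that traces are comparable across K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from . import _kernels
from ._rng import as_rng
from .emissions import (
    GammaPoissonEmissionParams,
    NormalEmissionParams,
    check_convex_ordering,
    emission_log_density_matrix,
    sort_states,
)
from .model_core import TransitionMatrix, stationary_distribution, validate_transition_matrix
from .smoothing import forward_only

__all__ = [
    "PriorConfig",
    "MCMCConfig",
    "MCMCTrace",
    "FitResult",
    "initialize_chain",
    "sample_transition_matrix",
    "sample_normal_params",
    "sample_latent_rates",
    "sample_state_rates",
    "sample_shared_shape",
    "run_mcmc",
    "write_fit_summary",
    "write_trace_tsv",
]


@dataclass
class PriorConfig:
    """Hyperparameters of the (partially informative) priors.

    mean_prior : (location, scale) of the shared normal prior on each
        state mean (normal family).
    var_prior : (shape, scale) of the inverse-gamma prior on sigma^2.
    rate_prior : (shape, rate) of the gamma prior on each state rate beta_i.
    shape_prior : (shape, rate) of the gamma prior on the shared shape alpha.
    dirichlet_concentration : pseudo-count added to every allowed
        transition in the Dirichlet row conditionals.
    proposal_sd_log_alpha : sd of the Gaussian random walk on log(alpha).
    """

    mean_prior: tuple = (0.0, 10.0)
    var_prior: tuple = (2.0, 1.0)
    rate_prior: tuple = (1.0, 1.0)
    shape_prior: tuple = (1.0, 1.0)
    dirichlet_concentration: float = 1.0
    proposal_sd_log_alpha: float = 0.1

    def __post_init__(self):
        for name in ("mean_prior", "var_prior", "rate_prior", "shape_prior"):
            a, b = getattr(self, name)
            if b <= 0 or (name != "mean_prior" and a <= 0):
                raise ValueError(f"{name} must have positive shape/scale, got {(a, b)}")
        if self.dirichlet_concentration <= 0 or self.proposal_sd_log_alpha <= 0:
            raise ValueError("concentration and proposal sd must be positive")

    @classmethod
    def default_for(cls, y, family: str) -> "PriorConfig":
        """Diffuse conjugate priors centred on method-of-moments estimates."""
        y = np.asarray(y, dtype=float)
        m, v = float(np.mean(y)), float(np.var(y))
        if family == "normal":
            sd = max(np.sqrt(v), 1e-12)
            return cls(mean_prior=(m, 3.0 * sd), var_prior=(2.0, v))
        alpha_mom = m * m / (v - m) if v > m else 1.0
        alpha_mom = float(np.clip(alpha_mom, 1e-3, 1e6))
        beta_mom = alpha_mom / max(m, 1e-12)
        return cls(
            rate_prior=(1.0, 1.0 / beta_mom),
            shape_prior=(1.0, 1.0 / alpha_mom),
        )


@dataclass
class MCMCConfig:
    """Run-length and reproducibility settings of a sampler run."""

    n_iter: int
    K: int
    family: str = "normal"
    burnin_fraction: float = 0.2
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if self.n_iter * (1.0 - self.burnin_fraction) < 1.0:
            raise ValueError("no retained iterations: n_iter * (1 - burnin) < 1")
        if self.family not in ("normal", "gamma-poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.K < 1 or self.thin < 1:
            raise ValueError("K and thin must be positive")

    @property
    def n_burnin(self) -> int:
        return int(round(self.n_iter * self.burnin_fraction))


@dataclass
class MCMCTrace:
    """Per-retained-iteration parameter draws and log-likelihoods."""

    family: str
    logliks: np.ndarray
    transition_matrices: np.ndarray  # (n, K, K)
    means: np.ndarray | None = None  # normal: (n, K)
    sds: np.ndarray | None = None  # normal: (n,)
    shapes: np.ndarray | None = None  # gamma-poisson: (n,)
    rates: np.ndarray | None = None  # gamma-poisson: (n, K)
    shape_accepted: np.ndarray | None = None  # gamma-poisson MH flags

    def __len__(self) -> int:
        return self.logliks.shape[0]

    def state_means(self) -> np.ndarray:
        if self.family == "normal":
            return self.means
        return self.shapes[:, None] / self.rates


@dataclass
class FitResult:
    """Posterior summaries of a converged run.

    gamma_mean is the across-iteration average of the per-sweep smoothing
    probabilities, i.e. a Monte-Carlo estimate of Pr(theta_l = i | y);
    hard_assignment is its per-position argmax (0-based), occupancy the
    fraction of positions per hard state, and posterior_mean_track the
    sum over states of gamma times the posterior-mean state means.
    """

    family: str
    K: int
    summary: pd.DataFrame
    gamma_mean: np.ndarray
    hard_assignment: np.ndarray
    posterior_mean_track: np.ndarray
    occupancy: np.ndarray
    mean_run_length: np.ndarray
    P_mean: np.ndarray
    state_means: np.ndarray
    state_sds: np.ndarray
    config: MCMCConfig | None = field(default=None, repr=False)

    def params(self):
        """Posterior-mean emission parameters as a parameter object."""
        s = self.summary.set_index("parameter")["mean"]
        if self.family == "normal":
            means = np.array([s[f"mean_{i + 1}"] for i in range(self.K)])
            return NormalEmissionParams(means=means, sd=float(s["sd"]), checked=False)
        rates = np.array([s[f"rate_{i + 1}"] for i in range(self.K)])
        return GammaPoissonEmissionParams(shape=float(s["shape"]), rates=rates, checked=False)


def initialize_chain(y, K: int, family: str, priors: PriorConfig | None = None, seed=None):
    """Deterministic-given-seed starting point for a sampler run.

    State means start at the (1..K)/(K+1) sample quantiles; the transition
    matrix starts with 0.8 on the diagonal and the remainder split equally
    over the 1--2 allowed neighbours; the path assigns each observation to
    the nearest initial state mean.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("y is empty")
    if K < 1:
        raise ValueError("K must be >= 1")
    import warnings

    if family == "normal" and np.unique(y).size < K:
        warnings.warn(f"K={K} exceeds the number of distinct values in y", stacklevel=2)

    qs = np.quantile(y, (np.arange(K) + 1.0) / (K + 1.0))
    # force strict increase for degenerate samples
    eps = max(1e-6, 1e-6 * (np.max(y) - np.min(y) + 1.0))
    for i in range(1, K):
        if qs[i] <= qs[i - 1]:
            qs[i] = qs[i - 1] + eps

    P = np.zeros((K, K))
    for i in range(K):
        lo, hi = max(0, i - 1), min(K - 1, i + 1)
        n_nb = hi - lo
        P[i, i] = 0.8 if n_nb else 1.0
        for j in range(lo, hi + 1):
            if j != i:
                P[i, j] = 0.2 / n_nb
    T = TransitionMatrix(P, checked=False)

    path = np.argmin(np.abs(y[:, None] - qs[None, :]), axis=1).astype(np.int64)

    if family == "normal":
        sd0 = float(np.std(y)) or 1.0
        params = NormalEmissionParams(means=qs, sd=sd0, checked=False)
    elif family == "gamma-poisson":
        m, v = float(np.mean(y)), float(np.var(y))
        alpha0 = float(np.clip(m * m / (v - m) if v > m else 1.0, 1e-3, 1e6))
        means0 = np.clip(qs, 0.05, None)
        rates0 = alpha0 / means0
        params = GammaPoissonEmissionParams(shape=alpha0, rates=rates0, checked=False)
    else:
        raise ValueError(f"unknown family {family!r}")
    return params, T, path


def sample_transition_matrix(path, K: int, concentration: float = 1.0, seed=None) -> TransitionMatrix:
    """Draw tridiagonal transition rows from their Dirichlet conditionals.

    Row i is Dirichlet(counts + concentration) over the band support
    {i-1, i, i+1}; entries outside the band are structural zeros.  Paths
    with a non-adjacent transition are rejected with an error (they cannot
    arise from FFBS under a tridiagonal matrix).
    """
    path = np.ascontiguousarray(np.asarray(path, dtype=np.int64))
    if path.size and (path.min() < 0 or path.max() >= K):
        raise ValueError("path labels out of range 0..K-1")
    if path.size > 1 and np.any(np.abs(np.diff(path)) > 1):
        bad = int(np.nonzero(np.abs(np.diff(path)) > 1)[0][0])
        raise ValueError(f"non-adjacent transition at position {bad}")
    counts = _kernels.transition_counts(path, K)
    return _sample_rows_from_counts(counts, concentration, as_rng(seed))


def _sample_rows_from_counts(counts, concentration, rng) -> TransitionMatrix:
    K = counts.shape[0]
    P = np.zeros((K, K))
    for i in range(K):
        lo, hi = max(0, i - 1), min(K - 1, i + 1)
        alpha = counts[i, lo : hi + 1].astype(float) + concentration
        P[i, lo : hi + 1] = rng.dirichlet(alpha)
    return TransitionMatrix(P, checked=False)


def sample_normal_params(y, path, K: int, sd: float, priors: PriorConfig, seed=None):
    """Conjugate draws of the state means and the shared sd.

    Each mean comes from its normal conditional given the observations
    currently assigned to that state and the current sigma; sigma^2 then
    comes from the inverse-gamma conditional pooling residuals across all
    states (computed with the freshly drawn means).  Empty states fall
    back to prior draws.  Draws are unconstrained; ordering is enforced
    afterwards by the joint relabelling sort.
    """
    rng = as_rng(seed)
    y = np.asarray(y, dtype=float)
    path = np.asarray(path)
    m0, s0 = priors.mean_prior
    a0, b0 = priors.var_prior

    counts = np.bincount(path, minlength=K).astype(float)
    sums = np.bincount(path, weights=y, minlength=K)
    prec = 1.0 / s0**2 + counts / sd**2
    post_mean = (m0 / s0**2 + sums / sd**2) / prec
    means = rng.normal(loc=post_mean, scale=np.sqrt(1.0 / prec))

    ssr = float(np.sum((y - means[path]) ** 2))
    var = stats.invgamma.rvs(a=a0 + y.size / 2.0, scale=b0 + ssr / 2.0, random_state=rng)
    return means, float(np.sqrt(var))


def sample_latent_rates(y, path, shape: float, rates, seed=None) -> np.ndarray:
    """Per-position Poisson intensities: ``lambda_l ~ Gamma(alpha + y_l, beta_{s_l} + 1)``."""
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    rng = as_rng(seed)
    rates = np.asarray(rates, dtype=float)
    lam = rng.gamma(shape=shape + y, scale=1.0 / (rates[np.asarray(path)] + 1.0))
    return np.clip(lam, 1e-300, None)


def sample_state_rates(lam, path, K: int, shape: float, rate_prior, seed=None) -> np.ndarray:
    """Conjugate draws of the state rates.

    ``beta_i ~ Gamma(a0 + n_i alpha, b0 + sum of lambda over state i)``;
    empty states draw from the prior.  Unconstrained; ordering follows in
    the joint sort.
    """
    rng = as_rng(seed)
    lam = np.asarray(lam, dtype=float)
    path = np.asarray(path)
    a0, b0 = rate_prior
    counts = np.bincount(path, minlength=K).astype(float)
    lam_sums = np.bincount(path, weights=lam, minlength=K)
    return rng.gamma(shape=a0 + counts * shape, scale=1.0 / (b0 + lam_sums))


def _log_target_shape(alpha, lam_log_sum, beta_log_weighted, L, shape_prior):
    c0, d0 = shape_prior
    return (
        (c0 - 1.0) * np.log(alpha)
        - d0 * alpha
        + alpha * beta_log_weighted
        - L * gammaln(alpha)
        + (alpha - 1.0) * lam_log_sum
    )


def sample_shared_shape(lam, path, rates, shape: float, priors: PriorConfig, seed=None):
    """Metropolis--Hastings step for the shared gamma shape alpha.

    Random walk on log(alpha) with Gaussian proposal; the acceptance ratio
    includes the log-scale Jacobian (a factor alpha'/alpha).  The target is
    the gamma prior times the product over positions of
    ``Gamma(lambda_l; alpha, beta_{s_l})``.
    Returns (new alpha, accepted flag).
    """
    rng = as_rng(seed)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("latent rates must be positive")
    rates = np.asarray(rates, dtype=float)
    path = np.asarray(path)
    L = lam.size
    lam_log_sum = float(np.sum(np.log(lam)))
    beta_log_weighted = float(np.sum(np.log(rates[path])))

    prop = shape * np.exp(rng.normal(0.0, priors.proposal_sd_log_alpha))
    log_ratio = (
        _log_target_shape(prop, lam_log_sum, beta_log_weighted, L, priors.shape_prior)
        - _log_target_shape(shape, lam_log_sum, beta_log_weighted, L, priors.shape_prior)
        + np.log(prop)
        - np.log(shape)
    )
    if np.log(rng.random()) < log_ratio:
        return float(prop), True
    return float(shape), False


def _mean_run_length(path, K) -> np.ndarray:
    """Average length of maximal constant runs, per state."""
    path = np.asarray(path)
    if path.size == 0:
        return np.full(K, np.nan)
    change = np.nonzero(np.diff(path) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [path.size]])
    lengths = ends - starts
    labels = path[starts]
    out = np.full(K, np.nan)
    for i in range(K):
        sel = labels == i
        if np.any(sel):
            out[i] = float(np.mean(lengths[sel]))
    return out


def _summarize(draws: dict) -> pd.DataFrame:
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(arr)),
                "median": float(np.median(arr)),
                "sd": float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
                "q2.5": float(np.quantile(arr, 0.025)),
                "q97.5": float(np.quantile(arr, 0.975)),
            }
        )
    return pd.DataFrame(rows)


def run_mcmc(y, K: int, family: str | None = None, config: MCMCConfig | None = None,
             priors: PriorConfig | None = None, progress=None):
    """Run the full Gibbs sampler and summarize the posterior.

    Per iteration: (1) emission log densities under the current parameters
    feed a forward pass whose marginal log-likelihood is recorded together
    with those parameters, and a full hidden path is drawn by backward
    sampling; (2) emission parameters are redrawn from their conditionals
    (latent intensities, rates and the shape MH step for counts); (3) the
    joint relabelling sort restores ascending-mean order across
    parameters, transition counts and path; (4) the tridiagonal transition
    rows are redrawn from Dirichlet conditionals on the sorted counts.
    Burn-in and thinning follow the config.  Identical seeds give
    identical results.

    Returns (FitResult, MCMCTrace).
    """
    if config is None:
        config = MCMCConfig(n_iter=1000, K=K, family=family or "normal")
    family = config.family
    if config.K != K:
        raise ValueError("config.K disagrees with K")
    y = np.asarray(y, dtype=float if family == "normal" else np.float64)
    if family == "gamma-poisson":
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("gamma-poisson family requires non-negative integer counts")
    if priors is None:
        priors = PriorConfig.default_for(y, family)

    rng = as_rng(config.seed)
    L = y.size
    params, T, path = initialize_chain(y, K, family, priors, seed=rng)
    pi = stationary_distribution(T.P) if K > 1 else np.ones(1)
    conc = priors.dirichlet_concentration

    if family == "gamma-poisson":
        lam = np.clip(y.astype(float), 0.1, None)

    n_ret = len(range(config.n_burnin, config.n_iter, config.thin))
    logliks = np.empty(n_ret)
    trace_P = np.empty((n_ret, K, K))
    gamma_sum = np.zeros((L, K))
    if family == "normal":
        trace_means = np.empty((n_ret, K))
        trace_sds = np.empty(n_ret)
    else:
        trace_shapes = np.empty(n_ret)
        trace_rates = np.empty((n_ret, K))
        trace_accept = np.zeros(n_ret, dtype=bool)

    retained = 0
    for it in range(config.n_iter):
        record = it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0

        if family == "normal":
            logdens = emission_log_density_matrix(y, params, mode="normal")
        else:
            logdens = emission_log_density_matrix(lam, params, mode="gamma-on-latent-rates")
        alpha_msgs, scalings, ll_cond = forward_only(logdens, T.P, pi)
        if progress is not None and it % max(config.n_iter // 20, 1) == 0:
            progress(it, ll_cond)

        if record:
            if family == "normal":
                logliks[retained] = ll_cond
                trace_means[retained] = params.means
                trace_sds[retained] = params.sd
            else:
                nb_logdens = emission_log_density_matrix(y, params, mode="negative-binomial-marginal")
                _, _, ll_marg = forward_only(nb_logdens, T.P, pi)
                logliks[retained] = ll_marg
                trace_shapes[retained] = params.shape
                trace_rates[retained] = params.rates
            trace_P[retained] = T.P
            b = np.exp(logdens - np.max(logdens, axis=1)[:, None])
            gamma_sum += _kernels.backward_smooth(alpha_msgs, np.ascontiguousarray(b), T.P, scalings)

        u = rng.random(L)
        path = _kernels.sample_path_from_messages(alpha_msgs, T.P, u)

        if family == "normal":
            means, sd = sample_normal_params(y, path, K, params.sd, priors, seed=rng)
            params = NormalEmissionParams(means=means, sd=sd, checked=False)
        else:
            lam = sample_latent_rates(y, path, params.shape, params.rates, seed=rng)
            rates = sample_state_rates(lam, path, K, params.shape, priors.rate_prior, seed=rng)
            new_shape, accepted = sample_shared_shape(
                lam, path, rates, params.shape, priors, seed=rng
            )
            params = GammaPoissonEmissionParams(shape=new_shape, rates=rates, checked=False)
            if record:
                trace_accept[retained] = accepted

        counts = _kernels.transition_counts(path, K)
        params, counts, path, _, _ = sort_states(params, counts, path)
        T = _sample_rows_from_counts(counts, conc, rng)
        pi = stationary_distribution(T.P) if K > 1 else np.ones(1)

        if record:
            retained += 1

    gamma_mean = gamma_sum / retained
    gamma_mean /= gamma_mean.sum(axis=1, keepdims=True)
    hard = np.argmax(gamma_mean, axis=1).astype(np.int64)

    if family == "normal":
        trace = MCMCTrace(
            family=family, logliks=logliks, transition_matrices=trace_P,
            means=trace_means, sds=trace_sds,
        )
        draws = {f"mean_{i + 1}": trace_means[:, i] for i in range(K)}
        draws["sd"] = trace_sds
        post_state_means = trace_means.mean(axis=0)
        post_state_sds = np.full(K, trace_sds.mean())
    else:
        trace = MCMCTrace(
            family=family, logliks=logliks, transition_matrices=trace_P,
            shapes=trace_shapes, rates=trace_rates, shape_accepted=trace_accept,
        )
        draws = {"shape": trace_shapes}
        draws.update({f"rate_{i + 1}": trace_rates[:, i] for i in range(K)})
        draws.update(
            {f"state_mean_{i + 1}": trace_shapes / trace_rates[:, i] for i in range(K)}
        )
        post_state_means = (trace_shapes[:, None] / trace_rates).mean(axis=0)
        a_hat, b_hat = trace_shapes.mean(), trace_rates.mean(axis=0)
        post_state_sds = np.sqrt(a_hat * (1.0 + b_hat) / b_hat**2)
    for i in range(K):
        lo, hi = max(0, i - 1), min(K - 1, i + 1)
        for j in range(lo, hi + 1):
            draws[f"T_{i + 1}{j + 1}"] = trace_P[:, i, j]
    draws["loglik"] = logliks

    occupancy = np.bincount(hard, minlength=K) / L
    fit = FitResult(
        family=family,
        K=K,
        summary=_summarize(draws),
        gamma_mean=gamma_mean,
        hard_assignment=hard,
        posterior_mean_track=gamma_mean @ post_state_means,
        occupancy=occupancy,
        mean_run_length=_mean_run_length(hard, K),
        P_mean=trace_P.mean(axis=0),
        state_means=post_state_means,
        state_sds=post_state_sds,
        config=config,
    )
    return fit, trace


def write_fit_summary(fit: FitResult, path) -> None:
    """JSON parameter summary of a fit (scalars and small arrays only)."""
    payload = {
        "family": fit.family,
        "K": fit.K,
        "summary": fit.summary.to_dict(orient="records"),
        "occupancy": fit.occupancy.tolist(),
        "mean_run_length": fit.mean_run_length.tolist(),
        "state_means": fit.state_means.tolist(),
        "state_sds": fit.state_sds.tolist(),
        "P_mean": fit.P_mean.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_trace_tsv(trace: MCMCTrace, path) -> None:
    """Trace as TSV: one row per retained iteration."""
    cols = {"iteration": np.arange(len(trace)), "loglik": trace.logliks}
    if trace.family == "normal":
        for i in range(trace.means.shape[1]):
            cols[f"mean_{i + 1}"] = trace.means[:, i]
        cols["sd"] = trace.sds
    else:
        cols["shape"] = trace.shapes
        for i in range(trace.rates.shape[1]):
            cols[f"rate_{i + 1}"] = trace.rates[:, i]
        cols["shape_accepted"] = trace.shape_accepted.astype(int)
    K = trace.transition_matrices.shape[1]
    for i in range(K):
        for j in range(max(0, i - 1), min(K - 1, i + 1) + 1):
            cols[f"T_{i + 1}{j + 1}"] = trace.transition_matrices[:, i, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def check_trace_invariants(trace: MCMCTrace) -> dict:
    """Audit a trace: ordering, tridiagonality and finite logliks.

    Returns counts of violations; all zero for a healthy run.
    """
    n_order = 0
    n_band = 0
    K = trace.transition_matrices.shape[1]
    band = np.abs(np.subtract.outer(np.arange(K), np.arange(K))) <= 1
    for t in range(len(trace)):
        if trace.family == "normal":
            p = NormalEmissionParams(means=trace.means[t], sd=trace.sds[t], checked=False)
        else:
            p = GammaPoissonEmissionParams(shape=trace.shapes[t], rates=trace.rates[t], checked=False)
        ok, _ = check_convex_ordering(p)
        n_order += not ok
        P = trace.transition_matrices[t]
        report = validate_transition_matrix(P)
        n_band += 0 if report.ok else 1
        if np.any(P[~band] != 0.0):
            n_band += 1
    return {
        "ordering_violations": n_order,
        "transition_violations": n_band,
        "nonfinite_logliks": int(np.sum(~np.isfinite(trace.logliks))),
    }
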