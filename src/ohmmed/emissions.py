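"""Convex emission families: shared-dispersion normal and gamma-Poisson.

Both families satisfy a likelihood-ratio monotonicity condition — for
states i < j and observations a < b,
``logdens(a|i) - logdens(a|j) >= logdens(b|i) - logdens(b|j)`` — which is
what makes a total ordering of hidden states by emitted mean well defined.
For normals this requires a shared standard deviation and strictly
increasing means; for gammas a shared shape and strictly decreasing rates
(state means ``alpha / beta_i`` then increase).  Counts arise by drawing a
Poisson intensity from the state's gamma, so the marginal count law is a
negative binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NormalEmissionParams",
    "GammaPoissonEmissionParams",
    "emission_log_density_matrix",
    "check_convex_ordering",
    "sort_states",
]


@dataclass(frozen=True)
class NormalEmissionParams:
    """State-specific means with one shared standard deviation."""

    means: np.ndarray
    sd: float
    checked: bool = field(default=True, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        if self.checked:
            if self.sd <= 0:
                raise ValueError(f"sd must be positive, got {self.sd}")
            ok, pair = check_convex_ordering(self)
            if not ok:
                raise ValueError(f"means not strictly increasing at states {pair}")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def state_means(self) -> np.ndarray:
        return self.means

    @property
    def state_sds(self) -> np.ndarray:
        return np.full(self.K, self.sd)


@dataclass(frozen=True)
class GammaPoissonEmissionParams:
    """Shared gamma shape ``alpha`` with state-specific rates ``beta_i``.

    State i emits a latent Poisson intensity ``lambda ~ Gamma(alpha,
    beta_i)`` (shape--rate parameterisation, mean ``alpha / beta_i``), then
    a count ``y ~ Poisson(lambda)``.  Rates are strictly decreasing so the
    state means increase.
    """

    shape: float
    rates: np.ndarray
    checked: bool = field(default=True, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if self.checked:
            if self.shape <= 0:
                raise ValueError(f"shape must be positive, got {self.shape}")
            if np.any(self.rates <= 0):
                raise ValueError("all rates must be positive")
            ok, pair = check_convex_ordering(self)
            if not ok:
                raise ValueError(f"rates not strictly decreasing at states {pair}")

    @property
    def K(self) -> int:
        return self.rates.shape[0]

    @property
    def state_means(self) -> np.ndarray:
        return self.shape / self.rates

    @property
    def state_sds(self) -> np.ndarray:
        # marginal (negative binomial) sd: var = alpha (1 + beta) / beta^2
        return np.sqrt(self.shape * (1.0 + self.rates) / self.rates**2)

    def nb_n_p(self):
        """Parameters (n, p) of the marginal scipy ``nbinom`` per state."""
        return self.shape, self.rates / (1.0 + self.rates)


def _require_counts(y: np.ndarray) -> np.ndarray:
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("count modes require non-negative integer observations")
    return y.astype(np.int64)


def emission_log_density_matrix(y, params, mode: str | None = None) -> np.ndarray:
    """L x K matrix of per-position, per-state emission log densities.

    Modes
    -----
    ``"normal"``
        ``y`` real; Normal(mean_i, sd) log pdf.
    ``"negative-binomial-marginal"``
        ``y`` non-negative integer counts; log pmf of the gamma-Poisson
        marginal (negative binomial with size ``alpha`` and success
        probability ``beta_i / (1 + beta_i)``).
    ``"gamma-on-latent-rates"``
        ``y`` holds positive latent Poisson intensities; Gamma(alpha,
        beta_i) log pdf.  This is the emission term the sampler conditions
        on inside a Gibbs sweep.

    The mode defaults to the natural one for the parameter family.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be one-dimensional")
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    if mode is None:
        mode = "normal" if isinstance(params, NormalEmissionParams) else "negative-binomial-marginal"

    if mode == "normal":
        return stats.norm.logpdf(y[:, None], loc=params.means[None, :], scale=params.sd)
    if mode == "negative-binomial-marginal":
        counts = _require_counts(y)
        n, p = params.nb_n_p()
        return stats.nbinom.logpmf(counts[:, None], n, p[None, :])
    if mode == "gamma-on-latent-rates":
        if np.any(y <= 0):
            raise ValueError("latent rates must be strictly positive")
        return stats.gamma.logpdf(y[:, None], a=params.shape, scale=1.0 / params.rates[None, :])
    raise ValueError(f"unknown mode {mode!r}")


def check_convex_ordering(params):
    """Whether the parameters admit the state ordering; first bad pair if not.

    Returns ``(True, None)`` when normal means are strictly increasing /
    gamma rates strictly decreasing, else ``(False, (i, i+1))`` with the
    first offending adjacent pair (0-based state indices).
    """
    if isinstance(params, NormalEmissionParams):
        v = np.asarray(params.means, dtype=float)
        bad = np.nonzero(np.diff(v) <= 0)[0]
    elif isinstance(params, GammaPoissonEmissionParams):
        v = np.asarray(params.rates, dtype=float)
        bad = np.nonzero(np.diff(v) >= 0)[0]
    else:
        raise TypeError(f"unknown emission parameter type {type(params)!r}")
    if bad.size:
        i = int(bad[0])
        return False, (i, i + 1)
    return True, None


def sort_states(params, matrix=None, path=None):
    """Relabel states into ascending-mean order, permuting everything consistently.

    Parameters
    ----------
    params : NormalEmissionParams | GammaPoissonEmissionParams
        Possibly unordered parameters (construct with ``checked=False``).
    matrix : ndarray, optional
        K x K transition matrix or transition-count matrix; rows and
        columns are permuted together.
    path : ndarray, optional
        State sequence (0-based labels); relabelled through the same
        permutation.

    Returns
    -------
    (params, matrix, path, perm) where ``perm`` is the permutation applied
    (new state k was old state ``perm[k]``), plus a ``ties`` flag on exact
    mean ties (broken stably by original index).
    """
    means = np.asarray(params.state_means, dtype=float)
    K = means.shape[0]
    perm = np.argsort(means, kind="stable")
    ties = bool(np.any(np.diff(means[perm]) == 0))

    if isinstance(params, NormalEmissionParams):
        new_params = NormalEmissionParams(means=params.means[perm], sd=params.sd, checked=False)
    else:
        new_params = GammaPoissonEmissionParams(shape=params.shape, rates=params.rates[perm], checked=False)

    new_matrix = None
    if matrix is not None:
        matrix = np.asarray(matrix)
        if matrix.shape != (K, K):
            raise ValueError(f"matrix shape {matrix.shape} inconsistent with K={K}")
        new_matrix = matrix[np.ix_(perm, perm)]

    new_path = None
    if path is not None:
        path = np.asarray(path)
        inverse = np.empty(K, dtype=np.int64)
        inverse[perm] = np.arange(K)
        new_path = inverse[path]

    return new_params, new_matrix, new_path, perm, ties
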