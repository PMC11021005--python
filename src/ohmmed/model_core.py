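"""Tridiagonal transition-matrix structure, stationarity and reversibility.

The hidden chain of an ordered HMM moves only between order-neighbour
states, so its transition matrix is tridiagonal.  A tridiagonal stochastic
matrix is the transition kernel of a birth--death chain, which is always
reversible with respect to its stationary distribution; the helpers here
validate that structure, solve for the stationary distribution and measure
the detailed-balance residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionMatrix",
    "ValidationReport",
    "validate_transition_matrix",
    "stationary_distribution",
    "detailed_balance_residual",
    "free_parameter_count",
    "random_tridiagonal_matrix",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """A K x K row-stochastic tridiagonal transition matrix.

    Parameters
    ----------
    P : ndarray of shape (K, K)
        Row-stochastic matrix; entries outside the tridiagonal band must be
        exactly zero.  Constructed via ``TransitionMatrix(P)``; set
        ``checked=False`` to skip validation (used internally by samplers
        that construct the band structurally).
    """

    P: np.ndarray
    checked: bool = field(default=True, compare=False)

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        if self.checked:
            report = validate_transition_matrix(P)
            if not report.ok:
                raise ValueError(f"invalid transition matrix: {report.summary()}")

    @property
    def K(self) -> int:
        return self.P.shape[0]

    def stationary(self) -> np.ndarray:
        return stationary_distribution(self)


@dataclass
class ValidationReport:
    """Outcome of structural validation of a candidate transition matrix.

    ``violations`` lists human-readable descriptions; an empty list means
    the matrix is a valid fitted matrix (row-stochastic, tridiagonal,
    irreducible).  ``warnings`` carries non-fatal notes.
    """

    violations: list
    warnings: list

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        return "; ".join(self.violations) if self.violations else "valid"


def validate_transition_matrix(P, tol: float = ROW_SUM_TOL) -> ValidationReport:
    """Check row sums, tridiagonal support and irreducibility of ``P``.

    Row sums are checked to ``tol``; tridiagonality is checked exactly
    (the samplers construct the off-band zeros structurally, so any
    non-zero there is a genuine defect).  Zero sub/super-diagonal entries
    make the chain reducible and are reported as violations.

    Raises
    ------
    ValueError
        If ``P`` is not a finite square matrix (a structural error, as
        opposed to a validation failure).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValueError("transition matrix contains non-finite entries")
    K = P.shape[0]
    violations, warnings = [], []

    row_sums = P.sum(axis=1)
    for i in np.nonzero(np.abs(row_sums - 1.0) > tol)[0]:
        violations.append(f"row {i} sums to {row_sums[i]:.17g}, not 1")
    if np.any(P < 0):
        violations.append("negative entries present")

    band = np.abs(np.subtract.outer(np.arange(K), np.arange(K))) <= 1
    off_band = P[~band]
    if off_band.size and np.any(off_band != 0.0):
        violations.append("non-zero entries outside the tridiagonal band")

    if K > 1:
        sub = np.diag(P, k=-1)
        sup = np.diag(P, k=1)
        zeros = [f"P[{i},{i + 1}]" for i in np.nonzero(sup == 0.0)[0]]
        zeros += [f"P[{i + 1},{i}]" for i in np.nonzero(sub == 0.0)[0]]
        if zeros:
            violations.append(
                "reducible: zero off-diagonal entries " + ", ".join(sorted(zeros))
            )
    return ValidationReport(violations=violations, warnings=warnings)


def stationary_distribution(P) -> np.ndarray:
    """Stationary distribution pi of an irreducible tridiagonal matrix.

    Solves the linear system ``pi P = pi`` with ``sum(pi) = 1`` directly
    (replace one balance equation by the normalisation constraint), which
    is deterministic and exact to solver tolerance.

    Raises
    ------
    ValueError
        If the matrix is reducible (a zero sub/super-diagonal entry); the
        error names the offending entry.
    """
    if isinstance(P, TransitionMatrix):
        P = P.P
    P = np.asarray(P, dtype=float)
    report = validate_transition_matrix(P)
    if not report.ok:
        raise ValueError(f"cannot compute stationary distribution: {report.summary()}")
    K = P.shape[0]
    # (P^T - I) pi = 0 with the last row replaced by sum(pi) = 1
    A = P.T - np.eye(K)
    A[-1, :] = 1.0
    b = np.zeros(K)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return pi


def detailed_balance_residual(P, pi) -> float:
    """max over (i, j) of ``|pi_i P_ij - pi_j P_ji|``.

    Zero iff the chain is exactly reversible with respect to ``pi``.  Any
    tridiagonal stochastic matrix paired with its own stationary
    distribution is reversible (birth--death chain), so the residual is a
    numerical audit of that theorem.
    """
    if isinstance(P, TransitionMatrix):
        P = P.P
    P = np.asarray(P, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if P.shape[0] != P.shape[1] or pi.shape[0] != P.shape[0]:
        raise ValueError(
            f"dimension mismatch: P is {P.shape}, pi has length {pi.shape[0]}"
        )
    flux = pi[:, None] * P
    return float(np.max(np.abs(flux - flux.T)))


def free_parameter_count(K: int, model: str = "ordered", family: str = "normal") -> int:
    """Number of free parameters of the K-state HMM.

    The ordered model has K state-specific location parameters plus one
    shared dispersion parameter (K + 1 emission parameters), a tridiagonal
    transition matrix with 2K - 2 free entries, and a stationary initial
    distribution determined by reversibility: 3K - 1 in total.  The
    unordered counterpart has 2K emission parameters, K^2 - K transition
    entries and K - 1 initial probabilities: K(K + 2) - 1.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if model == "ordered":
        return 3 * K - 1
    if model == "unordered":
        return K * (K + 2) - 1
    raise ValueError(f"unknown model {model!r}")


def random_tridiagonal_matrix(K: int, seed=None, diag: float | None = None) -> TransitionMatrix:
    """Draw a random row-stochastic tridiagonal matrix with positive band.

    If ``diag`` is given, each row keeps probability ``diag`` on the
    diagonal (boundary rows renormalised accordingly); otherwise row
    entries on the band are drawn from a Dirichlet(1,..,1).
    """
    from ._rng import as_rng

    rng = as_rng(seed)
    P = np.zeros((K, K))
    for i in range(K):
        lo, hi = max(0, i - 1), min(K - 1, i + 1)
        width = hi - lo + 1
        if diag is None:
            row = rng.dirichlet(np.ones(width))
        else:
            row = np.full(width, (1.0 - diag) / max(width - 1, 1))
            row[i - lo] = diag if width > 1 else 1.0
            row /= row.sum()
        P[i, lo : hi + 1] = row
    return TransitionMatrix(P)


def write_matrix_tsv(P, path) -> None:
    """Serialize a matrix as TSV with a ``#K=<int>`` header line.

    Values are written at 17 significant digits so that reading the file
    back reproduces the float64 entries bit-exactly.
    """
    if isinstance(P, TransitionMatrix):
        P = P.P
    P = np.asarray(P, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"#K={P.shape[0]}\n")
        for row in P:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix_tsv(path) -> np.ndarray:
    """Read a matrix written by :func:`write_matrix_tsv`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#K="):
            raise ValueError(f"missing #K= header in {path}")
        K = int(header[3:])
        rows = [
            [float(v) for v in line.split("\t")] for line in fh if line.strip()
        ]
    P = np.array(rows, dtype=float)
    if P.shape != (K, K):
        raise ValueError(f"matrix shape {P.shape} does not match header K={K}")
    return P
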