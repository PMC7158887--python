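"""Random-walk-with-restart (RWR) proximity on a composed network.

The proximity of every vertex to a seed set ``Q`` is the fixed point of

    x = (1 - alpha) * W @ x + alpha * r

where ``W`` is the column-stochastic matrix of the network (each nonzero
column of the adjacency matrix divided by its sum), ``r`` is the restart
vector (1 on seeds, 0 elsewhere) and ``alpha`` in (0, 1] is the restart
probability controlling locality.  Two solvers are provided:

* plain power iteration, whose error contracts at least by ``1 - alpha`` per
  step, and
* a Chebyshev semi-iterative acceleration of the same splitting, which
  reaches the same fixed point in substantially fewer iterations; its
  asymptotic convergence factor ``mu(alpha) = 2(1-alpha)/(2 + sqrt(2*alpha -
  alpha^2))`` is strictly below ``1 - alpha``.

Zero-degree (dangling) columns are left as zero columns: the iteration then
leaks probability mass but still converges, because the restart term keeps
the iteration operator's norm at ``1 - alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .builder import VertexRegistry
from .core import GraphInputError
from .integrate import PlainCSR

__all__ = [
    "StochasticOperator",
    "ProximityVector",
    "ConvergenceError",
    "column_stochastic",
    "restart_vector",
    "rwr_power",
    "rwr_chebyshev",
    "convergence_factor",
    "rank_vertices",
]

_NORMS = {
    "l1": lambda v: float(np.linalg.norm(v, 1)),
    "l2": lambda v: float(np.linalg.norm(v)),
    "linf": lambda v: float(np.linalg.norm(v, np.inf)),
}


class ConvergenceError(RuntimeError):
    """Raised when a solver exhausts its iteration budget."""

    def __init__(self, message: str, residual: float, iterations: int) -> None:
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


@dataclass
class StochasticOperator:
    """Column-normalized weight structure of a network."""

    W: sparse.csr_matrix
    dangling: np.ndarray  # zero-degree column indices

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class ProximityVector:
    """An RWR solution with its convergence diagnostics."""

    x: np.ndarray
    iterations: int
    residual: float
    method: str
    vertex_ids: np.ndarray | None = None


def column_stochastic(net: PlainCSR) -> StochasticOperator:
    """Normalize each nonzero column of the network's weights to sum to 1."""
    mat = net.matrix
    if mat.nnz and float(mat.data.min()) < 0:
        raise GraphInputError("negative edge weights cannot be made stochastic")
    colsum = np.asarray(mat.sum(axis=0)).ravel()
    dangling = np.flatnonzero(colsum == 0)
    inv = np.zeros_like(colsum)
    nz = colsum > 0
    inv[nz] = 1.0 / colsum[nz]
    W = (mat @ sparse.diags(inv)).tocsr()
    return StochasticOperator(W=W, dangling=dangling)


def restart_vector(
    seeds: Sequence[int], n: int, normalized: bool = False
) -> np.ndarray:
    """Indicator vector of the seed set (optionally scaled to sum to 1)."""
    seeds = list(seeds)
    if not seeds:
        raise GraphInputError("the seed set Q must be nonempty")
    r = np.zeros(n)
    for s in seeds:
        if not (0 <= s < n):
            raise GraphInputError(f"seed {s} out of range for {n} vertices")
        r[s] = 1.0
    if normalized:
        r /= len(seeds)
    return r


def _check_solver_args(alpha: float, eps: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise GraphInputError(f"alpha must be in (0, 1], got {alpha}")
    if eps <= 0:
        raise GraphInputError(f"epsilon must be positive, got {eps}")


def rwr_power(
    op: StochasticOperator | sparse.spmatrix,
    r: np.ndarray,
    alpha: float = 0.05,
    eps: float = 1e-12,
    max_iter: int = 100_000,
    norm: str = "l2",
) -> ProximityVector:
    """Solve the RWR fixed point by power iteration from ``x0 = r``.

    Stops when the step ``||x(t+1) - x(t)||`` falls below ``eps``.
    """
    _check_solver_args(alpha, eps)
    W = op.W if isinstance(op, StochasticOperator) else op
    norm_f = _NORMS[norm]
    x = r.astype(float).copy()
    ar = alpha * r
    for t in range(1, max_iter + 1):
        x_next = (1.0 - alpha) * (W @ x) + ar
        step = norm_f(x_next - x)
        x = x_next
        if step < eps:
            return ProximityVector(x=x, iterations=t, residual=step, method="power")
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last step {step:.3e})",
        residual=step,
        iterations=max_iter,
    )


def rwr_chebyshev(
    op: StochasticOperator | sparse.spmatrix,
    r: np.ndarray,
    alpha: float = 0.05,
    eps: float = 1e-12,
    max_iter: int = 100_000,
    norm: str = "l2",
) -> ProximityVector:
    """Chebyshev semi-iterative acceleration of the RWR fixed point.

    Applies the classical three-term recurrence for the splitting
    ``x = (1-alpha) W x + alpha r`` with spectral-radius bound
    ``rho = 1 - alpha``::

        w_1 = 1,   w_{t+1} = 1 / (1 - rho^2 w_t / 4)
        y_{t+1} = w_{t+1} ((1-alpha) W y_t + alpha r - y_{t-1}) + y_{t-1}

    started from ``y_0 = 0``, ``y_1 = r``.  It converges to the same fixed
    point as :func:`rwr_power` with asymptotic factor
    :func:`convergence_factor`, i.e. strictly faster than ``1 - alpha``.
    """
    _check_solver_args(alpha, eps)
    W = op.W if isinstance(op, StochasticOperator) else op
    norm_f = _NORMS[norm]
    rho = 1.0 - alpha
    ar = alpha * r
    y_prev = np.zeros_like(r, dtype=float)
    y = r.astype(float).copy()
    omega = 1.0
    step = norm_f(y - y_prev)
    if step < eps:
        return ProximityVector(x=y, iterations=1, residual=step, method="chebyshev")
    for t in range(1, max_iter + 1):
        omega = 1.0 / (1.0 - (rho * rho * omega) / 4.0)
        y_next = omega * ((1.0 - alpha) * (W @ y) + ar - y_prev) + y_prev
        step = norm_f(y_next - y)
        y_prev, y = y, y_next
        if step < eps:
            return ProximityVector(
                x=y, iterations=t, residual=step, method="chebyshev"
            )
    raise ConvergenceError(
        f"Chebyshev iteration did not converge in {max_iter} iterations "
        f"(last step {step:.3e})",
        residual=step,
        iterations=max_iter,
    )


def convergence_factor(alpha: float) -> float:
    """Asymptotic Chebyshev convergence factor ``mu(alpha) < 1 - alpha``."""
    if not (0.0 < alpha <= 1.0):
        raise GraphInputError(f"alpha must be in (0, 1], got {alpha}")
    return 2.0 * (1.0 - alpha) / (2.0 + math.sqrt(2.0 * alpha - alpha * alpha))


def fixed_point_residual(
    op: StochasticOperator | sparse.spmatrix,
    x: np.ndarray,
    r: np.ndarray,
    alpha: float,
    norm: str = "l2",
) -> float:
    """``||x - ((1-alpha) W x + alpha r)||`` — how far ``x`` is from the RWR
    fixed point."""
    W = op.W if isinstance(op, StochasticOperator) else op
    return _NORMS[norm](x - ((1.0 - alpha) * (W @ x) + alpha * r))


def rank_vertices(
    pv: ProximityVector,
    registry: VertexRegistry,
    kind_filter: str | None = None,
    vertex_ids: np.ndarray | None = None,
) -> list[tuple[str, float]]:
    """Vertices ordered by descending proximity score, ties broken by label.

    ``vertex_ids`` (or ``pv.vertex_ids``) maps solution rows to global
    registry indices; ``kind_filter`` restricts the output to one vertex kind
    (disease / protein / locus).
    """
    ids = vertex_ids if vertex_ids is not None else pv.vertex_ids
    if ids is None:
        ids = np.arange(len(pv.x))
    scored = []
    for row, gid in enumerate(ids):
        kind = registry.kind(int(gid))
        if kind_filter is not None and kind != kind_filter:
            continue
        scored.append((registry.label(int(gid)), float(pv.x[row])))
    scored.sort(key=lambda p: (-p[1], p[0]))
    return scored
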