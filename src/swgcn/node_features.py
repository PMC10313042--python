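"""Random-walk-with-restart node features over a similarity network.

Each node i is described by the stationary visiting distribution of a
walker that at every step follows the row-normalised similarity network
with probability 1 - alpha and teleports back to i with probability alpha:

    F_i <- (1 - alpha) * F_i S + alpha * y_i

with S the row-stochastic transition matrix and y_i the one-hot start
vector.  Because the update is a contraction with factor (1 - alpha), the
fixed point is unique and equals the direct solve
F_i = alpha * y_i (I - (1 - alpha) S)^{-1}.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .similarity import validate_similarity

__all__ = ["transition_matrix", "rwr_stationary", "rwr_features"]


def transition_matrix(sim: np.ndarray) -> np.ndarray:
    """Row-normalise a similarity matrix into a transition matrix."""
    validate_similarity(sim)
    row_sums = sim.sum(axis=1, keepdims=True)
    assert np.all(row_sums > 0), "zero row sum despite unit diagonal"
    return sim / row_sums


def rwr_features(
    sim: np.ndarray,
    restart: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 1000,
    method: str = "solve",
) -> np.ndarray:
    """Stationary RWR distributions for every node of a similarity network.

    Parameters
    ----------
    sim
        Square similarity matrix (unit diagonal, symmetric, in [0, 1]).
    restart
        Restart probability alpha in (0, 1].
    tol, max_iter
        Iteration controls for ``method="iterate"``; iteration stops when
        the max-abs change falls below ``tol``.
    method
        ``"solve"`` computes the fixed point by a direct linear solve,
        ``"iterate"`` by power iteration; the two agree to the contraction
        tolerance and the iterative path exists mostly as a cross-check.

    Returns
    -------
    (n, n) array whose i-th row is F_i^inf; rows are probability vectors.
    """
    return rwr_stationary(
        transition_matrix(sim), restart=restart, tol=tol, max_iter=max_iter,
        method=method,
    )


def rwr_stationary(
    s: np.ndarray,
    restart: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 1000,
    method: str = "solve",
) -> np.ndarray:
    """Stationary RWR distributions given a row-stochastic transition matrix.

    Same contract as :func:`rwr_features` but starting from the transition
    matrix itself.
    """
    if not (0.0 < restart <= 1.0):
        raise ValueError(f"restart probability must be in (0, 1], got {restart}")
    s = np.asarray(s, dtype=np.float64)
    if not np.allclose(s.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    n = s.shape[0]
    if method == "solve":
        # F (I - (1-a) S) = a I  row-wise, i.e. F = a (I - (1-a) S)^{-T}... but
        # F_i = a y_i (I - (1-a) S)^{-1}, so F = a (I - (1-a) S)^{-1} read
        # row-wise: solve X^T system once for all nodes.
        a = np.eye(n) - (1.0 - restart) * s
        f = restart * scipy.linalg.solve(a.T, np.eye(n)).T
    elif method == "iterate":
        f = np.eye(n)
        y = np.eye(n)
        for _ in range(max_iter):
            f_next = (1.0 - restart) * (f @ s) + restart * y
            delta = np.max(np.abs(f_next - f))
            f = f_next
            if delta < tol:
                break
        else:
            raise RuntimeError(
                f"RWR did not converge in {max_iter} iterations "
                f"(residual {delta:.3g} > tol {tol:.3g})"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    # Stationarity keeps rows stochastic; renormalisation only mops up
    # floating-point drift.
    np.clip(f, 0.0, None, out=f)
    f /= f.sum(axis=1, keepdims=True)
    return f
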