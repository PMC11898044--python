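"""Non-negative least squares by the Lawson-Hanson active-set algorithm.

Solves  min_x ||A x - b||_2  subject to  x >= 0.

This solver produces the meta-model weights of the super learner: the
constraint forbids negative votes for any base learner, so unhelpful or
anti-correlated learners are driven to exactly zero weight rather than
being cancelled against each other.

The implementation follows the classical active-set scheme: starting from
the all-zero (all-passive-constraints-active) point, repeatedly move the
variable with the most negative gradient of the objective into the passive
set, solve the unconstrained least-squares problem restricted to the
passive set, and step back along the line segment to the previous iterate
whenever that unconstrained solution leaves the feasible orthant. Each
outer iteration strictly decreases the objective, which guarantees finite
termination.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nnls", "kkt_residuals"]

_MAX_INNER_DEFAULT = 200


def nnls(A: np.ndarray, b: np.ndarray, tol: float | None = None, max_iter: int | None = None) -> np.ndarray:
    """Solve ``min ||A x - b||`` subject to ``x >= 0``.

    Parameters
    ----------
    A : (n, m) array
    b : (n,) array
    tol : optional dual-feasibility tolerance; default scales with the
        problem as ``10 * eps * ||A||_1 * max(n, m)`` (the customary
        Lawson-Hanson stopping rule).
    max_iter : safety cap on outer iterations; default ``3 * m``.

    Returns
    -------
    x : (m,) array with ``x >= 0`` elementwise satisfying the KKT
        conditions of the constrained problem.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"A must be 2-D, got shape {A.shape}")
    if b.ndim != 1 or b.shape[0] != A.shape[0]:
        raise ValueError(f"b shape {b.shape} incompatible with A shape {A.shape}")
    if not (np.isfinite(A).all() and np.isfinite(b).all()):
        raise ValueError("nnls requires finite inputs")

    n, m = A.shape
    if n < 1 or m < 1:
        raise ValueError("nnls needs at least one row and one column")
    if max_iter is None:
        max_iter = max(3 * m, 30)
    if tol is None:
        tol = 10.0 * np.finfo(float).eps * np.abs(A).sum(axis=0).max() * max(n, m)

    x = np.zeros(m)
    passive = np.zeros(m, dtype=bool)  # P in Lawson-Hanson; ~passive is Z
    # gradient of 0.5||Ax-b||^2 is A^T(Ax-b); w = -gradient
    w = A.T @ (b - A @ x)

    outer = 0
    while (~passive).any() and np.max(w[~passive]) > tol:
        outer += 1
        if outer > max_iter:
            break  # return best feasible iterate found so far
        # admit the most violated coordinate into the passive set
        j = int(np.argmax(np.where(~passive, w, -np.inf)))
        passive[j] = True

        degenerate = False
        for _ in range(_MAX_INNER_DEFAULT):
            z = np.zeros(m)
            z[passive], *_ = np.linalg.lstsq(A[:, passive], b, rcond=None)
            if not np.isfinite(z[passive]).all():
                # numerically degenerate subproblem (e.g. vanishing
                # columns); keep the best feasible iterate found so far
                degenerate = True
                break
            if np.min(z[passive]) > 0:
                x = z
                break
            # step toward z only as far as feasibility allows, then
            # retire every coordinate that hit zero
            mask = passive & (z <= 0)
            alpha = np.min(x[mask] / (x[mask] - z[mask]))
            x = x + alpha * (z - x)
            passive &= x > tol
            x[~passive] = 0.0
        else:  # pragma: no cover - inner loop is finite in exact arithmetic
            break
        if degenerate:
            break
        w = A.T @ (b - A @ x)

    return x


def kkt_residuals(A: np.ndarray, b: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """KKT violation of an NNLS candidate solution.

    Returns ``(stationarity, dual)`` where *stationarity* is the largest
    absolute gradient component over strictly positive coordinates (must be
    ~0 at an optimum) and *dual* is the largest negative part of the
    gradient over zero coordinates (the gradient must be >= 0 there).
    """
    A = np.asarray(A, dtype=float)
    g = A.T @ (A @ np.asarray(x, dtype=float) - np.asarray(b, dtype=float))
    pos = np.asarray(x) > 0
    stationarity = float(np.max(np.abs(g[pos]))) if pos.any() else 0.0
    dual = float(max(0.0, -np.min(g[~pos]))) if (~pos).any() else 0.0
    return stationarity, dual
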