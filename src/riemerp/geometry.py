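"""Riemannian geometry of symmetric positive-definite (SPD) matrices.

Covariance features of multichannel ERP epochs live on the SPD manifold.
Under the affine-invariant metric, the geodesic distance between two SPD
matrices ``A`` and ``B`` is

    delta_R(A, B) = || log(A^{-1} B) ||_F = sqrt( sum_n ln(w_n)^2 ),

where ``w_n`` are the (real, positive) eigenvalues of ``A^{-1} B``.  The
geometric (Karcher/Frechet) mean of a set of SPD matrices is the minimizer
of the sum of squared geodesic distances; it has no closed form for more
than two matrices and is computed here by the standard fixed-point
iteration in the tangent space at the current estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "check_spd",
    "riemannian_distance",
    "geometric_mean",
    "GeometricMeanResult",
    "ensure_spd",
    "EnsureSPDResult",
    "logm_spd",
    "expm_sym",
    "sqrtm_spd",
    "invsqrtm_spd",
]

# Symmetry checked at 1e-10 relative; eigenvalue floor at 1e-10 * trace/d.
# Covariance rank deficiency at short epochs must not crash the pipeline.
SYM_RTOL = 1e-10
EIG_FLOOR_REL = 1e-10


def _as_square(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square 2-D array, got shape {m.shape}")
    if m.shape[0] == 0:
        raise ValueError(f"{name} must have positive dimension")
    return m


def check_spd(m: np.ndarray, name: str = "matrix", sym_rtol: float = SYM_RTOL) -> np.ndarray:
    """Validate that ``m`` is symmetric positive definite.

    Symmetry is required to within ``sym_rtol`` relative tolerance and all
    eigenvalues must be strictly positive.  Returns the (exactly
    symmetrized) matrix; raises ``ValueError`` naming the failed invariant
    otherwise.
    """
    m = _as_square(m, name)
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > sym_rtol * scale:
        raise ValueError(f"{name} is not symmetric (relative asymmetry exceeds {sym_rtol})")
    sym = 0.5 * (m + m.T)
    w = linalg.eigvalsh(sym)
    if w[0] <= 0:
        raise ValueError(
            f"{name} is not positive definite (minimum eigenvalue {w[0]:.3e} <= 0)"
        )
    return sym


def _eigh_fun(m: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to a symmetric matrix via eigendecomposition."""
    w, v = linalg.eigh(0.5 * (m + m.T))
    return (v * fun(w)) @ v.T


def logm_spd(m: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    return _eigh_fun(m, np.log)


def expm_sym(m: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    return _eigh_fun(m, np.exp)


def sqrtm_spd(m: np.ndarray) -> np.ndarray:
    """Principal square root of an SPD matrix."""
    return _eigh_fun(m, np.sqrt)


def invsqrtm_spd(m: np.ndarray) -> np.ndarray:
    """Inverse principal square root of an SPD matrix."""
    return _eigh_fun(m, lambda w: 1.0 / np.sqrt(w))


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant geodesic distance between SPD matrices.

    Computed as ``sqrt(sum ln(w_n)^2)`` over the generalized eigenvalues
    ``w_n`` of the pencil ``(b, a)`` — i.e. the eigenvalues of
    ``a^{-1} b`` — which is numerically stable for symmetric pairs.

    The distance is symmetric in its arguments, zero iff ``a == b``, and
    invariant under congruence ``X -> W.T @ X @ W`` for invertible ``W``.
    """
    a = check_spd(a, "a")
    b = check_spd(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    w = linalg.eigvalsh(b, a)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


@dataclass
class GeometricMeanResult:
    """Outcome of a Karcher-mean computation.

    Attributes
    ----------
    mean : SPD matrix minimizing the summed squared Riemannian distances.
    converged : whether the tangent-space norm fell below ``tol``.
    iterations_used : number of fixed-point iterations performed.
    tol, max_iterations : the stopping parameters that were in force.
    """

    mean: np.ndarray
    converged: bool
    iterations_used: int
    tol: float
    max_iterations: int


def geometric_mean(
    matrices,
    tol: float = 1e-8,
    max_iterations: int = 50,
    return_info: bool = False,
):
    """Geometric (Karcher) mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration: initialize at the arithmetic mean; update

        C <- C^{1/2} exp( (1/J) sum_j log(C^{-1/2} C_j C^{-1/2}) ) C^{1/2}

    and stop when the Frobenius norm of the tangent-space mean drops below
    ``tol`` or after ``max_iterations`` iterations.  Non-convergence is
    reported via a warning and the ``converged`` flag, not an exception.

    Parameters
    ----------
    matrices : sequence of SPD arrays of equal dimension (J >= 1).
    tol : convergence threshold on the tangent-space norm (> 0).
    max_iterations : iteration cap.
    return_info : if True return a :class:`GeometricMeanResult`, else the
        mean matrix alone.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    mats = [check_spd(m, f"matrices[{i}]") for i, m in enumerate(matrices)]
    if len(mats) == 0:
        raise ValueError("geometric_mean requires at least one matrix")
    d = mats[0].shape[0]
    for i, m in enumerate(mats):
        if m.shape[0] != d:
            raise ValueError(f"dimension mismatch at matrices[{i}]: {m.shape[0]} != {d}")

    stack = np.stack(mats)
    c = stack.mean(axis=0)  # arithmetic-mean initialization
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        c_isq = invsqrtm_spd(c)
        tangent = np.zeros((d, d))
        for m in stack:
            tangent += logm_spd(c_isq @ m @ c_isq)
        tangent /= len(stack)
        if np.linalg.norm(tangent, "fro") < tol:
            converged = True
            break
        c_sq = sqrtm_spd(c)
        c = c_sq @ expm_sym(tangent) @ c_sq
        c = 0.5 * (c + c.T)
    if not converged:
        warnings.warn(
            f"geometric mean did not converge in {max_iterations} iterations "
            f"(J={len(stack)}, d={d}); returning last iterate",
            RuntimeWarning,
        )
        logger.warning("geometric mean non-convergence: J=%d d=%d", len(stack), d)
    result = GeometricMeanResult(
        mean=c,
        converged=converged,
        iterations_used=it,
        tol=tol,
        max_iterations=max_iterations,
    )
    return result if return_info else c


@dataclass
class EnsureSPDResult:
    """SPD projection of a square matrix, with a record of any regularization."""

    matrix: np.ndarray
    loading_applied: bool
    loading_value: float


def ensure_spd(m: np.ndarray, loading: float = EIG_FLOOR_REL) -> EnsureSPDResult:
    """Symmetrize and, if needed, diagonally load a matrix into the SPD cone.

    The input is symmetrized as ``(m + m.T)/2``.  If its minimum eigenvalue
    falls at or below the floor ``loading * trace/d`` (or the trace itself is
    not positive, as for a zero matrix), a diagonal ridge is added to raise
    the smallest eigenvalue to the floor.  A degenerate all-zero input
    becomes ``loading * I``.

    Rank-deficient sample covariances (short epochs, M < 3N) pass through
    here so that downstream eigendecompositions stay well-posed.
    """
    if loading <= 0:
        raise ValueError("loading must be positive")
    m = _as_square(m)
    sym = 0.5 * (m + m.T)
    w = linalg.eigvalsh(sym)
    tr = float(np.trace(sym))
    d = sym.shape[0]
    floor = loading * tr / d if tr > 0 else loading
    if w[0] > floor:
        return EnsureSPDResult(matrix=sym, loading_applied=False, loading_value=0.0)
    ridge = floor - w[0]
    out = sym + ridge * np.eye(d)
    return EnsureSPDResult(matrix=out, loading_applied=True, loading_value=float(ridge))
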