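"""Smooth and proper orthogonal decomposition of the tracking matrix.

SOD solves the symmetric-definite generalized eigenproblem

    Sigma_X phi = lambda Sigma_V phi,
    Sigma_X = X'X/m,   Sigma_V = V'V/m  (+ delta I regularization)

whose eigenvalues (smooth orthogonal values, SOVs) sort feature-space
directions by time scale: for a pure harmonic at angular frequency omega the
SOV equals 1/omega^2.  POD, the eigendecomposition of Sigma_X alone, sorts by
variance amplitude and is kept as the reference decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .errors import ConditioningError, ParameterError
from .track import TrackingMatrix

__all__ = [
    "SODResult",
    "PODResult",
    "smooth_orthogonal_decomposition",
    "proper_orthogonal_decomposition",
    "project",
    "generalized_eigenvalues_bruteforce",
]

#: relative Tikhonov regularization of Sigma_V (per design: 1e-10 tr(Sv)/K)
REG_SCALE = 1e-10


def _covariances(tm: TrackingMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    m = tm.n_records
    sx = tm.X.T @ tm.X / m
    sv = tm.V.T @ tm.V / m
    k = sx.shape[0]
    delta = REG_SCALE * np.trace(sv) / k
    return sx, sv, delta


def _fix_signs(modes: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each mode positive."""
    idx = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


@dataclass(frozen=True)
class SODResult:
    sovs: np.ndarray  # (K,) descending
    modes: np.ndarray  # (K, K), column i = phi_i, unit norm, sign-fixed
    socs: np.ndarray  # (m, K), column i = X @ phi_i
    timestamps: np.ndarray
    conditioning: float  # smallest regularized eigenvalue of Sigma_V
    degenerate_groups: tuple[tuple[int, ...], ...] = ()


@dataclass(frozen=True)
class PODResult:
    eigenvalues: np.ndarray  # (K,) descending variances
    modes: np.ndarray  # (K, K) orthonormal columns
    coordinates: np.ndarray  # (m, K)
    timestamps: np.ndarray


def smooth_orthogonal_decomposition(tm: TrackingMatrix) -> SODResult:
    """Solve Sigma_X phi = lambda (Sigma_V + delta I) phi.

    Modes are normalized to unit Euclidean norm with the sign convention that
    each mode's largest-magnitude component is positive; SOVs are returned in
    descending order with the SOCs ordered to match.  Near-equal SOVs (within
    1e-6 relative) are reported as degenerate groups.
    """
    if tm.n_records <= tm.n_features:
        warnings.warn(
            f"m = {tm.n_records} records <= K = {tm.n_features} features: "
            "covariances are rank-deficient", stacklevel=2)
    sx, sv, delta = _covariances(tm)
    svr = sv + delta * np.eye(sv.shape[0])
    cond_eigs = np.linalg.eigvalsh(svr)
    if cond_eigs.min() <= 0 or not np.isfinite(cond_eigs).all():
        null_dim = int(np.sum(cond_eigs <= 0))
        raise ConditioningError(
            f"V-covariance not positive definite after regularization "
            f"({null_dim}-dimensional null space)", null_dim=null_dim)
    try:
        lam, vec = scipy.linalg.eigh(sx, svr)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise ConditioningError(f"generalized eigensolver failed: {exc}") from exc
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    lam = np.clip(lam, 0.0, None)  # tiny negatives are regularization noise
    vec = vec / np.linalg.norm(vec, axis=0, keepdims=True)
    vec = _fix_signs(vec)
    socs = tm.X @ vec

    groups: list[tuple[int, ...]] = []
    scale = max(lam[0], np.finfo(float).tiny)
    i = 0
    while i < lam.size:
        j = i
        while j + 1 < lam.size and abs(lam[j + 1] - lam[i]) <= 1e-6 * scale:
            j += 1
        if j > i:
            groups.append(tuple(range(i, j + 1)))
        i = j + 1
    return SODResult(sovs=lam, modes=vec, socs=socs, timestamps=tm.timestamps,
                     conditioning=float(cond_eigs.min()),
                     degenerate_groups=tuple(groups))


def proper_orthogonal_decomposition(tm: TrackingMatrix) -> PODResult:
    """Eigendecomposition of Sigma_X: variance-ordered orthonormal modes."""
    sx, _, _ = _covariances(tm)
    lam, vec = np.linalg.eigh(sx)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = _fix_signs(vec[:, order])
    return PODResult(eigenvalues=lam, modes=vec, coordinates=tm.X @ vec,
                     timestamps=tm.timestamps)


def project(tm: TrackingMatrix, result: SODResult,
            modes: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """SOC columns for the selected mode indices, with their timestamps."""
    idx = np.asarray(list(modes), dtype=int)
    if idx.size == 0:
        raise ParameterError("empty mode selection")
    k = result.socs.shape[1]
    if idx.min() < 0 or idx.max() >= k:
        raise ParameterError(f"mode indices must lie in [0, {k})")
    return result.socs[:, idx], result.timestamps


def generalized_eigenvalues_bruteforce(sx: np.ndarray, sv: np.ndarray,
                                       delta: float = 0.0) -> np.ndarray:
    """Independent oracle: roots of det(Sigma_X - lambda (Sigma_V + delta I)).

    The determinant is a polynomial of degree K in lambda; its coefficients
    are obtained by exact Vandermonde interpolation of the determinant at
    K + 1 sample points, and the eigenvalues are the polynomial's roots.  No
    eigensolver is involved, so this is a genuinely independent route.
    """
    k = sx.shape[0]
    svr = sv + delta * np.eye(k)
    scale = np.trace(sx) / max(np.trace(svr), np.finfo(float).tiny)
    pts = scale * np.linspace(-1.5, 1.5, k + 1)
    dets = np.array([np.linalg.det(sx - lam * svr) for lam in pts])
    vander = np.vander(pts, k + 1, increasing=False)
    coeffs = np.linalg.solve(vander, dets)
    roots = np.roots(coeffs)
    roots = roots[np.abs(roots.imag) < 1e-8 * (1 + np.abs(roots.real))].real
    return np.sort(roots)[::-1]
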