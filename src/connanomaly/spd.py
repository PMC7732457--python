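"""Geometry of symmetric positive-definite (SPD) matrices.

Correlation/covariance matrices live on the SPD manifold; comparing them as
flat vectors ignores that geometry. The affine-invariant (Karcher) mean gives
a principled cohort reference point C, and each subject matrix S is mapped to
the tangent space at C as

    T = logm(C^{-1/2} S C^{-1/2})

— whitening by the reference followed by the matrix logarithm. Tangent
coefficients behave like ordinary Euclidean quantities, so per-edge means and
standard deviations across a cohort are well defined there.
"""
from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = [
    "is_spd",
    "shrink_correlation",
    "logm_spd",
    "expm_sym",
    "geometric_mean_spd",
    "log_euclidean_mean_spd",
    "tangent_embed",
    "tangent_inverse",
]


def _eigh_checked(mat: np.ndarray, *, what: str = "matrix") -> tuple[np.ndarray, np.ndarray]:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{what} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{what} is not symmetric")
    w, v = np.linalg.eigh(mat)
    if w.min() <= 0:
        raise ValueError(f"{what} is not positive definite (min eigenvalue {w.min():.3e})")
    return w, v


def is_spd(mat: np.ndarray, tol: float = 0.0) -> bool:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        return False
    if not np.allclose(mat, mat.T, atol=1e-10):
        return False
    return np.linalg.eigvalsh(mat).min() > tol


def shrink_correlation(corr: np.ndarray, lam: float = 1e-3) -> np.ndarray:
    """Shrink a correlation matrix toward the identity: (1-lam)*C + lam*I.

    Finite or censored time series can yield rank-deficient correlation
    matrices; a small ridge guarantees positive definiteness before any
    matrix logarithm while leaving the diagonal at 1.
    """
    if not 0 <= lam < 1:
        raise ValueError(f"shrinkage must be in [0, 1), got {lam}")
    n = corr.shape[0]
    return (1.0 - lam) * corr + lam * np.eye(n)


def clip_spd(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues up to `floor`, returning the nearest such SPD matrix.

    Individual subject matrices with planted or heavily processed entries can
    leave the PSD cone; clipping makes the matrix logarithm defined while
    leaving already-SPD inputs untouched.
    """
    mat = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(mat)
    if w.min() >= floor:
        return mat
    return (v * np.clip(w, floor, None)) @ v.T


def logm_spd(mat: np.ndarray) -> np.ndarray:
    w, v = _eigh_checked(mat)
    return (v * np.log(w)) @ v.T


def expm_sym(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    return (v * np.exp(w)) @ v.T


def _sqrt_and_inv_sqrt(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, v = _eigh_checked(mat)
    s = np.sqrt(w)
    return (v * s) @ v.T, (v / s) @ v.T


def geometric_mean_spd(matrices: list[np.ndarray], tol: float = 1e-8,
                       max_iter: int = 50) -> np.ndarray:
    """Affine-invariant (Karcher) mean of SPD matrices by fixed-point iteration.

    Iterates G <- G^{1/2} expm(mean_i logm(G^{-1/2} C_i G^{-1/2})) G^{1/2}
    until the Frobenius norm of the tangent-space mean update falls below
    `tol`. Raises if any input is not SPD or the iteration does not converge.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    mats = [np.asarray(m, dtype=float) for m in matrices]
    for i, m in enumerate(mats):
        _eigh_checked(m, what=f"input {i}")
    if len(mats) == 1:
        return mats[0].copy()

    def tangent_mean(point: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        sqrt_p, inv_sqrt_p = _sqrt_and_inv_sqrt(point)
        upd = np.mean([logm_spd(inv_sqrt_p @ c @ inv_sqrt_p) for c in mats], axis=0)
        upd = (upd + upd.T) / 2.0
        return upd, float(np.linalg.norm(upd, "fro")), sqrt_p

    mean = np.mean(mats, axis=0)  # arithmetic mean as starting point
    update, residual, sqrt_m = tangent_mean(mean)
    step = 1.0  # geodesic step, halved on overshoot (ill-conditioned inputs)
    for _ in range(max_iter):
        if residual < tol:
            return mean
        candidate = sqrt_m @ expm_sym(step * update) @ sqrt_m
        candidate = (candidate + candidate.T) / 2.0
        cand_update, cand_residual, cand_sqrt = tangent_mean(candidate)
        if cand_residual < residual:
            mean, update, residual, sqrt_m = candidate, cand_update, cand_residual, cand_sqrt
        else:
            step /= 2.0
    if residual < tol:
        return mean
    raise RuntimeError(
        f"geometric mean did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})"
    )


def log_euclidean_mean_spd(matrices: list[np.ndarray]) -> np.ndarray:
    """Log-Euclidean mean: expm(mean_i logm(C_i)). Cheaper, non-iterative
    alternative reference point."""
    if not matrices:
        raise ValueError("need at least one matrix")
    return expm_sym(np.mean([logm_spd(np.asarray(m, dtype=float)) for m in matrices],
                            axis=0))


def tangent_embed(mat: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map an SPD matrix to the tangent space at `reference`:
    logm(R^{-1/2} M R^{-1/2}). Output is symmetric."""
    mat = np.asarray(mat, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mat.shape != reference.shape:
        raise ValueError(f"shape mismatch: {mat.shape} vs {reference.shape}")
    _, inv_sqrt_r = _sqrt_and_inv_sqrt(reference)
    whitened = inv_sqrt_r @ mat @ inv_sqrt_r
    whitened = (whitened + whitened.T) / 2.0
    out = logm_spd(whitened)
    return (out + out.T) / 2.0


def tangent_inverse(tangent: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Inverse of `tangent_embed`: R^{1/2} expm(T) R^{1/2}."""
    tangent = np.asarray(tangent, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if tangent.shape != reference.shape:
        raise ValueError(f"shape mismatch: {tangent.shape} vs {reference.shape}")
    sqrt_r, _ = _sqrt_and_inv_sqrt(reference)
    out = sqrt_r @ expm_sym((tangent + tangent.T) / 2.0) @ sqrt_r
    return (out + out.T) / 2.0
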