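"""Covariance PCA with varimax rotation and regression score extraction.

The feature matrix is decomposed through the eigenstructure of its sample
covariance; loadings are eigenvectors scaled by the square root of their
eigenvalue. Retained loadings are varimax-rotated towards simple structure,
per-observation component scores are extracted by the regression method
(solving the covariance system for the score coefficients, i.e. the
contribution of each parcel), and explained variance is summarised as the
squared correlation between the data and its rank-m' reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .parcel_features import FeatureMatrix

__all__ = [
    "ComponentModel",
    "VarianceCurve",
    "covariance_pca",
    "varimax_rotate",
    "varimax_criterion",
    "retain_components",
    "component_scores",
    "variance_curve",
    "fit_component_model",
]


@dataclass
class VarianceCurve:
    """r2_by_m[m'] = R² of the rank-m' reconstruction, m' = 0 .. m_pre."""

    r2_by_m: np.ndarray

    def __post_init__(self):
        self.r2_by_m = np.asarray(self.r2_by_m, dtype=float)

    def smallest_m_reaching(self, theta: float) -> int:
        hit = np.flatnonzero(self.r2_by_m >= theta)
        if hit.size == 0:
            raise ValueError(f"no component count reaches R² = {theta}")
        return int(hit[0])


@dataclass
class ComponentModel:
    loadings: np.ndarray  # regions x m (varimax-rotated)
    rotation: np.ndarray  # m x m orthogonal
    eigenvalues: np.ndarray  # full spectrum, non-increasing
    scores: np.ndarray  # observations x m
    score_coefficients: np.ndarray  # regions x m
    column_means: np.ndarray
    m: int
    region_ids: list | None = None
    observation_ids: list | None = None
    condition: str | None = None

    def validate(self) -> None:
        m = self.m
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(m), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues not non-increasing")


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.atleast_2d(np.asarray(X, dtype=float))


def covariance_pca(X):
    """Eigendecomposition of the sample covariance.

    Returns (eigenvalues desc, loadings = eigenvectors * sqrt(eigenvalue),
    column means). Negative round-off eigenvalues are clipped to zero.
    """
    A = _as_array(X)
    n, p = A.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 observations and 2 regions")
    S = np.cov(A, rowvar=False, ddof=1)
    if np.allclose(S, 0):
        raise ValueError("constant matrix: covariance is identically zero")
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    loadings = evecs * np.sqrt(evals)[None, :]
    return evals, loadings, A.mean(axis=0)


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over columns of the variance of the squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax_rotate(
    loadings: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    kaiser_normalize: bool = True,
):
    """Orthogonal varimax rotation (SVD sweep algorithm).

    Returns (rotated loadings, rotation) with loadings @ rotation = rotated.
    With Kaiser normalization the rows are scaled to unit communality during
    the sweeps and rescaled afterwards.
    """
    L0 = np.atleast_2d(np.asarray(loadings, dtype=float))
    if not np.isfinite(L0).all():
        raise ValueError("non-finite loadings")
    n, m = L0.shape
    if m < 1:
        raise ValueError("need at least one component")
    if m == 1:
        return L0.copy(), np.eye(1)
    h = np.sqrt((L0**2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    X = L0 / h_safe[:, None] if kaiser_normalize else L0
    R = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        L = X @ R
        G = X.T @ (L**3 - L * ((L**2).sum(axis=0) / n))
        u, s, vt = np.linalg.svd(G)
        R = u @ vt
        d = s.sum()
        if d_old != 0.0 and d < d_old * (1.0 + tol):
            break
        d_old = d
    rotated = X @ R
    if kaiser_normalize:
        rotated = rotated * h_safe[:, None]
    return rotated, R


def _canonical_order_and_sign(rotated: np.ndarray, rotation: np.ndarray):
    """Order components by explained sum of squares, largest-|loading| positive."""
    ss = (rotated**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    rotated = rotated[:, order]
    rotation = rotation[:, order]
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(rotated.shape[1])])
    signs[signs == 0] = 1.0
    return rotated * signs, rotation * signs


def retain_components(
    eigenvalues,
    rule: str = "kaiser_mean",
    m: int | None = None,
    theta: float | None = None,
    curve: VarianceCurve | None = None,
) -> int:
    """How many components to keep.

    ``kaiser_mean`` keeps eigenvalues strictly above the spectrum mean (the
    covariance-matrix analogue of Kaiser's criterion); ``target_r2`` the
    smallest m whose variance curve reaches theta; ``fixed`` returns m.
    """
    evals = np.asarray(eigenvalues, dtype=float)
    if evals.size == 0:
        raise ValueError("empty spectrum")
    if rule == "kaiser_mean":
        return max(1, int(np.sum(evals > evals.mean())))
    if rule == "fixed":
        if m is None or m < 1 or m > evals.size:
            raise ValueError(f"fixed m={m} invalid for spectrum of length {evals.size}")
        return int(m)
    if rule == "target_r2":
        if theta is None or curve is None:
            raise ValueError("target_r2 needs theta and a VarianceCurve")
        return curve.smallest_m_reaching(theta)
    raise ValueError(f"unknown retention rule {rule!r}")


def component_scores(X, rotated_loadings: np.ndarray, column_means: np.ndarray | None = None):
    """Regression-method score extraction.

    The score coefficients W solve covariance(X) · W = loadings — the
    contribution of each parcel to each component — and the per-observation
    scores are (X − mean) · W. A near-singular covariance falls back to a
    ridge solve with an explicit warning.
    """
    A = _as_array(X)
    L = np.atleast_2d(np.asarray(rotated_loadings, dtype=float))
    means = A.mean(axis=0) if column_means is None else np.asarray(column_means, dtype=float)
    S = np.cov(A, rowvar=False, ddof=1)
    try:
        W = linalg.solve(S, L, assume_a="pos")
        if not np.isfinite(W).all():
            raise np.linalg.LinAlgError("non-finite solve")
    except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
        lam = 1e-8 * np.trace(S) / max(S.shape[0], 1)
        warnings.warn(f"singular covariance; ridge fallback with lambda={lam:.3e}")
        W = linalg.solve(S + lam * np.eye(S.shape[0]), L, assume_a="pos")
    scores = (A - means) @ W
    return scores, W


def variance_curve(X, eigenvalues=None, eigenvectors=None, column_means=None) -> VarianceCurve:
    """Reconstruction R² as a function of the number of (unrotated) components.

    r2_by_m[m'] is the squared Pearson correlation between the vectorised data
    and its reconstruction from the top m' principal components; m' = 0 gives 0.
    """
    A = _as_array(X)
    if eigenvectors is None:
        evals, loadings, column_means = covariance_pca(A)
        nz = np.sqrt(np.where(evals > 0, evals, 1.0))
        eigenvectors = loadings / nz[None, :]
    means = A.mean(axis=0) if column_means is None else column_means
    Ac = A - means
    pcs = Ac @ eigenvectors  # observations x m_pre
    flat = A.ravel()
    r2 = [0.0]
    recon = np.tile(means, (A.shape[0], 1))
    for j in range(eigenvectors.shape[1]):
        recon = recon + np.outer(pcs[:, j], eigenvectors[:, j])
        c = np.corrcoef(flat, recon.ravel())[0, 1]
        r2.append(float(c**2) if np.isfinite(c) else 0.0)
    return VarianceCurve(r2_by_m=np.array(r2))


def fit_component_model(
    X,
    retention: str = "kaiser_mean",
    m: int | None = None,
    theta: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    kaiser_normalize: bool = True,
) -> ComponentModel:
    """Full pipeline: covariance PCA → retention → varimax → regression scores."""
    A = _as_array(X)
    evals, loadings_full, means = covariance_pca(A)
    curve = None
    if retention == "target_r2":
        curve = variance_curve(A)
    m_keep = retain_components(evals, rule=retention, m=m, theta=theta, curve=curve)
    rotated, rotation = varimax_rotate(
        loadings_full[:, :m_keep], max_iter=max_iter, tol=tol, kaiser_normalize=kaiser_normalize
    )
    rotated, rotation = _canonical_order_and_sign(rotated, rotation)
    scores, coeffs = component_scores(A, rotated, means)
    model = ComponentModel(
        loadings=rotated,
        rotation=rotation,
        eigenvalues=evals,
        scores=scores,
        score_coefficients=coeffs,
        column_means=means,
        m=m_keep,
        region_ids=getattr(X, "region_ids", None),
        observation_ids=getattr(X, "observation_ids", None),
        condition=getattr(X, "condition", None),
    )
    model.validate()
    return model
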