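"""PCA shape models, parallel-analysis retention and mode reconstructions.

The model is the eigen-decomposition of the sample covariance of flattened
shape rows. When the ambient dimension (3 x n_points) exceeds the sample
count the dual (Gram-matrix) route is used; both routes agree to numerical
precision. Per-sample shape parameters are reported in SD units — the
projection onto an eigenvector divided by that mode's standard deviation —
so a score of +3 means "three SDs along this mode".
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Union

import numpy as np

from ._geometry import closest_points_on_mesh, nearest_points_in_cloud
from .alignment import AlignedDataset
from .shape_io import ShapeSample

__all__ = [
    "ShapeModel",
    "ParallelAnalysisResult",
    "fit_pca",
    "pca_eigenvalues",
    "parallel_analysis",
    "reconstruct_at_sd",
    "point_to_surface_distance",
]


@dataclasses.dataclass
class ShapeModel:
    mean_vector: np.ndarray       # (3n,)
    eigenvectors: np.ndarray      # (3n, m), orthonormal columns
    eigenvalues: np.ndarray       # (m,), descending variances
    scores_sd: np.ndarray         # (n_samples, m), SD units
    k_retained: Optional[int] = None

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    def project_sd(self, vectors: np.ndarray) -> np.ndarray:
        """SD-unit scores of arbitrary shape vectors under this model."""
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        return (vectors - self.mean_vector) @ self.eigenvectors / np.sqrt(self.eigenvalues)

    def reconstruct(self, scores_sd: np.ndarray) -> np.ndarray:
        """Shape vector(s) from SD-unit scores; accepts (m,) or (n, m)."""
        scores_sd = np.asarray(scores_sd, dtype=float)
        out = self.mean_vector + (np.atleast_2d(scores_sd)
                                  * np.sqrt(self.eigenvalues)) @ self.eigenvectors.T
        return out[0] if scores_sd.ndim == 1 else out


@dataclasses.dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    simulated_mean: np.ndarray
    simulated_p95: np.ndarray
    k_retained: int
    n_simulations: int
    criterion: str                 # 'mean' or 'percentile95'

    @property
    def simulated_criterion(self) -> np.ndarray:
        return self.simulated_mean if self.criterion == "mean" else self.simulated_p95


def _as_matrix(data: Union[AlignedDataset, np.ndarray]) -> np.ndarray:
    if isinstance(data, AlignedDataset):
        return data.data
    matrix = np.asarray(data, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D (n_samples, n_features) matrix")
    return matrix


def _spectrum(Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and eigenvectors of cov(X), dual trick when
    features outnumber samples. Returns only strictly informative modes
    (at most n_samples - 1, eigenvalues above numerical floor)."""
    n, d = Xc.shape
    if d <= n:
        cov = (Xc.T @ Xc) / (n - 1)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
    else:
        gram = (Xc @ Xc.T) / (n - 1)
        w, u = np.linalg.eigh(gram)
        w, u = w[::-1], u[:, ::-1]
        keep = w > max(w.max(), 0) * 1e-12
        w = w[keep]
        v = Xc.T @ u[:, keep] / np.sqrt(w * (n - 1))
    m = min(n - 1, d)
    w, v = w[:m], v[:, :m]
    floor = max(w.max(), 0) * 1e-12
    keep = w > floor
    return w[keep], v[:, keep]


def pca_eigenvalues(matrix: np.ndarray) -> np.ndarray:
    """Covariance eigenvalues only (descending), cheapest route."""
    Xc = matrix - matrix.mean(axis=0)
    n, d = Xc.shape
    small = Xc @ Xc.T if d > n else Xc.T @ Xc
    w = np.linalg.eigvalsh(small / (n - 1))[::-1]
    return w[:min(n - 1, d)]


def fit_pca(data: Union[AlignedDataset, np.ndarray]) -> ShapeModel:
    """Fit a PCA shape model to aligned rows.

    Eigenvector signs are fixed so the largest-magnitude loading of each
    mode is positive. ``scores_sd`` columns have sample mean 0 and sample
    SD 1 (ddof=1) on the fitting data by construction.
    """
    X = _as_matrix(data)
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("data has zero variance; cannot fit a shape model")
    w, v = _spectrum(Xc)
    # deterministic sign: largest-magnitude loading positive
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    v = v * signs
    scores_sd = (Xc @ v) / np.sqrt(w)
    return ShapeModel(mean_vector=mean, eigenvectors=v, eigenvalues=w,
                      scores_sd=scores_sd)


def parallel_analysis(data: Union[AlignedDataset, np.ndarray],
                      n_sim: int = 100, criterion: str = "mean",
                      seed: int = 0) -> ParallelAnalysisResult:
    """Horn-style parallel analysis for component retention.

    Simulated datasets are element-wise independent Gaussians whose
    per-variable variance matches the observed data (same n, same
    dimensionality). A rank is informative when its observed eigenvalue
    exceeds the simulated criterion (mean, or 95th percentile); retention
    stops at the first rank that fails, mirroring the intersection of the
    observed and simulated scree curves.
    """
    if n_sim < 50:
        raise ValueError("n_sim must be >= 50 for a stable criterion")
    if criterion not in ("mean", "percentile95"):
        raise ValueError("criterion must be 'mean' or 'percentile95'")
    X = _as_matrix(data)
    n, d = X.shape
    observed = pca_eigenvalues(X)
    col_sd = X.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, observed.shape[0]))
    for s in range(n_sim):
        noise = rng.normal(size=(n, d)) * col_sd
        sims[s] = pca_eigenvalues(noise)[:observed.shape[0]]
    sim_mean = sims.mean(axis=0)
    sim_p95 = np.percentile(sims, 95, axis=0)
    threshold = sim_mean if criterion == "mean" else sim_p95
    exceeds = observed > threshold
    k = int(np.argmin(exceeds)) if not exceeds.all() else int(exceeds.size)
    return ParallelAnalysisResult(observed_eigenvalues=observed,
                                  simulated_mean=sim_mean,
                                  simulated_p95=sim_p95,
                                  k_retained=k, n_simulations=n_sim,
                                  criterion=criterion)


def reconstruct_at_sd(model: ShapeModel, mode_index: int, c_sd: float) -> np.ndarray:
    """Shape vector ``mean + c_sd * sqrt(eigenvalue_j) * eigenvector_j``.

    ``mode_index`` is 1-based, matching how modes are reported (mode 1 =
    largest variance).
    """
    if not 1 <= mode_index <= model.n_modes:
        raise ValueError(f"mode_index must be in [1, {model.n_modes}], "
                         f"got {mode_index}")
    j = mode_index - 1
    return model.mean_vector + c_sd * np.sqrt(model.eigenvalues[j]) * model.eigenvectors[:, j]


def point_to_surface_distance(points: np.ndarray,
                              target: Union[ShapeSample, np.ndarray],
                              faces: Optional[np.ndarray] = None) -> np.ndarray:
    """Unsigned closest distance (mm) from each query point to a target.

    With faces the distance is point-to-triangle; without, it falls back to
    nearest point in the cloud (an upper bound on the surface distance).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if isinstance(target, ShapeSample):
        tpoints, tfaces = target.points, target.faces
    else:
        tpoints, tfaces = np.asarray(target, dtype=float), faces
    if tpoints.size == 0:
        raise ValueError("empty target geometry")
    if tfaces is not None and len(tfaces):
        _, dist, _ = closest_points_on_mesh(points, tpoints, tfaces)
    else:
        _, dist, _ = nearest_points_in_cloud(points, tpoints)
    return dist
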