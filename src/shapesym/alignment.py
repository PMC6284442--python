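"""Mirroring, groupwise similarity alignment and surface correspondence.

Alignment is classical iterative groupwise Procrustes: every sample is
registered to the current mean with the least-squares similarity transform
(rotation + translation, optionally uniform scale), the mean is refreshed,
and the loop repeats until the size-normalised objective stops improving.
Rotations come from the Kabsch/Umeyama construction with a determinant
correction, so reflections can never sneak in — mirroring is an explicit,
separate step. Gaussian-mixture registration parameters (``sigma``,
``n_mean_points``, ``lambda_tradeoff``) are accepted for config
compatibility and logged, but drive no computation here.
"""
from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ._geometry import closest_points_on_mesh
from .shape_io import ShapeSample

__all__ = [
    "RegistrationConfig",
    "AlignedDataset",
    "mirror_sagittal",
    "mirror_sample",
    "similarity_transform",
    "groupwise_align",
    "correspond_to_reference",
]


@dataclasses.dataclass
class RegistrationConfig:
    sigma: float = 3.0              # compatibility only; logged, unused
    n_mean_points: int = 2000       # compatibility only; logged, unused
    lambda_tradeoff: float = 1e-5   # compatibility only; logged, unused
    max_iter: int = 50
    tol: float = 1e-9
    allow_scaling: bool = True

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclasses.dataclass
class AlignedDataset:
    """Corresponded, aligned samples as a (n_samples, 3 n_points) matrix."""

    data: np.ndarray
    mean_vector: np.ndarray
    metadata: pd.DataFrame            # one row per data row
    transforms: List[dict]            # per-sample {rotation, scale, translation}
    objective_history: List[float]
    n_iterations: int
    config: RegistrationConfig

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1] // 3

    def rows_where(self, mask) -> np.ndarray:
        return self.data[np.asarray(mask, dtype=bool)]


def mirror_sagittal(points: np.ndarray) -> np.ndarray:
    """Reflect points in the sagittal plane x = 0 (first coordinate negated).

    An involution: applying it twice returns the input exactly.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or not np.all(np.isfinite(points)):
        raise ValueError("points must be a finite (n, 3) matrix")
    out = points.copy()
    out[:, 0] = -out[:, 0]
    return out


def mirror_sample(sample: ShapeSample) -> ShapeSample:
    """Mirror a sample's geometry; reverses triangle winding and flips the
    ``mirrored`` flag so downstream consumers know orientation changed."""
    faces = None if sample.faces is None else sample.faces[:, [0, 2, 1]]
    return sample.with_geometry(mirror_sagittal(sample.points), faces=faces,
                                mirrored=not sample.mirrored)


def similarity_transform(moving: np.ndarray, target: np.ndarray,
                         allow_scaling: bool = True):
    """Least-squares similarity registration of ``moving`` onto ``target``.

    Returns ``(aligned, transform)`` where ``aligned = s * moving @ R.T + t``
    and ``transform`` holds ``R`` (proper rotation, det +1), ``s`` and ``t``.
    """
    X = np.asarray(moving, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("moving and target must have identical shapes")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scaling:
        denom = np.einsum("ij,ij->", Xc, Xc)
        if denom == 0:
            raise ValueError("degenerate moving shape: zero spread")
        s = float((S @ np.diag(D)) / denom)
    else:
        s = 1.0
    t = my - s * R @ mx
    aligned = s * X @ R.T + t
    return aligned, {"rotation": R, "scale": s, "translation": t}


def _centroid_size(points: np.ndarray) -> float:
    return float(np.linalg.norm(points - points.mean(axis=0)))


def _canonical_rotation(centred: np.ndarray) -> np.ndarray:
    """Proper rotation taking a centred cloud's principal axes to x/y/z.

    Axis signs are fixed by an intrinsic property — the third moment of the
    point projections along each axis is made positive — so the resulting
    frame does not depend on how the input happened to be oriented. If the
    determinant then comes out negative, the axis with the least decisive
    skewness is flipped.
    """
    cov = centred.T @ centred
    _, v = np.linalg.eigh(cov)
    axes = v[:, ::-1].T.copy()  # rows = principal axes, descending variance
    skew = np.einsum("ni->i", (centred @ axes.T) ** 3)
    for i in range(3):
        if skew[i] < 0:
            axes[i] = -axes[i]
            skew[i] = -skew[i]
    if np.linalg.det(axes) < 0:
        j = int(np.argmin(skew))
        axes[j] = -axes[j]
    return axes


def groupwise_align(samples: Sequence[ShapeSample],
                    config: Optional[RegistrationConfig] = None) -> AlignedDataset:
    """Iterative groupwise similarity alignment of corresponded samples.

    All samples must already be in point-wise correspondence (equal point
    counts, index i = same location). The recorded objective is the total
    squared Procrustes distance to the mean divided by the squared mean
    centroid size, which is invariant to the joint renormalisation applied
    each round and non-increasing across iterations.
    """
    config = config or RegistrationConfig()
    if len(samples) < 2:
        raise ValueError("groupwise alignment needs at least 2 samples")
    n_pts = samples[0].n_points
    for s in samples:
        if s.n_points != n_pts:
            raise ValueError(
                f"sample {s.sample_id or '<unnamed>'} has {s.n_points} points, "
                f"expected {n_pts}: samples are not corresponded")
        if np.linalg.matrix_rank(s.points - s.points.mean(axis=0)) < 2:
            raise ValueError(
                f"sample {s.sample_id or '<unnamed>'} is degenerate "
                "(rank-deficient point set)")

    clouds = [np.asarray(s.points, dtype=float) for s in samples]
    # scale handling: normalise every cloud to unit centroid size up front,
    # then solve rotation + translation only — all post-alignment sizes are
    # then exactly equal and each loop step provably lowers the objective
    pre_scales = np.ones(len(clouds))
    if config.allow_scaling:
        pre_scales = np.array([1.0 / _centroid_size(c) for c in clouds])
        clouds = [c * s for c, s in zip(clouds, pre_scales)]
    mean = clouds[0] - clouds[0].mean(axis=0)

    history: List[float] = []
    prev_obj = np.inf
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        aligned = [similarity_transform(c, mean, allow_scaling=False)[0]
                   for c in clouds]
        new_mean = np.mean(aligned, axis=0)
        if _centroid_size(new_mean) == 0:
            raise ValueError("mean shape collapsed to a point")
        obj = sum(float(np.sum((a - new_mean) ** 2)) for a in aligned)
        history.append(obj)
        mean = new_mean - new_mean.mean(axis=0)
        if np.isfinite(prev_obj) and prev_obj - obj <= config.tol * max(prev_obj, 1e-300):
            break
        prev_obj = obj

    # final pass against the settled mean so rows and mean are consistent
    final = [similarity_transform(c, mean, allow_scaling=False)
             for c in clouds]
    clouds_out = [f[0] for f in final]
    transforms = [f[1] for f in final]
    for tf, s in zip(transforms, pre_scales):
        tf["scale"] = float(s)
        # aligned = R (s x) + t, so fold the pre-scale into the map
        # applied to the original coordinates

    # canonical output frame: centre the mean and rotate its principal axes
    # onto the coordinate axes, so the result does not depend on any common
    # similarity transform of the inputs (or on which sample seeded the mean)
    centre = mean.mean(axis=0)
    Rc = _canonical_rotation(mean - centre)
    clouds_out = [(c - centre) @ Rc.T for c in clouds_out]
    for tf in transforms:
        tf["rotation"] = Rc @ tf["rotation"]
        tf["translation"] = Rc @ (tf["translation"] - centre)

    data = np.stack([c.reshape(-1) for c in clouds_out])
    metadata = pd.DataFrame(
        [{"sample_id": s.sample_id, "subject_id": s.subject_id,
          "side": s.side, "sex": s.sex, "age": s.age,
          "mirrored": s.mirrored} for s in samples])
    return AlignedDataset(data=data, mean_vector=data.mean(axis=0),
                          metadata=metadata, transforms=transforms,
                          objective_history=history, n_iterations=n_iter,
                          config=config)


def correspond_to_reference(mesh_sample: ShapeSample,
                            reference_cloud: np.ndarray) -> ShapeSample:
    """Establish correspondence by closest point on the sample's surface.

    For each reference point the nearest point on the mesh (point-to-triangle)
    is taken, producing a cloud with one point per reference entry. This is a
    deterministic stand-in for dense surface correspondence; equidistant
    triangles resolve to the lowest triangle index.
    """
    if mesh_sample.faces is None or len(mesh_sample.faces) == 0:
        raise ValueError(
            f"sample {mesh_sample.sample_id or '<unnamed>'} has no faces; "
            "supply corresponded landmarks (CSV mode) instead")
    reference_cloud = np.asarray(reference_cloud, dtype=float)
    if reference_cloud.ndim != 2 or reference_cloud.shape[1] != 3:
        raise ValueError("reference_cloud must be an (n, 3) matrix")
    closest, _, _ = closest_points_on_mesh(reference_cloud,
                                           mesh_sample.points,
                                           mesh_sample.faces)
    return mesh_sample.with_geometry(closest, faces=None)
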