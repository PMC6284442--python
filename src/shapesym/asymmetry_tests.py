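"""Distance-based permutational tests of left/right shape group differences.

Three aspects of the two groups are compared, each with its own D-statistic:

* location — Euclidean distance between the group means;
* variance–covariance scale — absolute difference in the groups' average
  residual (mean distance of a sample to its own group mean);
* variance–covariance orientation — the projection metric between the
  groups' leading k-dimensional PCA subspaces, reported as the set
  D_1 … D_k obtained by adding principal angles one at a time.

Significance comes from permutation: group labels are reshuffled, the
statistic is recomputed from scratch (for orientation this means refitting
both subspaces), and the p-value is the fraction of permuted statistics
greater than or equal to the observed one. Ties count as exceedances, and
the default p-value is exactly n_exceed / n_perm (an ``add_one`` switch
gives the (N+1)-smoothed variant).
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Union

import numpy as np

__all__ = [
    "PermutationResult",
    "SubspaceComparison",
    "perm_p_value",
    "location_d",
    "scale_d",
    "principal_angles",
    "projection_metric",
    "projection_metric_set",
    "top_k_basis",
    "compare_subspaces",
    "permutation_test",
]

_STATISTICS = ("location", "scale", "orientation")


@dataclasses.dataclass
class PermutationResult:
    statistic: str
    d_observed: np.ndarray        # scalar () or (k,)
    d_perm: np.ndarray            # (n_perm,) or (n_perm, k)
    n_perm: int
    n_exceed: np.ndarray          # same shape as d_observed, integer counts
    p_perm: np.ndarray
    scheme: str
    seed: int
    k: Optional[int] = None
    add_one: bool = False


@dataclasses.dataclass
class SubspaceComparison:
    basis_left: np.ndarray        # (d, k), orthonormal columns
    basis_right: np.ndarray
    principal_angles: np.ndarray  # ascending, radians
    d_k_set: np.ndarray           # projection-metric distances D_1 … D_k


def perm_p_value(n_exceed, n_perm: int, add_one: bool = False):
    """Permutation p-value: the fraction of permuted statistics that are
    greater than or equal to the observed one, ``n_exceed / n_perm`` exactly
    (``add_one`` gives ``(n_exceed + 1) / (n_perm + 1)``)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_exceed = np.asarray(n_exceed)
    if np.any(n_exceed < 0) or np.any(n_exceed > n_perm):
        raise ValueError("n_exceed must lie in [0, n_perm]")
    if add_one:
        out = (n_exceed + 1) / (n_perm + 1)
    else:
        out = n_exceed / n_perm
    return float(out) if out.ndim == 0 else out


def _two_groups(left, right):
    L = np.atleast_2d(np.asarray(left, dtype=float))
    R = np.atleast_2d(np.asarray(right, dtype=float))
    if L.size == 0 or R.size == 0:
        raise ValueError("both groups must be non-empty")
    if L.shape[1] != R.shape[1]:
        raise ValueError(f"dimensionality mismatch: left has {L.shape[1]} "
                         f"features, right has {R.shape[1]}")
    return L, R


def location_d(left, right) -> float:
    """Euclidean distance between the two group means."""
    L, R = _two_groups(left, right)
    return float(np.linalg.norm(L.mean(axis=0) - R.mean(axis=0)))


def scale_d(left, right) -> float:
    """Absolute difference in average residual (distance to own group mean)."""
    L, R = _two_groups(left, right)
    res_l = np.linalg.norm(L - L.mean(axis=0), axis=1).mean()
    res_r = np.linalg.norm(R - R.mean(axis=0), axis=1).mean()
    return float(abs(res_l - res_r))


def principal_angles(basis_a: np.ndarray, basis_b: np.ndarray) -> np.ndarray:
    """Principal angles (ascending, radians) between two k-dim subspaces.

    ``theta_i = arccos(sigma_i)`` with sigma the singular values of
    ``basis_a.T @ basis_b``; bases must have orthonormal columns in the same
    ambient space.
    """
    A = np.asarray(basis_a, dtype=float)
    B = np.asarray(basis_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape != B.shape:
        raise ValueError("bases must be (d, k) matrices of identical shape")
    for name, M in (("basis_a", A), ("basis_b", B)):
        gram = M.T @ M
        if np.max(np.abs(gram - np.eye(M.shape[1]))) > 1e-6:
            raise ValueError(f"{name} does not have orthonormal columns")
    sigma = np.linalg.svd(A.T @ B, compute_uv=False)
    theta = np.arccos(np.clip(sigma, -1.0, 1.0))
    return np.sort(theta)


def projection_metric(theta: np.ndarray, j: int, squared: bool = False) -> float:
    """Projection-metric distance D_j from the first j principal angles.

    ``D_j = sqrt(j - sum_{i<=j} cos^2 theta_i)``, bounded by sqrt(j);
    ``squared=True`` drops the square root.
    """
    theta = np.asarray(theta, dtype=float)
    if not 1 <= j <= theta.shape[0]:
        raise ValueError(f"j must be in [1, {theta.shape[0]}], got {j}")
    d2 = j - float(np.sum(np.cos(theta[:j]) ** 2))
    d2 = max(d2, 0.0)
    return d2 if squared else float(np.sqrt(d2))


def projection_metric_set(theta: np.ndarray, squared: bool = False) -> np.ndarray:
    """All distances D_1 … D_k from incrementally added principal angles."""
    theta = np.asarray(theta, dtype=float)
    k = theta.shape[0]
    sin2 = np.sin(theta) ** 2  # j - sum cos^2 = sum sin^2, stabler cumulative
    d2 = np.maximum(np.cumsum(sin2), 0.0)
    return d2 if squared else np.sqrt(d2)


def top_k_basis(matrix: np.ndarray, k: int) -> np.ndarray:
    """Orthonormal basis (d, k) of a group's leading k PCA directions."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, d = X.shape
    if k < 1 or k > min(n - 1, d):
        raise ValueError(f"k must be in [1, {min(n - 1, d)}] for a group of "
                         f"{n} samples in {d} dimensions, got {k}")
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return vt[:k].T


def compare_subspaces(basis_left: np.ndarray, basis_right: np.ndarray,
                      squared: bool = False) -> SubspaceComparison:
    theta = principal_angles(basis_left, basis_right)
    return SubspaceComparison(basis_left=np.asarray(basis_left, dtype=float),
                              basis_right=np.asarray(basis_right, dtype=float),
                              principal_angles=theta,
                              d_k_set=projection_metric_set(theta, squared=squared))


def _top_gram(Xc: np.ndarray, k: int):
    """Top-k Gram eigenpairs (descending) of a centred row matrix."""
    w, u = np.linalg.eigh(Xc @ Xc.T)
    w, u = w[::-1][:k], u[:, ::-1][:, :k]
    if w[-1] <= 0:
        raise ValueError(f"group rank below k={k}; reduce k")
    return w, u


def _orientation_d(L: np.ndarray, R: np.ndarray, k: int,
                   squared: bool) -> np.ndarray:
    """D_1 … D_k between the groups' leading-k PCA subspaces.

    Uses the dual (Gram) route when the ambient dimension exceeds the group
    sizes: with Xc = U S V^T, the cross-product of the two V-bases equals
    the suitably normalised ``U_L^T (Xc_L Xc_R^T) U_R``, so the ambient
    bases are never materialised. Falls back to thin SVD otherwise.
    """
    Lc = L - L.mean(axis=0)
    Rc = R - R.mean(axis=0)
    d = Lc.shape[1]
    if d > max(Lc.shape[0], Rc.shape[0]):
        wl, ul = _top_gram(Lc, k)
        wr, ur = _top_gram(Rc, k)
        M = ul.T @ (Lc @ Rc.T) @ ur
        M /= np.sqrt(wl)[:, None]
        M /= np.sqrt(wr)[None, :]
        sigma = np.linalg.svd(M, compute_uv=False)
    else:
        def top_rows(X):
            _, _, vt = np.linalg.svd(X, full_matrices=False)
            return vt[:k]
        sigma = np.linalg.svd(top_rows(Lc) @ top_rows(Rc).T, compute_uv=False)
    theta = np.sort(np.arccos(np.clip(sigma, -1.0, 1.0)))
    return projection_metric_set(theta, squared=squared)


def permutation_test(statistic: str, left_samples, right_samples,
                     n_perm: int = 10_000, scheme: str = "side_swap",
                     seed: int = 0, k: Optional[int] = None,
                     squared: bool = False,
                     add_one: bool = False) -> PermutationResult:
    """Permutation test of a left/right group difference.

    Parameters
    ----------
    statistic : 'location', 'scale' or 'orientation'. Orientation requires
        ``k`` (subspace dimension, fixed for both groups at every
        permutation) and returns vectors D_1 … D_k with element-wise
        p-values.
    scheme : 'side_swap' exchanges each subject's pair independently with
        probability 1/2 (groups must be paired row-by-row); 'free' relabels
        all samples while preserving group sizes.
    add_one : report (N_i + 1) / (N_perm + 1) instead of N_i / N_perm.

    The statistic is fully recomputed on each permuted labelling; for
    orientation both PCA subspaces are re-estimated per permutation.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    if scheme not in ("side_swap", "free"):
        raise ValueError("scheme must be 'side_swap' or 'free'")
    L, R = _two_groups(left_samples, right_samples)
    if scheme == "side_swap" and L.shape[0] != R.shape[0]:
        raise ValueError("scheme='side_swap' needs groups paired by subject "
                         f"(got {L.shape[0]} left vs {R.shape[0]} right rows); "
                         "use scheme='free' for unpaired data")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-value resolution is "
                      f"only 1/{n_perm}", stacklevel=2)

    if statistic == "orientation":
        if k is None:
            raise ValueError("orientation statistic requires k")
        max_k = min(L.shape[0] - 1, R.shape[0] - 1, L.shape[1])
        if not 1 <= k <= max_k:
            raise ValueError(f"k must be in [1, {max_k}], got {k}")
        stat = lambda a, b: _orientation_d(a, b, k, squared)
    elif statistic == "location":
        stat = location_d
    else:
        stat = scale_d

    observed = np.asarray(stat(L, R), dtype=float)
    rng = np.random.default_rng(seed)
    n_l = L.shape[0]
    d_perm = np.empty((n_perm,) + observed.shape)
    if scheme == "side_swap":
        for p in range(n_perm):
            swap = rng.random(n_l) < 0.5
            pl = np.where(swap[:, None], R, L)
            pr = np.where(swap[:, None], L, R)
            d_perm[p] = stat(pl, pr)
    else:
        pooled = np.vstack([L, R])
        n_tot = pooled.shape[0]
        for p in range(n_perm):
            order = rng.permutation(n_tot)
            d_perm[p] = stat(pooled[order[:n_l]], pooled[order[n_l:]])

    n_exceed = np.sum(d_perm >= observed, axis=0)
    p_perm = perm_p_value(n_exceed, n_perm, add_one=add_one)
    return PermutationResult(statistic=statistic, d_observed=observed,
                             d_perm=d_perm, n_perm=n_perm,
                             n_exceed=np.asarray(n_exceed),
                             p_perm=np.asarray(p_perm, dtype=float),
                             scheme=scheme, seed=seed, k=k, add_one=add_one)
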