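"""Closest-point queries against triangle meshes and point clouds.

Shared by the correspondence and distance-map stages. Everything here is
plain numpy; queries are vectorised over triangles and chunked over query
points to bound memory.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_points_on_mesh", "nearest_points_in_cloud"]


def _closest_on_triangles(p: np.ndarray, a, b, c):
    """Closest point to ``p`` (3,) on each triangle (T, 3) -> (T, 3).

    Region-based construction (Voronoi regions of vertices/edges/face),
    branch-free via nested ``np.where`` so it vectorises over triangles.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        # edge AB
        t_ab = np.where(d1 - d3 != 0.0, d1 / (d1 - d3), 0.0)
        on_ab = a + t_ab[:, None] * ab
        # edge AC
        t_ac = np.where(d2 - d6 != 0.0, d2 / (d2 - d6), 0.0)
        on_ac = a + t_ac[:, None] * ac
        # edge BC
        num_bc = d4 - d3
        den_bc = num_bc + (d5 - d6)
        t_bc = np.where(den_bc != 0.0, num_bc / den_bc, 0.0)
        on_bc = b + t_bc[:, None] * (c - b)
        # interior
        denom = va + vb + vc
        denom = np.where(denom != 0.0, denom, 1.0)
        v = vb / denom
        w = vc / denom
        interior = a + v[:, None] * ab + w[:, None] * ac

    out = interior
    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(m_bc[:, None], on_bc, out)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(m_ac[:, None], on_ac, out)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(m_ab[:, None], on_ab, out)
    m_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(m_c[:, None], c, out)
    m_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(m_b[:, None], b, out)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_a[:, None], a, out)
    return out


def closest_points_on_mesh(points: np.ndarray, vertices: np.ndarray,
                           faces: np.ndarray):
    """Closest point on a triangulated surface for every query point.

    Parameters
    ----------
    points : (P, 3) query points.
    vertices : (V, 3) mesh vertices.
    faces : (T, 3) integer triangle indices.

    Returns
    -------
    closest : (P, 3) closest surface points.
    dist : (P,) unsigned Euclidean distances.
    tri_index : (P,) index of the owning triangle; exact ties resolve to
        the lowest triangle index.
    """
    points = np.asarray(points, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    if faces.size == 0:
        raise ValueError("mesh has no faces")
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]

    P = points.shape[0]
    closest = np.empty((P, 3))
    dist = np.empty(P)
    tri_index = np.empty(P, dtype=int)
    for i in range(P):
        cand = _closest_on_triangles(points[i], a, b, c)
        d2 = np.einsum("ij,ij->i", cand - points[i], cand - points[i])
        j = int(np.argmin(d2))  # argmin -> first minimum: lowest index wins
        closest[i] = cand[j]
        dist[i] = np.sqrt(d2[j])
        tri_index[i] = j
    return closest, dist, tri_index


def nearest_points_in_cloud(points: np.ndarray, cloud: np.ndarray):
    """Nearest-neighbour fallback when the target carries no faces."""
    tree = cKDTree(np.asarray(cloud, dtype=float))
    dist, idx = tree.query(np.asarray(points, dtype=float))
    return np.asarray(cloud)[idx], np.asarray(dist, dtype=float), idx
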