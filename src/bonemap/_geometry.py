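"""Vectorized triangle-mesh geometry kernels.

Minimal ray-casting and closest-point primitives (Moller-Trumbore and
point-triangle projection), batched with numpy.  Meshes in this package are
a few thousand triangles, so brute force over candidate triangles with a
KD-tree prefilter is fast and dependency-free.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

_EPS = 1e-12


def ray_chord_lengths(vertices: np.ndarray, faces: np.ndarray,
                      origins: np.ndarray, directions: np.ndarray,
                      *, offset: float = 1e-4,
                      chunk: int = 256) -> np.ndarray:
    """Distance from each origin to the first mesh intersection along its ray.

    Rays that hit nothing get +inf.  ``offset`` nudges each origin forward so
    a ray starting exactly on the surface does not immediately hit its own
    triangle.
    """
    tri = vertices[faces]  # (M, 3, 3)
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    out = np.full(len(origins), np.inf)
    for s in range(0, len(origins), chunk):
        o = origins[s:s + chunk] + offset * directions[s:s + chunk]
        d = directions[s:s + chunk]
        # Moller-Trumbore, broadcast rays x triangles
        p = np.cross(d[:, None, :], e2[None, :, :])
        det = np.einsum("mi,nmi->nm", e1, p)
        ok = np.abs(det) > _EPS
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        t_vec = o[:, None, :] - tri[None, :, 0, :]
        u = np.einsum("nmi,nmi->nm", t_vec, p) * inv
        q = np.cross(t_vec, e1[None, :, :])
        v = np.einsum("ni,nmi->nm", d, q) * inv
        t = np.einsum("mi,nmi->nm", e2, q) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > _EPS)
        t = np.where(hit, t, np.inf)
        out[s:s + chunk] = t.min(axis=1) + offset
    return out


def _point_triangle(points: np.ndarray, tri: np.ndarray):
    """Closest point on one triangle per (point, triangle) pair.

    ``points`` (K, 3) against ``tri`` (K, 3, 3); returns (closest (K, 3),
    barycentric (K, 3)).  Standard region-classification algorithm.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a
    d1 = np.einsum("ki,ki->k", ab, ap)
    d2 = np.einsum("ki,ki->k", ac, ap)
    bp = points - b
    d3 = np.einsum("ki,ki->k", ab, bp)
    d4 = np.einsum("ki,ki->k", ac, bp)
    cp = points - c
    d5 = np.einsum("ki,ki->k", ab, cp)
    d6 = np.einsum("ki,ki->k", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    bary = np.zeros((len(points), 3))
    # vertex regions
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    denom_ab = d1 - d3
    m_ab = (~m_a) & (~m_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    w_ab = np.where(np.abs(denom_ab) > _EPS, d1 / np.where(denom_ab == 0, 1, denom_ab), 0.0)
    denom_ac = d2 - d6
    m_ac = (~m_a) & (~m_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w_ac = np.where(np.abs(denom_ac) > _EPS, d2 / np.where(denom_ac == 0, 1, denom_ac), 0.0)
    denom_bc = (d4 - d3) + (d5 - d6)
    m_bc = (~m_b) & (~m_c) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    w_bc = np.where(np.abs(denom_bc) > _EPS,
                    (d4 - d3) / np.where(denom_bc == 0, 1, denom_bc), 0.0)

    # interior
    denom = va + vb + vc
    safe = np.where(np.abs(denom) > _EPS, denom, 1.0)
    v_int = vb / safe
    w_int = vc / safe
    bary[:, 0] = 1.0 - v_int - w_int
    bary[:, 1] = v_int
    bary[:, 2] = w_int

    bary[m_bc] = np.column_stack([np.zeros(m_bc.sum()), 1 - w_bc[m_bc], w_bc[m_bc]])
    bary[m_ac] = np.column_stack([1 - w_ac[m_ac], np.zeros(m_ac.sum()), w_ac[m_ac]])
    bary[m_ab] = np.column_stack([1 - w_ab[m_ab], w_ab[m_ab], np.zeros(m_ab.sum())])
    bary[m_c] = [0.0, 0.0, 1.0]
    bary[m_b] = [0.0, 1.0, 0.0]
    bary[m_a] = [1.0, 0.0, 0.0]

    bary = np.clip(bary, 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)
    closest = np.einsum("kj,kji->ki", bary, tri)
    return closest, bary


def closest_point_barycentric(vertices: np.ndarray, faces: np.ndarray,
                              points: np.ndarray, *, k: int = 10):
    """Project points onto a mesh: nearest triangle + barycentric weights.

    Candidate triangles are prefiltered by a KD-tree on triangle centroids
    (``k`` nearest per point), then refined exactly.  Returns
    ``(face_index, barycentric (N, 3), distance)``.
    """
    tri = vertices[faces]
    centroids = tri.mean(axis=1)
    k = min(k, len(faces))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand)
    n = len(points)
    rep_pts = np.repeat(points, k, axis=0)
    cand_flat = cand.ravel()
    closest, bary = _point_triangle(rep_pts, tri[cand_flat])
    d = np.linalg.norm(closest - rep_pts, axis=1).reshape(n, k)
    best = d.argmin(axis=1)
    rows = np.arange(n)
    face_idx = cand[rows, best]
    bary_best = bary.reshape(n, k, 3)[rows, best]
    return face_idx, bary_best, d[rows, best]
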