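"""Low-level vector geometry shared across modules.

All coordinates are world millimetres in a right-handed frame.
"""
from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raises on zero length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def orthonormal_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors (u, v) such that {u, v, normal} is right-handed.

    Uses a stable reference axis (the world axis least aligned with *normal*)
    so the result is deterministic.
    """
    n = unit(normal)
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(n)))] = 1.0
    u = unit(np.cross(ref, n))
    v = np.cross(n, u)  # already unit: n ⟂ u
    return u, v


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = unit(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def polyline_length(points: np.ndarray, closed: bool = False) -> float:
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    length = float(np.linalg.norm(seg, axis=1).sum())
    if closed and len(pts) > 1:
        length += float(np.linalg.norm(pts[0] - pts[-1]))
    return length


def resample_polyline(points: np.ndarray, n_out: int, closed: bool = False) -> np.ndarray:
    """Arc-length-uniform resampling of a polyline to ``n_out`` points.

    For a closed polyline the last input point is implicitly connected to the
    first and the output omits the duplicate closing point.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(pts[:1], n_out, axis=0)
    if closed:
        targets = np.linspace(0.0, total, n_out, endpoint=False)
    else:
        targets = np.linspace(0.0, total, n_out)
    out = np.empty((n_out, 3))
    for dim in range(3):
        out[:, dim] = np.interp(targets, s, pts[:, dim])
    return out


def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min distance from each of N points to each of M segments -> (N, M)."""
    p = np.asarray(points, dtype=float)[:, None, :]   # (N,1,3)
    a = np.asarray(a, dtype=float)[None, :, :]        # (1,M,3)
    b = np.asarray(b, dtype=float)[None, :, :]
    ab = b - a
    denom = np.einsum("nmk,nmk->nm", ab, ab)
    t = np.einsum("nmk,nmk->nm", p - a, ab) / np.where(denom == 0, 1.0, denom)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1)


def min_distance_to_polyline(points: np.ndarray, polyline: np.ndarray,
                             closed: bool = False) -> np.ndarray:
    """Exact shortest distance from each point to a polyline (per point)."""
    poly = np.asarray(polyline, dtype=float)
    if len(poly) < 2:
        raise ValueError("polyline needs at least 2 points")
    a, b = poly[:-1], poly[1:]
    if closed:
        a = np.vstack([a, poly[-1:]])
        b = np.vstack([b, poly[:1]])
    pts = np.asarray(points, dtype=float)
    # chunk over points to bound memory
    out = np.empty(len(pts))
    step = max(1, 2_000_000 // max(1, len(a)))
    for i in range(0, len(pts), step):
        out[i:i + step] = point_segment_distance(pts[i:i + step], a, b).min(axis=1)
    return out


def _point_triangle_distance_block(points: np.ndarray, v0, v1, v2) -> np.ndarray:
    """Distances from N points to M triangles -> (N, M). Exact (region test).

    Projects each point onto the triangle plane; inside-triangle projections
    use the plane distance, otherwise the minimum over the three edges.
    Degenerate (zero-area) triangles fall back to edge distances.
    """
    p = points[:, None, :]                       # (N,1,3)
    e0 = (v1 - v0)[None]                         # (1,M,3)
    e1 = (v2 - v0)[None]
    w = p - v0[None]
    nrm = np.cross(e0, e1)                       # (1,M,3)
    nn = np.einsum("nmk,nmk->nm", nrm, nrm)      # |n|^2
    # barycentric coordinates of in-plane projection
    d00 = np.einsum("nmk,nmk->nm", e0, e0)
    d01 = np.einsum("nmk,nmk->nm", e0, e1)
    d11 = np.einsum("nmk,nmk->nm", e1, e1)
    d20 = np.einsum("nmk,nmk->nm", w, e0)
    d21 = np.einsum("nmk,nmk->nm", w, e1)
    denom = d00 * d11 - d01 * d01
    safe = np.where(denom <= 0, 1.0, denom)
    u = (d11 * d20 - d01 * d21) / safe
    v = (d00 * d21 - d01 * d20) / safe
    inside = (u >= 0) & (v >= 0) & (u + v <= 1) & (denom > 0) & (nn > 0)
    dist_plane = np.abs(np.einsum("nmk,nmk->nm", w, nrm)) / np.sqrt(np.where(nn == 0, 1.0, nn))

    d_e = point_segment_distance(points, v0, v1)
    d_e = np.minimum(d_e, point_segment_distance(points, v1, v2))
    d_e = np.minimum(d_e, point_segment_distance(points, v2, v0))
    return np.where(inside, dist_plane, d_e)


def point_triangle_distance(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact min distance from each point to a triangle soup -> (N,).

    ``triangles`` has shape (M, 3, 3). Computed in blocks to bound memory.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(triangles, dtype=float)
    if tri.ndim != 3 or tri.shape[1:] != (3, 3):
        raise ValueError("triangles must have shape (M, 3, 3)")
    if len(tri) == 0:
        raise ValueError("empty triangle set")
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    best = np.full(len(pts), np.inf)
    pstep = max(1, 4_000_000 // max(1, len(tri)))
    for i in range(0, len(pts), pstep):
        block = _point_triangle_distance_block(pts[i:i + pstep], v0, v1, v2)
        best[i:i + pstep] = block.min(axis=1)
    return best


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cr, axis=1)


def shoelace_area(xy: np.ndarray) -> float:
    """Unsigned polygon area from ordered 2D vertices (closure implicit)."""
    p = np.asarray(xy, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
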