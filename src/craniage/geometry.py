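"""Small mesh-geometry routines: point-to-surface distance and a
triangle-triangle self-intersection scan.

These back the fit-accuracy measurements and the post-fit audit.  They
use exact point-triangle projection (Eberly's region decomposition) and
Moller's interval-overlap triangle intersection test, with KD-tree
culling so only nearby primitive pairs are tested.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
import trimesh


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distances from points p (N,3) to triangles tri (N,3,3), paired."""
    B, E0, E1 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    D = B - p
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    d = np.einsum("ij,ij->i", E0, D)
    e = np.einsum("ij,ij->i", E1, D)
    det = np.maximum(a * c - b * b, 1e-30)
    s = (b * e - c * d) / det
    t = (b * d - a * e) / det
    # clamp to the triangle's barycentric domain
    s = np.clip(s, 0.0, 1.0)
    t = np.clip(t, 0.0, 1.0)
    over = s + t > 1.0
    if np.any(over):
        # project onto the hypotenuse s + t = 1
        tmp = np.clip((c[over] + e[over] - b[over] - d[over])
                      / np.maximum(a[over] - 2 * b[over] + c[over], 1e-30),
                      0.0, 1.0)
        s[over] = tmp
        t[over] = 1.0 - tmp
    # clamping can move us off the constrained minimiser; also try the
    # three boundary 1-D minimisations and keep the best candidate
    s_edge = np.clip(-d / np.maximum(a, 1e-30), 0.0, 1.0)
    t_edge = np.clip(-e / np.maximum(c, 1e-30), 0.0, 1.0)
    cand_s = np.stack([s, s_edge, np.zeros_like(s)], axis=1)
    cand_t = np.stack([t, np.zeros_like(t), t_edge], axis=1)
    # hypotenuse candidate
    tmp = np.clip((c + e - b - d) / np.maximum(a - 2 * b + c, 1e-30), 0, 1)
    cand_s = np.concatenate([cand_s, tmp[:, None]], axis=1)
    cand_t = np.concatenate([cand_t, (1 - tmp)[:, None]], axis=1)
    pts = (B[:, None, :] + cand_s[..., None] * E0[:, None, :]
           + cand_t[..., None] * E1[:, None, :])
    d2 = np.sum((pts - p[:, None, :]) ** 2, axis=2)
    return np.sqrt(d2.min(axis=1))


def points_to_mesh_distance(points: np.ndarray, mesh: trimesh.Trimesh,
                            k: int = 24) -> np.ndarray:
    """Unsigned distance from each point to the triangulated surface.

    Candidate triangles are the ``k`` whose centroids are nearest each
    query point; exact point-triangle distances are then minimised.
    """
    tris = mesh.triangles
    cent = tris.mean(axis=1)
    tree = cKDTree(cent)
    k = min(k, len(tris))
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    n = len(points)
    best = np.full(n, np.inf)
    for j in range(idx.shape[1]):
        dj = _point_triangle_distance(points, tris[idx[:, j]])
        best = np.minimum(best, dj)
    return best


def mean_symmetric_distance(mesh_a: trimesh.Trimesh,
                            mesh_b: trimesh.Trimesh,
                            samples: int = 4000,
                            seed: int = 0) -> float:
    """Mean of the two directed mean surface distances, mm."""
    rng = np.random.default_rng(seed)

    def sample(m):
        pts = np.vstack([m.vertices, m.triangles.mean(axis=1)])
        if len(pts) > samples:
            pts = pts[rng.choice(len(pts), samples, replace=False)]
        return pts

    d_ab = points_to_mesh_distance(sample(mesh_a), mesh_b).mean()
    d_ba = points_to_mesh_distance(sample(mesh_b), mesh_a).mean()
    return 0.5 * (d_ab + d_ba)


# --------------------------------------------------------------------------
# triangle-triangle intersection audit
# --------------------------------------------------------------------------

def _tri_tri_overlap(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Vectorised Moller test for triangle pairs t1, t2 of shape (N,3,3).

    Returns a boolean per pair; shared-vertex (adjacent) pairs must be
    filtered out by the caller.
    """
    eps = 1e-10

    def plane(tri):
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        d = -np.einsum("ij,ij->i", n, tri[:, 0])
        return n, d

    n1, d1 = plane(t1)
    n2, d2 = plane(t2)
    s1 = np.einsum("nj,nkj->nk", n1, t2) + d1[:, None]
    s2 = np.einsum("nj,nkj->nk", n2, t1) + d2[:, None]
    sep1 = np.all(s1 > eps, axis=1) | np.all(s1 < -eps, axis=1)
    sep2 = np.all(s2 > eps, axis=1) | np.all(s2 < -eps, axis=1)
    cand = ~(sep1 | sep2)
    out = np.zeros(len(t1), dtype=bool)
    if not np.any(cand):
        return out
    # interval test on the intersection line L = cross(n1, n2)
    for i in np.nonzero(cand)[0]:
        L = np.cross(n1[i], n2[i])
        if np.linalg.norm(L) < eps:      # coplanar: treat via 2D overlap
            out[i] = _coplanar_overlap(t1[i], t2[i], n1[i])
            continue
        i1 = _line_interval(t1[i], s2[i], L)
        i2 = _line_interval(t2[i], s1[i], L)
        if i1 is None or i2 is None:
            continue
        out[i] = (min(i1[1], i2[1]) - max(i1[0], i2[0])) > eps
    return out


def _line_interval(tri, dists, L):
    """Projection interval of a triangle's plane crossing onto line L."""
    proj = tri @ L
    pos = dists > 1e-10
    neg = dists < -1e-10
    if pos.sum() == 0 or neg.sum() == 0:
        # no genuine crossing (vertices touching the plane are ignored)
        return None
    # the lone vertex lies on the side occupied by exactly one vertex
    lone_side = pos if pos.sum() == 1 else neg
    lone = int(np.nonzero(lone_side)[0][0])
    other = [j for j in range(3) if j != lone]
    pts = []
    for j in other:
        t = dists[lone] / (dists[lone] - dists[j])
        pts.append(proj[lone] + t * (proj[j] - proj[lone]))
    return (min(pts), max(pts))


def _coplanar_overlap(t1, t2, n) -> bool:
    ax = np.argmax(np.abs(n))
    keep = [j for j in range(3) if j != ax]
    a, b = t1[:, keep], t2[:, keep]

    def edges(t):
        return [(t[i], t[(i + 1) % 3]) for i in range(3)]

    def seg_int(p1, p2, p3, p4):
        d1 = np.cross(p4 - p3, p1 - p3)
        d2 = np.cross(p4 - p3, p2 - p3)
        d3 = np.cross(p2 - p1, p3 - p1)
        d4 = np.cross(p2 - p1, p4 - p1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    for e1 in edges(a):
        for e2 in edges(b):
            if seg_int(*e1, *e2):
                return True

    def inside(p, t):
        s = [np.cross(t[(i + 1) % 3] - t[i], p - t[i]) for i in range(3)]
        return all(x > 0 for x in s) or all(x < 0 for x in s)

    return inside(a[0], b) or inside(b[0], a)


def self_intersections(mesh: trimesh.Trimesh, max_pairs: int = 2_000_000) -> int:
    """Number of intersecting non-adjacent triangle pairs (0 = clean)."""
    tris = mesh.triangles
    faces = mesh.faces
    cent = tris.mean(axis=1)
    rad = np.linalg.norm(tris - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cent)
    pairs = tree.query_pairs(2.0 * rad.max(), output_type="ndarray")
    if len(pairs) > max_pairs:
        raise RuntimeError("too many candidate pairs for the audit")
    if len(pairs) == 0:
        return 0
    # drop pairs sharing a vertex and pairs whose bounding spheres miss
    share = np.array([len(set(faces[i]) & set(faces[j])) > 0
                      for i, j in pairs])
    pairs = pairs[~share]
    if len(pairs) == 0:
        return 0
    d = np.linalg.norm(cent[pairs[:, 0]] - cent[pairs[:, 1]], axis=1)
    close = d <= rad[pairs[:, 0]] + rad[pairs[:, 1]]
    pairs = pairs[close]
    if len(pairs) == 0:
        return 0
    hits = _tri_tri_overlap(tris[pairs[:, 0]], tris[pairs[:, 1]])
    return int(hits.sum())
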