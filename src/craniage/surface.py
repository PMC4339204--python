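"""Closed annotated subdivision surface modelling the fetal cranium.

The cranial surface is a smooth, closed, genus-0 surface controlled by a
small set of control vertices ``X`` arranged on a quad-dominant control
mesh derived from a subdivided cube.  Every point on the surface is an
affine (convex) combination of the control vertices::

    p = M(u, X) = X . b(u),   b(u) >= 0,  sum b(u) = 1

where ``u = (face_id, s, t)`` is a face-local surface coordinate.  The
mapping is realised by a fixed number of Catmull-Clark subdivision steps
applied to the control mesh, followed by bilinear interpolation on the
refined mesh.  Both subdivision and bilinear interpolation are linear
with non-negative convex weights, so the contract above holds exactly,
which is what the continuous surface-fitting optimiser relies on.

Control faces carry one of four coarse anatomical annotations (left and
right cerebral hemisphere, frontal cortex, falx cerebri) which are
propagated to every evaluated surface point.

Coordinate conventions: x separates the hemispheres (midsagittal plane
at x = 0, left hemisphere at x < 0), y points anterior (frontal cortex),
z superior.  The control-face unit square has corners
(0,0), (1,0), (1,1), (0,1) following the face's vertex winding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy.spatial.transform import Rotation

REGION_LABELS = ("left", "right", "frontal", "falx")


# --------------------------------------------------------------------------
# basic quad-mesh topology helpers
# --------------------------------------------------------------------------

def _edge_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def quad_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (i, j), i < j, of a quad mesh."""
    e = set()
    for f in faces:
        n = len(f)
        for k in range(n):
            e.add(_edge_key(int(f[k]), int(f[(k + 1) % n])))
    return np.array(sorted(e), dtype=np.int64)


def _midpoint_subdivide(vertices: np.ndarray, faces: np.ndarray):
    """One linear (midpoint) quad-subdivision step; used to build the
    control mesh itself, not the limit surface."""
    nv = len(vertices)
    edges = quad_edges(faces)
    eidx = {tuple(e): i for i, e in enumerate(edges.tolist())}
    face_pts = vertices[faces].mean(axis=1)
    edge_pts = 0.5 * (vertices[edges[:, 0]] + vertices[edges[:, 1]])
    new_v = np.vstack([vertices, face_pts, edge_pts])
    fofs, eofs = nv, nv + len(faces)
    new_faces = []
    for fi, f in enumerate(faces):
        for k in range(4):
            vk = int(f[k])
            e_next = eofs + eidx[_edge_key(vk, int(f[(k + 1) % 4]))]
            e_prev = eofs + eidx[_edge_key(int(f[(k - 1) % 4]), vk)]
            new_faces.append([vk, e_next, fofs + fi, e_prev])
    return new_v, np.asarray(new_faces, dtype=np.int64)


# --------------------------------------------------------------------------
# control mesh
# --------------------------------------------------------------------------

@dataclass
class ControlMesh:
    """Closed annotated quad control mesh of the cranial surface.

    Attributes
    ----------
    vertices : (NX, 3) float array, mm.  The control vertices X.
    faces : (NF, 4) int array, consistently (outward-CCW) wound quads.
    face_annotations : (NF,) array of region labels from REGION_LABELS.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_annotations: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (NX, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 4:
            raise ValueError("faces must be (NF, 4) quads")
        if len(self.face_annotations) != len(self.faces):
            raise ValueError("every face needs an annotation")
        unknown = set(map(str, self.face_annotations)) - set(REGION_LABELS)
        if unknown:
            raise ValueError(f"unknown region labels: {unknown}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edge_set(self) -> np.ndarray:
        """Symmetric vertex adjacency used by the surface regulariser."""
        return quad_edges(self.faces)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edge_set) + len(self.faces)


def default_annotated_sphere(subdiv_level: int = 2, falx_band: float = 0.25,
                             frontal_min_y: float = 0.55) -> ControlMesh:
    """Unit-radius annotated quad sphere used as the default skull model.

    A cube is midpoint-subdivided ``subdiv_level`` times and projected to
    the unit sphere; faces are annotated by centroid position: a band
    |x| < ``falx_band`` is falx, anterior faces (y > ``frontal_min_y``)
    are frontal cortex, the rest split into left/right hemispheres.
    """
    if subdiv_level < 1:
        raise ValueError("subdiv_level must be >= 1")
    # cube with outward-CCW winding
    v = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                  [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)
    f = np.array([[0, 3, 2, 1],   # bottom (z=-1)
                  [4, 5, 6, 7],   # top (z=+1)
                  [0, 1, 5, 4],   # y=-1
                  [2, 3, 7, 6],   # y=+1
                  [1, 2, 6, 5],   # x=+1
                  [3, 0, 4, 7]],  # x=-1
                 dtype=np.int64)
    for _ in range(subdiv_level):
        v, f = _midpoint_subdivide(v, f)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    cent = v[f].mean(axis=1)
    labels = np.empty(len(f), dtype=object)
    falx = np.abs(cent[:, 0]) < falx_band
    frontal = ~falx & (cent[:, 1] > frontal_min_y)
    left = ~falx & ~frontal & (cent[:, 0] < 0)
    labels[falx] = "falx"
    labels[frontal] = "frontal"
    labels[left] = "left"
    labels[~falx & ~frontal & ~left] = "right"
    return ControlMesh(v, f, labels)


def initialize(mesh: ControlMesh,
               translation: Sequence[float] = (0.0, 0.0, 0.0),
               rotation_deg: Sequence[float] = (0.0, 0.0, 0.0),
               scale: Sequence[float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """9-DoF similarity placement of the default control vertices.

    Returns X0 = R . diag(scale) . X_default + t applied per vertex,
    the anchor of the deformation-penalty term during fitting.  Rotation
    is extrinsic xyz Euler, degrees.
    """
    scale = np.asarray(scale, float)
    if np.any(scale <= 0):
        raise ValueError("scales must be positive")
    R = Rotation.from_euler("xyz", rotation_deg, degrees=True).as_matrix()
    return (mesh.vertices * scale) @ R.T + np.asarray(translation, float)


# --------------------------------------------------------------------------
# surface coordinates and regular sampling
# --------------------------------------------------------------------------

@dataclass
class SurfaceSampling:
    """NU face-local surface coordinates with a neighbour graph.

    ``face_ids`` (NU,), ``st`` (NU, 2) in the unit square, and
    ``neighbour_graph`` as an (E, 2) index array linking grid-adjacent
    samples within and across control faces.
    """

    face_ids: np.ndarray
    st: np.ndarray
    neighbour_graph: np.ndarray

    def __len__(self) -> int:
        return len(self.face_ids)


# edge k of a quad runs v_k -> v_{k+1}; border samples of an n x n grid
# along each edge, ordered in the edge direction
def _border_indices(per_face: int, edge: int) -> np.ndarray:
    n = per_face
    idx = np.arange(n)
    if edge == 0:    # v0->v1: t=0 row, increasing s
        return idx * n + 0
    if edge == 1:    # v1->v2: s=1 column, increasing t
        return (n - 1) * n + idx
    if edge == 2:    # v2->v3: t=1 row, decreasing s
        return (idx[::-1]) * n + (n - 1)
    return 0 * n + idx[::-1]  # v3->v0: s=0 column, decreasing t


def sample_regular(mesh: ControlMesh, per_face: int = 2) -> SurfaceSampling:
    """Stratified per_face x per_face sampling of every control face.

    Sample (i, j) of a face sits at ((i+.5)/n, (j+.5)/n); the neighbour
    graph links grid-adjacent samples, including across shared face
    edges (matched respecting edge orientation).
    """
    if per_face < 1:
        raise ValueError("per_face must be >= 1")
    n = per_face
    g = (np.arange(n) + 0.5) / n
    ss, tt = np.meshgrid(g, g, indexing="ij")
    st_face = np.column_stack([ss.ravel(), tt.ravel()])  # index i*n+j
    nf = len(mesh.faces)
    face_ids = np.repeat(np.arange(nf), n * n)
    st = np.tile(st_face, (nf, 1))

    edges = []
    for fi in range(nf):
        base = fi * n * n
        for i in range(n):
            for j in range(n):
                k = base + i * n + j
                if i + 1 < n:
                    edges.append((k, k + n))
                if j + 1 < n:
                    edges.append((k, k + 1))
    # cross-face links: for each shared control edge, pair border samples
    edge_owner: dict[tuple[int, int], tuple[int, int]] = {}
    for fi, f in enumerate(mesh.faces):
        for k in range(4):
            a, b = int(f[k]), int(f[(k + 1) % 4])
            key = _edge_key(a, b)
            if key in edge_owner:
                fj, kj = edge_owner[key]
                bi = _border_indices(n, k) + fi * n * n
                bj = _border_indices(n, kj) + fj * n * n
                # the shared edge is traversed in opposite directions in
                # the two faces (consistent winding), so reverse one side
                for p, q in zip(bi, bj[::-1]):
                    edges.append((int(p), int(q)))
            else:
                edge_owner[key] = (fi, k)
    e = np.unique(np.sort(np.asarray(edges, dtype=np.int64), axis=1), axis=0)
    return SurfaceSampling(face_ids, st, e)


# --------------------------------------------------------------------------
# Catmull-Clark refinement operator (linear, convex weights)
# --------------------------------------------------------------------------

def _catmull_clark_step(nv: int, faces: np.ndarray,
                        root_face: np.ndarray, corner_uv: np.ndarray):
    """One Catmull-Clark step on a closed quad mesh.

    Returns the sparse (nv_new, nv) refinement matrix, the child quads,
    and the per-child (root_face, corner_uv) bookkeeping that tracks
    where each child sits inside its root control face's unit square.
    """
    edges = quad_edges(faces)
    eidx = {tuple(e): i for i, e in enumerate(edges.tolist())}
    nf, ne = len(faces), len(edges)

    rows, cols, vals = [], [], []

    def add(r, c, w):
        rows.append(r)
        cols.append(c)
        vals.append(w)

    # ordering of new vertices: [updated originals | face points | edge points]
    fofs, eofs = nv, nv + nf

    # face points
    for fi, f in enumerate(faces):
        for vtx in f:
            add(fofs + fi, int(vtx), 0.25)

    # adjacency
    vert_faces: list[list[int]] = [[] for _ in range(nv)]
    for fi, f in enumerate(faces):
        for vtx in f:
            vert_faces[int(vtx)].append(fi)
    edge_faces: list[list[int]] = [[] for _ in range(ne)]
    for fi, f in enumerate(faces):
        for k in range(4):
            edge_faces[eidx[_edge_key(int(f[k]), int(f[(k + 1) % 4]))]].append(fi)
    vert_edges: list[list[int]] = [[] for _ in range(nv)]
    for ei, (a, b) in enumerate(edges):
        vert_edges[int(a)].append(ei)
        vert_edges[int(b)].append(ei)

    # edge points: average of the two endpoints and two adjacent face points
    for ei, (a, b) in enumerate(edges):
        fa, fb = edge_faces[ei]
        add(eofs + ei, int(a), 0.25)
        add(eofs + ei, int(b), 0.25)
        for vtx in faces[fa]:
            add(eofs + ei, int(vtx), 0.25 * 0.25)
        for vtx in faces[fb]:
            add(eofs + ei, int(vtx), 0.25 * 0.25)

    # vertex update: (Fbar + 2*Rbar + (val-3)*P) / val
    for vi in range(nv):
        val = len(vert_faces[vi])
        for fi in vert_faces[vi]:
            for vtx in faces[fi]:
                add(vi, int(vtx), 0.25 / (val * val))
        for ei in vert_edges[vi]:
            a, b = edges[ei]
            add(vi, int(a), 2.0 * 0.5 / (val * val))
            add(vi, int(b), 2.0 * 0.5 / (val * val))
        add(vi, vi, (val - 3.0) / val)

    A = sp.coo_matrix((vals, (rows, cols)),
                      shape=(nv + nf + ne, nv)).tocsr()
    A.sum_duplicates()

    new_faces, new_root, new_uv = [], [], []
    for fi, f in enumerate(faces):
        uv = corner_uv[fi]
        centre = uv.mean(axis=0)
        for k in range(4):
            vk = int(f[k])
            e_next = eofs + eidx[_edge_key(vk, int(f[(k + 1) % 4]))]
            e_prev = eofs + eidx[_edge_key(int(f[(k - 1) % 4]), vk)]
            new_faces.append([vk, e_next, fofs + fi, e_prev])
            new_root.append(root_face[fi])
            new_uv.append([uv[k],
                           0.5 * (uv[k] + uv[(k + 1) % 4]),
                           centre,
                           0.5 * (uv[(k - 1) % 4] + uv[k])])
    return (A, np.asarray(new_faces, dtype=np.int64),
            np.asarray(new_root, dtype=np.int64), np.asarray(new_uv, float))


class Surface:
    """Evaluable cranial surface: control mesh + fixed-depth refinement.

    Precomputes the linear operator S mapping control vertices to the
    refined mesh and a per-control-face cell table so that
    ``evaluate(face_ids, st, X)`` is a fast gather + bilinear blend.
    """

    def __init__(self, mesh: ControlMesh, depth: int = 3):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.mesh = mesh
        self.depth = depth
        nv = mesh.n_vertices
        faces = mesh.faces
        root = np.arange(len(faces), dtype=np.int64)
        uv = np.tile(np.array([[0., 0.], [1., 0.], [1., 1.], [0., 1.]]),
                     (len(faces), 1, 1))
        S = sp.identity(nv, format="csr")
        for _ in range(depth):
            A, faces, root, uv = _catmull_clark_step(S.shape[0], faces,
                                                     root, uv)
            S = A @ S
        self.S: sp.csr_matrix = S.tocsr()
        self.ref_faces = faces
        self.ref_root = root
        self.ref_corner_uv = uv

        # cell lookup: the children of a control face tile its unit
        # square with axis-aligned cells of side 2^-depth
        m = 2 ** depth
        self._m = m
        table = np.full((len(mesh.faces), m, m), -1, dtype=np.int64)
        mins = uv.min(axis=1)
        ci = np.rint(mins[:, 0] * m).astype(int)
        cj = np.rint(mins[:, 1] * m).astype(int)
        table[root, ci, cj] = np.arange(len(faces))
        if np.any(table < 0):
            raise RuntimeError("refinement cell table incomplete")
        self._cell_table = table
        # local frame inverse per refined face: st = c0 + a*(c1-c0) + b*(c3-c0)
        c0 = uv[:, 0]
        E = np.stack([uv[:, 1] - c0, uv[:, 3] - c0], axis=2)  # (F,2,2) cols
        self._cell_c0 = c0
        self._cell_Einv = np.linalg.inv(E)
        # per-control-face support of the basis (union over cells),
        # used for Jacobian sparsity in the fitting stage
        self._face_support: list[np.ndarray] = []
        indptr, indices = self.S.indptr, self.S.indices
        for fi in range(len(mesh.faces)):
            verts = np.unique(self.ref_faces[self.ref_root == fi])
            cols = np.unique(np.concatenate(
                [indices[indptr[v]:indptr[v + 1]] for v in verts]))
            self._face_support.append(cols)

    # -- mesh views ---------------------------------------------------

    def refined_vertices(self, X: np.ndarray) -> np.ndarray:
        return self.S @ np.asarray(X, float)

    def refined_triangles(self) -> np.ndarray:
        q = self.ref_faces
        return np.vstack([q[:, [0, 1, 2]], q[:, [0, 2, 3]]])

    def to_trimesh(self, X: np.ndarray) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.refined_vertices(X),
                               faces=self.refined_triangles(),
                               process=False)

    def signed_volume(self, X: np.ndarray) -> float:
        v = self.refined_vertices(X)
        t = v[self.refined_triangles()]
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def face_support(self, face_id: int) -> np.ndarray:
        """Control-vertex indices that can influence points on a face."""
        return self._face_support[face_id]

    # -- evaluation ---------------------------------------------------

    def _locate(self, face_ids, st):
        st = np.asarray(st, float)
        m = self._m
        ij = np.clip((st * m).astype(int), 0, m - 1)
        rf = self._cell_table[np.asarray(face_ids, int), ij[:, 0], ij[:, 1]]
        local = np.einsum("nij,nj->ni", self._cell_Einv[rf],
                          st - self._cell_c0[rf])
        return rf, np.clip(local, 0.0, 1.0)

    def evaluate(self, face_ids, st, X):
        """Points and outward unit normals at surface coordinates.

        Parameters are arrays (NU,), (NU, 2) and control vertices
        (NX, 3); returns (points (NU, 3), normals (NU, 3)).
        """
        X = np.asarray(X, float)
        rf, ab = self._locate(face_ids, st)
        refV = self.refined_vertices(X)
        P = refV[self.ref_faces[rf]]            # (NU, 4, 3)
        a = ab[:, :1]
        b = ab[:, 1:2]
        pts = ((1 - a) * (1 - b) * P[:, 0] + a * (1 - b) * P[:, 1]
               + a * b * P[:, 2] + (1 - a) * b * P[:, 3])
        da = (1 - b) * (P[:, 1] - P[:, 0]) + b * (P[:, 2] - P[:, 3])
        db = (1 - a) * (P[:, 3] - P[:, 0]) + a * (P[:, 2] - P[:, 1])
        nrm = np.cross(da, db)
        ln = np.linalg.norm(nrm, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        # outward orientation fixed by the signed volume of the mesh
        sign = np.sign(self.signed_volume(X))
        return pts, (sign if sign != 0 else 1.0) * nrm / ln

    def basis_weights(self, face_ids, st) -> np.ndarray:
        """Dense (NU, NX) convex basis b(u); evaluate() == b(u) @ X."""
        rf, ab = self._locate(face_ids, st)
        w = np.stack([(1 - ab[:, 0]) * (1 - ab[:, 1]),
                      ab[:, 0] * (1 - ab[:, 1]),
                      ab[:, 0] * ab[:, 1],
                      (1 - ab[:, 0]) * ab[:, 1]], axis=1)  # (NU, 4)
        Sd = self.S  # csr
        out = np.zeros((len(rf), Sd.shape[1]))
        corners = self.ref_faces[rf]  # (NU, 4)
        for k in range(4):
            rowsk = np.asarray(Sd[corners[:, k]].todense())
            out += w[:, k:k + 1] * rowsk
        return out

    def point_labels(self, sampling: SurfaceSampling) -> np.ndarray:
        """Region label per sample, propagated from control faces."""
        return np.asarray(
            [self.mesh.face_annotations[f] for f in sampling.face_ids],
            dtype=object)


@dataclass
class EvaluatedSurface:
    """Concrete surface points/normals with inherited region labels."""

    points: np.ndarray
    normals: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        n = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(n, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length")


def evaluate_sampling(surface: Surface, sampling: SurfaceSampling,
                      X: np.ndarray) -> EvaluatedSurface:
    pts, nrm = surface.evaluate(sampling.face_ids, sampling.st, X)
    return EvaluatedSurface(pts, nrm, surface.point_labels(sampling))


# --------------------------------------------------------------------------
# PLY I/O with per-face region annotation
# --------------------------------------------------------------------------

_REGION_TO_INT = {r: i for i, r in enumerate(REGION_LABELS)}


def save_control_mesh(mesh: ControlMesh, path) -> None:
    """ASCII PLY with an integer per-face ``region`` property."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property int region\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        for f, lab in zip(mesh.faces, mesh.face_annotations):
            fh.write(f"4 {f[0]} {f[1]} {f[2]} {f[3]} {_REGION_TO_INT[str(lab)]}\n")


def load_control_mesh(path) -> ControlMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        nv = nf = None
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                nv = int(line.split()[-1])
            elif line.startswith("element face"):
                nf = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.array([[float(x) for x in fh.readline().split()]
                          for _ in range(nv)])
        faces, labels = [], []
        for _ in range(nf):
            parts = fh.readline().split()
            cnt = int(parts[0])
            faces.append([int(x) for x in parts[1:1 + cnt]])
            labels.append(REGION_LABELS[int(parts[1 + cnt])])
    return ControlMesh(verts, np.asarray(faces), np.asarray(labels, object))
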