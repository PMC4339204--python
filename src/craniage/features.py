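"""Surface-anchored feature banks linking cranial geometry and image
appearance to gestational age.

Three banks are evaluated on a (volume, fitted surface) pair, always on
one cerebral hemisphere (the distal, non-occluded one):

* appearance: cuboidal volumes-of-interest (VOIs) whose side length
  scales with the distance ||p - p'|| between the anchoring cranial
  point p and its projection p' onto the midsagittal plane, so that the
  same descriptor samples anatomically corresponding tissue regardless
  of head size.  Scores are Haar-like two-cuboid differences, plain
  voxel sums (unary), or differences of sums at two cranial points
  (binary context).  Sulcal VOIs sit on the surface oriented along its
  normal; intracranial VOIs are displaced from p toward the midplane by
  r * ||p - p'||, r in (0, 1).
* local size: Euclidean or per-axis signed distances from a cranial
  point to one of its k = 9 nearest surface neighbours (ball-tree
  search), capturing local skull growth.
* biometric: the inner head circumference -- the perimeter of the
  closed contour where the transthalamic (TT) plane cuts the fitted
  inner-skull surface.

Descriptor parameters are drawn once at random (side-length ratio
ls ~ U(0, 0.5), displacement ratio r ~ U(0, 1), uniform point/template/
rank/axis) and then frozen, making every descriptor a deterministic,
serialisable measurement recipe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
import trimesh
from sklearn.neighbors import BallTree

from .surface import EvaluatedSurface

APPEARANCE_KINDS = ("haar3d", "unary", "binary_context")
SIZE_KINDS = ("size_euclid", "size_ortho")
ALL_KINDS = APPEARANCE_KINDS + SIZE_KINDS + ("inner_hc",)
N_HAAR_TEMPLATES = 6   # split along each VOI axis, two polarities
KNN = 9
VOI_GRID = 7           # fixed 7x7x7 trilinear sampling grid


# --------------------------------------------------------------------------
# hemisphere geometry
# --------------------------------------------------------------------------

@dataclass
class HemisphereSampling:
    """Cranial points of one hemisphere with midplane projections."""

    side: str                  # 'left' or 'right'
    points: np.ndarray         # (NPh, 3) mm
    normals: np.ndarray        # (NPh, 3) unit, outward
    plane_point: np.ndarray    # point on the midsagittal plane Ym
    plane_normal: np.ndarray   # unit, oriented toward the side
    _tree: BallTree | None = field(default=None, repr=False)

    @property
    def dist_to_plane(self) -> np.ndarray:
        return (self.points - self.plane_point) @ self.plane_normal

    @property
    def projections(self) -> np.ndarray:
        d = self.dist_to_plane
        return self.points - d[:, None] * self.plane_normal

    def tree(self) -> BallTree:
        if self._tree is None:
            self._tree = BallTree(self.points)
        return self._tree


def fit_midplane(surface: EvaluatedSurface) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the falx-labelled surface points."""
    falx = surface.points[np.asarray(surface.labels) == "falx"]
    if len(falx) < 3:
        raise ValueError("surface has no falx annotation to define the "
                         "midsagittal plane")
    centre = falx.mean(axis=0)
    _, _, vt = np.linalg.svd(falx - centre, full_matrices=False)
    normal = vt[-1] / np.linalg.norm(vt[-1])
    return centre, normal


def hemisphere_points(surface: EvaluatedSurface, side: str,
                      n_points: int = 200) -> HemisphereSampling:
    """Subsample the points of one hemisphere and set up the midplane.

    Points are the surface samples carrying the hemisphere's label,
    evenly strided down to ``n_points``; the midsagittal plane is fit to
    the falx-labelled points and oriented so the side's signed
    distances are positive.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    labels = np.asarray(surface.labels)
    sel = np.nonzero(labels == side)[0]
    if len(sel) == 0:
        raise ValueError(f"surface has no points labelled '{side}'")
    centre, normal = fit_midplane(surface)
    signed = (surface.points[sel] - centre) @ normal
    if np.mean(signed) < 0:
        normal = -normal
        signed = -signed
    sel = sel[signed > 0]
    if len(sel) == 0:
        raise ValueError(f"no '{side}' points on the positive side of Ym")
    if len(sel) > n_points:
        stride = np.linspace(0, len(sel) - 1, n_points).round().astype(int)
        sel = sel[np.unique(stride)]
    return HemisphereSampling(side=side, points=surface.points[sel],
                              normals=surface.normals[sel],
                              plane_point=centre, plane_normal=normal)


# --------------------------------------------------------------------------
# descriptors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDescriptor:
    """Serialisable recipe for one feature evaluation."""

    kind: str
    point_index: int = 0
    point_index2: int = 0          # binary_context only
    ls: float = 0.25               # VOI side ratio, (0, 0.5)
    placement: str = "sulcal"      # 'sulcal' or 'intracranial'
    r: float = 0.0                 # intracranial displacement ratio
    haar_template: int = 0         # 0..5
    neighbour_rank: int = 1        # 1..KNN, size features
    axis: int = 0                  # 0..2, size_ortho
    hemisphere: str = "left"

    def __post_init__(self):
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind in APPEARANCE_KINDS and not 0.0 < self.ls < 0.5:
            raise ValueError("ls must lie in (0, 0.5)")
        if self.kind in SIZE_KINDS and not 1 <= self.neighbour_rank <= KNN:
            raise ValueError(f"neighbour_rank must be 1..{KNN}")
        if self.kind in APPEARANCE_KINDS and self.placement not in (
                "sulcal", "intracranial"):
            raise ValueError("placement must be 'sulcal' or 'intracranial'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureDescriptor":
        return cls(**d)


def sample_feature_descriptor(rng: np.random.Generator,
                              enabled_banks: Sequence[str],
                              n_points: int,
                              hemisphere: str = "left") -> FeatureDescriptor:
    """Draw a descriptor: kind uniform over the enabled banks, then the
    kind's parameters from their stated distributions."""
    banks = list(enabled_banks)
    if not banks:
        raise ValueError("at least one feature bank must be enabled")
    kind = banks[rng.integers(len(banks))]
    kw: dict = dict(kind=kind, hemisphere=hemisphere)
    if kind in APPEARANCE_KINDS:
        kw["point_index"] = int(rng.integers(n_points))
        # open-interval guard: ls = 0 or 0.5 would be a degenerate VOI
        kw["ls"] = float(np.clip(rng.uniform(0.0, 0.5), 1e-6, 0.5 - 1e-9))
        kw["placement"] = "sulcal" if rng.random() < 0.5 else "intracranial"
        if kw["placement"] == "intracranial":
            kw["r"] = float(rng.uniform(0.0, 1.0))
        if kind == "haar3d":
            kw["haar_template"] = int(rng.integers(N_HAAR_TEMPLATES))
        if kind == "binary_context":
            kw["point_index2"] = int(rng.integers(n_points))
    elif kind in SIZE_KINDS:
        kw["point_index"] = int(rng.integers(n_points))
        kw["neighbour_rank"] = int(rng.integers(1, KNN + 1))
        if kind == "size_ortho":
            kw["axis"] = int(rng.integers(3))
    return FeatureDescriptor(**kw)


# --------------------------------------------------------------------------
# appearance features
# --------------------------------------------------------------------------

def _frame(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame (e1, e2, w) with deterministic
    in-plane axes."""
    w = w / np.linalg.norm(w)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(w @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(w, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(w, e1)
    return e1, e2, w


def _trilinear(volume: np.ndarray, vox: np.ndarray) -> tuple[np.ndarray, bool, bool]:
    """Trilinear samples at fractional voxel coords (N, 3); outside
    samples are zero-filled.  Returns (values, any_outside, all_outside)."""
    shape = np.array(volume.shape)
    inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    vals = np.zeros(len(vox))
    if np.any(inside):
        v = vox[inside]
        i0 = np.floor(v).astype(int)
        i0 = np.minimum(i0, shape - 2)
        f = v - i0
        c = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                         * np.where(dy, f[:, 1], 1 - f[:, 1])
                         * np.where(dz, f[:, 2], 1 - f[:, 2]))
                    c = c + w * volume[i0[:, 0] + dx, i0[:, 1] + dy,
                                       i0[:, 2] + dz]
        vals[inside] = c
    return vals, bool(np.any(~inside)), bool(np.all(~inside))


def _voi_samples(volume, spacing, centre, w_axis, side):
    """Sample grid values and the grid's signed axis coordinates."""
    e1, e2, w = _frame(w_axis)
    g = np.linspace(-side / 2.0, side / 2.0, VOI_GRID)
    ga, gb, gc = np.meshgrid(g, g, g, indexing="ij")
    offs = (ga.ravel()[:, None] * e1 + gb.ravel()[:, None] * e2
            + gc.ravel()[:, None] * w)
    mm = centre + offs
    vals, any_out, all_out = _trilinear(volume, mm / spacing)
    coords = np.column_stack([ga.ravel(), gb.ravel(), gc.ravel()])
    return vals, coords, any_out, all_out, mm


def _voi_centre_axis(hs: HemisphereSampling, d: FeatureDescriptor,
                     point_index: int):
    p = hs.points[point_index]
    pp = hs.projections[point_index]
    scale_dist = np.linalg.norm(p - pp)
    side = d.ls * scale_dist
    if d.placement == "sulcal":
        centre, axis = p, hs.normals[point_index]
    else:
        # displace from p toward the midplane by r * ||p - p'||
        centre = p - d.r * scale_dist * hs.plane_normal
        axis = hs.plane_normal
    return centre, axis, side


def eval_appearance(volume: np.ndarray, spacing: float,
                    hs: HemisphereSampling,
                    d: FeatureDescriptor) -> tuple[float, bool]:
    """Score an appearance descriptor; returns (score, clipped_flag).

    The flag marks VOIs that left the volume (zero-filled samples); a
    VOI entirely outside scores exactly 0.
    """
    if d.kind not in APPEARANCE_KINDS:
        raise ValueError(f"{d.kind} is not an appearance feature")

    def one(point_index):
        centre, axis, side = _voi_centre_axis(hs, d, point_index)
        vals, coords, any_out, all_out, _ = _voi_samples(
            volume, spacing, centre, axis, side)
        return vals, coords, any_out, all_out

    vals, coords, any_out, all_out = one(d.point_index)
    if all_out:
        return 0.0, True
    if d.kind == "unary":
        return float(vals.sum()), any_out
    if d.kind == "haar3d":
        ax = d.haar_template // 2
        sign = 1.0 if d.haar_template % 2 == 0 else -1.0
        pos = coords[:, ax] > 0
        neg = coords[:, ax] < 0
        return float(sign * (vals[pos].sum() - vals[neg].sum())), any_out
    # binary context: difference of unary sums at two cranial points
    vals2, _, any_out2, all_out2 = one(d.point_index2)
    if all_out2:
        return 0.0, True
    return float(vals.sum() - vals2.sum()), (any_out or any_out2)


# --------------------------------------------------------------------------
# local size features
# --------------------------------------------------------------------------

def eval_local_size(hs: HemisphereSampling, d: FeatureDescriptor) -> float:
    """Distance (mm) from point p to its rank-j nearest neighbour:
    Euclidean, or the signed component along one axis."""
    if d.kind not in SIZE_KINDS:
        raise ValueError(f"{d.kind} is not a size feature")
    if len(hs.points) <= KNN:
        raise ValueError(f"need more than {KNN} hemisphere points")
    if not 1 <= d.neighbour_rank <= KNN:
        raise ValueError(f"neighbour_rank must be 1..{KNN}")
    p = hs.points[d.point_index]
    _, idx = hs.tree().query(p[None], k=KNN + 1)
    neigh = [j for j in idx[0] if j != d.point_index][:KNN]
    pk = hs.points[neigh[d.neighbour_rank - 1]]
    if d.kind == "size_euclid":
        return float(np.linalg.norm(p - pk))
    return float(p[d.axis] - pk[d.axis])


# --------------------------------------------------------------------------
# biometric inner head circumference
# --------------------------------------------------------------------------

@dataclass
class TTPlaneDef:
    """Transthalamic plane anchored to the surface: the three reference
    points Ztt and the indices of the nearest surface points Ptt."""

    Ztt: np.ndarray            # (3, 3) mm
    Ptt: np.ndarray            # (3,) indices into the surface points

    def __post_init__(self):
        z = np.asarray(self.Ztt, float)
        if np.linalg.norm(np.cross(z[1] - z[0], z[2] - z[0])) < 1e-9:
            raise ValueError("TT reference points are collinear")


def make_tt_plane(surface_points: np.ndarray, Ztt: np.ndarray) -> TTPlaneDef:
    tree = BallTree(surface_points)
    _, idx = tree.query(np.asarray(Ztt, float), k=1)
    return TTPlaneDef(np.asarray(Ztt, float), idx[:, 0])


def tt_plane_for_ellipsoid(center, semi_axes, fraction: float = 0.15
                           ) -> np.ndarray:
    """Analytic TT reference points for a phantom: three points on the
    ellipsoid at a fixed fractional height, standing in for the manual
    three-point selection on a reference brain."""
    a, b, c = semi_axes
    f = fraction
    s = math.sqrt(1.0 - f * f)
    ang = [0.0, 2 * math.pi / 3, 4 * math.pi / 3]
    return np.array([[a * s * math.cos(t), b * s * math.sin(t), c * f]
                     for t in ang]) + np.asarray(center)


def _assemble_loops(segments: np.ndarray, tol: float = 1e-8):
    """Chain (N, 2, 3) segments into closed loops by endpoint matching."""
    def key(pt):
        return tuple(np.round(pt / tol).astype(np.int64))

    adj: dict[tuple, list[tuple[int, int]]] = {}
    for si, seg in enumerate(segments):
        for end in (0, 1):
            adj.setdefault(key(seg[end]), []).append((si, end))
    used = np.zeros(len(segments), bool)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        chain = [segments[start][0], segments[start][1]]
        used[start] = True
        closed = False
        while True:
            k = key(chain[-1])
            nxt = [(si, e) for si, e in adj.get(k, []) if not used[si]]
            if not nxt:
                closed = key(chain[-1]) == key(chain[0])
                break
            si, e = nxt[0]
            used[si] = True
            chain.append(segments[si][1 - e])
        loops.append((np.asarray(chain), closed))
    return loops


def eval_inner_hc(mesh: trimesh.Trimesh, surface_points: np.ndarray,
                  tt: TTPlaneDef) -> float:
    """Perimeter (mm) of the closed contour where the TT plane -- taken
    through the *current* positions of the anchored surface points Ptt
    -- intersects the fitted inner-skull mesh."""
    z = surface_points[tt.Ptt]
    normal = np.cross(z[1] - z[0], z[2] - z[0])
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("degenerate TT plane (anchor points collinear)")
    normal = normal / nn
    origin = z.mean(axis=0)
    segs = trimesh.intersections.mesh_plane(mesh, normal, origin)
    if len(segs) == 0:
        raise ValueError("TT plane does not intersect the surface")
    scale = max(1.0, np.abs(segs).max())
    loops = _assemble_loops(np.asarray(segs), tol=1e-8 * scale)
    closed = [c for c, ok in loops if ok]
    if not closed:
        raise ValueError("TT-plane intersection contour is not closed "
                         "(non-watertight mesh?)")
    lengths = [float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())
               for c in closed]
    return max(lengths)
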