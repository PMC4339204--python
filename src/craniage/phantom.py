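"""Synthetic 3D fetal-head ultrasound phantoms with known age and truth surface.

Each phantom is an ellipsoidal bright skull shell enclosing a darker
intracranial space, with

* a size that follows a linear head-circumference growth law over
  gestation (default HC = 11*age - 45 mm, age in gestational weeks),
* dark ridge ("sulcal") sheets anchored to the interior of the visible
  (distal) hemisphere whose number and depth increase with age,
* a bright midsagittal sheet standing in for the falx cerebri,
* multiplicative Rayleigh-style speckle, and
* depth-dependent attenuation of the hemisphere proximal to the probe
  (the occluded side), emulating the structural occlusion caused by
  skull reverberation.

The ground-truth surface is the noiseless inner-shell ellipsoid.  All
randomness is seeded: regenerating from the same spec is bit-identical.
Coordinates: world mm = 0-based voxel index * voxel_size (voxel-centre
convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import trimesh

DEFAULT_ASPECT_RATIOS = (1.0, 0.78, 0.80)  # a:b:c, cephalic-index-like
DEFAULT_HC_SLOPE = 11.0    # mm per gestational week
DEFAULT_HC_INTERCEPT = -45.0


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation of the ellipse perimeter."""
    return math.pi * (3.0 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))


def default_ridge_count_law(age: float) -> int:
    return int(math.floor(2 + 0.75 * (age - 18.0)))


def default_ridge_depth_law(age: float) -> float:
    """Ridge sheet depth below the inner skull surface, mm."""
    return 4.0 + 0.5 * (age - 18.0)


def growth_law(age: float,
               aspect_ratios: Sequence[float] = DEFAULT_ASPECT_RATIOS,
               hc_slope: float = DEFAULT_HC_SLOPE,
               hc_intercept: float = DEFAULT_HC_INTERCEPT) -> tuple[float, float, float]:
    """Semi-axes (a, b, c) in mm whose equatorial ellipse perimeter
    equals the head circumference HC(age) = slope*age + intercept.

    The perimeter is linear in overall scale, so the semi-axes are found
    by scaling the configured aspect ratios to match the Ramanujan
    perimeter of the (a, b) equatorial ellipse.
    """
    if not 14.0 <= age <= 40.0:
        raise ValueError(f"age {age} GW outside supported range [14, 40]")
    ra, rb, rc = aspect_ratios
    if min(ra, rb, rc) <= 0:
        raise ValueError("aspect ratios must be positive")
    hc = hc_slope * age + hc_intercept
    if hc <= 0:
        raise ValueError("growth law yields non-positive circumference")
    scale = hc / ramanujan_perimeter(ra, rb)
    return (ra * scale, rb * scale, rc * scale)


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; identical specs give identical data."""

    age: float
    grid_shape: tuple[int, int, int] | None = None
    voxel_size: float = 0.6
    aspect_ratios: tuple[float, float, float] = DEFAULT_ASPECT_RATIOS
    ridge_count_law: Callable[[float], int] = default_ridge_count_law
    ridge_depth_law: Callable[[float], float] = default_ridge_depth_law
    speckle_level: float = 0.35
    occluded_side: str = "left"
    seed: int = 0
    hc_slope: float = DEFAULT_HC_SLOPE
    hc_intercept: float = DEFAULT_HC_INTERCEPT
    shell_thickness: float = 3.0        # mm
    attenuation_per_mm: float = 0.04    # proximal-side intensity decay
    grid_margin: float = 1.35           # auto grid: extent / head diameter
    # per-subject biological/acquisition variability (all seeded):
    gain_jitter: float = 0.2            # log-normal scan gain sigma
    hc_jitter: float = 0.015            # biological HC scatter (rel. sigma)
    aspect_jitter: float = 0.03         # head-shape scatter (rel. sigma)

    def __post_init__(self):
        if not 18.0 <= self.age <= 34.0:
            raise ValueError("phantom age must lie in [18, 34] GW")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.speckle_level < 0:
            raise ValueError("speckle_level must be >= 0")
        if self.occluded_side not in ("left", "right"):
            raise ValueError("occluded_side must be 'left' or 'right'")

    def _jitters(self) -> tuple[float, float, float, float]:
        """Per-subject multiplicative scatter (gain, HC, two aspect
        ratios), reproducible from the seed alone."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 17]))
        z = rng.normal(size=4)
        return (math.exp(self.gain_jitter * z[0]),
                math.exp(self.hc_jitter * z[1]),
                math.exp(self.aspect_jitter * z[2]),
                math.exp(self.aspect_jitter * z[3]))

    def semi_axes(self) -> tuple[float, float, float]:
        _, hc_m, rb_m, rc_m = self._jitters()
        ra, rb, rc = self.aspect_ratios
        rb, rc = rb * rb_m, rc * rc_m
        hc = (self.hc_slope * self.age + self.hc_intercept) * hc_m
        scale = hc / ramanujan_perimeter(ra, rb)
        return (ra * scale, rb * scale, rc * scale)

    def resolved_grid_shape(self) -> tuple[int, int, int]:
        axes = self.semi_axes()
        if self.grid_shape is not None:
            shape = tuple(int(n) for n in self.grid_shape)
            for n, ax in zip(shape, axes):
                extent = n * self.voxel_size
                if 2 * ax + 2 * self.shell_thickness + 4.0 > extent:
                    raise ValueError(
                        f"grid extent {extent:.1f} mm too small for skull "
                        f"(needs {2 * ax + 2 * self.shell_thickness + 4:.1f} mm)")
                if 2 * ax < 0.5 * extent:
                    raise ValueError(
                        "cranium would occupy <50% of the image extent; "
                        "use a smaller grid or larger voxels")
            return shape
        return tuple(int(math.ceil(2 * ax * self.grid_margin / self.voxel_size))
                     for ax in axes)


@dataclass
class Phantom:
    """A generated volume plus its ground truth."""

    volume: np.ndarray            # 3D float32, arbitrary intensity units
    voxel_size: float             # mm, isotropic
    truth_mesh: trimesh.Trimesh   # inner-skull surface, mm
    age: float                    # GW
    hemisphere: str               # visible/distal side: 'left' or 'right'
    seed: int
    center: np.ndarray            # mm
    semi_axes: tuple[float, float, float]
    spec: PhantomSpec = field(repr=False, default=None)


def _truth_ellipsoid(center: np.ndarray, axes: Sequence[float],
                     subdivisions: int = 4) -> trimesh.Trimesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions)
    v = m.vertices * np.asarray(axes) + center
    return trimesh.Trimesh(vertices=v, faces=m.faces, process=False)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Render the phantom volume and its ground-truth surface."""
    shape = spec.resolved_grid_shape()
    vs = spec.voxel_size
    a, b, c = spec.semi_axes()
    center = (np.array(shape, float) - 1.0) / 2.0 * vs

    ii = np.arange(shape[0]) * vs - center[0]
    jj = np.arange(shape[1]) * vs - center[1]
    kk = np.arange(shape[2]) * vs - center[2]
    x, y, z = np.meshgrid(ii, jj, kk, indexing="ij")

    # normalised ellipsoidal radius and approximate signed distance (mm)
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    grad = np.sqrt((x / a ** 2) ** 2 + (y / b ** 2) ** 2
                   + (z / c ** 2) ** 2) / np.maximum(rho, 1e-9)
    d = (rho - 1.0) / np.maximum(grad, 1e-9)   # >0 outside inner shell

    base_in, base_out, shell_amp = 0.25, 0.05, 1.0
    up = 0.5 * (1.0 + np.tanh(d / 0.5))                     # inner edge
    down = 0.5 * (1.0 - np.tanh((d - spec.shell_thickness) / 0.75))
    shell = up * down
    interior = 1.0 - up
    vol = base_in * interior + shell_amp * shell + base_out * (1 - interior - shell)

    # falx: bright midsagittal sheet within the intracranial space
    falx = 0.5 * np.exp(-(x ** 2) / (2 * 0.6 ** 2)) * interior
    vol = vol + falx

    # ridge sheets on the distal (visible) hemisphere interior
    distal_sign = -1.0 if spec.occluded_side == "right" else 1.0
    # (occluded 'left' means left (x<0) is dark; distal side is x>0)
    n_ridges = max(0, int(spec.ridge_count_law(spec.age)))
    depth = float(spec.ridge_depth_law(spec.age))
    rng = np.random.default_rng(spec.seed)
    if n_ridges > 0:
        band = (d > -depth) & (d < -0.5) & (distal_sign * x > 2.0)
        angles = (np.linspace(0.0, np.pi, n_ridges, endpoint=False)
                  + rng.uniform(-0.05, 0.05, n_ridges))
        ridge_w = np.zeros_like(vol)
        for th in angles:
            nrm = np.array([0.0, -math.sin(th), math.cos(th)])
            dist = np.abs(y * nrm[1] + z * nrm[2])
            ridge_w += np.exp(-(dist ** 2) / (2 * 0.8 ** 2))
        vol = vol * (1.0 - 0.85 * np.clip(ridge_w, 0, 1) * band * interior.astype(bool))

    # attenuation of the proximal (occluded) hemisphere
    prox_depth = np.maximum(0.0, -distal_sign * x)
    vol = vol * np.exp(-spec.attenuation_per_mm * prox_depth)

    # multiplicative speckle (Rayleigh, unit mean, scaled toward 1)
    if spec.speckle_level > 0:
        r = rng.rayleigh(1.0, size=vol.shape) / math.sqrt(math.pi / 2.0)
        vol = vol * (1.0 + spec.speckle_level * (r - 1.0))

    # per-scan acquisition gain
    vol = vol * spec._jitters()[0]

    mesh = _truth_ellipsoid(center, (a, b, c))
    hemisphere = "right" if spec.occluded_side == "left" else "left"
    return Phantom(volume=vol.astype(np.float32), voxel_size=vs,
                   truth_mesh=mesh, age=spec.age, hemisphere=hemisphere,
                   seed=spec.seed, center=center, semi_axes=(a, b, c),
                   spec=spec)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def make_cohort(n: int,
                age_range: tuple[float, float] = (18.0, 34.0),
                seed: int = 0,
                voxel_size: float = 1.2,
                speckle_level: float = 0.35,
                hemispheres: str = "alternate",
                out_dir: str | Path | None = None,
                **spec_kwargs) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate ``n`` phantoms with ages drawn uniformly over ``age_range``.

    Returns the phantoms and a cohort table (id, path, hemisphere,
    age_weeks, plus ground-truth placement columns).  When ``out_dir``
    is given, volumes are written as .nii.gz, truth meshes as .ply and
    the table as cohort.csv; otherwise ``path`` is empty.

    The default cohort resolution is 1.2 mm: coarser than the 0.6 mm
    single-phantom default, chosen as the package's working problem size
    for forest training while retaining the shell, falx and ridge
    structures the features sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = age_range
    if not (hi > lo):
        raise ValueError("empty age range")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n)
    if hemispheres == "alternate":
        sides = ["left" if i % 2 == 0 else "right" for i in range(n)]
    elif hemispheres in ("left", "right"):
        sides = [hemispheres] * n
    else:
        raise ValueError("hemispheres must be 'alternate', 'left' or 'right'")
    # the cohort seed stream is derived from the cohort seed, one child
    # per phantom, keeping every phantom independently reproducible
    child_seeds = [int(s) for s in
                   np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    phantoms, rows = [], []
    for i in range(n):
        visible = sides[i]
        spec = PhantomSpec(age=float(ages[i]), voxel_size=voxel_size,
                           speckle_level=speckle_level,
                           occluded_side="left" if visible == "right" else "right",
                           seed=child_seeds[i], **spec_kwargs)
        ph = make_phantom(spec)
        phantoms.append(ph)
        path = ""
        if out is not None:
            path = str(out / f"phantom_{i:04d}.nii.gz")
            save_phantom_volume(ph, path)
            ph.truth_mesh.export(out / f"phantom_{i:04d}_truth.ply")
        rows.append(dict(id=f"phantom_{i:04d}", path=path,
                         hemisphere=ph.hemisphere, age_weeks=ph.age,
                         a=ph.semi_axes[0], b=ph.semi_axes[1],
                         c=ph.semi_axes[2], cx=ph.center[0],
                         cy=ph.center[1], cz=ph.center[2],
                         voxel_size=voxel_size, seed=child_seeds[i]))
    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out / "cohort.csv", index=False)
    return phantoms, table


def save_phantom_volume(ph: Phantom, path: str | Path) -> None:
    import nibabel as nib
    affine = np.diag([ph.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(ph.volume, affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume, returning (array, isotropic spacing mm)."""
    import nibabel as nib
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        raise ValueError(f"anisotropic spacing {zooms}; resample first")
    return np.asarray(img.get_fdata(), dtype=np.float32), float(zooms[0])
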