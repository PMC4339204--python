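"""Feature banks: hemisphere geometry, appearance VOIs, sizes, inner HC."""

import math

import numpy as np
import pytest
import trimesh
from scipy import ndimage

from craniage import features as fe
from craniage import surface as sf
from craniage.phantom import ramanujan_perimeter


@pytest.fixture(scope="module")
def sphere_surface(control_mesh):
    surf = sf.Surface(control_mesh, depth=3)
    samp = sf.sample_regular(control_mesh, 3)
    X = sf.initialize(control_mesh, translation=(50, 50, 50),
                      scale=(40, 40, 40))
    ev = sf.evaluate_sampling(surf, samp, X)
    return surf, samp, X, ev


@pytest.fixture(scope="module")
def hs_right(sphere_surface):
    return fe.hemisphere_points(sphere_surface[3], "right", 200)


def _manual_hs(points, normals=None, plane_normal=(1, 0, 0)):
    points = np.asarray(points, float)
    if normals is None:
        normals = np.tile([0.0, 0.0, 1.0], (len(points), 1))
    return fe.HemisphereSampling(side="right", points=points,
                                 normals=np.asarray(normals, float),
                                 plane_point=np.zeros(3),
                                 plane_normal=np.asarray(plane_normal,
                                                         float))


# -- hemisphere geometry ---------------------------------------------------

def test_hemisphere_sides_balanced(sphere_surface):
    ev = sphere_surface[3]
    labels = np.asarray(ev.labels)
    assert abs((labels == "left").sum() - (labels == "right").sum()) <= 1


def test_hemisphere_points_on_positive_side(hs_right):
    assert len(hs_right.points) == 200
    assert (hs_right.dist_to_plane > 0).all()


def test_projection_matches_plane_oracle(hs_right):
    n = hs_right.plane_normal
    c = hs_right.plane_point
    for p, pp in zip(hs_right.points[:20], hs_right.projections[:20]):
        ref = p - ((p - c) @ n) * n          # brute-force projection
        assert np.abs(pp - ref).max() < 1e-10
        assert abs((pp - c) @ n) < 1e-10


def test_hemisphere_requires_side_label(sphere_surface):
    with pytest.raises(ValueError):
        fe.hemisphere_points(sphere_surface[3], "up")


# -- appearance ------------------------------------------------------------

def test_appearance_constant_volume():
    hs = _manual_hs([[30, 30, 30]])
    vol = np.full((64, 64, 64), 2.0)
    d = fe.FeatureDescriptor(kind="haar3d", point_index=0, ls=0.3,
                             haar_template=3)
    score, flag = fe.eval_appearance(vol, 1.0, hs, d)
    assert score == pytest.approx(0.0, abs=1e-9)    # cuboids cancel
    d = fe.FeatureDescriptor(kind="unary", point_index=0, ls=0.3)
    score, flag = fe.eval_appearance(np.ones((64, 64, 64)), 1.0, hs, d)
    assert score == pytest.approx(fe.VOI_GRID ** 3)
    assert not flag


def test_appearance_fully_outside_flags_zero():
    hs = _manual_hs([[500.0, 500.0, 500.0]])
    d = fe.FeatureDescriptor(kind="unary", point_index=0, ls=0.3)
    score, flag = fe.eval_appearance(np.ones((16, 16, 16)), 1.0, hs, d)
    assert score == 0.0 and flag


def test_appearance_matches_resampling_oracle(rng):
    """Scores equal an independent map_coordinates re-summation."""
    vol = rng.random((32, 32, 32))
    for _ in range(20):
        p = rng.uniform(12, 20, 3)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        hs = _manual_hs([p], [n])
        kind = ["unary", "haar3d"][int(rng.integers(2))]
        d = fe.FeatureDescriptor(
            kind=kind, point_index=0, ls=float(rng.uniform(0.1, 0.45)),
            haar_template=int(rng.integers(6)),
            placement=["sulcal", "intracranial"][int(rng.integers(2))],
            r=float(rng.uniform(0, 0.3)))
        score, _ = fe.eval_appearance(vol, 1.0, hs, d)
        # oracle: rebuild the grid, sample with scipy, loop-sum
        centre, axis, side = fe._voi_centre_axis(hs, d, 0)
        e1, e2, w = fe._frame(axis)
        g = np.linspace(-side / 2, side / 2, fe.VOI_GRID)
        ref = 0.0
        for ia, ga in enumerate(g):
            for ib, gb in enumerate(g):
                for ic, gc in enumerate(g):
                    mm = centre + ga * e1 + gb * e2 + gc * w
                    val = float(ndimage.map_coordinates(
                        vol, mm[:, None], order=1, mode="constant")[0])
                    if kind == "unary":
                        ref += val
                    else:
                        ax = d.haar_template // 2
                        sgn = 1.0 if d.haar_template % 2 == 0 else -1.0
                        coord = (ga, gb, gc)[ax]
                        if coord > 0:
                            ref += sgn * val
                        elif coord < 0:
                            ref -= sgn * val
        assert score == pytest.approx(ref, abs=1e-9)


def test_binary_context_is_difference_of_unaries(rng):
    vol = rng.random((32, 32, 32))
    hs = _manual_hs([[15, 14, 16], [18, 17, 15]],
                    [[0, 0, 1], [0, 1, 0]])
    d = fe.FeatureDescriptor(kind="binary_context", point_index=0,
                             point_index2=1, ls=0.3)
    got, _ = fe.eval_appearance(vol, 1.0, hs, d)
    u0, _ = fe.eval_appearance(
        vol, 1.0, hs, fe.FeatureDescriptor(kind="unary", point_index=0,
                                           ls=0.3))
    u1, _ = fe.eval_appearance(
        vol, 1.0, hs, fe.FeatureDescriptor(kind="unary", point_index=1,
                                           ls=0.3))
    assert got == pytest.approx(u0 - u1, abs=1e-9)


def test_appearance_scale_covariance(coarse_phantom):
    """Same descriptor on a 1.2x upsampled copy: VOI size follows
    ||p - p'||, so the score is preserved within interpolation error."""
    from craniage import pipeline as pl
    ex = pl.example_from_phantom(coarse_phantom, bandpass=False)
    big = ndimage.zoom(coarse_phantom.volume.astype(float), 1.2, order=1)
    hs_big = fe.HemisphereSampling(
        side=ex.hs.side, points=ex.hs.points * 1.2,
        normals=ex.hs.normals, plane_point=ex.hs.plane_point * 1.2,
        plane_normal=ex.hs.plane_normal)
    rng = np.random.default_rng(0)
    rel_errs = []
    for _ in range(30):
        d = fe.FeatureDescriptor(
            kind="unary", point_index=int(rng.integers(len(ex.hs.points))),
            ls=float(rng.uniform(0.15, 0.45)))
        s1, f1 = fe.eval_appearance(ex.volume, ex.spacing, ex.hs, d)
        s2, f2 = fe.eval_appearance(big, ex.spacing, hs_big, d)
        if f1 or f2 or abs(s1) < 1.0:
            continue
        rel_errs.append(abs(s2 - s1) / abs(s1))
    assert len(rel_errs) > 10
    assert np.median(rel_errs) < 0.02


# -- local size ------------------------------------------------------------

def test_local_size_closed_form():
    pts = np.zeros((12, 3))
    pts[1] = [3.0, 4.0, 0.0]
    pts[2:] = np.arange(10)[:, None] * [10.0, 10.0, 10.0] + 50.0
    hs = _manual_hs(pts)
    d = fe.FeatureDescriptor(kind="size_euclid", point_index=0,
                             neighbour_rank=1)
    assert fe.eval_local_size(hs, d) == pytest.approx(5.0)   # ||(3,4,0)||
    for ax, want in zip(range(3), (-3.0, -4.0, 0.0)):
        d = fe.FeatureDescriptor(kind="size_ortho", point_index=0,
                                 neighbour_rank=1, axis=ax)
        assert fe.eval_local_size(hs, d) == pytest.approx(want)


def test_local_size_matches_brute_force_knn(rng):
    pts = rng.random((500, 3)) * 100
    hs = _manual_hs(pts)
    for _ in range(20):
        i = int(rng.integers(500))
        rank = int(rng.integers(1, fe.KNN + 1))
        d = fe.FeatureDescriptor(kind="size_euclid", point_index=i,
                                 neighbour_rank=rank)
        got = fe.eval_local_size(hs, d)
        dd = np.linalg.norm(pts - pts[i], axis=1)
        dd[i] = np.inf
        want = np.sort(dd)[rank - 1]
        assert got == pytest.approx(want, abs=1e-9)


def test_local_size_rank_bounds():
    hs = _manual_hs(np.random.default_rng(0).random((20, 3)))
    with pytest.raises(ValueError):
        fe.FeatureDescriptor(kind="size_euclid", point_index=0,
                             neighbour_rank=10)


# -- inner head circumference ----------------------------------------------

def test_inner_hc_sphere_closed_form():
    m = trimesh.creation.icosphere(subdivisions=4, radius=30.0)
    Ztt = fe.tt_plane_for_ellipsoid((0, 0, 0), (30, 30, 30), fraction=0.0)
    tt = fe.make_tt_plane(m.vertices, Ztt)
    hc = fe.eval_inner_hc(m, m.vertices, tt)
    assert abs(hc - 2 * math.pi * 30) / (2 * math.pi * 30) < 0.02


def test_inner_hc_ellipsoid_ramanujan():
    m = trimesh.creation.icosphere(subdivisions=4)
    m = trimesh.Trimesh(m.vertices * [40.0, 30.0, 35.0], m.faces,
                        process=False)
    Ztt = fe.tt_plane_for_ellipsoid((0, 0, 0), (40, 30, 35), fraction=0.0)
    tt = fe.make_tt_plane(m.vertices, Ztt)
    hc = fe.eval_inner_hc(m, m.vertices, tt)
    want = ramanujan_perimeter(40.0, 30.0)
    assert abs(hc - want) / want < 0.02


def test_inner_hc_homogeneous_under_scaling():
    m = trimesh.creation.icosphere(subdivisions=3, radius=30.0)
    tt = fe.make_tt_plane(m.vertices, fe.tt_plane_for_ellipsoid(
        (0, 0, 0), (30, 30, 30), 0.0))
    hc1 = fe.eval_inner_hc(m, m.vertices, tt)
    m15 = trimesh.Trimesh(m.vertices * 1.5, m.faces, process=False)
    hc15 = fe.eval_inner_hc(m15, m15.vertices, tt)
    assert abs(hc15 - 1.5 * hc1) < 1e-9


def test_inner_hc_plane_miss_raises():
    m = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    tt = fe.TTPlaneDef(np.array([[0, 0, 50.0], [1, 0, 50.0],
                                 [0, 1, 50.0]]), np.array([0, 1, 2]))
    pts = np.array([[0, 0, 50.0], [1, 0, 50.0], [0, 1, 50.0]])
    with pytest.raises(ValueError):
        fe.eval_inner_hc(m, pts, tt)
    with pytest.raises(ValueError):
        fe.TTPlaneDef(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]]),
                      np.array([0, 1, 2]))


# -- descriptor sampling ---------------------------------------------------

def test_descriptor_sampling_single_bank(rng):
    for _ in range(20):
        d = fe.sample_feature_descriptor(rng, ["inner_hc"], 100)
        assert d.kind == "inner_hc"


def test_descriptor_sampling_distributions():
    rng = np.random.default_rng(7)
    ls = [fe.sample_feature_descriptor(rng, ["haar3d"], 100).ls
          for _ in range(10_000)]
    assert np.mean(ls) == pytest.approx(0.25, abs=0.01)   # U(0, 0.5)


def test_descriptor_sampling_deterministic():
    a = [fe.sample_feature_descriptor(np.random.default_rng(5),
                                      fe.ALL_KINDS, 50) for _ in range(1)]
    rng1 = np.random.default_rng(5)
    rng2 = np.random.default_rng(5)
    seq1 = [fe.sample_feature_descriptor(rng1, fe.ALL_KINDS, 50)
            for _ in range(50)]
    seq2 = [fe.sample_feature_descriptor(rng2, fe.ALL_KINDS, 50)
            for _ in range(50)]
    assert seq1 == seq2


def test_descriptor_roundtrip_all_kinds(rng):
    for kind in fe.ALL_KINDS:
        for _ in range(20):
            d = fe.sample_feature_descriptor(rng, [kind], 30,
                                             hemisphere="right")
            back = fe.FeatureDescriptor.from_dict(d.to_dict())
            assert back == d       # field-for-field

    with pytest.raises(ValueError):
        fe.sample_feature_descriptor(rng, [], 10)
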