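import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import make_mask, random_mask
from liverseg.evaluation import (GeometryMismatchError, corrected_slices, dice,
                                 evaluate_case, extract_surface, hausdorff,
                                 msd, reports_to_frame, rve, signed_rve)
from liverseg.imaging_io import MaskVolume, VolumeGeometry
from liverseg.training import jaccard


def brute_force_surface_distances(test, ref):
    """All-pairs nearest-surface oracle in mm (O(|X||Y|))."""
    x = extract_surface(test).points
    y = extract_surface(ref).points
    d = cdist(x, y)
    d_xy = d.min(axis=1)
    d_yx = d.min(axis=0)
    msd_val = (d_xy.sum() + d_yx.sum()) / (len(x) + len(y))
    hd_val = max(d_xy.max(), d_yx.max())
    return msd_val, hd_val


def test_dice_trivials_and_enumeration():
    cube = make_mask(fg=[(i, j, k) for i in range(2) for j in range(2) for k in range(2)])
    half = make_mask(fg=[(i, j, k) for i in range(1) for j in range(2) for k in range(2)])
    assert dice(cube, cube) == 1.0
    assert abs(dice(cube, half) - 2 * 4 / (8 + 4)) < 1e-12
    other = make_mask(fg=[(5, 5, 5)])
    assert dice(cube, other) == 0.0
    empty = make_mask()
    assert dice(empty, empty) == 1.0
    with pytest.raises(GeometryMismatchError):
        dice(cube, make_mask(shape=(9, 9, 9)))


def test_rve_definition_and_asymmetry():
    ref = make_mask(shape=(20, 20, 20), fg=[(i, j, k) for i in range(10)
                                            for j in range(10) for k in range(1)])
    test = make_mask(shape=(20, 20, 20), fg=[(i, j, k) for i in range(10)
                                             for j in range(10) for k in range(1)]
                     + [(i, 0, 1) for i in range(5)])
    assert abs(rve(test, ref) - 5.0) < 1e-12
    assert rve(ref, ref) == 0.0
    assert rve(test, ref) != rve(ref, test)
    assert signed_rve(ref, test) < 0
    with pytest.raises(ValueError):
        rve(ref, make_mask(shape=(20, 20, 20)))


def test_rve_dilated_cube_voxel_arithmetic():
    cube = [(i, j, k) for i in range(5, 15) for j in range(5, 15) for k in range(5, 15)]
    dilated = [(i, j, k) for i in range(4, 16) for j in range(4, 16) for k in range(4, 16)]
    ref = make_mask(shape=(20, 20, 20), fg=cube)
    test = make_mask(shape=(20, 20, 20), fg=dilated)
    assert abs(rve(test, ref) - (12 ** 3 - 10 ** 3) / 10 ** 3 * 100) < 1e-9


def test_rve_supports_mismatched_geometries():
    ref = make_mask(shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0),
                    fg=[(0, 0, 0)])  # 8 mm^3
    test = make_mask(shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0),
                     fg=[(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)])  # 4 mm^3
    assert abs(rve(test, ref) - 50.0) < 1e-12


def test_surface_extraction_enumeration():
    single = make_mask(fg=[(3, 4, 5)])
    pts = extract_surface(single).points
    assert pts.shape == (1, 3)
    np.testing.assert_allclose(pts[0], [3.0, 4.0, 5.0])

    cube3 = make_mask(fg=[(i, j, k) for i in range(1, 4)
                          for j in range(1, 4) for k in range(1, 4)])
    assert len(extract_surface(cube3).points) == 26  # all but the center

    full = MaskVolume(np.ones((4, 4, 4)), VolumeGeometry(spacing_mm=(1, 1, 1)))
    assert len(extract_surface(full).points) == 4 ** 3 - 2 ** 3  # grid border

    with pytest.raises(ValueError):
        extract_surface(make_mask())


def test_msd_and_hausdorff_hand_cases():
    a = make_mask(fg=[(0, 0, 0)])
    b = make_mask(fg=[(5, 0, 0)])
    assert abs(msd(a, b) - 5.0) < 1e-12
    assert abs(hausdorff(a, b) - 5.0) < 1e-12
    assert msd(a, a) == 0.0 and hausdorff(a, a) == 0.0

    # single voxel vs pair at 3 mm and 7 mm: directed maxima give 7
    one = make_mask(fg=[(0, 0, 0)])
    pair = make_mask(fg=[(3, 0, 0), (7, 0, 0)])
    assert abs(hausdorff(one, pair) - 7.0) < 1e-12


def test_distance_transform_equals_brute_force_oracle():
    rng = np.random.default_rng(0)
    for trial in range(30):
        spacing = (1.0, 1.0, 1.0) if trial % 2 else (0.8, 1.1, 2.5)
        a = random_mask(rng, shape=(7, 7, 7), spacing=spacing, p=0.25)
        b = random_mask(rng, shape=(7, 7, 7), spacing=spacing, p=0.25)
        m_ref, h_ref = brute_force_surface_distances(a, b)
        assert abs(msd(a, b) - m_ref) < 1e-9
        assert abs(hausdorff(a, b) - h_ref) < 1e-9
        assert hausdorff(a, b) >= msd(a, b)


def test_distance_metrics_are_symmetric():
    rng = np.random.default_rng(5)
    a = random_mask(rng, p=0.3)
    b = random_mask(rng, p=0.3)
    assert msd(a, b) == msd(b, a)
    assert hausdorff(a, b) == hausdorff(b, a)


def test_metrics_invariant_under_axis_permutation():
    rng = np.random.default_rng(7)
    a = random_mask(rng, shape=(6, 7, 8), spacing=(1.0, 2.0, 3.0), p=0.3)
    b = random_mask(rng, shape=(6, 7, 8), spacing=(1.0, 2.0, 3.0), p=0.3)
    perm = (2, 0, 1)
    geom = VolumeGeometry(spacing_mm=tuple(np.array(a.geometry.spacing_mm)[list(perm)]))
    ap = MaskVolume(np.transpose(a.voxels, perm), geom)
    bp = MaskVolume(np.transpose(b.voxels, perm), geom)
    assert abs(dice(a, b) - dice(ap, bp)) < 1e-12
    assert abs(msd(a, b) - msd(ap, bp)) < 1e-9
    assert abs(hausdorff(a, b) - hausdorff(ap, bp)) < 1e-9


def test_dice_jaccard_relation():
    rng = np.random.default_rng(9)
    for _ in range(20):
        a = random_mask(rng, p=0.4)
        b = random_mask(rng, p=0.4)
        d = dice(a, b)
        j = jaccard(a.voxels, b.voxels)
        assert abs(d - 2 * j / (1 + j)) < 1e-12


def test_corrected_slices_counting():
    base = [(i, j, k) for i in range(3) for j in range(3) for k in range(10, 20)]
    auto = make_mask(shape=(6, 6, 30), fg=base)
    same = make_mask(shape=(6, 6, 30), fg=base)
    assert corrected_slices(auto, same, axis=2) == 0.0

    edited = make_mask(shape=(6, 6, 30),
                       fg=base + [(4, 4, 12), (4, 4, 13), (4, 4, 14)])
    assert abs(corrected_slices(auto, edited, axis=2) - 30.0) < 1e-12

    all_changed = make_mask(shape=(6, 6, 30),
                            fg=[(i, j, k) for i in range(4) for j in range(3)
                                for k in range(10, 20)])
    assert corrected_slices(auto, all_changed, axis=2) == 100.0
    with pytest.raises(ValueError):
        corrected_slices(make_mask(shape=(6, 6, 30)), same, axis=2)


def test_evaluate_case_bundles_and_round_trips(tmp_path):
    cube = make_mask(fg=[(i, j, k) for i in range(2, 6) for j in range(2, 6)
                         for k in range(2, 6)])
    report = evaluate_case(cube, cube)
    assert (report.dice, report.rve_pct, report.msd_mm, report.hd_mm) == (1.0, 0.0, 0.0, 0.0)
    assert report.cs_pct is None
    with_cs = evaluate_case(cube, cube, automatic=cube)
    assert with_cs.cs_pct == 0.0

    frame = reports_to_frame({"case0": report})
    path = tmp_path / "report.csv"
    frame.to_csv(path)
    import pandas as pd
    back = pd.read_csv(path, index_col=0)
    assert back.loc["case0", "dice"] == 1.0
    assert back.loc["case0", "hd_mm"] == 0.0
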