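import numpy as np
import pytest

from bnctdose import (
    ImageVolume,
    density_from_hu,
    rasterize_roi,
    read_volume,
    resample_to,
    voxel_mass_kg,
    write_volume,
    write_synthetic_dicom_series,
)


def make_volume(data, spacing=(1, 1, 1), origin=(0, 0, 0), direction=None, modality="CT"):
    return ImageVolume(np.asarray(data, float), spacing, origin, direction, modality)


# -- construction invariants ----------------------------------------------


def test_invalid_volumes_rejected():
    with pytest.raises(ValueError):
        make_volume(np.zeros((4, 4, 4)), spacing=(1, 0, 1))
    with pytest.raises(ValueError):
        ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1), direction=np.eye(3) * 2)
    with pytest.raises(ValueError):
        ImageVolume(np.zeros((4, 4)), (1, 1, 1))
    with pytest.raises(ValueError):
        make_volume(np.zeros((4, 4, 4)), modality="MRI")


def test_index_physical_round_trip():
    rot = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    vol = make_volume(np.zeros((5, 6, 7)), spacing=(1, 2, 3), origin=(-4, 5, 6), direction=rot)
    idx = np.array([[0, 0, 0], [4, 5, 6], [1.5, 2.5, 3.5]])
    back = vol.physical_to_index(vol.index_to_physical(idx))
    np.testing.assert_allclose(back, idx, atol=1e-12)


# -- NIfTI / DICOM round trips --------------------------------------------


def test_nifti_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    vol = make_volume(rng.normal(size=(6, 5, 4)), spacing=(0.98, 0.98, 3.75), origin=(-10.0, 4.5, 2.0))
    write_volume(vol, tmp_path / "vol.nii.gz")
    back = read_volume(tmp_path / "vol.nii.gz", "nifti", modality="CT")
    np.testing.assert_allclose(back.data, vol.data, atol=1e-6)
    np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)
    np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)
    np.testing.assert_allclose(back.direction, vol.direction, atol=1e-6)


def test_mask_round_trips_as_uint8(tmp_path):
    mask = np.zeros((4, 4, 3))
    mask[1:3, 1:3, 1] = 1
    vol = make_volume(mask, modality="MASK")
    write_volume(vol, tmp_path / "mask.nii")
    back = read_volume(tmp_path / "mask.nii", "nifti", modality="MASK")
    assert set(np.unique(back.data)) <= {0.0, 1.0}
    np.testing.assert_array_equal(back.data, mask)


def test_dicom_series_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    data = rng.integers(-1000, 2000, size=(8, 6, 3)).astype(float)
    series = write_synthetic_dicom_series(tmp_path / "ct", data, spacing_mm=(0.5, 0.75, 2.5),
                                          origin_mm=(1.0, -2.0, 3.0), rescale_intercept=-1024.0)
    vol = read_volume(series, "dicom-series")
    assert vol.modality == "CT"
    np.testing.assert_allclose(vol.data, data, atol=1e-9)
    np.testing.assert_allclose(vol.spacing, [0.5, 0.75, 2.5])
    np.testing.assert_allclose(vol.origin, [1.0, -2.0, 3.0])


def test_dicom_nonuniform_slice_spacing_errors(tmp_path):
    data = np.zeros((4, 4, 4))
    series = write_synthetic_dicom_series(tmp_path / "bad", data, spacing_mm=(1, 1, 2),
                                          slice_offsets_mm=[0.0, 0.0, 0.0, 2.0])
    with pytest.raises(ValueError, match="slice"):
        read_volume(series, "dicom-series")


def test_read_volume_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_volume(tmp_path / "missing.nii", "nifti")
    (tmp_path / "x.nii").write_bytes(b"")
    with pytest.raises(ValueError):
        read_volume(tmp_path / "x.nii", "hdf5")


# -- ROI rasterization -----------------------------------------------------


def square_contour(x0, x1, y0, y1, z):
    return np.array([[x0, y0, z], [x1, y0, z], [x1, y1, z], [x0, y1, z]], dtype=float)


def test_square_contour_covers_expected_centers():
    ref = make_volume(np.zeros((10, 10, 3)))
    roi = rasterize_roi([square_contour(0.6, 2.4, 0.6, 2.4, 1.0)], ref)
    assert roi.n_voxels == 4
    assert roi.mask[1:3, 1:3, 1].all()


def test_full_volume_rectangle_selects_everything():
    ref = make_volume(np.zeros((6, 5, 2)))
    contours = [square_contour(-0.5, 5.5, -0.5, 4.5, z) for z in (0.0, 1.0)]
    roi = rasterize_roi(contours, ref)
    assert roi.mask.all()


def test_circle_matches_brute_force_center_test():
    ref = make_volume(np.zeros((30, 30, 1)))
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    cx, cy, r = 14.2, 15.1, 10.0
    contour = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta), np.zeros_like(theta)])
    roi = rasterize_roi([contour], ref)
    ii, jj = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
    inside = (ii - cx) ** 2 + (jj - cy) ** 2 <= r**2
    # the polygon is a 720-gon, slightly inside the true circle: allow the
    # few centers within one chord-sagitta of the boundary to differ
    sagitta = r * (1 - np.cos(np.pi / 720))
    boundary = np.abs(np.hypot(ii - cx, jj - cy) - r) <= sagitta
    np.testing.assert_array_equal(roi.mask[:, :, 0] & ~boundary, inside & ~boundary)


def _crossing_number_inside(px, py, poly):
    """Independent even-odd point-in-polygon oracle."""
    inside = False
    n = len(poly)
    for a in range(n):
        x1, y1 = poly[a]
        x2, y2 = poly[(a + 1) % n]
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if x_at > px:
                inside = not inside
    return inside


def test_random_convex_polygons_match_even_odd_oracle():
    rng = np.random.default_rng(7)
    ref = make_volume(np.zeros((20, 20, 1)))
    for _ in range(20):
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=rng.integers(3, 9)))
        radius = rng.uniform(3, 8)
        center = rng.uniform(6, 13, size=2)
        poly = np.column_stack([center[0] + radius * np.cos(angles),
                                center[1] + radius * np.sin(angles)])
        # keep voxel centers away from edges to dodge boundary ties
        contour = np.column_stack([poly, np.zeros(len(poly))])
        try:
            roi = rasterize_roi([contour], ref)
            mask = roi.mask[:, :, 0]
        except ValueError:
            mask = np.zeros((20, 20), dtype=bool)
        for i in range(20):
            for j in range(20):
                expected = _crossing_number_inside(float(i), float(j), poly)
                d_edge = min(abs(np.hypot(i - center[0], j - center[1]) - radius), 1.0)
                if d_edge > 1e-6:
                    assert mask[i, j] == expected, (i, j, poly)


def test_contour_errors():
    ref = make_volume(np.zeros((5, 5, 2)))
    with pytest.raises(ValueError, match="N>=3"):
        rasterize_roi([np.array([[0, 0, 0], [1, 1, 0]])], ref)
    with pytest.raises(ValueError, match="outside"):
        rasterize_roi([square_contour(30, 40, 30, 40, 0)], ref)
    with pytest.raises(ValueError, match="empty ROI"):
        rasterize_roi([square_contour(2.2, 2.4, 2.2, 2.4, 0)], ref)
    with pytest.raises(ValueError, match="shape"):
        rasterize_roi(np.ones((3, 3, 3), dtype=bool), ref)


def test_voxel_mass_and_density():
    assert voxel_mass_kg(1.0, 1.0) == pytest.approx(1e-6)
    assert density_from_hu(0.0) == pytest.approx(1.0)
    assert density_from_hu(500.0) == pytest.approx((1.0 + 1.85) / 2)
    assert density_from_hu(-2000.0) == pytest.approx(0.00121)  # clamped at air


# -- resampling ------------------------------------------------------------


def test_resample_identity_is_bitwise():
    rng = np.random.default_rng(2)
    vol = make_volume(rng.normal(size=(8, 8, 8)))
    out = resample_to(vol, vol)
    assert np.array_equal(out.data, vol.data)


def test_resample_constant_stays_constant():
    src = make_volume(np.full((6, 6, 6), 3.25), spacing=(2, 2, 2))
    ref = make_volume(np.zeros((8, 8, 8)), origin=(1, 1, 1))
    out = resample_to(src, ref)
    np.testing.assert_allclose(out.data, 3.25, atol=1e-12)


def test_resample_linear_ramp_exact():
    x = np.arange(10) * 2.0  # f(x) = x sampled at 2 mm
    src = make_volume(np.broadcast_to(x[:, None, None], (10, 6, 6)).copy(), spacing=(2, 2, 2))
    ref = make_volume(np.zeros((16, 8, 8)), origin=(1.0, 1.0, 1.0))
    out = resample_to(src, ref)
    expected = 1.0 + np.arange(16)  # analytic ramp at the new voxel centers
    np.testing.assert_allclose(out.data, np.broadcast_to(expected[:, None, None], out.shape),
                               atol=1e-9)


def test_resample_affine_field_is_exact():
    rng = np.random.default_rng(3)
    a, b, c, d = rng.normal(size=4)
    ii, jj, kk = np.meshgrid(*[np.arange(12) * 1.5] * 3, indexing="ij")
    src = make_volume(a * ii + b * jj + c * kk + d, spacing=(1.5, 1.5, 1.5))
    ref = make_volume(np.zeros((10, 10, 10)), origin=(2.3, 1.1, 0.7))
    out = resample_to(src, ref)
    xi, yj, zk = np.meshgrid(*[np.arange(10) * 1.0] * 3, indexing="ij")
    expected = a * (xi + 2.3) + b * (yj + 1.1) + c * (zk + 0.7) + d
    np.testing.assert_allclose(out.data, expected, atol=1e-9)


def test_resample_disjoint_volumes_error():
    src = make_volume(np.zeros((4, 4, 4)))
    ref = make_volume(np.zeros((4, 4, 4)), origin=(100, 100, 100))
    with pytest.raises(ValueError, match="overlap"):
        resample_to(src, ref)
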