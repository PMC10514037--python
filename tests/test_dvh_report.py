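import numpy as np
import pytest

from bnctdose import (
    DoseField,
    ImageVolume,
    MethodResult,
    RadiobiologyWeights,
    compare_methods,
    component_fractions,
    compute_dvh,
    coverage_dose,
    dose_slice,
    percent_difference,
    rasterize_roi,
)


def roi_all(shape):
    ref = ImageVolume(np.zeros(shape), (1, 1, 1), modality="CT")
    return rasterize_roi(np.ones(shape, bool), ref, name="GTV")


def field_from(total_shape, b, n, p):
    return DoseField(
        d_phy_b10=np.full(total_shape, b), d_phy_n=np.full(total_shape, n),
        d_phy_p=np.full(total_shape, p), weights=RadiobiologyWeights())


def test_uniform_dose_gives_step_dvh():
    roi = roi_all((3, 3, 3))
    dvh = compute_dvh(np.full((3, 3, 3), 1.7), roi)
    for stat in (dvh.d_max, dvh.d_min, dvh.d_mean, dvh.d_80):
        assert stat == pytest.approx(1.7, rel=1e-12)
    # every dose level up to the (uniform) maximum covers the whole volume
    assert np.all(dvh.volume_fraction == 1.0)


def test_d80_rank_interpolation_on_1_to_10():
    roi = roi_all((10, 1, 1))
    dose = np.arange(1.0, 11.0).reshape(10, 1, 1)
    dvh = compute_dvh(dose, roi)
    assert dvh.d_80 == pytest.approx(3.0)
    assert dvh.d_max == 10.0 and dvh.d_min == 1.0


def test_dmean_equals_direct_voxel_mean():
    rng = np.random.default_rng(6)
    dose = rng.lognormal(size=(7, 5, 4))
    roi = roi_all((7, 5, 4))
    dvh = compute_dvh(dose, roi)
    assert dvh.d_mean == pytest.approx(dose.mean(), rel=1e-12)


def test_dvh_invariant_to_voxel_permutation():
    rng = np.random.default_rng(7)
    dose = rng.uniform(0.5, 3.0, size=(6, 6, 6))
    roi = roi_all((6, 6, 6))
    a = compute_dvh(dose, roi)
    shuffled = dose.ravel().copy()
    rng.shuffle(shuffled)
    b = compute_dvh(shuffled.reshape(6, 6, 6), roi)
    np.testing.assert_allclose(a.volume_fraction, b.volume_fraction, atol=1e-12)
    assert a.d_80 == pytest.approx(b.d_80, rel=1e-12)


def _brute_force_coverage_dose(values, coverage):
    """Oracle: explicit sort + rank interpolation, no numpy vector tricks."""
    ordered = sorted(values, reverse=True)
    n = len(ordered)
    p = coverage * n
    if p <= 1:
        return ordered[0]
    lo = int(np.floor(p))
    if lo >= n:
        return ordered[-1]
    frac = p - lo
    return ordered[lo - 1] + frac * (ordered[lo] - ordered[lo - 1])


def test_coverage_dose_matches_brute_force_sort():
    rng = np.random.default_rng(8)
    for n in (3, 10, 101, 1000):
        values = rng.uniform(0.2, 9.0, size=n)
        for q in (0.2, 0.5, 0.8, 0.95, 1.0):
            assert coverage_dose(values, q) == pytest.approx(
                _brute_force_coverage_dose(values, q), rel=1e-12)


def test_dvh_curve_monotone_and_anchored():
    rng = np.random.default_rng(9)
    dose = rng.uniform(0.0, 4.0, size=(8, 8, 8))
    dvh = compute_dvh(dose, roi_all((8, 8, 8)), n_bins=50)
    assert dvh.volume_fraction[0] == 1.0
    assert np.all(np.diff(dvh.volume_fraction) <= 0)
    assert dvh.d_min <= dvh.d_80 <= dvh.d_max
    assert dvh.d_min <= dvh.d_mean <= dvh.d_max


def test_percent_difference_convention_matches_reported_rows():
    assert round(percent_difference(1.908, 2.344), 1) == 22.9
    assert round(percent_difference(1.560, 0.935), 1) == -40.1
    assert round(percent_difference(3.85, 2.05), 1) == -46.8
    assert percent_difference(1.234, 1.234) == 0.0


def test_component_fractions_match_reported_percentages():
    assert round(component_fractions(2.095, 0.131, 0.118)[0], 1) == 89.4
    assert round(component_fractions(3.414, 0.126, 0.226)[0], 1) == 90.7
    assert round(component_fractions(1.480, 0.037, 0.150)[0], 1) == 88.8
    fractions = component_fractions(1.2, 0.3, 0.08)
    assert sum(fractions) == pytest.approx(100.0, abs=0.1)
    with pytest.raises(ValueError):
        component_fractions(0.0, 0.0, 0.0)


def test_compare_identical_methods_gives_zero_differences():
    rng = np.random.default_rng(10)
    shape = (5, 5, 5)
    roi = roi_all(shape)
    f = DoseField(d_phy_b10=rng.uniform(0.5, 1.0, shape), d_phy_n=rng.uniform(0.01, 0.1, shape),
                  d_phy_p=rng.uniform(0.01, 0.1, shape), weights=RadiobiologyWeights())
    m = MethodResult(dose=f, dvh=compute_dvh(f, roi), tnr=np.full(shape, 2.5))
    stats, comps = compare_methods(m, m, roi)
    diff = stats[stats.method == "difference_pct"].iloc[0]
    for stat in ("d_max", "d_min", "d_mean", "d_80"):
        assert diff[stat] == 0.0
    cd = comps[comps.method == "difference_pct"]
    np.testing.assert_allclose(cd[["tnr", "d_b_cgy_eq_s", "d_n_cgy_eq_s", "d_p_cgy_eq_s"]],
                               0.0, atol=1e-12)


def test_compare_methods_grid_mismatch_errors():
    roi = roi_all((4, 4, 4))
    f = field_from((5, 5, 5), 1.0, 0.1, 0.1)
    m = MethodResult(dose=f, dvh=compute_dvh(f, roi_all((5, 5, 5))), tnr=np.ones((5, 5, 5)))
    with pytest.raises(ValueError, match="grid"):
        compare_methods(m, m, roi)


def test_component_percentages_sum_to_100_at_extrema():
    rng = np.random.default_rng(11)
    shape = (6, 6, 6)
    roi = roi_all(shape)
    f = DoseField(d_phy_b10=rng.uniform(0.2, 1.0, shape), d_phy_n=rng.uniform(0.01, 0.1, shape),
                  d_phy_p=rng.uniform(0.01, 0.1, shape), weights=RadiobiologyWeights())
    m = MethodResult(dose=f, dvh=compute_dvh(f, roi), tnr=rng.uniform(1, 4, shape))
    _, comps = compare_methods(m, m, roi)
    rows = comps[comps.method != "difference_pct"]
    np.testing.assert_allclose(rows[["d_b_pct", "d_n_pct", "d_p_pct"]].sum(axis=1), 100.0,
                               atol=0.1)


def test_dose_slice_constant_and_identities():
    shape = (4, 5, 6)
    f = field_from(shape, 1.0, 0.5, 0.2)
    geo = ImageVolume(np.zeros(shape), (1, 2, 3), modality="CT")

    plane, meta = dose_slice(f, "y", 2, "physical", geometry=geo)
    np.testing.assert_allclose(plane, 1.7, atol=1e-12)
    assert plane.shape == (4, 6)
    assert meta["extent_mm"] == [0.0, 4.0, 0.0, 18.0]

    bio, _ = dose_slice(f, "z", 0, "bioequivalent")
    w = f.weights
    np.testing.assert_allclose(bio, w.cbe * 1.0 + w.rbe_n * 0.5 + w.rbe_p * 0.2, atol=1e-12)

    with pytest.raises(IndexError):
        dose_slice(f, "x", 99)
    with pytest.raises(ValueError):
        dose_slice(f, "q", 0)
    with pytest.raises(ValueError):
        dose_slice(f, "x", 0, kind="banana")
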