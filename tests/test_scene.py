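"""Solar forcing and the synthetic diurnal scene generator."""

import math

import numpy as np
import pytest

import sifpipe as sp
from sifpipe import solar
from sifpipe.grids import GridSpec
from sifpipe.instrument import SensorModel, SifSpectrumModel
from sifpipe.scene import CropArchetype, rasterize_layout
from shapely.geometry import box


# -- solar / PAR -------------------------------------------------------------

def test_overhead_sun_gives_2000_umol():
    g = solar.SolarGeometry(time=13.5, sza=0.0, saa=180.0, doy=180,
                            latitude=0.0)
    rec = solar.diurnal_par([g], par_max=438.0)[0]
    assert rec.ppfd == pytest.approx(2000.0)


def test_horizon_sun_gives_zero():
    g = solar.SolarGeometry(time=22.0, sza=90.0, saa=0.0, doy=180,
                            latitude=50.0)
    rec = solar.diurnal_par([g], par_max=438.0)[0]
    # cos(90 deg) in floats is ~6e-17, not exactly zero
    assert rec.ppfd == pytest.approx(0.0, abs=1e-9)


def test_irradiance_record_unit_invariants():
    recs = solar.diurnal_par(
        solar.geometry_series(solar.DEFAULT_OVERPASS_TIMES), 438.0)
    for r in recs:
        assert r.par_w == 0.219 * r.ppfd
        assert r.par_mw == 1000.0 * r.par_w


def test_diurnal_par_errors():
    with pytest.raises(ValueError):
        solar.diurnal_par([], 438.0)
    g = solar.solar_geometry(12.0)
    with pytest.raises(ValueError):
        solar.diurnal_par([g], 0.0)


def test_par_course_unimodal_peak_at_noon():
    t = np.arange(5.0, 21.0, 0.05)
    ppfd = solar.par_course(t)
    i = int(np.argmax(ppfd))
    assert abs(t[i] - solar.SOLAR_NOON) < 0.05
    day = ppfd > 0
    d = np.diff(ppfd[day])
    # one sign change: non-increasing after the max, non-decreasing before
    assert np.all(d[: i - np.argmax(day)] >= 0)
    assert np.all(np.diff(ppfd[t >= t[i]]) <= 0)


def test_smallest_sza_has_highest_par():
    geoms = solar.geometry_series(solar.DEFAULT_OVERPASS_TIMES)
    recs = solar.diurnal_par(geoms)
    szas = [g.sza for g in geoms]
    ppfds = [r.ppfd for r in recs]
    assert np.argmin(szas) == np.argmax(ppfds)


# -- truth generator ---------------------------------------------------------

def test_truth_invariants_exact(truths32):
    for t in truths32:
        np.testing.assert_array_equal(
            t.sif_leaf, t.eps_true * t.fapar_chl * t.par_mw)
        np.testing.assert_array_equal(
            t.sif_canopy, t.fesc * t.sif_leaf / math.pi)
        assert np.all(t.fapar_chl <= t.fapar_green + 1e-15)
        assert np.all((t.fapar_green >= 0) & (t.fapar_green <= 1))
        assert np.all((t.fesc > 0) & (t.fesc <= 1))


def test_wheat_fesc_constant_across_overpasses(truths32):
    wheat = truths32[0].crops.index("wheat-like")
    m = truths32[0].crop_id == wheat
    for t in truths32[1:]:
        np.testing.assert_array_equal(t.fesc[m], truths32[0].fesc[m])


def test_sugarbeet_fesc_rises_then_plateaus(truths32):
    beet = truths32[0].crops.index("sugarbeet-like")
    m = truths32[0].crop_id == beet
    means = [t.fesc[m].mean() for t in truths32]
    # strictly rising through 14:40 (ramp ends 14.5), then flat
    assert means[0] < means[1] < means[2] < means[3]
    assert means[3] == pytest.approx(means[4], rel=1e-12)
    assert means[4] == pytest.approx(means[5], rel=1e-12)


def test_afternoon_efficiency_depressed_at_matched_par():
    # symmetric times around solar noon have identical PAR, so any
    # difference is the lagged light history (NPQ memory)
    grid = GridSpec(100, 100)
    layout = sp.default_layout(grid)
    truths = sp.generate_truth(layout, times=(10.0, 17.0), seed=3, grid=grid)
    am, pm = truths
    assert am.ppfd == pytest.approx(pm.ppfd, rel=1e-12)
    veg = ~am.soil_mask
    assert veg.sum() > 5000
    for ci, name in enumerate(am.crops):
        m = am.crop_id == ci
        assert pm.eps_true[m].mean() < am.eps_true[m].mean(), name


def test_no_npq_no_hysteresis():
    arch = CropArchetype(name="flat", fapar_chl_base=0.6, fesc_base=0.6,
                         fesc_diurnal_amplitude=0.0,
                         spatial_heterogeneity=0.05, npq_depth=0.0)
    grid = GridSpec(24, 24)
    layout = sp.default_layout(grid, archetypes=[arch])
    am, pm = sp.generate_truth(layout, times=(10.0, 17.0), seed=3, grid=grid,
                               archetypes=[arch])
    np.testing.assert_array_equal(am.eps_true, pm.eps_true)


def test_seed_determinism_bit_identical(layout32, grid32, truths32):
    again = sp.generate_truth(layout32, seed=11, grid=grid32)
    for a, b in zip(truths32, again):
        np.testing.assert_array_equal(a.sif_canopy, b.sif_canopy)
        np.testing.assert_array_equal(a.fesc, b.fesc)
    other = sp.generate_truth(layout32, seed=12, grid=grid32)
    assert not np.array_equal(truths32[0].sif_canopy, other[0].sif_canopy)


def test_overlapping_fields_of_different_crops_error(grid32):
    layout = [
        sp.Field("a", "wheat-like", box(5, 5, 20, 20)),
        sp.Field("b", "sugarbeet-like", box(10, 10, 25, 25)),
    ]
    with pytest.raises(ValueError, match="overlaps"):
        rasterize_layout(layout, grid32, sp.scene.DEFAULT_ARCHETYPES)


def test_missing_par_record_error(layout32, grid32):
    recs = solar.diurnal_par(solar.geometry_series([10.0]), 438.0)
    with pytest.raises(ValueError, match="PAR record"):
        sp.generate_truth(layout32, times=(10.0, 12.0), grid=grid32, par=recs)


def test_empty_times_error(layout32, grid32):
    with pytest.raises(ValueError):
        sp.generate_truth(layout32, times=(), grid=grid32)


# -- truth -> reflectance ----------------------------------------------------

def test_consistent_mode_fcvi_exact(refl32, truth32):
    f = sp.fcvi(refl32)
    veg = ~truth32.soil_mask
    truth_fcvi = truth32.fapar_chl * truth32.fesc
    np.testing.assert_allclose(f[veg], truth_fcvi[veg], atol=1e-10)


def test_consistent_mode_fesc_roundtrip(refl32, truth32):
    from sifpipe import biophysics
    idx = biophysics.indices_from_reflectance(refl32)
    f = sp.fcvi(refl32)
    fesc, valid, _ = sp.escape_fraction(f, idx["fapar_chl"])
    good = valid & ~refl32.attrs["noninvertible_mask"]
    assert good.sum() > 100
    np.testing.assert_allclose(fesc[good], truth32.fesc[good], rtol=1e-10)


def test_soil_pixels_have_zero_fcvi(refl32, truth32):
    f = sp.fcvi(refl32)
    np.testing.assert_allclose(f[truth32.soil_mask], 0.0, atol=1e-12)


def test_reflectance_physical_range(refl32):
    assert np.all(refl32.data >= 0.0)
    assert np.all(refl32.data <= 1.0)


def test_noninvertible_pixels_flagged_not_silently_altered(truth32):
    cube = sp.truth_to_reflectance(truth32)
    mask = cube.attrs["noninvertible_mask"]
    assert mask.shape == truth32.grid.shape
    assert cube.attrs["n_noninvertible"] == int(mask.sum())
    # flagged pixels still carry the exact FCVI contrast
    if mask.any():
        f = sp.fcvi(cube)
        truth_fcvi = truth32.fapar_chl * truth32.fesc
        np.testing.assert_allclose(f[mask], truth_fcvi[mask], atol=1e-10)


def test_unknown_reflectance_mode_errors(truth32):
    with pytest.raises(ValueError, match="mode"):
        sp.truth_to_reflectance(truth32, mode="spline")


# -- reflectance -> at-sensor radiance ---------------------------------------

def test_at_sensor_matches_independent_oracle(rad32, refl32, truth32, atm):
    # recompute one vegetated pixel with straight-line numpy code
    i, j = np.argwhere(truth32.sif_canopy > 0.5)[0]
    assert truth32.sif_canopy[i, j] > 0
    sensor = SensorModel.regular()
    lam = sensor.fine_grid
    r_fine = np.interp(lam, refl32.wavelength, refl32.data[:, i, j])
    t_up = atm.t_up(lam, 1.0)
    l_fine = (atm.e_ground(lam) * truth32.cos_sza * atm.t_down(lam, 1.0)
              * t_up * r_fine / math.pi
              + SifSpectrumModel().shape_at(lam) * t_up
              * truth32.sif_canopy[i, j]
              + atm.l_path(lam, 1.0))
    expected = sensor.convolve(l_fine)
    np.testing.assert_allclose(rad32.data[:, i, j], expected, rtol=1e-10)


def test_zero_sif_scene_is_reflected_plus_path_only(truth32, refl32, atm):
    import dataclasses
    zero = dataclasses.replace(
        truth32, eps_true=np.zeros_like(truth32.eps_true),
        sif_leaf=np.zeros_like(truth32.sif_leaf),
        sif_canopy=np.zeros_like(truth32.sif_canopy))
    rad = sp.to_at_sensor(refl32, zero, atm, snr=np.inf, d=1.0)
    sensor = SensorModel.regular()
    lam = sensor.fine_grid
    i, j = 16, 20
    r_fine = np.interp(lam, refl32.wavelength, refl32.data[:, i, j])
    l_fine = (atm.e_ground(lam) * truth32.cos_sza * atm.t_down(lam, 1.0)
              * atm.t_up(lam, 1.0) * r_fine / math.pi + atm.l_path(lam, 1.0))
    np.testing.assert_allclose(rad.data[:, i, j], sensor.convolve(l_fine),
                               rtol=1e-10)


def test_noise_seed_determinism(refl32, truth32, atm):
    a = sp.to_at_sensor(refl32, truth32, atm, snr=250.0, seed=9)
    b = sp.to_at_sensor(refl32, truth32, atm, snr=250.0, seed=9)
    c = sp.to_at_sensor(refl32, truth32, atm, snr=250.0, seed=10)
    np.testing.assert_array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_nonpositive_snr_errors(refl32, truth32, atm):
    with pytest.raises(ValueError):
        sp.to_at_sensor(refl32, truth32, atm, snr=0.0)


def test_radiance_band_grid_and_units(rad32):
    assert rad32.units == "mW m-2 nm-1 sr-1"
    assert rad32.wavelength[0] == 670.0
    assert rad32.wavelength[-1] <= 780.0
    assert rad32.attrs["fwhm"] == 0.28
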