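"""Three-step spectral-fitting retrieval: references, calibration, fitting."""

import dataclasses
import math

import numpy as np
import pytest

import sifpipe as sp
from sifpipe.atmosphere import O2AAtmosphere
from sifpipe.grids import GridSpec, SpectralCube
from sifpipe.retrieval import (FLAG_CONVERGED, FLAG_FAILED, FLAG_REFERENCE,
                               DegenerateFitError, RetrievalConfig,
                               SpectralFitModel, select_reference_pixels)

GRID_STEP = 0.05   # distance-grid resolution of the default atmosphere


def _flat_reflectance(ny, nx, nir, red):
    """Constant-spectrum cube with prescribed NIR/red window reflectance."""
    lam = np.arange(400.0, 900.0001, 2.0)
    data = np.empty((lam.size, ny, nx))
    prof = np.where(lam >= 740.0, nir, red)
    data[:] = prof[:, None, None]
    return SpectralCube(data, lam, units="1", grid=GridSpec(ny, nx))


def _uniform_truth(ny, nx, sif, cos_sza=0.9):
    shape = (ny, nx)
    return sp.SceneTruth(
        time=12.5, grid=GridSpec(ny, nx),
        fapar_green=np.full(shape, 0.8), fapar_chl=np.full(shape, 0.6),
        fesc=np.full(shape, 0.6), eps_true=np.full(shape, 1e-4),
        sif_leaf=np.full(shape, sif * math.pi / 0.6),
        sif_canopy=np.full(shape, float(sif)),
        crop_id=np.zeros(shape, dtype=int), field_id=np.zeros(shape, int),
        par_mw=300000.0, ppfd=1500.0, cos_sza=cos_sza)


# -- reference selection -----------------------------------------------------

def test_reference_pixels_are_exactly_the_soil_pixels(rad32, refl32, truth32):
    refs = select_reference_pixels(rad32, refl32)
    expected = np.nonzero(truth32.soil_mask.reshape(-1))[0]
    np.testing.assert_array_equal(refs, expected)


def test_ndvi_threshold_is_inclusive():
    # ndvi = 0.125 / 1.25 == 0.1 exactly in floating point
    refl = _flat_reflectance(4, 4, nir=11 / 16, red=9 / 16)
    rad = SpectralCube(np.ones((3, 4, 4)), np.array([700.0, 750.0, 770.0]),
                       units="mW m-2 nm-1 sr-1", grid=GridSpec(4, 4))
    refs = select_reference_pixels(rad, refl, ndvi_max=0.1)
    assert refs.size == 16


def test_all_vegetation_scene_errors():
    refl = _flat_reflectance(4, 4, nir=0.5, red=0.05)
    rad = SpectralCube(np.ones((3, 4, 4)), np.array([700.0, 750.0, 770.0]),
                       units="mW m-2 nm-1 sr-1", grid=GridSpec(4, 4))
    with pytest.raises(ValueError, match="reference"):
        select_reference_pixels(rad, refl)


def test_radiance_proxy_selects_soil(rad32, truth32):
    # without the companion reflectance the radiance-ratio proxy is used
    refs = select_reference_pixels(rad32, None)
    expected = np.nonzero(truth32.soil_mask.reshape(-1))[0]
    np.testing.assert_array_equal(refs, expected)


# -- distance calibration ----------------------------------------------------

def test_calibrated_distance_within_one_grid_step(sfm32):
    assert abs(sfm32.d_star - 1.0) <= GRID_STEP


def test_mean_reference_sif_near_zero_at_dstar(sfm32):
    assert abs(sfm32.calibration["mean_ref_sif"]) <= 0.01
    assert not sfm32.calibration["warning"]


def test_reference_sweep_monotone_with_sign_change(rad32, refl32, atm):
    model = SpectralFitModel(rad32, atm, reflectance=refl32)
    refs = select_reference_pixels(rad32, refl32)
    d_values = np.array([0.8, 0.9, 1.0, 1.1, 1.2])
    means = model.reference_sif_sweep(refs, d_values)
    assert np.all(np.diff(means) > 0)
    assert means[0] < 0 < means[-1]


def test_wrong_distance_gives_opposite_sign_soil_sif(rad32, refl32, atm):
    model = SpectralFitModel(rad32, atm, reflectance=refl32)
    low = model.fit(d=0.8).calibration["mean_ref_sif"]
    high = model.fit(d=1.2).calibration["mean_ref_sif"]
    assert low < -0.01 and high > 0.01


def test_calibration_deterministic_subsample(rad32, refl32, atm):
    cfg = RetrievalConfig(ref_subsample=50, subsample_seed=7)
    d1, _ = SpectralFitModel(rad32, atm, config=cfg,
                             reflectance=refl32).calibrate_distance()
    d2, _ = SpectralFitModel(rad32, atm, config=cfg,
                             reflectance=refl32).calibrate_distance()
    assert d1 == d2


# -- per-pixel fitting -------------------------------------------------------

def test_injected_sif_2_recovered(atm):
    truth = _uniform_truth(2, 2, sif=2.0)
    refl = _flat_reflectance(2, 2, nir=0.45, red=0.45)
    rad = sp.to_at_sensor(refl, truth, atm, snr=np.inf, d=1.0)
    model = SpectralFitModel(rad, atm)
    sif, _, _, flag = model.fit_pixel(rad.data[:, 0, 0], d=1.0)
    assert flag == FLAG_CONVERGED
    assert sif == pytest.approx(2.0, abs=0.02)


def test_injected_zero_sif_near_zero(atm):
    truth = _uniform_truth(2, 2, sif=0.0)
    refl = _flat_reflectance(2, 2, nir=0.45, red=0.45)
    rad = sp.to_at_sensor(refl, truth, atm, snr=np.inf, d=1.0)
    sif, _, _, flag = SpectralFitModel(rad, atm).fit_pixel(
        rad.data[:, 0, 0], d=1.0)
    assert flag == FLAG_CONVERGED
    assert abs(sif) <= 0.01


def test_linearity_slope_one(atm):
    injected = np.arange(0.0, 4.01, 0.5)
    retrieved = []
    refl = _flat_reflectance(1, 1, nir=0.45, red=0.45)
    for s in injected:
        truth = _uniform_truth(1, 1, sif=s)
        rad = sp.to_at_sensor(refl, truth, atm, snr=np.inf, d=1.0)
        sif, *_ = SpectralFitModel(rad, atm).fit_pixel(rad.data[:, 0, 0],
                                                       d=1.0)
        retrieved.append(sif)
    slope = np.polyfit(injected, retrieved, 1)[0]
    assert slope == pytest.approx(1.0, abs=0.02)


def test_nonfinite_spectrum_flagged_failed_not_zero(rad32, atm):
    model = SpectralFitModel(rad32, atm)
    spec = rad32.data[:, 0, 0].copy()
    inside = np.argmin(np.abs(rad32.wavelength - 760.0))
    spec[inside] = np.nan
    sif, poly, rms, flag = model.fit_pixel(spec, d=1.0)
    assert flag == FLAG_FAILED
    assert math.isnan(sif) and math.isnan(rms) and np.all(np.isnan(poly))


def test_amplitude_below_floor_flagged(rad32, refl32, atm):
    # a spectrum with the emission trough inverted drives A far negative
    model = SpectralFitModel(rad32, atm, reflectance=refl32)
    x, offset, norms = model._design(1.0)
    n = model.n_poly
    fake = (x[:, :n] @ (np.array([0.3, 0.0, 0.0]) * norms[:n])
            + x[:, n] * (-5.0 * norms[n]) + offset)
    sif, _, _, flag = model.fit_pixel(fake, d=1.0)
    assert flag == FLAG_FAILED and math.isnan(sif)


def test_snr250_bias_within_two_se(refl32, truth32, atm):
    # per-pixel estimator property at the calibrated distance: with the
    # atmosphere known, noise should not bias the SIF amplitude
    rad = sp.to_at_sensor(refl32, truth32, atm, snr=250.0, seed=21, d=1.0)
    res = SpectralFitModel(rad, atm, reflectance=refl32).fit(d=1.0)
    veg = ~truth32.soil_mask & res.converged_mask
    err = res.sif760[veg] - truth32.sif_canopy[veg]
    assert veg.sum() >= 500
    se = err.std(ddof=1) / np.sqrt(err.size)
    assert abs(err.mean()) <= 2.0 * se


# -- full scene --------------------------------------------------------------

def test_noise_free_scene_recovery_one_percent(sfm32, truth32):
    strong = truth32.sif_canopy > 0.5
    assert strong.sum() > 100
    rel = (np.abs(sfm32.sif760 - truth32.sif_canopy)[strong]
           / truth32.sif_canopy[strong])
    assert np.nanmax(rel) <= 0.01


def test_reflectance760_recovered(sfm32, refl32):
    i760 = refl32.nearest_band(760.0)
    ok = sfm32.converged_mask
    np.testing.assert_allclose(sfm32.reflectance760[ok],
                               refl32.data[i760][ok], atol=1e-6)


def test_reference_pixels_flagged(sfm32, truth32):
    assert np.all(sfm32.flags[truth32.soil_mask] == FLAG_REFERENCE)
    assert np.all(sfm32.flags[~truth32.soil_mask] == FLAG_CONVERGED)


def test_residual_rms_nonnegative_and_tiny_noise_free(sfm32):
    ok = sfm32.converged_mask
    assert np.all(sfm32.residual_rms[ok] >= 0)
    # relative to the at-sensor radiance scale (~70 mW m-2 nm-1 sr-1) the
    # noise-free misfit is at the level of the secant tolerance on d*
    scale = float(np.nanmedian(np.abs(sfm32.model.radiance.data)))
    assert np.nanmedian(sfm32.residual_rms[ok]) < 1e-5 * scale


def test_no_band_scene_all_failed(refl32, truth32):
    flat_atm = O2AAtmosphere(depth=0.0)
    rad = sp.to_at_sensor(refl32, truth32, flat_atm, snr=np.inf, d=1.0)
    res = SpectralFitModel(rad, flat_atm, reflectance=refl32).fit()
    assert np.all(res.flags == FLAG_FAILED)
    assert np.all(np.isnan(res.sif760))
    assert math.isnan(res.d_star)


def test_no_band_calibration_raises_typed_error(refl32, truth32):
    flat_atm = O2AAtmosphere(depth=0.0)
    rad = sp.to_at_sensor(refl32, truth32, flat_atm, snr=np.inf, d=1.0)
    with pytest.raises(DegenerateFitError):
        SpectralFitModel(rad, flat_atm,
                         reflectance=refl32).calibrate_distance()


def test_retrieve_scene_wrapper_matches_model(rad32, refl32, atm, sfm32):
    res = sp.retrieve_scene(rad32, atm, reflectance=refl32)
    np.testing.assert_array_equal(res.sif760, sfm32.sif760)
    assert res.d_star == sfm32.d_star


def test_config_validation():
    with pytest.raises(ValueError, match="760"):
        RetrievalConfig(fit_window=(761.0, 770.0))
    with pytest.raises(ValueError):
        RetrievalConfig(poly_degree=-1)
    with pytest.raises(ValueError):
        RetrievalConfig(sif_model_kind="spline")


def test_mismatched_sif_model_still_recovers_roughly(rad32, refl32, atm,
                                                     truth32):
    # linear-in-window fluorescence model: a robustness check, not exact
    cfg = RetrievalConfig(sif_model_kind="linear")
    res = SpectralFitModel(rad32, atm, config=cfg, reflectance=refl32).fit()
    strong = truth32.sif_canopy > 0.5
    rel = (np.abs(res.sif760 - truth32.sif_canopy)[strong]
           / truth32.sif_canopy[strong])
    assert np.nanmedian(rel) <= 0.15


def test_summary_is_informative(sfm32):
    s = sfm32.summary()
    assert "SIF760" in s and "d*" in s
    assert "failed" in s
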