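"""Forward simulation of diurnal multi-overpass scenes with known truth.

The generator emulates an agricultural site observed six times over one
clear-sky day by a nadir-viewing imaging spectrometer: per-pixel canopy
truth (fAPAR_green, fAPAR_chl, escape fraction, leaf emission efficiency),
top-of-canopy reflectance consistent with that truth, and at-sensor radiance
around the O2-A band including atmospheric absorption, path radiance, sensor
convolution and shot-like noise.

Three crop archetypes span the structural gradient of the study system:

* sugarbeet-like — dense canopy whose leaf orientation shifts from
  erectophile in the morning to planophile in the afternoon, expressed as an
  escape fraction that rises from morning to mid-afternoon and plateaus;
* wheat-like — spherical, time-constant leaf angle distribution, hence a
  time-constant escape fraction, with a pronounced midday NPQ depression of
  the emission efficiency;
* orchard-like — sparser, strongly heterogeneous canopy.

The leaf emission efficiency follows a saturating light response with an
NPQ-like afternoon depression driven by lagged PAR history, so that
efficiency plotted against PAR traces a hysteresis loop with the afternoon
branch below the morning branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from . import solar
from .atmosphere import O2AAtmosphere
from .biophysics import DEFAULT_ALPHA, DEFAULT_K, FAPAR_INTERCEPT, FAPAR_SLOPE
from .grids import GridSpec, SpectralCube
from .instrument import SensorModel, SifSpectrumModel

__all__ = [
    "CropArchetype", "Field", "SceneTruth", "SUGARBEET", "WHEAT", "ORCHARD",
    "DEFAULT_ARCHETYPES", "default_layout", "rasterize_layout",
    "generate_truth", "truth_to_reflectance", "to_at_sensor",
]


@dataclass(frozen=True)
class CropArchetype:
    """Structural and physiological parameters of one crop type.

    fesc_diurnal_amplitude is the morning-to-mid-afternoon rise of the
    escape fraction (0 for a constant leaf angle distribution);
    spatial_heterogeneity is the relative SD of the per-pixel canopy-density
    truth fields (fAPAR, emission efficiency), while fesc_heterogeneity is
    the relative SD of the escape fraction: a crop with a constant leaf
    angle distribution has a spatially uniform escape fraction (0), whereas
    structurally variable canopies scatter around the base value.
    eps_max is the maximum leaf SIF emission efficiency (nm-1) and npq_depth
    the fractional midday depression of that efficiency at full lagged-light
    history.
    """

    name: str
    fapar_chl_base: float
    fesc_base: float
    fesc_diurnal_amplitude: float
    spatial_heterogeneity: float
    soil_fraction: float = 0.0
    eps_max: float = 1.0e-4
    npq_depth: float = 0.2
    fesc_heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("fapar_chl_base", "fesc_base", "fesc_diurnal_amplitude",
                     "spatial_heterogeneity", "soil_fraction", "npq_depth",
                     "fesc_heterogeneity"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.fesc_base <= 0:
            raise ValueError("fesc_base must be positive")
        if self.fesc_base + self.fesc_diurnal_amplitude > 1.0:
            raise ValueError("fesc_base + fesc_diurnal_amplitude must be <= 1")
        if self.fapar_chl_base > DEFAULT_K:
            raise ValueError(
                f"fapar_chl_base > {DEFAULT_K} implies fAPAR_green > 1")


SUGARBEET = CropArchetype(
    name="sugarbeet-like", fapar_chl_base=0.74, fesc_base=0.60,
    fesc_diurnal_amplitude=0.08, spatial_heterogeneity=0.08,
    eps_max=0.9e-4, npq_depth=0.08, fesc_heterogeneity=0.05)
WHEAT = CropArchetype(
    name="wheat-like", fapar_chl_base=0.62, fesc_base=0.55,
    fesc_diurnal_amplitude=0.0, spatial_heterogeneity=0.06,
    eps_max=5.5e-5, npq_depth=0.35, fesc_heterogeneity=0.0)
ORCHARD = CropArchetype(
    name="orchard-like", fapar_chl_base=0.50, fesc_base=0.55,
    fesc_diurnal_amplitude=0.05, spatial_heterogeneity=0.15,
    eps_max=8.0e-5, npq_depth=0.20, fesc_heterogeneity=0.12)

DEFAULT_ARCHETYPES = (SUGARBEET, WHEAT, ORCHARD)


@dataclass(frozen=True)
class Field:
    """One agricultural field: id, crop archetype name and footprint."""

    field_id: str
    crop: str
    polygon: Polygon


@dataclass
class SceneTruth:
    """Per-pixel ground truth for one overpass.

    Invariants (exact by construction):
        sif_leaf = eps_true * fapar_chl * par_mw
        sif_canopy = fesc * sif_leaf / pi
        0 <= fapar_chl <= fapar_green <= 1
    crop_id and field_id are -1 on bare-soil pixels.
    """

    time: float
    grid: GridSpec
    fapar_green: np.ndarray
    fapar_chl: np.ndarray
    fesc: np.ndarray
    eps_true: np.ndarray
    sif_leaf: np.ndarray        # mW m-2 nm-1, hemispherical
    sif_canopy: np.ndarray      # mW m-2 nm-1 sr-1, directional
    crop_id: np.ndarray
    field_id: np.ndarray
    par_mw: float
    ppfd: float
    cos_sza: float
    crops: tuple[str, ...] = ()
    fields: tuple[str, ...] = ()

    @property
    def soil_mask(self) -> np.ndarray:
        return self.crop_id < 0


# ---------------------------------------------------------------------------
# field layout


def default_layout(grid: GridSpec,
                   archetypes: Sequence[CropArchetype] = DEFAULT_ARCHETYPES,
                   fields_per_crop: int = 2,
                   soil_margin: float = 0.08) -> list[Field]:
    """Rectangular fields in columns (one column per crop) with a bare-soil
    margin on the left of the scene; gaps between fields stay bare soil."""
    width = grid.nx * grid.gsd
    height = grid.ny * grid.gsd
    x0 = soil_margin * width
    col_w = (width - x0) / len(archetypes)
    gap = max(grid.gsd, 0.01 * height)
    row_h = (height - (fields_per_crop + 1) * gap) / fields_per_crop
    out = []
    for ci, arch in enumerate(archetypes):
        cx0 = x0 + ci * col_w
        for fi in range(fields_per_crop):
            fy0 = gap + fi * (row_h + gap)
            out.append(Field(
                field_id=f"{arch.name.split('-')[0]}-{fi + 1}",
                crop=arch.name,
                polygon=box(cx0 + gap / 2, fy0, cx0 + col_w - gap / 2,
                            fy0 + row_h)))
    return out


def rasterize_layout(layout: Sequence[Field], grid: GridSpec,
                     archetypes: Sequence[CropArchetype],
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center rasterization of the field layout.

    Returns (crop_id, field_id) integer grids, -1 where no field covers the
    pixel center (bare soil). Overlapping fields of different archetypes
    raise; pixel centers exactly on a polygon edge are excluded.
    """
    crop_names = [a.name for a in archetypes]
    X, Y = grid.pixel_centers()
    crop_id = np.full(grid.shape, -1, dtype=int)
    field_id = np.full(grid.shape, -1, dtype=int)
    for fi, f in enumerate(layout):
        if f.crop not in crop_names:
            raise ValueError(f"field {f.field_id!r} uses unknown crop {f.crop!r}")
        ci = crop_names.index(f.crop)
        mask = shapely.contains_xy(f.polygon, X, Y)
        clash = mask & (crop_id >= 0) & (crop_id != ci)
        if np.any(clash):
            raise ValueError(
                f"field {f.field_id!r} overlaps a field of a different "
                f"archetype on {int(clash.sum())} pixel(s)")
        fresh = mask & (field_id < 0)
        crop_id[fresh] = ci
        field_id[fresh] = fi
    return crop_id, field_id


# ---------------------------------------------------------------------------
# truth generation


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _fesc_ramp(t: float, t_start: float = 10.0, t_end: float = 14.5) -> float:
    """Monotone 0->1 morning-to-mid-afternoon rise, then plateau."""
    return float(_smoothstep(np.array((t - t_start) / (t_end - t_start))))


def _light_response(ppfd: np.ndarray, ppfd_half: float) -> np.ndarray:
    """Saturating rise of emission efficiency with light."""
    return ppfd / (ppfd + ppfd_half)


def _par_history(times: np.ndarray, par_max: float, tau: float,
                 doy: int, latitude: float, solar_noon: float,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order-filtered, normalized PAR history H(t) on a fine grid.

    H lags the instantaneous PAR course, so afternoon times carry a larger
    accumulated light history than morning times at the same PAR level —
    the mechanism behind the efficiency hysteresis loop.
    """
    t_fine = np.arange(3.5, 21.0, 0.01)
    ppfd = solar.par_course(t_fine, par_max=par_max, doy=doy,
                            latitude=latitude, solar_noon=solar_noon)
    p_norm = ppfd / ppfd.max()
    h = np.zeros_like(p_norm)
    dt = 0.01
    for i in range(1, h.size):
        h[i] = h[i - 1] + dt / tau * (p_norm[i - 1] - h[i - 1])
    return t_fine, h, ppfd


def generate_truth(layout: Sequence[Field],
                   times: Sequence[float] = solar.DEFAULT_OVERPASS_TIMES,
                   seed: int = 0,
                   grid: GridSpec = GridSpec(64, 64),
                   archetypes: Sequence[CropArchetype] = DEFAULT_ARCHETYPES,
                   par: Sequence[solar.IrradianceRecord] | None = None,
                   par_max: float = 438.0,
                   ppfd_half: float = 600.0,
                   tau_npq: float = 1.5,
                   doy: int = solar.DEFAULT_DOY,
                   latitude: float = solar.DEFAULT_LATITUDE,
                   solar_noon: float = solar.SOLAR_NOON,
                   ) -> list[SceneTruth]:
    """Simulate per-pixel truth for each overpass time.

    Spatial heterogeneity is drawn once per pixel (the same field keeps its
    spatial pattern across the day); the diurnal course moves the escape
    fraction (crop-specific ramp) and the emission efficiency (light
    response x lagged-history NPQ depression). With a fixed seed the output
    is bit-identical across runs.

    If ``par`` records are supplied they must cover every overpass time.
    """
    times = list(times)
    if not times:
        raise ValueError("no overpass times given")
    geoms = solar.geometry_series(times, doy=doy, latitude=latitude,
                                  solar_noon=solar_noon)
    if par is None:
        records = solar.diurnal_par(geoms, par_max)
    else:
        lookup = {round(r.time, 6): r for r in par}
        records = []
        for t in times:
            r = lookup.get(round(t, 6))
            if r is None:
                raise ValueError(f"no PAR record for overpass time {t}")
            records.append(r)

    crop_id, field_id = rasterize_layout(layout, grid, archetypes)
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape

    # per-pixel static heterogeneity deviates (drawn once for the day)
    z_fapar = rng.standard_normal((ny, nx))
    z_fesc = rng.standard_normal((ny, nx))
    z_eps = rng.standard_normal((ny, nx))

    fapar_chl0 = np.zeros((ny, nx))
    fesc0 = np.ones((ny, nx))
    fesc_amp = np.zeros((ny, nx))
    eps_scale = np.zeros((ny, nx))
    npq_depth = np.zeros((ny, nx))
    for ci, arch in enumerate(archetypes):
        m = crop_id == ci
        het = arch.spatial_heterogeneity
        fapar_chl0[m] = np.clip(
            arch.fapar_chl_base * np.clip(1.0 + het * z_fapar[m], 0.2, 1.8),
            0.0, DEFAULT_K)
        fesc0[m] = np.clip(
            arch.fesc_base
            * np.clip(1.0 + arch.fesc_heterogeneity * z_fesc[m], 0.2, 1.8),
            0.05, 1.0 - arch.fesc_diurnal_amplitude)
        fesc_amp[m] = arch.fesc_diurnal_amplitude
        eps_scale[m] = arch.eps_max * np.clip(1.0 + het * z_eps[m], 0.2, 1.8)
        npq_depth[m] = arch.npq_depth

    t_fine, h_fine, _ = _par_history(np.array(times), par_max, tau_npq,
                                     doy, latitude, solar_noon)

    out = []
    veg = crop_id >= 0
    for t, g, rec in zip(times, geoms, records):
        fesc_t = np.where(veg, np.clip(
            fesc0 + fesc_amp * _fesc_ramp(t), 0.0, 1.0), 1.0)
        h_t = float(np.interp(t, t_fine, h_fine))
        light = _light_response(rec.ppfd, ppfd_half)
        eps_t = np.where(veg,
                         eps_scale * (1.0 - npq_depth * h_t) * light, 0.0)
        sif_leaf = eps_t * fapar_chl0 * rec.par_mw
        sif_canopy = fesc_t * sif_leaf / math.pi
        out.append(SceneTruth(
            time=t, grid=grid,
            fapar_green=fapar_chl0 / DEFAULT_K,
            fapar_chl=fapar_chl0.copy(),
            fesc=fesc_t, eps_true=eps_t,
            sif_leaf=sif_leaf, sif_canopy=sif_canopy,
            crop_id=crop_id.copy(), field_id=field_id.copy(),
            par_mw=rec.par_mw, ppfd=rec.ppfd, cos_sza=g.cos_sza,
            crops=tuple(a.name for a in archetypes),
            fields=tuple(f.field_id for f in layout)))
    return out


# ---------------------------------------------------------------------------
# truth -> top-of-canopy reflectance


DEFAULT_REFL_WAVELENGTHS = np.arange(400.0, 900.0001, 2.0)


def truth_to_reflectance(truth: SceneTruth,
                         mode: str = "consistent",
                         wavelengths: np.ndarray | None = None,
                         alpha: float = DEFAULT_ALPHA,
                         k: float = DEFAULT_K,
                         soil_albedo: float = 0.20) -> SpectralCube:
    """Construct a 400-900 nm top-of-canopy reflectance cube from truth.

    In ``consistent`` mode the spectrum of every vegetation pixel is built
    so that the downstream index algebra inverts it exactly: the reflectance
    at 770 nm minus the mean visible reflectance equals
    fAPAR_chl * fesc, and the NIR/red band means reproduce a WDRVI whose
    linear mapping returns the true fAPAR_green. The spectrum is a flat
    visible segment, a smooth red edge over 700-750 nm and a flat NIR
    plateau. Vegetation pixels whose fAPAR_green falls outside the
    invertible range of the linear mapping are rendered as flat soil spectra
    and flagged (cube.attrs['noninvertible_mask']), never silently altered.

    ``toy_rt`` mode uses an independent two-component vegetation/soil
    mixture with pigment structure in the visible and a sloped NIR, so
    pipeline recovery is only approximate — intended for robustness tests.
    """
    if mode not in ("consistent", "toy_rt"):
        raise ValueError(f"unknown reflectance mode {mode!r}")
    lam = (DEFAULT_REFL_WAVELENGTHS if wavelengths is None
           else np.asarray(wavelengths, dtype=float))
    ny, nx = truth.grid.shape
    veg = truth.crop_id >= 0

    fg = truth.fapar_green
    w_target = (fg - FAPAR_INTERCEPT) / FAPAR_SLOPE
    # the WDRVI constraint is solvable only while alpha*(1-W)/(1+W) < 1
    w_min = (alpha - 1.0) / (alpha + 1.0)
    invertible = veg & (w_target > w_min + 1e-9) & (w_target < 1.0 + 1e-12)
    w = np.clip(w_target, -1.0, 1.0)

    fcvi_true = truth.fapar_chl * truth.fesc
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = alpha * (1.0 - w) / (1.0 + w)
        nir = np.where(invertible, fcvi_true / (1.0 - ratio), np.nan)
        vis = np.where(invertible, nir - fcvi_true, np.nan)
    # vegetation pixels below the invertible fAPAR_green floor keep an
    # FCVI-exact spectrum (fixed visible albedo) but cannot reproduce their
    # fAPAR_green through the index chain; they are flagged, not altered
    odd = veg & ~invertible
    vis = np.where(odd, 0.05, vis)
    nir = np.where(odd, 0.05 + fcvi_true, nir)
    vis = np.where(~veg, soil_albedo, vis)
    nir = np.where(~veg, soil_albedo, nir)

    edge = _smoothstep((lam - 700.0) / 50.0)          # 0 below 700, 1 above 750
    if mode == "consistent":
        refl = (vis[None] + (nir - vis)[None] * edge[:, None, None])
    else:
        # pigment structure in the VIS, sloped NIR: approximate inversion
        # only. The pigment features belong to vegetation; bare soil is
        # spectrally smooth, so it keeps a flat albedo.
        vis_shape = (1.0 + 0.25 * np.exp(-0.5 * ((lam - 550.0) / 30.0) ** 2)
                     - 0.15 * np.exp(-0.5 * ((lam - 670.0) / 25.0) ** 2))
        in_vis = (lam >= 400.0) & (lam < 700.0)
        vis_shape = vis_shape / vis_shape[in_vis].mean()
        nir_slope = 1.0 + 4.0e-4 * (lam - 770.0)
        refl = (vis[None] * vis_shape[:, None, None] * (1.0 - edge[:, None, None])
                + nir[None] * nir_slope[:, None, None] * edge[:, None, None])
        refl = np.where(veg[None], refl,
                        np.broadcast_to(vis[None], refl.shape))

    cube = SpectralCube(
        refl, lam, units="1", grid=truth.grid,
        time=truth.time, cos_sza=truth.cos_sza,
        attrs={"mode": mode, "n_noninvertible": int(np.sum(veg & ~invertible))})
    cube.attrs["noninvertible_mask"] = veg & ~invertible
    return cube


# ---------------------------------------------------------------------------
# reflectance + truth -> at-sensor radiance


def to_at_sensor(reflectance: SpectralCube,
                 truth: SceneTruth,
                 atm: O2AAtmosphere,
                 sif_shape: SifSpectrumModel = SifSpectrumModel(),
                 sensor: SensorModel | None = None,
                 snr: float = math.inf,
                 seed: int = 0,
                 d: float = 1.0,
                 chunk: int = 4096) -> SpectralCube:
    """Simulate the at-sensor radiance cube around the O2-A band.

    On a high-resolution grid the radiance is

        L = E_g * cos(sza) * T_down * R / pi  +  SIF * T_up  +  L_path

    with the SIF spectrum scaled so its value at 760 nm equals the true
    canopy SIF; the result is convolved with the sensor's Gaussian response
    and resampled to its bands. Gaussian noise with per-band standard
    deviation signal/snr is added (snr = inf means noise-free).
    """
    if sensor is None:
        sensor = SensorModel.regular()
    lam = sensor.fine_grid
    if np.any(truth.sif_canopy != 0):
        sif_unit = sif_shape.shape_at(lam)      # raises if non-positive at 760
    else:
        sif_unit = np.zeros_like(lam)

    if lam[0] < reflectance.wavelength[0] or lam[-1] > reflectance.wavelength[-1]:
        raise ValueError("reflectance cube does not cover the sensor range")

    t_up = atm.t_up(lam, d)
    e_down = (atm.e_ground(lam) * truth.cos_sza * atm.t_down(lam, d)
              * t_up / math.pi)
    l_path = atm.l_path(lam, d)

    refl_flat = reflectance.flat()
    sif_flat = truth.sif_canopy.reshape(-1)
    npix = refl_flat.shape[1]

    # linear-interpolation weights from the coarse reflectance grid
    wl = reflectance.wavelength
    i1 = np.clip(np.searchsorted(wl, lam), 1, wl.size - 1)
    i0 = i1 - 1
    frac = (lam - wl[i0]) / (wl[i1] - wl[i0])

    nband = sensor.band_centers.size
    out = np.empty((nband, npix))
    for s in range(0, npix, chunk):
        e = slice(s, min(s + chunk, npix))
        r_fine = ((1.0 - frac)[:, None] * refl_flat[i0][:, e]
                  + frac[:, None] * refl_flat[i1][:, e])
        l_fine = (e_down[:, None] * r_fine
                  + (sif_unit * t_up)[:, None] * sif_flat[None, e]
                  + l_path[:, None])
        out[:, e] = sensor.convolve(l_fine)

    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, np.abs(out) / snr)

    return SpectralCube(
        out.reshape((nband,) + truth.grid.shape),
        sensor.band_centers,
        units="mW m-2 nm-1 sr-1",
        grid=truth.grid, time=truth.time, cos_sza=truth.cos_sza,
        attrs={"fwhm": sensor.fwhm, "true_distance": d,
               "snr": float(snr) if np.isfinite(snr) else -1.0})
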