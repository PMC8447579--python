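"""Vegetation indices, fAPAR estimation and PAR unit conversions.

The fraction of photosynthetically active radiation absorbed by green leaf
material (fAPAR_green) is estimated from the wide dynamic range vegetation
index (WDRVI), a variant of NDVI in which NIR reflectance is down-weighted
by a factor alpha to avoid saturation over dense canopies:

    WDRVI = (alpha * R_NIR - R_red) / (alpha * R_NIR + R_red)

with R_NIR and R_red the mean reflectances over 795-810 nm and 665-680 nm.
A linear calibration maps WDRVI to fAPAR_green,

    fAPAR_green = 0.516 * WDRVI + 0.726

and the chlorophyll-absorbed fraction is a fixed proportion of that,
fAPAR_chl = k * fAPAR_green with k = 0.79, valid for canopies with leaf
chlorophyll content above ~20 ug cm-2. APAR_chl is fAPAR_chl times incoming
PAR; quantum-unit PAR (PPFD, umol m-2 s-1) converts to energy units with
the broadband factor 0.219 W m-2 per umol m-2 s-1 over 400-700 nm.
"""

from __future__ import annotations

import logging

import numpy as np

from .grids import SpectralCube

__all__ = [
    "PPFD_TO_W", "FAPAR_SLOPE", "FAPAR_INTERCEPT", "DEFAULT_ALPHA", "DEFAULT_K",
    "NIR_WINDOW", "RED_WINDOW", "VIS_WINDOW",
    "band_mean", "wdrvi", "ndvi", "fapar_green", "fapar_green_to_wdrvi",
    "fapar_chl", "ppfd_to_w", "ppfd_to_mw", "apar_chl",
]

log = logging.getLogger(__name__)

#: Energy per quantum flux for broadband PAR, W m-2 per umol m-2 s-1.
PPFD_TO_W = 0.219
#: Linear WDRVI -> fAPAR_green calibration (slope, intercept).
FAPAR_SLOPE = 0.516
FAPAR_INTERCEPT = 0.726
#: WDRVI NIR weighting factor.
DEFAULT_ALPHA = 0.1
#: Ratio fAPAR_chl / fAPAR_green for chlorophyll-rich canopies.
DEFAULT_K = 0.79

#: Band windows (nm, half-open [lo, hi) on band centers).
NIR_WINDOW = (795.0, 810.0)
RED_WINDOW = (665.0, 680.0)
VIS_WINDOW = (400.0, 700.0)


def band_mean(cube: SpectralCube, window: tuple[float, float]) -> np.ndarray:
    """Unweighted mean over band centers in the half-open window [lo, hi).

    Returns a (ny, nx) grid. Raises if no band center falls in the window.
    """
    lo, hi = window
    idx = cube.bands_in(lo, hi)
    if idx.size == 0:
        raise ValueError(f"no band centers in window [{lo}, {hi}) nm")
    return cube.data[idx].mean(axis=0)


def wdrvi(nir: np.ndarray, red: np.ndarray,
          alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Wide dynamic range vegetation index.

    Pixels with nir == red == 0 are returned as NaN (index undefined).
    Negative reflectance raises: it signals a unit or calibration problem
    upstream rather than a value this index can interpret.
    """
    scalar = np.isscalar(nir) and np.isscalar(red)
    nir = np.atleast_1d(np.asarray(nir, dtype=float))
    red = np.atleast_1d(np.asarray(red, dtype=float))
    if np.any(nir < 0) or np.any(red < 0):
        raise ValueError("reflectance must be non-negative for WDRVI")
    num = alpha * nir - red
    den = alpha * nir + red
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out[0] if scalar else out


def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index (WDRVI with alpha = 1)."""
    return wdrvi(nir, red, alpha=1.0)


def fapar_green(wdrvi_grid: np.ndarray) -> np.ndarray:
    """fAPAR_green from WDRVI via the linear calibration, clamped to [0, 1].

    The linear mapping exceeds 1 for WDRVI > ~0.531; such pixels are clamped
    (dense canopies legitimately saturate) and counted in a log diagnostic.
    """
    w = np.asarray(wdrvi_grid, dtype=float)
    raw = FAPAR_SLOPE * w + FAPAR_INTERCEPT
    clamped = np.count_nonzero((raw < 0) | (raw > 1))
    if clamped:
        log.info("fapar_green: clamped %d pixel(s) to [0, 1]", clamped)
    return np.clip(raw, 0.0, 1.0)


def fapar_green_to_wdrvi(fg: np.ndarray) -> np.ndarray:
    """Inverse of the fAPAR_green calibration, clipped to WDRVI in [-1, 1]."""
    w = (np.asarray(fg, dtype=float) - FAPAR_INTERCEPT) / FAPAR_SLOPE
    return np.clip(w, -1.0, 1.0)


def fapar_chl(fapar_green_grid: np.ndarray, k: float = DEFAULT_K) -> np.ndarray:
    """fAPAR_chl = k * fAPAR_green. k must lie in (0, 1]."""
    if not 0.0 < k <= 1.0:
        raise ValueError(f"k must be in (0, 1], got {k}")
    return k * np.asarray(fapar_green_grid, dtype=float)


def ppfd_to_w(ppfd: np.ndarray) -> np.ndarray:
    """PPFD (umol m-2 s-1) to broadband PAR in W m-2."""
    p = np.asarray(ppfd, dtype=float)
    if np.any(p < 0):
        raise ValueError("PPFD must be non-negative")
    return PPFD_TO_W * p


def ppfd_to_mw(ppfd: np.ndarray) -> np.ndarray:
    """PPFD (umol m-2 s-1) to PAR in mW m-2, the unit SIF radiance pairs with."""
    return 1000.0 * ppfd_to_w(ppfd)


def apar_chl(fapar_chl_grid: np.ndarray, par_mw: float) -> np.ndarray:
    """Absorbed PAR by chlorophyll: fAPAR_chl * PAR (mW m-2), PAR a scene scalar."""
    if par_mw < 0:
        raise ValueError("PAR must be non-negative")
    return np.asarray(fapar_chl_grid, dtype=float) * par_mw


def indices_from_reflectance(cube: SpectralCube, alpha: float = DEFAULT_ALPHA,
                             k: float = DEFAULT_K) -> dict[str, np.ndarray]:
    """Convenience: WDRVI, NDVI, fAPAR_green and fAPAR_chl grids from a cube."""
    nir = band_mean(cube, NIR_WINDOW)
    red = band_mean(cube, RED_WINDOW)
    w = wdrvi(nir, red, alpha=alpha)
    n = ndvi(nir, red)
    fg = fapar_green(w)
    return {"wdrvi": w, "ndvi": n, "fapar_green": fg,
            "fapar_chl": fapar_chl(fg, k=k)}
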