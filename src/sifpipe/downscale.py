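"""FCVI, escape fraction and canopy-to-leaf downscaling of SIF760.

The fluorescence correction vegetation index (FCVI) — NIR reflectance at
770 nm minus the mean visible (400-700 nm) reflectance — approximates the
product of fAPAR and the far-red SIF escape fraction. Dividing by
fAPAR_chl isolates the escape fraction,

    f_esc ~= FCVI / fAPAR_chl,

and leaf-level hemispherical emission follows from the directional canopy
signal as SIF760_leaf = pi * SIF760_canopy / f_esc. The index is unreliable
over sparse canopies with visible soil, so pixels with FCVI below 0.18 are
excluded; pixels whose computed f_esc exceeds 1 are physically impossible
and are masked (not clipped) so they stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biophysics import VIS_WINDOW, band_mean
from .grids import SpectralCube

__all__ = [
    "DEFAULT_FCVI_MIN", "FLAG_VALID", "FLAG_LOW_FCVI", "FLAG_FESC_GT_1",
    "FLAG_NONPOS_FAPAR", "FLAG_MISSING", "DownscaleMaps",
    "fcvi", "escape_fraction", "sif_leaf", "downscale_maps",
]

#: FCVI below this is excluded (soil-contaminated sparse canopy).
DEFAULT_FCVI_MIN = 0.18

FLAG_VALID = 0
FLAG_LOW_FCVI = 1
FLAG_FESC_GT_1 = 2
FLAG_NONPOS_FAPAR = 3
FLAG_MISSING = 4


@dataclass
class DownscaleMaps:
    """Escape-fraction and leaf-SIF rasters with their validity mask.

    On valid pixels 0 < fesc <= 1 and sif_leaf = pi * sif_canopy / fesc
    exactly; each invalid pixel carries exactly one reason code.
    """

    fcvi: np.ndarray
    fesc: np.ndarray
    sif_leaf: np.ndarray          # mW m-2 nm-1 (hemispherical)
    valid_mask: np.ndarray
    flags: np.ndarray


def fcvi(reflectance: SpectralCube, nir_target: float = 770.0,
         nir_tol: float = 5.0) -> np.ndarray:
    """FCVI grid: R(770 nm) minus the mean reflectance over 400-700 nm.

    The NIR term uses the band center nearest 770 nm (within ``nir_tol``);
    the visible mean follows the half-open [400, 700) band-mean convention.
    """
    i_nir = reflectance.nearest_band(nir_target, tol=nir_tol)
    return reflectance.data[i_nir] - band_mean(reflectance, VIS_WINDOW)


def escape_fraction(fcvi_grid: np.ndarray, fapar_chl: np.ndarray,
                    fcvi_min: float = DEFAULT_FCVI_MIN,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Escape fraction FCVI / fAPAR_chl with validity mask and reason codes.

    Pixels fail, in priority order, for: missing inputs, FCVI < fcvi_min,
    non-positive fAPAR_chl, or a computed f_esc > 1. Returns
    (fesc, valid_mask, flags); fesc is NaN wherever invalid.
    """
    fcvi_grid = np.asarray(fcvi_grid, dtype=float)
    fapar_chl = np.asarray(fapar_chl, dtype=float)
    if fcvi_grid.shape != fapar_chl.shape:
        raise ValueError(
            f"misaligned grids: FCVI {fcvi_grid.shape} vs "
            f"fAPAR_chl {fapar_chl.shape}")

    flags = np.full(fcvi_grid.shape, FLAG_VALID, dtype=np.int8)
    missing = ~np.isfinite(fcvi_grid) | ~np.isfinite(fapar_chl)
    low = ~missing & (fcvi_grid < fcvi_min)
    nonpos = ~missing & ~low & (fapar_chl <= 0)

    fesc = np.full(fcvi_grid.shape, np.nan)
    ok = ~(missing | low | nonpos)
    np.divide(fcvi_grid, fapar_chl, out=fesc, where=ok)
    gt1 = ok & (fesc > 1.0)
    fesc[gt1] = np.nan

    flags[missing] = FLAG_MISSING
    flags[low] = FLAG_LOW_FCVI
    flags[nonpos] = FLAG_NONPOS_FAPAR
    flags[gt1] = FLAG_FESC_GT_1
    valid = flags == FLAG_VALID
    return fesc, valid, flags


def sif_leaf(sif_canopy: np.ndarray, fesc: np.ndarray,
             valid_mask: np.ndarray) -> np.ndarray:
    """Hemispherical leaf-level SIF760: pi * sif_canopy / fesc on valid
    pixels, NaN elsewhere. Units mW m-2 nm-1 (the steradian removed by pi).
    """
    sif_canopy = np.asarray(sif_canopy, dtype=float)
    fesc = np.asarray(fesc, dtype=float)
    if np.any(valid_mask & ~(fesc > 0)):
        raise ValueError("mask contract violated: fesc <= 0 on a valid pixel")
    out = np.full(sif_canopy.shape, np.nan)
    np.divide(np.pi * sif_canopy, fesc, out=out, where=valid_mask)
    return out


def downscale_maps(reflectance: SpectralCube, sif_canopy: np.ndarray,
                   fapar_chl: np.ndarray,
                   fcvi_min: float = DEFAULT_FCVI_MIN) -> DownscaleMaps:
    """Full downscaling stage: FCVI, escape fraction, leaf SIF and mask."""
    f = fcvi(reflectance)
    fesc, valid, flags = escape_fraction(f, fapar_chl, fcvi_min=fcvi_min)
    # retrieval failures (NaN canopy SIF) invalidate the leaf product too
    bad_sif = valid & ~np.isfinite(np.asarray(sif_canopy, dtype=float))
    valid = valid & ~bad_sif
    flags = flags.copy()
    flags[bad_sif] = FLAG_MISSING
    return DownscaleMaps(fcvi=f, fesc=np.where(valid, fesc, np.nan),
                         sif_leaf=sif_leaf(sif_canopy, fesc, valid),
                         valid_mask=valid, flags=flags)
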