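"""Parametric O2-A band atmosphere.

A compact stand-in for a full radiative-transfer atmosphere that preserves
exactly the structure the SIF retrieval exploits: telluric oxygen absorption
near 760 nm whose depth scales with an effective surface-sensor distance d
through Beer-Lambert attenuation,

    T(lambda, d) = exp(-k_O2(lambda) * d),

with k_O2 a fixed synthetic absorption profile (a sum of Gaussians spanning
759-770 nm, optical depth ~2.3 at the band core for d = 1, i.e. ~90% band
depth). Downwelling transmittance uses a longer path (solar geometry) than
the upwelling sensor path; path radiance is a small smooth continuum; the
spherical-albedo coupling term is set to zero.

Distances are a dimensionless scale: d = 1 corresponds to the nominal
sensor altitude the scene was simulated at.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = ["O2AAtmosphere", "TabulatedAtmosphere", "default_atmosphere"]

# (center nm, sigma nm, relative strength) of the synthetic O2-A line groups
_O2_LINES = (
    (759.4, 0.25, 1.00),
    (760.5, 0.45, 0.95),
    (761.7, 0.55, 0.80),
    (763.8, 1.30, 0.45),
    (766.3, 1.80, 0.25),
    (768.8, 1.10, 0.12),
)


def _raw_profile(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    k = np.zeros_like(lam)
    for c, s, w in _O2_LINES:
        k += w * np.exp(-0.5 * ((lam - c) / s) ** 2)
    return k


# normalization so the band-core optical depth equals `depth` at d = 1
_PEAK = float(_raw_profile(np.arange(755.0, 775.0, 0.001)).max())


@dataclass
class O2AAtmosphere:
    """Analytic atmosphere: transmittances, path radiance, ground irradiance.

    Parameters
    ----------
    depth : float
        Upward-path optical depth at the O2-A band core for d = 1.
    solar_path_factor : float
        Ratio of downwelling to upwelling absorption path length.
    e0 : float
        Solar irradiance continuum at the surface near 760 nm for overhead
        sun, mW m-2 nm-1.
    e0_slope : float
        Relative irradiance slope per nm around 760 nm (gentle continuum tilt).
    path_radiance : float
        Path radiance amplitude, mW m-2 nm-1 sr-1.
    d_grid : ndarray
        Distance-scale grid offered to the retrieval's calibration step.
    """

    depth: float = 2.3
    solar_path_factor: float = 1.5
    e0: float = 1200.0
    e0_slope: float = -3.0e-4
    path_radiance: float = 0.2
    d_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.5, 2.0001, 0.05))

    def k_o2(self, lam: np.ndarray) -> np.ndarray:
        """Absorption profile, optical depth per unit distance scale."""
        return self.depth / _PEAK * _raw_profile(lam)

    def t_up(self, lam: np.ndarray, d: float) -> np.ndarray:
        """Surface-to-sensor transmittance at distance scale d."""
        if d < 0:
            raise ValueError("distance scale must be non-negative")
        return np.exp(-self.k_o2(lam) * d)

    def t_down(self, lam: np.ndarray, d: float) -> np.ndarray:
        """Sun-to-surface transmittance, longer path than the sensor leg."""
        return np.exp(-self.k_o2(lam) * self.solar_path_factor * d)

    def l_path(self, lam: np.ndarray, d: float) -> np.ndarray:
        """Smooth additive path radiance, mW m-2 nm-1 sr-1."""
        lam = np.asarray(lam, dtype=float)
        return self.path_radiance * (d / (1.0 + d)) * (lam / 760.0) ** -4

    def e_ground(self, lam: np.ndarray) -> np.ndarray:
        """Continuum solar irradiance at the surface for overhead sun,
        mW m-2 nm-1 (excluding the O2 absorption, which t_down carries)."""
        lam = np.asarray(lam, dtype=float)
        return self.e0 * (1.0 + self.e0_slope * (lam - 760.0))

    def to_table(self, lam: np.ndarray,
                 d_grid: np.ndarray | None = None) -> xr.Dataset:
        """Sample the analytic model onto a (wavelength x distance) table."""
        d_grid = self.d_grid if d_grid is None else np.asarray(d_grid, float)
        lam = np.asarray(lam, dtype=float)
        t_up = np.stack([self.t_up(lam, d) for d in d_grid])
        t_down = np.stack([self.t_down(lam, d) for d in d_grid])
        l_path = np.stack([self.l_path(lam, d) for d in d_grid])
        return xr.Dataset(
            {
                "t_up": (("d", "wavelength"), t_up),
                "t_down": (("d", "wavelength"), t_down),
                "l_path": (("d", "wavelength"), l_path),
                "e_ground": (("wavelength",), self.e_ground(lam)),
            },
            coords={"d": d_grid, "wavelength": lam},
            attrs={"spherical_albedo": 0.0},
        )


class TabulatedAtmosphere:
    """Atmosphere backed by a (wavelength x distance) table.

    Transmittances are interpolated log-linearly in d (exact for
    Beer-Lambert attenuation) and linearly in wavelength; path radiance
    linearly in both.
    """

    def __init__(self, ds: xr.Dataset):
        for name in ("t_up", "t_down", "l_path", "e_ground"):
            if name not in ds:
                raise ValueError(f"atmosphere table missing variable '{name}'")
        self._lam = np.asarray(ds["wavelength"].values, dtype=float)
        self.d_grid = np.asarray(ds["d"].values, dtype=float)
        with np.errstate(divide="ignore"):
            self._log_t_up = np.log(np.asarray(ds["t_up"].values, dtype=float))
            self._log_t_down = np.log(np.asarray(ds["t_down"].values, dtype=float))
        self._l_path = np.asarray(ds["l_path"].values, dtype=float)
        self._e_ground = np.asarray(ds["e_ground"].values, dtype=float)

    def _interp_d(self, arr: np.ndarray, d: float) -> np.ndarray:
        j = np.clip(np.searchsorted(self.d_grid, d) - 1, 0, len(self.d_grid) - 2)
        w = (d - self.d_grid[j]) / (self.d_grid[j + 1] - self.d_grid[j])
        return (1.0 - w) * arr[j] + w * arr[j + 1]

    def t_up(self, lam: np.ndarray, d: float) -> np.ndarray:
        return np.interp(lam, self._lam, np.exp(self._interp_d(self._log_t_up, d)))

    def t_down(self, lam: np.ndarray, d: float) -> np.ndarray:
        return np.interp(lam, self._lam, np.exp(self._interp_d(self._log_t_down, d)))

    def l_path(self, lam: np.ndarray, d: float) -> np.ndarray:
        return np.interp(lam, self._lam, self._interp_d(self._l_path, d))

    def e_ground(self, lam: np.ndarray) -> np.ndarray:
        return np.interp(lam, self._lam, self._e_ground)


def default_atmosphere() -> O2AAtmosphere:
    """The package-default parametric atmosphere."""
    return O2AAtmosphere()
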