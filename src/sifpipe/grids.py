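"""Scene raster geometry and the spectral-cube container.

Rasters are row-major, north-up grids with square pixels (default 1 m ground
sampling distance). Pixel centers sit at half-integer grid coordinates, so
pixel (row, col) has its center at x = (col + 0.5) * gsd,
y = (ny - row - 0.5) * gsd with the origin at the grid's south-west corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = ["GridSpec", "SpectralCube"]


@dataclass(frozen=True)
class GridSpec:
    """Raster geometry: shape, pixel size and origin of a north-up grid."""

    ny: int
    nx: int
    gsd: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate grids, each of shape (ny, nx)."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.nx) + 0.5) * self.gsd
        rows = y0 + (self.ny - np.arange(self.ny) - 0.5) * self.gsd
        return np.meshgrid(cols, rows)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)


@dataclass
class SpectralCube:
    """Wavelength-indexed raster stack (radiance or reflectance).

    Parameters
    ----------
    data : ndarray, shape (nband, ny, nx)
        Per-band rasters. Radiance in mW m-2 nm-1 sr-1, reflectance unitless.
    wavelength : ndarray, shape (nband,)
        Band-center wavelengths in nm, strictly increasing.
    units : str
        Physical units of ``data``.
    grid : GridSpec
        Raster geometry shared by all bands.
    time : float, optional
        Acquisition time, local solar hours.
    cos_sza : float, optional
        Cosine of the solar zenith angle at acquisition. View is nadir.
    attrs : dict
        Free-form metadata carried through serialization.
    """

    data: np.ndarray
    wavelength: np.ndarray
    units: str
    grid: GridSpec
    time: float | None = None
    cos_sza: float | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must have shape (nband, ny, nx)")
        if self.data.shape[0] != self.wavelength.size:
            raise ValueError(
                f"{self.data.shape[0]} bands but {self.wavelength.size} wavelengths"
            )
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("cube data shape does not match grid")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    # -- band selection ----------------------------------------------------

    def bands_in(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bands whose centers fall in the half-open window [lo, hi)."""
        return np.nonzero((self.wavelength >= lo) & (self.wavelength < hi))[0]

    def nearest_band(self, target: float, tol: float = 5.0) -> int:
        """Index of the band center closest to ``target`` nm, within ``tol`` nm."""
        i = int(np.argmin(np.abs(self.wavelength - target)))
        if abs(self.wavelength[i] - target) > tol:
            raise ValueError(
                f"no band center within {tol} nm of {target} nm "
                f"(closest: {self.wavelength[i]:.2f} nm)"
            )
        return i

    def subset(self, lo: float, hi: float) -> "SpectralCube":
        """Cube restricted to band centers in [lo, hi) (shares memory)."""
        idx = self.bands_in(lo, hi)
        if idx.size == 0:
            raise ValueError(f"no bands in window [{lo}, {hi}) nm")
        return SpectralCube(
            self.data[idx], self.wavelength[idx], self.units, self.grid,
            time=self.time, cos_sza=self.cos_sza, attrs=dict(self.attrs),
        )

    @property
    def npix(self) -> int:
        return self.grid.ny * self.grid.nx

    def flat(self) -> np.ndarray:
        """View of the data as (nband, npix)."""
        return self.data.reshape(self.data.shape[0], -1)

    # -- xarray bridge -----------------------------------------------------

    def to_xarray(self) -> xr.DataArray:
        attrs = {
            "units": self.units,
            "gsd": self.grid.gsd,
            "origin_x": self.grid.origin[0],
            "origin_y": self.grid.origin[1],
        }
        if self.time is not None:
            attrs["time"] = self.time
        if self.cos_sza is not None:
            attrs["cos_sza"] = self.cos_sza
        attrs.update(self.attrs)
        return xr.DataArray(
            self.data,
            dims=("wavelength", "y", "x"),
            coords={"wavelength": self.wavelength},
            attrs=attrs,
            name="cube",
        )

    @classmethod
    def from_xarray(cls, da: xr.DataArray) -> "SpectralCube":
        if "wavelength" not in da.coords:
            raise ValueError("DataArray has no 'wavelength' coordinate")
        attrs = dict(da.attrs)
        grid = GridSpec(
            ny=da.sizes["y"], nx=da.sizes["x"],
            gsd=float(attrs.pop("gsd", 1.0)),
            origin=(float(attrs.pop("origin_x", 0.0)),
                    float(attrs.pop("origin_y", 0.0))),
        )
        time = attrs.pop("time", None)
        cos_sza = attrs.pop("cos_sza", None)
        units = attrs.pop("units", "")
        return cls(
            np.asarray(da.values, dtype=float),
            np.asarray(da["wavelength"].values, dtype=float),
            units, grid,
            time=None if time is None else float(time),
            cos_sza=None if cos_sza is None else float(cos_sza),
            attrs=attrs,
        )
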