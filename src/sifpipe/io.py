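"""Readers and writers for the pipeline's interchange formats.

Spectral cubes: NetCDF (wavelength coordinate mandatory) or ENVI BSQ (text
header + band-sequential float32 binary). Single-band grids: plain TIFF via
tifffile with metadata in the image description tag (JSON). Field layouts:
GeoJSON polygons with crop labels. PAR series: CSV. Missing data are IEEE
NaN in float rasters.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
from shapely.geometry import mapping, shape

from .grids import GridSpec, SpectralCube
from .scene import Field
from .solar import IrradianceRecord

__all__ = [
    "read_cube", "write_cube", "write_grid", "read_grid",
    "write_par_csv", "read_par_csv", "write_layout", "read_layout",
    "write_atmosphere", "read_atmosphere",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# spectral cubes


def write_cube(cube: SpectralCube, path: str | Path) -> Path:
    """Write a cube as NetCDF (*.nc) or ENVI BSQ (any other suffix pairs a
    text .hdr with a raw binary file). Non-scalar attributes are dropped."""
    path = Path(path)
    if path.suffix == ".nc":
        da = cube.to_xarray()
        da.attrs = {k: v for k, v in da.attrs.items()
                    if np.isscalar(v) or isinstance(v, str)}
        da.astype(np.float32).to_dataset(name="cube").to_netcdf(
            path, engine="scipy")
    else:
        _write_envi(cube, path)
    return path


def read_cube(path: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_cube` (NetCDF or ENVI)."""
    path = Path(path)
    if not path.exists() and not path.with_suffix(".hdr").exists():
        raise FileNotFoundError(f"no such cube: {path}")
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            if "wavelength" not in ds.coords:
                raise ValueError(f"{path}: missing wavelength coordinate")
            return SpectralCube.from_xarray(ds["cube"].load())
    return _read_envi(path)


def _write_envi(cube: SpectralCube, path: Path) -> None:
    data = cube.data.astype(np.float32)
    data.tofile(path)
    meta = {
        "samples": cube.grid.nx, "lines": cube.grid.ny,
        "bands": cube.wavelength.size,
        "data type": 4, "interleave": "bsq", "byte order": 0,
        "wavelength units": "Nanometers",
        "units": cube.units, "gsd": cube.grid.gsd,
        "origin x": cube.grid.origin[0], "origin y": cube.grid.origin[1],
    }
    if cube.time is not None:
        meta["acquisition time"] = cube.time
    if cube.cos_sza is not None:
        meta["cos sza"] = cube.cos_sza
    lines = ["ENVI"]
    lines += [f"{k} = {v}" for k, v in meta.items()]
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelength)
    lines.append("wavelength = { %s }" % wl)
    path.with_suffix(".hdr").write_text("\n".join(lines) + "\n")


def _parse_envi_header(text: str) -> dict:
    import re

    out = {}
    for m in re.finditer(r"([\w ]+?)\s*=\s*\{([^}]*)\}", text, re.S):
        out[m.group(1).strip()] = m.group(2)
    plain = re.sub(r"[\w ]+?\s*=\s*\{[^}]*\}", "", text, flags=re.S)
    for ln in plain.splitlines():
        if "=" in ln:
            k, v = ln.split("=", 1)
            out.setdefault(k.strip(), v.strip())
    return out


def _read_envi(path: Path) -> SpectralCube:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise ValueError(f"{path}: missing ENVI header {hdr_path.name}")
    hdr = _parse_envi_header(hdr_path.read_text())
    if "wavelength" not in hdr:
        raise ValueError(f"{path}: ENVI header has no wavelength block")
    wl = np.array([float(x) for x in hdr["wavelength"].split(",")])
    nx, ny, nb = int(hdr["samples"]), int(hdr["lines"]), int(hdr["bands"])
    data = np.fromfile(path, dtype=np.float32).reshape(nb, ny, nx)
    grid = GridSpec(ny=ny, nx=nx, gsd=float(hdr.get("gsd", 1.0)),
                    origin=(float(hdr.get("origin x", 0.0)),
                            float(hdr.get("origin y", 0.0))))
    t = hdr.get("acquisition time")
    c = hdr.get("cos sza")
    return SpectralCube(
        data.astype(float), wl, units=hdr.get("units", ""), grid=grid,
        time=None if t is None else float(t),
        cos_sza=None if c is None else float(c))


# ---------------------------------------------------------------------------
# single-band grids (plain TIFF + JSON metadata in the description tag)


def write_grid(arr: np.ndarray, path: str | Path, grid: GridSpec | None = None,
               **meta) -> Path:
    path = Path(path)
    if grid is not None:
        meta.update(gsd=grid.gsd, origin=list(grid.origin))
    a = np.asarray(arr)
    a = a.astype(np.float32) if a.dtype.kind == "f" else a
    tifffile.imwrite(path, a, description=json.dumps(meta))
    return path


def read_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    return arr, meta


# ---------------------------------------------------------------------------
# PAR series, layouts, atmosphere tables


def write_par_csv(records: Sequence[IrradianceRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([{"time": r.time, "ppfd": r.ppfd, "par_w": r.par_w,
                   "par_mw": r.par_mw} for r in records]).to_csv(
        path, index=False)
    return path


def read_par_csv(path: str | Path) -> list[IrradianceRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing PAR series: {path}")
    df = pd.read_csv(path)
    return [IrradianceRecord(time=r.time, ppfd=r.ppfd, par_w=r.par_w,
                             par_mw=r.par_mw) for r in df.itertuples()]


def write_layout(fields: Sequence[Field], path: str | Path) -> Path:
    fc = {"type": "FeatureCollection", "features": [
        {"type": "Feature",
         "properties": {"field_id": f.field_id, "crop": f.crop},
         "geometry": mapping(f.polygon)} for f in fields]}
    path = Path(path)
    path.write_text(json.dumps(fc, indent=1))
    return path


def read_layout(path: str | Path) -> list[Field]:
    fc = json.loads(Path(path).read_text())
    return [Field(field_id=ft["properties"]["field_id"],
                  crop=ft["properties"]["crop"],
                  polygon=shape(ft["geometry"]))
            for ft in fc["features"]]


def write_atmosphere(ds: xr.Dataset, path: str | Path) -> Path:
    path = Path(path)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_atmosphere(path: str | Path):
    from .atmosphere import TabulatedAtmosphere
    with xr.open_dataset(path, engine="scipy") as ds:
        return TabulatedAtmosphere(ds.load())
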