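"""Per-field diurnal statistics, canopy-vs-leaf correlation, hysteresis.

Zonal aggregation uses pixel-center containment (a pixel belongs to a field
when its center lies strictly inside the polygon; centers on an edge are
excluded). Percentiles interpolate linearly between order statistics.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .grids import GridSpec
from .scene import Field

__all__ = ["field_masks", "field_stats", "canopy_leaf_correlation",
           "crop_mean_correlation", "hysteresis"]

log = logging.getLogger(__name__)

_PCTS = (0, 25, 50, 75, 100)


def field_masks(fields: Sequence[Field], grid: GridSpec) -> dict[str, np.ndarray]:
    """Boolean pixel-membership mask per field (pixel-center containment)."""
    X, Y = grid.pixel_centers()
    out = {}
    for f in fields:
        out[f.field_id] = shapely.contains_xy(f.polygon, X, Y)
    return out


def field_stats(grid_map: np.ndarray, valid_mask: np.ndarray,
                fields: Sequence[Field], grid: GridSpec,
                variable: str, time: float) -> pd.DataFrame:
    """Box-plot statistics (0/25/50/75/100th percentiles, mean, SD) of one
    variable over the valid pixels of each field at one overpass.

    Fields with zero valid pixels are omitted with a logged warning.
    """
    masks = field_masks(fields, grid)
    rows = []
    for f in fields:
        sel = masks[f.field_id] & valid_mask & np.isfinite(grid_map)
        vals = np.asarray(grid_map, dtype=float)[sel]
        if vals.size == 0:
            log.warning("field %s: no valid pixels for %s at t=%.2f h — "
                        "summary omitted", f.field_id, variable, time)
            continue
        p = np.percentile(vals, _PCTS)   # linear interpolation
        rows.append({
            "field_id": f.field_id, "crop": f.crop, "time": time,
            "variable": variable,
            "p0": p[0], "p25": p[1], "p50": p[2], "p75": p[3], "p100": p[4],
            "mean": vals.mean(), "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
            "n": vals.size,
        })
    return pd.DataFrame(rows)


def canopy_leaf_correlation(sif_canopy: np.ndarray, sif_leaf: np.ndarray,
                            valid_mask: np.ndarray, fields: Sequence[Field],
                            grid: GridSpec, time: float) -> pd.DataFrame:
    """Pearson r between canopy and leaf SIF760 over corresponding valid
    pixels of each field. Zero variance in either map gives r = NaN with a
    ``degenerate`` flag; fields need at least 3 valid pixels.
    """
    masks = field_masks(fields, grid)
    both = (valid_mask & np.isfinite(np.asarray(sif_canopy, dtype=float))
            & np.isfinite(np.asarray(sif_leaf, dtype=float)))
    rows = []
    for f in fields:
        sel = masks[f.field_id] & both
        x = np.asarray(sif_canopy, dtype=float)[sel]
        y = np.asarray(sif_leaf, dtype=float)[sel]
        if x.size < 3:
            log.warning("field %s: fewer than 3 valid pixels at t=%.2f h — "
                        "correlation omitted", f.field_id, time)
            continue
        degenerate = x.std() == 0 or y.std() == 0
        r = np.nan if degenerate else float(stats.pearsonr(x, y).statistic)
        rows.append({"field_id": f.field_id, "crop": f.crop, "time": time,
                     "r": r, "n": x.size, "degenerate": degenerate})
    return pd.DataFrame(rows)


def crop_mean_correlation(corr: pd.DataFrame) -> pd.DataFrame:
    """Crop-level aggregation: unweighted mean +/- SD over field-level r
    values per crop and overpass."""
    ok = corr[~corr["degenerate"] & corr["r"].notna()]
    out = (ok.groupby(["crop", "time"])["r"]
           .agg(r_mean="mean", r_sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                n_fields="size")
           .reset_index())
    return out


def hysteresis(records: Sequence[tuple[float, np.ndarray, float | np.ndarray]],
               fields: Sequence[Field], grid: GridSpec,
               crop: str) -> pd.DataFrame:
    """Diurnal efficiency-vs-light series for one crop.

    ``records`` is a chronologically ordered sequence of
    (time, efficiency map, driver) where the driver is either a scene
    scalar (PAR) or a map (APAR_chl). Returns one row per overpass with the
    driver mean and efficiency mean +/- SD over the crop's valid pixels.
    Raises for fewer than 2 overpasses or unsorted times.
    """
    if len(records) < 2:
        raise ValueError("hysteresis needs at least 2 overpasses")
    times = [t for t, _, _ in records]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("overpass times must be strictly increasing")
    crop_fields = [f for f in fields if f.crop == crop]
    if not crop_fields:
        raise ValueError(f"no fields with crop {crop!r}")
    masks = field_masks(crop_fields, grid)
    crop_mask = np.any(list(masks.values()), axis=0)

    rows = []
    for t, eps_map, driver in records:
        eps_map = np.asarray(eps_map, dtype=float)
        sel = crop_mask & np.isfinite(eps_map)
        if np.isscalar(driver):
            drv = float(driver)
        else:
            driver = np.asarray(driver, dtype=float)
            dsel = sel & np.isfinite(driver)
            drv = float(driver[dsel].mean()) if dsel.any() else np.nan
        vals = eps_map[sel]
        rows.append({
            "crop": crop, "time": t, "driver_mean": drv,
            "eps_mean": vals.mean() if vals.size else np.nan,
            "eps_sd": (vals.std(ddof=1) if vals.size > 1 else 0.0),
            "n": vals.size,
        })
    return pd.DataFrame(rows)
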