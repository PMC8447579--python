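"""End-to-end pipeline: simulate -> retrieve -> downscale -> analyze.

All randomness flows from the single config seed through per-stage derived
substreams, so individual stages are independently reproducible; a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, biophysics, diurnal, io, normalize, solar
from .atmosphere import default_atmosphere
from .config import RunConfig
from .downscale import DownscaleMaps, downscale_maps
from .grids import GridSpec, SpectralCube
from .instrument import SifSpectrumModel
from .retrieval import RetrievalConfig, SFMResults, SpectralFitModel
from .scene import (DEFAULT_ARCHETYPES, SceneTruth, default_layout,
                    generate_truth, to_at_sensor, truth_to_reflectance)

__all__ = ["OverpassProducts", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)

_STAT_VARIABLES = ("sif_canopy", "sif_leaf", "fcvi", "fapar_chl", "fesc",
                   "eps_fcvi")


@dataclass
class OverpassProducts:
    """Everything derived for one overpass."""

    time: float
    truth: SceneTruth
    reflectance: SpectralCube
    radiance: SpectralCube
    retrieval: SFMResults
    indices: dict[str, np.ndarray]
    maps: DownscaleMaps
    eps_par: np.ndarray
    eps_aparchl: np.ndarray
    eps_fcvi: np.ndarray


@dataclass
class PipelineResult:
    config: RunConfig
    layout: list
    overpasses: list[OverpassProducts]
    stats: pd.DataFrame
    correlations: pd.DataFrame
    crop_correlations: pd.DataFrame
    hysteresis: pd.DataFrame
    manifest: dict


def _stage_seeds(seed: int, n_overpass: int) -> dict:
    """Derive independent per-stage seeds (< 2**31) from the config seed."""
    ss = np.random.SeedSequence(seed)
    truth_s, noise_s, sub_s = ss.spawn(3)
    return {
        "truth": int(truth_s.generate_state(1)[0] % (2 ** 31)),
        "noise": [int(s) for s in noise_s.generate_state(n_overpass) % (2 ** 31)],
        "subsample": int(sub_s.generate_state(1)[0] % (2 ** 31)),
    }


def run_pipeline(config: RunConfig | None = None,
                 write: bool | None = None) -> PipelineResult:
    """Run the full pipeline on a simulated diurnal scene.

    Any stage failure aborts with the stage name in the exception message.
    When ``write`` is true (default: config.write_cubes) all artifacts are
    written under ``config.output_dir``.
    """
    cfg = config or RunConfig()
    write = cfg.write_cubes if write is None else write
    out_dir = Path(cfg.output_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)

    seeds = _stage_seeds(cfg.seed, len(cfg.overpass_times))
    grid = GridSpec(cfg.ny, cfg.nx)
    layout = default_layout(grid)
    atm = default_atmosphere()
    sif_shape = SifSpectrumModel(peak_wavelength=cfg.sif_peak,
                                 sigma=cfg.sif_sigma)
    ret_cfg = RetrievalConfig(
        fit_window=cfg.fit_window, poly_degree=cfg.poly_degree,
        sif_shape=sif_shape, ndvi_reference_max=cfg.ndvi_ref_max,
        subsample_seed=seeds["subsample"])

    # -- simulate ----------------------------------------------------------
    try:
        truths = generate_truth(
            layout, times=cfg.overpass_times, seed=seeds["truth"], grid=grid,
            par_max=cfg.par_max)
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    par_records = solar.diurnal_par(
        solar.geometry_series(cfg.overpass_times), cfg.par_max)
    if write:
        io.write_par_csv(par_records, out_dir / "par.csv")
        io.write_layout(layout, out_dir / "layout.geojson")

    overpasses = []
    stats_frames, corr_frames = [], []
    for i, truth in enumerate(truths):
        tag = f"t{truth.time:05.2f}".replace(".", "")
        # forward model
        try:
            refl = truth_to_reflectance(truth, mode=cfg.reflectance_mode,
                                        alpha=cfg.alpha, k=cfg.k)
            rad = to_at_sensor(refl, truth, atm, sif_shape=sif_shape,
                               snr=cfg.snr, seed=seeds["noise"][i],
                               d=cfg.true_distance)
        except Exception as e:
            raise RuntimeError(
                f"stage 'simulate' failed at t={truth.time:.2f}: {e}") from e

        # SFM retrieval
        try:
            res = SpectralFitModel(rad, atm, config=ret_cfg,
                                   reflectance=refl).fit()
        except Exception as e:
            raise RuntimeError(
                f"stage 'retrieve' failed at t={truth.time:.2f}: {e}") from e

        # biophysics + downscaling + normalization
        try:
            idx = biophysics.indices_from_reflectance(refl, alpha=cfg.alpha,
                                                      k=cfg.k)
            maps = downscale_maps(refl, res.sif760, idx["fapar_chl"],
                                  fcvi_min=cfg.fcvi_min)
            e_par = normalize.eps_par(maps.sif_leaf, truth.par_mw)
            e_apar = normalize.eps_aparchl(maps.sif_leaf, idx["fapar_chl"],
                                           truth.par_mw)
            e_fcvi = normalize.eps_fcvi(res.sif760, maps.fcvi, truth.par_mw,
                                        valid_mask=maps.valid_mask)
        except Exception as e:
            raise RuntimeError(
                f"stage 'downscale' failed at t={truth.time:.2f}: {e}") from e

        op = OverpassProducts(time=truth.time, truth=truth, reflectance=refl,
                              radiance=rad, retrieval=res, indices=idx,
                              maps=maps, eps_par=e_par, eps_aparchl=e_apar,
                              eps_fcvi=e_fcvi)
        overpasses.append(op)

        # per-field statistics
        try:
            grids = {"sif_canopy": res.sif760, "sif_leaf": maps.sif_leaf,
                     "fcvi": maps.fcvi, "fapar_chl": idx["fapar_chl"],
                     "fesc": maps.fesc, "eps_fcvi": e_fcvi}
            for var in _STAT_VARIABLES:
                stats_frames.append(diurnal.field_stats(
                    grids[var], maps.valid_mask, layout, grid, var,
                    truth.time))
            corr_frames.append(diurnal.canopy_leaf_correlation(
                res.sif760, maps.sif_leaf, maps.valid_mask, layout, grid,
                truth.time))
        except Exception as e:
            raise RuntimeError(
                f"stage 'diurnal' failed at t={truth.time:.2f}: {e}") from e

        if write:
            io.write_cube(refl, out_dir / f"reflectance_{tag}.nc")
            io.write_cube(rad, out_dir / f"radiance_{tag}.nc")
            for name, arr in (("sif_canopy", res.sif760),
                              ("sif_leaf", maps.sif_leaf),
                              ("fesc", maps.fesc), ("fcvi", maps.fcvi),
                              ("fapar_chl", idx["fapar_chl"]),
                              ("eps_fcvi", e_fcvi),
                              ("valid_mask", maps.valid_mask.astype(np.uint8)),
                              ("flags", maps.flags)):
                io.write_grid(arr, out_dir / f"{name}_{tag}.tif", grid=grid,
                              time=truth.time)
            (out_dir / f"calibration_{tag}.json").write_text(json.dumps(
                {"d_star": res.d_star,
                 "mean_ref_sif": res.calibration["mean_ref_sif"],
                 "n_ref": res.calibration["n_ref"]}, indent=1))

    stats = pd.concat(stats_frames, ignore_index=True)
    corrs = pd.concat(corr_frames, ignore_index=True)
    crop_corrs = diurnal.crop_mean_correlation(corrs)

    # hysteresis per crop: eps_par vs PAR and eps_fcvi vs mean APAR_chl.
    # A diurnal loop needs at least two overpasses; single-overpass runs
    # get an empty table rather than an error.
    hyst_frames = []
    if len(overpasses) < 2:
        hyst_frames.append(pd.DataFrame(
            columns=["crop", "driver", "time", "driver_mean", "eps_mean",
                     "eps_sd", "n"]))
    for arch in (DEFAULT_ARCHETYPES if len(overpasses) >= 2 else ()):
        rec_par = [(op.time, op.eps_par, op.truth.par_mw) for op in overpasses]
        rec_fcvi = [(op.time, op.eps_fcvi,
                     biophysics.apar_chl(op.indices["fapar_chl"],
                                         op.truth.par_mw))
                    for op in overpasses]
        for driver, recs in (("par", rec_par), ("apar_chl", rec_fcvi)):
            h = diurnal.hysteresis(recs, layout, grid, arch.name)
            h.insert(1, "driver", driver)
            hyst_frames.append(h)
    hyst = pd.concat(hyst_frames, ignore_index=True)

    manifest = {
        "software": "sifpipe", "version": __version__,
        "seed": cfg.seed, "config_hash": cfg.content_hash(),
        "config": cfg.to_dict(),
        "n_overpasses": len(overpasses),
    }
    if write:
        stats.to_csv(out_dir / "field_stats.csv", index=False)
        corrs.to_csv(out_dir / "correlations.csv", index=False)
        crop_corrs.to_csv(out_dir / "crop_correlations.csv", index=False)
        hyst.to_csv(out_dir / "hysteresis.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PipelineResult(config=cfg, layout=layout, overpasses=overpasses,
                          stats=stats, correlations=corrs,
                          crop_correlations=crop_corrs, hysteresis=hyst,
                          manifest=manifest)
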