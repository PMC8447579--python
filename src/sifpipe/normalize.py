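"""SIF emission-efficiency variants.

Leaf-level SIF is driven primarily by incoming light, so comparing
physiology across the day requires normalizing it away. Three efficiency
variants (all nm-1, since they divide mW m-2 nm-1 by mW m-2):

* eps_par      = SIF760_leaf / PAR            — per unit incoming PAR;
* eps_aparchl  = SIF760_leaf / (fAPAR_chl * PAR) — per unit PAR absorbed by
  chlorophyll, the quantity most directly tied to photosystem regulation;
* eps_fcvi     = pi * SIF760_canopy / (FCVI * PAR) — algebraically equal to
  eps_aparchl when the escape fraction comes from FCVI / fAPAR_chl, but
  computable without fAPAR_chl or the leaf product at all (the fAPAR_chl
  cancellation).

PAR is a scene scalar per overpass (single weather station).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["eps_par", "eps_aparchl", "eps_fcvi"]


def eps_par(sif_leaf: np.ndarray, par_mw: float) -> np.ndarray:
    """Apparent emission efficiency per unit incoming PAR (nm-1)."""
    if par_mw <= 0:
        raise ValueError("PAR must be positive")
    return np.asarray(sif_leaf, dtype=float) / par_mw


def eps_aparchl(sif_leaf: np.ndarray, fapar_chl: np.ndarray,
                par_mw: float) -> np.ndarray:
    """Emission efficiency per unit PAR absorbed by chlorophyll (nm-1).

    Raises if fAPAR_chl is zero on a pixel with a finite leaf-SIF value
    (the caller's validity mask should have excluded it).
    """
    if par_mw <= 0:
        raise ValueError("PAR must be positive")
    sif_leaf = np.asarray(sif_leaf, dtype=float)
    fapar_chl = np.asarray(fapar_chl, dtype=float)
    if np.any(np.isfinite(sif_leaf) & (fapar_chl <= 0)):
        raise ValueError("fAPAR_chl <= 0 on a pixel with finite leaf SIF")
    out = np.full(sif_leaf.shape, np.nan)
    np.divide(sif_leaf, fapar_chl * par_mw, out=out,
              where=np.isfinite(sif_leaf))
    return out


def eps_fcvi(sif_canopy: np.ndarray, fcvi: np.ndarray,
             par_mw: float, valid_mask: np.ndarray | None = None,
             ) -> np.ndarray:
    """Emission efficiency from canopy SIF and FCVI alone (nm-1).

    pi * SIF760_canopy / (FCVI * PAR): fAPAR_chl cancels, so no leaf-level
    product or fAPAR map is needed. Raises on non-positive FCVI inside the
    validity mask.
    """
    if par_mw <= 0:
        raise ValueError("PAR must be positive")
    sif_canopy = np.asarray(sif_canopy, dtype=float)
    fcvi = np.asarray(fcvi, dtype=float)
    if valid_mask is None:
        valid_mask = np.isfinite(sif_canopy) & np.isfinite(fcvi)
    if np.any(valid_mask & ~(fcvi > 0)):
        raise ValueError("FCVI <= 0 on a valid pixel")
    out = np.full(sif_canopy.shape, np.nan)
    np.divide(math.pi * sif_canopy, fcvi * par_mw, out=out, where=valid_mask)
    return out
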