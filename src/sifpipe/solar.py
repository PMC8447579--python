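"""Solar geometry and the clear-sky diurnal PAR course.

The simulated campaign day follows a mid-latitude site at the end of June:
six airborne overpasses at 10:10, 11:15, 12:30, 14:40, 15:50 and 17:15
local time, three before and three after local solar noon at 13:30.
Incoming PAR follows the clear-sky cosine of the solar zenith angle, scaled
so that overhead sun would deliver ``par_max`` W m-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .biophysics import PPFD_TO_W

__all__ = [
    "SolarGeometry", "IrradianceRecord", "solar_geometry", "geometry_series",
    "diurnal_par", "DEFAULT_OVERPASS_TIMES", "SOLAR_NOON", "DEFAULT_LATITUDE",
    "DEFAULT_DOY",
]

#: The six overpass times, local solar hours (10:10 ... 17:15).
DEFAULT_OVERPASS_TIMES = (
    10 + 10 / 60, 11 + 15 / 60, 12 + 30 / 60,
    14 + 40 / 60, 15 + 50 / 60, 17 + 15 / 60,
)
#: Local solar noon of the campaign day, hours.
SOLAR_NOON = 13.5
#: Site latitude (deg N) and day of year (end of June).
DEFAULT_LATITUDE = 50.62
DEFAULT_DOY = 180


@dataclass(frozen=True)
class SolarGeometry:
    """Sun position at one time point."""

    time: float          # local solar hours
    sza: float           # solar zenith angle, deg
    saa: float           # solar azimuth, deg (0 = north, clockwise)
    doy: int
    latitude: float

    @property
    def cos_sza(self) -> float:
        return max(math.cos(math.radians(self.sza)), 0.0)


@dataclass(frozen=True)
class IrradianceRecord:
    """Incoming PAR at one time in all three unit representations.

    Invariants: par_w = 0.219 * ppfd and par_mw = 1000 * par_w exactly.
    """

    time: float
    ppfd: float          # umol m-2 s-1
    par_w: float         # W m-2
    par_mw: float        # mW m-2

    def __post_init__(self) -> None:
        if self.ppfd < 0:
            raise ValueError("PPFD must be non-negative")


def solar_geometry(time: float, doy: int = DEFAULT_DOY,
                   latitude: float = DEFAULT_LATITUDE,
                   solar_noon: float = SOLAR_NOON) -> SolarGeometry:
    """Sun position from a standard declination + hour-angle formula."""
    decl = math.radians(23.45) * math.sin(2 * math.pi * (284 + doy) / 365)
    hour_angle = math.radians(15.0 * (time - solar_noon))
    lat = math.radians(latitude)
    cos_z = (math.sin(lat) * math.sin(decl)
             + math.cos(lat) * math.cos(decl) * math.cos(hour_angle))
    cos_z = min(max(cos_z, -1.0), 1.0)
    sza = math.degrees(math.acos(cos_z))
    # azimuth from the hour angle; adequate for a diurnal forcing course
    saa = (180.0 + math.degrees(hour_angle)) % 360.0
    return SolarGeometry(time=time, sza=sza, saa=saa, doy=doy,
                         latitude=latitude)


def geometry_series(times: Sequence[float], doy: int = DEFAULT_DOY,
                    latitude: float = DEFAULT_LATITUDE,
                    solar_noon: float = SOLAR_NOON) -> list[SolarGeometry]:
    return [solar_geometry(t, doy=doy, latitude=latitude,
                           solar_noon=solar_noon) for t in times]


def diurnal_par(geometry: Sequence[SolarGeometry],
                par_max: float = 438.0) -> list[IrradianceRecord]:
    """Clear-sky PAR records for a series of sun positions.

    ``par_max`` is the broadband PAR (W m-2) that overhead sun (sza = 0)
    would deliver; PPFD scales with the cosine of the solar zenith angle:

        ppfd(t) = (par_max / 0.219) * max(cos sza(t), 0)

    The default of 438 W m-2 corresponds to an overhead-sun PPFD of
    2000 umol m-2 s-1, a typical clear-sky midsummer peak.
    """
    if len(geometry) == 0:
        raise ValueError("empty solar geometry series")
    if par_max <= 0:
        raise ValueError("par_max must be positive")
    records = []
    for g in geometry:
        ppfd = par_max / PPFD_TO_W * g.cos_sza
        par_w = PPFD_TO_W * ppfd
        records.append(IrradianceRecord(
            time=g.time, ppfd=ppfd, par_w=par_w, par_mw=1000.0 * par_w))
    return records


def par_course(times: np.ndarray, par_max: float = 438.0,
               doy: int = DEFAULT_DOY, latitude: float = DEFAULT_LATITUDE,
               solar_noon: float = SOLAR_NOON) -> np.ndarray:
    """PPFD (umol m-2 s-1) sampled on an arbitrary fine time grid."""
    recs = diurnal_par(geometry_series(times, doy=doy, latitude=latitude,
                                       solar_noon=solar_noon), par_max)
    return np.array([r.ppfd for r in recs])
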