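"""Imaging-spectrometer spectral model shared by the simulator and retrieval.

The fluorescence imager records 670-780 nm with a Gaussian spectral response
(default FWHM 0.28 nm). Both the forward simulation and the retrieval's
design matrix convolve high-resolution spectra with the same band response,
represented as a sparse (nband x nfine) matrix whose rows integrate to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = ["SifSpectrumModel", "SensorModel", "DEFAULT_FWHM",
           "DEFAULT_BAND_SPACING", "FINE_STEP"]

#: Sensor spectral resolution (nm); band sampling interval (nm, configurable —
#: the instrument's interval is not part of its public characterization).
DEFAULT_FWHM = 0.28
DEFAULT_BAND_SPACING = 0.11
#: High-resolution grid step used for forward modeling (nm).
FINE_STEP = 0.05

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SifSpectrumModel:
    """Single-Gaussian far-red SIF emission shape.

    Peaked at 740 nm with sigma 25 nm; strictly positive on 670-780 nm for
    positive amplitude. SIF760 is defined as the value at exactly 760 nm.
    """

    peak_wavelength: float = 740.0
    sigma: float = 25.0
    amplitude: float = 1.0

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        return self.amplitude * np.exp(
            -0.5 * ((lam - self.peak_wavelength) / self.sigma) ** 2)

    def shape_at(self, lam: np.ndarray, ref: float = 760.0) -> np.ndarray:
        """The shape normalized to 1 at the reference wavelength, so a free
        amplitude multiplying it is directly SIF at ``ref``."""
        ref_val = float(self.__call__(np.array([ref]))[0])
        if ref_val <= 0:
            raise ValueError(f"SIF shape non-positive at {ref} nm")
        return self.__call__(lam) / ref_val


@dataclass
class SensorModel:
    """Band centers plus the Gaussian response convolution operator."""

    band_centers: np.ndarray
    fwhm: float = DEFAULT_FWHM
    fine_step: float = FINE_STEP
    fine_pad: float = 2.0
    _fine: np.ndarray = field(init=False, repr=False)
    _response: sparse.csr_matrix = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        lo = self.band_centers[0] - self.fine_pad
        hi = self.band_centers[-1] + self.fine_pad
        n = int(round((hi - lo) / self.fine_step)) + 1
        self._fine = lo + self.fine_step * np.arange(n)
        self._response = self._build_response()

    @classmethod
    def regular(cls, lo: float = 670.0, hi: float = 780.0,
                spacing: float = DEFAULT_BAND_SPACING,
                fwhm: float = DEFAULT_FWHM) -> "SensorModel":
        n = int(np.floor((hi - lo) / spacing + 1e-9)) + 1
        return cls(band_centers=lo + spacing * np.arange(n), fwhm=fwhm)

    @property
    def fine_grid(self) -> np.ndarray:
        return self._fine

    def _build_response(self) -> sparse.csr_matrix:
        sigma = self.fwhm * _FWHM_TO_SIGMA
        half = max(int(np.ceil(4.0 * sigma / self.fine_step)), 1)
        rows, cols, vals = [], [], []
        nfine = self._fine.size
        centers_idx = np.round(
            (self.band_centers - self._fine[0]) / self.fine_step).astype(int)
        offsets = np.arange(-half, half + 1)
        for b, c in enumerate(centers_idx):
            j = c + offsets
            ok = (j >= 0) & (j < nfine)
            j = j[ok]
            w = np.exp(-0.5 * ((self._fine[j] - self.band_centers[b]) / sigma) ** 2)
            w /= w.sum()
            rows.append(np.full(j.size, b))
            cols.append(j)
            vals.append(w)
        return sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.band_centers.size, nfine))

    def convolve(self, spectra_fine: np.ndarray) -> np.ndarray:
        """Convolve (nfine, ...) high-resolution spectra to sensor bands."""
        flat = spectra_fine.reshape(spectra_fine.shape[0], -1)
        out = self._response @ flat
        return out.reshape((self.band_centers.size,) + spectra_fine.shape[1:])
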