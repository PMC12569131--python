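"""Core in-memory containers for reflectance spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Spectrum", "PolarizedSpectra"]


def _as_grid(wavelengths_nm) -> np.ndarray:
    lam = np.asarray(wavelengths_nm, dtype=float)
    if lam.ndim != 1 or lam.size < 2:
        raise ValueError("wavelength grid must be 1-d with at least 2 points")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return lam


@dataclass
class Spectrum:
    """A reflectance spectrum on a monotone wavelength grid.

    ``reflectance`` is dimensionless (fraction of incident light); values
    slightly above 1 occur with imperfect white calibration and are
    tolerated but reported via :attr:`overshoot`.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    area_mm2: float | None = None
    polarization: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = _as_grid(self.wavelengths_nm)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != self.wavelengths_nm.shape:
            raise ValueError("reflectance and wavelength arrays must match")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    @property
    def overshoot(self) -> bool:
        """True when calibration pushed any band above unit reflectance."""
        return bool(np.any(self.reflectance > 1.0))


# The wing experiments use the same container; keep the domain name.
WingSpectrum = Spectrum


@dataclass
class PolarizedSpectra:
    """Co- and de-polarized reflectance of one specimen on a shared grid."""

    wavelengths_nm: np.ndarray
    r_copol: np.ndarray
    r_depol: np.ndarray
    area_mm2: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = _as_grid(self.wavelengths_nm)
        self.r_copol = np.asarray(self.r_copol, dtype=float)
        self.r_depol = np.asarray(self.r_depol, dtype=float)
        for name, arr in (("r_copol", self.r_copol), ("r_depol", self.r_depol)):
            if arr.shape != self.wavelengths_nm.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            # small negative excursions are calibration noise; reject worse
            if np.any(arr < -0.05):
                raise ValueError(f"{name} has values below -0.05")

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    def copol_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.r_copol, self.area_mm2, "co")

    def depol_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.r_depol, self.area_mm2, "de")
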