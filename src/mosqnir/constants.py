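"""Wavelength-dependent optical constants for mosquito tissue models.

Three ingredients feed every forward model in this package:

* the refractive index of wing chitin, a Cauchy-type dispersion
  ``n(lambda) = n_inf + C / lambda**2``,
* the absorption coefficient of pure water, interpolated from an embedded
  literature table (the two shortwave-infrared bands near 1450 nm and
  1940 nm are the water signatures that body spectra exhibit),
* the absorption coefficient of eumelanin, modelled as an exponential
  decay toward longer near-infrared wavelengths.

All absorption coefficients are in inverse micrometres so that a metric
pathlength in micrometres times a coefficient is a dimensionless
absorbance.  Constants are bundled in :class:`OpticalConstants`, which can
be serialised to/from JSON so that a population study pins one convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "AbsorptionSpectrum",
    "ChitinDispersion",
    "ExponentialMelanin",
    "OpticalConstants",
    "DEFAULT_CONSTANTS",
    "n_chitin",
    "fresnel_reflectance",
    "mu_water",
    "mu_melanin",
    "water_absorption_table",
]

# Pure-water absorption anchors (wavelength nm, coefficient cm^-1),
# Hale & Querry-era liquid-water values.  Converted below to um^-1 and
# densified to a 5 nm grid; fits interpolate the dense grid linearly.
_WATER_ANCHORS_NM_PER_CM = np.array([
    [850.0, 0.0433], [875.0, 0.0514], [900.0, 0.0679], [925.0, 0.158],
    [950.0, 0.388], [975.0, 0.469], [1000.0, 0.363], [1025.0, 0.223],
    [1050.0, 0.130], [1075.0, 0.148], [1100.0, 0.186], [1125.0, 0.351],
    [1150.0, 0.700], [1175.0, 0.980], [1200.0, 1.04], [1225.0, 0.99],
    [1250.0, 0.885], [1275.0, 1.00], [1300.0, 1.35], [1325.0, 1.81],
    [1350.0, 3.16], [1375.0, 5.94], [1400.0, 12.4], [1425.0, 20.5],
    [1450.0, 28.5], [1475.0, 26.8], [1500.0, 20.6], [1525.0, 14.8],
    [1550.0, 10.1], [1575.0, 7.66], [1600.0, 6.19], [1650.0, 5.13],
    [1700.0, 5.55], [1750.0, 6.93], [1800.0, 8.30], [1850.0, 13.2],
    [1900.0, 67.4], [1925.0, 103.0], [1940.0, 122.0], [1950.0, 120.0],
    [1975.0, 95.0], [2000.0, 69.2], [2050.0, 39.1], [2100.0, 23.7],
    [2150.0, 17.9], [2200.0, 16.5], [2250.0, 19.0], [2300.0, 27.3],
    [2350.0, 41.4], [2400.0, 45.0], [2450.0, 58.0], [2500.0, 75.0],
])


@dataclass
class AbsorptionSpectrum:
    """Tabulated absorption coefficient of a chromophore.

    Parameters
    ----------
    wavelengths_nm : ndarray
        Strictly increasing wavelength grid, nanometres.
    mu_per_um : ndarray
        Absorption coefficient at each grid point, inverse micrometres
        (non-negative).
    label : str
        Chromophore name, e.g. ``"water"``.
    """

    wavelengths_nm: np.ndarray
    mu_per_um: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.mu_per_um = np.asarray(self.mu_per_um, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size < 2:
            raise ValueError("absorption table needs a 1-d grid with >= 2 points")
        if self.mu_per_um.shape != self.wavelengths_nm.shape:
            raise ValueError("grid and coefficient arrays must match in shape")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.mu_per_um < 0):
            raise ValueError("absorption coefficients must be non-negative")

    @property
    def span_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def __call__(self, lambda_nm):
        """Linear interpolation; wavelengths outside the table raise."""
        lam = np.asarray(lambda_nm, dtype=float)
        lo, hi = self.span_nm
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside {self.label or 'absorption'} table span "
                f"[{lo:g}, {hi:g}] nm"
            )
        out = np.interp(lam, self.wavelengths_nm, self.mu_per_um)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ChitinDispersion:
    """Cauchy dispersion of wing chitin, n = n_inf + C / lambda^2."""

    n_inf: float = 1.517
    dispersion_coeff_nm2: float = 8800.0

    def __call__(self, lambda_nm):
        lam = np.asarray(lambda_nm, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("wavelength must be positive")
        out = self.n_inf + self.dispersion_coeff_nm2 / lam**2
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ExponentialMelanin:
    """Eumelanin absorption, mu(lambda) = mu_ref * exp(-beta (lambda - lambda_ref)).

    The absolute scale of near-infrared melanin absorption is a convention;
    pathlengths fitted against it are comparable only within one constants
    configuration.  Defaults: mu_ref = 0.01 um^-1 at 1000 nm, decay
    beta = 0.0062 nm^-1 (absorption falls toward longer wavelengths).
    """

    mu_ref_per_um: float = 0.01
    beta_per_nm: float = 0.0062
    lambda_ref_nm: float = 1000.0

    def __call__(self, lambda_nm):
        lam = np.asarray(lambda_nm, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("wavelength must be positive")
        out = self.mu_ref_per_um * np.exp(-self.beta_per_nm * (lam - self.lambda_ref_nm))
        return out if out.ndim else float(out)


def water_absorption_table(step_nm: float = 5.0) -> AbsorptionSpectrum:
    """Build the pure-water absorption table on a dense grid.

    Anchors (cm^-1) are converted to um^-1 and densified by monotone PCHIP
    interpolation in log-coefficient, which preserves the positivity and
    band shapes of the sparse literature anchors.
    """
    anchors_nm = _WATER_ANCHORS_NM_PER_CM[:, 0]
    mu_um = _WATER_ANCHORS_NM_PER_CM[:, 1] * 1e-4  # cm^-1 -> um^-1
    grid = np.arange(anchors_nm[0], anchors_nm[-1] + 0.5 * step_nm, step_nm)
    dense = np.exp(PchipInterpolator(anchors_nm, np.log(mu_um))(grid))
    return AbsorptionSpectrum(grid, dense, label="water")


@dataclass
class OpticalConstants:
    """Bundle of chitin dispersion and water/melanin absorption spectra."""

    chitin: ChitinDispersion = field(default_factory=ChitinDispersion)
    water: AbsorptionSpectrum = field(default_factory=water_absorption_table)
    melanin: ExponentialMelanin = field(default_factory=ExponentialMelanin)

    def to_json(self, path) -> None:
        payload = {
            "chitin": {
                "n_inf": self.chitin.n_inf,
                "dispersion_coeff_nm2": self.chitin.dispersion_coeff_nm2,
            },
            "water": {
                "wavelengths_nm": self.water.wavelengths_nm.tolist(),
                "mu_per_um": self.water.mu_per_um.tolist(),
            },
            "melanin": {
                "mu_ref_per_um": self.melanin.mu_ref_per_um,
                "beta_per_nm": self.melanin.beta_per_nm,
                "lambda_ref_nm": self.melanin.lambda_ref_nm,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "OpticalConstants":
        payload = json.loads(Path(path).read_text())
        kwargs = {}
        if "chitin" in payload:
            kwargs["chitin"] = ChitinDispersion(**payload["chitin"])
        if "water" in payload:
            w = payload["water"]
            kwargs["water"] = AbsorptionSpectrum(
                np.asarray(w["wavelengths_nm"]), np.asarray(w["mu_per_um"]), "water"
            )
        if "melanin" in payload:
            kwargs["melanin"] = ExponentialMelanin(**payload["melanin"])
        return cls(**kwargs)


DEFAULT_CONSTANTS = OpticalConstants()


def n_chitin(lambda_nm, dispersion: ChitinDispersion | None = None):
    """Refractive index of chitin at ``lambda_nm`` (nanometres)."""
    return (dispersion or DEFAULT_CONSTANTS.chitin)(lambda_nm)


def fresnel_reflectance(n1, n2):
    """Normal-incidence Fresnel reflectance between media of index n1, n2.

    ``((n1 - n2) / (n1 + n2))**2``; symmetric, in [0, 1).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("refractive indices must be positive")
    out = ((n1 - n2) / (n1 + n2)) ** 2
    return out if out.ndim else float(out)


def mu_water(lambda_nm, table: AbsorptionSpectrum | None = None):
    """Pure-water absorption coefficient, um^-1 (table interpolation)."""
    return (table or DEFAULT_CONSTANTS.water)(lambda_nm)


def mu_melanin(lambda_nm, model: ExponentialMelanin | None = None):
    """Eumelanin absorption coefficient, um^-1 (parametric model)."""
    return (model or DEFAULT_CONSTANTS.melanin)(lambda_nm)
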