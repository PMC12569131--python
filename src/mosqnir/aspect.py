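"""Aspect-angle dependence of the backscatter cross-section.

A mosquito body rotated in yaw in front of a co-located source/detector
changes its backscatter cross-section sigma with observation angle psi
(head at 0 degrees).  Three polar harmonics describe the dependence,

    sigma(lambda, psi) = k0(lambda) - k1(lambda) cos(psi) - k2(lambda) cos(2 psi),

where ``k0`` is the all-angle average cross-section, ``k1`` the reduction
toward the head, and ``k2`` the gain from the sagittal (side) aspect.
Dimensionless shape descriptors follow: elongation ``k2 / (k2 + k0)`` and
head/tail asymmetry ``k1 / (k1 + k0)``.  A singular value decomposition of
the raw angle-by-band matrix quantifies how much of the scan is a single
spectral component (relative variance = squared singular values over
their sum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AspectScan",
    "HarmonicFit",
    "harmonic_forward",
    "fit_harmonics",
    "elongation",
    "asymmetry",
    "svd_relative_variance",
]

DEFAULT_YAW_DEG = np.arange(0.0, 360.0, 15.0)


@dataclass
class AspectScan:
    """Backscatter cross-sections over yaw angles x wavelength bands."""

    yaw_deg: np.ndarray
    wavelengths_nm: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.yaw_deg = np.asarray(self.yaw_deg, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.yaw_deg < 0) or np.any(self.yaw_deg >= 360):
            raise ValueError("yaw angles must lie in [0, 360)")
        if np.unique(self.yaw_deg).size < 8:
            raise ValueError("need at least 8 distinct yaw angles")
        if self.sigma.shape != (self.yaw_deg.size, self.wavelengths_nm.size):
            raise ValueError("sigma must be (n_angles, n_bands)")
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma must be finite")
        if np.any(self.sigma < 0):
            raise ValueError("cross-sections must be non-negative")


@dataclass
class HarmonicFit:
    """Per-band polar-harmonic coefficients and shape descriptors."""

    wavelengths_nm: np.ndarray
    k0: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    rss: np.ndarray

    @property
    def elongation(self) -> np.ndarray:
        return elongation(self)

    @property
    def asymmetry(self) -> np.ndarray:
        return asymmetry(self)

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "k0": self.k0.tolist(),
            "k1": self.k1.tolist(),
            "k2": self.k2.tolist(),
            "elongation": self.elongation.tolist(),
            "asymmetry": self.asymmetry.tolist(),
            "rss": self.rss.tolist(),
        }


def harmonic_forward(yaw_deg, k0, k1, k2):
    """Three-harmonic cross-section k0 - k1 cos(psi) - k2 cos(2 psi)."""
    psi = np.deg2rad(np.asarray(yaw_deg, dtype=float))
    out = k0 - k1 * np.cos(psi) - k2 * np.cos(2.0 * psi)
    return out if np.ndim(out) else float(out)


def fit_harmonics(scan: AspectScan) -> HarmonicFit:
    """Least-squares polar-harmonic coefficients per wavelength band.

    Ordinary least squares on the design ``{1, -cos(psi), -cos(2 psi)}``;
    exact (to machine precision) whenever the data lie in the model span.
    On a uniform full-circle grid such as 0:15:345 the columns are
    orthogonal and the ``k0`` estimate is the plain angle average.
    """
    if scan.yaw_deg.size < 6:
        raise ValueError("need at least 6 angles")
    psi = np.deg2rad(scan.yaw_deg)
    X = np.column_stack([np.ones_like(psi), -np.cos(psi), -np.cos(2.0 * psi)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("angle set is rank-deficient for three harmonics")
    coef, _, _, _ = np.linalg.lstsq(X, scan.sigma, rcond=None)
    resid = scan.sigma - X @ coef
    return HarmonicFit(
        wavelengths_nm=scan.wavelengths_nm,
        k0=coef[0].copy(),
        k1=coef[1].copy(),
        k2=coef[2].copy(),
        rss=np.sum(resid**2, axis=0),
    )


def elongation(fit: HarmonicFit) -> np.ndarray:
    """Side-on vs average gain, k2 / (k2 + k0), per band."""
    den = fit.k2 + fit.k0
    if np.any(den == 0):
        raise ZeroDivisionError("k2 + k0 is zero for some band")
    return fit.k2 / den


def asymmetry(fit: HarmonicFit) -> np.ndarray:
    """Head/tail contrast, k1 / (k1 + k0), per band."""
    den = fit.k1 + fit.k0
    if np.any(den == 0):
        raise ZeroDivisionError("k1 + k0 is zero for some band")
    return fit.k1 / den


def svd_relative_variance(scan: AspectScan, n_components: int | None = None) -> np.ndarray:
    """Relative variance of the scan's spectral components.

    Squared singular values of the uncentered angle-by-band matrix,
    normalised to sum to one, in descending order.  The first fraction
    measures how much of the scan is one mean-like spectral shape,
    i.e. how little the spectrum changes with aspect.
    """
    s = np.linalg.svd(scan.sigma, compute_uv=False)
    frac = s**2 / np.sum(s**2)
    if n_components is not None:
        frac = frac[:n_components]
    return frac
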