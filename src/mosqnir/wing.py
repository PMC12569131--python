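"""Thin-film interference model of mosquito wing reflectance.

A wing membrane of chitin (thickness ``d``, a few hundred nanometres)
between air interfaces acts as a Fabry-Perot etalon: reflections from the
front and back surface interfere, producing a deep spectral fringe.  With
a single fringe period inside the shortwave-infrared window the measured
spectrum is fitted by an affine transform of the fringe function

    F(lambda, d) = 4 R sin^2(phi) / ((1 - R)^2 + 4 R sin^2(phi)),
    phi = 2 pi d n_chi(lambda) / lambda,

where ``R`` is the normal-incidence Fresnel reflectance of the air/chitin
interface.  Constructive interference (resonant backscatter) occurs at

    lambda_m = 2 d n_chi(lambda_m) / (m - 1/2) * sqrt(1 - sin^2(theta)/n^2),

solved here as a fixed point per mode ``m``; at normal incidence the
square-root factor is unity.  Fitting the fringe position recovers the
membrane thickness to nanometre precision, the basis of species and sex
contrast in wing interference patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import ChitinDispersion, DEFAULT_CONSTANTS, fresnel_reflectance
from .spectra import Spectrum
from .stats import adjusted_r2, linearized_ci95

__all__ = [
    "WingFit",
    "FitError",
    "fringe_reflectance",
    "resonant_wavelengths",
    "wing_model",
    "fit_wing",
    "modulation_depth",
    "band_ratio",
    "brdf_cos_power",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


@dataclass
class WingFit:
    """Result of fitting the thin-film model to one wing spectrum.

    ``a`` and ``b`` are the fringe amplitude and bias of the affine model
    (reflectance ``(a F + b) / 2`` at spectral exponent ``k = 0``);
    ``modulation_depth = a / (a + b)`` is the fringe contrast.
    """

    d_nm: float
    a: float
    b: float
    k: float
    ci95_d_nm: float
    ci95_a: float
    ci95_b: float
    r2_adj: float
    modulation_depth: float
    n_bands: int
    converged: bool
    indeterminate: bool

    def to_dict(self) -> dict:
        return {
            "d_nm": self.d_nm,
            "ci95_d_nm": self.ci95_d_nm,
            "a": self.a,
            "b": self.b,
            "k": self.k,
            "modulation_depth": self.modulation_depth,
            "r2_adj": self.r2_adj,
            "n_bands": self.n_bands,
            "converged": self.converged,
            "indeterminate": self.indeterminate,
        }


def fringe_reflectance(lambda_nm, d_nm, dispersion: ChitinDispersion | None = None):
    """Fringe function F(lambda, d) of the air/chitin/air film.

    Bounded by ``4R/(1+R)^2`` (at phase maxima) and 0 (at phase zeros).
    """
    disp = dispersion or DEFAULT_CONSTANTS.chitin
    lam = np.asarray(lambda_nm, dtype=float)
    d = np.asarray(d_nm, dtype=float)
    if np.any(d < 0):
        raise ValueError("thickness must be non-negative")
    n = disp(lam)
    R = fresnel_reflectance(1.0, n)
    s = np.sin(2.0 * np.pi * d * n / lam) ** 2
    out = 4.0 * R * s / ((1.0 - R) ** 2 + 4.0 * R * s)
    return out if out.ndim else float(out)


def resonant_wavelengths(
    d_nm: float,
    theta_deg: float = 0.0,
    m_max: int = 1,
    dispersion: ChitinDispersion | None = None,
    tol_nm: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Wavelengths of resonant backscatter for modes m = 1..m_max.

    Solves the fixed point ``lambda = 2 d n(lambda) (m - 1/2)^-1 *
    sqrt(1 - sin^2(theta) / n(lambda)^2)`` per mode; at normal incidence
    (``theta = 0``) the square-root factor is omitted.  Wavelengths are
    returned in mode order and are strictly decreasing in ``m``.
    """
    if d_nm <= 0:
        raise ValueError("thickness must be positive")
    if not 0.0 <= theta_deg < 90.0:
        raise ValueError("incidence angle must be in [0, 90) degrees")
    if m_max < 1:
        raise ValueError("need at least one mode")
    disp = dispersion or DEFAULT_CONSTANTS.chitin
    sin2 = np.sin(np.deg2rad(theta_deg)) ** 2
    out = np.empty(m_max)
    for m in range(1, m_max + 1):
        lam = 2.0 * d_nm * disp.n_inf / (m - 0.5)
        for _ in range(max_iter):
            n = disp(lam)
            new = 2.0 * d_nm * n / (m - 0.5)
            if theta_deg != 0.0:
                new *= np.sqrt(1.0 - sin2 / n**2)
            if abs(new - lam) < tol_nm:
                lam = new
                break
            lam = new
        else:
            raise FitError(f"resonance fixed point did not converge for m={m}")
        out[m - 1] = lam
    return out


def wing_model(
    lambda_nm,
    d_nm: float,
    a: float,
    b: float,
    k: float = 0.0,
    lambda0_nm: float | None = None,
    dispersion: ChitinDispersion | None = None,
):
    """Forward wing reflectance (a F(lambda,d) lambda^k + b lambda0^k) / (lambda0^k + lambda^k).

    With the spectral exponent ``k = 0`` (the only case that one fringe can
    constrain) this reduces to ``(a F + b) / 2``.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    F = fringe_reflectance(lam, d_nm, dispersion)
    if k == 0.0:
        out = (a * F + b) / 2.0
    else:
        if lambda0_nm is None or lambda0_nm <= 0:
            raise ValueError("lambda0_nm must be positive when k != 0")
        lk = lam**k
        l0k = lambda0_nm**k
        out = (a * F * lk + b * l0k) / (l0k + lk)
    return out if np.ndim(out) else float(out)


def _profile_d(lam, F_cache, y, d_grid):
    """Linear (a', b') fit per candidate thickness; returns SSE-ranked grid."""
    ones = np.ones_like(lam)
    sses = np.empty(d_grid.size)
    coefs = np.empty((d_grid.size, 2))
    for i, d in enumerate(d_grid):
        X = np.column_stack([F_cache[i], ones])
        c, *_ = np.linalg.lstsq(X, y, rcond=None)
        c = np.clip(c, 0.0, None)
        sses[i] = np.sum((X @ c - y) ** 2)
        coefs[i] = c
    order = np.argsort(sses, kind="stable")  # ties -> smallest d first
    return order, sses, coefs


def fit_wing(
    spectrum: Spectrum,
    d_bounds: tuple[float, float] = (50.0, 600.0),
    d_grid_step_nm: float = 5.0,
    n_polish: int = 3,
    dispersion: ChitinDispersion | None = None,
) -> WingFit:
    """Fit thickness and fringe amplitude/bias to a measured wing spectrum.

    The thickness axis is multimodal (fringe-mode ambiguity), so the fit
    profiles candidate thicknesses on a 100-500 nm grid (5 nm step, SSE of
    the per-thickness linear amplitude/bias fit) and polishes the best
    candidates with bounded nonlinear least squares.  95 % CIs come from
    the linearized covariance at the optimum.
    """
    if spectrum.n_bands < 50:
        raise ValueError("need at least 50 bands to fit the thin-film model")
    y = spectrum.reflectance
    if np.any(y < 0) or np.any(y > 1.5):
        raise ValueError("reflectance outside [0, 1.5]; check calibration")
    lam = spectrum.wavelengths_nm
    dmin, dmax = d_bounds
    grid = np.arange(max(dmin, 100.0), min(dmax, 500.0) + 0.1, d_grid_step_nm)
    F_cache = [fringe_reflectance(lam, d, dispersion) for d in grid]
    order, _, coefs = _profile_d(lam, F_cache, y, grid)

    def resid(p):
        return wing_model(lam, p[0], p[1], p[2], dispersion=dispersion) - y

    best = None
    for idx in order[:n_polish]:
        a0 = max(2.0 * coefs[idx, 0], 1e-6)  # internal a' = a/2
        b0 = max(2.0 * coefs[idx, 1], 1e-9)
        try:
            res = least_squares(
                resid,
                [grid[idx], a0, b0],
                bounds=([dmin, 0.0, 0.0], [dmax, 3.0, 3.0]),
                method="trf",
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("all wing-fit starts failed to converge")

    d_hat, a_hat, b_hat = best.x
    ci = linearized_ci95(best.jac, best.fun)
    yhat = wing_model(lam, d_hat, a_hat, b_hat, dispersion=dispersion)
    r2a = adjusted_r2(y, yhat, 3)
    depth = a_hat / (a_hat + b_hat) if (a_hat + b_hat) > 0 else np.nan
    return WingFit(
        d_nm=float(d_hat),
        a=float(a_hat),
        b=float(b_hat),
        k=0.0,
        ci95_d_nm=float(ci[0]),
        ci95_a=float(ci[1]),
        ci95_b=float(ci[2]),
        r2_adj=float(r2a),
        modulation_depth=float(depth),
        n_bands=spectrum.n_bands,
        converged=True,
        indeterminate=bool(d_hat - ci[0] <= 0.0),
    )


def modulation_depth(fit: WingFit) -> float:
    """Fringe contrast a / (a + b) of a fitted wing model."""
    if fit.a + fit.b <= 0:
        raise ValueError("modulation depth undefined for a + b <= 0")
    return fit.a / (fit.a + fit.b)


def band_ratio(
    d_nm: float,
    lambda1_nm: float,
    lambda2_nm: float,
    dispersion: ChitinDispersion | None = None,
) -> float:
    """Fringe reflectance ratio between two sensor bands.

    Dual-band instruments exploit this ratio; as thickness varies the ratio
    can cross unity, inverting the bands' relative brightness.
    """
    num = fringe_reflectance(lambda1_nm, d_nm, dispersion)
    den = fringe_reflectance(lambda2_nm, d_nm, dispersion)
    if den < 1e-9:
        raise ZeroDivisionError("fringe reflectance at lambda2 is ~0")
    return num / den


def brdf_cos_power(theta_deg, r: float):
    """Directional scattering lobe I/I0 = cos(theta)^(1/r).

    Surface roughness ``r`` in (0, 1]: r = 1 is an ideal diffuser, small r
    an increasingly mirror-like lobe.  r = 0 (ideal mirror) is a delta
    function and is rejected rather than evaluated.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("roughness r must be in (0, 1]")
    th = np.asarray(theta_deg, dtype=float)
    if np.any(th < 0) or np.any(th > 90):
        raise ValueError("scattering angle must be in [0, 90] degrees")
    out = np.cos(np.deg2rad(th)) ** (1.0 / r)
    return out if out.ndim else float(out)
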