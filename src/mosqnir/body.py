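"""Specular/diffuse decomposition of polarized mosquito body reflectance.

Near-infrared light transport through a mosquito body is ballistic: the
body is thin and poorly scattering at these wavelengths, so the two-flux
(Kubelka-Munk) thin-slab limit applies.  Reflectance splits into

* a spectrally flat specular part ``R_spec``, estimated as the median
  absolute difference between co- and de-polarized spectra (surface gloss
  preserves polarization, multiple scattering does not), and
* a diffuse part ``S / (1 + S + A)`` with scatterance
  ``S(lambda) = (D_half / lambda)**alpha`` and absorbance
  ``A(lambda) = ell_H2O mu_H2O(lambda) + ell_mel mu_mel(lambda)``.

``D_half`` is the wavelength at which half the light would be diffusely
reflected absent absorption; ``alpha`` tilts the scattering spectrum; the
``ell`` parameters are equivalent absorption pathlengths in micrometres of
pure water and melanin.  Fitting the four diffuse parameters to a
hyperspectral body spectrum therefore reads off metric chromophore
pathlengths of the living animal.

The bright abdominal spots of *Aedes aegypti* are modelled separately by a
short-pass curve ``1 / (1 + (lambda / D_half)**alpha)`` whose cut
wavelength marks where sub-wavelength scattering structures stop
resolving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import OpticalConstants, DEFAULT_CONSTANTS
from .spectra import PolarizedSpectra, Spectrum
from .stats import adjusted_r2, linearized_ci95
from .wing import FitError

__all__ = [
    "BodyFit",
    "SpotFit",
    "specular_estimate",
    "scatterance",
    "absorbance",
    "body_forward",
    "fit_body",
    "spot_forward",
    "fit_spot",
]

_DIFFUSE_PARAMS = ("d_half_nm", "alpha", "ell_h2o_um", "ell_mel_um")
_BOUNDS_LO = np.array([100.0, 0.0, 0.0, 0.0])
_BOUNDS_HI = np.array([5000.0, 10.0, 1000.0, 1000.0])


@dataclass
class BodyFit:
    """Four-parameter diffuse fit for one polarization channel.

    ``r_spec`` is the pair-level specular estimate (subtracted from the
    co-polarized channel before fitting; the de-polarized channel is
    fitted as pure diffuse reflectance).  ``indeterminate`` is set when
    any diffuse parameter's 95 % CI lower bound touches zero.
    """

    polarization: str
    r_spec: float
    d_half_nm: float
    alpha: float
    ell_h2o_um: float
    ell_mel_um: float
    ci95: dict = field(default_factory=dict)
    r2_adj: float = np.nan
    n_bands: int = 0
    converged: bool = False
    indeterminate: bool = False
    indeterminate_params: tuple = ()

    def to_dict(self) -> dict:
        return {
            "polarization": self.polarization,
            "r_spec": self.r_spec,
            "d_half_nm": self.d_half_nm,
            "alpha": self.alpha,
            "ell_h2o_um": self.ell_h2o_um,
            "ell_mel_um": self.ell_mel_um,
            "ci95": dict(self.ci95),
            "r2_adj": self.r2_adj,
            "n_bands": self.n_bands,
            "converged": self.converged,
            "indeterminate": self.indeterminate,
            "indeterminate_params": list(self.indeterminate_params),
        }


@dataclass
class SpotFit:
    """Short-pass fit of a white abdominal spot."""

    d_half_nm: float
    alpha: float
    ci95_d_half_nm: float
    ci95_alpha: float
    r2_adj: float
    n_bands: int

    def to_dict(self) -> dict:
        return {
            "d_half_nm": self.d_half_nm,
            "alpha": self.alpha,
            "ci95_d_half_nm": self.ci95_d_half_nm,
            "ci95_alpha": self.ci95_alpha,
            "r2_adj": self.r2_adj,
            "n_bands": self.n_bands,
        }


def specular_estimate(spectra: PolarizedSpectra) -> float:
    """Wavelength-independent specular reflectance of a polarized pair.

    Median over wavelength of ``|R_copol - R_depol|``; exact when the
    diffuse component depolarizes fully and the gloss not at all.
    """
    return float(np.median(np.abs(spectra.r_copol - spectra.r_depol)))


def scatterance(lambda_nm, d_half_nm, alpha):
    """Dimensionless scatterance S = (D_half / lambda)**alpha (1 at D_half)."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0) or np.any(np.asarray(d_half_nm) <= 0):
        raise ValueError("wavelength and D_half must be positive")
    out = (d_half_nm / lam) ** alpha
    return out if np.ndim(out) else float(out)


def absorbance(lambda_nm, ell_h2o_um, ell_mel_um, constants: OpticalConstants | None = None):
    """Dimensionless absorbance A = ell_H2O mu_H2O + ell_mel mu_mel."""
    if ell_h2o_um < 0 or ell_mel_um < 0:
        raise ValueError("pathlengths must be non-negative")
    c = constants or DEFAULT_CONSTANTS
    out = ell_h2o_um * c.water(lambda_nm) + ell_mel_um * c.melanin(lambda_nm)
    return out if np.ndim(out) else float(out)


def body_forward(
    lambda_nm,
    r_spec: float,
    d_half_nm: float,
    alpha: float,
    ell_h2o_um: float,
    ell_mel_um: float,
    constants: OpticalConstants | None = None,
):
    """Forward body reflectance R_spec + S / (1 + S + A).

    The diffuse term tends to 1 as S grows without bound and to 0 as
    absorption dominates or scattering vanishes.
    """
    S = scatterance(lambda_nm, d_half_nm, alpha)
    A = absorbance(lambda_nm, ell_h2o_um, ell_mel_um, constants)
    out = r_spec + S / (1.0 + S + A)
    return out if np.ndim(out) else float(out)


def _fit_diffuse(lam, y, constants, n_polish):
    """Bounded least-squares fit of the four diffuse parameters.

    Starts on a 3^4 grid of interior points ranked by SSE; the best few
    are polished with trust-region reflective least squares.
    """
    muw = constants.water(lam)
    mum = constants.melanin(lam)

    def model(p):
        S = (p[0] / lam) ** p[1]
        return S / (1.0 + S + p[2] * muw + p[3] * mum)

    def resid(p):
        return model(p) - y

    starts = [
        np.array([dh, al, lw, lm])
        for dh in (300.0, 1000.0, 3000.0)
        for al in (1.0, 3.0, 7.0)
        for lw in (50.0, 300.0, 700.0)
        for lm in (50.0, 300.0, 700.0)
    ]
    scored = sorted(starts, key=lambda s: float(np.sum(resid(s) ** 2)))
    best = None
    for s in scored[:n_polish]:
        try:
            res = least_squares(resid, s, bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("all diffuse-fit starts failed to converge")
    ci = linearized_ci95(best.jac, best.fun)
    r2a = adjusted_r2(y, model(best.x), 4)
    return best.x, ci, r2a


def fit_body(
    spectra: PolarizedSpectra,
    lambda_max_nm: float = 1600.0,
    constants: OpticalConstants | None = None,
    n_polish: int = 6,
) -> tuple[BodyFit, BodyFit]:
    """Fit the diffuse body model to both polarization channels.

    The specular estimate is computed first from the co/de difference and
    subtracted from the co-polarized spectrum; the de-polarized spectrum
    is fitted without subtraction.  Wavelengths above ``lambda_max_nm``
    (default 1600 nm, beyond which grating second orders contaminate the
    instrument class this models) are excluded.  Returns the
    (co-polarized, de-polarized) fit pair.
    """
    c = constants or DEFAULT_CONSTANTS
    keep = spectra.wavelengths_nm <= lambda_max_nm
    lam = spectra.wavelengths_nm[keep]
    if lam.size < 100:
        raise ValueError("need at least 100 bands at or below lambda_max_nm")
    if lam[0] > 950.0 or lam[-1] < 1550.0:
        raise ValueError("grid must span roughly 900-1600 nm for the body fit")
    r_spec = specular_estimate(spectra)
    fits = []
    for pol, y in (("co", spectra.r_copol[keep] - r_spec), ("de", spectra.r_depol[keep])):
        params, ci, r2a = _fit_diffuse(lam, y, c, n_polish)
        lower = params - ci
        indet = tuple(
            name for name, lo in zip(_DIFFUSE_PARAMS, lower) if lo <= 0.0
        )
        fits.append(
            BodyFit(
                polarization=pol,
                r_spec=r_spec,
                d_half_nm=float(params[0]),
                alpha=float(params[1]),
                ell_h2o_um=float(params[2]),
                ell_mel_um=float(params[3]),
                ci95={k: float(v) for k, v in zip(_DIFFUSE_PARAMS, ci)},
                r2_adj=float(r2a),
                n_bands=int(lam.size),
                converged=True,
                indeterminate=bool(indet),
                indeterminate_params=indet,
            )
        )
    return fits[0], fits[1]


def spot_forward(lambda_nm, d_half_nm: float, alpha: float):
    """Short-pass reflectance 1 / (1 + (lambda / D_half)**alpha).

    Value 1/2 at the cut wavelength; decreasing in wavelength for
    positive steepness.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0) or d_half_nm <= 0:
        raise ValueError("wavelength and D_half must be positive")
    out = 1.0 / (1.0 + (lam / d_half_nm) ** alpha)
    return out if out.ndim else float(out)


def fit_spot(spectrum: Spectrum, n_polish: int = 4) -> SpotFit:
    """Fit the short-pass cut wavelength and steepness of a white spot."""
    if spectrum.n_bands < 50:
        raise ValueError("need at least 50 bands to fit the spot model")
    lam = spectrum.wavelengths_nm
    y = spectrum.reflectance

    def resid(p):
        return spot_forward(lam, p[0], p[1]) - y

    starts = [
        np.array([dh, al])
        for dh in (np.quantile(lam, 0.25), np.median(lam), np.quantile(lam, 0.75))
        for al in (1.0, 4.0, 8.0)
    ]
    scored = sorted(starts, key=lambda s: float(np.sum(resid(s) ** 2)))
    best = None
    for s in scored[:n_polish]:
        try:
            res = least_squares(
                resid, s, bounds=([100.0, 0.0], [5000.0, 20.0]), method="trf"
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("all spot-fit starts failed to converge")
    ci = linearized_ci95(best.jac, best.fun)
    r2a = adjusted_r2(y, spot_forward(lam, *best.x), 2)
    return SpotFit(
        d_half_nm=float(best.x[0]),
        alpha=float(best.x[1]),
        ci95_d_half_nm=float(ci[0]),
        ci95_alpha=float(ci[1]),
        r2_adj=float(r2a),
        n_bands=spectrum.n_bands,
    )
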