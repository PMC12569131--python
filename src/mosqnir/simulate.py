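"""Synthetic-data generators for every input the pipeline consumes.

Each generator evaluates the corresponding forward model on the
instrument grid it emulates and adds seeded Gaussian noise:

* wing spectra — 288 bands over 900–2500 nm (shortwave-infrared
  push-broom imager), default SNR 100:1;
* polarized body spectra — 382 bands over 900–1600 nm, default SNR 50:1
  co-polarized and 100:1 de-polarized;
* white-spot spectra — same body grid;
* aspect scans — 24 yaw angles (15 degree steps) in seven shortwave
  infrared laser bands between 1000 and 1640 nm;
* specimen cubes — an elliptical body on a dark background, for
  exercising calibration, masking and spectrum extraction.

Noise is additive, Gaussian and homoscedastic per spectrum, with
``sigma = mean(signal) / SNR``.  All generators are pure functions of
their arguments including the seed.  Population draws are lognormal so
every physical parameter stays positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aspect import DEFAULT_YAW_DEG, AspectScan, harmonic_forward
from .body import body_forward, spot_forward
from .constants import OpticalConstants, DEFAULT_CONSTANTS
from .io import SpecimenMask, SpectralCube
from .spectra import PolarizedSpectra, Spectrum
from .wing import wing_model

__all__ = [
    "WING_GRID_NM",
    "BODY_GRID_NM",
    "ASPECT_BANDS_NM",
    "DEPOL_MEDIANS",
    "GroupSpec",
    "SyntheticSpecimen",
    "gen_wing_spectrum",
    "gen_body_spectra",
    "gen_spot_spectrum",
    "gen_aspect_scan",
    "gen_specimen_cube",
    "gen_population",
]

WING_GRID_NM = np.linspace(900.0, 2500.0, 288)
BODY_GRID_NM = np.linspace(900.0, 1600.0, 382)
# seven laser-diode bands spanning 1000-1640 nm (three match the
# false-color channels used for shortwave-infrared mosquito imagery)
ASPECT_BANDS_NM = np.array([1002.0, 1064.0, 1213.0, 1291.0, 1409.0, 1463.0, 1640.0])

# De-polarized population medians differ from the co-polarized ones
# (backscatter interrogates deeper, depolarized paths); used as the
# default de-polarized group in gen_population so co/de contrast exists.
DEPOL_MEDIANS = {"ell_h2o_um": 61.0, "ell_mel_um": 32.0}


def _noisy(signal: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    if snr <= 0:
        raise ValueError("snr must be positive")
    sigma = float(np.mean(np.abs(signal))) / snr
    return signal + rng.normal(0.0, sigma, signal.shape)


def gen_wing_spectrum(
    d_nm: float,
    a: float = 0.9,
    b: float = 0.1,
    lambda_grid=None,
    snr: float = 100.0,
    seed=None,
    area_mm2: float | None = None,
) -> Spectrum:
    """Synthetic wing spectrum: thin-film forward model plus noise.

    Defaults give a modulation depth a/(a+b) of 0.9, typical of the deep
    single fringe these membranes show.
    """
    lam = np.asarray(lambda_grid if lambda_grid is not None else WING_GRID_NM, dtype=float)
    rng = np.random.default_rng(seed)
    y = wing_model(lam, d_nm, a, b)
    return Spectrum(lam, _noisy(y, snr, rng), area_mm2=area_mm2)


def gen_body_spectra(
    r_spec: float = 0.03,
    d_half_nm: float = 330.0,
    alpha: float = 1.0,
    ell_h2o_um: float = 51.0,
    ell_mel_um: float = 25.0,
    depol_params: dict | None = None,
    lambda_grid=None,
    snr_copol: float = 50.0,
    snr_depol: float = 100.0,
    seed=None,
    constants: OpticalConstants | None = None,
    area_mm2: float | None = None,
) -> PolarizedSpectra:
    """Synthetic polarized body spectra.

    The co-polarized channel is the diffuse model plus the flat specular
    offset; the de-polarized channel is pure diffuse.  ``depol_params``
    may override any of ``d_half_nm, alpha, ell_h2o_um, ell_mel_um`` for
    the de-polarized channel; by default the channels share diffuse
    parameters, so the specular estimator inverts exactly on noiseless
    output.
    """
    lam = np.asarray(lambda_grid if lambda_grid is not None else BODY_GRID_NM, dtype=float)
    rng = np.random.default_rng(seed)
    co_diff = body_forward(lam, 0.0, d_half_nm, alpha, ell_h2o_um, ell_mel_um, constants)
    de_kwargs = {
        "d_half_nm": d_half_nm,
        "alpha": alpha,
        "ell_h2o_um": ell_h2o_um,
        "ell_mel_um": ell_mel_um,
    }
    if depol_params:
        unknown = set(depol_params) - set(de_kwargs)
        if unknown:
            raise ValueError(f"unknown depol parameters: {sorted(unknown)}")
        de_kwargs.update(depol_params)
    de_diff = body_forward(lam, 0.0, constants=constants, **de_kwargs)
    r_co = _noisy(co_diff + r_spec, snr_copol, rng)
    r_de = _noisy(de_diff, snr_depol, rng)
    return PolarizedSpectra(lam, r_co, r_de, area_mm2=area_mm2)


def gen_spot_spectrum(
    d_half_nm: float = 1215.0,
    alpha: float = 4.2,
    lambda_grid=None,
    snr: float = 100.0,
    seed=None,
) -> Spectrum:
    """Synthetic white-spot spectrum: short-pass model plus noise."""
    lam = np.asarray(lambda_grid if lambda_grid is not None else BODY_GRID_NM, dtype=float)
    rng = np.random.default_rng(seed)
    y = spot_forward(lam, d_half_nm, alpha)
    return Spectrum(lam, _noisy(y, snr, rng))


def gen_aspect_scan(
    k0,
    k1,
    k2,
    bands=None,
    yaw_deg=None,
    noise_sd: float = 0.0,
    seed=None,
) -> AspectScan:
    """Synthetic aspect scan from per-band harmonic coefficients.

    Coefficients may be scalars (shared across bands) or arrays matching
    the band count.  Gaussian noise of absolute standard deviation
    ``noise_sd`` is added; cross-sections are clipped at zero.
    """
    lamb = np.asarray(bands if bands is not None else ASPECT_BANDS_NM, dtype=float)
    yaw = np.asarray(yaw_deg if yaw_deg is not None else DEFAULT_YAW_DEG, dtype=float)
    k0, k1, k2 = (np.broadcast_to(np.asarray(k, dtype=float), lamb.shape) for k in (k0, k1, k2))
    sigma = harmonic_forward(yaw[:, None], k0[None, :], k1[None, :], k2[None, :])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma + rng.normal(0.0, noise_sd, sigma.shape)
    return AspectScan(yaw, lamb, np.clip(sigma, 0.0, None))


def gen_specimen_cube(
    shape: tuple[int, int] = (48, 48),
    specimen_params: dict | None = None,
    background_level: float = 0.02,
    pixel_size_um: float = 33.0,
    jitter: float = 0.05,
    lambda_grid=None,
    seed=None,
    constants: OpticalConstants | None = None,
) -> tuple[SpectralCube, SpecimenMask]:
    """Synthetic calibrated specimen cube with ground-truth mask.

    An elliptical specimen (semi-axes 0.35 and 0.2 of the frame) whose
    pixels follow the body forward model with per-pixel lognormal
    brightness jitter, on a uniform dark background.
    """
    if shape[0] < 8 or shape[1] < 8:
        raise ValueError("cube must be at least 8x8 pixels")
    lam = np.asarray(
        lambda_grid if lambda_grid is not None else np.linspace(900.0, 1600.0, 64), dtype=float
    )
    p = {"r_spec": 0.03, "d_half_nm": 330.0, "alpha": 1.0, "ell_h2o_um": 51.0, "ell_mel_um": 25.0}
    if specimen_params:
        p.update(specimen_params)
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    ell = ((rr - cy) / (0.35 * shape[0])) ** 2 + ((cc - cx) / (0.2 * shape[1])) ** 2 <= 1.0
    spec = body_forward(lam, p["r_spec"], p["d_half_nm"], p["alpha"], p["ell_h2o_um"],
                        p["ell_mel_um"], constants)
    data = np.full((*shape, lam.size), background_level, dtype=float)
    gain = np.exp(rng.normal(0.0, jitter, int(ell.sum())))
    data[ell] = gain[:, None] * spec[None, :]
    return SpectralCube(data, lam, pixel_size_um), SpecimenMask(ell, pixel_size_um)


@dataclass
class GroupSpec:
    """One synthetic population group (species/sex/state).

    ``params`` holds the median parameter values of the group's forward
    model (wing: ``d_nm``, ``a``, ``b``; body: ``r_spec``, ``d_half_nm``,
    ``alpha``, ``ell_h2o_um``, ``ell_mel_um``); ``dispersion`` the
    relative IQR per parameter (scalar applies to all).
    """

    label: str
    kind: str  # "wing" | "body"
    params: dict
    dispersion: float | dict = 0.1
    n: int = 1
    seed: int | None = None
    snr: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("wing", "body"):
            raise ValueError("kind must be 'wing' or 'body'")
        if self.n < 1:
            raise ValueError("need n >= 1 specimens")
        disp = self.dispersion
        vals = disp.values() if isinstance(disp, dict) else [disp]
        if any(v < 0 for v in vals):
            raise ValueError("dispersions must be non-negative")


@dataclass
class SyntheticSpecimen:
    """A drawn specimen: its true parameters and generated input data."""

    label: str
    params: dict
    data: Spectrum | PolarizedSpectra


def _lognormal_sigma(rel_iqr: float) -> float:
    # median m, relative IQR q: q = 2 sinh(z75 * s) with z75 = 0.67449
    return float(np.arcsinh(rel_iqr / 2.0) / 0.6744897501960817)


def gen_population(groups: list[GroupSpec], seed=None) -> list[SyntheticSpecimen]:
    """Draw per-specimen parameters and spectra for each group.

    Parameters are drawn from lognormal distributions whose median is the
    group value and whose relative IQR is the requested dispersion, then
    fed through the matching spectrum generator.  A de-polarized body
    contrast (water/melanin pathlengths from :data:`DEPOL_MEDIANS`) is
    applied unless the group overrides ``extra['depol_params']``.
    """
    out: list[SyntheticSpecimen] = []
    for gi, g in enumerate(groups):
        g_seed = g.seed if g.seed is not None else gi
        rng = np.random.default_rng([0 if seed is None else seed, g_seed])
        for i in range(g.n):
            draw = {}
            for name, center in g.params.items():
                rel = g.dispersion.get(name, 0.0) if isinstance(g.dispersion, dict) else g.dispersion
                if rel == 0.0 or center == 0.0:
                    draw[name] = float(center)
                else:
                    draw[name] = float(center * rng.lognormal(0.0, _lognormal_sigma(rel)))
            child = rng.integers(0, 2**31 - 1)
            if g.kind == "wing":
                data = gen_wing_spectrum(
                    **draw, snr=g.snr if g.snr is not None else 100.0, seed=int(child)
                )
            else:
                depol = g.extra.get("depol_params", dict(DEPOL_MEDIANS))
                data = gen_body_spectra(
                    **draw,
                    depol_params=depol,
                    snr_copol=g.snr if g.snr is not None else 50.0,
                    snr_depol=g.extra.get("snr_depol", 100.0),
                    seed=int(child),
                )
            out.append(SyntheticSpecimen(label=g.label, params=draw, data=data))
    return out
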