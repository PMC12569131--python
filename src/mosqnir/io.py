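"""File I/O, hyperspectral-cube handling, calibration and masking.

Spectra travel as delimited text tables (columns ``wavelength_nm`` plus
either ``reflectance`` or ``r_copol``/``r_depol``).  Hyperspectral cubes
use the ENVI convention: a plain-text ``.hdr`` file describing an
accompanying raw binary file.  A restricted dialect is supported —
interleaves BSQ/BIL/BIP, little-endian, uint16 or float32 — which covers
what push-broom shortwave-infrared instruments export.

Reflectance calibration follows the standard white/dark scheme
``R = rho_ref * (raw - dark) / (white - dark)`` where ``rho_ref`` is the
reflectivity of the (gray) reference panel.  Specimen masks are obtained
by thresholding the band-mean image against the border-background level
and keeping the largest connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .spectra import PolarizedSpectra, Spectrum

__all__ = [
    "FormatError",
    "SegmentationError",
    "SpectralCube",
    "SpecimenMask",
    "read_spectra_table",
    "write_spectra_table",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_reflectance",
    "segment_specimen",
    "area_from_mask",
    "mean_spectrum",
    "read_mask",
    "write_mask",
]


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


class SegmentationError(RuntimeError):
    """No specimen found in the cube."""


@dataclass
class SpectralCube:
    """rows x cols x bands data cube with band-center wavelengths."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_size_um: float = 33.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise ValueError("band count must equal wavelength count")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SpecimenMask:
    """Boolean foreground mask matching a cube's spatial grid."""

    mask: np.ndarray
    pixel_size_um: float = 33.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-d")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# spectra tables

def read_spectra_table(path) -> Spectrum | PolarizedSpectra:
    """Read a delimited spectra table.

    Requires a header with ``wavelength_nm`` and either ``reflectance``
    (returning a :class:`Spectrum`, honouring an optional ``polarization``
    column) or both ``r_copol`` and ``r_depol`` (returning a
    :class:`PolarizedSpectra`).  Decimal separator is '.' regardless of
    locale.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - any parse failure is a format error
        raise FormatError(f"cannot parse spectra table {path}: {exc}") from exc
    cols = set(df.columns)
    if "wavelength_nm" not in cols:
        raise FormatError("missing required column 'wavelength_nm'")
    for col in df.columns:
        if col == "polarization":
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"column '{col}' is not numeric")
    lam = df["wavelength_nm"].to_numpy(float)
    if {"r_copol", "r_depol"} <= cols:
        return PolarizedSpectra(lam, df["r_copol"].to_numpy(float), df["r_depol"].to_numpy(float))
    if "reflectance" in cols:
        pol = None
        if "polarization" in cols:
            uniq = df["polarization"].unique()
            pol = str(uniq[0]) if len(uniq) == 1 else None
        return Spectrum(lam, df["reflectance"].to_numpy(float), polarization=pol)
    raise FormatError("need column 'reflectance' or columns 'r_copol' and 'r_depol'")


def write_spectra_table(path, obj: Spectrum | PolarizedSpectra) -> None:
    """Write a spectra table (inverse of :func:`read_spectra_table`).

    Round-trips losslessly to 9 significant digits.
    """
    if isinstance(obj, PolarizedSpectra):
        df = pd.DataFrame(
            {"wavelength_nm": obj.wavelengths_nm, "r_copol": obj.r_copol, "r_depol": obj.r_depol}
        )
    elif isinstance(obj, Spectrum):
        df = pd.DataFrame({"wavelength_nm": obj.wavelengths_nm, "reflectance": obj.reflectance})
        if obj.polarization is not None:
            df["polarization"] = obj.polarization
    else:
        raise TypeError("expected Spectrum or PolarizedSpectra")
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# ENVI cubes

_ENVI_DTYPES = {4: np.float32, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing magic line)")
    fields: dict[str, str] = {}
    key, buf, in_block = None, [], False
    for line in text.splitlines()[1:]:
        line = line.strip()
        if not line:
            continue
        if in_block:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf)
                in_block = False
            continue
        if "=" not in line:
            raise FormatError(f"malformed header line: {line!r}")
        key, _, val = (s.strip() for s in line.partition("="))
        key = key.lower()
        if val.startswith("{") and not val.endswith("}"):
            buf = [val]
            in_block = True
        else:
            fields[key] = val
    return fields


def read_envi_cube(header_path) -> SpectralCube:
    """Read an ENVI-style cube (text header + raw binary data file)."""
    hdr = Path(header_path)
    fields = _parse_envi_header(hdr.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field {exc}") from exc
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian (byte order = 0) is supported")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    wl_raw = fields.get("wavelength")
    if wl_raw is None:
        raise FormatError("ENVI header missing wavelength list")
    wl = np.array([float(t) for t in wl_raw.strip("{} ").replace(",", " ").split()])
    if wl.size != bands:
        raise FormatError("wavelength count does not match band count")
    data_path = None
    for cand in (hdr.with_suffix(""), hdr.with_suffix(".img"), hdr.with_suffix(".raw")):
        if cand.exists() and cand != hdr:
            data_path = cand
            break
    if data_path is None:
        raise FormatError(f"no data file found next to {hdr}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<")
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise FormatError("binary size does not match header dimensions")
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(lines, samples, bands)
    return SpectralCube(np.ascontiguousarray(cube), wl)


def write_envi_cube(header_path, cube: SpectralCube, interleave: str = "bsq") -> None:
    """Write a cube as ENVI header (``.hdr``) plus raw binary (``.img``)."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    data = cube.data
    dt = np.dtype(np.float32) if data.dtype.kind == "f" else np.dtype(data.dtype)
    if dt not in _ENVI_CODES:
        raise FormatError(f"unsupported dtype {data.dtype}; use uint16 or float32")
    data = data.astype(dt.newbyteorder("<"), copy=False)
    lines, samples, bands = data.shape
    hdr = Path(header_path)
    if hdr.suffix != ".hdr":
        hdr = hdr.with_suffix(".hdr")
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths_nm)
    hdr.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        f"data type = {_ENVI_CODES[dt]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    np.ascontiguousarray(out).tofile(hdr.with_suffix(".img"))


# ---------------------------------------------------------------------------
# calibration, masking, extraction

def calibrate_reflectance(
    raw: SpectralCube,
    white: SpectralCube,
    dark: SpectralCube | None = None,
    reference_reflectivity: float = 1.0,
) -> SpectralCube:
    """Convert raw counts to reflectance against a white/gray reference.

    ``R = rho_ref * (raw - dark) / (white - dark)`` per pixel and band.
    Pixels where the reference leaves no signal are set to NaN and their
    count reported through a warning.
    """
    if white.data.shape != raw.data.shape:
        raise ValueError("white reference shape must match the raw cube")
    r = raw.data.astype(float)
    w = white.data.astype(float)
    if dark is not None:
        if dark.data.shape != raw.data.shape:
            raise ValueError("dark frame shape must match the raw cube")
        d = dark.data.astype(float)
        r = r - d
        w = w - d
    bad = w == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = reference_reflectivity * r / w
    if bad.any():
        refl[bad] = np.nan
        warnings.warn(f"{int(bad.sum())} cube elements had zero reference signal", stacklevel=2)
    return SpectralCube(refl, raw.wavelengths_nm.copy(), raw.pixel_size_um)


def segment_specimen(cube: SpectralCube, threshold_factor: float = 3.0) -> SpecimenMask:
    """Threshold the band-mean image against the border background.

    Background statistics come from the outer two-pixel frame of the
    band-mean image (the specimen is mounted against a dark border).  A
    pixel is foreground when its band-mean exceeds ``threshold_factor``
    times the background median; the largest connected component is kept.
    """
    img = np.nanmean(cube.data, axis=2)
    border = np.ones_like(img, dtype=bool)
    border[2:-2, 2:-2] = False
    bg = float(np.nanmedian(img[border]))
    fg = img > threshold_factor * bg
    if not fg.any():
        raise SegmentationError("no pixels exceed the background threshold")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return SpecimenMask(labels == keep, cube.pixel_size_um)


def area_from_mask(mask: SpecimenMask) -> float:
    """Specimen area in mm^2: pixel count times squared pixel pitch."""
    return mask.n_pixels * (mask.pixel_size_um / 1000.0) ** 2


def mean_spectrum(cube: SpectralCube, mask: SpecimenMask) -> Spectrum:
    """Spatial average of the cube over the masked specimen pixels."""
    if mask.mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must match the cube's spatial grid")
    if mask.n_pixels == 0:
        raise ValueError("mask is empty")
    vals = np.nanmean(cube.data[mask.mask], axis=0)
    return Spectrum(cube.wavelengths_nm.copy(), vals)


def write_mask(path, mask: SpecimenMask) -> None:
    """Write a mask as a 0/1 text grid (first line: pixel pitch in um)."""
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_um {mask.pixel_size_um:g}\n")
        np.savetxt(fh, mask.mask.astype(np.uint8), fmt="%d")


def read_mask(path) -> SpecimenMask:
    """Read a 0/1 text-grid mask written by :func:`write_mask`."""
    pix = 33.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# pixel_size_um"):
            pix = float(first.split()[-1])
            grid = np.loadtxt(fh)
        else:
            fh.seek(0)
            grid = np.loadtxt(fh)
    if grid.ndim != 2 or not np.isin(grid, (0, 1)).all():
        raise FormatError("mask file must be a 2-d 0/1 grid")
    return SpecimenMask(grid.astype(bool), pix)
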