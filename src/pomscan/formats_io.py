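"""Image-cube and spectral-library I/O plus library resampling.

The pipeline touches two on-disk formats:

* an ENVI-style hyperspectral cube — a plain-text header (``samples``,
  ``lines``, ``bands``, ``interleave``, ``data type``, ``byte order``,
  ``wavelength``) next to a flat binary file, the container line-scanner
  software writes; and
* a delimited-text spectral library — wavelength column in nm plus one
  reflectance column per sample, the shape a lab spectroradiometer export
  takes after conversion to text.

Libraries measured at 1 nm on a contact probe must be brought onto the
coarser camera wavelength grid before they can serve as unmixing
endmembers; :func:`resample_library` does this by boxcar band-averaging.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "ImageCube",
    "EndmemberLibrary",
    "FormatError",
    "CorruptionError",
    "ResamplingError",
    "read_cube",
    "write_cube",
    "read_library",
    "write_library",
    "smooth_library",
    "resample_library",
]


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class CorruptionError(IOError):
    """Header and binary payload disagree (truncated or mismatched file)."""


class ResamplingError(ValueError):
    """A target band interval contains no source sample."""


_WL_MIN, _WL_MAX = 350.0, 2500.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Band-center wavelengths (nm), optionally with per-band FWHM."""

    centers: np.ndarray
    fwhm: np.ndarray | None = None

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("wavelength grid needs at least one band")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("wavelength centers must be strictly increasing")
        if centers[0] < _WL_MIN or centers[-1] > _WL_MAX:
            raise ValueError(
                f"wavelengths must lie in [{_WL_MIN:g}, {_WL_MAX:g}] nm, "
                f"got [{centers[0]:g}, {centers[-1]:g}]"
            )
        if self.fwhm is not None:
            fwhm = np.asarray(self.fwhm, dtype=float)
            if fwhm.shape != centers.shape:
                raise ValueError("fwhm must match centers in length")
            object.__setattr__(self, "fwhm", fwhm)

    def __len__(self) -> int:
        return self.centers.size

    @property
    def spacing(self) -> float:
        """Median band-to-band distance (nm); 0 for a single band."""
        if len(self) < 2:
            return 0.0
        return float(np.median(np.diff(self.centers)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.centers, other.centers)


@dataclass
class ImageCube:
    """Line-scanner cube: lines x samples x bands, line 0 = soil surface.

    ``units`` is ``"radiance"`` (camera counts) or ``"reflectance"``
    (dimensionless).  Reflectance above 1 is legal (bright facets against
    a grey panel) and is never clipped.  ``pixel_size`` is
    (along-track mm, across-track mm).
    """

    data: np.ndarray
    grid: WavelengthGrid
    units: str = "radiance"
    pixel_size: tuple[float, float] = (0.25, 0.25)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"band axis ({self.data.shape[2]}) does not match "
                f"wavelength grid ({len(self.grid)})"
            )
        if self.units not in ("radiance", "reflectance"):
            raise ValueError(f"unknown units tag {self.units!r}")
        if self.units == "reflectance":
            if not np.all(np.isfinite(self.data)):
                raise ValueError("reflectance cube contains non-finite values")
            if np.any(self.data < 0):
                raise ValueError("reflectance cube contains negative values")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class EndmemberLibrary:
    """Named reflectance spectra sharing one wavelength grid.

    ``spectra`` is (bands x samples), column *j* belonging to ``names[j]``.
    """

    names: list[str]
    spectra: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2-D (bands, samples)")
        if self.spectra.shape != (len(self.grid), len(self.names)):
            raise ValueError(
                f"spectra shape {self.spectra.shape} does not match "
                f"{len(self.grid)} bands x {len(self.names)} names"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate spectrum names")
        if np.any(self.spectra < 0) or np.any(self.spectra > 1.5):
            raise ValueError("reflectance outside [0, 1.5]")

    def spectrum(self, name: str) -> np.ndarray:
        """Return the named spectrum as a 1-D band vector."""
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no spectrum named {name!r}; have {self.names}") from None
        return self.spectra[:, j]


# ---------------------------------------------------------------------------
# ENVI-style cube I/O

_DTYPE_CODES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_DTYPE_TO_CODE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}
_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type",
                  "wavelength")


def _data_path(header_path: Path) -> Path:
    return header_path.with_suffix(".img")


def _parse_header(text: str) -> dict[str, str]:
    # "key = value" lines; brace-delimited values may span lines.
    text = re.sub(r"^ENVI\s*", "", text.strip())
    fields: dict[str, str] = {}
    pattern = re.compile(r"^(.+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        fields[key] = val
    return fields


def read_cube(header_path: str | Path) -> ImageCube:
    """Read an ENVI-style header + flat binary cube.

    The binary file is expected next to the header with an ``.img``
    suffix.  Supported interleaves: BIL, BIP, BSQ; values are returned
    bit-identical to the file contents.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise FormatError(f"header {header_path} missing key {key!r}")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise FormatError(f"unsupported data type code {code}")
    dtype = np.dtype(_DTYPE_CODES[code])
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian (byte order = 0) is supported")

    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace(",", " ").split()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    fwhm = None
    if "fwhm" in fields:
        fwhm = np.array(
            [float(tok) for tok in fields["fwhm"].replace(",", " ").split()]
        )

    raw = np.fromfile(_data_path(header_path), dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise CorruptionError(
            f"{_data_path(header_path)}: expected {expected} samples "
            f"({lines}x{samples}x{bands}), found {raw.size}"
        )
    if interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:  # bsq
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    units = fields.get("units", "radiance")
    if "pixel size" in fields:
        px = [float(tok) for tok in fields["pixel size"].replace(",", " ").split()]
        pixel_size = (px[0], px[1])
    else:
        pixel_size = (0.25, 0.25)
    grid = WavelengthGrid(wavelengths, fwhm)
    return ImageCube(np.ascontiguousarray(data), grid, units, pixel_size)


def write_cube(cube: ImageCube, header_path: str | Path,
               interleave: str = "bil") -> None:
    """Write a cube as ENVI-style header + flat binary (``.img`` alongside).

    Round-trips bit-exactly through :func:`read_cube` for every supported
    interleave and dtype.  Wavelengths are printed with full ``repr``
    precision so the grid survives the text round trip.
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_TO_CODE:
        raise ValueError(f"unsupported dtype {dtype}; use one of "
                         f"{sorted(str(np.dtype(d)) for d in _DTYPE_TO_CODE)}")
    header_path = Path(header_path)

    data = cube.data
    if interleave == "bil":
        out = data.transpose(0, 2, 1)
    elif interleave == "bip":
        out = data
    else:
        out = data.transpose(2, 0, 1)
    out.astype(dtype, copy=False).tofile(_data_path(header_path))

    wl = ", ".join(repr(float(w)) for w in cube.grid.centers)
    lines = [
        "ENVI",
        f"samples = {cube.samples}",
        f"lines = {cube.lines}",
        f"bands = {cube.bands}",
        f"interleave = {interleave}",
        f"data type = {_DTYPE_TO_CODE[dtype]}",
        "byte order = 0",
        f"units = {cube.units}",
        f"pixel size = {{{cube.pixel_size[0]!r}, {cube.pixel_size[1]!r}}}",
        f"wavelength = {{{wl}}}",
    ]
    if cube.grid.fwhm is not None:
        fw = ", ".join(repr(float(w)) for w in cube.grid.fwhm)
        lines.append(f"fwhm = {{{fw}}}")
    header_path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Spectral libraries


def _sniff_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else r"\s+"


def read_library(table_path: str | Path) -> EndmemberLibrary:
    """Read a delimited-text spectral library.

    First column: wavelength (nm), strictly increasing.  Remaining
    columns: one reflectance spectrum each, named by the header row.
    Delimiter is auto-detected among comma, tab and semicolon.
    """
    table_path = Path(table_path)
    with open(table_path) as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first)
    df = pd.read_csv(table_path, sep=sep, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{table_path}: need a wavelength column plus at "
                          "least one spectrum")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{table_path}: non-numeric cell at row {row + 2}, "
                f"column {col!r}"
            )
        df[col] = pd.to_numeric(df[col])
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise FormatError(f"{table_path}: wavelength column is not strictly "
                          "increasing")
    grid = WavelengthGrid(wl)
    names = [str(c) for c in df.columns[1:]]
    return EndmemberLibrary(names, df.iloc[:, 1:].to_numpy(dtype=float), grid)


def write_library(lib: EndmemberLibrary, table_path: str | Path,
                  sep: str = ",") -> None:
    df = pd.DataFrame(lib.spectra, columns=lib.names)
    df.insert(0, "wavelength_nm", lib.grid.centers)
    df.to_csv(table_path, sep=sep, index=False)


def smooth_library(lib: EndmemberLibrary, window: int) -> EndmemberLibrary:
    """Sliding-mean smoothing with a centred odd window.

    Interior bands become the mean over ``window`` neighbours; the first
    and last ``window // 2`` bands use the truncated window that fits.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 1 <= window <= len(lib.grid):
        raise ValueError(f"window must be in [1, {len(lib.grid)}]")
    if window == 1:
        return replace(lib, spectra=lib.spectra.copy())
    kernel = np.ones(window)
    counts = np.convolve(np.ones(len(lib.grid)), kernel, mode="same")
    smoothed = np.empty_like(lib.spectra)
    for j in range(lib.spectra.shape[1]):
        smoothed[:, j] = np.convolve(lib.spectra[:, j], kernel, mode="same") / counts
    return replace(lib, spectra=smoothed)


def _band_widths(centers: np.ndarray) -> np.ndarray:
    if centers.size == 1:
        raise ValueError("cannot infer band width from a single-band grid; "
                         "provide fwhm")
    widths = np.empty_like(centers)
    widths[1:-1] = (centers[2:] - centers[:-2]) / 2.0
    widths[0] = centers[1] - centers[0]
    widths[-1] = centers[-1] - centers[-2]
    return widths


def resample_library(lib: EndmemberLibrary,
                     target: WavelengthGrid) -> EndmemberLibrary:
    """Resample a library onto a target grid by boxcar band-averaging.

    Each target band takes the mean of the source samples in the
    half-open interval [center - w/2, center + w/2), w being the target
    band width (FWHM if present, otherwise the local center spacing).
    A boxcar response is used throughout: it needs no instrument FWHM
    model and is exactly the "mean of neighbouring bands" convention used
    elsewhere in the pipeline.
    """
    src = lib.grid.centers
    if target.centers[0] < src[0] or target.centers[-1] > src[-1]:
        raise ResamplingError(
            f"target grid [{target.centers[0]:g}, {target.centers[-1]:g}] nm "
            f"extends outside source range [{src[0]:g}, {src[-1]:g}]"
        )
    widths = (target.fwhm if target.fwhm is not None
              else _band_widths(target.centers))
    out = np.empty((len(target), len(lib.names)))
    for i, (c, w) in enumerate(zip(target.centers, widths)):
        lo = np.searchsorted(src, c - w / 2.0, side="left")
        hi = np.searchsorted(src, c + w / 2.0, side="left")
        if hi <= lo:
            raise ResamplingError(
                f"target band {i} at {c:g} nm (width {w:g} nm) contains no "
                "source sample"
            )
        out[i] = lib.spectra[lo:hi].mean(axis=0)
    return EndmemberLibrary(list(lib.names), out, target)
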