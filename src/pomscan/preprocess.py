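"""Radiance-to-reflectance calibration, SNR binning, band masking, geometry.

A push-broom line scanner illuminates the sample with lamps whose output
is not perfectly uniform along the scan, so reflectance is computed per
image line against a white reference panel recorded in the same scan:

    rho_obj(line, s, b) = L_obj(line, s, b) / L_ref(line, b) * rho_ref(b)

Any gain that multiplies object and panel radiance jointly — lamp drift,
integration-time changes — cancels exactly.  Averaging n pixels improves
the signal-to-noise ratio by sqrt(n), which motivates the spatial and
spectral binning steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .formats_io import ImageCube, ResamplingError, WavelengthGrid

__all__ = [
    "ReferencePanel",
    "BandMask",
    "CalibrationError",
    "calibrate",
    "bin_spatial",
    "bin_spectral",
    "apply_mask",
    "pixel_geometry",
    "line_count",
]


class CalibrationError(ValueError):
    """Reference panel radiance unusable (non-positive) somewhere."""


@dataclass
class ReferencePanel:
    """White-reference observation: a radiance cube over the panel region.

    ``rho_ref`` is the certified panel reflectance, scalar or per band.
    If the panel cube has the same line count as the object cube its
    per-line sample mean is used line by line; a panel imaged separately
    with a different line count contributes a single per-band mean that
    is broadcast to every object line.
    """

    cube: ImageCube
    rho_ref: float | np.ndarray = 0.99

    def __post_init__(self) -> None:
        if self.cube.units != "radiance":
            raise ValueError("reference panel must be a radiance cube")
        rho = np.asarray(self.rho_ref, dtype=float)
        if np.any(rho <= 0) or np.any(rho > 1):
            raise ValueError("panel reflectance must lie in (0, 1]")
        if rho.ndim == 1 and rho.size != self.cube.bands:
            raise ValueError("per-band rho_ref length must equal band count")

    def line_reference(self, n_lines: int) -> np.ndarray:
        """L_ref as (n_lines, bands): per-line panel mean, or broadcast."""
        per_line = self.cube.data.mean(axis=1, dtype=float)  # (panel lines, bands)
        if self.cube.lines == n_lines:
            return per_line
        return np.broadcast_to(per_line.mean(axis=0), (n_lines, per_line.shape[1]))


@dataclass
class BandMask:
    """Per-band keep flags with a human-readable reason per masked range."""

    keep: np.ndarray
    reasons: list[str]

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if not self.keep.any():
            raise ValueError("band mask removes every band")

    @classmethod
    def from_ranges(cls, grid: WavelengthGrid,
                    drop_nm: list[tuple[float, float]],
                    reason: str = "masked range") -> "BandMask":
        """Mask all bands whose centers fall inside any [lo, hi] nm range."""
        keep = np.ones(len(grid), dtype=bool)
        reasons = []
        for lo, hi in drop_nm:
            inside = (grid.centers >= lo) & (grid.centers <= hi)
            keep &= ~inside
            reasons.append(f"{reason}: {lo:g}-{hi:g} nm")
        return cls(keep, reasons)


def calibrate(cube: ImageCube, panel: ReferencePanel) -> ImageCube:
    """Per-line reflectance calibration against the white panel.

    L_ref(line, b) is the mean over the panel's across-track samples for
    that line.  Output is reflectance, never clipped: values above 1 are
    legal for facets brighter than the panel.
    """
    if cube.units != "radiance":
        raise ValueError("calibrate expects a radiance cube")
    if cube.bands != panel.cube.bands:
        raise ValueError("panel and cube band counts differ")
    l_ref = panel.line_reference(cube.lines)
    bad = l_ref <= 0
    if bad.any():
        line, band = np.argwhere(bad)[0]
        raise CalibrationError(
            f"panel radiance non-positive at line {line}, band {band}"
        )
    rho = np.asarray(panel.rho_ref, dtype=float)
    data = cube.data.astype(float) / l_ref[:, None, :] * rho
    return ImageCube(data, cube.grid, "reflectance", cube.pixel_size)


def bin_spatial(cube: ImageCube, factor: int) -> ImageCube:
    """Average non-overlapping factor x factor pixel blocks.

    Trailing lines/samples that do not fill a block are dropped, so every
    output pixel is a true factor^2-pixel mean (preserving the sqrt(n)
    SNR gain).  Pixel size scales by the factor.
    """
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    if factor == 1:
        return replace(cube, data=cube.data.copy())
    nl = cube.lines // factor
    ns = cube.samples // factor
    if nl < 1 or ns < 1:
        raise ValueError(f"cube {cube.lines}x{cube.samples} too small for "
                         f"factor {factor}")
    trimmed = cube.data[: nl * factor, : ns * factor]
    binned = trimmed.reshape(nl, factor, ns, factor, cube.bands).mean(axis=(1, 3))
    px = (cube.pixel_size[0] * factor, cube.pixel_size[1] * factor)
    return ImageCube(binned, cube.grid, cube.units, px)


def bin_spectral(cube: ImageCube, target_spacing: float) -> ImageCube:
    """Average contiguous source bands into half-open target intervals.

    Intervals start at the first band center and are ``target_spacing``
    wide; each output band center is the mean of its member centers.
    """
    native = cube.grid.spacing
    if target_spacing < native - 1e-9:
        raise ValueError(
            f"target spacing {target_spacing:g} nm finer than native "
            f"{native:g} nm"
        )
    centers = cube.grid.centers
    groups = np.floor((centers - centers[0]) / target_spacing + 1e-9).astype(int)
    uniq = np.unique(groups)
    new_centers = np.array([centers[groups == g].mean() for g in uniq])
    new_data = np.stack(
        [cube.data[:, :, groups == g].mean(axis=2) for g in uniq], axis=2
    )
    return ImageCube(new_data, WavelengthGrid(new_centers), cube.units,
                     cube.pixel_size)


def apply_mask(cube: ImageCube, mask: BandMask) -> ImageCube:
    """Drop masked bands from data and grid."""
    if mask.keep.size != cube.bands:
        raise ValueError(
            f"mask length {mask.keep.size} does not match {cube.bands} bands"
        )
    grid = WavelengthGrid(cube.grid.centers[mask.keep],
                          None if cube.grid.fwhm is None
                          else cube.grid.fwhm[mask.keep])
    return ImageCube(cube.data[:, :, mask.keep], grid, cube.units,
                     cube.pixel_size)


def pixel_geometry(swath_mm: float, n_across: int) -> float:
    """Across-track pixel width (µm) from swath width and pixel count."""
    if swath_mm <= 0 or n_across <= 0:
        raise ValueError("swath and pixel count must be positive")
    return swath_mm / n_across * 1000.0


def line_count(profile_length_mm: float, pixel_size_um: float) -> int:
    """Number of scan lines covering a profile at a given pixel pitch."""
    if profile_length_mm <= 0 or pixel_size_um <= 0:
        raise ValueError("length and pixel size must be positive")
    return math.floor(profile_length_mm * 1000.0 / pixel_size_um)
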