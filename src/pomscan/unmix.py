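"""Five-band fully constrained two-endmember linear spectral unmixing.

Most soil-profile pixels contain both organic and mineral material, so a
per-pixel classification is meaningless; instead each pixel spectrum s is
modelled as a convex combination of two endmembers,

    s = a * E_om + (1 - a) * E_min + e,      0 <= a <= 1,

and the organic fraction a is estimated by least squares under both the
non-negativity and the sum-to-one constraint (FCLS).  To avoid the
overfitting that full-spectrum regression invites with millions of image
spectra, only five diagnostic SWIR bands enter the fit: 2012, 2108, 2228
and 2276 nm sit in cellulose/lignin absorption features of organic
matter, while 2204 nm marks the Al-OH lattice absorption of
phyllosilicate clays, the mineral identifier.

For two endmembers the FCLS problem has a closed form: project the
spectrum onto the segment between the endmember vectors and clamp to
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import EndmemberLibrary, ImageCube, WavelengthGrid

__all__ = [
    "DEFAULT_BAND_TARGETS",
    "DEFAULT_BAND_ROLES",
    "BandSet",
    "EndmemberMatrix",
    "AbundanceMap",
    "BandSelectionError",
    "select_bands",
    "build_endmember_matrix",
    "unmix_pixel",
    "unmix_image",
]

# Diagnostic wavelengths (nm): four organic-matter identifiers plus the
# 2204 nm phyllosilicate identifier.
DEFAULT_BAND_TARGETS: tuple[float, ...] = (2012.0, 2108.0, 2204.0, 2228.0, 2276.0)
DEFAULT_BAND_ROLES: tuple[str, ...] = ("organic", "organic", "mineral",
                                       "organic", "organic")


class BandSelectionError(ValueError):
    """A target wavelength has no grid band within tolerance."""


@dataclass(frozen=True)
class BandSet:
    """Target wavelengths resolved onto a concrete grid."""

    targets: tuple[float, ...]
    indices: tuple[int, ...]
    centers: tuple[float, ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.targets):
            raise ValueError("indices/targets length mismatch")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("band indices must be strictly increasing")


@dataclass(frozen=True)
class EndmemberMatrix:
    """Endmember reflectance at the selected bands, columns (oPOM, MinRest)."""

    E: np.ndarray
    names: tuple[str, str] = ("oPOM", "MinRest")

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        if E.ndim != 2 or E.shape[1] != 2:
            raise ValueError("endmember matrix must be (bands, 2)")
        if np.any(E < 0):
            raise ValueError("endmember reflectance must be non-negative")

    @property
    def organic(self) -> np.ndarray:
        return self.E[:, 0]

    @property
    def mineral(self) -> np.ndarray:
        return self.E[:, 1]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.E))


@dataclass
class AbundanceMap:
    """Per-pixel organic fraction a_om in [0, 1] plus RMS fit residual."""

    a_om: np.ndarray
    residual: np.ndarray
    pixel_size: tuple[float, float] = (0.25, 0.25)

    def __post_init__(self) -> None:
        self.a_om = np.asarray(self.a_om, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.a_om.shape != self.residual.shape:
            raise ValueError("abundance and residual shapes differ")
        if np.any(self.a_om < 0) or np.any(self.a_om > 1):
            raise ValueError("abundance outside [0, 1]")
        if np.any(self.residual < 0):
            raise ValueError("negative residual")


def select_bands(grid: WavelengthGrid,
                 targets: tuple[float, ...] = DEFAULT_BAND_TARGETS,
                 tolerance: float = 6.0,
                 roles: tuple[str, ...] = DEFAULT_BAND_ROLES) -> BandSet:
    """Map target wavelengths to nearest grid bands within a tolerance.

    Ties between two equidistant centers resolve toward the lower
    wavelength.  The default 6 nm tolerance is about one SWIR band.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(roles) != len(targets):
        raise ValueError("one role per target required")
    indices = []
    centers = []
    for t in targets:
        dist = np.abs(grid.centers - t)
        i = int(np.argmin(dist))  # argmin takes the first = lower wavelength
        if dist[i] > tolerance:
            raise BandSelectionError(
                f"no band within {tolerance:g} nm of {t:g} nm "
                f"(nearest center: {grid.centers[i]:g} nm)"
            )
        indices.append(i)
        centers.append(float(grid.centers[i]))
    order = np.argsort(indices)
    return BandSet(tuple(targets[i] for i in order),
                   tuple(indices[i] for i in order),
                   tuple(centers[i] for i in order),
                   tuple(roles[i] for i in order))


def build_endmember_matrix(lib: EndmemberLibrary, bands: BandSet,
                           organic: str = "oPOM",
                           mineral: str = "MinRest") -> EndmemberMatrix:
    """Extract the (bands x 2) endmember matrix from a resampled library.

    The library may hold any number of fractions; only the organic and
    mineral endmember columns are used.  Raises if the two columns are
    numerically collinear at the selected bands.
    """
    idx = np.asarray(bands.indices)
    E = np.column_stack([lib.spectrum(organic)[idx], lib.spectrum(mineral)[idx]])
    em = EndmemberMatrix(E, (organic, mineral))
    if not np.isfinite(em.condition_number) or em.condition_number > 1e6:
        raise ValueError(
            f"endmembers nearly collinear at selected bands "
            f"(condition number {em.condition_number:.3g})"
        )
    return em


def _project_simplex(spectra: np.ndarray, E: EndmemberMatrix
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form FCLS for two endmembers on (..., bands) spectra."""
    d = E.organic - E.mineral
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("degenerate endmembers: organic equals mineral")
    a = ((spectra - E.mineral) @ d) / denom
    a = np.clip(a, 0.0, 1.0)
    fit = a[..., None] * E.organic + (1.0 - a[..., None]) * E.mineral
    residual = np.sqrt(np.mean((fit - spectra) ** 2, axis=-1))
    return a, residual


def unmix_pixel(spectrum: np.ndarray, E: EndmemberMatrix
                ) -> tuple[float, float]:
    """FCLS estimate for one spectrum at the selected bands.

    Solves min ||E a - s|| s.t. a >= 0, sum(a) = 1; returns the organic
    fraction and the RMS fit residual.  Out-of-simplex spectra clamp to
    the nearest vertex (a = 0 or 1).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (E.E.shape[0],):
        raise ValueError(
            f"spectrum length {spectrum.shape} does not match "
            f"{E.E.shape[0]} selected bands"
        )
    if not np.all(np.isfinite(spectrum)):
        raise ValueError("spectrum contains non-finite values")
    a, r = _project_simplex(spectrum[None, :], E)
    return float(a[0]), float(r[0])


def unmix_image(cube: ImageCube, lib: EndmemberLibrary,
                bands: BandSet | None = None,
                tolerance: float = 6.0) -> AbundanceMap:
    """Pixel-wise FCLS over a reflectance cube.

    ``lib`` must already be resampled to the cube's wavelength grid and
    contain the oPOM and MinRest endmembers.
    """
    if cube.units != "reflectance":
        raise ValueError("unmixing requires a reflectance cube")
    if len(lib.grid) != cube.bands or not np.allclose(
            lib.grid.centers, cube.grid.centers):
        raise ValueError("library is not on the cube's wavelength grid; "
                         "resample it first")
    if bands is None:
        bands = select_bands(cube.grid, tolerance=tolerance)
    em = build_endmember_matrix(lib, bands)
    spectra = cube.data[:, :, np.asarray(bands.indices)].astype(float)
    a, residual = _project_simplex(spectra, em)
    return AbundanceMap(a, residual, cube.pixel_size)
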