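"""Ground-truthed synthetic soil-core scenes for end-to-end testing.

No public dataset accompanies this kind of soil-core imaging study, so
the pipeline is exercised on simulated scenes whose every intermediate
is known exactly:

* **Endmember spectra.**  A mineral endmember (MinRest, the residue left
  after particulate organic matter removal) with a convex rising visible
  continuum, water absorption dips at 1450 and ~1930 nm and the sharp
  Al-OH phyllosilicate feature at 2206 nm; and an organic endmember
  (oPOM, occluded particulate organic matter) that is darker in the
  visible and carries a broad cellulose/lignin absorption trough between
  2000 and 2300 nm with no 2206 nm dip.
* **Particle field.**  Elongated, ellipse-shaped POM particles (roots,
  leaf residues) whose areal density decays exponentially with depth;
  particle interiors have organic abundance 1 and a one-pixel rim has
  abundance 0.5 to model sub-pixel mixing at particle edges.
* **Radiance rendering.**  Per-pixel reflectance is the linear mixture
  of the two endmembers plus sensor noise; radiance multiplies that by a
  smooth per-line illumination gain and a lamp spectral curve, and a
  white reference panel (reflectance 0.99) is rendered under the same
  illumination so that per-line calibration can invert the model.
* **Fraction tables.**  Per-ROI-block carbon stocks statistically
  coupled to the true block abundance, standing in for the laboratory
  fractionation data that image metrics are correlated against.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .formats_io import EndmemberLibrary, ImageCube, WavelengthGrid
from .profile_stats import ROIGrid

__all__ = [
    "PANEL_RHO",
    "SceneConfig",
    "GroundTruth",
    "asd_grid",
    "swir_camera_grid",
    "make_endmembers",
    "place_particles",
    "render_scene",
    "make_fraction_table",
    "noise_sigma_for_r",
    "expected_particle_count",
    "simulate_scene",
]

#: reflectance of the rendered white reference panel (certified Spectralon
#: panels are ~0.99 across the VisNIR)
PANEL_RHO = 0.99

#: abundance assigned to the one-pixel partial-cover rim of each particle
RIM_ABUNDANCE = 0.5


def asd_grid() -> WavelengthGrid:
    """Contact-spectrometer grid: 350-2500 nm at 1 nm (2151 bands)."""
    return WavelengthGrid(np.arange(350.0, 2501.0, 1.0))


def swir_camera_grid(spacing: float = 5.5) -> WavelengthGrid:
    """SWIR line-scanner grid: 970-2500 nm at the native 5.5 nm sampling."""
    return WavelengthGrid(np.arange(970.0, 2500.0 + spacing / 2, spacing))


@dataclass
class SceneConfig:
    """Study conditions for one simulated soil-core profile face.

    Defaults emulate a 30 cm deep Chernozem profile imaged by a SWIR
    line scanner at 0.25 mm pixels: a few particles per cm^2 at the
    surface falling off with an 8 cm e-folding depth, elongated root-like
    shapes of 8-40 pixels, a 10% smooth along-track illumination
    non-uniformity, and additive sensor noise of 0.005 reflectance units
    after calibration.
    """

    lines: int = 240
    samples: int = 120
    grid: WavelengthGrid = field(default_factory=swir_camera_grid)
    pixel_size_mm: tuple[float, float] = (0.25, 0.25)
    particle_count_surface: float = 3.0   # expected particles per cm^2 at depth 0
    depth_decay: float = 8.0              # e-folding depth of density (cm)
    particle_axis_ratio_range: tuple[float, float] = (2.0, 6.0)
    particle_area_range: tuple[int, int] = (8, 40)
    illumination_amplitude: float = 0.10  # relative per-line gain variation
    noise_sigma: float = 0.005            # reflectance units
    panel_samples: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lines < 1 or self.samples < 1:
            raise ValueError("scene dimensions must be positive")
        if self.depth_decay <= 0:
            raise ValueError("depth_decay must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.particle_count_surface < 0:
            raise ValueError("particle density must be non-negative")
        lo, hi = self.particle_area_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid particle_area_range")
        if hi > self.lines * self.samples:
            raise ValueError("particle_area_range exceeds image area")


@dataclass
class GroundTruth:
    """True per-pixel organic abundance, particle labels, block means."""

    abundance: np.ndarray
    particle_labels: np.ndarray
    block_abundance: pd.DataFrame
    roi: ROIGrid
    n_particles: int

    def __post_init__(self) -> None:
        if np.any(self.abundance < 0) or np.any(self.abundance > 1):
            raise ValueError("true abundance outside [0, 1]")
        if self.abundance.shape != self.particle_labels.shape:
            raise ValueError("abundance/label shape mismatch")


# ---------------------------------------------------------------------------
# Endmember spectra


def _gauss(wl: np.ndarray, center: float, width: float,
           depth: float) -> np.ndarray:
    return depth * np.exp(-0.5 * ((wl - center) / width) ** 2)


def _smooth_perturbation(wl: np.ndarray, rng: np.random.Generator,
                         amplitude: float = 0.006) -> np.ndarray:
    """Low-frequency random wiggle, small enough to preserve all features."""
    span = wl[-1] - wl[0]
    t = (wl - wl[0]) / span
    out = np.zeros_like(wl)
    for k in range(1, 4):
        out += rng.normal(0.0, amplitude / k) * np.cos(
            np.pi * k * t + rng.uniform(0, 2 * np.pi)
        )
    return out


def make_endmembers(grid: WavelengthGrid, seed: int = 0) -> EndmemberLibrary:
    """Generate MinRest and oPOM reference spectra on a full-range grid.

    The grid must span at least 410-2400 nm (in particular it must cover
    the 2276 nm organic identifier).  Seeded low-frequency perturbations
    make each library unique while every diagnostic feature survives.
    """
    wl = grid.centers
    if wl[0] > 410.0 or wl[-1] < 2400.0:
        raise ValueError(
            f"endmember grid must span [410, 2400] nm, got "
            f"[{wl[0]:g}, {wl[-1]:g}]"
        )
    rng = np.random.default_rng(seed)

    # Mineral endmember: convex rising visible continuum onto a SWIR
    # plateau; water dips at 1450/1930 nm; sharp Al-OH dip at 2206 nm.
    minrest = 0.16 + 0.30 / (1.0 + np.exp(-(wl - 750.0) / 260.0))
    minrest -= _gauss(wl, 1450.0, 22.0, 0.05)
    minrest -= _gauss(wl, 1930.0, 40.0, 0.11)
    minrest -= _gauss(wl, 2206.0, 13.0, 0.07)
    minrest += _smooth_perturbation(wl, rng)

    # Organic endmember: dark, concave visible part; broad
    # cellulose/lignin absorption across 2000-2300 nm; no 2206 nm dip.
    opom = 0.06 + 0.24 / (1.0 + np.exp(-(wl - 1250.0) / 330.0))
    opom -= _gauss(wl, 1930.0, 45.0, 0.04)
    opom -= _gauss(wl, 2150.0, 120.0, 0.085)
    opom += _smooth_perturbation(wl, rng)

    spectra = np.clip(np.column_stack([minrest, opom]), 0.02, 0.9)
    return EndmemberLibrary(["MinRest", "oPOM"], spectra, grid)


# ---------------------------------------------------------------------------
# Particle placement


def _line_intensity(cfg: SceneConfig) -> np.ndarray:
    """Expected particle count per image line (Poisson intensity)."""
    depth_cm = np.arange(cfg.lines) * cfg.pixel_size_mm[0] / 10.0
    line_area_cm2 = (cfg.samples * cfg.pixel_size_mm[1]
                     * cfg.pixel_size_mm[0] / 100.0)
    return (cfg.particle_count_surface
            * np.exp(-depth_cm / cfg.depth_decay) * line_area_cm2)


def expected_particle_count(cfg: SceneConfig) -> float:
    """Expected total number of particles in the scene."""
    return float(_line_intensity(cfg).sum())


def _rasterize_particle(n_px: int, ratio: float, angle: float,
                        center: tuple[int, int],
                        shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Exactly n_px pixels of a rotated ellipse around an integer center.

    Pixels are ranked by normalised elliptical distance (raster order
    breaking ties) and the closest n_px are taken, so the configured
    pixel count is met exactly.
    """
    b = np.sqrt(n_px / (np.pi * ratio))
    a = ratio * b
    r = int(np.ceil(a)) + 1
    cy, cx = center
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    u = xx * np.cos(angle) + yy * np.sin(angle)
    v = -xx * np.sin(angle) + yy * np.cos(angle)
    dist = (u / a) ** 2 + (v / b) ** 2
    flat = dist.ravel()
    order = np.lexsort((np.arange(flat.size), flat))[:n_px]
    ys = yy.ravel()[order] + cy
    xs = xx.ravel()[order] + cx
    keep = (ys >= 0) & (ys < shape[0]) & (xs >= 0) & (xs < shape[1])
    return ys[keep], xs[keep]


def place_particles(cfg: SceneConfig) -> GroundTruth:
    """Draw the particle field and its ground-truth abundance map.

    Particle count per line is Poisson with an exponentially
    depth-decaying intensity; each particle is a filled rotated ellipse
    with pixel count drawn uniformly from the configured area range
    (realised exactly), interior abundance 1 and a one-pixel rim at 0.5.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    abundance = np.zeros((cfg.lines, cfg.samples))
    labels = np.zeros((cfg.lines, cfg.samples), dtype=np.int32)

    amin, amax = cfg.particle_area_range
    rmax = int(np.ceil(np.sqrt(amax * cfg.particle_axis_ratio_range[1] / np.pi))) + 1
    counts = rng.poisson(_line_intensity(cfg))
    next_label = 0
    for line in np.flatnonzero(counts):
        for _ in range(int(counts[line])):
            n_px = int(rng.integers(amin, amax + 1))
            ratio = rng.uniform(*cfg.particle_axis_ratio_range)
            angle = rng.uniform(0.0, np.pi)
            cy = int(np.clip(line, rmax, max(rmax, cfg.lines - 1 - rmax)))
            cx = int(rng.integers(0, cfg.samples))
            cx = int(np.clip(cx, rmax, max(rmax, cfg.samples - 1 - rmax)))
            ys, xs = _rasterize_particle(n_px, ratio, angle, (cy, cx),
                                         abundance.shape)
            next_label += 1
            abundance[ys, xs] = 1.0
            labels[ys, xs] = next_label

    # one-pixel partial-cover rim around every particle
    interior = abundance == 1.0
    shell = ndimage.binary_dilation(interior, structure=np.ones((3, 3))) & ~interior
    abundance[shell] = RIM_ABUNDANCE
    rim_labels = ndimage.grey_dilation(labels, footprint=np.ones((3, 3)))
    labels[shell] = rim_labels[shell]

    roi = ROIGrid.regular(cfg.lines, cfg.samples)
    rows = []
    for b in roi.blocks:
        block = abundance[b.line_start:b.line_stop, b.sample_start:b.sample_stop]
        rows.append({"row": b.row, "col": b.col, "depth_cm": b.depth_cm,
                     "abundance": float(block.mean())})
    return GroundTruth(abundance, labels, pd.DataFrame(rows), roi, next_label)


# ---------------------------------------------------------------------------
# Radiance rendering


def _lamp_curve(wl: np.ndarray, peak_counts: float = 1.0e4) -> np.ndarray:
    """Smooth halogen-lamp-like spectral radiance shape (camera units)."""
    # Planck shape at 3000 K; absolute scale is arbitrary camera units.
    c2 = 1.4388e7  # nm*K
    shape = wl ** -5.0 / (np.exp(c2 / (wl * 3000.0)) - 1.0)
    return shape / shape.max() * peak_counts


def render_scene(truth: GroundTruth, lib: EndmemberLibrary,
                 cfg: SceneConfig) -> tuple[ImageCube, ImageCube]:
    """Render the radiance cube and its white-panel cube.

    Per-pixel reflectance is a*oPOM + (1-a)*MinRest plus additive
    Gaussian noise (floored at zero — a dark-corrected sensor records no
    negative radiance); radiance multiplies reflectance by a smooth
    per-line illumination gain and a lamp spectral curve.  The panel is
    rendered noise-free under the same gain and curve.
    """
    opom = lib.spectrum("oPOM")
    minrest = lib.spectrum("MinRest")
    a = truth.abundance
    if a.shape != (cfg.lines, cfg.samples):
        raise ValueError("truth does not match scene dimensions")

    refl = a[:, :, None] * opom + (1.0 - a)[:, :, None] * minrest
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng([cfg.seed, 7])
        refl = refl + rng.normal(0.0, cfg.noise_sigma, refl.shape)
        refl = np.maximum(refl, 0.0)

    gain = 1.0 + cfg.illumination_amplitude * np.sin(
        2.0 * np.pi * np.arange(cfg.lines) / max(cfg.lines, 2)
    )
    curve = _lamp_curve(cfg.grid.centers)
    radiance = refl * gain[:, None, None] * curve
    panel = (PANEL_RHO * gain[:, None, None]
             * np.ones((cfg.lines, cfg.panel_samples, 1)) * curve)

    cube = ImageCube(radiance, cfg.grid, "radiance", cfg.pixel_size_mm)
    panel_cube = ImageCube(panel, cfg.grid, "radiance", cfg.pixel_size_mm)
    return cube, panel_cube


# ---------------------------------------------------------------------------
# Physical-fraction tables


#: default split of the POM carbon stock among the three POM fractions
#: (free > occluded ~ small), mirroring stock ordering in grassland topsoils
POM_SPLIT = (0.55, 0.25, 0.20)


def noise_sigma_for_r(block_abundance: np.ndarray, alpha: float,
                      r: float) -> float:
    """Noise std giving theoretical Pearson r between stock and abundance.

    From r = alpha*s_a / sqrt(alpha^2 s_a^2 + sigma^2) with s_a the
    sample std of the block abundances.
    """
    if not 0 < r <= 1:
        raise ValueError("target r must be in (0, 1]")
    s_a = float(np.std(block_abundance, ddof=1))
    return alpha * s_a * np.sqrt(1.0 / r**2 - 1.0)


def make_fraction_table(truth, alpha: float, sigma: float, seed: int = 0,
                        plot: str = "grazed", profile: int = 1,
                        proportions: tuple[float, float, float] = POM_SPLIT
                        ) -> pd.DataFrame:
    """Simulate per-block physical-fraction carbon stocks (mg C / g soil).

    The total POM stock of each ROI block is alpha times its true mean
    organic abundance plus Gaussian noise, floored at zero, then split
    among fPOM/oPOM/soPOM in fixed proportions.  The MinRest stock
    follows an independent depth-declining trend; bulk soil carbon is
    the sum of all fractions.  ``truth`` may be a :class:`GroundTruth`
    or any frame with row/col/depth_cm/abundance columns.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    blocks = (truth.block_abundance if isinstance(truth, GroundTruth)
              else truth).copy()
    rng = np.random.default_rng(seed)
    a = blocks["abundance"].to_numpy(dtype=float)
    pom = np.maximum(alpha * a + rng.normal(0.0, sigma, a.size), 0.0)
    depth_mid = np.array([np.mean(d) for d in blocks["depth_cm"]])
    minrest = np.maximum(
        12.0 - 0.12 * depth_mid + rng.normal(0.0, 0.8, a.size), 0.0
    )
    out = pd.DataFrame({
        "plot": plot, "profile": profile,
        "row": blocks["row"], "col": blocks["col"],
        "depth_cm": blocks["depth_cm"],
        "fPOM": proportions[0] * pom,
        "oPOM": proportions[1] * pom,
        "soPOM": proportions[2] * pom,
        "MinRest": minrest,
        "abundance": a,
    })
    out["bulk"] = out[["fPOM", "oPOM", "soPOM", "MinRest"]].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Convenience driver


def simulate_scene(cfg: SceneConfig):
    """Full forward model: endmembers -> particles -> rendered cubes.

    Reference spectra are generated on the 1 nm contact-spectrometer
    grid, smoothed with a three-band sliding mean and boxcar-resampled
    to the scene's camera grid — the same path field libraries take.
    Returns (truth, resampled library, radiance cube, panel cube).
    """
    from .formats_io import resample_library, smooth_library

    asd_lib = make_endmembers(asd_grid(), cfg.seed)
    lib = resample_library(smooth_library(asd_lib, 3), cfg.grid)
    truth = place_particles(cfg)
    cube, panel = render_scene(truth, lib, cfg)
    return truth, lib, cube, panel
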