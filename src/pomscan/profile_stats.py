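"""Depth profiles, ROI-block metrics, and correlations with lab fractions.

The imaged profile face is divided into a grid of ROI blocks (2 columns
x 5 depth rows per imaged layer, nominally 4.5 x 6 cm) matching the
blocks cut out for physical density/ultrasonication fractionation.  Per
block this module computes the SpecPOM metrics — percent area covered by
the organic endmember and mean particle size in pixels — and correlates
them against the carbon stocks of the physically separated fractions
(fPOM, oPOM, soPOM, MinRest, their sums, and bulk soil carbon) with
Pearson's r, overall and per grazing treatment, optionally with listed
outlier blocks excluded.

Line-wise cover condenses the abundance map into a depth profile at the
scanner's native line resolution, far finer than any block sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .unmix import AbundanceMap

__all__ = [
    "ROIBlock",
    "ROIGrid",
    "FRACTION_VARIABLES",
    "SPECPOM_METRICS",
    "linewise_cover",
    "roi_aggregate",
    "pearson",
    "correlation_table",
]

#: lab-fraction variables correlated against the image metrics
FRACTION_VARIABLES = ("bulk", "fPOM", "oPOM", "soPOM", "MinRest",
                      "POM", "fPOM_oPOM")
SPECPOM_METRICS = ("SpecPOM_pct", "SpecPOM_size")

#: nominal depth rows of the sampling grid (cm)
DEPTH_ROWS_CM = ((0, 6), (6, 12), (12, 18), (18, 24), (24, 30))


@dataclass(frozen=True)
class ROIBlock:
    row: int
    col: int
    line_start: int
    line_stop: int
    sample_start: int
    sample_stop: int
    depth_cm: tuple[float, float]


@dataclass(frozen=True)
class ROIGrid:
    """Non-overlapping ROI rectangles tiling an image, surface row first."""

    blocks: tuple[ROIBlock, ...]
    lines: int
    samples: int

    @classmethod
    def regular(cls, lines: int, samples: int, n_rows: int = 5,
                n_cols: int = 2,
                depth_rows_cm=DEPTH_ROWS_CM) -> "ROIGrid":
        """Split an image into an n_rows x n_cols grid of equal blocks.

        Trailing lines/samples that do not divide evenly are absorbed by
        the last row/column so the grid tiles the image exactly.
        """
        if lines < n_rows or samples < n_cols:
            raise ValueError("image smaller than requested grid")
        if len(depth_rows_cm) < n_rows:
            raise ValueError("need one depth label per row")
        l_edges = [round(i * lines / n_rows) for i in range(n_rows + 1)]
        s_edges = [round(j * samples / n_cols) for j in range(n_cols + 1)]
        blocks = tuple(
            ROIBlock(r, c, l_edges[r], l_edges[r + 1],
                     s_edges[c], s_edges[c + 1],
                     tuple(depth_rows_cm[r]))
            for r in range(n_rows) for c in range(n_cols)
        )
        return cls(blocks, lines, samples)


def linewise_cover(amap: AbundanceMap, window: int = 10) -> pd.DataFrame:
    """Summed fractional cover over non-overlapping windows of scan lines.

    The per-line cover c_l is the mean organic abundance across the
    line's samples (normalised by sample count so profiles from cameras
    of different widths are comparable); a window's value is the sum of
    c_l over ``window`` consecutive lines.  A trailing partial window is
    reported with its actual line count.  Depth is the window's starting
    line times the along-track pixel size.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    per_line = amap.a_om.mean(axis=1)
    n = per_line.size
    starts = np.arange(0, n, window)
    rows = []
    for s in starts:
        chunk = per_line[s:s + window]
        rows.append({
            "depth_cm": s * amap.pixel_size[0] / 10.0,
            "cover": float(chunk.sum()),
            "n_lines": int(chunk.size),
        })
    return pd.DataFrame(rows)


def roi_aggregate(amap: AbundanceMap, pm, grid: ROIGrid) -> pd.DataFrame:
    """Per-block SpecPOM metrics: percent cover and mean particle size.

    SpecPOM % is 100 x the mean organic abundance over the block's
    pixels; SpecPOM size is the mean size of the particles anchored in
    the block (see :func:`pomscan.particles.particle_stats`).
    """
    from .particles import particle_stats

    lines, samples = amap.a_om.shape
    if grid.lines != lines or grid.samples != samples:
        raise ValueError("ROI grid does not match abundance map shape")
    sizes = particle_stats(pm, grid).set_index(["row", "col"])
    rows = []
    for b in grid.blocks:
        block_a = amap.a_om[b.line_start:b.line_stop,
                            b.sample_start:b.sample_stop]
        sz = sizes.loc[(b.row, b.col)]
        rows.append({
            "row": b.row, "col": b.col, "depth_cm": b.depth_cm,
            "SpecPOM_pct": 100.0 * float(block_a.mean()),
            "SpecPOM_size": float(sz["mean_size_px"]),
            "particle_count": int(sz["particle_count"]),
        })
    return pd.DataFrame(rows)


def pearson(x, y) -> float:
    """Pearson product-moment correlation.

    Returns NaN — the undefined-statistic flag, deliberately not a
    usable number — when either input is constant or shorter than 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _with_derived_sums(ft: pd.DataFrame) -> pd.DataFrame:
    ft = ft.copy()
    ft["POM"] = ft["fPOM"] + ft["oPOM"] + ft["soPOM"]
    ft["fPOM_oPOM"] = ft["fPOM"] + ft["oPOM"]
    return ft


def correlation_table(ft: pd.DataFrame,
                      strata: tuple[str, ...] = ("All", "Grazed", "Ungrazed"),
                      exclusions: list | None = None) -> pd.DataFrame:
    """Pearson r of each SpecPOM metric against each fraction variable.

    ``ft`` is the merged block table: one record per ROI block with the
    lab carbon stocks (mg C per g soil) for fPOM/oPOM/soPOM/MinRest and
    bulk, plus the image metrics SpecPOM_pct and SpecPOM_size and a
    ``plot`` column ('grazed'/'ungrazed').  The derived sums POM and
    fPOM+oPOM are recomputed here.  ``exclusions`` lists (plot, profile,
    row, col) keys of records to drop in a parallel outlier-excluded
    variant; r is flagged undefined (NaN, ``defined`` False) when a
    stratum has < 3 records or a constant variable.

    Returns a tidy frame: metric, variable, stratum, excluded, r, defined, n.
    """
    ft = _with_derived_sums(ft)
    variants = [(False, ft)]
    if exclusions:
        keys = ft.set_index(["plot", "profile", "row", "col"]).index
        drop = keys.isin([tuple(e) for e in exclusions])
        variants.append((True, ft.loc[~drop]))
    out = []
    for excluded, table in variants:
        for stratum in strata:
            if stratum == "All":
                sub = table
            else:
                sub = table[table["plot"].str.lower() == stratum.lower()]
            for metric in SPECPOM_METRICS:
                for var in FRACTION_VARIABLES:
                    r = (pearson(sub[metric], sub[var])
                         if len(sub) >= 3 else float("nan"))
                    out.append({
                        "metric": metric, "variable": var,
                        "stratum": stratum, "excluded": excluded,
                        "r": r, "defined": bool(np.isfinite(r)),
                        "n": int(len(sub)),
                    })
    return pd.DataFrame(out)
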