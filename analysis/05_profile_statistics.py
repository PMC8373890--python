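#!/usr/bin/env python
"""Depth profiles and image-vs-lab correlation tables.

Builds the line-wise fractional-cover depth profile for each profile
face (summed over 10-line windows), merges the per-block SpecPOM metrics
with the simulated physical-fraction table, and computes the Pearson
correlation matrix (all 40 blocks, and per grazing treatment) between
the image metrics and each lab fraction variable.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pomscan import formats_io as fio
from pomscan import profile_stats as ps
from pomscan.unmix import AbundanceMap

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

TAGS = [("grazed", 1), ("grazed", 2), ("ungrazed", 1), ("ungrazed", 2)]


def main() -> None:
    profiles = []
    for plot, prof in TAGS:
        tag = f"{plot}{prof}"
        cube = fio.read_cube(SCRATCH / f"{tag}_abundance.hdr")
        amap = AbundanceMap(cube.data[:, :, 0].astype(float),
                            np.zeros(cube.data.shape[:2]), cube.pixel_size)
        cover = ps.linewise_cover(amap, window=10)
        cover.insert(0, "profile", prof)
        cover.insert(0, "plot", plot)
        profiles.append(cover)
    cover_table = pd.concat(profiles, ignore_index=True)
    cover_table.to_csv(RESULTS / "linewise_cover.csv", index=False)

    blocks = pd.read_csv(RESULTS / "block_metrics.csv")
    fractions = pd.read_csv(RESULTS / "fraction_table.csv")
    merged = fractions.drop(columns=["depth_cm"]).merge(
        blocks[["plot", "profile", "row", "col",
                "SpecPOM_pct", "SpecPOM_size"]],
        on=["plot", "profile", "row", "col"], validate="one_to_one")
    merged.to_csv(RESULTS / "blocks_merged.csv", index=False)

    corr = ps.correlation_table(merged)
    corr.to_csv(RESULTS / "correlation_table.csv", index=False)

    wide = corr[~corr.excluded].pivot_table(
        index=["metric", "stratum"], columns="variable", values="r")
    print("Pearson r, SpecPOM metrics vs lab fractions:")
    print(wide.round(2).to_string())
    top = cover_table[cover_table.depth_cm < 6].groupby("plot")["cover"].mean()
    print("\nmean 10-line summed cover in 0-6 cm:")
    print(top.round(3).to_string())


if __name__ == "__main__":
    main()
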