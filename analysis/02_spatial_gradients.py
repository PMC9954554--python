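#!/usr/bin/env python
"""Spatial stage: interface zones, band densities, immunogradient indicators.

Consumes the slides generated by 01_simulate_slides.py, traces the
epithelium-stroma interface (short boundaries removed), builds the signed
10 µm band map, assigns CD8+ centroids, and evaluates the immunodrop and
center-of-mass indicators over the zone-width variant grid.  Expected
picture: slides generated with a stronger epithelial decay show larger
ID(2) and more negative CM.  Writes results/indicators.csv and per-slide
band profiles.
"""

import sys
from pathlib import Path

import pandas as pd

from immunogradient import RunConfig
from immunogradient.config import SlideInput
from immunogradient.pipeline import run_spatial

SLIDES = Path("scratch/analysis_slides")
RESULTS = Path("results")


def main() -> None:
    masks = sorted(SLIDES.glob("slide_*.png"))
    if not masks:
        print("run analysis/01_simulate_slides.py first", file=sys.stderr)
        return 1
    config = RunConfig(
        pixel_size_um=1.0,
        min_boundary_um=500.0,
        variant_widths_um=tuple(range(20, 151, 10)),
        output_dir=str(RESULTS),
        seed=1,
        slides=[
            SlideInput(
                slide=p.stem,
                mask=str(p),
                cells=str(p.with_name(p.stem + "_cells.csv")),
            )
            for p in masks
        ],
    )
    table = run_spatial(config)
    summary = pd.read_csv(RESULTS / "slide_summary.csv")
    best = table[(table["indicator"] == "ID") & (table["rank"] == 2)][
        ["slide", "value"]
    ].rename(columns={"value": "id_10_20um"})
    cm = table[(table["indicator"] == "CM") & (table["rank"] == 2)][
        ["slide", "value"]
    ].rename(columns={"value": "cm_0_20um"})
    merged = summary.merge(best, on="slide").merge(cm, on="slide")
    print(merged.to_string(index=False))
    corr = merged["decay_epithelial"].corr(merged["id_10_20um"], method="spearman")
    print(f"\nSpearman(decay, ID 10-20um) = {corr:.2f} "
          "(stronger programmed decay -> larger immunodrop)")
    merged.to_csv(RESULTS / "slide_indicators.csv", index=False)
    return 0


if __name__ == "__main__":
    sys.exit(main())
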