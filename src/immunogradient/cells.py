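"""Cell-to-band assignment and density computation.

Cells are represented by their centroids (µm coordinates in the mask frame)
with a CD8+ flag.  A centroid contributes to the band of the pixel that
contains it; CD8- cells are carried through I/O but ignored by every
density computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import OUTSIDE, BandMap
from .masks import EPITHELIUM, STROMA, TissueMask


@dataclass
class CellSet:
    """Cell centroids (x_um, y_um) with CD8 positivity flags."""

    xy_um: np.ndarray  # (n, 2)
    cd8_positive: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.xy_um = np.atleast_2d(np.asarray(self.xy_um, dtype=float))
        if self.xy_um.size == 0:
            self.xy_um = self.xy_um.reshape(0, 2)
        self.cd8_positive = np.asarray(self.cd8_positive, dtype=bool).ravel()
        if self.xy_um.shape != (len(self.cd8_positive), 2):
            raise ValueError("xy_um must be (n, 2) matching cd8_positive length")
        if not np.isfinite(self.xy_um).all():
            raise ValueError("cell coordinates must be finite")

    def __len__(self) -> int:
        return len(self.cd8_positive)

    @property
    def n_positive(self) -> int:
        return int(self.cd8_positive.sum())


def read_cells(path, column_map: dict[str, str] | None = None) -> CellSet:
    """Read a centroid table CSV with columns x_um, y_um, cd8_positive."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = {"x_um", "y_um", "cd8_positive"} - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    return CellSet(df[["x_um", "y_um"]].to_numpy(float), df["cd8_positive"].to_numpy() != 0)


def write_cells(path, cells: CellSet) -> None:
    pd.DataFrame(
        {
            "x_um": cells.xy_um[:, 0],
            "y_um": cells.xy_um[:, 1],
            "cd8_positive": cells.cd8_positive.astype(int),
        }
    ).to_csv(path, index=False)


@dataclass
class BandCounts:
    """CD8+ counts per band rank, with bookkeeping for conservation checks."""

    counts: dict[int, int]
    outside_iz: int  # CD8+ cells on in-bounds pixels outside the zone
    excluded: int  # CD8+ cells outside the raster bounds

    @property
    def total_in_bands(self) -> int:
        return int(sum(self.counts.values()))


def _pixel_indices(cells: CellSet, band_map: BandMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row/col of the pixel containing each CD8+ centroid, plus in-bounds mask."""
    pos = cells.xy_um[cells.cd8_positive]
    col = np.floor(pos[:, 0] / band_map.pixel_size_um).astype(np.int64)
    row = np.floor(pos[:, 1] / band_map.pixel_size_um).astype(np.int64)
    H, W = band_map.rank_raster.shape
    inb = (row >= 0) & (row < H) & (col >= 0) & (col < W)
    return row, col, inb


def assign_cells_to_bands(cells: CellSet, band_map: BandMap) -> BandCounts:
    """Count CD8+ centroids per band rank (containing-pixel rule).

    Centroids on artifact/background pixels or beyond the zone width count as
    outside the interface zone; centroids outside the raster bounds are
    excluded (logged in the result, not fatal).
    """
    row, col, inb = _pixel_indices(cells, band_map)
    ranks = band_map.rank_raster[row[inb], col[inb]]
    counts = {r: 0 for r in band_map.ranks}
    vals, n = np.unique(ranks, return_counts=True)
    outside = 0
    for v, k in zip(vals.tolist(), n.tolist()):
        if v == OUTSIDE:
            outside = k
        else:
            counts[int(v)] = int(k)
    return BandCounts(counts=counts, outside_iz=outside, excluded=int((~inb).sum()))


@dataclass
class BandDensityProfile:
    """Per-rank CD8+ densities across the interface zone.

    ``densities[r] = counts[r] / areas_mm2[r]`` in cells/mm^2 where the band
    has positive area; zero-area bands are flagged undefined (NaN density).
    """

    ranks: list[int]
    counts: dict[int, int]
    areas_mm2: dict[int, float]
    densities: dict[int, float] = field(init=False)
    defined: dict[int, bool] = field(init=False)

    def __post_init__(self) -> None:
        self.densities, self.defined = {}, {}
        for r in self.ranks:
            c, a = self.counts[r], self.areas_mm2[r]
            if c < 0 or a < 0:
                raise ValueError(f"negative count or area at rank {r}")
            if a > 0:
                self.densities[r] = c / a
                self.defined[r] = True
            else:
                self.densities[r] = float("nan")
                self.defined[r] = False

    @property
    def max_rank(self) -> int:
        return max(self.ranks)

    def density(self, r: int) -> float:
        return self.densities[r]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "count": [self.counts[r] for r in self.ranks],
                "area_mm2": [self.areas_mm2[r] for r in self.ranks],
                "density_per_mm2": [self.densities[r] for r in self.ranks],
            }
        )


def band_density_profile(
    counts: dict[int, int] | BandCounts, areas_mm2: dict[int, float]
) -> BandDensityProfile:
    """Combine per-rank counts and areas into a density profile."""
    if isinstance(counts, BandCounts):
        counts = counts.counts
    if set(counts) != set(areas_mm2):
        raise ValueError("counts and areas must be keyed by identical rank sets")
    ranks = sorted(counts)
    return BandDensityProfile(ranks=ranks, counts=dict(counts), areas_mm2=dict(areas_mm2))


@dataclass
class CompartmentDensities:
    """Absolute CD8+ densities (cells/mm^2) per compartment and overall zone.

    Undefined (zero-area) compartments carry NaN.
    """

    epithelial_density: float
    stromal_density: float
    overall_iz_density: float


def compartment_densities(
    cells: CellSet, mask: TissueMask, band_map: BandMap
) -> CompartmentDensities:
    """Absolute densities over epithelium, stroma and the whole interface zone.

    Compartment areas exclude artifact pixels by construction (artifacts are
    their own label class); the overall zone uses pixels with |rank| <= R.
    """
    if mask.labels.shape != band_map.rank_raster.shape:
        raise ValueError("mask and band map shapes differ")
    row, col, inb = _pixel_indices(cells, band_map)
    labels_at = mask.labels[row[inb], col[inb]]
    ranks_at = band_map.rank_raster[row[inb], col[inb]]
    px_area = mask.pixel_size_um**2 * 1e-6

    def dens(count: int, npix: int) -> float:
        return count / (npix * px_area) if npix > 0 else float("nan")

    epi = dens(int((labels_at == EPITHELIUM).sum()), int((mask.labels == EPITHELIUM).sum()))
    stro = dens(int((labels_at == STROMA).sum()), int((mask.labels == STROMA).sum()))
    iz = dens(int((ranks_at != OUTSIDE).sum()), int((band_map.rank_raster != OUTSIDE).sum()))
    return CompartmentDensities(
        epithelial_density=epi, stromal_density=stro, overall_iz_density=iz
    )
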