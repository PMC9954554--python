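"""Immunogradient indicators: immunodrop (ID) and center of mass (CM).

Both indicators summarise the CD8+ density profile across the interface
zone and are dimensionless:

* ``ID(r) = rho[-r] / rho[r]`` - the ratio of the stromal to the epithelial
  density in the rank-r band pair.  ID > 1 means the density drops on
  entering the epithelium.
* ``CM(R') = sum(r * rho[r]) / sum(rho[r])`` over the signed ranks
  ``-R'..-1, 1..R'`` - the density-weighted mean band rank.  CM < 0 means
  the CD8+ mass is skewed toward the stroma.

Undefined values (zero denominators, zero-area bands) are returned as NaN
and carry a textual reason in :class:`GradientIndicators`, so downstream
survival models can drop them as missing instead of crashing.
"""

from __future__ import annotations

import math

import pandas as pd

from .cells import BandDensityProfile

DEFAULT_VARIANT_WIDTHS_UM = tuple(range(20, 301, 10))


def immunodrop(profile: BandDensityProfile, r: int) -> float:
    """Stromal-to-epithelial density ratio of the rank-``r`` band pair.

    Returns NaN when the epithelial band density is zero or either band has
    zero area.
    """
    if r <= 0:
        raise ValueError(f"immunodrop rank must be positive, got {r}")
    if r not in profile.ranks or -r not in profile.ranks:
        raise ValueError(f"rank +/-{r} not present in profile (max {profile.max_rank})")
    if not (profile.defined[r] and profile.defined[-r]):
        return float("nan")
    denom = profile.densities[r]
    if denom == 0:
        return float("nan")
    return profile.densities[-r] / denom


def center_of_mass(profile: BandDensityProfile, half_width: int) -> float:
    """Density-weighted mean band rank over ``-half_width..half_width``.

    Zero-area bands are skipped; returns NaN when the total density is zero
    or no band in the range is defined.
    """
    if half_width <= 0:
        raise ValueError(f"half_width must be positive, got {half_width}")
    ranks = [r for r in profile.ranks if 0 < abs(r) <= half_width]
    if len(ranks) != 2 * half_width:
        raise ValueError(
            f"half_width {half_width} exceeds the profile range (max {profile.max_rank})"
        )
    num = den = 0.0
    any_defined = False
    for r in ranks:
        if not profile.defined[r]:
            continue
        any_defined = True
        num += r * profile.densities[r]
        den += profile.densities[r]
    if not any_defined or den == 0:
        return float("nan")
    return num / den


class GradientIndicators:
    """ID and CM values over a grid of interface-zone width variants.

    Stored as a table with one row per variant: ``indicator`` (ID/CM),
    ``rank`` (band-pair rank or half-width), ``label`` (µm range),
    ``value``, ``defined`` and ``reason`` for undefined entries.
    """

    def __init__(self, rows: list[dict]):
        self.table = pd.DataFrame(
            rows, columns=["indicator", "rank", "label", "value", "defined", "reason"]
        )

    def id_values(self) -> dict[int, float]:
        sub = self.table[self.table["indicator"] == "ID"]
        return dict(zip(sub["rank"], sub["value"]))

    def cm_values(self) -> dict[int, float]:
        sub = self.table[self.table["indicator"] == "CM"]
        return dict(zip(sub["rank"], sub["value"]))

    def value(self, indicator: str, rank: int) -> float:
        sub = self.table
        row = sub[(sub["indicator"] == indicator) & (sub["rank"] == rank)]
        if row.empty:
            raise KeyError(f"{indicator}({rank}) not in the variant grid")
        return float(row["value"].iloc[0])


def variant_grid(
    profile: BandDensityProfile,
    widths_um: tuple[float, ...] = DEFAULT_VARIANT_WIDTHS_UM,
    band_width_um: float = 10.0,
) -> GradientIndicators:
    """Evaluate ID and CM at every zone-width variant up to ``max(widths_um)``.

    Emits ``ID(r)`` for every band-pair rank r and ``CM(R')`` for every
    half-width R' with ``r * band_width_um <= max(widths_um)``.
    """
    widths = sorted(widths_um)
    for w in widths:
        ratio = w / band_width_um
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"variant width {w} is not a multiple of the band width")
    max_rank = int(round(max(widths) / band_width_um))
    if max_rank > profile.max_rank:
        raise ValueError(
            f"variant grid needs ranks up to {max_rank}, profile has {profile.max_rank}"
        )
    rows = []
    for r in range(1, max_rank + 1):
        v = immunodrop(profile, r)
        rows.append(
            {
                "indicator": "ID",
                "rank": r,
                "label": f"ID {int((r - 1) * band_width_um)}-{int(r * band_width_um)} um",
                "value": v,
                "defined": not math.isnan(v),
                "reason": "" if not math.isnan(v) else "zero denominator or zero-area band",
            }
        )
    for rp in range(1, max_rank + 1):
        v = center_of_mass(profile, rp)
        rows.append(
            {
                "indicator": "CM",
                "rank": rp,
                "label": f"CM 0-{int(rp * band_width_um)} um",
                "value": v,
                "defined": not math.isnan(v),
                "reason": "" if not math.isnan(v) else "zero total density",
            }
        )
    return GradientIndicators(rows)
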