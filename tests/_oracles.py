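"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: distances
are exact point-to-segment minima over all boundary polylines, and the
concordance index is a literal double loop over all subject pairs.
"""

from __future__ import annotations

import numpy as np


def min_distance_to_polylines(points: np.ndarray, polylines) -> np.ndarray:
    """Exact minimum Euclidean distance from each point to any polyline segment.

    ``points``: (n, 2) array of (x, y); ``polylines``: iterable of (m, 2)
    vertex arrays.
    """
    points = np.asarray(points, dtype=float)
    best = np.full(len(points), np.inf)
    for verts in polylines:
        v = np.asarray(verts, dtype=float)
        a, b = v[:-1], v[1:]
        ab = b - a
        ab2 = (ab**2).sum(axis=1)
        ab2[ab2 == 0] = 1.0
        for i, p in enumerate(points):
            t = np.clip(((p - a) * ab).sum(axis=1) / ab2, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.hypot(*(proj - p).T).min()
            if d < best[i]:
                best[i] = d
    return best


def brute_force_band_ranks(
    labels: np.ndarray,
    polylines_um,
    pixel_size_um: float,
    band_width_um: float,
    max_width_um: float,
    epithelium: int,
    stroma: int,
    sentinel: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference band ranks: exact segment distances + ceil(d/w) rule.

    Returns (rank raster, distance raster in µm).
    """
    H, W = labels.shape
    yy, xx = np.mgrid[0:H, 0:W]
    centers = np.column_stack(
        [(xx.ravel() + 0.5) * pixel_size_um, (yy.ravel() + 0.5) * pixel_size_um]
    )
    d = min_distance_to_polylines(centers, polylines_um).reshape(H, W)
    mag = np.maximum(1, np.ceil(d / band_width_um).astype(int))
    rank = np.full(labels.shape, sentinel, dtype=int)
    max_rank = int(round(max_width_um / band_width_um))
    inside = mag <= max_rank
    epi = (labels == epithelium) & inside
    stro = (labels == stroma) & inside
    rank[epi] = mag[epi]
    rank[stro] = -mag[stro]
    return rank, d


def brute_force_concordance(risks, times, events) -> float:
    """Harrell's C by explicit enumeration of all subject pairs.

    A pair is comparable if the earlier time is an event (or the two times
    differ and the shorter one had an event).  Concordant when the higher
    risk has the shorter time; risk ties count 1/2.
    """
    risks = np.asarray(risks, float)
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                # tied times are convention-dependent; the tests use
                # continuous times so this branch is never exercised
                continue
            first, second = (i, j) if times[i] < times[j] else (j, i)
            if not events[first]:
                continue  # earlier subject censored: not comparable
            den += 1
            if risks[first] > risks[second]:
                num += 1.0
            elif risks[first] == risks[second]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den
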