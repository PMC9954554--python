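"""Extraction of the epithelium-stroma interface from a labeled mask.

The interface is the set of maximal boundary polylines along which an
epithelium pixel is 4-adjacent to a stroma pixel.  Boundary pieces where
either neighbour is artifact or background are excluded, so cautery or
slide-edge contours never generate interface-zone bands.

Tracing works on inter-pixel "cracks": each epithelium/stroma 4-adjacent
pixel pair contributes the unit segment of the pixel lattice separating the
two pixels.  Cracks sharing lattice corners are chained into maximal
polylines; the staircase chain is then smoothed (crack midpoints, terminal
corners kept for open chains) and simplified with Douglas-Peucker at 0.8 px
tolerance, which brings traced lengths of straight and circular fixtures
within a fraction of a percent of their analytic values.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

from .masks import EPITHELIUM, STROMA, TissueMask

#: Douglas-Peucker tolerance for boundary simplification, in pixels.
SIMPLIFY_TOL_PX = 0.8


@dataclass
class Boundary:
    """One maximal interface polyline, in micrometre coordinates (x, y)."""

    vertices: np.ndarray  # (n, 2) float, µm
    closed: bool

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("boundary needs at least two (x, y) vertices")

    @property
    def length_um(self) -> float:
        """Summed segment length of the polyline."""
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def as_linestring(self) -> LineString:
        return LineString(self.vertices)


@dataclass
class InterfaceSet:
    """All epithelium-stroma boundary polylines of one slide."""

    boundaries: list[Boundary] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boundaries)

    def __iter__(self):
        return iter(self.boundaries)

    @property
    def total_length_um(self) -> float:
        return float(sum(b.length_um for b in self.boundaries))

    def lengths_um(self) -> np.ndarray:
        return np.array([b.length_um for b in self.boundaries])


def _crack_segments(labels: np.ndarray) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Unit crack segments between epithelium/stroma 4-adjacent pixel pairs.

    Segments are given as corner-node pairs ``((row, col), (row, col))`` on the
    pixel-corner lattice.  Only pairs where one pixel is epithelium and the
    other stroma are emitted, which implements artifact/background exclusion.
    """
    segs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    a = labels
    left, right = a[:, :-1], a[:, 1:]
    pair = ((left == EPITHELIUM) & (right == STROMA)) | (
        (left == STROMA) & (right == EPITHELIUM)
    )
    for y, x in zip(*np.nonzero(pair)):
        segs.append(((int(y), int(x) + 1), (int(y) + 1, int(x) + 1)))
    top, bot = a[:-1, :], a[1:, :]
    pair = ((top == EPITHELIUM) & (bot == STROMA)) | (
        (top == STROMA) & (bot == EPITHELIUM)
    )
    for y, x in zip(*np.nonzero(pair)):
        segs.append(((int(y) + 1, int(x)), (int(y) + 1, int(x) + 1)))
    return segs


def _chain_segments(segs) -> list[list[tuple[int, int]]]:
    """Chain crack segments into maximal corner-vertex polylines.

    Open chains are started from odd-degree corners; remaining segments form
    cycles.  At degree-4 corners (checkerboard configurations) the walk
    prefers to continue straight through, a deterministic tie-break.
    """
    adj: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, (a, b) in enumerate(segs):
        adj[a].append(i)
        adj[b].append(i)
    used = np.zeros(len(segs), dtype=bool)
    chains: list[list[tuple[int, int]]] = []

    def walk(start: tuple[int, int], first: int) -> list[tuple[int, int]]:
        pts = [start]
        node, i = start, first
        while True:
            used[i] = True
            a, b = segs[i]
            node = b if a == node else a
            pts.append(node)
            options = [j for j in adj[node] if not used[j]]
            if not options:
                break
            prev = (node[0] - pts[-2][0], node[1] - pts[-2][1])
            nxt = options[0]
            for j in options:
                a2, b2 = segs[j]
                other = b2 if a2 == node else a2
                if (other[0] - node[0], other[1] - node[1]) == prev:
                    nxt = j  # straight ahead
                    break
            i = nxt
        return pts

    for node in sorted(n for n, lst in adj.items() if len(lst) % 2 == 1):
        for i in adj[node]:
            if not used[i]:
                chains.append(walk(node, i))
    for i in range(len(segs)):
        if not used[i]:
            chains.append(walk(segs[i][0], i))
    return chains


def _smooth_chain(pts: list[tuple[int, int]], closed: bool, tol_px: float) -> np.ndarray:
    """Midpoint-smooth a corner chain and Douglas-Peucker simplify it.

    Returns (n, 2) vertices as (x, y) in pixel-corner units.
    """
    p = np.asarray(pts, dtype=float)  # (row, col)
    mids = (p[:-1] + p[1:]) / 2.0
    if closed:
        verts = np.vstack([mids, mids[:1]])
    else:
        verts = np.vstack([p[:1], mids, p[-1:]])
    xy = verts[:, ::-1]  # (x, y)
    ls = LineString(xy).simplify(tol_px)
    return np.asarray(ls.coords)


def extract_interface(mask: TissueMask, simplify_tol_px: float = SIMPLIFY_TOL_PX) -> InterfaceSet:
    """Trace every maximal epithelium-stroma boundary polyline of a mask.

    A mask with no epithelium-stroma adjacency anywhere yields an empty
    :class:`InterfaceSet` (not an error).
    """
    segs = _crack_segments(mask.labels)
    boundaries: list[Boundary] = []
    for pts in _chain_segments(segs):
        closed = pts[0] == pts[-1]
        xy_px = _smooth_chain(pts, closed, simplify_tol_px)
        boundaries.append(Boundary(xy_px * mask.pixel_size_um, closed=closed))
    return InterfaceSet(boundaries)


def filter_short_boundaries(
    interfaces: InterfaceSet, min_length_um: float = 1000.0
) -> InterfaceSet:
    """Drop boundary polylines shorter than ``min_length_um``.

    The threshold is inclusive on the keep side: a boundary of exactly
    ``min_length_um`` is retained.  Short boundaries typically come from
    small misclassified foci and only add noise to the band statistics.
    """
    if not np.isfinite(min_length_um) or min_length_um < 0:
        raise ValueError(f"min_length_um must be >= 0, got {min_length_um!r}")
    kept = [b for b in interfaces if b.length_um >= min_length_um]
    return InterfaceSet(kept)
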