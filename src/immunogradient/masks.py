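"""Labeled tissue masks: the geometric substrate of the interface-zone analysis.

A slide is represented as a single-channel label raster in which every pixel
is background, epithelium, stroma, or artifact, together with the physical
pixel size in micrometres.  Masks come from an upstream tissue classifier
(or from the synthetic generator in :mod:`immunogradient.synthetic`); this
package never classifies tissue itself.

Coordinate convention: pixel ``(row, col)`` has its centre at
``x = (col + 0.5) * pixel_size_um``, ``y = (row + 0.5) * pixel_size_um``,
with y increasing downwards (image convention).  Pixel *corners* therefore
sit at integer multiples of the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# canonical label codes
BACKGROUND = 0
EPITHELIUM = 1
STROMA = 2
ARTIFACT = 3

LABEL_NAMES = {
    BACKGROUND: "background",
    EPITHELIUM: "epithelium",
    STROMA: "stroma",
    ARTIFACT: "artifact",
}

#: default scan resolution (20x magnification); overridable everywhere
DEFAULT_PIXEL_SIZE_UM = 0.5


@dataclass
class TissueMask:
    """Label raster plus physical scale.

    Parameters
    ----------
    labels
        2-D integer array with values in ``{BACKGROUND, EPITHELIUM, STROMA,
        ARTIFACT}``.
    pixel_size_um
        Side length of one pixel in micrometres (> 0).
    """

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("mask labels must be a non-empty 2-D raster")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um!r}")
        bad = ~np.isin(self.labels, list(LABEL_NAMES))
        if bad.any():
            raise ValueError(
                f"mask contains {int(bad.sum())} pixels with labels outside "
                f"{sorted(LABEL_NAMES)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def area_mm2(self, label: int) -> float:
        """Total area of one label class in mm^2."""
        n = int(np.count_nonzero(self.labels == label))
        return n * self.pixel_size_um**2 * 1e-6


def read_mask(
    path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    label_codes: dict[str, int] | None = None,
) -> TissueMask:
    """Read a label raster from a PNG or TIFF file.

    ``label_codes`` maps class names (``background``/``epithelium``/``stroma``/
    ``artifact``) to the integer codes used in the file; by default the file is
    assumed to use the canonical codes 0..3.
    """
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:  # paletted/multichannel export of a label image
        raw = raw[..., 0]
    if label_codes is not None:
        canon = {"background": BACKGROUND, "epithelium": EPITHELIUM,
                 "stroma": STROMA, "artifact": ARTIFACT}
        out = np.full(raw.shape, -1, dtype=np.int64)
        for name, code in label_codes.items():
            if name not in canon:
                raise ValueError(f"unknown label class {name!r}")
            out[raw == code] = canon[name]
        if (out < 0).any():
            raise ValueError("mask contains pixel values not covered by label_codes")
        raw = out
    return TissueMask(raw.astype(np.int64), pixel_size_um=pixel_size_um)


def write_mask(path, mask: TissueMask) -> None:
    """Write the label raster (canonical codes) as PNG or TIFF."""
    import imageio.v3 as iio

    iio.imwrite(path, mask.labels.astype(np.uint8))


def rasterize_geojson(
    geojson,
    pixel_size_um: float,
    shape: tuple[int, int] | None = None,
) -> TissueMask:
    """Rasterize polygon annotations into a :class:`TissueMask`.

    ``geojson`` is a GeoJSON ``FeatureCollection`` (dict, or path to a file)
    whose features carry a ``class`` property in
    ``{"epithelium", "stroma", "artifact"}`` and polygon coordinates in
    micrometres.  Classes are painted stroma first, then epithelium, then
    artifact, so artifact annotations always win; unpainted pixels remain
    background.  ``shape`` (rows, cols) defaults to the bounding box of all
    polygons.
    """
    import json

    from shapely.geometry import shape as shp_shape
    from skimage.draw import polygon as draw_polygon

    if isinstance(geojson, (str, bytes)) or hasattr(geojson, "__fspath__"):
        with open(geojson) as fh:
            geojson = json.load(fh)
    feats = geojson.get("features", [])
    class_code = {"epithelium": EPITHELIUM, "stroma": STROMA, "artifact": ARTIFACT}
    geoms: list[tuple[int, object]] = []
    for feat in feats:
        cls = (feat.get("properties") or {}).get("class")
        if cls not in class_code:
            raise ValueError(f"feature class {cls!r} not in {sorted(class_code)}")
        geoms.append((class_code[cls], shp_shape(feat["geometry"])))
    if not geoms:
        raise ValueError("GeoJSON contains no features")

    if shape is None:
        xmax = max(g.bounds[2] for _, g in geoms)
        ymax = max(g.bounds[3] for _, g in geoms)
        shape = (int(np.ceil(ymax / pixel_size_um)), int(np.ceil(xmax / pixel_size_um)))
    labels = np.full(shape, BACKGROUND, dtype=np.int64)

    def paint(geom, code):
        polys = getattr(geom, "geoms", [geom])
        for poly in polys:
            ext = np.asarray(poly.exterior.coords) / pixel_size_um
            rr, cc = draw_polygon(ext[:, 1], ext[:, 0], shape=shape)
            keep = np.ones(len(rr), bool)
            for ring in poly.interiors:
                hole = np.asarray(ring.coords) / pixel_size_um
                hr, hc = draw_polygon(hole[:, 1], hole[:, 0], shape=shape)
                hole_set = set(zip(hr.tolist(), hc.tolist()))
                keep &= ~np.fromiter(
                    ((r, c) in hole_set for r, c in zip(rr, cc)), bool, len(rr)
                )
            labels[rr[keep], cc[keep]] = code

    for code in (STROMA, EPITHELIUM, ARTIFACT):  # paint order fixes precedence
        for c, geom in geoms:
            if c == code:
                paint(geom, code)
    return TissueMask(labels, pixel_size_um=pixel_size_um)
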