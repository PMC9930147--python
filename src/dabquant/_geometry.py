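"""Raster/vector conversions shared by scoring, validation and IO.

All region arithmetic in this package happens on the rasterized tissue
grid (pixel-centre coordinates, x = column, y = row); polygons are the
interchange format.  Conversions are accurate to about one boundary pixel,
which is the stated tolerance for every region metric.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.validation import make_valid
from skimage import measure

__all__ = [
    "rasterize_polygons",
    "mask_to_polygons",
    "as_polygon_list",
    "remove_small_components",
    "fill_small_holes",
]


def remove_small_components(mask: np.ndarray, min_px: float) -> np.ndarray:
    """Drop connected components with fewer than ``min_px`` pixels."""
    from scipy import ndimage as ndi

    if min_px <= 1 or not mask.any():
        return mask
    labels, n = ndi.label(mask)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def fill_small_holes(mask: np.ndarray, max_px: float) -> np.ndarray:
    """Fill background components (holes) smaller than ``max_px`` pixels."""
    from scipy import ndimage as ndi

    if max_px <= 0 or not mask.any():
        return mask
    labels, n = ndi.label(~mask)
    sizes = np.bincount(labels.ravel())
    fill = sizes < max_px
    fill[0] = False
    return mask | fill[labels]


def as_polygon_list(geoms) -> list[Polygon]:
    """Flatten polygons/multipolygons into a list of simple polygons."""
    out: list[Polygon] = []
    for g in geoms:
        if g.is_empty:
            continue
        g = make_valid(g)
        if isinstance(g, Polygon):
            out.append(g)
        elif isinstance(g, MultiPolygon):
            out.extend(p for p in g.geoms if not p.is_empty)
        elif hasattr(g, "geoms"):  # GeometryCollection
            out.extend(as_polygon_list(g.geoms))
    return out


def rasterize_polygons(polygons, shape: tuple[int, int]) -> np.ndarray:
    """Burn polygons (pixel coordinates) into a boolean (H, W) mask.

    A pixel is set when the polygon covers its centre (boundary points
    included), so rasterize(mask_to_polygons(mask)) reproduces the mask.
    """
    import shapely

    out = np.zeros(shape, dtype=bool)
    for poly in as_polygon_list(polygons):
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.ceil(minx - 1e-9)))
        c1 = min(shape[1] - 1, int(np.floor(maxx + 1e-9)))
        r0 = max(0, int(np.ceil(miny - 1e-9)))
        r1 = min(shape[0] - 1, int(np.floor(maxy + 1e-9)))
        if c1 < c0 or r1 < r0:
            continue
        xs = np.arange(c0, c1 + 1)
        ys = np.arange(r0, r1 + 1)
        xx, yy = np.meshgrid(xs, ys)
        pts = shapely.points(xx.ravel(), yy.ravel())
        shapely.prepare(poly)
        inside = shapely.covers(poly, pts).reshape(xx.shape)
        out[r0 : r1 + 1, c0 : c1 + 1] |= inside
    return out


def mask_to_polygons(mask: np.ndarray, min_ring_area_px: float = 1.0):
    """Vectorize a boolean mask into simple shapely polygons with holes.

    Each connected component becomes one polygon: its longest 0.5-level
    contour is the exterior, remaining contours are interior rings.
    """
    from scipy import ndimage as ndi

    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask)
    polygons: list[Polygon] = []
    for idx, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        crop = labels[sl] == idx
        padded = np.pad(crop, 1).astype(float)
        contours = measure.find_contours(padded, 0.5)
        rings = []
        for contour in contours:
            # (row, col) -> (x, y) in parent-image coordinates
            xy = np.stack(
                [
                    contour[:, 1] - 1 + sl[1].start,
                    contour[:, 0] - 1 + sl[0].start,
                ],
                axis=1,
            )
            if len(xy) >= 4:
                rings.append(xy)
        if not rings:
            continue
        rings.sort(key=lambda r: -Polygon(r).area)
        holes = [
            r for r in rings[1:] if Polygon(r).area >= min_ring_area_px
        ]
        poly = Polygon(rings[0], holes)
        if not poly.is_valid:
            poly = make_valid(poly)
        polygons.extend(as_polygon_list([poly]))
    return polygons
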