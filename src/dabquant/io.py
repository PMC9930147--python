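"""Readers and writers binding the pipeline stages together.

Formats: 8-bit RGB TIFF/PNG for images; GeoJSON FeatureCollections in
pixel coordinates (with a top-level ``pixel_size_um`` property and
QuPath-style ``properties.classification``) for regions and cells; CSV
(UTF-8, comma, header, ``.`` decimal, areas in µm²) for tables; YAML for
configuration and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image
from shapely.geometry import mapping, shape

from ._geometry import as_polygon_list, mask_to_polygons
from .scoring import ClassifierConfig, FragmentResult, RegionSet
from .segmentation import CellObject, CellSegmentation, TissueMask
from .stains import RGBImage, StainMatrix

__all__ = [
    "read_image",
    "write_image",
    "read_tissue_mask",
    "write_tissue_mask",
    "write_regions_geojson",
    "read_regions_geojson",
    "cells_to_dataframe",
    "write_cells_csv",
    "read_cells_csv",
    "write_cells_geojson",
    "write_fragment_result_csv",
    "write_provenance",
    "read_stain_matrix_yaml",
]

CELL_CSV_COLUMNS = [
    "id",
    "centroid_x",
    "centroid_y",
    "nucleus_area_um2",
    "cell_area_um2",
    "nucleus_dab_od",
    "cytoplasm_dab_od",
    "nucleus_hema_od",
    "cytoplasm_hema_od",
    "label",
]


# ---------------------------------------------------------------- images

def read_image(path, pixel_size_um: float = 0.25) -> RGBImage:
    """Read an 8-bit RGB TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    return RGBImage(pixels.astype(np.uint8), pixel_size_um=pixel_size_um)


def write_image(image: RGBImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels.astype(np.uint8))
    else:
        Image.fromarray(image.pixels.astype(np.uint8)).save(path)


def read_tissue_mask(path, pixel_size_um: float) -> TissueMask:
    """Read a tissue mask image (any nonzero pixel counts as tissue)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    return TissueMask(np.asarray(arr) > 0, pixel_size_um)


def write_tissue_mask(tissue: TissueMask, path) -> None:
    arr = (tissue.mask.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


# --------------------------------------------------------------- geojson

def write_regions_geojson(regions: RegionSet, path, extra=None) -> None:
    features = []
    for i, poly in enumerate(regions.polygons):
        features.append(
            {
                "type": "Feature",
                "id": i,
                "geometry": mapping(poly),
                "properties": {
                    "source": regions.source,
                    "classification": {"name": "Positive region"},
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "pixel_size_um": regions.tissue.pixel_size_um,
        "source": regions.source,
        "features": features,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc))


def read_regions_geojson(path, tissue: TissueMask, source=None) -> RegionSet:
    doc = json.loads(Path(path).read_text())
    polys = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        polys.extend(as_polygon_list([geom]))
    return RegionSet(source or doc.get("source", "unknown"), polys, tissue)


def write_cells_geojson(seg: CellSegmentation, path) -> None:
    """One Feature per cell polygon, measurements in properties."""
    from scipy import ndimage as ndi

    features = []
    slices = ndi.find_objects(seg.cell_labels)
    for cell in seg.cells:
        sl = slices[cell.id - 1]
        if sl is None:
            continue
        crop = seg.cell_labels[sl] == cell.id
        polys = mask_to_polygons(crop)
        moved = []
        from shapely import affinity

        for p in polys:
            moved.append(
                affinity.translate(p, xoff=sl[1].start, yoff=sl[0].start)
            )
        if not moved:
            continue
        geometry = mapping(moved[0]) if len(moved) == 1 else {
            "type": "MultiPolygon",
            "coordinates": [mapping(p)["coordinates"] for p in moved],
        }
        features.append(
            {
                "type": "Feature",
                "id": cell.id,
                "geometry": geometry,
                "properties": {
                    "classification": {"name": cell.label.capitalize()},
                    "measurements": {
                        "nucleus_area_um2": cell.nucleus_area_um2,
                        "cell_area_um2": cell.cell_area_um2,
                        **{
                            f"{comp}_{stain}_od": v
                            for (comp, stain), v in cell.mean_od.items()
                        },
                    },
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "pixel_size_um": seg.pixel_size_um,
        "source": "cells",
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


# ------------------------------------------------------------------ csv

def cells_to_dataframe(cells: list[CellObject]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append(
            {
                "id": c.id,
                "centroid_x": c.centroid_xy[0],
                "centroid_y": c.centroid_xy[1],
                "nucleus_area_um2": c.nucleus_area_um2,
                "cell_area_um2": c.cell_area_um2,
                "nucleus_dab_od": c.mean_od.get(("nucleus", "dab"), np.nan),
                "cytoplasm_dab_od": c.mean_od.get(
                    ("cytoplasm", "dab"), np.nan
                ),
                "nucleus_hema_od": c.mean_od.get(
                    ("nucleus", "hematoxylin"), np.nan
                ),
                "cytoplasm_hema_od": c.mean_od.get(
                    ("cytoplasm", "hematoxylin"), np.nan
                ),
                "label": c.label,
            }
        )
    return pd.DataFrame(rows, columns=CELL_CSV_COLUMNS)


def write_cells_csv(cells: list[CellObject], path) -> None:
    cells_to_dataframe(cells).to_csv(path, index=False)


def read_cells_csv(path) -> list[CellObject]:
    df = pd.read_csv(path)
    cells = []
    for row in df.itertuples(index=False):
        mean_od = {}
        for comp, stain, col in [
            ("nucleus", "dab", "nucleus_dab_od"),
            ("cytoplasm", "dab", "cytoplasm_dab_od"),
            ("nucleus", "hematoxylin", "nucleus_hema_od"),
            ("cytoplasm", "hematoxylin", "cytoplasm_hema_od"),
        ]:
            if hasattr(row, col):
                mean_od[(comp, stain)] = float(getattr(row, col))
        cells.append(
            CellObject(
                id=int(row.id),
                centroid_xy=(float(row.centroid_x), float(row.centroid_y)),
                nucleus_area_um2=float(row.nucleus_area_um2),
                cell_area_um2=float(row.cell_area_um2),
                mean_od=mean_od,
                label=getattr(row, "label", "unclassified"),
                cytoplasm_missing=bool(
                    np.isnan(mean_od.get(("cytoplasm", "dab"), np.nan))
                ),
            )
        )
    return cells


def write_fragment_result_csv(results, path) -> None:
    """One row per fragment; accepts a single result or a mapping."""
    if isinstance(results, FragmentResult):
        results = {"fragment": results}
    rows = []
    for frag_id, res in results.items():
        rows.append(
            {
                "fragment_id": frag_id,
                "marker": res.classifier.marker_name,
                "compartment": res.classifier.compartment,
                "threshold_od": res.classifier.threshold_od,
                "n_cells": res.n_cells,
                "n_positive": res.n_positive,
                "n_unclassified": res.n_unclassified,
                "positive_area_fraction": res.positive_area_fraction,
                "category": res.category,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------------- yaml

def write_provenance(path, config: dict) -> None:
    """Echo the fully resolved run configuration next to the outputs."""
    from . import __version__

    doc = {"dabquant_version": __version__, **_yaml_safe(config)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, StainMatrix):
        return obj.vectors.tolist()
    if isinstance(obj, ClassifierConfig):
        return {
            "marker_name": obj.marker_name,
            "compartment": obj.compartment,
            "threshold_od": obj.threshold_od,
        }
    if hasattr(obj, "to_dict"):
        return _yaml_safe(obj.to_dict())
    return obj


def read_stain_matrix_yaml(path) -> StainMatrix:
    """Load a stain matrix from YAML: keys hematoxylin, dab, [residual]."""
    doc = yaml.safe_load(Path(path).read_text())
    return StainMatrix.from_unnormalized(
        h=doc["hematoxylin"], dab=doc["dab"], residual=doc.get("residual")
    )
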