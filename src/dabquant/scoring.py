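"""Cell positivity, fragment-level scores and positive-region delineation.

A cell is positive when the mean DAB optical density of the configured
compartment reaches the marker threshold: nuclear DAB OD >= 0.65 for the
"strong HIF-1α" preset, cytoplasmic DAB OD >= 0.10 for the pimonidazole
(PIMO) preset.  The fragment-level readout is the positive area fraction —
area of all positive cells over area of all classified cells — collapsed
to the semi-quantitative category 0 (<1%), 1 (1–33%) or 2 (>33%).

Positive regions ("hotspots") are delineated from the spatial density of
positive-cell centroids: the count inside a disk kernel, normalised to
cells/mm², thresholded, cleaned morphologically and vectorized to
polygons.  A fragment whose detected cell density is too low produces an
empty region set even when the detected cells themselves are positive —
a known false-negative mode of density-based delineation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from ._geometry import (
    fill_small_holes,
    mask_to_polygons,
    rasterize_polygons,
    remove_small_components,
)
from .segmentation import CellObject, TissueMask

__all__ = [
    "ClassifierConfig",
    "PIMO_PRESET",
    "HIF1A_PRESET",
    "FragmentResult",
    "RegionParams",
    "RegionSet",
    "NoCellsError",
    "classify_cells",
    "positive_area_fraction",
    "categorical_score",
    "score_fragment",
    "delineate_regions",
]


class NoCellsError(RuntimeError):
    """Raised when a fragment has no classified cells to score."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Compartment-specific DAB-OD positivity rule for one marker."""

    marker_name: str
    compartment: str  # "nucleus" | "cytoplasm"
    threshold_od: float
    stain: str = "dab"

    def __post_init__(self) -> None:
        if self.compartment not in ("nucleus", "cytoplasm"):
            raise ValueError("compartment must be 'nucleus' or 'cytoplasm'")
        if self.threshold_od <= 0:
            raise ValueError("threshold_od must be strictly positive")


#: Cytoplasmic pimonidazole hypoxia marker: weak staining, low threshold.
PIMO_PRESET = ClassifierConfig("pimo", "cytoplasm", 0.10)
#: Nuclear HIF-1α, counting only strongly stained nuclei as positive.
HIF1A_PRESET = ClassifierConfig("hif1a", "nucleus", 0.65)

PRESETS = {"pimo": PIMO_PRESET, "hif1a": HIF1A_PRESET}


@dataclass
class ClassificationCounts:
    n_cells: int
    n_positive: int
    n_negative: int
    n_unclassified: int


def classify_cells(
    cells: list[CellObject], config: ClassifierConfig
) -> ClassificationCounts:
    """Label each cell positive/negative by the configured threshold.

    The threshold is inclusive (mean OD == threshold is positive).  Cells
    whose configured compartment has no measurement (e.g. fully clipped
    cytoplasm) become ``unclassified`` and are excluded from any later
    fraction, with their count reported.
    """
    key = (config.compartment, config.stain)
    n_pos = n_neg = n_unc = 0
    if cells and all(key not in c.mean_od for c in cells):
        raise ValueError(
            f"no cell carries a measurement for compartment "
            f"{config.compartment!r} / stain {config.stain!r}"
        )
    for cell in cells:
        value = cell.mean_od.get(key, math.nan)
        if math.isnan(value):
            cell.label = "unclassified"
            n_unc += 1
        elif value >= config.threshold_od:
            cell.label = "positive"
            n_pos += 1
        else:
            cell.label = "negative"
            n_neg += 1
    return ClassificationCounts(len(cells), n_pos, n_neg, n_unc)


def positive_area_fraction(cells: list[CellObject]) -> float:
    """Area of all positive cells over area of all classified cells.

    Whole-cell areas are used for both marker types and in both numerator
    and denominator; unclassified cells appear in neither.
    """
    total = pos = 0.0
    n_classified = 0
    for cell in cells:
        if cell.label == "unclassified":
            continue
        n_classified += 1
        total += cell.cell_area_um2
        if cell.label == "positive":
            pos += cell.cell_area_um2
    if n_classified == 0 or total <= 0:
        raise NoCellsError("no classified cells in fragment")
    return pos / total


def categorical_score(fraction: float) -> int:
    """Collapse a positive area fraction to the 3-category score.

    0: <1% positive; 1: 1–33% (both bounds included); 2: >33%.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction < 0.01:
        return 0
    if fraction <= 0.33:
        return 1
    return 2


@dataclass
class FragmentResult:
    """Fragment-level positivity summary with full parameter provenance."""

    n_cells: int
    n_positive: int
    n_unclassified: int
    positive_area_fraction: float
    category: int
    classifier: ClassifierConfig
    params: dict = field(default_factory=dict)


def score_fragment(
    cells: list[CellObject],
    config: ClassifierConfig,
    params: dict | None = None,
) -> FragmentResult:
    """Classify, compute the positive area fraction and its category."""
    counts = classify_cells(cells, config)
    fraction = positive_area_fraction(cells)
    return FragmentResult(
        n_cells=counts.n_cells,
        n_positive=counts.n_positive,
        n_unclassified=counts.n_unclassified,
        positive_area_fraction=fraction,
        category=categorical_score(fraction),
        classifier=config,
        params=dict(params or {}),
    )


@dataclass
class RegionParams:
    """Positive-region (hotspot) delineation settings.

    density_mode 'absolute' thresholds the positive-cell density in
    cells/mm²; 'fraction' thresholds the local fraction of positive cells
    among all detected cells (requires at least one cell in the kernel).
    """

    density_radius_um: float = 50.0
    min_positive_density: float = 500.0  # cells/mm² ('absolute' mode)
    min_positive_fraction: float = 0.3  # ('fraction' mode)
    density_mode: str = "absolute"
    min_region_area_um2: float = 5000.0
    fill_holes_below_um2: float = 2000.0

    def __post_init__(self) -> None:
        if self.density_radius_um <= 0:
            raise ValueError("density_radius_um must be strictly positive")
        if self.min_region_area_um2 <= 0 or self.fill_holes_below_um2 < 0:
            raise ValueError("region areas must be positive")
        if self.density_mode not in ("absolute", "fraction"):
            raise ValueError("density_mode must be 'absolute' or 'fraction'")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RegionSet:
    """A named set of positive-region polygons over one tissue mask."""

    source: str  # "dia", an observer id, or "consensus"
    polygons: list  # shapely Polygons, pixel coordinates
    tissue: TissueMask

    def rasterize(self) -> np.ndarray:
        mask = rasterize_polygons(self.polygons, self.tissue.shape)
        return mask & self.tissue.mask

    @property
    def total_area_um2(self) -> float:
        return float(self.rasterize().sum()) * self.tissue.pixel_size_um**2

    @property
    def is_empty(self) -> bool:
        return len(self.polygons) == 0


def _disk_kernel(radius_px: float) -> np.ndarray:
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= radius_px**2).astype(float)


def _centroid_count_surface(
    cells, tissue: TissueMask, radius_um: float, predicate
) -> np.ndarray:
    """Count centroids matching ``predicate`` within a disk of each pixel."""
    px = tissue.pixel_size_um
    impulse = np.zeros(tissue.shape, dtype=float)
    for cell in cells:
        if predicate(cell):
            x, y = cell.centroid_xy
            r, c = int(round(y)), int(round(x))
            if 0 <= r < impulse.shape[0] and 0 <= c < impulse.shape[1]:
                impulse[r, c] += 1.0
    kernel = _disk_kernel(radius_um / px)
    counts = fftconvolve(impulse, kernel, mode="same")
    return np.maximum(counts, 0.0)


def delineate_regions(
    cells: list[CellObject],
    tissue: TissueMask,
    params: RegionParams | None = None,
    source: str = "dia",
) -> RegionSet:
    """Delineate regions with a high density of positive cells.

    Builds the positive-cell density surface with a hard disk kernel on
    centroids, thresholds it, intersects with tissue, fills small holes,
    drops small components and vectorizes the result.  An empty region
    set is a valid output.
    """
    params = params or RegionParams()
    px = tissue.pixel_size_um
    pos_counts = _centroid_count_surface(
        cells, tissue, params.density_radius_um,
        lambda c: c.label == "positive",
    )
    disk_area_mm2 = math.pi * (params.density_radius_um / 1000.0) ** 2
    if params.density_mode == "absolute":
        density = pos_counts / disk_area_mm2
        mask = density >= params.min_positive_density
    else:
        all_counts = _centroid_count_surface(
            cells, tissue, params.density_radius_um,
            lambda c: c.label != "unclassified",
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(all_counts > 0.5, pos_counts / all_counts, 0.0)
        mask = frac >= params.min_positive_fraction
    mask &= tissue.mask

    mask = fill_small_holes(mask, params.fill_holes_below_um2 / px**2)
    mask = remove_small_components(mask, params.min_region_area_um2 / px**2)
    mask &= tissue.mask

    return RegionSet(source, mask_to_polygons(mask), tissue)
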