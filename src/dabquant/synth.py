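"""Synthetic H-DAB fragment generator with exact ground truth.

Every component of the pipeline is testable without slide data by
rendering fragments whose truth is known by construction: a smoothed
random tissue blob, non-overlapping elliptical nuclei placed by hard-core
dart throwing, Bernoulli positivity with locally elevated probability
inside hotspot polygons, hematoxylin painted on nuclei over a faint
tissue background, DAB painted in the compartment appropriate to the
marker mode (nucleus + a small halo for nuclear markers, the true
cytoplasmic annulus for cytoplasmic markers), truncated-Gaussian OD
noise, and finally Beer–Lambert composition to an 8-bit RGB image.

Two documented failure modes of real slides can be injected: red-blood-
cell pigment (DAB-tinted, hematoxylin-free clumps that the low
cytoplasmic threshold picks up as false positives) and the edge effect
(non-specific extra cytoplasmic DAB in a rim along the tissue border,
which does NOT change ground-truth labels).

All randomness flows from a single generator seeded by ``config.seed``:
the same config yields a bit-identical image and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from shapely import affinity
from shapely.geometry import Point, Polygon

from ._geometry import as_polygon_list, mask_to_polygons, rasterize_polygons
from .scoring import RegionSet, categorical_score
from .segmentation import TissueMask, expand_cells
from .stains import HDAB_DEFAULT, ODImage, RGBImage, StainMatrix, compose
from .validation import ObserverAnnotations

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_fragment",
    "add_rbc_artifacts",
    "add_edge_effect",
    "make_observer_annotations",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed."""


@dataclass
class SynthConfig:
    """All knobs of the fragment generator (units in field names).

    Defaults describe a moderately cellular tumour fragment at a 0.5 µm
    pixel (20x-equivalent sampling of a 40x scan): ~500 cells in a blob
    covering just under half of a 1536 px canvas, nucleus radii around
    4 µm, strong nuclear hematoxylin (~0.8 OD) over a faint tissue
    background, positive-cell DAB around 0.6 OD against a ~0.02 OD
    negative background, and 0.03 OD measurement noise.
    """

    seed: int = 0
    canvas_px: int = 1536
    pixel_size_um: float = 0.5

    # tissue blob: radial Fourier perturbation of a disk
    tissue_radius_frac: float = 0.38
    tissue_wobble: float = 0.07

    # cells
    n_cells: int = 500
    nucleus_radius_um_mean: float = 4.0
    nucleus_radius_um_sd: float = 0.5
    nucleus_radius_um_bounds: tuple[float, float] = (2.5, 6.0)
    nucleus_aspect_max: float = 1.3
    min_gap_um: float = 4.0
    max_placement_attempts_per_cell: int = 200

    # marker model
    marker_mode: str = "cytoplasmic"  # or "nuclear"
    base_positive_fraction: float = 0.05
    n_hotspots: int = 0
    hotspot_radius_um: float = 100.0
    hotspot_positive_fraction: float = 0.9
    cytoplasm_expansion_um: float = 6.0
    dab_nuclear_halo_um: float = 2.0

    # optical densities
    hema_od_mean: float = 0.8
    hema_od_sd: float = 0.1
    background_hema_od: float = 0.08
    dab_od_positive_mean: float = 0.6
    dab_od_positive_sd: float = 0.1
    dab_od_negative_mean: float = 0.02
    dab_od_negative_sd: float = 0.01
    noise_sd: float = 0.03

    # artifacts (disabled by default)
    rbc_count: int = 0
    rbc_cluster_radius_um: float = 15.0
    rbc_dab_od: float = 0.15
    edge_rim_width_um: float = 0.0
    edge_extra_dab_od: float = 0.2

    stains: StainMatrix = field(default_factory=lambda: HDAB_DEFAULT)

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_positive_fraction <= 1.0:
            raise ValueError("base_positive_fraction must lie in [0, 1]")
        if not 0.0 <= self.hotspot_positive_fraction <= 1.0:
            raise ValueError("hotspot_positive_fraction must lie in [0, 1]")
        if self.marker_mode not in ("nuclear", "cytoplasmic"):
            raise ValueError("marker_mode must be 'nuclear' or 'cytoplasmic'")
        if self.pixel_size_um <= 0 or self.canvas_px <= 0:
            raise ValueError("canvas and pixel size must be positive")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["stains"] = self.stains.vectors.tolist()
        return d


@dataclass
class GroundTruth:
    """Everything the generator knows about one rendered fragment."""

    tissue: TissueMask
    nucleus_labels: np.ndarray  # generation-time rasters, 0 = background
    cell_labels: np.ndarray
    cell_ids: np.ndarray
    centroids_xy: np.ndarray  # (n, 2) float pixel coordinates
    nucleus_radii_um: np.ndarray
    positive: np.ndarray  # (n,) bool ground-truth labels
    positive_area_fraction: float
    category: int
    hotspot_polygons: list  # shapely, clipped to tissue
    artifact_masks: dict  # {"rbc": mask|None, "edge_rim": mask|None}
    painted_dab_od: np.ndarray  # DAB OD field before noise
    config: SynthConfig

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())

    def hotspot_regionset(self) -> RegionSet:
        return RegionSet("truth", list(self.hotspot_polygons), self.tissue)


def _tissue_blob(config: SynthConfig, rng: np.random.Generator) -> TissueMask:
    """Smoothed random blob occupying roughly 40-50% of the canvas."""
    n_theta = 720
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    r = np.full(n_theta, config.tissue_radius_frac * config.canvas_px)
    for k in range(2, 7):
        amp = rng.uniform(-config.tissue_wobble, config.tissue_wobble)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        r *= 1.0 + amp * np.cos(k * theta + phase) / math.sqrt(k)
    cx = cy = config.canvas_px / 2.0
    xy = np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1)
    mask = rasterize_polygons([Polygon(xy)], (config.canvas_px,) * 2)
    return TissueMask(mask, config.pixel_size_um)


def _place_nuclei(
    config: SynthConfig,
    tissue: TissueMask,
    rng: np.random.Generator,
):
    """Hard-core dart throwing: centres, radii, aspects, orientations."""
    px = config.pixel_size_um
    inside_dist = ndi.distance_transform_edt(tissue.mask, sampling=px)
    h, w = tissue.shape
    lo, hi = config.nucleus_radius_um_bounds

    centers: list[tuple[float, float]] = []
    radii: list[float] = []  # effective (major) radius, µm
    mean_radii: list[float] = []
    aspects: list[float] = []
    angles: list[float] = []
    arr_c = np.empty((0, 2))
    arr_r = np.empty((0,))

    attempts_left = config.max_placement_attempts_per_cell * config.n_cells
    while len(centers) < config.n_cells:
        if attempts_left <= 0:
            raise PlacementError(
                f"placed only {len(centers)}/{config.n_cells} nuclei; "
                "tissue too small for the requested density/gap"
            )
        attempts_left -= 1
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        radius = float(
            np.clip(
                rng.normal(config.nucleus_radius_um_mean,
                           config.nucleus_radius_um_sd),
                lo, hi,
            )
        )
        aspect = rng.uniform(1.0, config.nucleus_aspect_max)
        major = radius * math.sqrt(aspect)
        ri, ci = min(int(y), h - 1), min(int(x), w - 1)
        if inside_dist[ri, ci] < major + px:
            continue
        if len(centers) > 0:
            d_um = np.hypot(arr_c[:, 0] - x, arr_c[:, 1] - y) * px
            if np.any(d_um < arr_r + major + config.min_gap_um):
                continue
        centers.append((x, y))
        radii.append(major)
        mean_radii.append(radius)
        aspects.append(aspect)
        angles.append(rng.uniform(0.0, math.pi))
        arr_c = np.append(arr_c, [[x, y]], axis=0)
        arr_r = np.append(arr_r, [major])
    return (
        np.array(centers),
        np.array(mean_radii),
        np.array(aspects),
        np.array(angles),
    )


def _paint_nuclei(
    shape, centers, radii_um, aspects, angles, pixel_size_um
) -> np.ndarray:
    """Rasterize elliptical nuclei into a label image (1..n)."""
    labels = np.zeros(shape, dtype=np.int32)
    h, w = shape
    for i in range(len(centers)):
        x, y = centers[i]
        r_px = radii_um[i] / pixel_size_um
        a1 = r_px * math.sqrt(aspects[i])  # semi-major
        a2 = r_px / math.sqrt(aspects[i])  # semi-minor
        phi = angles[i]
        half = int(math.ceil(a1)) + 1
        r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
        c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dx, dy = xx - x, yy - y
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        inside = (u / a1) ** 2 + (v / a2) ** 2 <= 1.0
        patch = labels[r0:r1, c0:c1]
        patch[inside & (patch == 0)] = i + 1
    return labels


def _make_hotspots(
    config: SynthConfig, tissue: TissueMask, rng: np.random.Generator
) -> list[Polygon]:
    """Circular hotspots placed in the tissue interior, clipped to tissue."""
    if config.n_hotspots <= 0:
        return []
    px = config.pixel_size_um
    inside_dist = ndi.distance_transform_edt(tissue.mask, sampling=px)
    r_px = config.hotspot_radius_um / px
    candidates = np.argwhere(inside_dist >= 0.8 * config.hotspot_radius_um)
    if len(candidates) == 0:
        raise PlacementError("tissue too small for the requested hotspots")
    tissue_polys = mask_to_polygons(tissue.mask)
    from shapely.ops import unary_union

    tissue_geom = unary_union(tissue_polys)
    hotspots: list[Polygon] = []
    guard = 0
    while len(hotspots) < config.n_hotspots and guard < 2000:
        guard += 1
        ri, ci = candidates[rng.integers(len(candidates))]
        circle = Point(float(ci), float(ri)).buffer(r_px, quad_segs=64)
        if any(circle.intersects(hs) for hs in hotspots):
            continue
        clipped = circle.intersection(tissue_geom)
        hotspots.extend(as_polygon_list([clipped]))
    if len(hotspots) < config.n_hotspots:
        raise PlacementError("could not place non-overlapping hotspots")
    return hotspots


def _value_map(labels: np.ndarray, values_by_id: np.ndarray) -> np.ndarray:
    """Expand per-cell values onto a label raster (0 stays 0)."""
    lut = np.zeros(len(values_by_id) + 1, dtype=float)
    lut[1:] = values_by_id
    return lut[labels]


def add_rbc_artifacts(
    dab_od: np.ndarray,
    tissue: TissueMask,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add DAB-tinted, hematoxylin-free red-blood-cell clumps in place.

    Returns the artifact mask.  Each clump is a union of a few
    overlapping disks around a random tissue-interior point; its pixels
    gain ``config.rbc_dab_od`` of DAB and no hematoxylin, emulating the
    faint brown erythrocyte pigment that a low cytoplasmic threshold
    misreads as positive staining.
    """
    mask = np.zeros(tissue.shape, dtype=bool)
    if config.rbc_count <= 0:
        return mask
    px = tissue.pixel_size_um
    inside_dist = ndi.distance_transform_edt(tissue.mask, sampling=px)
    candidates = np.argwhere(inside_dist >= 0.5 * config.rbc_cluster_radius_um)
    if len(candidates) == 0:
        return mask
    h, w = tissue.shape
    for _ in range(config.rbc_count):
        ri, ci = candidates[rng.integers(len(candidates))]
        n_blobs = rng.integers(4, 8)
        for _ in range(int(n_blobs)):
            off = rng.normal(0.0, 0.35 * config.rbc_cluster_radius_um / px, 2)
            br = rng.uniform(0.6, 1.0) * config.rbc_cluster_radius_um / px
            y0, x0 = ri + off[0], ci + off[1]
            half = int(math.ceil(br)) + 1
            r0, r1 = max(0, int(y0) - half), min(h, int(y0) + half + 1)
            c0, c1 = max(0, int(x0) - half), min(w, int(x0) + half + 1)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            blob = (yy - y0) ** 2 + (xx - x0) ** 2 <= br**2
            mask[r0:r1, c0:c1] |= blob
    mask &= tissue.mask
    dab_od[mask] += config.rbc_dab_od
    return mask


def add_edge_effect(
    dab_od: np.ndarray,
    tissue: TissueMask,
    cyto_labels: np.ndarray,
    centroids_xy: np.ndarray,
    config: SynthConfig,
) -> np.ndarray:
    """Add non-specific cytoplasmic DAB to cells near the tissue border.

    Models the "edge effect" of tissue lifting during staining: every
    cell whose centroid lies within ``edge_rim_width_um`` of the tissue
    boundary gains ``edge_extra_dab_od`` on its cytoplasm.  Ground-truth
    labels are deliberately NOT changed.  Returns the rim mask.
    """
    if config.edge_rim_width_um <= 0:
        return np.zeros(tissue.shape, dtype=bool)
    px = tissue.pixel_size_um
    inside_dist = ndi.distance_transform_edt(tissue.mask, sampling=px)
    rim = tissue.mask & (inside_dist <= config.edge_rim_width_um)
    if len(centroids_xy) == 0:
        return rim
    rows = np.clip(np.round(centroids_xy[:, 1]).astype(int), 0,
                   tissue.shape[0] - 1)
    cols = np.clip(np.round(centroids_xy[:, 0]).astype(int), 0,
                   tissue.shape[1] - 1)
    in_rim = rim[rows, cols]
    extra = _value_map(
        cyto_labels, np.where(in_rim, config.edge_extra_dab_od, 0.0)
    )
    dab_od += extra
    return rim


def generate_fragment(config: SynthConfig) -> tuple[RGBImage, GroundTruth]:
    """Render one synthetic H-DAB fragment and its ground truth."""
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    shape = (config.canvas_px, config.canvas_px)

    tissue = _tissue_blob(config, rng)
    hotspots = _make_hotspots(config, tissue, rng)
    centers, radii_um, aspects, angles = _place_nuclei(config, tissue, rng)
    n = len(centers)

    nucleus_labels = _paint_nuclei(
        shape, centers, radii_um, aspects, angles, px
    )
    cell_labels = expand_cells(
        nucleus_labels, tissue, config.cytoplasm_expansion_um
    )
    cyto_labels = np.where(nucleus_labels == 0, cell_labels, 0)

    # positivity: elevated Bernoulli rate inside hotspots
    p_local = np.full(n, config.base_positive_fraction)
    if hotspots:
        hs_mask = rasterize_polygons(hotspots, shape)
        rows = np.clip(np.round(centers[:, 1]).astype(int), 0, shape[0] - 1)
        cols = np.clip(np.round(centers[:, 0]).astype(int), 0, shape[1] - 1)
        p_local[hs_mask[rows, cols]] = config.hotspot_positive_fraction
    positive = rng.uniform(size=n) < p_local

    # stain painting
    hema = np.where(tissue.mask, config.background_hema_od, 0.0)
    hema_amp = np.clip(
        rng.normal(config.hema_od_mean, config.hema_od_sd, n), 0.3, None
    )
    hema += _value_map(nucleus_labels, hema_amp)

    dab_pos = np.clip(
        rng.normal(config.dab_od_positive_mean, config.dab_od_positive_sd, n),
        0.2, None,
    )
    dab_neg = np.clip(
        rng.normal(config.dab_od_negative_mean, config.dab_od_negative_sd, n),
        0.0, None,
    )
    dab = np.zeros(shape, dtype=float)
    if n > 0:
        if config.marker_mode == "cytoplasmic":
            values = np.where(positive, dab_pos, dab_neg)
            dab += _value_map(cyto_labels, values)
        else:  # nuclear: DAB on nucleus plus a small halo (stain spread)
            halo_labels = expand_cells(
                nucleus_labels, tissue, config.dab_nuclear_halo_um
            )
            dab += _value_map(halo_labels, np.where(positive, dab_pos, 0.0))
            dab += _value_map(nucleus_labels,
                              np.where(positive, 0.0, dab_neg))

    artifact_masks: dict = {"rbc": None, "edge_rim": None}
    if config.rbc_count > 0:
        artifact_masks["rbc"] = add_rbc_artifacts(dab, tissue, config, rng)
    if config.edge_rim_width_um > 0:
        artifact_masks["edge_rim"] = add_edge_effect(
            dab, tissue, cyto_labels, centers, config
        )

    painted_dab = dab.copy()

    # truncated-Gaussian OD noise on the two real stain channels
    noisy_hema = np.clip(hema + rng.normal(0, config.noise_sd, shape), 0, None)
    noisy_dab = np.clip(dab + rng.normal(0, config.noise_sd, shape), 0, None)
    channels = np.stack(
        [noisy_hema, noisy_dab, np.zeros(shape)], axis=2
    )
    stain_od = ODImage(channels, ("hematoxylin", "dab", "residual"), px)
    image = compose(stain_od, config.stains)

    # ground-truth fragment score from the generation-time rasters
    if n > 0:
        cell_areas = np.bincount(cell_labels.ravel(), minlength=n + 1)[1:]
        total = float(cell_areas.sum())
        frac = float(cell_areas[positive].sum()) / total if total else 0.0
    else:
        frac = 0.0

    truth = GroundTruth(
        tissue=tissue,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        cell_ids=np.arange(1, n + 1),
        centroids_xy=centers,
        nucleus_radii_um=radii_um,
        positive=positive,
        positive_area_fraction=frac,
        category=categorical_score(frac),
        hotspot_polygons=hotspots,
        artifact_masks=artifact_masks,
        painted_dab_od=painted_dab,
        config=config,
    )
    return image, truth


def make_observer_annotations(
    reference: RegionSet,
    seed: int,
    n_observers: int = 3,
    shift_sd_um: float = 6.0,
    buffer_sd_um: float = 8.0,
    miss_prob: float = 0.0,
) -> ObserverAnnotations:
    """Derive pseudo-observer delineations by perturbing reference regions.

    Each observer independently shifts every reference polygon by a
    Gaussian offset, dilates or erodes it by a Gaussian margin and may
    skip it entirely with ``miss_prob`` — a simple stand-in for human
    delineation variability used to exercise the validation module.
    """
    rng = np.random.default_rng(seed)
    px = reference.tissue.pixel_size_um
    observers: dict[str, RegionSet] = {}
    for i in range(n_observers):
        polys = []
        for poly in reference.polygons:
            if rng.uniform() < miss_prob:
                continue
            dx, dy = rng.normal(0.0, shift_sd_um / px, 2)
            margin = rng.normal(0.0, buffer_sd_um / px)
            perturbed = affinity.translate(poly, xoff=dx, yoff=dy).buffer(
                margin
            )
            polys.extend(as_polygon_list([perturbed]))
        observers[f"observer{i + 1}"] = RegionSet(
            f"observer{i + 1}", polys, reference.tissue
        )
    return ObserverAnnotations(observers, reference.tissue)
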