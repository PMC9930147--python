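"""Tissue detection, nucleus detection, cell expansion and measurement."""

import math

import numpy as np
import pytest

import dabquant as dq
from dabquant.segmentation import build_cells
from dabquant.stains import STAIN_CHANNELS, ODImage

PX = 0.5  # µm/px used by hand-built fixtures


def stain_image(hema=None, dab=None, shape=None, pixel_size=PX):
    shape = shape or hema.shape
    channels = np.zeros(shape + (3,))
    if hema is not None:
        channels[..., 0] = hema
    if dab is not None:
        channels[..., 1] = dab
    return ODImage(channels, STAIN_CHANNELS, pixel_size)


def full_tissue(shape, pixel_size=PX):
    return dq.TissueMask(np.ones(shape, dtype=bool), pixel_size)


def paint_disk(arr, cy, cx, r, value):
    yy, xx = np.mgrid[: arr.shape[0], : arr.shape[1]]
    arr[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value
    return arr


# ------------------------------------------------------------- tissue

def test_detected_tissue_area_matches_generated(small_fragment, small_analysis):
    _, _, truth = small_fragment
    detected = small_analysis.tissue
    assert detected.area_um2 == pytest.approx(truth.tissue.area_um2, rel=0.05)


def test_uniform_white_image_raises_no_tissue():
    od = stain_image(hema=np.zeros((128, 128)))
    with pytest.raises(dq.NoTissueFoundError):
        dq.detect_tissue(od)


def test_tissue_mask_invariant_to_white_padding():
    hema = np.zeros((320, 320))
    paint_disk(hema, 160, 160, 130, 0.4)
    mask = dq.detect_tissue(stain_image(hema=hema)).mask
    padded = np.pad(hema, 40)
    mask_p = dq.detect_tissue(stain_image(hema=padded)).mask
    assert (mask_p[40:-40, 40:-40] == mask).all()
    assert mask_p.sum() == mask.sum()


# ------------------------------------------------------------- nuclei

def test_blank_tissue_has_zero_nuclei():
    tissue = full_tissue((128, 128))
    labels = dq.detect_nuclei(np.zeros((128, 128)), tissue)
    assert labels.max() == 0


def test_separated_nuclei_found_with_accurate_centroids():
    config = dq.SynthConfig(seed=4, n_cells=10, canvas_px=512)
    image, truth = dq.generate_fragment(config)
    od = dq.deconvolve(dq.rgb_to_od(image))
    tissue = dq.detect_tissue(od)
    labels = dq.detect_nuclei(od.channel("hematoxylin"), tissue)
    assert labels.max() == 10
    seg = build_cells(
        labels, labels, tissue, dq.SegmentationParams()
    )
    detected = np.array([c.centroid_xy for c in seg.cells])
    match = dq.match_centroids(
        detected, truth.centroids_xy, max_dist_um=2 * config.pixel_size_um,
        pixel_size_um=config.pixel_size_um,
    )
    assert match.n_matched == 10


def test_touching_nuclei_split_by_watershed():
    hema = np.zeros((128, 128))
    paint_disk(hema, 64, 54, 8, 0.8)
    paint_disk(hema, 64, 68, 8, 0.8)  # overlapping pair
    tissue = full_tissue(hema.shape)
    split = dq.detect_nuclei(
        hema, tissue, dq.SegmentationParams(split_touching=True)
    )
    merged = dq.detect_nuclei(
        hema, tissue, dq.SegmentationParams(split_touching=False)
    )
    assert split.max() == 2
    assert merged.max() == 1


def test_detection_is_deterministic(small_analysis):
    od = small_analysis.stain_od
    tissue = small_analysis.tissue
    a = dq.detect_nuclei(od.channel("hematoxylin"), tissue)
    b = dq.detect_nuclei(od.channel("hematoxylin"), tissue)
    assert (a == b).all()


def test_nuclei_respect_area_gate_and_tissue():
    hema = np.zeros((128, 128))
    paint_disk(hema, 30, 30, 4, 0.8)  # ~12.5 µm² at 0.5 µm/px: kept
    paint_disk(hema, 90, 90, 40, 0.8)  # ~1250 µm²: too large
    tissue = full_tissue(hema.shape)
    labels = dq.detect_nuclei(hema, tissue)
    assert labels.max() == 1
    # the surviving detection is the small nucleus, not a blob shard
    rows, cols = np.where(labels == 1)
    assert abs(rows.mean() - 30) < 2 and abs(cols.mean() - 30) < 2


# ------------------------------------------------------- cell expansion

def test_single_nucleus_expansion_matches_disk_area():
    shape = (200, 200)
    nuclei = np.zeros(shape, dtype=np.int32)
    r_px = 8  # 4 µm at 0.5 µm/px
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    nuclei[(yy - 100) ** 2 + (xx - 100) ** 2 <= r_px**2] = 1
    tissue = full_tissue(shape)
    e_um = 5.0
    cells = dq.expand_cells(nuclei, tissue, e_um)
    area_um2 = (cells == 1).sum() * PX**2
    expected = math.pi * (r_px * PX + e_um) ** 2
    assert area_um2 == pytest.approx(expected, rel=0.03)


def test_two_nuclei_partition_at_perpendicular_bisector():
    shape = (120, 240)
    nuclei = np.zeros(shape, dtype=np.int32)
    paint_disk(nuclei, 60, 80, 6, 1)
    paint_disk(nuclei, 60, 120, 6, 2)
    tissue = full_tissue(shape)
    cells = dq.expand_cells(nuclei, tissue, 12.0)
    assert ((cells == 1) & (cells == 2)).sum() == 0
    cols_1 = np.where(cells == 1)[1]
    cols_2 = np.where(cells == 2)[1]
    # boundary at x=100 (midpoint), tolerance one pixel
    assert cols_1.max() <= 100
    assert cols_2.min() >= 100


def test_expansion_clipped_to_tissue_but_contains_nucleus():
    shape = (100, 100)
    tissue_mask = np.zeros(shape, dtype=bool)
    tissue_mask[:, :50] = True
    nuclei = np.zeros(shape, dtype=np.int32)
    paint_disk(nuclei, 50, 46, 5, 1)  # nucleus at tissue border
    nuclei[~tissue_mask] = 0
    tissue = dq.TissueMask(tissue_mask, PX)
    cells = dq.expand_cells(nuclei, tissue, 5.0)
    assert ((cells == 1) & ~tissue_mask).sum() == 0
    assert (cells[nuclei == 1] == 1).all()


def test_expansion_monotone_in_radius():
    shape = (150, 150)
    nuclei = np.zeros(shape, dtype=np.int32)
    paint_disk(nuclei, 75, 75, 6, 1)
    paint_disk(nuclei, 40, 40, 6, 2)
    tissue = full_tissue(shape)
    small = dq.expand_cells(nuclei, tissue, 3.0)
    large = dq.expand_cells(nuclei, tissue, 7.0)
    for cid in (1, 2):
        assert ((small == cid) & (large != cid)).sum() == 0


def test_cells_disjoint_and_within_tissue(small_analysis):
    seg = small_analysis.segmentation
    cell_area = sum(c.cell_area_um2 for c in seg.cells)
    assert cell_area <= seg.tissue.area_um2
    assert (seg.cell_labels[~seg.tissue.mask] == 0).all()
    # nucleus ⊆ cell for every cell
    assert (
        (seg.nucleus_labels > 0) & (seg.cell_labels != seg.nucleus_labels)
    ).sum() == 0


# --------------------------------------------------------- measurement

def _toy_segmentation(shape=(60, 60)):
    nuclei = np.zeros(shape, dtype=np.int32)
    paint_disk(nuclei, 30, 30, 5, 1)
    tissue = full_tissue(shape)
    cells = dq.expand_cells(nuclei, tissue, 4.0)
    return build_cells(nuclei, cells, tissue, dq.SegmentationParams())


def test_uniform_od_gives_uniform_means():
    seg = _toy_segmentation()
    od = stain_image(dab=np.full(seg.tissue.shape, 0.5),
                     shape=seg.tissue.shape)
    seg = dq.measure_cells(seg, od)
    cell = seg.cells[0]
    assert cell.mean_od[("nucleus", "dab")] == pytest.approx(0.5)
    assert cell.mean_od[("cytoplasm", "dab")] == pytest.approx(0.5)


def test_mean_over_handbuilt_three_pixel_mask():
    shape = (8, 8)
    nuclei = np.zeros(shape, dtype=np.int32)
    nuclei[2, 2:5] = 1
    tissue = full_tissue(shape)
    seg = build_cells(nuclei, nuclei.copy(), tissue, dq.SegmentationParams())
    dab = np.zeros(shape)
    dab[2, 2:5] = [0.1, 0.2, 0.6]
    seg = dq.measure_cells(seg, stain_image(dab=dab, shape=shape))
    assert seg.cells[0].mean_od[("nucleus", "dab")] == pytest.approx(0.3)


def test_empty_cytoplasm_is_flagged_not_zero():
    shape = (8, 8)
    nuclei = np.zeros(shape, dtype=np.int32)
    nuclei[2:5, 2:5] = 1
    tissue = full_tissue(shape)
    seg = build_cells(nuclei, nuclei.copy(), tissue, dq.SegmentationParams())
    seg = dq.measure_cells(seg, stain_image(dab=np.ones(shape), shape=shape))
    cell = seg.cells[0]
    assert cell.cytoplasm_missing
    assert math.isnan(cell.mean_od[("cytoplasm", "dab")])


def test_nuclear_marker_confined_to_nuclei():
    config = dq.SynthConfig(
        seed=9, n_cells=60, canvas_px=768, marker_mode="nuclear",
        base_positive_fraction=1.0, dab_od_positive_mean=1.0,
    )
    image, truth = dq.generate_fragment(config)
    analysis = dq.analyze_fragment(image, dq.HIF1A_PRESET)
    nuc = [c.mean_od[("nucleus", "dab")] for c in analysis.segmentation.cells]
    cyto = [
        c.mean_od[("cytoplasm", "dab")]
        for c in analysis.segmentation.cells
        if not c.cytoplasm_missing
    ]
    assert np.median(nuc) > 0.65
    assert np.median(cyto) < 0.25
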