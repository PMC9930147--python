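"""One-call convenience wrapper: image in, cells + score + regions out."""

from __future__ import annotations

from dataclasses import dataclass

from .scoring import (
    ClassifierConfig,
    FragmentResult,
    RegionParams,
    RegionSet,
    delineate_regions,
    score_fragment,
)
from .segmentation import (
    CellSegmentation,
    SegmentationParams,
    TissueMask,
    TissueParams,
    segment_fragment,
)
from .stains import HDAB_DEFAULT, ODImage, RGBImage, StainMatrix, deconvolve, rgb_to_od

__all__ = ["FragmentAnalysis", "analyze_fragment"]


@dataclass
class FragmentAnalysis:
    """Everything the pipeline produced for one fragment."""

    stain_od: ODImage
    tissue: TissueMask
    segmentation: CellSegmentation
    result: FragmentResult
    regions: RegionSet


def analyze_fragment(
    image: RGBImage,
    classifier: ClassifierConfig,
    seg_params: SegmentationParams | None = None,
    region_params: RegionParams | None = None,
    tissue_params: TissueParams | None = None,
    tissue: TissueMask | None = None,
    stains: StainMatrix = HDAB_DEFAULT,
) -> FragmentAnalysis:
    """Run deconvolution, segmentation, scoring and region delineation."""
    stain_od = deconvolve(rgb_to_od(image), stains)
    seg = segment_fragment(
        stain_od, tissue=tissue, params=seg_params, tissue_params=tissue_params
    )
    result = score_fragment(
        seg.cells, classifier,
        params={"segmentation": seg.params.to_dict()},
    )
    regions = delineate_regions(seg.cells, seg.tissue, region_params)
    return FragmentAnalysis(stain_od, seg.tissue, seg, result, regions)
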