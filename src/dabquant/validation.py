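"""Observer-validation metrics for categorical scores and region overlap.

Two validation questions are covered.  For categorical positivity scores,
agreement between two raters (or between the automated score and an
observer consensus) is summarised by percent agreement and the linearly
weighted Cohen's kappa, which corrects for agreement expected by chance
under independent marginals.  For positive-region delineations, a
consensus reference (area covered by at least ``min_observers`` of the
observers) is compared with the automated region set through object-level
false-positive / false-negative calls and area-level PPV, sensitivity and
Dice, plus false-positive / false-negative percentages of the tissue area.

Two different false-positive references deliberately coexist: an
automated region counts as a false-positive *object* (and contributes to
the FP tissue-area percentage) only when it misses the union of ALL
observers, while the pixel-level FP inside PPV and Dice is taken against
the consensus.  Undefined 0/0 metrics are reported as None with a reason,
never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scoring import RegionSet
from .segmentation import TissueMask

__all__ = [
    "RatingTable",
    "AgreementResult",
    "ObserverAnnotations",
    "RegionCalls",
    "OverlapMetrics",
    "DetectionMatch",
    "weighted_kappa",
    "consensus_regions",
    "region_confusion",
    "area_overlap_metrics",
    "match_centroids",
]


@dataclass
class RatingTable:
    """Paired categorical scores from two raters over the same fragments."""

    fragment_ids: list
    rater_a: np.ndarray
    rater_b: np.ndarray
    n_categories: int = 3

    def __post_init__(self) -> None:
        self.rater_a = np.asarray(self.rater_a, dtype=int)
        self.rater_b = np.asarray(self.rater_b, dtype=int)
        if len(self.rater_a) != len(self.rater_b):
            raise ValueError("rater score vectors must have equal length")
        if len(self.rater_a) != len(self.fragment_ids):
            raise ValueError("fragment_ids must match score vectors")
        if len(self.rater_a) < 1:
            raise ValueError("at least one rated fragment is required")
        for scores in (self.rater_a, self.rater_b):
            if scores.min() < 0 or scores.max() >= self.n_categories:
                raise ValueError("scores must lie in 0..n_categories-1")

    @property
    def n(self) -> int:
        return len(self.rater_a)


@dataclass
class AgreementResult:
    """Confusion matrix, percent agreement and weighted kappa."""

    confusion: np.ndarray  # (k, k) counts, rows = rater_a
    percent_agreement: float  # 0..100
    weighted_kappa: float | None  # None when chance disagreement is 0
    weight_scheme: str = "linear"
    kappa_undefined_reason: str | None = None


def linear_weights(k: int) -> np.ndarray:
    """Linear disagreement weights w_ij = |i - j| / (k - 1)."""
    idx = np.arange(k)
    if k == 1:
        return np.zeros((1, 1))
    return np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def confusion_matrix(table: RatingTable) -> np.ndarray:
    k = table.n_categories
    conf = np.zeros((k, k), dtype=float)
    np.add.at(conf, (table.rater_a, table.rater_b), 1.0)
    return conf


def kappa_from_confusion(
    observed: np.ndarray, weights: np.ndarray | None = None
) -> float | None:
    """Weighted kappa = 1 - Σ w·O / Σ w·E with E from the marginals.

    Returns None when the expected weighted disagreement is zero (both
    raters constant and identical), where kappa is undefined.
    """
    observed = np.asarray(observed, dtype=float)
    n = observed.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    if weights is None:
        weights = linear_weights(observed.shape[0])
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    denom = float((weights * expected).sum())
    if denom == 0.0:
        return None
    return 1.0 - float((weights * observed).sum()) / denom


def weighted_kappa(table: RatingTable) -> AgreementResult:
    """Percent agreement and linearly weighted Cohen's kappa."""
    conf = confusion_matrix(table)
    agreement = 100.0 * float(np.trace(conf)) / table.n
    kappa = kappa_from_confusion(conf, linear_weights(table.n_categories))
    return AgreementResult(
        confusion=conf,
        percent_agreement=agreement,
        weighted_kappa=kappa,
        kappa_undefined_reason=(
            None if kappa is not None
            else "both raters constant and identical (no chance disagreement)"
        ),
    )


@dataclass
class ObserverAnnotations:
    """Region delineations of one fragment by one or more observers."""

    observers: dict  # observer id -> RegionSet
    tissue: TissueMask

    def __post_init__(self) -> None:
        if not self.observers:
            raise ValueError("at least one observer is required")

    def union_mask(self) -> np.ndarray:
        """Pixels delineated by ANY observer."""
        out = np.zeros(self.tissue.shape, dtype=bool)
        for rs in self.observers.values():
            out |= rs.rasterize()
        return out

    def coverage_counts(self) -> np.ndarray:
        """Per-pixel number of observers covering that pixel."""
        counts = np.zeros(self.tissue.shape, dtype=np.int32)
        for rs in self.observers.values():
            counts += rs.rasterize().astype(np.int32)
        return counts


def consensus_regions(
    annotations: ObserverAnnotations, min_observers: int = 2
) -> RegionSet:
    """Reference-standard regions: covered by >= min_observers observers."""
    if len(annotations.observers) < min_observers:
        raise ValueError(
            f"need at least {min_observers} observers, "
            f"got {len(annotations.observers)}"
        )
    from ._geometry import mask_to_polygons

    mask = annotations.coverage_counts() >= min_observers
    return RegionSet("consensus", mask_to_polygons(mask), annotations.tissue)


@dataclass
class RegionCalls:
    """Object-level region verdicts.

    An automated region is a false positive when it was delineated by no
    observer at all; a consensus region is a false negative when the
    automated set missed it.  Overlaps below ``overlap_epsilon_frac`` of
    the region's own area count as a miss.
    """

    false_positive_indices: list[int] = field(default_factory=list)
    matched_dia_indices: list[int] = field(default_factory=list)
    false_negative_indices: list[int] = field(default_factory=list)
    matched_consensus_indices: list[int] = field(default_factory=list)

    @property
    def n_false_positive(self) -> int:
        return len(self.false_positive_indices)

    @property
    def n_false_negative(self) -> int:
        return len(self.false_negative_indices)


def region_confusion(
    dia: RegionSet,
    annotations: ObserverAnnotations,
    min_observers: int = 2,
    overlap_epsilon_frac: float = 0.01,
) -> RegionCalls:
    """Classify each region object as matched, false positive or negative."""
    calls = RegionCalls()
    any_mask = annotations.union_mask()
    consensus = consensus_regions(annotations, min_observers)
    dia_mask = dia.rasterize()

    from ._geometry import rasterize_polygons

    for i, poly in enumerate(dia.polygons):
        pmask = rasterize_polygons([poly], dia.tissue.shape) & dia.tissue.mask
        area = pmask.sum()
        if area == 0:
            continue
        overlap = (pmask & any_mask).sum()
        if overlap < overlap_epsilon_frac * area:
            calls.false_positive_indices.append(i)
        else:
            calls.matched_dia_indices.append(i)

    for j, poly in enumerate(consensus.polygons):
        pmask = rasterize_polygons([poly], dia.tissue.shape) & dia.tissue.mask
        area = pmask.sum()
        if area == 0:
            continue
        overlap = (pmask & dia_mask).sum()
        if overlap < overlap_epsilon_frac * area:
            calls.false_negative_indices.append(j)
        else:
            calls.matched_consensus_indices.append(j)
    return calls


@dataclass
class OverlapMetrics:
    """Area-level overlap between automated and reference regions.

    ppv, sensitivity and dice are None when undefined (0/0), with the
    reason recorded.  fp_fraction_of_tissue uses the ANY-observer union
    as reference; fn_fraction_of_tissue uses the consensus.
    """

    tp_area_um2: float
    fp_area_um2: float
    fn_area_um2: float
    ppv: float | None
    sensitivity: float | None
    dice: float | None
    fp_fraction_of_tissue: float
    fn_fraction_of_tissue: float
    undefined: dict = field(default_factory=dict)


def area_overlap_metrics(
    dia: RegionSet,
    consensus: RegionSet,
    any_observer_union: RegionSet | None = None,
    tissue: TissueMask | None = None,
) -> OverlapMetrics:
    """PPV, sensitivity, Dice and FP/FN tissue-area fractions.

    All sets are rasterized on the tissue grid and clipped to tissue.
    Dice is ``2·TP / (2·TP + FP + FN)``: undefined when both sets are
    empty, 0 when exactly one is.
    """
    tissue = tissue or dia.tissue
    if not tissue.mask.any():
        raise ValueError("empty tissue mask")
    px2 = tissue.pixel_size_um**2

    dia_mask = dia.rasterize() & tissue.mask
    ref_mask = consensus.rasterize() & tissue.mask
    any_mask = (
        any_observer_union.rasterize() & tissue.mask
        if any_observer_union is not None
        else ref_mask
    )

    tp = float((dia_mask & ref_mask).sum())
    fp = float((dia_mask & ~ref_mask).sum())
    fn = float((~dia_mask & ref_mask).sum())

    undefined: dict = {}
    if dia_mask.any():
        ppv = tp / (tp + fp)
    else:
        ppv = None
        undefined["ppv"] = "automated region set is empty (0/0)"
    if ref_mask.any():
        sensitivity = tp / (tp + fn)
    else:
        sensitivity = None
        undefined["sensitivity"] = "reference region set is empty (0/0)"
    if dia_mask.any() or ref_mask.any():
        dice = 2.0 * tp / (2.0 * tp + fp + fn)
    else:
        dice = None
        undefined["dice"] = "both region sets empty (0/0)"

    tissue_area = float(tissue.mask.sum())
    fp_tissue = float((dia_mask & ~any_mask).sum()) / tissue_area
    fn_tissue = float((ref_mask & ~dia_mask).sum()) / tissue_area

    return OverlapMetrics(
        tp_area_um2=tp * px2,
        fp_area_um2=fp * px2,
        fn_area_um2=fn * px2,
        ppv=ppv,
        sensitivity=sensitivity,
        dice=dice,
        fp_fraction_of_tissue=fp_tissue,
        fn_fraction_of_tissue=fn_tissue,
        undefined=undefined,
    )


@dataclass
class DetectionMatch:
    """One-to-one matching of detected vs ground-truth object centroids."""

    n_detected: int
    n_truth: int
    n_matched: int
    matched_pairs: list  # (detected index, truth index)
    distances_um: np.ndarray

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0


def match_centroids(
    detected_xy,
    truth_xy,
    max_dist_um: float = 5.0,
    pixel_size_um: float = 1.0,
) -> DetectionMatch:
    """Optimal one-to-one centroid matching within ``max_dist_um``.

    Uses a minimum-total-distance assignment (Hungarian algorithm) on the
    pairwise distance matrix, discarding pairs beyond the cut-off; the
    resulting matched count gives detection precision and recall.
    """
    from scipy.optimize import linear_sum_assignment

    detected = np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth_xy, dtype=float).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return DetectionMatch(
            len(detected), len(truth), 0, [], np.array([])
        )
    d = np.hypot(
        detected[:, None, 0] - truth[None, :, 0],
        detected[:, None, 1] - truth[None, :, 1],
    ) * pixel_size_um
    cut = max_dist_um
    cost = np.where(d <= cut, d, 1e9)
    rows, cols = linear_sum_assignment(cost)
    keep = d[rows, cols] <= cut
    pairs = list(zip(rows[keep].tolist(), cols[keep].tolist()))
    return DetectionMatch(
        len(detected), len(truth), len(pairs), pairs, d[rows[keep], cols[keep]]
    )
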