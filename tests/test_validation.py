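"""Agreement statistics and region-overlap validation metrics."""

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import box

import dabquant as dq
from dabquant._geometry import mask_to_polygons
from dabquant.validation import kappa_from_confusion, linear_weights


def table(a, b, k=3):
    a = list(a)
    return dq.RatingTable(list(range(len(a))), a, list(b), n_categories=k)


def brute_force_weighted_kappa(observed, k=3):
    """Independent double-loop evaluation of 1 - Σw·O / Σw·E."""
    observed = np.asarray(observed, dtype=float)
    n = observed.sum()
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = abs(i - j) / (k - 1)
            e = observed[i, :].sum() * observed[:, j].sum() / n
            num += w * observed[i, j]
            den += w * e
    return None if den == 0 else 1.0 - num / den


def random_confusion(rng, k=3, max_count=20):
    while True:
        o = rng.integers(0, max_count + 1, size=(k, k))
        if o.sum() > 0:
            return o


# ---------------------------------------------------------------- kappa

def test_identical_ratings_give_perfect_agreement():
    r = dq.weighted_kappa(table([0, 1, 2, 1, 0], [0, 1, 2, 1, 0]))
    assert r.weighted_kappa == pytest.approx(1.0)
    assert r.percent_agreement == pytest.approx(100.0)


def test_degenerate_marginals_give_zero_kappa():
    r = dq.weighted_kappa(table([0] * 6, [1] * 6))
    assert r.weighted_kappa == pytest.approx(0.0)
    assert r.percent_agreement == pytest.approx(0.0)


def test_constant_identical_raters_kappa_undefined():
    r = dq.weighted_kappa(table([1] * 5, [1] * 5))
    assert r.weighted_kappa is None
    assert r.kappa_undefined_reason
    assert r.percent_agreement == pytest.approx(100.0)


def test_kappa_matches_brute_force_oracle(rng):
    for _ in range(200):
        o = random_confusion(rng)
        expected = brute_force_weighted_kappa(o)
        got = kappa_from_confusion(o)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_kappa_matches_sklearn_linear_weights(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    for _ in range(20):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        t = table(a, b)
        ours = dq.weighted_kappa(t).weighted_kappa
        ref = sklearn_metrics.cohen_kappa_score(
            a, b, labels=[0, 1, 2], weights="linear"
        )
        assert ours == pytest.approx(ref, abs=1e-12)


def test_two_category_linear_equals_unweighted(rng):
    for _ in range(20):
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        t = table(a, b, k=2)
        ours = dq.weighted_kappa(t).weighted_kappa
        # unweighted kappa from the same confusion matrix
        o = np.zeros((2, 2))
        np.add.at(o, (a, b), 1)
        n = o.sum()
        po = np.trace(o) / n
        pe = (o.sum(1) * o.sum(0)).sum() / n**2
        if pe == 1.0:
            assert ours is None
        else:
            assert ours == pytest.approx((po - pe) / (1 - pe), abs=1e-12)


def test_rating_table_validation_errors():
    with pytest.raises(ValueError):
        table([0, 1], [0])
    with pytest.raises(ValueError):
        table([0, 3], [0, 1])
    with pytest.raises(ValueError):
        table([], [])


# ------------------------------------------------------------ consensus

def square_regions(tissue, *boxes, source="obs"):
    return dq.RegionSet(source, [box(*b) for b in boxes], tissue)


@pytest.fixture
def tissue():
    return dq.TissueMask(np.ones((120, 120), dtype=bool), 1.0)


def test_identical_observers_reproduce_their_regions(tissue):
    rs = square_regions(tissue, (10, 10, 60, 60))
    ann = dq.ObserverAnnotations({f"o{i}": rs for i in range(3)}, tissue)
    consensus = dq.consensus_regions(ann)
    assert consensus.total_area_um2 == pytest.approx(
        rs.total_area_um2, rel=0.05
    )


def test_single_observer_region_excluded_from_consensus(tissue):
    lone = square_regions(tissue, (70, 70, 110, 110), source="o1")
    empty = dq.RegionSet("o", [], tissue)
    ann = dq.ObserverAnnotations(
        {"o1": lone, "o2": empty, "o3": empty}, tissue
    )
    assert dq.consensus_regions(ann).is_empty


def test_pairwise_intersection_defines_consensus(tissue):
    a = square_regions(tissue, (10, 10, 50, 50), source="a")
    b = square_regions(tissue, (30, 10, 70, 50), source="b")
    c = dq.RegionSet("c", [], tissue)
    ann = dq.ObserverAnnotations({"a": a, "b": b, "c": c}, tissue)
    consensus = dq.consensus_regions(ann)
    # set identity: consensus == A ∩ B exactly on the raster
    expected = (a.rasterize() & b.rasterize()).sum()
    assert consensus.total_area_um2 == pytest.approx(float(expected))
    # geometric 20x40 overlap up to the one-pixel boundary layer
    assert consensus.total_area_um2 == pytest.approx(800.0, rel=0.1)


def test_consensus_shrinks_with_more_required_observers(tissue):
    a = square_regions(tissue, (10, 10, 50, 50), source="a")
    b = square_regions(tissue, (30, 10, 70, 50), source="b")
    c = square_regions(tissue, (40, 10, 80, 50), source="c")
    ann = dq.ObserverAnnotations({"a": a, "b": b, "c": c}, tissue)
    areas = [
        dq.consensus_regions(ann, m).total_area_um2 for m in (1, 2, 3)
    ]
    assert areas == sorted(areas, reverse=True)


def test_too_few_observers_rejected(tissue):
    ann = dq.ObserverAnnotations(
        {"a": square_regions(tissue, (0, 0, 10, 10))}, tissue
    )
    with pytest.raises(ValueError):
        dq.consensus_regions(ann, min_observers=2)


# ------------------------------------------------------- object calls

def test_region_object_calls(tissue):
    obs = square_regions(tissue, (10, 10, 50, 50))
    ann = dq.ObserverAnnotations({f"o{i}": obs for i in range(3)}, tissue)
    dia = dq.RegionSet(
        "dia", [box(10, 10, 50, 50), box(80, 80, 110, 110)], tissue
    )
    calls = dq.region_confusion(dia, ann)
    assert calls.n_false_positive == 1  # the far square
    assert calls.matched_dia_indices == [0]
    assert calls.n_false_negative == 0

    empty_dia = dq.RegionSet("dia", [], tissue)
    calls = dq.region_confusion(empty_dia, ann)
    assert calls.n_false_negative == 1


# ------------------------------------------------------- area metrics

def test_perfect_overlap_metrics(tissue):
    dia = square_regions(tissue, (20, 20, 80, 80), source="dia")
    consensus = square_regions(tissue, (20, 20, 80, 80), source="consensus")
    m = dq.area_overlap_metrics(dia, consensus, consensus, tissue)
    assert m.ppv == pytest.approx(1.0)
    assert m.sensitivity == pytest.approx(1.0)
    assert m.dice == pytest.approx(1.0)
    assert m.fp_fraction_of_tissue == 0.0
    assert m.fn_fraction_of_tissue == 0.0


def test_disjoint_sets_metrics(tissue):
    dia = square_regions(tissue, (0, 0, 30, 30), source="dia")
    consensus = square_regions(tissue, (60, 60, 90, 90), source="consensus")
    m = dq.area_overlap_metrics(dia, consensus, consensus, tissue)
    assert m.ppv == 0.0 and m.sensitivity == 0.0 and m.dice == 0.0


def test_formula_arithmetic_on_known_areas(tissue):
    # 60x20 vs shifted 60x20: tp=40x20, fp=fn=20x20 -> all metrics 2/3
    dia = square_regions(tissue, (0, 0, 60, 20), source="dia")
    consensus = square_regions(tissue, (20, 0, 80, 20), source="consensus")
    m = dq.area_overlap_metrics(dia, consensus, consensus, tissue)
    for value in (m.ppv, m.sensitivity, m.dice):
        assert value == pytest.approx(2 / 3, abs=0.03)
    # exact identities on the reported areas
    tp, fp, fn = m.tp_area_um2, m.fp_area_um2, m.fn_area_um2
    assert m.ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
    assert m.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
    assert m.dice == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)


def test_degenerate_empty_set_contracts(tissue):
    full = square_regions(tissue, (10, 10, 50, 50))
    empty = dq.RegionSet("x", [], tissue)
    m = dq.area_overlap_metrics(empty, full, full, tissue)
    assert m.ppv is None and "ppv" in m.undefined
    assert m.sensitivity == 0.0
    assert m.dice == 0.0
    m = dq.area_overlap_metrics(full, empty, empty, tissue)
    assert m.ppv == 0.0
    assert m.sensitivity is None and "sensitivity" in m.undefined
    assert m.dice == 0.0
    m = dq.area_overlap_metrics(empty, empty, empty, tissue)
    assert m.ppv is None and m.sensitivity is None and m.dice is None


def test_fp_references_differ_between_union_and_consensus(tissue):
    # one observer delineates extra area: it protects the DIA from the
    # FP-area-of-tissue count, but still counts as pixel FP inside PPV
    consensus = square_regions(tissue, (10, 10, 50, 50), source="consensus")
    union = square_regions(
        tissue, (10, 10, 50, 50), (50, 10, 70, 50), source="union"
    )
    dia = square_regions(tissue, (10, 10, 70, 50), source="dia")
    m = dq.area_overlap_metrics(dia, consensus, union, tissue)
    assert m.ppv < 1.0
    assert m.fp_fraction_of_tissue == pytest.approx(0.0, abs=0.01)


def random_region_pair(rng, shape=(96, 96)):
    t = dq.TissueMask(np.ones(shape, dtype=bool), 1.0)
    masks = []
    for _ in range(2):
        field = rng.normal(size=shape)
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(field, 8)
        masks.append(smooth > np.quantile(smooth, rng.uniform(0.6, 0.95)))
    a = dq.RegionSet("a", mask_to_polygons(masks[0]), t)
    b = dq.RegionSet("b", mask_to_polygons(masks[1]), t)
    return t, a, b


def test_overlap_metric_identities_on_random_regions(rng):
    for _ in range(30):
        t, a, b = random_region_pair(rng)
        m_ab = dq.area_overlap_metrics(a, b, b, t)
        m_ba = dq.area_overlap_metrics(b, a, a, t)
        if m_ab.dice is not None and m_ba.dice is not None:
            assert m_ab.dice == pytest.approx(m_ba.dice, abs=1e-12)
        if m_ab.ppv is not None and m_ba.sensitivity is not None:
            assert m_ab.ppv == pytest.approx(m_ba.sensitivity, abs=1e-12)
        if (
            m_ab.ppv not in (None, 0.0)
            and m_ab.sensitivity not in (None, 0.0)
        ):
            harm = (
                2 * m_ab.ppv * m_ab.sensitivity
                / (m_ab.ppv + m_ab.sensitivity)
            )
            assert m_ab.dice == pytest.approx(harm, abs=1e-12)


def test_metrics_invariant_under_translation(tissue):
    dia = square_regions(tissue, (10, 10, 40, 40), source="dia")
    ref = square_regions(tissue, (20, 20, 50, 50), source="c")
    m1 = dq.area_overlap_metrics(dia, ref, ref, tissue)
    shift = lambda rs, s: dq.RegionSet(
        rs.source,
        [affinity.translate(p, xoff=30, yoff=30) for p in rs.polygons],
        tissue,
    )
    m2 = dq.area_overlap_metrics(shift(dia, 30), shift(ref, 30), shift(ref, 30),
                                 tissue)
    assert m1.dice == pytest.approx(m2.dice, abs=1e-12)
    assert m1.ppv == pytest.approx(m2.ppv, abs=1e-12)


# ------------------------------------------------------ centroid match

def test_match_centroids_counts_and_cutoff():
    detected = [(0, 0), (10, 0), (50, 50)]
    truth = [(1, 0), (10, 1), (90, 90)]
    m = dq.match_centroids(detected, truth, max_dist_um=3, pixel_size_um=1.0)
    assert m.n_matched == 2
    assert m.precision == pytest.approx(2 / 3)
    assert m.recall == pytest.approx(2 / 3)
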