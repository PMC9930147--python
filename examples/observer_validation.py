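"""Validate automated delineations against (synthetic) observers.

Three pseudo-observers are derived by perturbing the true hotspot
(random shift, dilation/erosion per observer).  The consensus — area
delineated by at least two observers — is the reference standard; the
automated delineation is scored with PPV, sensitivity, Dice and the
false-positive / false-negative percentage of the tissue area.  The
categorical agreement section shows percent agreement and the linearly
weighted Cohen's kappa on paired fragment scores.
"""

import dabquant as dq

config = dq.SynthConfig(seed=3, n_cells=500, canvas_px=1536, n_hotspots=1,
                        base_positive_fraction=0.05,
                        hotspot_positive_fraction=0.9)
image, truth = dq.generate_fragment(config)
analysis = dq.analyze_fragment(image, dq.PIMO_PRESET)

observers = dq.make_observer_annotations(truth.hotspot_regionset(), seed=30)
consensus = dq.consensus_regions(observers, min_observers=2)
any_union = dq.RegionSet(
    "any", [p for rs in observers.observers.values() for p in rs.polygons],
    analysis.tissue,
)
m = dq.area_overlap_metrics(analysis.regions, consensus, any_union,
                            analysis.tissue)
calls = dq.region_confusion(analysis.regions, observers)
print("--- region validation vs consensus of 3 observers")
print(f"PPV {m.ppv:.3f}  sensitivity {m.sensitivity:.3f}  dice {m.dice:.3f}")
print(f"FP area {100 * m.fp_fraction_of_tissue:.2f}% of tissue, "
      f"FN area {100 * m.fn_fraction_of_tissue:.2f}%")
print(f"object calls: {calls.n_false_positive} FP region(s), "
      f"{calls.n_false_negative} FN region(s)")

# categorical agreement on a toy set of paired fragment scores
table = dq.RatingTable(
    fragment_ids=list(range(10)),
    rater_a=[0, 0, 1, 1, 1, 1, 2, 2, 2, 1],
    rater_b=[0, 1, 1, 1, 1, 2, 2, 2, 2, 1],
)
agr = dq.weighted_kappa(table)
print("--- categorical agreement")
print(f"agreement {agr.percent_agreement:.1f}%  "
      f"weighted kappa {agr.weighted_kappa:.3f}")
# Kappa corrects the raw agreement for agreement expected by chance from
# the two raters' marginal score distributions.
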