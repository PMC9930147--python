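"""Reproduce two documented failure modes of threshold-based IHC analysis.

1. Red-blood-cell pigment: faint brown erythrocyte clumps (DAB OD ~0.15)
   exceed the low cytoplasmic threshold (0.10) and create false-positive
   cells — but stay far below the strong-nuclear threshold (0.65).
2. Low detected cell density: a fragment whose cells are all positive but
   sparse produces NO positive regions, because regions require a high
   local density of positive cells.
"""

import dabquant as dq
from dabquant.scoring import classify_cells

print("--- red blood cell artifacts")
config = dq.SynthConfig(seed=31, n_cells=300, canvas_px=1024,
                        base_positive_fraction=0.0,
                        rbc_count=15, rbc_cluster_radius_um=15.0,
                        rbc_dab_od=0.15)
image, truth = dq.generate_fragment(config)
stain_od = dq.deconvolve(dq.rgb_to_od(image))
seg = dq.segment_fragment(stain_od)
n_pimo = classify_cells(seg.cells, dq.PIMO_PRESET).n_positive
n_hif = classify_cells(seg.cells, dq.HIF1A_PRESET).n_positive
print(f"truth positives: 0; cytoplasmic-rule false positives: {n_pimo}; "
      f"strong-nuclear-rule false positives: {n_hif}")

print("--- low cell density suppresses regions")
config = dq.SynthConfig(seed=32, n_cells=20, canvas_px=1024,
                        base_positive_fraction=1.0)
image, _ = dq.generate_fragment(config)
analysis = dq.analyze_fragment(image, dq.PIMO_PRESET)
print(f"positive cells: {analysis.result.n_positive}, "
      f"regions delineated: {len(analysis.regions.polygons)}")
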