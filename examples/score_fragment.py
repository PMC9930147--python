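"""Score one synthetic H-DAB fragment end to end.

Renders a fragment with a known positive fraction, runs colour
deconvolution, cell detection and the cytoplasmic (PIMO-style,
DAB OD >= 0.10) positivity rule, and prints the estimated positive area
fraction next to the generator's ground truth.
"""

import dabquant as dq

config = dq.SynthConfig(seed=1, n_cells=300, canvas_px=1024,
                        base_positive_fraction=0.2)
image, truth = dq.generate_fragment(config)
analysis = dq.analyze_fragment(image, dq.PIMO_PRESET)

result = analysis.result
print(f"cells detected:          {result.n_cells} (truth {truth.n_cells})")
print(f"positive cells:          {result.n_positive}")
print(f"positive area fraction:  {result.positive_area_fraction:.4f} "
      f"(truth {truth.positive_area_fraction:.4f})")
print(f"categorical score:       {result.category} (truth {truth.category})")
# The fraction is area-weighted (positive cell area / all cell area); the
# category buckets it into 0 (<1%), 1 (1-33%) or 2 (>33%).
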