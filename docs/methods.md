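# Methods

## Stain model

Brightfield transmission follows Beer–Lambert: with incident intensity
`I0` (the white reference, default 255 per channel) and transmitted
intensity `I`, the optical density `OD = -log10(I / I0)` is linear in
chromogen concentration and additive across chromogens. A pixel's raw
RGB-OD vector is therefore `od_rgb = Σ_s a_s · v_s`, where `v_s` are
unit stain vectors and `a_s` the per-stain amounts. `deconvolve` solves
this 3×3 system per pixel and clamps negative (non-physical) solutions
to zero; `compose` is the exact forward model used by the synthetic
generator, followed by rounding to 8-bit integers.

Defaults: the Ruifrok–Johnson H-DAB basis, H ≈ (0.65, 0.70, 0.29),
DAB ≈ (0.27, 0.57, 0.78), residual = normalized cross product. The
vectors of any particular scanner/staining batch differ and can be
supplied as YAML. Intensities are floored at `i_floor = 1` count before
the logarithm, capping OD at `log10(255) ≈ 2.407`.

**Numerical accuracy of the round trip.** 8-bit quantization perturbs
each raw-OD channel by up to `log10((I+0.5)/(I-0.5))`, which grows as
intensity falls: ~0.002 OD at I=100 but ~0.07 OD at I=3 (raw OD 2).
Propagated through the unmixing matrix (absolute row sums ≈ 1.6–2.8),
the per-stain round-trip error is ≤0.01 OD only while stain ODs stay
roughly below 0.5–0.6; beyond summed raw OD ≈ 2.4 the intensity floor
makes the error grow without bound. The test suite asserts the exact
analytic bound everywhere and the 0.01 figure in the moderate-OD
working range. The generator paints ODs well inside that range
(hematoxylin ≈ 0.9 peak, DAB ≤ ~0.9), so pipeline measurements are not
quantization-limited.

## Tissue detection

Total OD (sum of channels) is thresholded at `background_od` (default
0.08 — midway between bare glass under the generator's noise model,
~0.024, and the faint tissue background, ~0.12), followed by
morphological closing (2 µm) then opening (8 µm), hole filling
(<5000 µm²) and a minimum component area (10 000 µm²). The closing
radius is deliberately small: a wide closing bridges isolated
noise-speckle on glass before the opening can remove it. Morphology is
computed with exact Euclidean-disk erosions/dilations (distance
transforms) on a padded array, making the mask invariant to white
padding. An empty result raises `NoTissueFoundError` rather than
returning an empty mask.

## Nucleus detection and cell expansion

The hematoxylin channel is smoothed with a Gaussian
(`smoothing_sigma_um`, default 1.5 µm), thresholded at
`nucleus_threshold_od` (default 0.1), restricted to tissue and
labelled. Touching nuclei are split by a watershed whose seeds are the
local maxima of a hybrid relief: smoothed OD plus 0.01·(Euclidean
distance transform of the binary mask) per pixel. The distance term
only breaks ties on intensity plateaus, pulling seeds to shape centres;
it leaves ordinary dome-shaped nuclei with a single seed, gives one
seed per lobe of a touching pair, and — importantly — yields a *single*
seed for a wide uniform blob, so the subsequent area gate
(10–400 µm²) can reject it instead of accepting watershed shards.
Components are renumbered in raster order; the pipeline is fully
deterministic.

Cells are expanded isotropically: every tissue pixel within
`cell_expansion_um` (default 5 µm) of a nucleus joins the cell of its
*nearest* nucleus (Euclidean distance-transform partition, clipped to
tissue), so neighbouring cells meet at perpendicular bisectors and
never overlap. A geodesic (inside-tissue) distance would differ only
where a cell wraps around a tissue concavity; the Euclidean partition
was chosen for exactness and speed, with clipping preserving the
"masks ⊆ tissue" contract. Mean ODs are measured per compartment; a
cytoplasm entirely clipped away yields NaN plus a flag, never a silent
zero.

Pixel size defaults to 0.25 µm (a typical 40× scan) for file input and
is configurable everywhere; the synthetic fixtures use 0.5 µm to halve
the raster dimensions.

## Scoring and regions

Classification is an inclusive threshold on the configured
compartment's mean DAB OD (`pimo`: cytoplasm ≥ 0.10; `hif1a`: nucleus
≥ 0.65 — "strong" staining only). Cells without a measurable
compartment are excluded from both numerator and denominator and
reported separately. The area fraction uses whole-cell areas for both
marker types. Category boundaries are 0: f < 1%; 1: 1% ≤ f ≤ 33%;
2: f > 33% (both boundary values in category 1, the only reading
consistent with all three printed brackets).

Positive regions: the number of positive-cell centroids within a hard
disk of radius `density_radius_um` (50 µm) of each pixel, normalised to
cells/mm², is thresholded at `min_positive_density` (500 cells/mm²;
alternatively a local positive *fraction* threshold via
`density_mode="fraction"`), intersected with tissue, holes <2000 µm²
filled, components <5000 µm² dropped, and the result vectorized to
polygons. Two consequences are inherent to density-based delineation
and are reproduced deliberately: detected regions extend beyond a true
hotspot by up to roughly the kernel radius (boundary smearing), and
fragments whose *detected* cell density is below the threshold produce
no regions even when every cell is positive.

## Validation metrics

Weighted kappa uses linear disagreement weights `w_ij = |i-j|/(k-1)`
and the marginal-product expected matrix:
`κ = 1 − Σ w·O / Σ w·E`. When both raters are constant and identical,
`Σ w·E = 0` and κ is reported as undefined (with 100% agreement), not
as a number. Percent agreement is reported on the 0–100 scale.

All region arithmetic happens on the rasterized tissue grid; polygons
are rasterized by exact pixel-centre point-in-polygon tests, so
`rasterize(vectorize(mask))` reproduces the mask and set identities
hold to the pixel. Consensus = pixels covered by ≥ `min_observers`
(default 2). Two false-positive references coexist by design: a DIA
region is an FP *object* (and contributes FP tissue-area) only if it
misses the union of ALL observers, while pixel-level FP inside PPV and
Dice is taken against the consensus. FN uses the consensus in both
roles. Object calls use an overlap epsilon of 1% of the region's own
area (configurable). Dice is `2·TP/(2·TP+FP+FN)`; 0/0 cases are
explicit nulls with reason codes.

## Synthetic fragments

The generator emulates the statistical structure the pipeline assumes,
not slide photorealism. One seeded PRNG drives everything; identical
configs give bit-identical images and truth.

- **Tissue**: a radial-Fourier blob (harmonics 2–6, wobble 0.07) with
  radius 0.38·canvas, covering ~45% of the canvas.
- **Cells** (default 500 on a 1536 px / 0.5 µm canvas ≈ 1900
  cells/mm², a moderately cellular tumour fragment): elliptical nuclei
  (radius 4 ± 0.5 µm truncated to [2.5, 6], aspect ≤ 1.3) placed by
  hard-core dart throwing with a 4 µm boundary gap, fully inside
  tissue.
- **Positivity**: Bernoulli per cell; probability
  `hotspot_positive_fraction` (0.9) inside hotspot polygons, else
  `base_positive_fraction` (0.05). Hotspots are 100 µm circles in the
  tissue interior, clipped to tissue.
- **Staining**: nuclear hematoxylin 0.8 ± 0.1 OD over a 0.08 OD tissue
  background. Cytoplasmic markers paint DAB (positive 0.6 ± 0.1 OD,
  negative 0.02 ± 0.01) on the cell's true annulus — the nucleus
  expanded by a *generation-time* 6 µm, independent of the
  analysis-time expansion, so segmentation mismatch is a measurable
  error source rather than a hidden assumption. Nuclear markers paint
  the nucleus plus a 2 µm halo, modelling chromogen spread and optical
  blur; without the halo the detected nucleus (which the smoothing
  threshold slightly over-grows) would dilute the measured mean below
  the painted value.
- **Noise**: truncated-Gaussian OD noise (σ = 0.03) on the two real
  stain channels, then Beer–Lambert composition to 8-bit RGB.
- **Artifacts** (off by default): red-blood-cell clumps — DAB-tinted
  (OD 0.15), hematoxylin-free unions of disks around ~15 µm centres,
  the scale of packed erythrocytes, recorded in an artifact mask; and
  the edge effect — extra cytoplasmic DAB (0.2 OD) for cells whose
  centroid lies within a rim of the tissue boundary, with ground-truth
  labels deliberately unchanged (it models non-specific staining).
- **Pseudo-observers**: per-observer random shift (σ 6 µm) and
  dilation/erosion (σ 8 µm) of reference polygons, a minimal stand-in
  for human delineation variability.

What the generator does **not** model: chromatin texture and nucleolar
structure, stain inhomogeneity and batch variation, stroma/tumour
compartments, scanner artifacts (focus, stitching), and real observer
behaviour. Passing tests therefore demonstrate the correctness and
internal consistency of the measurement chain under the stated noise
model — not clinical performance on real slides.

## Problem sizes in tests and the acceptance script

Unit tests run on 512–1024 px canvases with 20–300 cells; recovery
checks use 10-seed batches at 300–500 cells (1024–1536 px); the
acceptance script uses 4-fragment batches per study plus 1000 random
confusion matrices and 500 random region pairs. These sizes were chosen
so the whole suite completes in minutes while keeping ≥300 cells per
fragment, enough for binomial sampling error to stay well inside the
tested tolerances.

## Known limitations

- The exact analysis settings behind any published study (stain
  vectors, detection parameters, density script settings) are rarely
  recoverable; all defaults here are documented substitutes and every
  output carries a provenance YAML.
- Absolute-OD thresholds are vulnerable to batch-to-batch DAB intensity
  variation; no colour normalisation is performed.
- Watershed splitting handles touching, roughly convex nuclei; heavily
  overlapping or pleomorphic nuclei are out of scope.
- The kappa shares the known weakness of chance-corrected agreement
  under skewed marginals; only linear weights are implemented.
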