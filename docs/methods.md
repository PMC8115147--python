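# Methods

This note documents the models and numerical choices behind `larynx-cad`:
what each stage computes, which parameters matter, and what the synthetic
phantom does and does not emulate.

## Problem setting

A laryngoscopic recording shows the glottis — the dark, inverted-triangle
space between the vocal cords — flanked by two pale cord bands, under
illumination that varies with lens distance. The pipeline (1) picks the
clearest frame, (2) normalises brightness, (3) segments glottis and cords,
(4) measures three discriminative features, and (5) classifies the image as
healthy, polyp, cyst, leukoplakia or tumor.

Coordinates are row-major with the origin top-left; y grows downward, so
the "lowest point" of the glottis is its maximal-row pixel (the apex of the
inverted triangle).

## Frame screening

Frames whose PSNR (10·log10(255²/MSE)) to the preceding frame falls below
`psnr_min` (default 20 dB) are treated as motion/noise bursts and dropped.
The wording of the underlying decision rule is ambiguous in the source
material for this method; "discard on large inter-frame error, threshold
configurable" is our documented reading, and the first frame — having no
predecessor — is always eligible.

Each surviving frame is thresholded with the **fast Otsu** search: the
gray range is split at the background-class mean, the global mean and the
foreground-class mean, the best between-class variance is found inside each
of the four intervals, and the best of the four is returned. Because the
intervals tile [0, 255] this equals the exhaustive Otsu threshold
(smallest maximiser on ties); the test suite asserts exact agreement with a
brute-force search. The glottis is darker than the mucosa, so candidate
glottal blocks are 8-connected components of the **sub-threshold** class.
Three structural conditions screen candidates:

* centroid row in [50, 240] — quoted at a 288-row frame and rescaled
  proportionally for other heights;
* bounding-box aspect ratio (width/height) ≤ 0.85 — an inverted triangle
  is taller than wide, east–west elongated blocks are excluded;
* area ≥ 900 px.

The frame whose largest screened block is maximal wins (ties: earliest
frame). All three thresholds are boundary-value tested (49/50, 0.85/0.86,
899/900).

## Brightness compensation

Histogram translation shifts every pixel by `S − O_m`, where `O_m` is the
image mean (optionally excluding a black endoscope border unified to gray
0) and `S = 125` is the target mean, low enough not to over-compensate
bright images. The result is returned as float so that, absent clipping,
`mean(output) = S` holds exactly; it is idempotent and leaves the gray
standard deviation — the hue feature — untouched. Quantisation to 8 bits
happens only where a raster is written.

## Contrast enhancement

CLAHE (tile grid 8×8, clip limit 2.0 on the histogram-multiple scale,
mapped to scikit-image's normalised limit as clip/256) followed by Gaussian
smoothing (5×5 kernel, σ = 1 px). These defaults are configurable; the
pipeline's quantitative guarantees do not depend on them. CLAHE is applied
only on the thresholding path (glottis extraction): tile-wise equalisation
exaggerates the cord/glottis edge relative to the much weaker cord/mucosa
edge, which destabilises the snake, so the cord evolution runs on the
compensated, lightly smoothed image instead.

## Adaptive vocal-cord segmentation

**Seeds.** A horizontal transect through the glottic centroid and a
vertical cut through the lowest glottis point organise the periglottic
space. The seed for each cord is the band of pixels within `seed_width`
(default 9 px) outside the glottis boundary, on its side of the vertical
cut. The exact construction of the seed image is under-specified in the
source method; by default the band spans the full medial edge
(`seed_row_extent="full"`) because a 3×3-neighbourhood snake cannot
traverse the cord's length within the iteration cap if the seed covers
only the rows below the centroid; the `below_centroid` variant remains
available in the configuration.

**Snake.** A greedy active contour: each sweep visits every vertex once
and accepts the 3×3-neighbourhood move that lowers the total energy

E = Σᵢ w_cont·((|vᵢ−vᵢ₋₁|−d̄)/d̄)² + w_curv·|vᵢ₋₁−2vᵢ+vᵢ₊₁|²/d̄²
  + E_ext(vᵢ)

with the spacing normaliser d̄ frozen at sweep start, so the energy is
non-increasing within every sweep by construction (asserted in the tests).
The external energy combines three terms:

* −w_image · normalised gradient magnitude (Sobel of the σ=1.2-smoothed
  image). The gradient is normalised by its 99.5th percentile *outside*
  an 8-px rim around the glottis: the cord/glottis edge is far stronger
  than the cord/mucosa edge and would otherwise drown it out whenever the
  cord/background contrast is low.
* −w_balloon · distance from the seed region (an outward inflation of
  ≈1 px per sweep wherever the image is flat).
* a +6 energy barrier on the already-segmented glottis, which implements
  "previously segmented areas are removed before cord segmentation" and
  keeps the contour out of the glottic space.

Weights default to w_cont = 0.5, w_curv = 0.1, w_image = 3.0,
w_balloon = 0.18. The internal terms are deliberately light: because they
are normalised by d̄ they price each one-pixel kink, and heavier settings
freeze the inflation long before the cord boundary (the continuity- and
curvature-dominated regime is appropriate for edge-locking snakes, not for
growing ones). The balloon weight must stay below the per-pixel drop of
the image term at a true boundary (≈0.3 with these settings) or the
contour leaks into the mucosa. Vertices are re-distributed to uniform
spacing only when spacing drifts (max > 2×mean or min < 0.25×mean): a
converged contour must be bit-stable between sweeps so that the entropy
trace of a saturated growth range goes exactly flat.

**Adaptive iteration count.** Lens distance changes apparent cord size, so
a fixed sweep count under- or over-grows. The contour is evolved to the
upper bound while recording the Shannon entropy (log₂, 256-bin histogram)
of the enclosed "growth range" on the glottis-removed image. Candidate k
compares the entropies after iterations `iter_min−1+k` and `iter_min−2+k`;
the selected count is `iter_min−1+k*`, where k* minimises |ΔH| with ties
broken toward smaller k. With the bounds [13, 41], a minimal difference at
the 23rd candidate selects iteration 35 — growth has saturated between the
35th and 36th sweep. The result lies in [13, 41] by construction. Left
and right cords run independently and may select different counts.

Segmentation quality is quantified as the relative area error
100·|auto − reference|/reference against the phantom ground truth; the
acceptance suite requires a batch-mean ≤ 10% on noiseless phantoms
(typical values are 1–3%, with occasional early-stop outliers when the
entropy trace dips during growth).

## Features

For each cord, the medial (glottis-facing) edge is sampled per row over
the rows the glottis spans (the snake's rounded caps beyond them are not
cord edge), trimming ~6% at each end against corner effects. The straight
line through the anterior- and posterior-most edge points is the cord
baseline; the signed distance of edge points beyond it toward the glottis
gives:

* `geometric_abnormal`: max deviation > 3 px, quoted at a 100-px cord and
  scaled linearly with cord length so lens distance cannot change the
  verdict (the source method judges this visually; the number is ours);
* `protrusion_length` = max deviation; `protrusion_width` = extent along
  the baseline of the contiguous super-threshold run containing the
  maximum; `lw_ratio` = length/width. A semicircular bump of radius r
  measures (r, 2r, 0.5) at zero threshold — polyps are tall and narrow
  (ratio ≳ 0.5), cysts broad and shallow (ratio ≲ 0.35);
* `gray_std`: population standard deviation of the compensated gray values
  under the cord mask. White patches (leukoplakia) and heterogeneous
  texture (tumor) both raise it; compensation being a pure shift makes it
  comparable across exposures.

## Classification

Binary RBF-SVMs (C = 10, standardised inputs) arranged in a fixed tree
that mirrors the feature logic:

1. **geometry**: {polyp, cyst} vs {healthy, leukoplakia, tumor} on
   (any_abnormal, max_deviation);
2. **protrusion**: polyp vs cyst on (lw_ratio, max_deviation);
3. **hue**: healthy vs {leukoplakia, tumor} on gray_std_max;
4. **texture**: leukoplakia vs tumor on (gray_std_max, max_deviation).

The topology is declared, not learned — the binary splits of the original
classifier are not recoverable from the available description, so the tree
encodes the feature narrative directly. Routing is exhaustive and
exclusive; each node trains on exactly the samples its subtree owns.
"Hierarchical" cross-validation is read as stratified k-fold (default 10).
Lesion-side information is not needed at prediction time: the classifier
consumes per-image aggregates (max deviation across cords, ratio of the
dominant cord, max gray std).

## The phantom

The generator renders the geometry the pipeline assumes: an inverted
triangular glottis (default ~5 400 px) flanked by cord bands (default
26 px wide), mid-bright mucosa, a mild radial illumination falloff
(default 20 gray levels at the frame corner) that exercises compensation,
plus per-image Gaussian noise (σ = 4), slight blur (σ = 0.6) and a random
exposure offset (±20) in the benchmark. Lesions follow the feature
phenomenology: polyps and cysts are half-elliptical medial protrusions
(polyp: depth 10–14 px on a 14–20 px base; cyst: 6–9 px on 26–36 px),
leukoplakia a bright elliptical patch (gray 228–245), tumors smoothed
intensity heterogeneity (σ 15–22) with a mildly irregular edge (≤ 2.5 px,
below the abnormality threshold). These ranges are this package's own
choices — no quantitative lesion model exists in the source material —
and were fixed so that the three features separate the classes on clean
images; the classifier then has to cope with noise, segmentation error
and overlap near the boundaries.

What the phantom does **not** emulate: specular highlights, mucus and
saliva, vascular texture, stroboscopic motion, color (everything is
grayscale), the endoscope's circular field stop, or anatomical variation
beyond affine geometry jitter. Passing the synthetic benchmark therefore
demonstrates that the pipeline's stages compose correctly and that the
features separate the modelled phenomenology at realistic noise — not
clinical-grade performance on real laryngoscopy.

## Problem sizes and determinism

Default frames are 288×352 (the centroid screening bounds are quoted at
288 rows). The acceptance suite uses 200 benchmark images (40 per class),
a 20-phantom cord-scale batch for the iteration bounds, 200 mixture images
for the Otsu equivalence, and 50 sequences for frame selection; everything
is seeded, and identical seeds reproduce images, folds and predictions
bit-for-bit.

## Known limitations

* The snake's balloon inflation grows ≈1 px per sweep, so structures whose
  half-width exceeds `seed_width + iter_max` pixels from the seed cannot be
  fully covered within the iteration cap; at the 2× cord scale the contour
  is still growing at the cap (the bounds clamp guarantees a legal count).
* On noiseless images the entropy trace is nearly flat and can dip during
  active growth, occasionally selecting an early stop (the 10% acceptance
  bar is a batch mean for this reason); with realistic noise the trace is
  better behaved.
* Left/right iteration counts on a mirror-symmetric phantom can differ by
  a sweep or two from vertex-phase discretisation.
* The leukoplakia/tumor margin rests on the gray-std separation of the
  phantom's lesion models; with heavier noise the two classes blur first.
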