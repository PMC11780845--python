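# Methods

## Problem setting

Decellularized extracellular matrix (dECM) products are screened for
residual donor nuclei on stained histological sections. Two failure modes
make the naked-eye call unreliable: particulate contamination (dust) that
mimics nuclear staining, and inter-observer subjectivity. The package
formalizes a quantitative workflow: detect every "suspicious point" on a
section, measure six morphometric parameters per point, score points against
a reference-nucleus benchmark, aggregate to a whole-section score, and
combine independent staining chemistries into a sample-level decision.
Because no public image data accompany this problem, a synthetic slide
simulator with exact ground truth stands in for the wet-lab study; it is
first-class, tested code, and its defaults define the study conditions used
everywhere in the test suite and the acceptance script.

## Morphometry

Each object is a connected pixel set. Conventions:

* **Boundary.** The object polygon is the outline of its pixel squares
  (pixel-corner convention). A single pixel is a unit square: Feret = √2,
  MinFeret = 1.
* **Area** = pixel count (px²).
* **Perimeter** = Crofton estimate (4 directions) on the binary mask, which
  tracks ImageJ-family particle analysis closely.
* **Feret** = maximum pairwise distance over the convex-hull vertices of the
  pixel corners — the longest caliper diameter.
* **MinFeret** = minimum caliper width, computed exactly by rotating
  calipers: for a convex polygon the minimum width is attained with one jaw
  flush against an edge, so it is the minimum over edges of the farthest
  vertex-to-edge distance.
* **Feret ratio** = Feret / MinFeret ≥ 1, the elongation index.
* **Average grayscale** ḡ = (1/N) Σ I(i) over the object's pixels on the
  analysis channel used for detection (0 = black, 255 = white).

A deliberately naive oracle (`caliper_bruteforce`: all corner pairs for
Feret; a 0.1° sweep of projected widths for MinFeret) is kept independent of
the production path. On 200 random synthetic masks Feret agrees exactly
(both are maxima over the same finite point set) and MinFeret agrees within
the 0.1° grid's discretization, ≈0.1% in practice. One property worth
knowing: on a rasterized disk the corner convention stretches Feret by about
one pixel but not MinFeret (the oracle gives 41.11/39.0 = 1.054 at radius
20), so even ideal circles show ratios slightly above 1.

## Scoring

**Criterion 1 (single point).** The benchmark is the per-parameter sample
mean and SD (n−1) of reference nuclei. Parameter score: 3 within 1σ, 2
within 2σ, 1 within 3σ, 0 beyond. Interval boundaries are closed toward the
better score (|x−μ| = kσ earns the higher category); σ = 0 degenerates to
exact-match-or-zero. Dimension scores are plain averages — size = (area,
perimeter), shape = (Feret, MinFeret, ratio), color = (grayscale) — and the
total is the weighted sum of dimensions. The importance weights are
genuinely open (no published values exist); the default is neutral (1, 1, 1),
giving a 0–9 total, and they are exposed in configuration. The nucleus-call
threshold defaults to 60% of the maximum total; `calibrate_threshold` picks
it by maximizing balanced accuracy on labeled calibration totals instead
when labeled samples are available. Because every parameter score is
non-increasing in |x−μ|, moving any parameter toward the benchmark mean can
never lower the total (tested exhaustively by property test).

**Criterion 2 (whole section).** Integer count bins, endpoints resolved to
the lower category since the printed ranges abut:

| component | 0 | 1 | 2 | 3 | 4 |
|---|---|---|---|---|---|
| overall suspicious points | 0 | 1–10 | 11–20 | 21–50 | >50 |
| points called nuclei (×2) | 0 | 1–2 | 3–5 | 6–10 | >10 |
| points in the ECM | 0 | 1–5 | 6–10 | 11–20 | >20 |

Total = s_overall + 2·s_nucleus + s_ecm ∈ [0, 16]. The nucleus component is
double-weighted because residual nuclei are the direct evidence of
incomplete decellularization. For counting "points called nuclei" the
pipeline scores each point against both reference nucleus types of its stain
and takes the larger total — a section containing either nucleus type should
alarm, and this is the natural generalization to multiple benchmark types.

**Consensus.** A stain alarms when its section total reaches the alarm
threshold (default 6 — above anything an all-"rare" section can reach,
1 + 2·1 + 1 = 4). ≥2 alarming stains ⇒ residual nuclei; exactly 1 ⇒
contamination suspect, since dust chemistry fools at most one staining
principle at a time (and is invisible to DAPI entirely); 0 ⇒ decellularized.
Fewer than two provided stains still yields a decision, flagged
`insufficient_stains`.

**Stratified protocol.** Per staining group: 5 of the 15 positive sections
chosen uniformly among those with enough objects, then 5 nuclei and 5
impurities per chosen section without replacement — 25 + 25 per group, and
25 per class per stain (300 objects over the 4-stain × 3-class design).
DAPI's protocol samples nuclei only (its dust is invisible, so there is
nothing to select). On reduced study grids (fewer than 5 sections) the
protocol keeps the 5-objects-per-section density and shrinks the section
count, so benchmarks shrink proportionally.

## Synthetic slides

The simulator renders what the four stains qualitatively show, in pixel
units (no physical pixel size is claimed; ~0.5 µm/px imagery guided the
magnitudes).

* **Nuclei** are rasterized ellipses with aspect ratio drawn from the
  configured Feret-ratio distribution and area from the area distribution;
  with probability `curvature` the ellipse is bent along a circular arc of
  radius 2a (banana shape). Brightfield defaults: nucleus type 1
  area 420 ± 60 px², ratio 3.0 ± 0.3, curvature 0.35; type 2 330 ± 50 px²,
  ratio 2.5 ± 0.25 — elongated fibroblast-like nuclei, ratio well above 2.
  DAPI nuclei are larger and rounder (620/520 px², ratio 1.6/1.45), bright
  (gray 200/185) on a dim field.
* **Dust** is an irregular near-round blob: the top-A pixels of a noisy
  anisotropic radial field (noise amplitude 0.25), largest connected
  component, holes filled. Defaults: area 260 ± 120 px² (about twice the
  nuclei's relative spread — contamination is size-heterogeneous), ratio
  1.05 ± 0.04, gray 55 ± 12 (darker than nuclei; impurity grayscale tends
  toward black). 25% of brightfield dust is rendered out of focus
  (Gaussian-blurred sprite, σ ~ N(1.0, 0.3) truncated at 0), emulating
  particles suspended above the section plane; the rest sit in or on the
  matrix.
* **Colors.** Per-stain fixed hue directions normalized to unit luminance,
  multiplied by the object's sampled gray level, with 4% multiplicative
  shading noise: HE blue-purple nuclei on eosin-pink ECM (luminance 205) and
  near-white background (238); Feulgen purplish-red nuclei, faint pink ECM;
  acetocarmine red nuclei, lightly stained ECM; DAPI is single-channel with
  background glow 22 and ECM 30. **DAPI dust is rendered at background
  intensity** — present in the ground truth, invisible in the image — so
  detectors can be tested to find nothing.
* **Placement.** The ECM is a thresholded smooth noise field at the
  configured coverage (default 0.55). Objects never overlap (rejection
  sampling, 50 retries, 2 px moat so components cannot merge); failure
  raises an error naming the class. Nuclei are preferentially embedded in
  the ECM (85% rejection of off-matrix positions), dust lands anywhere.
* **Study grid.** Five groups — two decellularized samples, two cellular
  positive controls (one per reference nucleus type, 12–18 nuclei + 5–10
  dust per section), one acellular negative control (4–9 dust) — × 4 stains
  × 15 sections. Per-slide seeds derive from (master seed, group, stain,
  section) via `SeedSequence`, so the whole grid is a pure function of the
  master seed and any slide can be re-rendered in isolation.

**Fidelity contract.** Measured per-class means of area, Feret ratio and
grayscale stay within 20% of the configured generative means for rendered
objects (rasterization, bending and focus blur cost a few percent each; the
worst case is the dust ratio, measured ≈1.2 against a configured 1.05).
DAPI dust is excluded from grayscale recovery — it is not rendered, by
design.

**What the simulator does not model**, and hence what passing tests cannot
show about real slides: stain chemistry and its batch variability, optics
(only a flat multiplicative shading field and per-sprite Gaussian blur),
textured chromatin, touching/overlapping nuclei, tissue-fragment
contamination, section folds and edge artifacts. Results on synthetic
studies demonstrate the correctness and internal consistency of the
measurement and scoring machinery, not clinical performance.

## Detection

The analysis channel is fixed-weight luminance (0.299/0.587/0.114) for RGB
brightfield images and the raw channel for single-channel (DAPI) input; a
"stain_distance" mode (Euclidean RGB distance to a per-stain reference
nucleus color) is available. Detection thresholds the channel and takes
8-connected components, size-filtered to [10 px², 1% of the image] by
default — the analogue of excluding particles too small or too large to be
credible nuclei. Ids follow raster order of centroids.

The default threshold is **three-class multi-Otsu**, using the threshold on
the object side of the stain's polarity (dark objects for brightfield,
bright for DAPI). Plain two-class Otsu is unreliable here: slide images have
three intensity populations (background, ECM, objects), and when objects are
sparse Otsu splits background from ECM, swallowing every object that touches
the matrix into one giant (size-filtered) component. Multi-Otsu resolves all
three modes regardless of object abundance. A degenerate-input guard
declares the image object-free when the mean foreground–background contrast
of an *automatic* threshold falls below 25 gray levels — on a truly empty
field any threshold just slices background noise (contrast ≈ 8 levels on
synthetic DAPI blanks, vs ≥ 85 when real objects are present). Fixed
user-supplied thresholds bypass the guard. ECM membership uses a ≥50%
pixel-overlap majority rule.

Tiling covers every pixel with `ceil((L−T)/S)+1` tiles per axis, zero-pads
edge tiles to full size recording the padding, and stitching the unpadded
regions reproduces the original exactly. Dataset splitting uses
largest-remainder rounding, so a 6:2:2 split of 10 items is exactly
(6, 2, 2), subsets are disjoint and exhaustive, and assignment is a pure
function of the seed.

## Classifier

Logistic regression (L2, C = 1) on the six features, standardized with
statistics learned on the training split only; a small random forest
(50 trees, depth ≤ 6) is available behind the same interface. Both serialize
to plain JSON (coefficients or explicit tree tables) and predict from the
stored arrays, so a loaded model needs only numpy. Labels are binary
(nucleus/impurity) per stain; DAPI is excluded from the classifier dataset
because its impurities are invisible, leaving nothing to label. Metrics:
per-class recall TP/(TP+FN), overall accuracy, full confusion matrix;
evaluation can be restricted to the test split via split tags.

## Problem sizes and determinism

The default synthetic study used by the acceptance script and the end-to-end
tests is the full 5 × 4 × 15 = 300-slide grid at 384 × 384 px — large enough
for ~3 300 detected objects, 25-nucleus benchmarks and stable metrics, small
enough to run in well under a minute on one CPU. Unit tests use single
slides or reduced 3-section grids. Every random draw flows from one master
seed through named `SeedSequence` substreams (scene rendering, per-section
counts, sampling protocol, threshold-calibration splits, classifier split
and training); there is no global RNG state, and identical configuration +
seed reproduces bit-identical images and reports.

## Known limitations

* All geometry is in pixels; no µm calibration is attempted, so absolute
  sizes are not comparable to physical-slide measurements.
* The criterion-1 dimension weights and nucleus-call cutoff have no
  published values; the neutral defaults are choices, surfaced in
  configuration, and the calibration helper is the recommended route when
  labeled reference objects exist.
* The consensus rule formalizes "combining four staining methods" as a
  k-of-n alarm vote across per-stain sections of the same sample; physical
  serial sections are not identical tissue, which the synthetic study does
  not model.
* Whole-section counting semantics assume one detection pass per section
  image; slide-scanner tiling is provided but stitching of per-tile
  detections across tile borders is not (objects are small relative to the
  default tile overlap).
* The scoring table's 0–4 range is only reachable for the whole-section
  components; single-parameter scores span 0–3 by construction.
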