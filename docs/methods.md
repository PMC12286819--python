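# Methods

## Model and assumptions

The pipeline assumes a single glottis per frame, imaged roughly en face, so
that the glottal gap is the darkest structure, the folds flank it as
brighter bands, and a single top-to-bottom axis describes the glottal
orientation.  Everything downstream is driven by one upstream signal: a
per-pixel glottis probability map (post-sigmoid, in [0, 1]) from any
segmentation network.  Thresholds are applied to probabilities, never to
logits; adapters for networks that emit logits must apply a sigmoid first.
Binarization uses a strict `p > t` test so that `t = 0.5` on a 0.5-valued
tie is deterministic.

Two regimes of the same map are used.  At 0.5 the mask is the conventional
glottis segmentation.  At an extremely low threshold (default 10⁻²⁰, the
best-performing value in the 10⁻¹⁵…10⁻²¹ grid explored on annotated
clinical data) the mask additionally covers a rough fold outline plus
scattered false positives; the box-prompt stage is designed to digest
exactly that: fuse, verticalize, close, select the glottis-containing
contour, box it.

Coordinates are 0-based with `x` = column (rightward), `y` = row
(downward), continuous coordinates at pixel centers.  "Left fold" means
image left, not patient left.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| low threshold | 1e-20 | probability | fold-mining regime; best value of the clinical grid |
| CLAHE clip limit | 2.0 | multiple of uniform bin height | conventional mild setting; converted internally to scikit-image's normalized clip (clip/256) |
| CLAHE tiles | 8×8 | — | conventional tiling |
| closing radius | 5 | px | bridges the few-pixel gaps between low-threshold fragments without merging distant speckle |
| detector-failure area | 25 | px² | boxes smaller than this are treated as absent; undersized boxes are a known detector failure mode |
| detector-label margin | 30 | px | "a few dozen" pixels of context around the glottis box for detector training labels |
| smoothing window | 5 | stations (px) | moving average of the scan-line derivative |
| prominence | 5.0 | gray/px | see below |
| backend iterations | 2 | — | best value in the clinical grid |
| midline stations n | 3 | — | quarter/half/three-quarter stations |
| march radius | image width / 2 | px | bound for perpendicular fold search |

**Prominence.**  The boundary detector keeps only smoothed-derivative
extrema with `scipy.signal.find_peaks` prominence ≥ 5.0 gray/px.  The
value follows from noise propagation, not taste: a central difference
maps pixel noise σ to σ/√2, and the window-5 moving average divides by a
further √5, so σ = 5 gray of image noise leaves ≈ 1.6 gray/px of
derivative noise whose peak prominences reach a few units.  A threshold of
5.0 sits above that floor while a weak 30-gray edge still produces a
response of ≈ 6.  Thresholds of order 1 cannot separate noise extrema
from edges at realistic noise levels.

**Peak localization.**  A step edge smeared by the moving average yields a
flat-topped extremum straddling the true boundary.  Peaks are therefore
detected with `plateau_size=(1, None)` and resolved to the plateau edge
nearest the glottis (right edge for the left-boundary maximum, left edge
for the right-boundary minimum): of the stations tied at the extremum, the
one nearest the glottis lies on the fold side of the edge.  Under noise
the localization still scatters by roughly ±2 px — the boundary-recovery
tests bound the *mean* absolute error, not the worst case.

## Pose normalization

The rigid transform rotates about the glottis middle point (mask centroid,
which is robust to asymmetric shapes, unlike the top/bottom midpoint) and
then translates the middle to the image center.  The target center is
`(w//2, h//2)` — a pixel center — because a half-pixel target (e.g.
127.5) leaves the verticalized axis between pixel columns and makes the
rasterized lens tip systematically asymmetric.  Binary masks are resampled
by nearest neighbor, which preserves binarity.

The residual angle after normalization, re-measured from the warped mask's
landmarks, is quantized at ≈ atan(1 px / axis length): the top and bottom
landmarks are midpoints of single pixel runs and carry ±0.5…1 px of
lateral rasterization noise each.  An 80 px axis therefore cannot resolve
residuals below ≈ 0.7°; the half-degree checks run on a phantom with a
200 px axis, where the bound is ≈ 0.29°.  This is a property of the
measurement, not of the transform (which is exact in continuous
coordinates).

## Iterative prompting and fold splitting

The backend contract is a callable `(image, points, box, mask_logits) →
(mask, logits, score)`.  The schedule: iteration 1 passes points only;
iterations 2…k−1 pass points plus previous logits; iteration k adds the
box; `k = 1` degenerates to one call with points and box together.  In the
no-prompt ablation mode, a backend exposing `generate(image)` has its
candidate masks ranked by reported confidence and the best one is taken;
single-output backends are called once without prompts.

The final vocal-fold mask excludes the glottal gap before splitting (a
`include_glottal_gap` switch restores the alternative reading, since
published per-fold scores are consistent with either); the split is a
signed-area test against the infinite line through the top and bottom
landmarks, on-line pixels going left.  The glottis label always comes from
the 0.5-threshold mask, never from the backend.

Closed-glottis frames (empty 0.5 mask) are flagged and produce empty fold
labels; any other per-frame failure is captured in the result object so
batch runs never abort.  Whether the three glottis landmarks belong in a
*fold* prompt is genuinely ambiguous (the gap is not fold tissue); they
are included by default, with `include_glottis_points=False` available.

## Waveforms

The midline is hypothesized from the glottis mask alone: D = midpoint of
the bottommost mask row's run, C = centroid, T = the last mask pixel along
the ray D→C (marched at 0.25 px steps; the final sample is pulled back to
the projection of the last inside pixel's center, so T is a mask pixel, not
a cell edge).  Stations C_i = D + i(T−D)/(n+1).  Perpendiculars through
each station are marched at 1 px steps; the first fold pixel met is the
inner boundary and the last pixel of that contiguous run the outer one.
Per frame and station, VFM = (inner + outer)/2, VFW = outer − inner, and
GAW = glottis pixel count (zero for a closed glottis — a physiological
value, not a missing one).

Frames without a glottal area cannot support the midline construction and
are *flagged* missing in both VFM and VFW rather than dropped, keeping the
series aligned with frame indices; the width-waveform convention of
excluding such frames is applied at CSV export (`--exclude-missing`).

## The phantom

The phantom emulates the geometry and photometry that the pipeline
actually keys on: a dark lens-shaped glottis (intersection of two circular
arcs, half-length h = 40 px, half-width g = 10 px by default — the lens
gives distinct top/bottom landmarks), two brighter rigid fold bands of
fixed width w = 14 px whose inner edges track the oscillating half-width
g(t) = g + A·sin(2πft), a linear illumination gradient along the image
diagonal (so CLAHE has something to equalize), and Gaussian noise added
after quantization.  Closed-glottis frames (g(t) ≤ 0) keep their fold
bands, exercising the frame-exclusion logic.  Gray levels default to
background 60, folds 150, glottis 20.

The emulated probability map assigns ≥ 0.5 to glottis pixels, a tiny value
(10⁻¹⁸) to fold pixels and to a seeded 1% of background pixels — the
low-threshold mining phenomenon and its speckle.  The detector stub
produces the true fold-region box with per-corner jitter, or the
characteristic failures: no box, a grossly displaced box, a 0.3× box.

What the phantom does **not** emulate: color and specularity, mucus
bridges, camera motion, spatially correlated network errors, partial
occlusions, and probability maps that disagree with the ground truth
geometry.  Passing tests therefore demonstrate that the prompt
construction, backend protocol and waveform extraction are correct on
well-behaved geometry — not that any particular clinical Dice level will
be reached; that depends on the real glottis network and backend plugged
in.

## Problem sizes in the shipped checks

The test-suite and acceptance-script runs use 256² frames (512² only for
the pose-residual check, for the angular-resolution reason above), 20
frames per condition in the boundary-recovery sweep (six conditions:
tilt ∈ {−20°, 0°, 20°} × noise ∈ {0, 5}), 50 frames for the end-to-end
oracle suite, 100 frames for waveform frequency recovery (spectral
resolution 0.01 cycles/frame), and 100 seeded cases for the
contour-selection oracle comparison.

## Known limitations

* Boundary points are station-quantized (1 px) with no sub-pixel
  refinement; under noise their scatter (±2 px) can place individual
  points just outside a thin fold.
* The midline split assumes a straight glottal axis; strongly curved
  glottides would need a curved midline.
* Detector boxes that are plausible in size but misplaced are trusted and
  averaged in, degrading the box prompt — only absent or degenerate boxes
  are rejected, since misplacement cannot be detected without ground
  truth.
* Per-frame prompting only; no temporal propagation between frames.
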