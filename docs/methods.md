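# Methods

`bronchoscore` implements a slice-level bronchiectasis detection and
severity-scoring chain for axial lung CT: contrast enhancement, lung-lobe
segmentation, instance detection with severity classification, and
rule-based composite scoring. This note records the models, the parameters
that matter, the synthetic data the tests run on, and the design choices
made where more than one reasonable implementation existed.

## Severity grading and composite scores

A bronchiectasis finding is graded from the ratio r of the dilated airway's
lumen diameter to the diameter of the adjacent pulmonary vessel:

* r ≤ 1 — grade 0 (not dilated),
* 1 < r ≤ 2 — grade 1 (mild),
* 2 < r ≤ 3 — grade 2 (moderate),
* r > 3 — grade 3 (severe).

The clinical interval descriptions ("1–2 times", "2–3 times") overlap at
their endpoints; we resolve boundaries downward (a ratio of exactly 2.0 is
mild), a convention applied consistently by the grading function and the phantom
generator. Ratios at or below 1 return grade 0 rather than erroring so the
scorer can consume arbitrary measured ratios.

Two composites are computed from per-lobe grades, each lobe carrying the
grade of its most dilated finding:

* **Modified Reiff** — the sum of per-region grades. On the six-region
  scheme (five lobes plus the lingula) the maximum is 18; on the deployed
  four-lobe scheme (upper/lower × left/right) it is 12.
* **BRICS** — the worst grade anywhere (0–3) plus an emphysema-range band
  (none → 0, 1–5 → 1, >5 → 2), maximum 5. The bronchiectasis component
  being the across-lobe maximum is inferred from the single
  "degree of bronchiectasis" row of the BRICS rubric together with the
  worked system example (one grade-1 lobe scoring BRICS 1). The emphysema
  extent defaults to 0 — the scoring chain does not measure emphysema — but
  is accepted as user input.

Both lobe schemes are supported throughout; the four-lobe scheme is the
default because the end-to-end system output uses it. Whether the lingula
should contribute to deployed four-lobe scores is left to the caller's
choice of scheme.

## ACER enhancement

ACER composes adaptive contrast enhancement (ACE) with single-scale Retinex
(SSR), in that order: ACE sharpens local detail, then SSR removes the
smooth illumination component from the sharpened image.

SSR computes `r = log(I + ε) − log((I ∗ G) + ε)` with a center-surround
Gaussian `G ∝ exp(−(x² + y²)/(2δ²))`. Numerical choices:

* The discrete kernel is normalized to unit sum so constant images map to
  zero reflectance exactly (the continuous normalization 1/(2πδ²) does not
  sum to 1 on a truncated grid).
* ε = 1.0 on the 0–255 scale avoids log 0; standard SSR practice.
* Kernel support is ⌈6δ⌉ (odd), borders are reflect-padded, and the
  convolution runs via FFT — identical to direct convolution to roundoff.
* The log-ratio is mapped to the display range by a percentile-clipped
  (1%/99% by default) linear rescale. Without clipping, a handful of
  extreme log-ratio pixels (dark lumens beside bright walls) consume the
  whole dynamic range and the displayed contrast *drops*; this is the usual
  Retinex display mapping. A constant log-ratio maps to the range midpoint.

ACE splits the image into a Gaussian low-pass part and the high-pass
residual (`low + high == image` exactly) and recombines as
`low + CG·high`, where the local gain `CG = clip(global_std / local_std, 1,
cg_max)` is an amplification factor computed over an odd window — never an
attenuation, so `cg_max = 1` is the identity, and a uniform image (zero
global deviation) passes through unchanged. No formula for CG accompanies
the method description in the source line of work; this classical local-
statistics gain is our choice and is configurable.

Defaults (δ = 30 px, low-pass σ = 5 px, window 15, cg_max = 3, output range
0–255) are engineering choices; none are prescribed by the method's
description. CT slices are single-channel and processed once; a 3-channel
input is processed per channel and merged. One exact invariance worth
noting: ACE is equivariant to additive intensity offsets, and SSR is
approximately invariant to multiplicative gain (exactly, for ε = 0). The
full ACER output is *not* invariant to additive offsets — the log-ratio
does not cancel a DC shift — so no such property is claimed or tested.

## RDU-Net lobe segmentation

A U-shaped encoder–decoder whose basic unit is a pre-activation residual
block: two 3×3 convolutions at the level's dilation rate (instance norm →
ReLU → conv, twice) plus an identity shortcut added at the end, or a 1×1
projection when channel counts change. Because no nonlinearity follows the
addition, a block with zero convolution weights is exactly the identity —
the motivating property that a badly-learned block cannot degrade features.

The dilation rate cycles small–large–small across resolution levels
(default 1-2-4-2-1 at depth 5), mirrored on the decoder. Pooling is
replaced: downsampling is by stride-2 convolution (classic max-pooling
remains available behind a flag), upsampling by nearest-neighbour plus
convolution, with U-Net skip concatenations. A literal no-downsampling
network at 256² is memory-prohibitive and the architecture retains a
U-shape, so "removing pooling" is interpreted as replacing it with learned
strided convolution. Channel widths double per level from `base_channels`;
the loss is per-pixel cross-entropy (the source work names none). Inputs
must be multiples of 2^(depth−1) per side; violations raise a shape error
naming the constraint.

Training is one Adam step per sample with seeded shuffling; the best-loss
snapshot is returned. All computation is float64 NumPy through the
package's own reverse-mode autodiff engine (`bronchoscore.nn`), so training
traces are bit-reproducible for a fixed seed.

## HDC schedule analysis and the gridding oracle

Stacked dilated convolutions can leave input pixels that never influence an
output — the gridding effect. `receptive_field_coverage` measures this
exactly: starting from one output position, each layer spreads dependency
to offsets `rate × tap`, and the final reachable set is the exact
receptive-field support (the computation is a Minkowski sum, so layer order
is irrelevant).

Defining "gridding-free" needs care at the footprint boundary. For any
schedule whose largest rate exceeds 1, the outer band of the square
footprint (width `(r_max − 1)·(k//2)`) is reachable only through extremal
tap chains and is sparse regardless of the schedule — a truncation
artifact, not lattice gridding. We therefore evaluate coverage over the
footprint interior (Chebyshev radius `R − (r_max − 1)·(k//2)`, with
`R = (k//2)·Σ rates`): a schedule is gridding-free iff every interior
offset is reachable. Under this oracle the canonical gridding cases
(stacked 2-2-2, any singleton rate > 1, shared-factor stacks) all show
interior holes, while the three 5-layer candidates with maximum rate 5 —
1-2-5-2-1, 1-3-5-3-1, 2-3-5-3-2 — are all gridding-free. The full-footprint
coverage fraction is also reported; notably 2-3-5-3-2 misses the offsets
±14 at footprint radius 15, which is why the naive full-square criterion
would misclassify it.

The schedule enumerator returns every rate stack satisfying the three
design conditions: distinct rates pairwise coprime ("no common factor",
interpreted over the distinct-rate set since valid schedules repeat rates),
a unimodal small–large–small cycle, and interior gridding-freedom, with
rates bounded by `max_rate`.

## HDC Mask R-CNN detector

A compact two-stage detector in the Mask R-CNN mould, sized for CPU
training on phantoms:

* **Backbone** — a 3×3 stem plus two stride-2 stages (output stride 4,
  widths 8/16/32 by default), then the HDC stage: the schedule's stacked
  dilated 3×3 convolutions at constant resolution. The stage that would
  normally downsample again instead dilates, so the deepest features keep
  the stride of the preceding stage — the design intent of trading
  resolution loss for receptive field. Where exactly dilation replaces
  downsampling is not specified by the source description; placing it in
  the deepest stage keeps the rest of the detector standard.
* **RPN** — one square anchor per feature cell (side 20 px by default,
  matched to phantom lesion sizes), objectness plus 4 box deltas in the
  standard parametrization.
* **RoI heads** — RoIAlign (bilinear, 7×7) → fc → class scores over
  severity grades {1, 2, 3} plus background, and class-agnostic box
  refinement; a mask head (RoIAlign 14×14 → conv) predicts the instance
  mask. "No finding" is the absence of detections, not a class.

Training uses ground-truth boxes plus jittered copies as positive RoI
proposals and random non-overlapping crops as negatives — the standard
shortcut that decouples head learning from proposal quality at small scale
— while the RPN trains on IOU-matched anchors (positive ≥ 0.5 or best per
target, negative < 0.3) and alone generates proposals at inference. The
per-step trace records the combined objectness + box + class + mask loss.
Inference: top RPN proposals (NMS 0.7) → heads → confidence threshold 0.5
and NMS 0.5, all configurable.

Detections are assigned to the lobe their instance mask overlaps most
(ties to the lower lobe id; zero overlap leaves them unassigned; the box
footprint is the fallback when no mask is available), and each lobe's grade
is the maximum severity class among its detections.

## Evaluation statistics

The evaluation unit for detection confusion counts is per-lobe-per-image: a
unit is truth-positive if it contains an annotated lesion and
prediction-positive if any detection was assigned to it — a mislocated
detection makes its lobe predicted-positive (and the lesion's lobe a miss),
which matches how the per-lobe scoring system consumes detections.
Sensitivity is TP/(TP+FN), specificity TN/(TN+FP), both raising an explicit
error when undefined. Localized agreement is reported separately: greedy
confidence-descending one-to-one matching at IOU ≥ 0.5 yields the mean
matched IOU (reported over matched pairs) and the matched class pairs for
classification accuracy, whose per-class breakdown is the fraction of
class-c *calls* that are correct.

## The phantom generator

Real screening LDCT with expert lesion annotations is not distributable
with this package, so all tests run on seeded synthetic phantoms that
emulate the *structure* of such data: an 8-bit slice with two elliptical
dark lung fields (≈40/255) on a soft-tissue background (≈150/255),
partitioned into lobes by a fixed four- or six-region template; bright
vessel disks (≈200/255); and each lesion drawn as a bright annular airway
wall (2 px thick) around a darker lumen, with an adjacent vessel disk at a
center-to-center offset of 1.5 lumen diameters. The lumen diameter is
`ratio × vessel diameter`, so every annotation's severity class follows
from the same grading rule the scorer applies, and per-lobe ground-truth
findings are exact by construction. Default conditions: 256² grid, vessel
radius 4 px (scaling proportionally on smaller grids), Gaussian noise σ=2,
smooth background shading of amplitude 6, and a severity mix of
mild : moderate : severe ≈ 588 : 566 : 838 — the class distribution of the
motivating screening cohort; per-lesion ratios and lobes can be pinned
explicitly. Placement rejection-samples lesion centers until the whole
airway cross-section lies inside the target lobe; exhaustion raises an
error naming the lobe.

What the phantoms do *not* model: fissure anatomy, airway trees seen
obliquely, HU calibration, emphysema texture, 3D continuity. Passing tests
therefore demonstrate correctness of the algorithmic chain (enhancement
identities, geometry-exact ground truth, score propagation, trainability),
not clinical performance on real LDCT; the headline clinical metrics of the
motivating study are out of scope by design.

## Desk-scale training budgets

The recovery experiments are sized for a single CPU: segmentation uses
depth 4 / base 8 at 64×64 on 20 phantoms for 30 epochs (mean held-out lobe
IOU ≥ 0.8, typically ≈0.99), and the detector overfits two 96×96 phantoms,
halving its combined loss within 200 steps and recovering the planted
lesions (box IOU ≥ 0.5, correct class) by 400 steps. These sizes are the
package's reference configurations for its own test suite, not claims about
full-scale training.

## Known limitations

* The neural models are desk-scale by design; no GPU path exists.
* The pipeline runs the detector once over the lung-masked slice and then
  assigns detections to lobes, rather than detecting per lobe crop; the
  per-lobe crop API (`extract_lobe_images`, with offsets for mapping
  detections back) is available to callers who want the latter.
* Scoring is per-slice; volumetric aggregation across slices is out of
  scope.
* DICOM support covers single-frame CT with rescale slope/intercept and a
  configurable display window (default −1000…400 HU).
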