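# Methods

## The quality-control problem

A lumbar radiograph is *qualified* when every objective criterion of its
projection passes. The criteria operate on a per-pixel anatomical label
mask, so the pipeline is segmentation followed by deterministic rule
evaluation. The package covers three projections with separate label
schemas:

| projection | labels |
|---|---|
| anteroposterior | background, vertebral_body, spinous_process, pelvis, l3, bilateral_shadow, outer_contour |
| lateral | background, vertebral_body, spinous_process, l3, bilateral_shadow, outer_contour, intervertebral_foramen, sacral_vertebrae |
| oblique | background, vertebral_body, inferior_articular, pelvis |

L3 carries its own label because the bilateral-shadow criterion needs its
area, but it is still a vertebra: spine counting and the anatomy-relative
reference frame use the union of `vertebral_body` and `l3`.

## Criterion measurements

* **Spine count** — 8-connected components of the vertebral-column labels
  with area at least the visibility floor. Exactly 7 (T11–L5) is required;
  both under- and over-inclusion fail (too many thoracic vertebrae is the
  dominant real-world defect).
* **Bilateral-shadow ratio** — shadow area A over L3 area B, directly from
  pixel counts. Must lie in (0, 0.21); a ratio of exactly 0 passes, since
  absence of the artifact is the desired state.
* **Spinous centreline (AP)** — mean horizontal centroid of all
  spinous-process components, normalized by the vertebral-column bounding
  box (box-left → 0, box-right → 1). Required range (0.4, 0.6).
* **Visibility** (pelvis, spinous, foramen, sacrum) — total label area at
  least the floor.
* **Dog sign (oblique)** — at least 3 inferior-articular components, and
  their mean horizontal centroid within (0.265, 0.365) of the column
  width. Count rule and interval endpoints are configurable (a strict
  "> 3" variant exists because both conventions appear in the field).

Numerical conventions: 0-based pixel indices; centroids are unweighted
means of member-pixel coordinates; all interval endpoints are inclusive by
default (configurable); the visibility floor defaults to 0.05% of the
image area. Positions are measured in the column bounding box rather than
the image frame, which makes every verdict invariant to collimation,
cropping and uniform translation; patient rotation still registers because
it displaces the spinous processes *relative to* the vertebral bodies.
Unmeasurable quantities (no spinous component, empty L3) fail their
criterion with an explicit reason rather than raising.

## Segmentation network

The segmenter is an encoder-decoder U-net whose every encoder and decoder
convolution block is followed by a concurrent spatial/channel
squeeze-and-excitation (scSE) block:

* sSE: a learned 1×1 projection squeezes the C channels to one map q;
  M̂[h,w,c] = M[h,w,c]·σ(q[h,w]).
* cSE: global average pooling squeezes space to z ∈ R^C; two affine maps
  C → C/r → C with ReLU and a logistic gate give channel weights in (0,1).
* The branches combine elementwise; default is max (sum is available).
  The reduction ratio defaults to r = 2, which keeps a non-trivial
  bottleneck at the small channel counts used here.

Defaults: depth 4 and 16 base channels at 256×256 input (the tests and the
acceptance experiment use depth 2 / 8 channels at 64×64 to stay desk
scale); He initialization; soft-dice + cross-entropy loss (robust to the
extreme class imbalance of thin structures); Adam with learning rate
1e-3–2e-3. Input images are min-max normalized to [0, 1] per image;
constant images are rejected as contrast-free.

Everything is implemented in NumPy with explicit forward and backward
passes (im2col convolution, argmax-routed max pooling, nearest-neighbour
upsampling, SE blocks, softmax/dice/cross-entropy gradients, Adam). Ties
in the max-combine go to the spatial branch; ties in pooling to the first
window element — both deterministic. Training is bit-reproducible given
the seed. The backward pass is verified against central finite differences
in float64 (relative error < 1e-3 away from non-differentiable tie
points), and the SE blocks against independent scalar-loop oracles.

Inference is a two-stage cascade: a binary network first delineates the
lumbar region, then a multi-class network labels structures, with pixels
outside the stage-1 region forced to background. The three projections use
independent model pairs. Checkpoints are a `weights.npz` plus a JSON
sidecar carrying the full configuration and label schema.

## Synthetic phantoms

No annotated clinical dataset is distributable, so training and validation
run on seeded geometric phantoms: stacked rectangular vertebral bodies
(with gaps), elliptical spinous processes placed at a controllable offset
within the column width, an L3 shadow region grown pixel-exactly to a
target area ratio, round inferior-articular facets at a controllable
column position, a trapezoid pelvis, tapering sacrum, lucent foramina and
a thin outer contour, rendered with per-structure intensities, contrast
jitter and additive Gaussian noise (sd 0.03 by default). Geometry is a
deterministic function of the spec; only intensities consume randomness.

Each continuous control is expressed in the exact units its criterion
measures, so rendered geometry hits the requested value to within half a
pixel (≲ 0.01 normalized at 256×256), and each defect type flips exactly
one criterion. Datasets draw qualified samples from comfortably in-range
distributions (centre offset U(0.44, 0.56), shadow ratio U(0.03, 0.18),
IAP offset U(0.285, 0.345), 3–4 IAPs) and unqualified samples from one or
two defects chosen uniformly per projection (extra vertebrae, off-centre,
heavy shadow, missing pelvis/spinous/foramen/sacrum, displaced IAP line,
too few IAPs). Ground-truth criterion labels are computed from the spec
against the *same* threshold object the engine uses, so generator and
engine are threshold-consistent by construction; samples whose continuous
controls fall within 0.01 of a threshold endpoint are flagged borderline
and excluded from round-trip statistics because rasterization can move the
measurement across the boundary.

What the phantoms do **not** emulate: projection physics, bone texture and
overlap, soft-tissue gradients, scoliosis/curvature beyond a simple
lateral bend, foreign bodies, and exposure faults. Passing phantom tests
therefore demonstrates the correctness of the measurement/verdict logic
and the trainability of the network, not clinical segmentation accuracy on
real radiographs.

## Evaluation statistics

Per-structure DSC = 2|P∩T| / (|P|+|T|); when both masks lack the structure
the DSC is defined as 1.0 and flagged, since the two agree it is absent.
Summaries over structures report the unweighted mean, sample (n−1)
standard deviation and extremes, rounded to two decimals. Verdict
agreement uses a 2×2 table with "qualified" as the positive class:
accuracy (tp+tn)/N, sensitivity tp/(tp+fn), specificity tn/(tn+fp), and
qualified rates as percentages with half-up one-decimal rounding, the
presentation convention of clinical reports.

## Problem sizes

The test suite and `scripts/acceptance.py` use 200 phantoms at 256×256 for
the round-trip statistic and a 50-train / 10-held-out cascade experiment
at 64×64 (depth 2, 8 base channels, 25 epochs, batch 8) — sizes chosen so
the full run stays in the minutes range on a single CPU core while leaving
wide margins over the asserted thresholds (round-trip agreement ≥ 95%,
held-out foreground DSC ≥ 0.80; measured ≈ 100% and ≈ 0.99).

## Known limitations

* Training at clinical resolution (512+ pixels, hundreds of images) is out
  of reach of the NumPy implementation's speed; the architecture supports
  it, the wall-clock does not.
* The lateral projection has no centring criterion (its criterion set
  deliberately mirrors the reference standard), so a laterally decentred
  lateral image with all structures visible is reported qualified.
* Subjective criteria (penetration, contrast, trabecular detail) and
  foreign-body detection are not modeled.
* Intensity-based image quality (noise, resolution, dose) is out of scope;
  the verdict depends only on the label mask.
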