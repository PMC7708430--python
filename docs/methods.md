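# Methods

## Scope and model

`panseg` quantifies three histologic classes in H&E-stained pancreas
sections — normal acinar tissue, acinar-to-ductal metaplasia (ADM), and
dysplasia — plus a residual "other" cellular class and white background.
Each class is segmented by an independent binary UNet; the three probability
maps are fused by fixed priority rules into one label map, which is then
quantified as area fractions of the cellular region.  The central modelling
assumptions are:

* non-tissue pixels are white: every channel strictly greater than 200
  (8-bit).  This single rule defines background everywhere — in
  normalization statistics, in fusion, and in the denominator of every area
  fraction;
* a binary network per class, rather than one multi-class head, so each
  model can be trained, tuned and thresholded independently;
* conflicts between binary predictions are resolved by biology-informed
  priority (acinar over ADM over dysplasia over generic tissue), not by
  argmax of probabilities;
* serial-section references (IF masks) are spatially unaligned with the
  H&E section, so cohort agreement is measured by area-fraction rank
  correlation and windowed SSIM, not pixel-wise overlap.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| background threshold | 200, strict `>` | 8-bit intensity | definition of non-tissue |
| normalization crop | 5000 px, 50% overlap | pixels | corrects within-section staining gradients |
| tile size / stride | 512 / 256 (desk: 64 / 32) | pixels | training and inference unit; 50% overlap averaging |
| epochs, batch, lr | 50, 32, 7e-4 (Adam) | — | published training recipe |
| relevant / other tile fractions | 0.8 / 0.075 | — | training-set composition; 0.075 is the midpoint of the stated 5–10% range |
| class thresholds | 0.3 / 0.5 / 0.7 | probability | published operating points (acinar / ADM / dysplasia), inclusive `≥` |
| BCE clamp ε | 1e-7 | — | keeps log finite at saturated predictions |
| SSIM | window 7, k₁ 0.01, k₂ 0.03, L from joint range | — | stated metric parameters |
| shear augmentation | ±10° | degrees | magnitude unstated upstream; modest, configurable |

## The UNet and its numerics

No neural-network framework is assumed: the UNet (two 3×3 convolutions +
ReLU per level, 2×2 max-pool, nearest-neighbour upsampling with skip
concatenation, 1×1 sigmoid head) and its backpropagation are implemented in
numpy, trained with Adam.  Design choices:

* **Reflect padding, not zero padding.**  A constant tile then stays
  constant through every layer, so predictions carry no tile-border
  artifact and stitching overlapping tiles of a featureless region is
  exactly constant.  Gradients are folded back through the reflection.
* **Same-padded convolutions** keep output aligned with input, which
  overlap-averaged stitching requires (the original architecture crops).
* **Loss on logits.**  BCE is computed in the numerically stable
  softplus form and the gradient `(σ(z) − y)/N` is taken directly.
* **Scale presets.**  Full scale is depth 4 / 64 base channels / 512-px
  tiles.  The desk preset is depth 2 / 8 base channels / 64-px tiles: on a
  single CPU a depth-4/base-16 model costs ~1 GFLOP per tile step and
  cannot finish the desk experiments in minutes, while the depth-2 model
  trains all three classes in ~5 min and reaches held-out Dice > 0.9 on the
  synthetic task.  Every code path is identical across presets.
* **Model selection.**  Lowest held-out BCE epoch by default; highest
  held-out Dice (computed on tiles, the training unit) when
  `selection="dice"`.
* Training is bit-reproducible for a fixed seed on one thread; max-pool
  ties are broken by first argmax, single winner.

## Stitching: exact conservation

Stitched pixels are the unweighted mean of all covering tile predictions.
Floating-point sum/count rounds off 1 ulp when an odd number of identical
values is averaged, so the stitcher tracks per-pixel min and max of the
contributions and returns the common value verbatim wherever min == max.
This makes cut→stitch a bit-exact round trip without changing the
mathematical definition.

## Stain normalization

Reinhard colour transfer is the default, computed in CIELAB (D65); the
original lαβ space is available as `space="lab_ruderman"`.  Statistics are
computed over tissue pixels only, and background pixels are copied through
unchanged by every normalizer.  A zero-variance source channel maps to the
reference mean (degenerate rule; arises on synthetic constant regions —
channel standard deviations below 1e-9 are snapped to zero).  Crop-wise
mode normalizes overlapping crops independently and blends overlaps by
unweighted averaging; how overlaps should be blended is not specified
upstream, and averaging was chosen over last-write for smoothness.  Images
smaller than one crop degrade to whole-image normalization with a logged
notice.

Macenko (SVD of the optical-density cloud, 1st/99th percentile angles) and
Vahadane-style (sparse NMF; scikit-learn's NMF with an L1 penalty stands in
for the original SPAMS dictionary learner) normalizers are comparison
baselines.  Both raise on rank-deficient OD input (e.g. gray images).

## The synthetic-histology generator

The generator emulates exactly the statistical structure the pipeline
assumes: spatially coherent classes with distinct colour/texture, white
background, ring-shaped ductal lesions with background lumina, a smooth
multiplicative staining gradient within each image, per-channel colour
shifts between images, and Gaussian pixel noise applied after class
colouring so the label map stays exact by construction.  Matched binarized
IF channels are derived from the truth map (AMY = acinar,
panK = ADM ∪ dysplasia, DAPI = all cellular).

Default composition (acinar 0.45, ADM 0.20, dysplasia 0.15, other 0.20 of
the cellular area; ~72% tissue coverage; noise σ = 4; gradient amplitude
0.15) reflects a mid-progression section dominated by acinar tissue with
substantial ductal lesions.  Cohort factories draw compositions from a
Dirichlet centred on that mix so area fractions vary across samples, and
colour shifts up to ±10% emulate between-image staining differences.  The
palette is a free, documented choice — classes are separable primarily by
colour, with ring morphology as a secondary cue — because the source
tissues' colour distributions are not characterised anywhere we could
inherit them from.

Lesion placement: rings are sized so the nominal per-class lesion count
covers the class's area quota; when a dense packing cannot fit, radii
shrink and extra smaller rings top up the quota, so realized fractions
track targets within ±0.05.  What a green test on this generator
establishes is that the *pipeline machinery* (normalization, training,
stitching, fusion, quantification, statistics) works end to end; it does
not establish performance on real histology, where classes differ by
subtler morphology than colour.

## Stain-perturbation robustness

Robustness to staining differences is probed by synthetically altering an
image — each RGB channel multiplied by an independent factor up to ±25%,
plus Gaussian pixel noise — renormalizing, re-predicting, and computing the
Dice of each class's fused indicator mask against the unperturbed run.  The
harness computes the background mask once from the unperturbed image and
reuses it for every perturbed run: the perturbation emulates staining
variation of one physical section whose glass geometry is invariant, and a
strong downward channel gain would otherwise pull the white background below
the 200-intensity rule, flooding the normalization statistics with glass
pixels (measured: the residual tissue difference after renormalization
triples when that happens).

## Degenerate inputs and conventions

* Dice of two empty masks is 1 (agreement on absence).
* SSIM with zero joint dynamic range (two identical constant images)
  is 1 by the identity property; SSIM's optional Gaussian pre-blur default
  is 0, with σ = 1 used in the cohort harness.
* Mann–Whitney U uses the exact null distribution when min(n) ≤ 8 and the
  data are tie-free, otherwise the normal approximation with continuity
  and tie corrections; U counts (a, b) pairs with a > b plus ½ per tie.
* Spearman on a constant vector raises; the cohort evaluator catches this
  and flags the channel instead of failing the run.
* An all-background label map reports undefined (None/NaN) fractions, not
  zeros.
* Fusion thresholds are inclusive (`≥`), also at the non-default operating
  points.
* quantify() of 0 cellular pixels, empty tile lists, single-class training
  masks, and images smaller than one tile/crop all follow explicit
  documented rules (error, warn-and-proceed, or degrade) rather than
  crashing.

## Known limitations

* The synthetic task is easier than real histology; desk-scale Dice values
  (~0.9) say nothing about performance on real sections.
* The numpy UNet is CPU-bound and desk-scale; the full-scale preset is
  provided for completeness but is not practical without hardware
  acceleration.
* Vahadane normalization approximates sparse dictionary learning with
  plain sparse NMF; stain vectors recovered on synthetic two-stain
  mixtures are within 5° of truth, but it is not the reference
  implementation.
* Pyramidal whole-slide formats, lesion-instance counting and PanIN
  grading are out of scope.
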