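# Methods

## The problem and the model

Early gastric cancer (EGC) management hinges on two image-level decisions:
is a lesion present (detection, EGC vs non-EGC), and how deep does it
invade (depth, mucosal T1a vs submucosal T1b)?  Both are fine-grained
calls: the class evidence lives in subtle textural and chromatic changes
inside a small part of the frame, and a classifier trained on frame-level
labels alone is free to exploit any background regularity of the
collection instead — dataset bias.  The remedy implemented here is
attention supervision: train the classifier so that its own
class-evidence map is pushed onto the expert-annotated lesion region.

The class-evidence map is gradient-weighted class activation mapping
(Grad-CAM).  For class score `y^c` and last-convolutional-layer feature
maps `A^k` (K maps of `u x v`):

    alpha_k = (1/uv) * sum_ij  d y^c / d A^k_ij
    L^c     = relu( sum_k alpha_k A^k )

The composite training objective is

    L = w_ce * CE(softmax(y), class) + w_cam * MSE( Lhat^c , M )

where `M` is the ground-truth lesion mask downsampled to the feature grid
(all-zero for frames without a lesion, so activation on normal frames is
penalised), `Lhat^c` is a normalised training surrogate of the Grad-CAM
map of the *true* class, and `w_ce = w_cam = 1` by default.  A soft-Dice
alternative for the localization term is available
(`TrainingConfig(cam_loss="dice")`).

## Numerical choices in the localization term

Three choices make the term trainable; all are deliberate and local to
training — evaluation always uses the standard rectified, per-image
max-normalised Grad-CAM.

1. **Stop-gradients on `alpha_k` and the normalising scale.**  The pooled
   weights and the scale are treated as constants during backpropagation,
   so the term shapes the feature maps `A^k` directly (first order).  Full
   differentiation through `alpha_k` would require second-order
   backpropagation for no clear benefit at this scale.
2. **No rectification inside the loss.**  `Lhat` uses the unrectified
   weighted sum: rectifying first would zero the gradient wherever the map
   is negative, and an all-negative start (common at initialisation) could
   never recover.  Background cells are still driven to 0 and lesion cells
   to 1, so the rectified evaluation map converges to the mask.
3. **Batch-level scale, not per-image.**  `Lhat = pre / max_batch|pre|`.
   Normalising each frame by its own maximum rescales even a vanishing
   activation to unit magnitude, so a frame with an all-zero target could
   never satisfy its target and the penalty would erode feature responses
   indefinitely (observed as a collapse of both localization and
   classification).  With one shared batch scale, weakly activated frames
   score near zero and lesion frames set the scale.

The mask enters the loss at feature resolution (area-mean then threshold
0.5), which keeps the differentiable path small; for evaluation the CAM is
instead bilinearly upsampled to image resolution and compared with the
full-resolution mask, mirroring how activation maps are read clinically.

## Backbone

Three architectures satisfy the same contract (class scores, last-conv
feature maps, and gradients of any class score w.r.t. those maps):
`tiny-test` (two conv blocks, for unit tests and finite-difference
oracles), `vgg-style` (three double-conv blocks with 2x2 max pooling; the
default), and `resnet-style` (conv stem plus identity-skip residual
blocks).  The implementation is a compact, fully deterministic CNN engine
with explicit forward/backward passes over numpy arrays; weights are He
initialised from a seed, optimisation is Adam, and inference is
deterministic.  Pretrained weights are not used: transfer learning is not
what this package studies, and every experiment here is self-contained.
Gradient correctness is enforced by finite-difference tests (1e-3 relative
tolerance on `d y^c / d A^k`).

The Grad-CAM hook point is the activation of the last convolutional layer;
for `vgg-style` the third block's pooling stage sits after the hook, so
the map retains input/4 resolution (16 x 16 for 64 px frames).

## Synthetic cohorts

The study-scale endoscopy collection this method was designed for is
hospital data and not publicly deposited, so the package ships a seeded
generator whose cohorts reproduce the *statistical structure* that makes
the problem interesting:

- **Patient grouping.**  Each patient contributes 2–6 frames of one class
  sharing lesion morphology with per-frame viewpoint variation; all of a
  patient's frames stay in one cross-validation fold.
- **Class imbalance.**  The default class mix is 85.2 / 7.8 / 7.0 percent
  (non-EGC / T1a / T1b), matching the study-like regime where normal
  frames dominate.
- **Subtle in-lesion cues.**  Backgrounds are warm, texture-correlated
  mucosa with smooth rugal folds.  Lesions are connected blobs (1–40% of
  the frame, ellipse with smoothed radial perturbation) whose class cues
  sit ~2x above the background noise floor: surface roughness
  (texture_contrast 0.12) and a mild reddish shift for T1a; stronger
  roughness (0.15), a brighter marginal rim (0.35) and a stronger colour
  shift for T1b — echoing the clinical depth cues (irregular surface,
  marginal elevation).
- **Dataset bias.**  Tiny bright procedure-artifact specks appear in the
  background (never inside the lesion) with probability 0.9 on
  lesion-class frames and 0.05 on normal frames.  This is the deliberate
  shortcut channel: real exam collections carry exactly this kind of
  class-correlated background regularity (cancer endoscopies involve more
  manipulation), and an unguided classifier can reach high AUC from it
  while attending nowhere near the lesion.  30% of normal frames also
  carry a smooth benign prominence without a mask.

What the generator does **not** emulate: real mucosal appearance,
instrument/illumination diversity, inter-annotator mask variability, and
background mucosa whose inflammatory state itself correlates with cancer
risk.  Passing tests on these cohorts therefore demonstrate that the
training machinery behaves as designed — that attention supervision moves
the evidence map onto the lesion when shortcuts exist — not that any
particular clinical accuracy would be reached on real endoscopy.

## Data preparation

Quality exclusion mirrors the study's criteria operationally: a frame is
dropped when the variance of a discrete Laplacian of its luminance (blur /
defocus score) falls below a threshold or when the fraction of
near-saturated pixels (all channels >= 0.98; halation) exceeds one.  Both
thresholds are disabled by default — the study states criteria, not
detectors, so the operators are this package's choice.  "Poor air
insufflation" has no operational definition and is not implemented.

Patients are shuffled by seed and dealt round-robin into five folds
(near-equal patient counts; image counts differ since patients contribute
different numbers of frames).  The five rotation groups use folds
(g, g+1, g+2) for training, g+3 for validation and g+4 for testing, so
each fold tests exactly once.  The design is fixed at k = 5; other k are
rejected rather than silently supported.  Fixed-size per-class test
sampling (e.g. 150 + 150 frames for depth) is provided to equalise test
sets across rotation groups.

## Evaluation

Classification: sensitivity, specificity, PPV, NPV (percent; undefined
rates reported as missing, never as 0) and ROC AUC by trapezoidal
integration, pooled across folds by concatenating score/label vectors.

Localization: the normalised CAM is upsampled to frame resolution,
binarised at half its maximum, and the largest 8-connected component is
the suspected lesion region.  Overlap is intersection-over-union against
the truth mask (both-empty counts as correct non-activation; an
intersection-over-truth alternative is available since the study's exact
metric definition is in an unavailable appendix).  The correct ratio is
the fraction of frames reaching 0.5 overlap.  Localization is scored only
on frames that carry a truth mask.

## The mode-comparison experiment

`run_mode_comparison(seed)` draws a cohort of 120 patients (~600 frames at
64 px; experiment class mix 0.50/0.25/0.25 for statistical resolution at
desk scale), takes rotation group 0, and trains the same seeded
`vgg-style` backbone twice — plain cross-entropy vs the composite
objective — with identical initialisation, batch order and budget
(15 epochs, Adam lr 3e-3, batch 16).  It reports per-mode test AUC,
diagnostic rates and the correct ratio at 0.5 overlap.  Problem sizes were
chosen so a full comparison runs in a few minutes on one CPU core.

Expected behaviour, and its limits: the lesion-supervised model should
localize well and classify well; the plain model typically reaches a
similar AUC (partly through the speck shortcut) while its activated
regions often miss the lesion.  The size of the correct-ratio gap
fluctuates between seeds — on some draws the plain model also finds the
lesion — which is why directional conclusions should be taken from
several seeds, not one.

## Contingency statistics

2x2 tables are laid out rows = exposure (reference first), columns =
outcome (accurate, inaccurate).  The odds ratio of an accurate outcome for
the comparison row vs the reference is (c/d)/(a/b) with a 95% Wald
interval `exp(ln OR ± 1.96 sqrt(1/a+1/b+1/c+1/d))`; a zero cell requires
the documented Haldane 0.5 correction, which is flagged in the result.
Chi-squared is Pearson's statistic without continuity correction; Fisher's
exact test is two-sided (mass of all margin-fixed tables no more probable
than the observed one, verified against full enumeration in tests).
Percentages round half-up to one decimal, matching clinical-table
convention.  Multivariable (adjusted) odds ratios are out of scope: their
underlying joint cross-tabulations are not available, so they are not
reproducible from printed counts.

## Known limitations

- The CNN engine is desk-scale by design; it is not a route to study-scale
  training, and no pretrained weights are involved.
- The localization term's stop-gradient treatment makes the gradient of
  the composite loss a first-order approximation; finite-difference checks
  therefore validate the Grad-CAM map itself, not the full second-order
  loss gradient.
- Synthetic cohorts prove machinery, not clinical performance (see above).
- The correct-ratio gap between training modes is seed-dependent at this
  problem size.
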