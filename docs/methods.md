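# Methods

## Problem and model

`cardioseg` segments ten cardiac substructures in thoracic CT — the four
chambers (LV, RV, LA, RA), three medium vessels (ascending aorta AA,
descending aorta DA, pulmonary artery PA) and three small veins
(pulmonary vein PV, inferior vena cava IVC, superior vena cava SVC) —
with a two-stage, coarse-to-fine cascade of 2D U-Nets:

1. **LS-Net** (coarse stage) segments the coarse group (CG) of large,
   easy structures from each normalized slice.
2. **SS-Net** (fine stage) segments the fine group (FG). Its input
   concatenates the slice with one binary channel per CG structure,
   taken from LS-Net's predicted masks. These channels are an
   *anatomical prior*: they hand the second network the position, shape
   and scale of the large structures, which is exactly the information
   that disambiguates small, low-contrast veins (the PV enters the LA,
   the IVC sits below the RA, the SVC runs beside the AA).
3. The stage outputs are fused into one label map; on conflicting
   voxels the coarse label wins, so CG structures constrain the region
   in which FG structures may appear and false positives outside it are
   suppressed.

The rationale for the cascade is the severe size imbalance of the task:
in a typical case the LV is an order of magnitude larger than the SVC,
and a single flat 11-class network underfits the small classes.
Splitting the label space lets each network solve a balanced subtask,
and the prior channels couple the two subtasks anatomically.

Three built-in groupings are provided (`registry.builtin_groupings`):
by circulatory anatomy, by size (chambers coarse / vessels fine), and a
deliberately unconnected grouping. The size-based grouping is the
default; the grouping-sweep harness reproduces the comparison that
motivated that choice.

Both networks share one topology: four encoder modules of two 3×3
convolutions (BN + ReLU) followed by 2×2 max-pooling, a bottleneck, a
symmetric decoder with skip concatenations, then an output module of
two 3×3 convolutions, dropout, and a softmax-activated 1×1 convolution.
Batch normalization is applied to every convolution except the final
1×1. Upsampling is nearest-neighbour ×2 followed by a 3×3 convolution
(a learned 2×2 transposed convolution is available via
`NetSpec.transposed_up`). Channel widths double per level from
`base_width` (64 at full scale; the test suite uses 8 or less). The
networks are 2D and volumes are processed slice-by-slice, which matches
the strongly anisotropic acquisitions this framework targets (5 mm
slices vs ~1 mm in-plane).

### Tensor backend

No deep-learning framework is used: the `cardioseg.nn` subpackage
implements the required layers (3×3/1×1 convolution, batch norm, ReLU,
max-pool, nearest and transposed-conv upsampling, dropout, channel
softmax) directly on NumPy with hand-derived backward passes, plus the
Adam optimizer. Convolutions are evaluated channels-last as nine
shifted (N·H·W, C)×(C, O) BLAS products. All layers are verified
against finite-difference gradients in the test suite. The engine is
single-threaded-CPU oriented; everything is float32 and fully seedable.

## Loss

Training minimizes `loss = dice + α · sd`:

- **Dice term** `1 − (1/C) Σ_c k·Σ P_c G_c / (Σ P_c² + Σ G_c²)` with
  `k = 2` (standard soft Dice) by default. A literal variant with
  `k = 1`, under which a perfect prediction scores 0.5 instead of 0, is
  kept behind `LossConfig.dice_as_printed` for fidelity testing; both
  variants have identical minimizers.
- **SD term** `(1/C) Σ_c (1/V) Σ_i (P_ic − G_ic)² D_ic^γ`, where `D` is
  each voxel's unsigned Euclidean distance (in mm, slice-wise 2D) to
  the boundary of the gold region of class `c`, normalized by its
  per-slice maximum so `D ∈ [0, 1]`. Errors far from the true boundary
  are penalized hardest, complementing Dice's insensitivity to boundary
  placement.

Defaults: `α = 1`, `γ = 1`, background channel included in the class
sums. `V` is the per-channel voxel count. Distances are 2D per slice to
match the 2D training regime, and are precomputed once per run when no
augmentation is active (the gold labels are static); with augmentation
they are recomputed per epoch from the augmented labels. The max
normalization keeps the two loss terms on comparable scales at `α = 1`.

## Training protocol

Adam (β = 0.9/0.999), initial learning rate 1e−4, batches of 12 slices,
up to 300 epochs, 6:2:2 random train/validation/test split and optional
five-fold cross-validation over the non-test 80%. After every epoch the
validation hybrid loss is evaluated; if it has not strictly decreased
for 10 consecutive epochs the learning rate is halved
(`PlateauScheduler`). The weights of the lowest-validation-loss epoch
are kept. SS-Net's training priors default to the frozen LS-Net's
predictions (`prior_source="predicted"`); gold-mask priors are
available as an ablation. Augmentation (train-time only) is a random
horizontal flip, up to ±5% in-plane translation and 95–105% isotropic
scaling, applied with one shared transform to image, labels and prior
channels (nearest-neighbour for the discrete channels, zero fill
outside the frame).

Scaled-down protocols used by the test suite and acceptance script keep
this structure but shrink the problem (see below) and raise the
learning rate to 3–5e−3 with batches of 4–12, since only a few hundred
optimizer steps fit in a desk-scale run; augmentation and dropout are
disabled there because those runs operate far below the overfitting
regime.

## Preprocessing

CT volumes are in Hounsfield units; normalization clips to [0, 2048]
and divides by 2048 (`normalize_hu`), so −100 HU → 0, 1024 HU → 0.5 and
3000 HU → 1. A guard rejects double normalization.

## Evaluation

Per case and per structure, in 3D with physical spacing:
DSC `2|G∩P|/(|G|+|P|)`, Recall `|G∩P|/|G|`, Precision `|G∩P|/|P|`, and
HD95 — the symmetric 95th-percentile distance between the two boundary
point sets (face-connectivity boundaries; `percentile=100` recovers the
classic max–min Hausdorff distance). Conventions for degenerate masks:
DSC is 1 when both masks are empty and 0 when exactly one is (a
structure never predicted scores 0, not NaN); HD95 and the ratio
metrics are flagged undefined (NaN in reports) when a required mask is
empty, never silently 0. The distance-transform fast path is verified
against an exhaustive all-pairs oracle (`hd_bruteforce`) in the tests.

## Synthetic phantoms

The clinical dataset this framework was built around is private, so the
`phantom` module generates seedable stand-ins that preserve the
properties the method actually responds to:

- ten structures from parametric primitives — four ellipsoidal chambers
  in the four-chamber in-slice arrangement (LV upper-left, RV
  upper-right, LA lower-left, RA lower-right), AA/DA as axial tubes
  with circular cross-sections (DA at the posterior edge), a branching
  PA touching the RV, and three thin veins (PV entering the LA, IVC
  below the RA, SVC right of the AA);
- the real size imbalance: chambers ≫ medium vessels ≫ veins, LV
  largest, SVC smallest;
- overlapping intensity distributions on a 0–2048 HU-like scale, with
  each vein's mean placed 20 HU from its anatomical neighbour so the
  shared border is nearly invisible under blur (σ = 1 voxel in-plane)
  and additive noise (σ = 40) — reproducing the low-contrast regime
  that makes small veins hard;
- anisotropic geometry (default 16×96×96 voxels at 5×1×1 mm; a
  512×512-style grid is available by configuration);
- inter-patient variability via per-structure position jitter (±2% of
  each dimension) and size jitter (±10%) in `generate_dataset`.

What the phantoms deliberately do **not** model: deformable/irregular
organ shapes, cardiac motion, contrast-agent kinetics, CT physics
(beam hardening, streaks), or annotation noise. Tests passing on
phantoms therefore demonstrate that the cascade's mechanics — grouping,
prior injection, fusion, losses, metrics, training loop — behave as
designed under realistic size imbalance and low contrast; they do not
certify clinical accuracy.

## Scaled-down study sizes

The default test/acceptance problem sizes were chosen so the entire
pipeline is exercised end-to-end on one CPU:

- *Overfit smoke test*: one phantom case at 16×96×96 (5×1×1 mm),
  base width 8, learning rate 5e−3, batch 4, up to 200 epochs with a
  convergence stop once each stage's training-slice Dice reaches 0.98
  in the mean with no class below 0.90 (the fused map inherits coarse
  boundary errors through fusion precedence, so the coarse stage must
  not stop early); three seeds.  The plateau signal is evaluated on
  every second validation slice.
- *Method comparison*: 20 phantom cases at 8×48×48 (5×2×2 mm),
  6:2:2 split, base width 8, learning rate 3e−3, batch 12, 24 epochs,
  three seeds; arms are the single 11-class baseline, the two-stage
  cascade without priors, and the full cascade.  The two-stage and
  full arms share the identically-trained coarse network (same task,
  same seed), which cuts training cost without changing results.

## Numerical choices and edge cases

- Distance maps for an absent class are undefined; a uniform map of 1s
  is substituted with a warning (`DistanceMap.degenerate`).
- Soft-Dice class terms with a zero denominator (class absent and
  predicted identically zero) score as perfect agreement on absence.
- Label remapping to dense stage targets is by ascending original code;
  the code table is kept with the model for exact inversion.
- Fusion checks that the two stage outputs carry disjoint code sets and
  raises otherwise (a shared code indicates a remapping error).
- All randomness flows from integer seeds through
  `derive_seed(seed, component)` (BLAKE2s, < 2³¹); two runs with the
  same seed on the same platform are bit-identical.
- Augmentation fills out-of-frame regions with 0 for both image and
  label — the clipped intensity floor and the background code.

## Known limitations

- The desk-scale comparison reproduces the prior-injection benefit —
  the full cascade's small-vein DSC exceeds both comparison arms — but
  not the intermediate step of the clinical-scale finding: in our runs
  the plain two-stage arm does *not* beat the single-network baseline.
  At clinical resolution (512² slices, ~130 per case) the tiny veins
  occupy ~0.01% of the voxels and a flat 11-class network collapses on
  them, which is precisely what groupwise training rescues; at 48² with
  a class-averaged Dice loss that collapse never happens, so the
  two-stage arm pays the cost of treating chambers as background
  without the compensating rescue.  The effect appears to require
  clinical-scale class imbalance and is not reproducible at this
  problem size.
- 2D slice-wise networks cannot use through-plane context; structures
  entering/leaving the stack are localized only by the prior channels.
- The NumPy backend is practical at reduced resolution and width; a
  512×512, width-64 configuration builds and runs but trains slowly.
- HD95 values on coarse phantoms are dominated by voxel size
  (≥ in-plane spacing per boundary-cell mismatch).
- The phantom generator's fixed layout means position is highly
  informative; real anatomies vary more, so absolute phantom scores
  overstate clinical performance (relative comparisons between arms are
  the meaningful output).
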