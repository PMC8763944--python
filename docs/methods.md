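# Methods

## Problem

Stereotactic-radiosurgery planning for cerebral arteriovenous
malformations (AVMs) requires telling intranidal arteries (the target)
apart from veins, brain parenchyma, CSF and embolized vessels (EV),
and no single MR sequence shows all of them well. `vascmap` implements
a voxel-wise mapping pipeline over three co-registered contrasts —
TOF MRA (arteries bright), T1 post-contrast (enhancing vessels
bright), and T2 (CSF bright, flow voids dark) — that produces a
whole-brain categorical map over {artery, vein, brain, CSF, EV},
with extracranial voxels carrying an excluded code (0) that never
participates in training, prediction or evaluation.

The pipeline has three model stages plus evaluation:

1. **Bootstrap labeling** (`bootstrap_labeler`). A per-subject
   multiclass classifier over raw intensity triplets, built from small
   per-class sample contours: features standardized to zero mean and
   unit scale, one linear-kernel SVM per column of an
   error-correcting-output-codes (ECOC) coding matrix (one-vs-one by
   default, so C(5,2)=10 binary learners), and hinge loss-weighted
   decoding

       class(x) = argmin_k  sum_l |m_kl| max(0, 1 - m_kl s_l(x)) / (2 sum_l |m_kl|)

   over learner margins s_l. Ties break to the lowest class code. In a
   clinical workflow the resulting rough map would be hand-edited; on
   phantoms the simulator's ground truth plays the role of the edited
   map, and the bootstrap stage is validated against it directly.
2. **CNN segmentation** (`cnn_segmenter`). A 2D U-Net modified to take
   3 input channels and end in a 1x1 convolution with 5 output
   channels plus voxel-wise softmax. Training: per-slice min-max
   normalization to [0, 1], offline left-right reflection augmentation
   (exact doubling), categorical cross-entropy masked to non-excluded
   voxels, Adam at canonical defaults (lr 1e-3, betas 0.9/0.999),
   batch size 6.
3. **Evaluation** (`evaluation`). Per-class Dice similarity
   coefficient DSC_x = 2|X_label ∩ X_pred| / (|X_label| + |X_pred|)
   over non-excluded voxels, per subject and pooled.

## Phantom simulator

No public clinical dataset exists for this task, so the `phantom`
module generates seeded synthetic cohorts that preserve the features
the method actually exploits:

- **Geometry.** An ellipsoidal intracranial mask (semi-axes 0.42 of
  each grid dimension). CSF occupies a peripheral shell (the
  thinnest-distance rind of the mask) plus two ventricle-like central
  ellipsoids, carved around the nidus so the nidus always realises its
  configured volume. Arterial and venous trees are curvature-limited
  3D random walks dilated to tubes of 1–2.4 voxel radius; each walk
  carries a persistent drift along the slice axis (seeds spread over
  the slice range, drift direction alternating across trees) because
  cerebral vessels traverse the whole head — essentially every axial
  slice of a real brain contains arteries and veins, and per-slice
  intensity normalization makes this property load-bearing. The AVM
  nidus is a sphere filled with a tangle of short vessel tubes whose
  artery/vein/EV voxel shares follow the configured mixing fractions
  (the remainder stays brain, as AVMs enmesh normal parenchyma);
  labels are spatially coherent segments, never independent per-voxel
  draws, matching what the classes physically are — embolized vessels
  in particular are contiguous agent-filled segments. EV shortfall
  against its prevalence target is made up by "embolized feeder"
  tubes. No hemodynamic or atlas-level realism is attempted.
- **Prevalence control.** Class targets default to the fractions of a
  typical clinical training cohort (artery 0.9%, vein 4.2%, brain
  84.3%, CSF 10.4%, EV 0.2% of intracranial voxels). CSF regions are
  sized by exact count quantiles and vessel growth stops when the
  class budget is reached, so achieved fractions track targets far
  inside the ±30% relative tolerance the tests assert.
- **Intensities.** Each (class, contrast) pair maps to a relative
  mean in [0, 1]: low = 0.10, low-moderate = 0.25, moderate = 0.50,
  high = 0.90. TOF: artery high, vein and brain moderate, CSF
  low-moderate, EV low. T1+c: vein high, artery drawn per subject
  from [0.5, 0.9] (arterial enhancement is variable in practice),
  brain moderate, CSF low-moderate, EV low. T2: CSF high, brain
  moderate, vessels and EV low. A validator enforces these qualitative
  orderings for any custom table.
- **Corruption.** A smooth multiplicative bias field (low-frequency
  random field scaled to amplitude 0.1 of the mean by default) and
  additive Gaussian noise (default sigma 0.05 of the dynamic range),
  clipped to [0, 1]. Gaussian rather than Rician noise is a deliberate
  simplification at these SNRs; the rendering hook is the single place
  a Rician option would plug in.
- **Confounders.** Optional lesions reproducing reported failure
  modes: a vein segment rendered at brain-level T1+c (poorly enhancing
  draining vein), a vein segment rendered TOF-bright with moderate T2
  (thrombosed vein), and a TOF slab covering only part of the head.
  Injection returns the affected voxel sets so tests can assert exact
  locality. Their frequency is left to configuration; no prevalence is
  asserted.

**What passing tests do and do not show.** Phantom classes are
separable by intensity alone up to noise, with hard (non-partial-
volume) boundaries, a single scanner "appearance", and schematic
anatomy. Success here demonstrates that the pipeline's mechanics —
normalization, masking, augmentation, optimization, decoding,
evaluation — are correct and that the network can recover a
known generative model; it does not demonstrate clinical-grade
performance on real MR data, where labels are noisy, boundaries are
mixed, and appearance varies across scanners.

## Network and numerical choices

- The layer stack (`nn`) is a compact NumPy implementation:
  channels-last im2col + BLAS float32 GEMM convolutions (with an
  optional numba-jitted patch gather; both paths produce bit-identical
  matrices), explicit backward passes, and Adam. Weights use He
  initialization from a seeded generator; two builds with one seed are
  bit-identical.
- `padding_mode="same"` (default): feature maps keep the input size;
  inputs must be divisible by 2^depth. `padding_mode="paper_valid"`:
  valid convolutions with center-cropped skip connections, the input
  zero-padded by the traced convolution loss (16, 40, 88, 184 for
  depths 1–4, so a 512 output implies a 696 input at depth 4). The
  loss-only pad does not always satisfy the even-halving constraint at
  every pooling step (696 itself does not); the implementation then
  pads to the next feasible size and center-crops the output back, so
  the contract "output equals the original matrix size" always holds.
- Max-pool ties route their gradient to the first maximal element;
  softmax/argmax ties resolve to the lowest class code; both choices
  are deterministic and documented rather than random.
- Excluded voxels are handled by loss masking (zero weight and zero
  gradient), not slice removal, so partially extracranial slices still
  contribute their intracranial content. A batch with no included
  voxel is skipped with a warning.
- Augmentation is applied once, offline (the doubled slice count is
  part of the training contract); slice order is reshuffled each epoch
  from the training seed.
- Plain unweighted cross-entropy is used despite brain dominating the
  intracranial volume (~84%); class weighting is deliberately not
  applied. The bootstrap SVMs, by contrast, use balanced class weights
  because sample contours are small and their sizes are operator-
  dependent.
- Constant slices normalize to all zeros (the degenerate min = max
  case, matching background-slice semantics). Raw min/max is used
  rather than percentile clipping.
- Determinism: every stochastic component consumes an explicit seed
  through `numpy.random.SeedSequence`; per-subject seeds derive from
  (master seed, subject index). Model serialization stores exact
  float32 weights, so save → load → predict is bit-for-bit.

## Problem sizes

The end-to-end protocol (`experiments.scaled_validation_run`, also
driven by `scripts/acceptance.py`) uses ten phantoms of 48x128x128
voxels, split 8 train / 2 validation, a depth-3, 16-base-filter
same-padding network, and five epochs — sizes chosen so the whole
protocol, including simulation and inference, completes in minutes on
a single CPU core while still exercising every stage at realistic
class imbalance. The smoke pipeline used for reproducibility checks is
smaller still (two 32x64x64 subjects, depth-2 network, two epochs).

## Known limitations

- Anatomy is schematic: no gyri/sulci, no partial-volume mixing, no
  hemorrhage or edema, one intensity "scanner" per table.
- With unweighted cross-entropy the rarest class (embolized vessel,
  ~0.2% of intracranial voxels) is the last to converge: its training
  Dice is still rising steeply when the scaled-down epoch budget ends,
  and it scores lowest of the five classes — consistent with embolized
  vessels being the weakest, under-predicted class in clinical use of
  this kind of pipeline. Thin (~1-voxel-radius) feeder tubes account
  for most of its residual error.
- Registration is accepted as input (identity for phantoms); only
  transform application and resampling are implemented, plus a
  convenience translation-only cross-correlation estimate. No
  deformable registration, bias-field correction or skull stripping.
- The 2D slice-wise network carries no through-plane context; 3D
  architectures and alternative losses are out of scope.
- Dice is the only metric; surface-distance metrics are not computed.
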