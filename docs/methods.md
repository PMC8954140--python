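# Methods

## Problem and model

`lgeseg` segments late-gadolinium-enhancement (LGE) cardiac MR volumes into
five classes — background, left-ventricular (LV) cavity, healthy myocardium,
infarct scar (MI) and microvascular obstruction (MVO) — and classifies each
patient as infarcted or normal.  The anatomy dictates a strict nesting:
MVO ⊂ MI ⊂ myocardial wall, with the cavity enclosed by the wall.  The
pipeline encodes that nesting structurally rather than hoping a single
network learns it:

1. **Anatomical stage.**  A 3D U-Net labels background / cavity / wall
   (wall = myocardium ∪ scar ∪ MVO).  Blocks are convolution → instance
   normalisation → leaky ReLU (slope 0.01); down-sampling is by strided
   convolutions.  The loss is cross-entropy plus a soft Dice term kept in
   its negative convention (optimum −1 when every class is present):

       L = L_CE + L_DICE,
       L_DICE = −(2/|K|) Σ_k  Σ_i u_ik v_ik / (Σ_i u_ik + Σ_i v_ik)

   with `u` the softmax output and `v` the one-hot ground truth.  Adam with
   initial rate 3·10⁻⁴ and polynomial decay (power 0.9) over the schedule.

2. **Pathological stage.**  A second 3D U-Net family (convolution → batch
   norm → ReLU, max-pool down-sampling) relabels the pre-segmented wall into
   {outside-wall, healthy myocardium, scar, MVO}; the cavity is owned by the
   anatomical stage, so background and cavity are merged into class 0 here.
   Input is two channels: the pre-processed image and the wall mask.
   Training windows are sampled so that every window overlaps the wall, and
   half of them are centred on a pathology voxel when the case has any —
   scar and MVO are two orders of magnitude rarer than wall voxels and a
   uniform sampler lets the network collapse onto the majority classes at
   the schedule lengths used here.  The objective is

       L_final = L_seg + λ_IC·L_IC + λ_CC·L_CC

   where `L_seg` is 1 − mean per-class soft IoU (the raw overlap,
   maximised at 1, is exposed as `soft_iou_overlap`), `L_IC` the inclusion
   constraint and `L_CC` a binary patient-class cross-entropy attached to
   the U-Net bottleneck by global average pooling (training-time only).

3. **Inclusion constraint (shape prior).**  A 3D convolutional variational
   autoencoder (CVAE) with two stride-2 encoding stages and a 64-dimensional
   diagonal-Gaussian latent is pretrained on one-hot ground-truth shapes at
   the training-window size, then frozen.  Both the soft prediction and the
   ground-truth one-hot are passed through it, and

       L_IC = Σ_i ‖RP_i − RG_i‖²_F

   penalises reconstructions of implausible shapes.  The exported
   `loss_inclusion` is this verbatim Frobenius sum; *inside the training
   objective* the sum is divided by the number of grid entries.  The raw
   sum grows linearly with window volume (≈10⁴ entries at the scales used
   here), so at the published λ range it would dominate the O(1) IoU term
   by two orders of magnitude — in scaled runs that regime visibly
   destroyed the segmentation (hundreds of stray pathology voxels).  The
   per-entry form is the same L2 criterion up to a constant and keeps
   λ ∈ (10⁻², 5·10⁻¹) meaningful at any window size.

4. **Ensemble and fusion.**  One pathological model is trained per
   (λ_IC, λ_CC) pair.  The full roster is the 8 paired values along the
   grid λ = 0.01, 0.08, …, 0.50 (start 10⁻², step 7·10⁻², ceiling
   5·10⁻¹); a Cartesian-product roster is available via
   `LambdaGrid(values, pairs=...)`.  At fusion, a voxel becomes
   pathological when at least `quorum` members vote any infarct class (MVO
   votes count: MVO is a subclass of MI); the class is the plurality of
   pathological votes, ties resolved to scar; otherwise the anatomical
   label stands.  The quorum is 3 for 8 members and scales proportionally (rounded, minimum
   1) for rosters of m members — 1-of-3 in the desk-scale profile, i.e. a
   union over members whose false positives are controlled by the
   64-voxel component floor in post-processing.  `select_ensemble` picks the member subset with the
   highest mean training DSC over pathological classes (ties to the
   smaller subset).

5. **Post-processing.**  The infarct region (scar ∪ MVO) is opened
   slice-wise with a 3×3 structuring element; its 3D connected components
   (26-connectivity) below 64 voxels are relabelled to myocardium
   (preserving the anatomical shell); MVO components left without adjacent
   scar become scar.  The three steps are iterated to a fixed point (≤4
   rounds), making the operation idempotent.  Opening and the size floor
   act on the infarct region as a whole: at ~18 mm³/voxel a per-class
   opening would erase essentially all true MVO (50–150 voxels), which is
   inconsistent with MVO being detectable at all.

## Pre-processing

Volumes are cropped in-plane to a window centred on the LV-cavity centroid
(ground truth at training time; at test time a first anatomical pass on a
centre-cropped copy supplies the centroid, falling back to the image
centre), padded with zeros where the window crosses the border, and
extended to a fixed slice count by appending empty slices (full-scale
target 96×96×16).  Slice-wise CLAHE (clip limit 0.01, 8×8 tiles) maps
intensities to [0, 1]; 3D non-local-means denoising follows (patch 5,
search window 11, strength 0.8·σ̂ with σ̂ estimated from the data; 0
disables).  Equalisation and denoising run on the cropped volume — the
local statistics are the same and the cost is far lower.  The crop is
recorded and inverted exactly when predictions are restored to the
original grid; content on appended slices is dropped.

## Topology audit

`check_topology` reports, per label map: (a) pathology voxels outside the
hole-filled myocardial region, where the region is the union of
{myocardium, scar, MVO} connected components containing at least one
healthy-myocardium voxel — so a pathology island floating in the
background is a violation even though it trivially belongs to the class
union; (b) voxels of MVO components with no scar voxel inside or touching
the component (26-connectivity); (c) a flag for maps with MVO but no scar.
Ground-truth phantoms report zero everywhere; raw (unmasked) network
predictions use (a) as the ablation readout for the inclusion constraint.
Final fused maps are guaranteed (a)=0 by construction because pathological
relabelling is confined to the anatomical wall.

## Synthetic phantom cohort

Each phantom is a short-axis stack (default 48×48×8 voxels at
1.5×1.5×8 mm) of concentric discs: bright blood pool (intensity 0.9),
darker wall (0.3), hyper-enhanced scar wedge (0.8) and hypo-enhanced MVO
core (0.15) over a 0.05 background, with additive Gaussian noise σ=0.05.
Radii taper linearly to 40% at the apex with per-slice jitter (SD 0.5
voxels); the centre is offset by up to 10% of the grid to exercise the
automatic cropping.  Wall geometry is anatomically scaled: cavity radius
6.5 voxels (≈10 mm) and wall thickness 6 voxels (≈9 mm); the scar is an
angular wedge (default 110°) spanning 85% of the wall thickness from the
endocardium, on slices where the annulus is large enough; the MVO core is
a centred sub-wedge occupying ~40% of the scar area.  These sizes were
fixed from anatomical plausibility plus one structural requirement checked
on ground truth only: true pathology must survive the pipeline's fixed
post-processing constants (3×3 opening, 64-voxel floor), since no
segmentation method can be evaluated on targets its own published cleanup
would delete.  Cohorts are stratified healthy / scar-only / scar+MVO
(default proportions 33/27/40 per hundred) with per-case randomised
geometry, fully reproducible under a seed.

What the phantom does **not** model: MR physics (coil bias fields, Rician
noise, partial-volume mixing), papillary muscles, the right ventricle,
respiratory slice misalignment, and the intensity overlap between scar and
blood pool that makes real LGE segmentation hard.  Passing the scaled
end-to-end checks therefore demonstrates that the pipeline's machinery —
constraints, fusion, post-processing, metrics — is correct and trainable,
not that it reaches clinical-grade accuracy on patient data.

## Scaled (desk) profile

The published protocol (12³ patches, batch 4, 200k iterations, five-fold
cross-validation, 96×96×16 grids) is far beyond a single CPU.  The
`fast_dev` profile keeps every pipeline component and shrinks the scale:
48×48×8 grids, U-Nets of depth 2 with 8 base channels, 16×16×8 training
windows, 220 anatomical steps, 600 pathological steps per member, 1200
CVAE steps, a 3-member roster (λ = 0.01, 0.08, 0.15 paired) with quorum 1.
Learning rates are raised roughly tenfold (3·10⁻³ anatomical, 10⁻³
pathological) in proportion to the shortened schedules.  Problem sizes in
the reproduction script: 40 phantoms (30 train / 10 held out) for the
end-to-end run, 21 (16/5) for the inclusion ablation, 20 whole-volume
shapes for the CVAE reconstruction check.

## Numerical choices

* Ratio losses clamp their denominators at ε = 10⁻⁶: classes absent from
  both operands contribute zero overlap, values elsewhere are exact.
* Cross-entropy clamps probabilities at 10⁻¹²  before the log.
* Dice of two empty masks is 1 (agreement on absence — relevant for MVO);
  Hausdorff on an empty mask is undefined and reported as missing, never 0.
* Hausdorff boundaries are 6-connectivity erosion residues with
  spacing-scaled Euclidean distances; the symmetric max-of-both-directions
  form is the reporting default, the directed form is available.
* AVDR is reported in percent of the manual wall volume (wall = myocardium
  ∪ scar ∪ MVO).
* All training is seed-deterministic on one device; CVAE sampling uses the
  reparameterisation trick with a caller-supplied generator and decodes
  from the latent mean when run deterministically.
* Networks compute in float32; losses evaluated on float64 inputs stay in
  float64 (scalar constants adopt the operand dtype).

## Known limitations

* The networks run on an in-repo NumPy autodiff engine written for this
  package; it is gradient-checked against central differences but has no
  GPU path, so full-scale (200k-iteration, 96×96×16) training is out of
  practical reach here.
* The cascade U-Net variant is implemented as a coarse-to-fine pair and
  shape-tested, but the scaled experiments use the plain 3D U-Net.
* MVO Dice at desk scale is limited by the 8 mm slice thickness of the
  phantom: an MVO core is only 60–150 voxels, so single-voxel boundary
  errors cost several Dice points.
* The patient classifier head participates in training only; the reported
  patient verdict comes from the post-processed segmentation, mirroring
  the two-stage design.
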