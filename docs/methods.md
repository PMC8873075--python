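# Methods

`aorticroot` implements a fully automatic measurement chain for TAVI
planning CT: a cascade of three 3D U-Nets localizes the aortic root,
segments the aorta with the valve, and segments the region around the
aortic annulus; the annulus plane is then inferred by principal component
analysis (PCA) of the segmented region, the area-derived annulus diameter
is measured in cross-sections parallel to that plane, and a prosthesis
size is suggested from fixed sizing bands.  Because clinical TAVI CT
collections with expert annotations are not freely available, the package
ships a parametric phantom generator that renders CT-like aortic roots
with exact ground truth; all training and verification in the test suite
run on these phantoms.

## The phantom model

The phantom is a rotationally symmetric contrast-filled tube swept along a
straight, tilted axis through the volume center.  Its radius profile is
piecewise linear in arclength with knots

    LVOT -> annulus waist -> sinus bulge -> sinotubular junction -> aorta,

so the waist is the global minimum of the profile and the true area-derived
annulus diameter equals twice the waist radius by construction.  Around the
lumen sits a soft-tissue body cylinder in air.  Optional calcific blobs
(spheres of 1.5-3 mm radius at the lumen wall near the valve) are rendered
above the 850 HU scoring threshold, and additive Gaussian noise is applied
to the image only — masks, hinge points, plane and diameter truths stay
exact.  A voxel belongs to a structure when its center lies inside the
analytic surface.

Ground truth mirrors the annotations the cascade needs: the aorta mask is
the lumen from the annulus segment upward (valve + ascending aorta, no
LVOT); the root+LVOT mask is the lumen of LVOT, annulus and sinus; the
three hinge points sit on the waist circle 120° apart; the true plane
passes through the waist center perpendicular to the tube axis.

Default parameters (all overridable):

| parameter | default | rationale |
|---|---|---|
| HU blood/tissue/air/calcium | 300 / 40 / −1000 / 1000 | typical contrast-CT values; calcium above the 850 HU threshold |
| annulus radius | U(8.75, 16) mm | diameters 17.5–32 mm, covering the adult TAVI range |
| LVOT / sinus / aorta radius | annulus + U(0.5, 2.5) / + U(3, 6) / + U(1, 4) mm | textbook proportions: the sinus is the widest segment, the waist the narrowest |
| segment lengths | 20 / 10 / 22 / 28 mm | plausible adult root, total 80 mm |
| tilt about x, y | U(−15°, 15°) each | annulus planes are oblique to the scanner axis |
| noise SD | U(10, 25) HU | routine contrast CT noise |
| calcification blobs | 0–4 | covers the none-to-moderate calcification range |
| spacing / extent | 0.6 mm / 96×96×120 mm | near the native resolution of planning CT |

Radii are sampled as offsets from the annulus radius rather than
independently: independent draws can produce roots without a sinus bulge
(e.g. a sinus narrower than the LVOT), which are not the anatomy the
phantom is supposed to emulate.

What the phantom does **not** model: valve leaflets and commissures,
non-circular (elliptic) annuli, bicuspid or post-implant anatomy, wall
thickness (the "outer contour" masks are lumen masks), curved centerlines,
motion or beam-hardening artifacts, and surrounding organs (the body is a
uniform tissue cylinder).  Passing tests therefore demonstrate that the
pipeline machinery — label generation, training, inference, postprocessing
and measurement — is correct and self-consistent at desk scale, not that
the shipped desk-scale weights transfer to patient data.

## Preprocessing

Volumes live in DICOM-native LPS patient coordinates; HEAD is +z.  The
chain is: resample to a coarse isotropic detection grid (2 mm full scale),
crop to a fixed 256×256×384 mm³ window centered 128 mm toward HEAD from
the image center (air-padded, −1024 HU, where the scan ends), and
normalize intensities to zero mean / unit variance over the subimage being
processed.  After ROI detection the original volume is resampled to a fine
isotropic grid (0.6 mm full scale) and cropped to the detected
80×80×80 mm³ box.  Images are interpolated linearly, label masks with
nearest neighbor.

## Network and losses

All three steps use the same U-Net: a contracting path of (levels ×
convs_per_level + 1 bottleneck) 3×3×3 convolutions — nine under the
defaults of 4 levels × 2 — each with batch normalization and ReLU, max
pooling and dropout (rate 0.2) between levels; an expansive path
alternating 2×2×2 transposed convolutions, skip concatenations and
convolution blocks; and a 1×1×1 sigmoid head.  The first convolution has
18 filters by default; filters double per level.  Batch normalization uses
batch statistics during training and frozen running averages at inference,
which makes eval-mode prediction a fixed, translation-equivariant function
— predictions do not depend on the size or global content of the inference
window, so networks trained on small crops can be applied to full ROIs.

The network and training loop are implemented directly on NumPy (layers
with hand-written backward passes, Adam), in float32, with convolutions
lowered to BLAS matrix products.  Training is single-threaded and fully
deterministic given the seed.

Four loss families operate on the predicted probabilities: binary
cross-entropy; focal loss (γ = 2); the Tversky loss 1 − T with
T = Σyŷ / (Σyŷ + βΣ(1−y)ŷ + (1−β)Σy(1−ŷ)), where β weighs false positives
against false negatives and β = 0.5 recovers Dice; and the focal Tversky
loss (1 − T)^(1/γ).  The exponent 1/γ flattens the loss near T = 1; some
of the literature applies γ directly instead, and that variant is
available via `exponent="direct"`, but 1/γ is the default.  Voxel-wise
losses are reduced by the mean over the batch volume; the Tversky sums run
over the whole batch with a smoothing term ε = 1 in numerator and
denominator so the empty-mask case is defined; probabilities are clipped
at 10⁻⁷ inside logarithms.  Candidate βs come from the grid 0.45, 0.50, …,
0.95.

## Training protocol

Full scale: batch size 2, Adam (default learning rate 10⁻⁴), one random
translation of up to 5 voxels per image per epoch (no rotation, no
deformation), one model per candidate loss, selection of the four
combinations with the best validation result (highest IoG/F1, or lowest
diameter error for step 3, ties broken by the training value), then six
models per selected loss in sixfold cross-validation, bagged by a flat
uniform mean over all members (identical to the two-stage mean for equal
weights).

Desk scale (what the tests and the acceptance script actually run, sized
for a single CPU): 4 base filters, 3 levels, 20 phantoms at 1.2 mm voxels,
a 2.4 mm detection grid and a 1.5 mm ROI grid, 48³ training crops for the
aorta step and 40³ for detection and annulus, learning rate 3×10⁻²
(constant for steps 1–2, cosine-decayed for step 3), 25–30 epochs.  Three
desk-specific training choices matter:

- **Detector-consistent ROIs.**  The steps-2/3 training crops are centered
  on the ROI box predicted by the already-trained detector on the training
  cases, not on the ground-truth hinge midpoint.  The desk-scale detector
  places its box with a consistent offset from the hinge midpoint; training
  downstream models on the same placement removes a train/test distribution
  shift that otherwise dominates the error budget.
- **Hard negatives for detection.**  Half the detection training cases
  contribute an extra crop centered over the upper ascending aorta, where
  bright lumen lies outside the ROI-cube label.  In addition, detection
  probabilities are kept only for voxels whose centers lie inside the
  original scan: the air padding of the fixed window is synthetic and
  predictions there are meaningless.
- **Fine-tuned ensemble members.**  The 4-loss × 2-fold bagged ensemble
  fine-tunes every member from one pre-trained step-2 model (6 epochs,
  cosine-decayed 10⁻²) instead of training 8 models from scratch, which
  makes member quality uniform at a fraction of the cost.  This trades
  member diversity for convergence and is a desk-scale compromise; the
  full-scale protocol trains members independently.

## Plane inference and measurement

The annulus-region prediction is masked with the contour of the step-2
aorta segmentation (the mask minus its one-voxel erosion, dilated by one
voxel as tolerance) and reduced to its largest 26-connected component;
PCA of the surviving voxel coordinates gives the plane: centroid as
midpoint, the eigenvector of the smallest covariance eigenvalue as normal
(oriented toward HEAD; eigenvalue gaps under 5% trigger an
ill-conditioned-plane warning).  This is valid because the region is a
10 mm slab whose in-plane diameter (≥ 17 mm) exceeds its height.

The aorta and annulus masks are united and cut to a 10 mm slab around the
plane; voxel centers are binned into slabs one grid-step thick along the
normal, projected into the plane, and each slab's area A is the 2D convex
hull of the projected centers corrected for digitization by the Minkowski
terms A + P·s/2 + s² (P the hull perimeter, s the effective pixel pitch
√(voxel volume / step)); the area-derived diameter is 2√(A/π).  Slabs with
fewer than three non-collinear points fall back to count × pixel area.
The reported annulus diameter is the minimum over slabs after discarding
entries below the 17 mm floor (a smaller cross-section cannot contain all
three leaflets) and, in the cascade, after discarding the outermost slabs
that the ±5 mm cut planes truncate — their partial hulls would register
spuriously small diameters.  The reference diameter applies the same
machinery to the annotated root+LVOT mask within ±5 mm of the hinge-point
plane; there the mask continues beyond the window, so no trim is needed.

Device sizes follow the ladder 20/23/26/29/34 mm with band edges 19.5,
22.5, 26.5, 29.5 mm; shared edges are resolved half-open [lo, hi).
Calcification volume is the count of valve-mask voxels at or above 850 HU
times the voxel volume, and refuses intensity-normalized input.

## Numerical and design choices

- Pad value −1024 HU (air) everywhere a crop leaves the scan.
- "Image center" is the geometric center of the voxel grid in patient mm.
- Binarization threshold 0.5 for all three steps.
- The 10 mm annulus slab is centered on the hinge plane (±5 mm).
- PCA normals are sign-normalized toward HEAD so angles are well defined.
- Degenerate inputs raise typed errors with stage identity
  (`CascadeError`); an empty annulus/contour intersection falls back to
  the unmasked prediction with a logged warning.
- Step 3's network sees the ROI image only; the step-2 mask enters in
  postprocessing (contour masking), not as a network input.

## Known limitations

- Desk-scale accuracy on phantoms (plane normals within a few degrees,
  diameter errors below 2 mm; the acceptance script prints the measured
  values) does not predict clinical accuracy; the phantom lacks leaflets,
  elliptic annuli and calcification-induced segmentation errors.
- The thin-slab PCA normal is very sensitive to systematically asymmetric
  boundary errors: a height-bias gradient of half a voxel across the slab
  tilts the normal by several degrees.  Bagging and the contour mask
  mitigate but do not remove this.
- The fixed 80 mm ROI assumes adult anatomy; very large roots near the box
  edge are not handled specially.
- The NumPy training loop is practical up to desk scale only; full-scale
  training (18 filters, 0.6 mm grids, 100 epochs) assumes dedicated
  numerical hardware and is supported by the code but not exercised in the
  tests.
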