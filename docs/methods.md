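# Methods

`voxmotion` estimates three-dimensional respiratory motion in real time
from two-dimensional intrafraction imaging data, for image-guided
radiotherapy of moving thoracoabdominal targets.  A patient-specific
neural network maps a 2D view acquired during treatment (an x-ray
projection, a coronal/sagittal slice pair, or raw k-space) together with
reference pretreatment data to a dense 3D deformation vector field (DVF)
`φ` relating the acquired anatomy `Y` to the peak-exhale reference image
`X`, i.e. `X·φ = Y`.  The predicted DVF drives target/organ tracking and
volumetric imaging (warping `X` into an estimate of the instantaneous
anatomy).

## Diffeomorphic motion model

Deformations are parameterised by stationary velocity fields.  For a
velocity field `u`, the flow ODE

    dφ_t/dt = u(φ_t),   φ_0 = id,   t ∈ [0, 1]

defines `φ = φ(1)`, a member of the one-parameter subgroup generated by
`u`: smooth, invertible, and topology-preserving.  Integration uses
scaling and squaring: `u` is scaled by `2^-T` so that
`φ(2^-T) ≈ id + u·2^-T`, and the resulting small displacement is composed
with itself `T` times (`φ(1/2^(T-1)) = φ(1/2^T) ∘ φ(1/2^T)`).  `T = 10`
is the default; the composition uses trilinear interpolation with edge
clamping, displacements are stored in millimetres and converted to voxel
units per axis only when sampling.  Against a 1024-step forward-Euler
integration of the same ODE, `T = 10` agrees to well under 0.05 voxels on
smooth test fields; the numerical inverse (fixed-point iteration
`ψ ← -φ(v + ψ(v))`) composes with the forward field to under 0.1 voxels.

The Jacobian determinant of `v ↦ v + φ(v)` is computed with central
differences on the interior and one-sided differences at the boundary, in
voxel units.  The fraction of voxels with `det J ≤ 0` is the discrete
topology-violation measure reported throughout.

In practice the scaling-and-squaring construction is extremely robust:
integrating the phantom's smooth velocity template never produced a
folded field even at absurd amplitudes (the edge-clamped composition
saturates instead).  The phantom builder therefore rejects a requested
amplitude both when a ground-truth DVF folds *and* when the peak
displacement exceeds half the field of view, which is the practically
reachable failure mode.

## Network architectures

Five variants share one layer grammar.  Encoding arms consist of residual
blocks: a 4×4 convolution with stride 2 and padding 1 halves the spatial
size, a 3×3 convolution (stride 1, padding 1) with batch normalisation
refines it, and the block output is `ReLU(h + BN(conv(h)))`.  Block output
channels double the block input channels, and the number of blocks is
determined by image size (log2 of the input width: 7 blocks for 128×128
inputs, 5 for 32×32), so every arm ends in a `k×1×1` latent.  The latent
is reshaped to `k×1×1×1` and decoded by an equally deep arm of residual
blocks built from 4×4×4 transposed convolutions (stride 2, padding 1) and
3×3×3 convolutions with batch normalisation.  Two further 3×3×3
convolutions at the output size produce the 3-channel stationary velocity
field; the penultimate layer uses Tanh, the final layer is linear, and
all other layers use ReLU.  Convolutions followed by batch normalisation
carry no bias.  The velocity is multiplied by a configurable scale (mm)
and passed through the scaling-and-squaring layers, so predictions are
diffeomorphic whenever the velocity stays in the smooth regime.

The variants differ in their encoding arms:

* **A** — early fusion: reference and acquired projections concatenated
  into one 2-channel encoder.
* **B** — late fusion: separate 1-channel encoders for reference and
  acquired projections, latents concatenated.
* **C** — the acquired projection in a 2D encoder plus the reference 3D
  volume in a 3D encoder (4×4×4/3×3×3 kernels), latents concatenated.
* **D** — MR slice pairs: `{x_c, x_s}` and `{y_c, y_s}` each form a
  2-channel encoder, latents concatenated.
* **E** — k-space: four 2-channel encoders (real coronal, real sagittal,
  imaginary coronal, imaginary sagittal pairs); the two real latents are
  added, the two imaginary latents are added, and the sums concatenated.

### Channel-plan calibration

The prose description fixes the layer grammar but not the per-layer
widths.  They were pinned against the published trainable-parameter
totals, which act as an architecture checksum.  Applying the doubling
rule to the raw input channel count, and decoding with widths that halve
from the concatenated latent with the last block pinned at 3 channels
(variant A, which has a single encoder and no latent concatenation to
merge, instead keeps its latent width through the first decoder block:
256, 128, …, 4), reproduces all five totals exactly at the 128-input /
128³-output reference scale:

| variant | encoders | trainable parameters |
|---------|----------|----------------------|
| A | 1 × 2-ch | 10,836,973 |
| B | 2 × 1-ch | 4,130,925 |
| C | 2D + 3D | 5,048,373 |
| D | 2 × 2-ch | 16,516,901 |
| E | 4 × 2-ch | 19,489,717 |

Two internal consistency checks support this reading: the B→C difference
equals exactly the cost of swapping a 1-channel 2D encoder for its 3D
analogue, and the D→E difference equals exactly two additional 2-channel
encoders (E/D = 1.18, matching the quoted "18% more" parameters).

### Numerical boundary handling

Two choices matter at desk-scale grids, where the boundary ring is a
large fraction of the volume.  The 3×3×3 convolutions in the decoder use
edge-replicate padding rather than zero padding, and the outermost
two-voxel band of the predicted velocity field (the reduced-support band
of a 4/2/1 transposed convolution) is replicated from the adjacent
interior slice before integration.  Both address the same artefact: the outermost
voxels of a transposed-convolution stack receive reduced kernel support
and, with a masked training loss, no supervision, which otherwise leaves
millimetre-scale velocity jumps at the field-of-view border (in air,
outside every structure) that violate `det J > 0` after discretisation.
Neither choice changes the parameter counts.

For the same reason the scaled-down training profile enables a weak
Sobolev prior on the pre-integration velocity (mean squared forward
difference, weight 0.1 relative to the masked MSE; default 0, i.e. the
reference objective is unchanged).  Scaling and squaring guarantees a
diffeomorphism only while the velocity stays in the smooth regime;
full-scale networks reach that regime implicitly through capacity and
data volume, and the prior substitutes for it at desk scale, where the
masked loss leaves more than half of a 32³ field of view unsupervised.

## Synthetic 4D phantom

Licensed anthropomorphic phantoms cannot be redistributed, so the package
generates its own digital thorax: a body ellipsoid containing a
left-atrium-like spherical target, stomach, esophagus, two lungs, and a
spinal cord, each defined as fractions of the field of view (so one
configuration scales across grid sizes) with separate x-ray and MR
intensity tables.  Defaults are a 64³ grid at 4 mm (32³ at 3 mm for
end-to-end tests; the reference protocol's 128³ remains configurable).

Breathing traces are quasi-periodic `sin^4` cycles (dwelling at exhale,
0 = peak exhale, 1 = nominal peak inhale), with per-cycle Gaussian
amplitude and period jitter (default 5%) and an optional small additive
high-frequency cardiac term (off by default).  The nominal period is 4 s,
sampled at 10.5 Hz; peak diaphragm excursion presets are 5 and 10 mm.
Amplitude-based binning into 10 equal-width bands defines the respiratory
phases; bin 1 (peak exhale) is the reference, and each bin's
representative amplitude is its mean trace amplitude, shifted so bin 1 is
exactly zero.

Ground-truth motion comes from a fixed smooth unit velocity template:
dominant superior-inferior component with full magnitude at and below the
diaphragm plane, a long quartic-Gaussian decay superiorly (length 0.6 of
the SI extent, so the cardiac target translates quasi-rigidly rather than
compressing), a gentle radial suppression to zero at the spinal cord, and
an anterior coupling of 0.4 (inhalation moves the diaphragm inferiorly
and the anterior wall forward).  The template scaled by
`amplitude × trace value` is integrated with the same scaling-and-squaring
operator used at the network output, so every label is diffeomorphic by
construction and bin volumes/structure masks round-trip exactly through
`warp_volume`.  Intrafraction sequences scale the template continuously
(not just at the 10 bin amplitudes) while the gantry angle sweeps a 360°
arc linearly (630 views over one minute at 10.5 Hz); a bin-snapped
variant reproduces the protocol in which each view comes from the nearest
4D-CT phase.

The thoracoabdominal mask is the convex hull of both lungs (half-space
rasterisation of the hull facets), dilated by 8 mm, and extended
inferiorly to the bottom of the image within the hull's axial footprint.

What the phantom does *not* model: real CT/MR contrast and artefacts,
cardiac-cycle deformation of the heart surface, hysteresis between
inspiration and expiration, interfraction anatomy change, cone-beam
geometry, and realistic scatter physics (a parametric Poisson +
blurred-scatter model stands in at test time).  Passing the end-to-end
suite therefore demonstrates that the estimator recovers the motion
manifold it was trained on under controlled conditions — not clinical
performance on patient data.

## Imaging chain

The projector is a parallel-beam line integral: the volume is rotated by
`-α` about the SI axis (trilinear resampling) and summed along AP; the
detector has SI rows and rotated-LR columns.  The geometry is tagged so a
cone-beam projector can replace it behind the same contract; all learning
and evaluation properties used here are geometry-agnostic.  Slice pairs
are axis-aligned coronal/sagittal planes; the central k×k lattice of
(coronal, sagittal) index pairs (default 16×16) enumerates training slice
positions.  K-space uses the centred orthonormal 2D DFT split into real
and imaginary parts (Parseval-exact, inverse round-trips to 1e-9).
Test-time degradation applies Poisson photon noise through an
attenuation-style transform at a configurable count scale plus an
additive Gaussian-blurred scatter term; training data are always clean.
Downsampling is box averaging with integer factors, preserving physical
extent (512×256×512 at 1 mm → 128³ at 4×2×4 mm).

## Training

For x-ray variants, every bin is projected at every arc angle: 10 bins ×
630 angles = 6300 acquired projections in the reference protocol (60
angles in the scaled-down runs), each paired with the reference
projection at the same angle and labelled with the bin's ground-truth
DVF.  For MR variants, each bin contributes the slice pairs (or their
spectra) on the central lattice.  The loss is the mean squared DVF error
over (thoracoabdominal-mask voxels × 3 components), in mm²; a masked mean
rather than a sum keeps the loss grid-size invariant.  Optimisation is
Adam; the reference protocol is learning rate 1e-5, batch 8, 50 epochs.
Inputs are min/max-scaled to [-1, 1] per input arm using dataset-wide
ranges recorded in the checkpoint: with bias-free first convolutions,
all-positive [0, 1] inputs left most first-block ReLU channels dead at
narrow widths (the network then stalls at predicting the dataset-mean
DVF), while zero-centred inputs give ~50% activation for every seed.
Every tenth projection angle (or the first lattice row) is held out for
convergence monitoring only.

The networks and the optimiser run on a small reverse-mode automatic
differentiation engine written on numpy, with numba-compiled kernels for
the 3D convolutions and the trilinear squaring step; gradients of every
operator are verified against central finite differences in the test
suite, and the training-time integrator agrees with the scipy-based
reference integrator to 1e-3 voxels.

## Evaluation

Per timestep, the predicted DVF warps the reference structures and image,
which are scored against the instantaneous ground truth: Dice similarity
`2|G∩P|/(|G|+|P|)` per structure (averaged over timesteps for sequences),
Euclidean target centroid error in mm (unweighted voxel centroids),
global single-window SSIM with the conventional stabilisers
`c1 = (0.01 L)²`, `c2 = (0.03 L)²` (L = ground-truth dynamic range),
restricted to the thoracoabdominal mask, and the negative-Jacobian
fraction of the prediction.  Structure masks are warped with linear
interpolation and thresholded at 0.5.

The standard-of-care comparator is the internal target volume (ITV): the
union of the target over the breathing cycle, seen from a static beam.
Its centroid serves as the static prediction for the baseline centroid
error.  The tracked alternative shifts the beam by the negative of the
predicted target-centroid displacement (nearest-voxel translation); the
union of the so-shifted target masks is the dynamically shifted target
volume, which collapses toward the single-phase target volume as
prediction quality improves.  Tracking traces record ground-truth and
predicted centroid displacement on the (LR, AP, SI) axes.

## Scaled-down study conditions

The end-to-end demonstration runs at 32³ (3 mm voxels, 96 mm field of
view), 10 mm amplitude, 60 training angles, Network A with base width 2
(latent 32), velocity scale 16 mm (bounding the velocity to ~1.6× the
programmed excursion), learning rate 3e-3, batch 8, 10 epochs, T = 10,
smoothness prior weight 0.1 — about five to six minutes on one CPU per
run.  The absolute numbers published
for licensed phantom data are not reproducible without that data; the
scaled-down study checks the qualitative claims instead: the trained
network's mean centroid error is several times smaller than the static
ITV baseline's, the dynamically shifted target volume is ~20% smaller
than the ITV, and every predicted DVF satisfies `det J > 0`.

## Known limitations

* The velocity-scale bound, base width, and learning rate of the
  scaled-down runs are tuned for the 32³ demonstration; the 128³
  reference protocol retains the published hyperparameters but has not
  been run end-to-end here (hours of GPU work in the original setting).
* Binary-mask centroids quantise to whole voxels under quasi-rigid
  motion; centroid-based metrics at coarse grids carry ±half-voxel noise.
* `invert` on a non-diffeomorphic field warns and returns a best-effort
  result rather than failing.
* The parametric noise model reproduces dose-dependent variance and a
  low-frequency scatter floor, not beam hardening or detector physics.
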