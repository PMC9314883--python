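# Methods

This note documents the models, algorithms, numerical choices and
limitations of `persardose`.  The package implements a subject-specific
RF-dosimetry chain for 7T parallel-transmit (PTx) neuroimaging: tissue
segmentation of T1-weighted head data by a 2.5D multi-decoder network,
DREAM-based intensity bias correction, and 10 g-averaged SAR / Q-matrix
dosimetry with random-RF-shim safety-margin statistics.  Because no real
7T data ship with the package, a seeded synthetic-data module generates
every input the pipeline consumes.

## Synthetic phantoms and images

`synth.make_phantom` builds a minimal head anatomy from nested ellipsoidal
shells — subcutaneous fat, muscle, cranial bone, CSF, gray matter, white
matter from the surface inwards — on a neck column with a bone core, plus
two eye spheres and 1–3 paranasal-sinus-like air cavities embedded in the
bone with an enforced wall of at least 2 voxels (2 mm at 1 mm voxels).
The geometry reproduces every tissue adjacency the SAR averaging and the
segmentation must handle; it makes no claim to anatomical realism.  Shell
fractions are chosen so that at the 64^3 working resolution every
structure spans at least ~2–4 voxels: real subcutaneous fat (5–10 mm), eye
globes (~24 mm) and sinuses (~10–30 mm) are several voxels across at any
realistic resolution, and sub-voxel structures would make overlap metrics
meaningless.  `enforce_skin_layer` replaces fat within 1 mm of the
background with muscle (skin is dielectrically muscle-like); the operation
is idempotent and leaves every non-fat voxel untouched.

T1w-like images are formed as `tissue mean x bias + noise`.  The tissue
means follow T1w contrast (white matter bright, CSF dark, fat brightest).
The bias field is the GRE signal model `sin(gamma tau B1+) * B1-` built
from synthetic transmit/receive profiles:

- the transmit map has the 7T centre-brightening bump (slightly
  off-centre, as in a real circularly polarized drive) and a logistic
  attenuation towards the inferior end of the grid (`neck_dropoff_strength`,
  default 0.75) that reproduces the severe signal loss towards the neck;
- the receive-weighted proton-density map carries a peripheral
  brightening (`receive_amplitude`, default 1.0) as produced by a
  sum-of-squares combination of a close-fitting array, plus a mild
  low-order ripple.

Noise is Gaussian by default (Rician available as a config switch; at the
simulated SNR the difference is negligible).  `noise_sd` is expressed in
the unity intensity scale of the tissue means; 0.05 corresponds to SNR 20
against the typical (~0.5) tissue signal.  The optional `noise_profile`
scales the noise SD spatially: at 7T thermal noise is body-noise dominated
and follows the receive sensitivity, so passing the receive profile
reproduces array data in which intensity bias and noise share the same
spatial envelope.  The study driver uses this model.

Per-channel complex E-fields are band-limited Gaussian random fields
(Gaussian-kernel smoothing; the kernel width is set so the field's
autocorrelation magnitude decays to 1/sqrt(e) at `smoothness_mm`),
modulated by a channel-specific plane-wave phase ramp and a proximity
envelope from a loop-array-like azimuthal channel placement, and zeroed
outside the body.  They are deliberately not Maxwell-consistent: every
dosimetry quantity downstream (SAR, Q-matrices, margins) is agnostic to
how the fields were produced, and a full FDTD solver is out of scope.

## DREAM bias correction

The DREAM stimulated-echo/FID pair encodes the actual STEAM flip angle as
`alpha = arctan(sqrt(2 STE / FID))`; dividing by the nominal STEAM angle
(default 50 deg) gives the relative transmit field, and the FID amplitude
given `alpha` returns the receive-weighted proton density.  Voxels with
non-positive FID are excluded from the mask and logged.  The forward
simulator and the map derivation are exact inverses on noiseless input
(round-trip error < 1e-10 in tests).

Both maps are then fitted by weighted least squares onto a smooth
"spherical function basis".  Pure solid harmonics `r^l Y_lm` span only
harmonic (Laplace-free) functions and provably cannot represent the
centre-bright 7T transmit profile; the basis therefore includes even
radial powers, `r^(l+2k) Y_lm` with `l + 2k <= order`, which spans every
polynomial of total degree <= order.  The basis is evaluated on the voxel
lattice, centred on the mask centroid and scaled by the mask radius for
conditioning; the fit order defaults to 6 (84 functions) and is exposed as
config.  The smooth fit is what removes the tissue-wise (piecewise
constant) M0 component and the noise: only slowly varying structure
survives.  Rank deficiency (degenerate masks) raises an explicit error,
and the residual norm is non-increasing in the order by construction.

The bias estimate is `sin(tau_gamma * B1+_hat) * B1-_hat` for GRE
(`sin^3` for FSE), normalized to mean 1 on the mask.  `tau_gamma` is the
effective nominal flip angle at unit relative transmit field; the default
(10 deg, the PDw gradient-echo imaging flip) keeps the model in the
small-angle regime where the GRE bias is proportional to `B1+ B1-`.
Correction divides by the bias clipped from below at a floor (default 5%
of the mean bias) to avoid amplifying noise where the estimate is tiny,
and zeroes everything outside the mask.

Correction quality is summarized by the pooled within-tissue coefficient
of variation: the RMS deviation of each voxel from its tissue-class mean
over the grand tissue mean.  On severe known-bias phantoms with 5% noise
the DREAM-estimated correction cuts this statistic by more than a factor
of five.  Two caveats that the synthetic result does and does not show:
with body-noise-dominated (receive-weighted) noise, bias division does
not amplify the noise floor — this is the realistic regime for array
reconstructions and the one the tests exercise; with spatially uniform
noise, division amplifies the noise wherever the bias is far below its
mean, and no correction method can beat that floor.  Correction accuracy
is evaluated where signal exists (moderate neck attenuation); dividing
out a near-zero transmit field is ill-posed regardless of method.

## 2.5D multi-decoder segmentation

One 2D network per orthogonal slice orientation (transverse, coronal,
sagittal), each a fully convolutional multi-decoder U-net-like topology:
a single common encoder and nine parallel decoders, one sigmoid output
per tissue class plus background.  The default (full-size) spec follows
the stated design: 23 layers along an encoder-decoder path of which 6 are
2x2 max-poolings, 3x3 stride-1 same-padded convolutions, 2x2 stride-2
transposed convolutions, batch normalization (momentum 0.9, epsilon
0.001) and ReLU after every convolution, first layer 8 feature maps
doubling after every pooling (8..512).  Decoder widths start at a cap of
`base_features * 2^(P-2)` (=128) and halve per upsampling level with a
floor at `base_features`, with three width-preserving 3x3 refinement
convolutions at the middle levels and a 1x1 output convolution.  This
reconciliation gives 4,774,353 trainable parameters — 5 million to the
nearest million — with no skip connections needed; the closed-form count
is asserted in the tests.  Each decoder's output bias is initialized to
-2 so that all sigmoids start quiet and the soft-Dice gradients of small
classes are not swamped at initialization.

Training follows the stated protocol: slices of the raw (biased) T1w
volumes, shuffled by seed, 90%/10% train/validation split, mini-batches
of 10, Adam, soft-Dice loss (1 minus the mean over the nine outputs of
`(2 sum(p t) + 1) / (sum(p) + sum(t) + 1)`, aggregated over the batch).
Inputs are scaled per volume by the 99th-percentile intensity — the only
preprocessing, needed for numerical stability.  Training is bit-exact
reproducible for a fixed seed on single-threaded execution.

At inference the three orientations' probability maps are summed and each
voxel takes the argmax channel (ties to the lowest index).  Voxels where
every summed channel is exactly zero receive the modal label of their
26-neighborhood, background excluded whenever any tissue neighbor exists,
so no voxel is left unclassified.

The engine underneath is a self-contained numpy implementation
(im2col convolutions, manual backpropagation) whose gradients are
verified against finite differences in the test suite.

### Scaled-down study conditions

The full protocol (10 subjects at 192x256x256, 40 epochs, ~9000 optimizer
steps) is GPU-scale training.  The packaged study is designed as a
faithful miniature that trains in minutes on one CPU: 3–10 subjects at
64^3 and 1 mm, `base_features` 4,
10 epochs (~110 optimizer steps per network).  Two parameters are scaled
*with* the resolution rather than copied: the network uses 4 pooling
steps, which keeps the same bottleneck-to-field-of-view ratio as 6
poolings at 256^2 (a 64^2 slice pooled six times collapses to 1x1 and
discards all spatial structure), and the learning rate is raised to 2e-2
with a cosine decay — the framework-default 1e-3 demonstrably cannot
converge within the ~80x-reduced step budget.  The scaled network also
enables additive encoder-to-decoder skip connections (1x1 projections
added into the refinement levels): without them the decoders must
re-synthesize all spatial detail from the bottleneck alone, which the
small step budget cannot pay for (held-out Dice plateaus near 0.72; with
skips it reaches ~0.90).  The full-size default spec keeps the plain
skip-free topology and its parameter count.  All of these are recorded
as deliberate deviations from the full-size protocol.

## SAR and Q-matrix dosimetry

Fields are peak-amplitude phasors, so pointwise SAR is
`sigma |E|^2 / (2 rho)` — the factor 2 silently changes all absolute
values, hence it is fixed here as a documented convention.  Tissue
conductivity and density at 300 MHz come from the standard literature
(Gabriel parametrization / IT'IS values), shipped as an editable table;
no test depends on specific table values.  Background carries no mass;
internal air contributes neither mass nor power.

10 g averaging uses region growing: around each tissue voxel, tissue
voxels join in order of increasing Euclidean centre distance (ties broken
by lexicographic voxel index) until the accumulated mass reaches 0.010 kg
exactly, the final shell voxel contributing fractionally.  This keeps the
averaging mass-correct at the outer borders of the body without cubical
volume constraints.  The averaged value is the mass-weighted mean of the
pointwise SAR (equivalently the mass-weighted Q sum over the target
mass).  Voxels whose reachable mass falls short of 10 g take the
whole-body average with a logged warning; a body lighter than 10 g is an
error.  The inner loop is numba-compiled; the test suite checks every
voxel of a seeded phantom against an independent brute-force
sort-and-accumulate oracle to < 1e-12 relative and asserts the exact
region mass.

Q-matrices collect `sigma/(2 rho) conj(E_a) . E_b` per voxel — Hermitian
and positive semi-definite Gram matrices by construction — and are
averaged entry-wise over the *identical* regions, stored as packed upper
triangles (voxel-major).  Local SAR for a shim `w` is `w^H Q w`,
evaluated vectorized over all voxels; the Q path and the direct
combined-field path agree to < 1e-10 relative in the tests.  Shims are
normalized to 1 W total input power (`||w||^2 = 1`); un-normalized shims
are normalized with a warning.  SAR is invariant to a global phase and
scales linearly with `||w||^2`.

Random RF shims draw phases uniform on [0, 2pi) and amplitudes uniform on
[0, 1] before power normalization (the amplitude law is a config choice;
the seed is recorded in results).  The quadrature (birdcage-like)
reference drive uses equal amplitudes with successive `360/C` degree
phase increments on a 16-port synthetic field set; physical coil modeling
is out of scope.

## Exposure statistics and safety margins

For a ground-truth / generated model pair evaluated under the same shims,
the per-shim peak-SAR10g underestimation error is
`100 (peak_gt - peak_gen) / peak_gt` (positive = unsafe underestimation).
The study reports the mean and the 95th-percentile error
(linear-interpolation quantiles) and a safety margin defined
constructively: the multiplicative factor on generated-model peaks such
that the stated confidence fraction (default 95%) of shims is
conservative — i.e. the 95th percentile of `peak_gt / peak_gen`, minus
one, in percent.  The generic "one-size-fits-all" comparison covers each
model by the worst peak over the other models per shim and reports the
overestimation distribution.

## Degenerate inputs and numerical choices

- Label volumes validate their code range (0..8); geometry mismatches
  raise explicit errors naming the offending operation.
- The phantom generator raises if the grid cannot contain the nested
  shells (minimum dimension 32).
- `arctan`/`sqrt` in the DREAM inversion are exact for flip angles below
  90 deg; the nominal 50 deg STEAM angle keeps realistic transmit fields
  (up to ~1.7x nominal) inside that branch.
- Quantiles use linear interpolation between order statistics throughout.
- argmax ties (fusion) break to the lowest channel index; max-pooling
  ties route the gradient to the first maximum.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every study artifact records its config and seeds in a YAML
  sidecar sufficient to regenerate it bit-identically.

## What passing tests do and do not show

The synthetic phantoms share one geometric family, piecewise-constant
tissue intensity, and smooth analytic bias and field models.  Passing the
packaged studies shows the pipeline's bookkeeping, algorithms and
statistics are correct and that the network can learn this family from
few examples; it does not certify segmentation accuracy, bias-correction
quality or SAR-prediction error on clinical 7T data, whose anatomy,
contrast mechanisms and electromagnetic fields are far richer.  The
quantitative headline numbers of the underlying study (Dice, peak-SAR
errors, margins on real subjects) are not reproducible without 7T
acquisitions and an FDTD solver and are not asserted by this package.
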