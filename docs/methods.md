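# Methods

This note records the models, conventions and numerical choices behind
`respmoco`, and what the synthetic experiments do and do not demonstrate.

## Conventions

* Axes: `x` = foot-head (the fully sampled frequency-encode direction),
  `y` = left-right, `z` = anterior-posterior. Volumes are `(nx, ny, nz)`.
* k-space: unitary centered FFT (`fftshift(fft(ifftshift(.)))`,
  `norm="ortho"`), DC at index `n//2` on every axis. Unitarity makes the
  inverse FFT and the adjoint coincide, so the zero-filled adjoint and
  the encoding adjoint share code.
* Displacement fields are in voxel units with the warp convention
  `out(x) = in(x + d(x))`, trilinear interpolation, clamp-to-edge
  boundaries (avoiding zeros leaking into data-consistency residuals at
  patch borders).
* Respiratory translations are stored as *position minus mean position*
  (mm, foot-head then left-right). Under the negative-exponent forward
  DFT, multiplying each sample at 2D k-position `(k_x, k_y)` (cycles/mm)
  by `exp(2πi k·T_m)` then aligns every heartbeat to the mean position.
  The correction factor has unit modulus, so sample magnitudes are
  untouched.

## Trajectory model

Spiral-profile phase-encode ordering is reproduced qualitatively, not
bit-exactly: each heartbeat acquires one Archimedean arm in normalized
elliptical coordinates (angle monotone in radius, successive arms rotated
by the golden angle ≈ 111.25°), with radial spacing growing with radius
and a retention law `p(r) ∝ (1 + β(r − r_c))^(−γ)` outside the fully
sampled center disc `r ≤ r_c` (β = γ = 2 by default). The DC point is
re-acquired every heartbeat and the center disc is distributed
round-robin across heartbeats, as a real acquisition revisits the center
throughout the scan.

The number of *unique* acquired locations is forced to exactly
`round(count(shutter)/nominal_accel)` by adding or removing locations
according to the same density law. On the reference 200×60 grid the
discrete shutter contains 9407 of 12000 points, and the effective
rectangular-grid factors for nominal 3/4/7 come out at 3.8/5.1/8.9 — the
4/π elliptical-shutter economy.

Retrospective undersampling segments the plane into 20 elliptic annuli
with boundaries equally spaced in normalized elliptical radius (the
equal-area alternative was considered and rejected for simplicity; the
choice only relabels which locations fall in which ring). Acquisition
fractions are counted on unique locations, not readout multiplicity.
Within each annulus a seeded random subset of acquired locations is
retained so the fraction matches the target within one readout; all
readouts at a retained location keep their heartbeat assignment. The
output is a strict subset of the input — no synthetic k-space is ever
introduced into training data.

## Phantom and ground truth

The phantom is a sum of analytic primitives (soft-edged ellipsoids by
default; Gaussian-profile blobs where Fourier-shift identities must hold
to high precision, since logistic edges are not band-limited enough at
2 mm voxels). Respiration is parameterized by a motion state `s ∈ [0, 1]`
(raised cosine over ~8 heartbeats plus slow drift; `s = 0` is
end-expiration) driving:

* a bulk translation `(amp_fh·s, amp_lr·s)` — what the navigators see;
* a foot-head grading of the foot-head displacement (diaphragm-driven
  motion is strongest inferiorly), a mild z-dependent left-right shear,
  and a smooth large-scale sinusoidal component (default amplitude 8 mm)
  that does **not** vanish over the heart. The navigator-derived
  translations are defined as the bulk term only, so the residual after
  translational correction — what the motion network must estimate — is
  about 1.5 voxels on average over the heart at the default settings.
  This emulates an iNAV that tracks bulk motion but cannot capture
  non-rigid deformation.

Rendering evaluates each primitive at pulled-back coordinates
`I_s(x) = I_0(x − d_s(x))`, so deformed volumes are alias-free and the
per-bin forward fields `u_b ≈ r_ref − r_b` (residual pullback
displacements at the bin-mean states) are analytic; inverse fields come
from a fixed-point iteration and satisfy `‖inv ∘ fwd − id‖_mean` well
below 0.1 voxel at the default amplitudes. Coil maps are smooth complex
Gaussians around the y-z perimeter with low-order phase, RSS-normalized;
k-space noise is i.i.d. circular complex Gaussian (σ = 0.05 against
references normalized to a 99th percentile of 1, i.e. SNR ≈ 20 in the
k-space center).

What the phantom does *not* model: bSSFP contrast, T2-preparation,
fat saturation, off-resonance, cardiac-phase motion (the sequence is
ECG-triggered to a quiescent window), through-plane iNAV motion, and
realistic anatomy. Passing tests therefore demonstrate the correctness
and trainability of the *pipeline*, not clinical image quality.

## Operators and solvers

`E = U F S M` is assembled per respiratory bin; samples acquired several
times remain separate rows, so re-acquired center readouts accumulate in
the least-squares adjoint (natural density weighting). Soft-gating
weights enter both `E` and `E*` — the weighted-least-squares reading, so
`E*E` carries `w²` while `E*b` applies `w` once to the raw data. The
zero-filled *image* (the framework input) instead averages duplicate
acquisitions by each location's total acquisition count: this keeps it a
proper projection of the fully sampled image (its energy cannot exceed
it) and makes disjoint hard bins sum to the pooled zero-filled image.

Two motion adjoints are implemented: the exact transpose of the
trilinear warp (splatting), under which `⟨Eρ, y⟩ = ⟨ρ, E*y⟩` holds to
machine precision and dense-matrix equivalence is verified on 4×8×8
grids; and the cheap inverse-field warp used inside the reconstruction,
which is what makes diffeomorphic fields valuable in the first place.

The conjugate-gradient solver records residual norms and returns the
candidate iterate (warm start included) with the smallest
normal-equation residual. Plain CG does not guarantee monotone residual
norms; this safeguard does, at the cost of occasionally repeating an
iterate, and gives the data-consistency step its "never increases the
residual" contract. The data-consistency normal equations follow the
printed form `E*Eρ = E*b` with the prior entering only through the warm
start; the conventional `(E*E + λI)ρ = E*b + λz` variant is available as
`dc_mode="modl"`.

The right-hand side is computed as `E*b` on the tape; with the inverse
motion fields applied per bin this is identical to warping the per-bin
zero-filled adjoint images to the reference frame.

## Patching

Volumes are split only along the fully sampled readout direction, where
undersampling artifacts do not propagate. A slab of the hybrid
(x, ky, kz) data re-transformed along x within the slab is an exact
per-patch k-space up to slab-truncation edge effects, which the
5-voxel edge discard absorbs; retained regions overlap by 4 voxels and
are averaged with a partition-of-unity weighting, so recombination is
exact on patch-independent content. Full-FOV zero-filled and SENSE bin
images are computed once and patched afterwards — patching the *images*,
not the reconstruction problem.

## Networks

Both networks are 3D U-Nets (two convolutions per level, leaky-ReLU 0.1,
average-pool down / trilinear up, concatenation skips). The motion
network takes the jointly max-normalized magnitude pair
(end-expiration bin, moving bin) on a 2× average-pooled grid and
regresses a 3-channel stationary velocity field; scaling and squaring
(6 steps: divide by 2⁶, then 6 self-compositions) integrates `+v` and
`−v` into forward and inverse diffeomorphic displacements, which are
trilinearly upsampled ×2 with their values doubled. The denoiser acts on
the real/imaginary channel pair with a residual connection.

Both heads are zero-initialized, so the untrained framework is exactly
translational-correction-plus-data-consistency — the reduction the tests
pin down. Contract-level defaults are 3 levels at 16/32/64 channels;
the scaled experiments use 2 levels at 8 channels.

Because no deep-learning framework is assumed, the package carries a
small reverse-mode autodiff tape over numpy arrays. Complex images are
carried as two real channels, making every node real and the adjoint
rules elementary; the unitary FFT, constant complex multiplication,
weighted sampling/scatter, convolution (im2col GEMM) and warping (in
both image and displacement arguments) are primitives with hand-written
gradients, each verified against central finite differences at 1e-6.
Where a warp coordinate is clamped to the volume edge, the displacement
gradient is zeroed to match the clamped forward map.

## Training

The composite loss is `L = λ1·L_mot + λ2·L_recon + λ3·L_reg` with
λ = (100, 10, 1) at full scale. `L_mot` is the mean Charbonnier distance
`√(x² + ε²)`, ε = 1e-3 on unit-normalized images, between the
end-expiration reference and each remaining bin reference warped to
end-expiration by the estimated inverse fields, plus a squared
forward-difference gradient penalty on the velocities (weight 0.01).
`L_recon` is the Charbonnier distance between reference and
reconstruction on the real/imaginary pair. `L_reg` is the summed squared
convolution kernels. Optimization is Adam (β = 0.9/0.999) at 3e-4,
halved every 400 epochs, 1600 epochs, one step per subject per epoch on
a random 48-voxel readout patch — the full-scale schedule, retained in
the defaults.

**Scaled study conditions** (fixed once, used by the tests and the
`scaled_training_experiment` entry point): 32×32×16 volumes at 2 mm,
48 heartbeats, 4 coils, 4 bins (softness 0.5), sources at nominal
4-fold subset to the average annulus profile of eight prospective
7-fold trajectories (clipped per-sample to feasibility on this tiny
grid), 8 training + 2 held-out phantoms with jittered geometry and
breathing, 60 epochs at learning rate 2e-3 (halved every 20), 16-voxel
patches, and λ3 = 1e-3 — the kernel-norm term is scale-dependent and at
λ3 = 1 would dominate the scaled losses. Gradients flow end to end
through the unrolled CG (differentiating through the fixed 3 iterations,
not implicit differentiation), the warps and the integration. Training
samples are normalized so the reference magnitude's 99th percentile is 1;
since the denoiser is not scale equivariant, held-out acquisitions are
brought to the same intensity convention before reconstruction (on real
data a data-derived surrogate such as the zero-filled 99th percentile
would serve). At these conditions the held-out mean heart-ROI
displacement error drops from ≈1.5 voxels (uncorrected) to below 1 voxel
and the reconstruction SSIM exceeds the translational-only zero-filled
baseline by ≈0.1–0.15.

## Evaluation

ROI metrics intensity-match the reconstruction to the reference by the
ratio of ROI means (invariance to global scaling without biasing the
noise level), normalize both by the reference's ROI 99th percentile,
clip to [0, 1], and report MSE and single-scale SSIM (Gaussian windows,
`win_size=7`, data range 1). Group comparisons use the two-sided
paired-samples t-test, with an explicit degenerate branch for
zero-variance differences. The phantom's heart bounding box stands in
for the manually drawn cardiac ROI.

## Known limitations

* The spiral-profile ordering approximates the reference sequence's
  variable-density profile but not its eddy-current-optimized ordering
  or RR-adaptive interleaf sizing.
* iNAV registration is 2D template matching with upsampled-DFT
  refinement; through-plane motion and hysteresis are unmodelled
  (the simulator's drift term exercises bin non-stationarity only
  mildly).
* The numpy tape is single-threaded and keeps the whole graph in
  memory; it is sized for the phantom scale, not for 272³ clinical
  volumes.
* CG through soft-gated multi-bin operators is ill-conditioned when
  weights become tiny; rows below 1e-8 are dropped, and the unrolled
  reconstruction relies on only 3 warm-started iterations per step
  rather than convergence.
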