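# Methods

## The problem

Magnitude diffusion-weighted images (DWI) at high b-values have very low
SNR.  Taking the modulus of complex data with Gaussian channel noise
produces a *rectified noise floor*: where the true signal approaches zero
(high-b CSF, strongly attenuated white matter), the measured magnitude
converges to a positive constant instead.  The floor depends on the coil
combination: a root-sum-of-squares (SoS) combine of N channels yields a
non-central chi magnitude with 2N degrees of freedom and floor mean
`sigma * sqrt(2) * Gamma(N + 1/2) / Gamma(N)` (about `3.94 sigma` for
N = 8), while a phase-aware matched-filter combine (SENSE1 / adaptive
combine) yields a Rician magnitude whose floor, `sigma_eff * sqrt(pi/2)`,
is much lower.  The floor is additive in distribution but not in value, so
PCA-style denoisers that remove zero-mean noise components cannot remove
it, and tensor or higher-order model fits on floored data are biased (MD
and FA are underestimated in the affected regions).

## The denoiser

`dwicnn.cnn` implements a small regression network that operates on the
*temporal* profile of each voxel: the length-T vector of intensities
across all DWI volumes.  Architecture:

    input (T x 1)
      conv1d: 16 kernels, length 16, same padding, ReLU
      max pool, kernel 2, stride 2
      conv1d: 32 kernels, length 8, same padding, ReLU
      max pool, kernel 2, stride 2
      dense:  32 * floor(T/4) -> T, linear

Training minimizes the mean-squared error between the network output for a
noisy voxel time course and the corresponding low-noise reference time
course, with plain stochastic gradient descent (momentum is available in
`DenoiserConfig` but off by default).  Because each masked voxel is one
training sample, a single paired dataset provides 10^4-10^5 samples, and a
model trained on one subject/phantom transfers to any dataset acquired
with the same gradient table (a protocol-signature hash guards against
accidental protocol mismatch; reordered tables only warn).

Unlike MP-PCA, the network learns the conditional expectation of the clean
signal given the noisy time course, which includes learning to subtract
the rectified floor — the property the simulation experiment verifies.

Design choices where the architecture description leaves room:

* **Pooling**: one max-pooling layer after each convolutional layer (two
  total), giving the five-layer structure 2 conv + 2 pool + 1 dense and a
  flattened feature size of `32 * floor(T/4)`.
* **Padding**: `same` for both convolutions, so the feature length is
  well defined for arbitrary T >= 16.
* **Loss**: MSE, matching RMSE as the evaluation metric.
* **Normalization**: intensities are divided by one global scale — the
  99th percentile of the reference b0 intensities at training time,
  recomputed from the input dataset by the same rule at inference time.
  This makes training and inference covariant to arbitrary scanner units
  and lets a model trained on one intensity scale denoise data on another.
* **Output**: linear; negative predictions are clipped to zero only when
  the denoised dataset is assembled (magnitudes are nonnegative), never
  inside the loss.
* **Initialization**: He-normal for the ReLU convolutions, Glorot for the
  dense layer, from a seeded generator; training is bit-reproducible for
  fixed seeds.

The implementation is pure NumPy (float32) with explicit backward passes;
convolutions are im2col + one BLAS GEMM per layer, with numba kernels for
the window gather/scatter.  The backward pass is verified against central
finite differences in the test suite.

### Hyper-parameters

`DenoiserConfig` defaults to the full-scale reference settings: 20000
epochs, learning rate 0.001, batch size 6000.  The optimum is dataset- and
protocol-specific — learning rate and batch size interact, and both should
be re-tuned per protocol with `grid_search`, which trains on 75% of the
voxels and reports held-out RMSE over a (learning rate x batch size) grid.

For the desk-scale phantom experiment (`dwicnn.pipeline.desk_profile`),
the search on the simulated SNR-10 pair selected the Adam optimizer at
the reference learning rate 0.001 with batch size 250, 2000 epochs, and a
1000-voxel training subsample.  Two observations drove this choice.
First, with ~250x fewer gradient updates than a full-scale run, plain SGD
at a fixed step faces a dilemma: small steps barely move, and large steps
leave a gradient-noise plateau (training MSE ~1e-3 in normalized units)
that keeps the *small* targets — the CSF diffusion-weighted signals, ~5%
of b0 at b=1000 and ~0.25% at b=2000 — unresolved; the log-domain tensor
fit amplifies exactly those residuals into an MD overestimate.  Second,
Adam's per-parameter step adaptation reaches a training loss two orders
of magnitude lower (~4e-5) in the same epoch budget and recovers the CSF
decay curve, so the MD bias shrinks by an order of magnitude instead of
flipping sign.  Heavy-ball momentum and Adam both live behind
`DenoiserConfig.optimizer`/`momentum`; the full-scale default remains
plain SGD.

## Simulation framework

### Phantom (`dwicnn.phantom`)

Ground truth comes from the closed-form single-tensor model
`S(b, g) = S0 * exp(-b g^T D g)` on a 64 x 64 x 4 labeled phantom: per
slice a CSF core, a GM band, and a WM annulus whose principal fiber
direction rotates with azimuthal angle (so the network sees a continuum of
decay curves, not one per tissue).  Tissue parameters are conventional
literature values and are configuration, not fitted quantities:

| tissue | S0   | eigenvalues (mm^2/s)      |
|--------|------|---------------------------|
| CSF    | 1000 | 3.0e-3 isotropic          |
| GM     | 800  | (0.9, 0.7, 0.7) e-3       |
| WM     | 700  | (1.7, 0.3, 0.3) e-3       |

Different phantom seeds jitter region centers, radii, and the
orientation-field phase — the "different subject" mechanism for transfer
experiments.  The default protocol is 4 b0 + 90 directions at b=1000 +
90 at b=2000 s/mm^2 (T=184), directions placed by electrostatic repulsion
with antipodal symmetry.  No motion, eddy-current, susceptibility, or
physiological effects are simulated, and there is no k-space/EPI physics:
the phantom isolates exactly the noise-statistics phenomenon the denoiser
targets.  Consequently the experiments here say nothing about motion
robustness or artifact interactions on real data.

### Noise model (`dwicnn.noise`)

An eight-channel coil model (Gaussian-magnitude sensitivity profiles
centered on a circle around the FOV, smooth phase ramps, normalized so the
mean root-sum-of-squares sensitivity is 1) produces per-channel complex
data `c_i * S + (eta_r + i eta_i)`, `eta ~ N(0, sigma^2)` i.i.d. per
channel, voxel, and volume (no noise covariance).  The object signal is
real with zero phase; all phase structure lives in the sensitivities.
Two combines are implemented:

* `sos`: `sqrt(sum |s_i|^2)` — non-central chi, high floor;
* `sense1`: `|sum conj(c_i) s_i| / sum |c_i|^2` — the matched filter with
  known sensitivities (identical to an adaptive combine with exact
  sensitivity estimates), Rician, low floor.

Both calls with the same seed consume the same channel noise, so an
SoS/SENSE1 pair differs only in the combine operator.  The *ground truth*
for each branch is the sigma -> 0 limit of the same combine (for SoS, the
signal times the root-sum-of-squares sensitivity), which keeps every
comparison on one intensity scale.

SNR is defined as mean reference-tissue (WM) b0 intensity of the combined
image divided by the analytic SD of that intensity, computed from the
exact non-central chi moments (`scipy.special.hyp1f1`, with the
`sqrt(nu^2 + (2N-1) sigma^2)` asymptotic above `nu^2/(2 sigma^2) = 500`).
`sigma_for_snr` inverts this relation by bracketing; a Monte-Carlo check
in the tests confirms the calibration to within 2%.

### MP-PCA baseline (`dwicnn.mppca`)

The comparator is a from-scratch Marchenko-Pastur PCA denoiser: for each
masked voxel the M x T matrix of patch time courses is eigen-decomposed
(patch default 5x5x5; the simulation uses 9x9x3, matching the 4-slice
geometry); the largest trailing eigenvalue set whose spread fits the MP
bulk width `4 sigma^2 sqrt(p/max(M,T))` is classified as noise, and the
center voxel is rebuilt from the remaining components (sliding window,
center-voxel output; windows shift inward at borders so M is constant).
The estimator is validated against pure-noise and rank-1 oracles; on
noise-free data the spectrum has no MP bulk and the input passes through
unchanged.

### Tensor fit (`dwicnn.dti`)

Weighted least squares in two passes: OLS on `ln S`, then one reweighted
pass with weights equal to the squared fitted signals.  Intensities are
floored at `1e-6` of the dataset's 99th percentile before the log.
Negative eigenvalues are clipped to zero for FA/MD, keeping FA in [0, 1].
On noise-free phantom data the fit recovers per-tissue FA and MD to
relative error below 1e-6 (identifiability), which is the only
equivalence claimed — no bit-level agreement with any external fitting
tool is asserted.

Because higher-order models (NODDI etc.) are out of scope, the package
reports a direct noise-floor readout instead: the *high-b floor index*,
the mean normalized b=2000 signal in a tissue minus its ground-truth
value.  In CSF the true b=2000 signal is `exp(-6) ~ 0.25%` of S0, so the
index isolates the rectified floor almost purely.

## The seven-dataset experiment (`dwicnn.pipeline`)

One run produces: (1) the noise-free combined ground truth; (2, 3)
low-noise (SNR 30) and high-noise (SNR 10) corrupted datasets; (4, 5) each
denoised by the 1D-CNN; (6, 7) each denoised by MP-PCA.  Models are
trained on one corrupted realization and applied to an independently
corrupted realization of the same phantom (train/test dataset split); the
evaluation report contains RMSE per shell, within-tissue correlations
(volumes pooled after per-volume mean removal, so offsets do not inflate
r; strata with zero within-tissue variance — uniform tissue interiors of
the noise-free phantom — are omitted), FA/MD bias per tissue with
histograms (100 equal-width bins over the pooled range), the CSF high-b
floor index, and full provenance.  Reports serialize losslessly to JSON
and flatten to CSV; fixed seeds give byte-identical reports.

Expected pattern, reproduced by the acceptance suite: at SNR 10 the noisy
SoS data show a large positive CSF floor index and *under*estimated CSF MD
(the floor flattens the apparent decay); MP-PCA reduces RMSE but leaves
most of the floor; the CNN removes most of both.  At SNR 30 the floor is
small and CNN and MP-PCA perform comparably.

## Transfer experiment (`dwicnn.evaluation.transfer_experiment`)

Round-robin across >= 3 phantom seeds at one SNR: train on phantom i,
denoise phantoms j != i, report per ordered pair the noisy and denoised
RMSE to the reference, and per test phantom the Pearson correlation
between FA/MD maps denoised with models from two different training
phantoms (against the noisy-vs-truth correlation as the baseline).  High
cross-model correlation means the choice of training phantom has
negligible influence on the denoised data.

## Numerical and scale choices

* All training mathematics in float32; evaluation statistics in float64.
* Desk-scale problem sizes used by the tests and the acceptance script:
  the full 64 x 64 x 4 phantom with T=184 for the main experiment
  (~9000 masked voxels, 1000 training voxels, 2000 epochs); a
  64 x 64 x 2 phantom with 400-epoch trainings for the transfer
  experiment; a 24 x 24 x 2 phantom with T=26 for the end-to-end
  determinism run.  Full-scale settings remain available through
  `RunConfig`.
* Max-pooling ties break toward the earlier sample, in both the forward
  pass and the routed gradient.
* The repulsion optimizer for gradient directions clamps pair distances
  at 1e-6 to survive transient collisions; the best of 3 restarts is kept.

## Known limitations

* The phantom has uniform tissue interiors, a single-fiber WM model, and
  no artifact physics; results demonstrate noise-statistics behavior, not
  performance on real scanner data.
* The SENSE1/adaptive combine assumes exactly known sensitivities; with
  estimated sensitivities real adaptive-combine images have a slightly
  higher floor than simulated here.
* MP-PCA is implemented in its standard magnitude-domain form; complex
  domain variants that avoid the floor are out of scope.
* The denoiser requires the inference protocol to match the training
  protocol (same T and gradient table); cross-protocol transfer is
  deliberately unsupported.
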