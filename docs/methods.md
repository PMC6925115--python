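# Methods

## The model

`mlnrecon` implements *minimal linear networks* (MLNs) for MR image
reconstruction: complex-valued networks with no bias terms, no activation
functions and no depth beyond what the MR physics requires. Because MR
signal formation is linear in the image, a reconstruction operator is a
(left-)inverse of a known but often ill-conditioned and underdetermined
linear system, and can itself be represented as a shallow linear network
trained directly on simulated (signal, image) pairs.

### Subspace-connected layers

All networks are built from one primitive, the subspace fully-connected
(SFC) layer: a tensor contraction in which each input axis is declared
*fully connected* (matrix multiplication along that axis, with optional
resizing), *shared* (the same weights broadcast over the axis) or
*independent* (separate weights at each position, no mixing). A 1D Fourier
transform of an image is FC on one axis / shared on the other; coil
compression is FC on the channel axis / shared over k-space; GRAPPA-style
kernels are FC over (neighbour, channel) and shared or independent over
k-space location. The weight tensor holds one `(in, out)` axis pair per FC
axis, one axis per independent axis, nothing for shared axes; parameter
counts are twice the complex tensor sizes (split-real counting, no biases).

### The k + I network

The central topology reconstructs images from arbitrary (non-Cartesian)
trajectories under B0 inhomogeneity with two trainable tensors around a
fixed unitary Fourier stage:

    S[i,j,n,c]   gather: the n-th nearest acquired sample to grid cell (i,j),
                 channel c
    K[i,j,t]   = sum_{n,c} S[i,j,n,c] * H[i,j,n,c,t]
    I_hat[i,j] = sum_t M[i,j,t] * iFT2{K[:,:,t]}[i,j]

`H` (shape `[N, N, N_N, N_ch, N_TS]`) is a grid-location-specific regridding
kernel — a GRAPPA generalized to arbitrary trajectories — producing one
k-space grid per "time segment"; `M` (shape `[N, N, N_TS]`) combines the
per-segment images pixel-wise, playing the role of the time-segment
interpolation and absorbing residual sensitivity structure. A second
topology (`knuft_mln`) mimics the transposed time-segmented non-uniform
Fourier pipeline more tightly, with a trajectory-side expansion into
segments before regridding; with one segment the two topologies are the
same operator, and the package builds them identically in that case.

### Forward models

The simulators use one convention throughout: DC-centered pixel coordinates
`r in {-N/2 .. N/2-1}^2`, k in cycles/FOV, unitary centered DFT stages, B0
in rad/s with accrued phase `exp(-i B0 t)`. The exact non-uniform transform
is the raw Fourier sum (on grid locations it equals `N x` the unitary FT;
this global scale is documented here once and asserted in a test). Off
resonance is handled by time segmentation: L segments mean L+1 phase-map
nodes at spacing `Delta = T/L`, combined per sample by an interpolation
matrix G whose rows sum to one (linear interpolation by default, Hanning
behind a switch; min-max-optimal interpolators are out of scope). The exact
continuous-phase signal, computed by dense summation, is the oracle against
which segmentation error is measured; no fast (gridding-kernel) NUFFT is
implemented — the trainable H plays the gridding role.

The spiral generator is an Archimedean-type variable-density design
(`radius ∝ u^{1/(1-vd)}`, uniform dwell), parameterized to reach the regime
of interest — 12.5 ms readout, effective undersampling ~3.2 (Nyquist cells
in the covered disk over samples acquired) — without claiming equivalence
to any scanner-specific design. Poisson-disk undersampling masks use
continuous Bridson dart throwing snapped to the grid, with the exclusion
radius bisected so the realized sampled fraction matches `1/acc^2`; the DC
cell is always sampled. Coil maps are broad complex Gaussian lobes on a
ring (sum-of-squares positive everywhere); B0 maps are smooth random
low-order polynomial + sinusoid fields scaled to a stated peak (±100 Hz in
the experiments, a realistic ultra-high-field regime).

## Training

Adam with fixed learning rate 0.002, beta1 = 0.9, L1 loss, no
regularization, no schedules, no biases. Complex weights are optimized as
split real parameters; since every stage is complex-linear the gradients
are exact closed-form expressions (verified against finite differences in
tests) — no approximate autodiff is involved. beta2 = 0.999 and
epsilon = 1e-8 are the standard Adam constants. The L1 loss is
component-wise (`mean(|Re d| + |Im d|)`), the behaviour of mainstream
frameworks on split-real complex parameters; a modulus variant is available.
Weight initialisation is a complex Gaussian with per-component variance
1/fan_in (fan_in = product of contracted input lengths), keeping initial
outputs O(1); it is deterministic per seed, as is batch ordering, so
training is bit-reproducible.

Convergence monitoring compares consecutive 200-step mean losses; with
stochastic batches these means fluctuate at the percent level once the loss
plateaus, so the default relative tolerance (1e-4) is deliberately
conservative and the step budget normally binds. Desk-scale defaults are
batch size 8 and 5,000 steps at N ≤ 64.

## Synthetic corpora

Training data are paired (signal, complex image) records simulated through
a known forward model. Magnitude sources are either multi-ellipse phantoms
(sums of random ellipses, intensities in [-0.5, 1], clipped to [0, 1]) or
procedural *brain-like* images: head-shaped support, white-matter interior,
a cortical-ribbon annulus, smoothed random blobs and ventricle-like dark
structures. The brain-like generator is a synthetic stand-in for a database
of real brain images: it reproduces the intensity statistics needed for the
two-domain generalization experiment, not anatomy, so passing tests speak
to the phantom-vs-brain-domain contrast rather than to clinical data.
A random smooth phase — three sinusoids with amplitudes U[0, pi] and
frequencies U[0.5, 3] cycles evaluated on a random quadratic form of the
pixel coordinates, constants chosen to produce the multi-radian smooth
phase of real coils and shim (no published constants exist for this model)
— makes the images complex. Augmentation is random cropping from a 1.25x
oversized source, per-axis flips and 0/90° rotation. Per-sample seeds are
counter-derived from the master seed, so corpora are deterministic and
generation-order independent. Signals are noiseless by default; complex
Gaussian signal noise is available in the corpus configuration.

## Evaluation

SSIM uses K1 = 0.01, K2 = 0.03, a 7x7 uniform window, and the reference's
maximum magnitude as data range, on magnitude images. NRMSE is the complex
l2 error over the reference norm. Noise amplification is estimated by the
pseudo-replica method (per-pixel standard deviation of magnitudes over
noise-perturbed reconstructions of one signal). Interpretability maps:
per-grid-cell RMS of H (low on the sampled trajectory, high between
samples) and the N_TS image-domain maps `M[:,:,t]`.

## Desk-scale experiment sizes

The experiment drivers run the studies at sizes a single CPU completes in
minutes, chosen once as the package's study conditions:

* inverse-DFT recovery: N = 16, 500 fully sampled single-coil samples;
* learning-rate robustness: N = 32, 300 samples, 800 steps, 3 seeds;
* operator-matrix equivalence: N = 8, 2 channels, 2 segments, 3 neighbours;
* segmentation fidelity: N = 32, ±100 Hz B0, 12.5 ms spiral, L ∈ {1,3,7,15};
* generalization gap: N = 32, 4 channels, 3 segments, 6 neighbours,
  256-sample spiral (~3.1x effective undersampling), 160 training and 24
  held-out images per arm, 5,000 steps, 3 seeds; the gap statistic is the
  ratio of median held-out NRMSE pooled over seeds (pooling makes the
  statistic stable at these test-set sizes);
* benchmark: N = 32, 8 channels, Poisson-disk accelerations {2, 4, 8},
  single-segment k+I vs the zero-filled adjoint, 160/16 train/test
  brain-like images, 1,500 steps, 3 seeds. The zero-filled adjoint
  (conjugate-sensitivity combination) is the in-package baseline; external
  regularized reconstructions are out of scope, so benchmark claims are
  ordering claims, not absolute-quality claims.

## Design choices where the design was open

* **Grid size of the k-side tensor**: H is built on the N x N grid (the
  shape its declared dimensions imply); an oversampled grid would be a
  straightforward variant but is not the default.
* **TS-shared variant**: sharing H's (neighbour, channel, segment) kernel
  across grid locations is implemented behind a flag; the published
  closed-form count for that variant is internally inconsistent with its
  tabulated value, so the package reports the count of the tensors it
  actually builds (and exposes the printed formula separately, for
  reference).
* **Segment-count bookkeeping**: L segments always means L + 1 interpolation
  nodes; node counts are reported explicitly wherever ambiguity is possible.
* **No-B0 topology**: with a single segment the image-side combination is
  redundant, so `mln_no_b0` fixes M ≡ 1 and trains only H, making its
  parameter count exactly `2 N^2 N_ch N_N`.
* **Ties in neighbour gathering**: exact distance ties are broken by lower
  sample index (stable sort), making the gather deterministic.

## Known limitations

* All simulators are dense; nothing here scales to clinical matrix sizes or
  real-time use, by design.
* The brain-like corpus is procedural; conclusions about real anatomy,
  scanner data, motion or flow are out of scope.
* The trained operator is a left-inverse on the training vector space;
  noise amplification is expected and measured but not mitigated (no
  regularization or denoising stages, deliberately).
* Training uses a fixed learning rate; no schedules, so the final operator
  error floors at the Adam oscillation scale rather than machine precision.
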