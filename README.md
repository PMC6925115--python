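# mlnrecon — minimal linear networks for MR image reconstruction

MR images are acquired indirectly: the scanner samples the spatial-frequency
(k-space) domain, through multiple receive coils, sometimes along
non-Cartesian (e.g. spiral) trajectories, and — at high field — under B0
inhomogeneity that accrues off-resonance phase during the readout. Signal
formation is linear in the image, so reconstruction is the inversion of a
known, often underdetermined linear system.

`mlnrecon` implements that inversion as a *minimal linear network*: a
complex-valued network stripped of every hallmark of deep learning except
training itself — no activation functions, no bias terms, no depth beyond
what the physics requires. The networks are assembled from one primitive,
the subspace fully-connected layer, a tensor contraction whose axes are
declared fully connected, shared or independent (a 1D FT is fully connected
on one axis and shared on the other; coil compression is fully connected on
channels and shared over k-space; GRAPPA kernels are fully connected over
neighbours and channels). Trained on simulated (signal, image) pairs with
Adam and an L1 loss, such a network learns a data-driven left-inverse of the
sampling operator.

The central "k + I" topology trains two tensors around a fixed unitary FT:

    K[i,j,t]   = Σ_{n,c} S[i,j,n,c] · H[i,j,n,c,t]        (k-space side)
    Î[i,j]     = Σ_t M[i,j,t] · iFT2{K[:,:,t]}[i,j]        (image side)

where `S` gathers, at each Cartesian grid cell, the data of the N_N nearest
acquired samples over all N_ch channels; `H` is a location-specific
regridding kernel (a GRAPPA generalized to arbitrary trajectories) producing
one grid per "time segment", and `M` combines the per-segment images,
playing the role of time-segmented B0 correction. The package also builds
the transposed time-segmented NUFT pipeline, plain 2D-FC and separated
2×1D Fourier networks, software/geometric coil-compression front-ends and a
Cartesian parallel-imaging kernel network, all from the same layer
vocabulary, with exact parameter accounting for each.

Intended users: researchers studying learned MR reconstruction who want a
fully transparent, linear, desk-scale testbed — every operator can be
assembled as an explicit matrix and every gradient is a closed-form
expression.

## Worked example

Reconstruct 8-channel Cartesian data undersampled 2× per axis with a
Poisson-disk mask, training a single-segment k + I network on a synthetic
brain-like corpus:

```python
import numpy as np
from mlnrecon import (CartesianForwardModel, CorpusConfig, MLNReconstructor,
                      corpus_arrays, make_coil_maps, poisson_mask, ssim, nrmse)

n, n_ch, acc = 32, 8, 2
coils = make_coil_maps(n, n_ch, seed=0)
mask = poisson_mask(n, acc, seed=0)
fm = CartesianForwardModel(coils, mask)
print(f"mask fraction: {mask.mean():.4f} (target {1/acc**2:.4f})")

train_sigs, train_imgs = corpus_arrays(
    CorpusConfig(n_images=160, n=n, source="brainlike", master_seed=0), fm)
test_sigs, test_imgs = corpus_arrays(
    CorpusConfig(n_images=8, n=n, source="brainlike", master_seed=7), fm)

est = MLNReconstructor(topology="k_plus_i_mln", n=n, n_ch=n_ch, n_ts=1,
                       n_n=8, trajectory=fm.traj, max_steps=1500, seed=0)
est.fit(train_sigs, train_imgs)
print(f"trainable real parameters: {est.n_params_}")

recon = est.predict(test_sigs)
base = fm.zero_filled_adjoint(test_sigs)
print(f"median SSIM  mln={np.median([ssim(r,t) for r,t in zip(recon,test_imgs)]):.3f}  "
      f"zero-filled={np.median([ssim(b,t) for b,t in zip(base,test_imgs)]):.3f}")
print(f"median NRMSE mln={np.median([nrmse(r,t) for r,t in zip(recon,test_imgs)]):.3f}  "
      f"zero-filled={np.median([nrmse(b,t) for b,t in zip(base,test_imgs)]):.3f}")
```

Output:

```
mask fraction: 0.2510 (target 0.2500)
trainable real parameters: 133120
median SSIM  mln=0.633  zero-filled=0.154
median NRMSE mln=0.282  zero-filled=0.787
```

The mask sampled 25.1% of k-space (4-fold reduction). The network holds
133,120 real parameters (H: 32·32·8·8 complex entries, M: 32·32). On
held-out images the trained reconstruction reaches SSIM 0.63 against the
ground truth, versus 0.15 for the zero-filled adjoint baseline, and less
than half its error norm — the learned regridding kernels fill in the
missing k-space from neighbouring sampled locations across coils.

The same estimator handles non-Cartesian sampling under B0 inhomogeneity by
passing a `SpiralForwardModel` trajectory and `n_ts > 1` segments; see
`docs/methods.md` for the model, conventions and the desk-scale experiment
sizes. A `mlnrecon` CLI (`simulate`, `train`, `evaluate`, `count-params`,
`benchmark`) wraps the same functions.

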