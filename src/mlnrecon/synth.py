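"""Synthetic training corpora.

The networks are trained on paired (signal, ground-truth complex image)
samples simulated through a known forward model. Two image sources are
provided:

* ``ellipse`` -- sums of random ellipses (modified Shepp-Logan style
  phantoms);
* ``brainlike`` -- procedural images with head-shaped support, a cortical
  ribbon, smooth interior blobs and ventricle-like dark structures. These
  stand in for a database of real brain magnitude images; they reproduce the
  qualitative two-domain setup (phantom corpus vs brain-like corpus) needed
  to study cross-domain generalization, not real anatomy.

A random smooth phase map (a short sum of sinusoids evaluated on a random
quadratic form of the pixel coordinates) turns each magnitude source into a
complex image, emulating the phase structure imparted by receive coils and
imperfect shim. Augmentation is random cropping, per-axis flips and 0/90
degree rotation.

Every sample is generated from a counter-derived seed, so corpora are fully
deterministic per master seed and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage

__all__ = [
    "SynthSample",
    "CorpusConfig",
    "multi_ellipse_phantom",
    "random_phase",
    "brainlike_image",
    "augment",
    "make_corpus",
    "corpus_arrays",
]


def multi_ellipse_phantom(n: int, n_ellipses: int = 8, seed: int = 0) -> np.ndarray:
    """Sum of random ellipses, clipped to [0, 1]. Deterministic per seed."""
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(seed)
    c = (np.arange(n) - n / 2 + 0.5) / (n / 2)
    x, y = np.meshgrid(c, c, indexing="ij")
    img = np.zeros((n, n))
    for _ in range(n_ellipses):
        cx, cy = rng.uniform(-0.55, 0.55, 2)
        ax, ay = rng.uniform(0.1, 0.55, 2)
        th = rng.uniform(0, np.pi)
        amp = rng.uniform(-0.5, 1.0)
        xr = (x - cx) * np.cos(th) + (y - cy) * np.sin(th)
        yr = -(x - cx) * np.sin(th) + (y - cy) * np.cos(th)
        img += amp * ((xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0)
    return np.clip(img, 0.0, 1.0)


def random_phase(
    n: int,
    seed: int = 0,
    n_sinusoids: int = 3,
    amp_range: tuple[float, float] = (0.0, np.pi),
    freq_range: tuple[float, float] = (0.5, 3.0),
) -> np.ndarray:
    """Smooth random phase map (radians): sinusoids on a random quadratic form.

    ``phase(r) = sum_j a_j sin(2 pi f_j q(r) + phi_j)`` where ``q`` is a
    random quadratic polynomial of the normalized pixel coordinates, rescaled
    to [0, 1] over the image. Amplitudes up to pi and a handful of cycles
    across the FOV give the multi-radian, smoothly varying phase seen in
    practice. Deterministic per seed.
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(seed)
    c = (np.arange(n) - n / 2 + 0.5) / (n / 2)
    x, y = np.meshgrid(c, c, indexing="ij")
    q = (rng.normal() * x * x + rng.normal() * y * y + rng.normal() * x * y
         + rng.normal() * x + rng.normal() * y)
    lo, hi = q.min(), q.max()
    if hi > lo:
        q = (q - lo) / (hi - lo)
    phase = np.zeros((n, n))
    for _ in range(n_sinusoids):
        a = rng.uniform(*amp_range)
        f = rng.uniform(*freq_range)
        phi = rng.uniform(0, 2 * np.pi)
        phase += a * np.sin(2 * np.pi * f * q + phi)
    return phase


def brainlike_image(n: int, seed: int = 0) -> np.ndarray:
    """Procedural brain-like magnitude image in [0, 1]. Deterministic per seed.

    Head-shaped elliptical support, white-matter interior, a cortical-ribbon
    annulus, smoothed random blobs as gray-matter structure and dark
    ventricle-like blobs near the center. Synthetic: emulates the intensity
    statistics of brain images, not anatomy.
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(seed)
    c = (np.arange(n) - n / 2 + 0.5) / (n / 2)
    x, y = np.meshgrid(c, c, indexing="ij")
    ax, ay = rng.uniform(0.75, 0.9), rng.uniform(0.85, 0.97)
    rho = np.sqrt((x / ax) ** 2 + (y / ay) ** 2)
    head = rho <= 1.0
    img = np.where(head, 0.55, 0.0)
    # cortical ribbon
    ribbon = (rho > 0.8) & (rho <= 0.97)
    img[ribbon] = 0.85
    # gray-matter-like blobs from a smoothed random field
    f = ndimage.gaussian_filter(rng.normal(size=(n, n)), sigma=n / 12)
    f /= max(np.std(f), 1e-12)
    img[head & (rho <= 0.8) & (f > 0.6)] = 0.8
    # ventricles
    for sx in (-1, 1):
        vx, vy = 0.12 * sx + rng.uniform(-0.04, 0.04), rng.uniform(-0.1, 0.05)
        vent = ((x - vx) / 0.1) ** 2 + ((y - vy) / 0.25) ** 2 <= 1.0
        img[vent & head] = 0.15
    img = ndimage.gaussian_filter(img, sigma=0.02 * n)
    return np.clip(img, 0.0, 1.0)


def augment(
    img: np.ndarray,
    seed: int = 0,
    target: int | None = None,
    crop: bool = True,
    flip: bool = True,
    rotate: bool = True,
) -> np.ndarray:
    """Random crop to the target size, per-axis flips, 0/90 degree rotation.

    With all augmentations disabled (and matching sizes) this is the
    identity. Deterministic per seed.
    """
    img = np.asarray(img)
    rng = np.random.default_rng(seed)
    m = img.shape[0]
    t = target if target is not None else m
    if m < t:
        raise ValueError("source image smaller than the target size")
    if crop:
        i0 = rng.integers(0, m - t + 1)
        j0 = rng.integers(0, m - t + 1)
    else:
        i0 = j0 = (m - t) // 2
    out = img[i0:i0 + t, j0:j0 + t]
    if flip:
        if rng.integers(0, 2):
            out = out[::-1, :]
        if rng.integers(0, 2):
            out = out[:, ::-1]
    if rotate and rng.integers(0, 2):
        out = np.rot90(out)
    return out.copy()


# ---------------------------------------------------------------------------
# corpus


@dataclass(frozen=True)
class SynthSample:
    """One paired training record: complex image, simulated signal, metadata.

    ``meta`` carries everything needed to regenerate the sample bit-exactly:
    the master seed, sample index, source type and the forward-model id.
    """

    image: np.ndarray
    signal: np.ndarray
    meta: dict


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions of a synthetic corpus."""

    n_images: int
    n: int
    source: str = "ellipse"          # "ellipse" | "brainlike"
    master_seed: int = 0
    n_ellipses: int = 8
    oversize: float = 1.25           # source images before random cropping
    crop: bool = True
    flip: bool = True
    rotate: bool = True
    phase_sinusoids: int = 3
    noise_sd: float = 0.0            # complex Gaussian noise on signals (off)

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.source not in ("ellipse", "brainlike"):
            raise ValueError(f"unknown source {self.source!r}")


def _sample_seeds(master_seed: int, k: int, n_streams: int = 4) -> list[int]:
    """Counter-derived per-sample seeds (order-independent, < 2**31)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(k),))
    return [int(s) % (2**31) for s in ss.generate_state(n_streams)]


def sample_image(cfg: CorpusConfig, k: int) -> np.ndarray:
    """The k-th complex ground-truth image of the corpus."""
    s_img, s_aug, s_phase, _ = _sample_seeds(cfg.master_seed, k)
    m = int(round(cfg.oversize * cfg.n)) if cfg.crop else cfg.n
    if cfg.source == "ellipse":
        mag = multi_ellipse_phantom(m, cfg.n_ellipses, seed=s_img)
    else:
        mag = brainlike_image(m, seed=s_img)
    mag = augment(mag, seed=s_aug, target=cfg.n,
                  crop=cfg.crop, flip=cfg.flip, rotate=cfg.rotate)
    phase = random_phase(cfg.n, seed=s_phase, n_sinusoids=cfg.phase_sinusoids)
    return mag * np.exp(1j * phase)


def make_sample(cfg: CorpusConfig, fm, k: int) -> SynthSample:
    """Generate (or regenerate, bit-exactly) the k-th sample of the corpus."""
    img = sample_image(cfg, k)
    sig = fm.simulate(img)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(_sample_seeds(cfg.master_seed, k)[3])
        sig = sig + cfg.noise_sd * (rng.standard_normal(sig.shape)
                                    + 1j * rng.standard_normal(sig.shape))
    meta = {"index": k, "master_seed": cfg.master_seed,
            "source": cfg.source, "forward_model": fm.id}
    return SynthSample(img, sig, meta)


def make_corpus(cfg: CorpusConfig, fm) -> Iterator[SynthSample]:
    """Lazy stream of ``cfg.n_images`` paired samples."""
    for k in range(cfg.n_images):
        yield make_sample(cfg, fm, k)


def corpus_arrays(cfg: CorpusConfig, fm) -> tuple[np.ndarray, np.ndarray]:
    """Materialize the corpus as stacked (signals, images) arrays.

    Signals are simulated in one batched pass through the forward model
    (identical, by linearity and determinism, to per-sample simulation).
    """
    imgs = np.stack([sample_image(cfg, k) for k in range(cfg.n_images)])
    sigs = fm.simulate(imgs)
    if cfg.noise_sd > 0:
        for k in range(cfg.n_images):
            rng = np.random.default_rng(_sample_seeds(cfg.master_seed, k)[3])
            sigs[k] += cfg.noise_sd * (rng.standard_normal(sigs[k].shape)
                                       + 1j * rng.standard_normal(sigs[k].shape))
    return sigs, imgs
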