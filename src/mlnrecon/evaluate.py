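"""Image-quality metrics, noise maps and interpretability maps.

SSIM follows the standard constants (K1 = 0.01, K2 = 0.03) with a 7 x 7
uniform window and the reference's maximum magnitude as the data range.
NRMSE is the complex l2 error normalized by the reference norm. Noise
amplification is estimated by the pseudo-replica method: reconstruct many
noise-perturbed copies of one signal and map the per-pixel standard
deviation of the magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.metrics import structural_similarity

from .builder import MLNModel

__all__ = [
    "ssim",
    "nrmse",
    "noise_map",
    "kernel_rms_map",
    "segment_maps",
    "MetricReport",
]


def ssim(recon: np.ndarray, ref: np.ndarray) -> float:
    """Structural similarity between magnitude images.

    Computed on ``|recon|`` and ``|ref|`` with the reference's maximum as
    the data range, 7 x 7 uniform window, K1 = 0.01, K2 = 0.03. Invariant to
    a global sign/phase of either input.
    """
    a = np.abs(np.asarray(recon))
    b = np.abs(np.asarray(ref))
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    rng = float(b.max())
    if rng == 0:
        raise ValueError("reference image is identically zero")
    return float(structural_similarity(
        a, b, data_range=rng, win_size=7, gaussian_weights=False,
        K1=0.01, K2=0.03))


def nrmse(recon: np.ndarray, ref: np.ndarray) -> float:
    """``||recon - ref||_2 / ||ref||_2`` on complex values."""
    recon = np.asarray(recon)
    ref = np.asarray(ref)
    if recon.shape != ref.shape:
        raise ValueError("shape mismatch")
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise ValueError("reference image is identically zero")
    return float(np.linalg.norm(recon - ref) / denom)


def noise_map(
    reconstruct: Callable[[np.ndarray], np.ndarray],
    signal: np.ndarray,
    noise_sd: float,
    n_reps: int = 64,
    seed: int = 0,
) -> np.ndarray:
    """Pseudo-replica noise map of a reconstruction operator.

    ``reconstruct`` maps a batch of signals ``[B, ...]`` to images
    ``[B, N, N]``. Complex Gaussian noise with per-component standard
    deviation ``noise_sd`` is added to ``n_reps`` copies of the fixed
    signal; the per-pixel standard deviation of the reconstructed magnitudes
    is returned. For a linear operator this estimates the analytic noise
    propagation to Monte-Carlo accuracy.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    signal = np.asarray(signal, dtype=np.complex128)
    reps = np.broadcast_to(signal, (n_reps,) + signal.shape).copy()
    reps += noise_sd * (rng.standard_normal(reps.shape)
                        + 1j * rng.standard_normal(reps.shape))
    imgs = reconstruct(reps)
    return np.std(np.abs(imgs), axis=0)


def kernel_rms_map(model: MLNModel) -> np.ndarray:
    """Per-grid-location RMS of the regridding tensor H.

    ``map[i, j] = sqrt(mean over (neighbour, channel, segment) of |H|^2)``.
    Grid locations close to acquired trajectory points need only small
    weights; locations between samples demand larger ones, so this map reads
    out how hard the network works per k-space cell.
    """
    h = model.H
    return np.sqrt(np.mean(np.abs(h) ** 2, axis=(2, 3, 4)))


def segment_maps(model: MLNModel) -> list[np.ndarray]:
    """The image-side combination maps ``M[:, :, t]``, one per segment.

    After training under field inhomogeneity these resemble the segment
    phase maps ``exp(-i B0 l Delta)`` blended with residual sensitivity
    structure.
    """
    return [model.M[:, :, t].copy() for t in range(model.M.shape[2])]


@dataclass
class MetricReport:
    """Aggregated evaluation of one benchmark arm."""

    topology: str
    acceleration: float
    ssim_values: list = field(default_factory=list)
    nrmse_values: list = field(default_factory=list)
    seeds: list = field(default_factory=list)

    @property
    def median_ssim(self) -> float:
        return float(np.median(self.ssim_values))

    @property
    def iqr_ssim(self) -> float:
        q1, q3 = np.percentile(self.ssim_values, [25, 75])
        return float(q3 - q1)

    @property
    def median_nrmse(self) -> float:
        return float(np.median(self.nrmse_values))

    def as_dict(self) -> dict:
        return {
            "topology": self.topology,
            "acceleration": self.acceleration,
            "median_ssim": self.median_ssim,
            "iqr_ssim": self.iqr_ssim,
            "median_nrmse": self.median_nrmse,
            "n": len(self.ssim_values),
        }
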