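"""MR image-to-signal forward models.

Conventions used throughout the package (chosen once, tested once):

* Image pixel coordinates are DC-centered integers ``r = (x, y)`` with
  ``x, y in {-N/2, ..., N/2 - 1}`` for matrix size ``N``.
* k-space coordinates are in cycles per field of view, ``|k| <= N/2``.
* The fixed Fourier stages are *unitary* centered DFTs (``1/sqrt(n)`` per
  axis). The exact non-uniform transform :func:`nuft_exact` is the raw
  (unnormalized) Fourier sum; on Cartesian grid locations it equals the
  unitary 2D pipeline times a global factor ``N``.
* Off-resonance maps ``B0(r)`` are in radians/second; the phase accrued by
  time ``t`` is ``exp(-i * B0(r) * t)``.

Field inhomogeneity is handled by *time segmentation*: the continuous phase
evolution ``exp(-i B0 t)`` over an acquisition of duration ``T`` is
approximated by interpolating between ``L + 1`` phase maps evaluated at the
segment nodes ``l * Delta``, ``Delta = T / L``. The signal model is

    s_hat = sum_l  G[:, l] * F_u{ I * P_l },     P_l = exp(-i B0 l Delta)

where ``F_u`` is the non-uniform Fourier transform along the trajectory and
``G`` holds per-sample interpolation coefficients (rows sum to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Trajectory",
    "SegmentInterpolator",
    "dft_matrix",
    "ft2c",
    "ift2c",
    "phase_evolution",
    "nuft_exact",
    "nuft_matrix",
    "exact_signal_matrix",
    "segmented_forward",
    "build_segment_interpolator",
    "make_spiral",
    "effective_undersampling",
    "poisson_mask",
    "make_coil_maps",
    "make_b0_map",
    "CartesianForwardModel",
    "SpiralForwardModel",
    "centered_coords",
]


def centered_coords(n: int) -> np.ndarray:
    """DC-centered integer coordinates ``{-n//2, ..., n - n//2 - 1}``."""
    return np.arange(n) - n // 2


# ---------------------------------------------------------------------------
# Fourier stages


def dft_matrix(n: int) -> np.ndarray:
    """Unitary DC-centered DFT matrix: ``F[k, r] = exp(-2i pi k r / n)/sqrt(n)``.

    ``k`` and ``r`` both run over :func:`centered_coords`. ``F @ F.conj().T``
    is the identity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    c = centered_coords(n)
    return np.exp(-2j * np.pi * np.outer(c, c) / n) / np.sqrt(n)


def ft2c(img: np.ndarray) -> np.ndarray:
    """Centered unitary 2D FT (image -> k-space) over the last two axes."""
    axes = (-2, -1)
    n = img.shape[-1] * img.shape[-2]
    x = np.fft.ifftshift(img, axes=axes)
    return np.fft.fftshift(np.fft.fft2(x, axes=axes), axes=axes) / np.sqrt(n)


def ift2c(ksp: np.ndarray) -> np.ndarray:
    """Centered unitary 2D inverse FT (k-space -> image), last two axes."""
    axes = (-2, -1)
    n = ksp.shape[-1] * ksp.shape[-2]
    x = np.fft.ifftshift(ksp, axes=axes)
    return np.fft.fftshift(np.fft.ifft2(x, axes=axes), axes=axes) * np.sqrt(n)


# ---------------------------------------------------------------------------
# trajectories and interpolators


@dataclass(frozen=True)
class Trajectory:
    """Non-Cartesian k-space sample locations with acquisition times.

    ``coords`` is (n_samples, 2) in cycles/FOV; ``times`` is seconds,
    non-decreasing within ``[0, duration]``.
    """

    coords: np.ndarray
    times: np.ndarray
    duration: float

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n_samples, 2)")
        if times.shape != (coords.shape[0],):
            raise ValueError("times must match the number of samples")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        if times.size and (times[0] < 0 or times[-1] > self.duration + 1e-12):
            raise ValueError("times must lie within [0, duration]")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def check_in_range(self, n: int) -> None:
        if np.any(np.abs(self.coords) > n / 2 + 1e-9):
            raise ValueError(f"trajectory coordinates exceed +-{n / 2} for matrix size {n}")

    def save(self, path) -> None:
        np.savez(path, coords=self.coords, times=self.times,
                 duration=np.float64(self.duration))

    @classmethod
    def load(cls, path) -> "Trajectory":
        d = np.load(path)
        return cls(d["coords"], d["times"], float(d["duration"]))


@dataclass(frozen=True)
class SegmentInterpolator:
    """Per-sample interpolation coefficients between segment phase nodes.

    ``coeffs`` has shape (n_samples, L + 1): L segments means L + 1 nodes at
    times ``l * delta``, ``delta = T / L``. Every row sums to one, and a
    sample lying exactly on a node gets a one-hot row.
    """

    coeffs: np.ndarray
    n_segments: int
    delta: float
    scheme: str = "linear"

    @property
    def n_nodes(self) -> int:
        return self.n_segments + 1


def build_segment_interpolator(
    traj: Trajectory,
    n_segments: int,
    scheme: Literal["linear", "hanning"] = "linear",
) -> SegmentInterpolator:
    """Interpolation matrix G for time-segmented off-resonance correction."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    L = int(n_segments)
    delta = traj.duration / L
    u = np.asarray(traj.times, dtype=float) / delta
    i0 = np.clip(np.floor(u).astype(int), 0, L - 1)
    frac = u - i0
    g = np.zeros((len(traj), L + 1))
    rows = np.arange(len(traj))
    if scheme == "linear":
        w1 = frac
    elif scheme == "hanning":
        w1 = 0.5 * (1.0 - np.cos(np.pi * frac))
    else:
        raise ValueError(f"unknown interpolation scheme {scheme!r}")
    g[rows, i0] = 1.0 - w1
    g[rows, i0 + 1] += w1
    return SegmentInterpolator(g, L, delta, scheme)


# ---------------------------------------------------------------------------
# off-resonance phase and exact transforms


def phase_evolution(b0: np.ndarray, l: int, delta: float) -> np.ndarray:
    """Per-pixel phase map ``P_l(r) = exp(-i B0(r) l Delta)``.

    ``b0`` is in radians/second. The caller forms ``D_l = I * P_l``.
    """
    b0 = np.asarray(b0, dtype=float)
    return np.exp(-1j * b0 * (l * delta))


def nuft_matrix(traj: Trajectory, n: int) -> np.ndarray:
    """Dense non-uniform Fourier matrix E with ``E[m, r] = exp(-2i pi k_m.r/n)``.

    ``r`` runs row-major over the flattened DC-centered image grid.
    """
    traj.check_in_range(n)
    c = centered_coords(n)
    x, y = np.meshgrid(c, c, indexing="ij")
    rx, ry = x.ravel(), y.ravel()
    kx = traj.coords[:, 0][:, None]
    ky = traj.coords[:, 1][:, None]
    return np.exp(-2j * np.pi * (kx * rx[None, :] + ky * ry[None, :]) / n)


def nuft_exact(img: np.ndarray, traj: Trajectory) -> np.ndarray:
    """Exact (slow, dense) non-uniform Fourier transform of an N x N image.

    ``signal[m] = sum_r img(r) exp(-2i pi k_m . r / N)``. This is the oracle
    the trainable regridding stages are measured against; it is O(N^2 * M).
    On Cartesian grid locations it equals ``N *`` the unitary :func:`ft2c`.
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("img must be square (N x N)")
    e = nuft_matrix(traj, img.shape[0])
    return e @ img.ravel()


def exact_signal_matrix(
    traj: Trajectory, n: int, b0: np.ndarray, sens: np.ndarray | None = None
) -> np.ndarray:
    """Dense matrix of the *continuous-phase* signal model for one channel.

    ``A[m, r] = sens(r) exp(-i B0(r) t_m) exp(-2i pi k_m . r / n)``, so that
    ``s = A @ img.ravel()`` is the exact signal without any time-segmentation
    approximation. Serves as the oracle for the segmented operator.
    """
    e = nuft_matrix(traj, n)
    ph = np.exp(-1j * np.outer(traj.times, np.asarray(b0, dtype=float).ravel()))
    a = e * ph
    if sens is not None:
        a = a * np.asarray(sens).ravel()[None, :]
    return a


def segmented_forward(
    img: np.ndarray,
    coils: np.ndarray,
    b0: np.ndarray,
    traj: Trajectory,
    seg: SegmentInterpolator,
) -> np.ndarray:
    """Time-segmented multi-coil signal, shape (n_ch, n_samples).

    Per channel: ``s_hat = sum_l G[:, l] * F_u{ coil * img * P_l }``. With a
    zero B0 map every P_l is one and, because rows of G sum to one, the
    result collapses exactly to the coil-weighted :func:`nuft_exact`.
    """
    img = np.asarray(img)
    coils = np.atleast_3d(np.asarray(coils))
    if coils.shape[1:] != img.shape or np.asarray(b0).shape != img.shape:
        raise ValueError("coils/b0 shapes must match the image")
    if seg.coeffs.shape[0] != len(traj):
        raise ValueError("segment interpolator was not built for this trajectory")
    e = nuft_matrix(traj, img.shape[0])
    out = np.zeros((coils.shape[0], len(traj)), dtype=np.complex128)
    for l in range(seg.n_nodes):
        p = phase_evolution(b0, l, seg.delta)
        src = (coils * (img * p)[None]).reshape(coils.shape[0], -1)
        out += seg.coeffs[:, l][None, :] * (src @ e.T)
    return out


# ---------------------------------------------------------------------------
# trajectory / mask / map generators


def make_spiral(
    n: int,
    n_samples: int,
    duration: float = 12.5e-3,
    vd_exponent: float = 0.0,
    n_turns: float | None = None,
) -> Trajectory:
    """Archimedean-type variable-density spiral from k = 0 out to |k| = n/2.

    Radial sample density is proportional to ``radius ** (-vd_exponent)``
    with ``0 <= vd_exponent < 1`` (0 = uniform-in-radius density), i.e.
    larger exponents oversample the k-space center. Uniform dwell time
    ``duration / n_samples``. ``n_turns`` defaults to ``n / 4``, which at
    full radius leaves about two k-units between revolutions; fewer turns or
    fewer samples undersample the disk.
    """
    if n_samples < n:
        raise ValueError("need at least n samples")
    if not 0 <= vd_exponent < 1:
        raise ValueError("vd_exponent must be in [0, 1)")
    if n_turns is None:
        n_turns = n / 4
    u = np.linspace(0.0, 1.0, n_samples)
    radius = (n / 2) * u ** (1.0 / (1.0 - vd_exponent))
    theta = 2 * np.pi * n_turns * u
    coords = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
    # keep strictly inside the +-n/2 box
    coords = np.clip(coords, -n / 2, n / 2 - 1e-9)
    times = np.arange(n_samples) * (duration / n_samples)
    return Trajectory(coords, times, duration)


def effective_undersampling(traj: Trajectory, n: int) -> float:
    """Nyquist samples needed over samples acquired, for the covered k-disk.

    "Needed" counts the Nyquist-grid cells inside the disk of the largest
    sampled radius; values > 1 mean the trajectory undersamples that disk.
    """
    rmax = float(np.max(np.hypot(traj.coords[:, 0], traj.coords[:, 1])))
    c = centered_coords(n)
    x, y = np.meshgrid(c, c, indexing="ij")
    needed = int(np.sum(x * x + y * y <= rmax * rmax))
    return needed / len(traj)


def _bridson(n: int, radius: float, seed: int, k: int = 30) -> np.ndarray:
    """Poisson-disk sample of the [0, n)^2 square snapped to grid cells.

    Bridson dart throwing in the continuous plane (minimum point distance
    ``radius``), started at the DC cell center, then rasterized. Continuous
    positions make the realized density a smooth function of the radius, so
    a target sampled fraction can be met by bisection.
    """
    cell = radius / np.sqrt(2.0)
    gn = int(np.ceil(n / cell))
    grid = -np.ones((gn, gn), dtype=np.intp)
    pts: list[tuple[float, float]] = []
    rng = np.random.default_rng(seed)

    def gcell(p):
        return min(int(p[0] / cell), gn - 1), min(int(p[1] / cell), gn - 1)

    def fits(p):
        gi, gj = gcell(p)
        for ii in range(max(0, gi - 2), min(gn, gi + 3)):
            for jj in range(max(0, gj - 2), min(gn, gj + 3)):
                q = grid[ii, jj]
                if q >= 0:
                    dx = pts[q][0] - p[0]
                    dy = pts[q][1] - p[1]
                    if dx * dx + dy * dy < radius * radius:
                        return False
        return True

    def insert(p):
        pts.append(p)
        gi, gj = gcell(p)
        grid[gi, gj] = len(pts) - 1

    insert((n // 2 + 0.5, n // 2 + 0.5))
    active = [0]
    while active:
        a = int(rng.integers(len(active)))
        p = pts[active[a]]
        for _ in range(k):
            r = radius * (1.0 + rng.random())
            th = 2 * np.pi * rng.random()
            q = (p[0] + r * np.cos(th), p[1] + r * np.sin(th))
            if 0 <= q[0] < n and 0 <= q[1] < n and fits(q):
                insert(q)
                active.append(len(pts) - 1)
                break
        else:
            active[a] = active[-1]
            active.pop()
    mask = np.zeros((n, n), dtype=bool)
    for p in pts:
        mask[int(p[0]), int(p[1])] = True
    return mask


def poisson_mask(n: int, acc: float, seed: int = 0) -> np.ndarray:
    """Poisson-disk undersampling mask, equal acceleration on both axes.

    The overall sampled fraction targets ``1 / acc**2``; the minimum point
    distance of the underlying continuous Poisson-disk process is chosen by
    bisection so the realized fraction matches the target closely. The DC
    cell (n//2, n//2) is always sampled. Deterministic per seed.
    """
    if acc < 1:
        raise ValueError("acc must be >= 1")
    target = 1.0 / acc**2
    if acc == 1:
        return np.ones((n, n), dtype=bool)
    if target > 0.6:
        # denser than a disk process resolves on the grid: random selection
        rng = np.random.default_rng(seed)
        m = np.zeros(n * n, dtype=bool)
        m[rng.permutation(n * n)[:int(round(target * n * n))]] = True
        mask = m.reshape(n, n)
        mask[n // 2, n // 2] = True
        return mask

    # Bridson sampling realizes fraction ~= 0.68 / radius^2; bracket around
    # that guess, widening if the realized fractions do not straddle target
    r0 = np.sqrt(0.68 / target)
    lo, hi = 0.75 * r0, 1.35 * r0
    while lo > 0.8 and _bridson(n, lo, seed).mean() < target:
        lo *= 0.75
    while hi < 4 * n and _bridson(n, hi, seed).mean() > target:
        hi *= 1.35
    best = None
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        m = _bridson(n, mid, seed)
        f = m.mean()
        if best is None or abs(f - target) < abs(best[1] - target):
            best = (m, f)
        if f > target:
            lo = mid
        else:
            hi = mid
    mask = best[0].copy()
    mask[n // 2, n // 2] = True
    return mask


def make_coil_maps(n: int, n_ch: int, seed: int = 0) -> np.ndarray:
    """Smooth synthetic coil sensitivity maps, shape (n_ch, n, n).

    Each channel is a broad complex Gaussian lobe centered on a ring around
    the FOV (a single channel degenerates to a centered, near-uniform lobe),
    with a smooth linear phase ramp. The sum-of-squares magnitude is strictly
    positive everywhere. Deterministic per seed.
    """
    if n_ch < 1:
        raise ValueError("n_ch must be >= 1")
    rng = np.random.default_rng(seed)
    c = centered_coords(n).astype(float)
    x, y = np.meshgrid(c, c, indexing="ij")
    ring = 0.0 if n_ch == 1 else 0.45 * n
    sigma = 0.9 * n if n_ch == 1 else 0.55 * n
    maps = np.zeros((n_ch, n, n), dtype=np.complex128)
    for k in range(n_ch):
        ang = 2 * np.pi * k / n_ch + rng.uniform(-0.1, 0.1)
        cx, cy = ring * np.cos(ang), ring * np.sin(ang)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
        gx, gy = rng.uniform(-0.8, 0.8, 2)
        phi0 = rng.uniform(0, 2 * np.pi)
        phase = 2 * np.pi * (gx * x + gy * y) / n + phi0
        maps[k] = mag * np.exp(1j * phase)
    return maps


def make_b0_map(n: int, max_hz: float, seed: int = 0) -> np.ndarray:
    """Smooth synthetic off-resonance map in radians/second, shape (n, n).

    A random low-order polynomial plus two sinusoids, rescaled so the maximum
    magnitude is ``2 pi max_hz``. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    c = centered_coords(n).astype(float) / (n / 2)
    x, y = np.meshgrid(c, c, indexing="ij")
    coef = rng.normal(size=6)
    f = (coef[0] + coef[1] * x + coef[2] * y + coef[3] * x * y
         + coef[4] * x * x + coef[5] * y * y)
    for _ in range(2):
        a = rng.normal()
        fx, fy = rng.uniform(0.3, 1.2, 2)
        ph = rng.uniform(0, 2 * np.pi)
        f = f + a * np.sin(np.pi * (fx * x + fy * y) + ph)
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    return f * (2 * np.pi * max_hz)


# ---------------------------------------------------------------------------
# forward models


class CartesianForwardModel:
    """Multi-coil Cartesian sampling: unitary 2D FT of each coil-weighted
    image, sampled where the binary mask is True (row-major sample order)."""

    def __init__(self, coils: np.ndarray, mask: np.ndarray):
        self.coils = np.asarray(coils, dtype=np.complex128)
        self.mask = np.asarray(mask, dtype=bool)
        self.n = self.mask.shape[0]
        if self.mask.shape != (self.n, self.n):
            raise ValueError("mask must be square")
        if self.coils.shape[1:] != self.mask.shape:
            raise ValueError("coil maps must match the mask size")
        self.n_ch = self.coils.shape[0]
        ii, jj = np.nonzero(self.mask)
        c = centered_coords(self.n)
        coords = np.stack([c[ii], c[jj]], axis=1).astype(float)
        self.traj = Trajectory(coords, np.zeros(len(ii)), 0.0)
        self._idx = (ii, jj)
        self.id = f"cartesian(n={self.n},nch={self.n_ch},frac={self.mask.mean():.3f})"

    @property
    def n_samples(self) -> int:
        return len(self.traj)

    def simulate(self, imgs: np.ndarray) -> np.ndarray:
        """imgs (..., N, N) -> signals (..., n_samples, n_ch)."""
        imgs = np.asarray(imgs, dtype=np.complex128)
        k = ft2c(imgs[..., None, :, :] * self.coils)  # (..., ch, N, N)
        sig = k[..., self._idx[0], self._idx[1]]       # (..., ch, n_samples)
        return np.moveaxis(sig, -2, -1)

    def zero_filled_adjoint(self, signals: np.ndarray) -> np.ndarray:
        """Zero-fill, inverse FT, conjugate-sensitivity coil combination."""
        signals = np.asarray(signals)
        batch = signals.shape[:-2]
        k = np.zeros(batch + (self.n_ch, self.n, self.n), dtype=np.complex128)
        k[..., :, self._idx[0], self._idx[1]] = np.moveaxis(signals, -1, -2)
        imgs = ift2c(k)
        sos = np.sum(np.abs(self.coils) ** 2, axis=0)
        return np.sum(imgs * np.conj(self.coils), axis=-3) / np.maximum(sos, 1e-12)


class SpiralForwardModel:
    """Non-Cartesian multi-coil sampling with time-segmented B0 evolution.

    Precomputes one dense signal matrix per channel so that repeated
    simulation over a corpus is a single matrix product. With
    ``exact=True`` the continuous-phase model (no segmentation error) is
    used instead; that variant is the oracle for segmentation fidelity.
    """

    def __init__(
        self,
        coils: np.ndarray,
        b0: np.ndarray,
        traj: Trajectory,
        n_segments: int = 1,
        scheme: str = "linear",
        exact: bool = False,
    ):
        self.coils = np.asarray(coils, dtype=np.complex128)
        self.b0 = np.asarray(b0, dtype=float)
        self.traj = traj
        self.n = self.b0.shape[0]
        self.n_ch = self.coils.shape[0]
        if self.coils.shape[1:] != self.b0.shape:
            raise ValueError("coil maps must match the B0 map")
        traj.check_in_range(self.n)
        self.exact = bool(exact)
        self.n_segments = int(n_segments)
        self.scheme = scheme
        if exact:
            mats = [exact_signal_matrix(traj, self.n, self.b0, s) for s in self.coils]
            self.seg = None
        else:
            self.seg = build_segment_interpolator(traj, n_segments, scheme)
            e = nuft_matrix(traj, self.n)
            mats = []
            for s in self.coils:
                a = np.zeros_like(e)
                for l in range(self.seg.n_nodes):
                    p = (s * phase_evolution(self.b0, l, self.seg.delta)).ravel()
                    a += self.seg.coeffs[:, l][:, None] * (e * p[None, :])
                mats.append(a)
        self._mats = np.stack(mats)  # (n_ch, n_samples, N^2)
        tag = "exact" if exact else f"L={n_segments},{scheme}"
        self.id = f"spiral(n={self.n},nch={self.n_ch},m={len(traj)},{tag})"

    @property
    def n_samples(self) -> int:
        return len(self.traj)

    def simulate(self, imgs: np.ndarray) -> np.ndarray:
        """imgs (..., N, N) -> signals (..., n_samples, n_ch)."""
        imgs = np.asarray(imgs, dtype=np.complex128)
        batch = imgs.shape[:-2]
        v = imgs.reshape(batch + (-1,))
        sig = np.einsum("cmr,...r->...mc", self._mats, v, optimize=True)
        return sig
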