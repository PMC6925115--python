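"""Network topologies for MR reconstruction.

The central topology is the "k + I" minimal linear network: trajectory data
are gathered onto the Cartesian grid (each grid cell collects its N_N
nearest acquired samples over all channels, forming the tensor
``S[i, j, neighbour, channel]``), contracted with a trainable location
specific regridding tensor ``H[i, j, neighbour, channel, segment]`` into
per-segment k-space grids, inverse Fourier transformed with a fixed unitary
stage, and combined pixel-wise by a trainable image-side tensor
``M[i, j, segment]``:

    K[i, j, t] = sum_{n, c} S[i, j, n, c] * H[i, j, n, c, t]
    I_hat[i, j] = sum_t  M[i, j, t] * iFT2{K[:, :, t]}[i, j]

H plays the role of a GRAPPA-like, location-specific regridding kernel; M
plays the role of the time-segment combination (and absorbs residual
sensitivity structure). Other topologies (plain 2D fully connected, the
2 x 1D separated Fourier pair, coil-compression front-ends, the Cartesian
parallel-imaging kernel network, and the transposed time-segmented NUFT
pipeline) are built from the same stage vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import (EinsumStage, FourierStage, GatherStage, LinearNetwork,
                      WindowStage, _centered_fft)
from .physics import Trajectory, centered_coords

__all__ = [
    "NeighborTable",
    "gather_neighbors",
    "assemble_S",
    "MLNModel",
    "k_plus_i_apply",
    "TopologySpec",
    "build_topology",
    "count_topology_params",
    "TOPOLOGY_IDS",
]

TOPOLOGY_IDS = ("fc2d", "two_by_1d", "scc", "gcc", "pi_kernel",
                "knuft_mln", "k_plus_i_mln", "mln_no_b0")

# formula-only rows (networks out of scope; counts still computable)
FORMULA_IDS = ("automap", "full_transform", "mln_ts_shared_printed")


# ---------------------------------------------------------------------------
# neighbour gathering


@dataclass(frozen=True)
class NeighborTable:
    """Nearest trajectory samples for every Cartesian grid cell.

    ``indices[i, j, :]`` are the sample indices of the ``n_neighbors``
    closest trajectory points to grid location (i, j) (DC-centered coords),
    distances non-decreasing, exact ties broken by lower sample index.
    ``offsets`` are the corresponding k-space displacement vectors.
    """

    indices: np.ndarray
    offsets: np.ndarray
    distances: np.ndarray
    n: int
    n_traj: int

    @property
    def n_neighbors(self) -> int:
        return self.indices.shape[2]


def gather_neighbors(traj: Trajectory, n: int, n_neighbors: int) -> NeighborTable:
    """Euclidean nearest-neighbour table from grid cells to trajectory samples."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if n_neighbors > len(traj):
        raise ValueError("n_neighbors exceeds the number of trajectory samples")
    c = centered_coords(n).astype(float)
    gx, gy = np.meshgrid(c, c, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)  # (n*n, 2)
    coords = traj.coords
    idx = np.empty((n * n, n_neighbors), dtype=np.intp)
    dist = np.empty((n * n, n_neighbors))
    chunk = max(1, int(2e6 // max(len(traj), 1)))
    for s in range(0, n * n, chunk):
        g = grid[s:s + chunk]
        d2 = ((g[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        order = np.argsort(d2, axis=1, kind="stable")[:, :n_neighbors]
        idx[s:s + len(g)] = order
        dist[s:s + len(g)] = np.sqrt(np.take_along_axis(d2, order, axis=1))
    idx = idx.reshape(n, n, n_neighbors)
    dist = dist.reshape(n, n, n_neighbors)
    offs = coords[idx] - np.stack([gx, gy], axis=-1)[:, :, None, :]
    return NeighborTable(idx, offs, dist, n, len(traj))


def assemble_S(signal: np.ndarray, nt: NeighborTable) -> np.ndarray:
    """Gather trajectory data into the tensor ``S[i, j, neighbour, channel]``.

    ``signal`` is (n_traj, n_ch) (or batched ``(..., n_traj, n_ch)``); the
    result has shape ``(..., n, n, n_neighbors, n_ch)``. Pure gather, linear
    in the signal.
    """
    signal = np.asarray(signal)
    if signal.shape[-2] != nt.n_traj:
        raise ValueError("signal length does not match the neighbour table")
    return signal[..., nt.indices, :]


# ---------------------------------------------------------------------------
# the k + I model container


@dataclass
class MLNModel:
    """Trained tensors of a k + I network plus its fixed structure."""

    H: np.ndarray          # [n, n, n_neighbors, n_ch, n_ts]
    M: np.ndarray          # [n, n, n_ts]
    table: NeighborTable
    topology: str = "k_plus_i_mln"

    @property
    def n(self) -> int:
        return self.H.shape[0]

    @property
    def n_ts(self) -> int:
        return self.H.shape[4]

    def n_real_params(self, trainable_m: bool = True) -> int:
        n = 2 * self.H.size
        if trainable_m:
            n += 2 * self.M.size
        return n

    def save(self, path) -> None:
        np.savez(path, H=self.H, M=self.M, indices=self.table.indices,
                 offsets=self.table.offsets, distances=self.table.distances,
                 n=self.table.n, n_traj=self.table.n_traj,
                 topology=self.topology)

    @classmethod
    def load(cls, path) -> "MLNModel":
        d = np.load(path, allow_pickle=False)
        table = NeighborTable(d["indices"], d["offsets"], d["distances"],
                              int(d["n"]), int(d["n_traj"]))
        return cls(d["H"], d["M"], table, str(d["topology"]))


def k_plus_i_apply(S: np.ndarray, model: MLNModel) -> np.ndarray:
    """Reconstruct an image from the gathered tensor S.

    ``K[..., i, j, t] = sum_{n, c} S[..., i, j, n, c] H[i, j, n, c, t]`` and
    ``I_hat = sum_t M[:, :, t] * iFT2{K[..., t]}``. Linear in S.
    """
    S = np.asarray(S, dtype=np.complex128)
    if S.shape[-4:] != model.H.shape[:4]:
        raise ValueError("S shape does not match the model's H tensor")
    k = np.einsum("...ijnc,ijnct->...ijt", S, model.H, optimize=True)
    img_t = _centered_fft(k, axes=(-3, -2), inverse=True)
    return np.einsum("...ijt,ijt->...ij", img_t, model.M, optimize=True)


# ---------------------------------------------------------------------------
# topology construction


@dataclass(frozen=True)
class TopologySpec:
    """Dimensions and sharing options of one network topology."""

    id: str
    n: int
    n_ch: int = 1
    n_ts: int = 1
    n_n: int = 1
    acc: float = 1.0
    n_traj: int = 0
    n_comp: int = 2                 # compressed channels for scc / gcc
    kernel: tuple[int, int] = (3, 3)  # parallel-imaging kernel window
    ts_shared: bool = False         # share H over grid location
    seed: int = 0

    def __post_init__(self):
        if self.id not in TOPOLOGY_IDS + FORMULA_IDS:
            raise ValueError(f"unknown topology id {self.id!r}")
        for name in ("n", "n_ch", "n_ts", "n_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.ts_shared and self.id not in ("k_plus_i_mln",):
            raise ValueError("ts_shared only applies to the k-side tensor of k_plus_i_mln")


def _rand(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    sd = 1.0 / np.sqrt(fan_in)
    return (rng.normal(0, sd, shape) + 1j * rng.normal(0, sd, shape))


def build_topology(spec: TopologySpec, traj: Trajectory | None = None) -> LinearNetwork:
    """Construct the requested network with freshly initialised weights.

    Trajectory-based topologies (``k_plus_i_mln``, ``knuft_mln``,
    ``mln_no_b0``) require ``traj``; Cartesian ones take grid inputs.
    Initialisation is the same fan-in-scaled complex Gaussian used by
    :func:`mlnrecon.sfc.build_sfc`, deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, n_ch = spec.n, spec.n_ch

    if spec.id == "fc2d":
        w = _rand(rng, (n, n, n, n), n * n)
        stages = [EinsumStage("Bkl", "klxy", "Bxy", w, name="fc2d")]
        return LinearNetwork(stages, (n, n), "fc2d")

    if spec.id == "two_by_1d":
        w1 = _rand(rng, (n, n), n)
        w2 = _rand(rng, (n, n), n)
        stages = [
            EinsumStage("Bkl", "kx", "Bxl", w1, name="fc_ro"),
            EinsumStage("Bxl", "ly", "Bxy", w2, name="fc_pe"),
        ]
        return LinearNetwork(stages, (n, n), "two_by_1d")

    if spec.id in ("pi_kernel", "scc", "gcc"):
        stages = []
        ch = n_ch
        if spec.id == "scc":
            wc = _rand(rng, (n_ch, spec.n_comp), n_ch)
            stages.append(EinsumStage("Bklc", "cd", "Bkld", wc, name="scc"))
            ch = spec.n_comp
        elif spec.id == "gcc":
            stages.append(FourierStage(axes=(1,), inverse=True, name="ft_ro"))
            wg = _rand(rng, (n, n_ch, spec.n_comp), n_ch)
            stages.append(EinsumStage("Bxlc", "xcd", "Bxld", wg, name="gcc"))
            stages.append(FourierStage(axes=(1,), inverse=False, name="ift_ro"))
            ch = spec.n_comp
        k1, k2 = spec.kernel
        stages.append(WindowStage(n, (k1, k2)))
        wk = _rand(rng, (k1 * k2, ch), k1 * k2 * ch)
        stages.append(EinsumStage("Bklwc", "wc", "Bkl", wk, name="pi_kernel"))
        stages.append(FourierStage(axes=(1, 2), inverse=True, name="ift2"))
        return LinearNetwork(stages, (n, n, n_ch), spec.id)

    if spec.id in ("k_plus_i_mln", "knuft_mln", "mln_no_b0"):
        if traj is None:
            raise ValueError(f"{spec.id} requires a trajectory")
        table = gather_neighbors(traj, n, spec.n_n)
        stages: list = []
        n_ts = 1 if spec.id == "mln_no_b0" else spec.n_ts
        if spec.id == "knuft_mln" and n_ts > 1:
            # trajectory-side expansion into segments, shared along channels
            w1 = _rand(rng, (len(traj), n_ts), 1)
            stages.append(EinsumStage("Btc", "ts", "Btcs", w1, name="seg_expand"))
            stages.append(GatherStage(table.indices, len(traj), name="regrid"))
            # grid-location-specific collapse, shared along segments
            w2 = _rand(rng, (n, n, spec.n_n, n_ch), spec.n_n * n_ch)
            stages.append(EinsumStage("Bijncs", "ijnc", "Bijs", w2, name="H"))
        else:
            stages.append(GatherStage(table.indices, len(traj), name="regrid"))
            if spec.ts_shared:
                h = _rand(rng, (spec.n_n, n_ch, n_ts), spec.n_n * n_ch)
                stages.append(EinsumStage("Bijnc", "ncs", "Bijs", h, name="H"))
            else:
                h = _rand(rng, (n, n, spec.n_n, n_ch, n_ts), spec.n_n * n_ch)
                stages.append(EinsumStage("Bijnc", "ijncs", "Bijs", h, name="H"))
        stages.append(FourierStage(axes=(1, 2), inverse=True, name="ift2"))
        if spec.id == "mln_no_b0":
            m = np.ones((n, n, 1), dtype=np.complex128)
            stages.append(EinsumStage("Bijs", "ijs", "Bij", m,
                                      trainable=False, name="M_fixed"))
        else:
            m = _rand(rng, (n, n, n_ts), n_ts)
            stages.append(EinsumStage("Bijs", "ijs", "Bij", m, name="M"))
        net = LinearNetwork(stages, (len(traj), n_ch), spec.id)
        net.neighbor_table = table
        net.spec = replace(spec, n_traj=len(traj))
        return net

    raise ValueError(f"unknown or non-buildable topology id {spec.id!r}")


def network_to_model(net: LinearNetwork) -> MLNModel:
    """Extract the (H, M) tensors of a built k+I-family network."""
    if not hasattr(net, "neighbor_table"):
        raise ValueError("network has no neighbour table (not a k+I family net)")
    table = net.neighbor_table
    stages = {s.name: s for s in net.stages}
    h = stages["H"].w
    if h.ndim == 4:            # knuft collapse: fold the segment expansion in
        if net.topology == "knuft_mln" and "seg_expand" in stages:
            w1 = stages["seg_expand"].w          # [n_traj, n_ts]
            h = h[..., None] * w1[table.indices][:, :, :, None, :]
        else:
            h = h[..., None]
    elif h.ndim == 3:          # ts_shared: broadcast over grid locations
        h = np.broadcast_to(h, (table.n, table.n) + h.shape).copy()
    m = stages.get("M", stages.get("M_fixed")).w
    return MLNModel(h, m, table, net.topology)


# ---------------------------------------------------------------------------
# parameter counting


def count_topology_params(spec: TopologySpec) -> int:
    """Real trainable parameter count of a topology (complex weights x 2).

    For buildable topologies this is the summed size of the trainable
    tensors (2 x complex entries); it always matches the built network.
    ``automap`` and ``full_transform`` evaluate the corresponding published
    closed-form counts (with the convolutional constant set to zero) --
    these architectures themselves are out of scope.
    ``mln_ts_shared_printed`` evaluates the published closed-form expression
    for a grid-shared regridding tensor; note that expression is internally
    inconsistent with its tabulated value and is kept for reference only.
    """
    n, n_ch, n_ts, n_n = spec.n, spec.n_ch, spec.n_ts, spec.n_n
    n2, n4 = n * n, n**4
    if spec.id == "fc2d":
        return 2 * n4
    if spec.id == "two_by_1d":
        return 2 * 2 * n2
    if spec.id == "pi_kernel":
        return 2 * spec.kernel[0] * spec.kernel[1] * n_ch
    if spec.id == "scc":
        return 2 * (n_ch * spec.n_comp
                    + spec.kernel[0] * spec.kernel[1] * spec.n_comp)
    if spec.id == "gcc":
        return 2 * (n * n_ch * spec.n_comp
                    + spec.kernel[0] * spec.kernel[1] * spec.n_comp)
    if spec.id == "k_plus_i_mln":
        if spec.ts_shared:
            return 2 * (n_n * n_ch * n_ts + n2 * n_ts)
        return 2 * (n_ch * n_ts * n_n * n2 + n2 * n_ts)
    if spec.id == "mln_no_b0":
        return 2 * n2 * n_ch * n_n
    if spec.id == "knuft_mln":
        expand = spec.n_traj * n_ts if n_ts > 1 else 0
        return 2 * (expand + n2 * n_n * n_ch + n2 * n_ts)
    if spec.id == "automap":
        return int(round(n_ch * n4 / spec.acc + 2 * n4))
    if spec.id == "full_transform":
        return int(round(2 * n_ch * n4 / spec.acc))
    if spec.id == "mln_ts_shared_printed":
        return int(round(2 * n2 * n_ch / spec.acc + 2 * n2 * n_ts * n_n
                         + 2 * n2 * n_ts))
    raise ValueError(f"unknown topology id {spec.id!r}")
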