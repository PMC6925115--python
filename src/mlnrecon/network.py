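"""Composable complex-linear network stages with exact gradients.

Every network in this package is a composition of complex-linear stages
(tensor contractions, gathers, fixed Fourier transforms). Training treats
the real and imaginary parts of each complex weight as independent real
parameters. For a real-valued loss ``L`` we propagate the combined cotangent

    g = dL/d(Re out) + i * dL/d(Im out)

backwards; for a stage ``out = einsum(x, w)`` that is C-linear in both
arguments the exact split-real gradients are

    grad_w = einsum(g, conj(x)),    grad_x = einsum(g, conj(w)),

with subscripts transposed accordingly. Fixed linear stages propagate
``grad_x = A^H g``. These are closed-form expressions, not approximations:
the networks contain no nonlinearities.

All stages operate on arrays with a leading batch axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EinsumStage",
    "GatherStage",
    "WindowStage",
    "FourierStage",
    "LinearNetwork",
]


def _centered_fft(x: np.ndarray, axes: tuple[int, ...], inverse: bool) -> np.ndarray:
    """Unitary DC-centered (i)FFT over the given axes."""
    n = np.prod([x.shape[a] for a in axes])
    y = np.fft.ifftshift(x, axes=axes)
    y = np.fft.ifftn(y, axes=axes) if inverse else np.fft.fftn(y, axes=axes)
    y = np.fft.fftshift(y, axes=axes)
    scale = np.sqrt(n) if inverse else 1.0 / np.sqrt(n)
    return y * scale


class Stage:
    """One complex-linear operation. Subclasses implement forward/backward."""

    trainable: bool = False
    name: str = ""
    w: np.ndarray | None = None

    def forward(self, x: np.ndarray):
        raise NotImplementedError

    def backward(self, g: np.ndarray, cache):
        """Return ``(grad_input, grad_weights_or_None)``."""
        raise NotImplementedError

    @property
    def n_real_params(self) -> int:
        return 2 * self.w.size if self.trainable else 0


class EinsumStage(Stage):
    """``out = einsum(x_sub, w_sub -> y_sub, x, w)`` with trainable ``w``.

    Subscripts must include the batch letter in ``x_sub``/``y_sub``.
    """

    def __init__(self, x_sub: str, w_sub: str, y_sub: str, w: np.ndarray,
                 trainable: bool = True, name: str = ""):
        self.x_sub, self.w_sub, self.y_sub = x_sub, w_sub, y_sub
        self.w = np.asarray(w, dtype=np.complex128)
        self.trainable = trainable
        self.name = name

    def forward(self, x):
        y = np.einsum(f"{self.x_sub},{self.w_sub}->{self.y_sub}", x, self.w,
                      optimize=True)
        return y, x

    def backward(self, g, cache):
        x = cache
        gx = np.einsum(f"{self.y_sub},{self.w_sub}->{self.x_sub}", g,
                       np.conj(self.w), optimize=True)
        gw = None
        if self.trainable:
            gw = np.einsum(f"{self.y_sub},{self.x_sub}->{self.w_sub}", g,
                           np.conj(x), optimize=True)
        return gx, gw


class GatherStage(Stage):
    """Gather along axis 1: ``out[b, *idx.shape, rest] = x[b, idx, rest]``.

    ``idx`` is an integer array of source positions (e.g. the neighbour table
    mapping each Cartesian grid cell to trajectory sample indices). The
    adjoint is scatter-add.
    """

    def __init__(self, idx: np.ndarray, n_src: int, name: str = "gather"):
        self.idx = np.asarray(idx, dtype=np.intp)
        self.n_src = int(n_src)
        if self.idx.size and (self.idx.min() < 0 or self.idx.max() >= n_src):
            raise ValueError("gather index out of range")
        self.name = name

    def forward(self, x):
        return x[:, self.idx], x.shape

    def backward(self, g, cache):
        in_shape = cache
        rest = in_shape[2:]
        gx = np.zeros(in_shape, dtype=np.complex128)
        flat_idx = self.idx.ravel()
        gf = g.reshape(g.shape[0], flat_idx.size, *rest)
        for b in range(g.shape[0]):
            np.add.at(gx[b], flat_idx, gf[b])
        return gx, None


class WindowStage(Stage):
    """Gather a Cartesian K1 x K2 neighbourhood (zero padded at edges).

    ``x[b, i, j, c] -> out[b, i, j, w, c]`` where ``w`` runs over the window
    offsets in row-major order.
    """

    def __init__(self, n: int, kernel: tuple[int, int], name: str = "window"):
        self.n = int(n)
        self.k1, self.k2 = int(kernel[0]), int(kernel[1])
        self.offsets = [(di - self.k1 // 2, dj - self.k2 // 2)
                        for di in range(self.k1) for dj in range(self.k2)]
        self.name = name

    def forward(self, x):
        b, n, _, c = x.shape
        p1, p2 = self.k1 // 2, self.k2 // 2
        xp = np.zeros((b, n + self.k1 - 1, n + self.k2 - 1, c), dtype=x.dtype)
        xp[:, p1:p1 + n, p2:p2 + n] = x
        out = np.empty((b, n, n, len(self.offsets), c), dtype=x.dtype)
        for w, (di, dj) in enumerate(self.offsets):
            out[:, :, :, w] = xp[:, p1 + di:p1 + di + n, p2 + dj:p2 + dj + n]
        return out, x.shape

    def backward(self, g, cache):
        b, n, _, c = cache
        p1, p2 = self.k1 // 2, self.k2 // 2
        gp = np.zeros((b, n + self.k1 - 1, n + self.k2 - 1, c),
                      dtype=np.complex128)
        for w, (di, dj) in enumerate(self.offsets):
            gp[:, p1 + di:p1 + di + n, p2 + dj:p2 + dj + n] += g[:, :, :, w]
        return gp[:, p1:p1 + n, p2:p2 + n], None


class FourierStage(Stage):
    """Fixed unitary DC-centered (i)FFT over the given (batched) axes.

    The adjoint of a unitary transform is its inverse, so the backward pass
    applies the opposite-direction transform.
    """

    def __init__(self, axes: tuple[int, ...], inverse: bool = True,
                 name: str = "fft"):
        self.axes = tuple(axes)
        self.inverse = bool(inverse)
        self.name = name

    def forward(self, x):
        return _centered_fft(x, self.axes, self.inverse), None

    def backward(self, g, cache):
        return _centered_fft(g, self.axes, not self.inverse), None


class LinearNetwork:
    """A sequence of complex-linear stages applied to batched inputs.

    ``input_shape`` excludes the batch axis. The network's end-to-end action
    is multiplication by a fixed complex matrix (given its current weights);
    :meth:`as_matrix` assembles that matrix column by column from unit
    inputs, which serves as the exhaustive oracle in tests.
    """

    def __init__(self, stages: list[Stage], input_shape: tuple[int, ...],
                 topology: str = ""):
        self.stages = stages
        self.input_shape = tuple(int(s) for s in input_shape)
        self.topology = topology

    # -- application ------------------------------------------------------
    def apply(self, x: np.ndarray) -> np.ndarray:
        """Apply to a batched input ``[B, *input_shape]``."""
        y, _ = self.forward(x)
        return y

    def apply_single(self, x: np.ndarray) -> np.ndarray:
        return self.apply(np.asarray(x)[None])[0]

    def forward(self, x: np.ndarray):
        x = np.asarray(x, dtype=np.complex128)
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match {self.input_shape}")
        caches = []
        for st in self.stages:
            x, c = st.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, g: np.ndarray, caches) -> list[np.ndarray]:
        """Propagate an output cotangent; return grads for trainable stages."""
        grads: dict[int, np.ndarray] = {}
        first_trainable = next(
            (i for i, s in enumerate(self.stages) if s.trainable), None)
        for i in range(len(self.stages) - 1, -1, -1):
            st = self.stages[i]
            if st.trainable and i == first_trainable:
                # input gradient below the first trainable stage is unused
                if isinstance(st, EinsumStage):
                    grads[i] = np.einsum(
                        f"{st.y_sub},{st.x_sub}->{st.w_sub}", g,
                        np.conj(caches[i]), optimize=True)
                    break
            g, gw = st.backward(g, caches[i])
            if st.trainable:
                grads[i] = gw
        return [grads[i] for i in sorted(grads)]

    # -- parameters -------------------------------------------------------
    @property
    def trainable_stages(self) -> list[Stage]:
        return [s for s in self.stages if s.trainable]

    @property
    def n_real_params(self) -> int:
        return sum(s.n_real_params for s in self.stages)

    def get_weights(self) -> list[np.ndarray]:
        return [s.w.copy() for s in self.trainable_stages]

    def set_weights(self, ws: list[np.ndarray]) -> None:
        stages = self.trainable_stages
        if len(ws) != len(stages):
            raise ValueError("wrong number of weight arrays")
        for s, w in zip(stages, ws):
            if w.shape != s.w.shape:
                raise ValueError(f"shape mismatch for stage {s.name}")
            s.w = np.asarray(w, dtype=np.complex128)

    # -- oracle -----------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        """Explicit (out_size x in_size) complex matrix of the network."""
        size = int(np.prod(self.input_shape))
        basis = np.eye(size, dtype=np.complex128).reshape(
            (size,) + self.input_shape)
        out = self.apply(basis)
        return out.reshape(size, -1).T

    def save(self, path) -> None:
        arrs = {f"w{i}": s.w for i, s in enumerate(self.trainable_stages)}
        np.savez(path, topology=self.topology,
                 input_shape=np.array(self.input_shape), **arrs)
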