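"""Complex-valued subspace fully-connected (SFC) layers.

The building block of every network in this package is a tensor contraction
with an *axis-dependent* connection topology: each axis of the input tensor
is declared either

* ``fully_connected`` -- all input positions along the axis are linearly
  mixed into all positions of a (possibly resized) output axis, i.e. a matrix
  multiplication along that axis;
* ``shared`` -- the same weights are applied at every position of the axis
  (the axis is broadcast over);
* ``independent`` -- a separate set of weights is used at every position of
  the axis (no mixing across positions).

A plain fully-connected layer is the special case where every axis is
fully connected; a 1D Fourier transform of an image is fully connected on
one axis and shared on the other; GRAPPA-style kernels are fully connected
over (neighbour, channel) and shared or independent over k-space location.
Layers are purely linear on the complex field: no bias terms, no activation
functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "AxisRole",
    "SFCLayerSpec",
    "build_sfc",
    "sfc_apply",
    "param_count",
    "sfc_apply_reference",
]


class AxisRole(str, Enum):
    """Connection role of one tensor axis in an SFC layer."""

    FULLY_CONNECTED = "fully_connected"
    SHARED = "shared"
    INDEPENDENT = "independent"


def _as_role(r: "AxisRole | str") -> AxisRole:
    return AxisRole(r)


@dataclass(frozen=True)
class SFCLayerSpec:
    """Declarative description of one subspace-connected complex linear layer.

    Parameters
    ----------
    input_shape : mapping axis-name -> length, in input axis order.
    axis_roles : mapping axis-name -> :class:`AxisRole` (or its string value).
        Every input axis must be assigned exactly one role and at least one
        axis must be fully connected (otherwise the layer would be a pure
        broadcast and is rejected).
    output_lengths : mapping axis-name -> output length for fully connected
        axes. Fully connected axes not listed keep their input length.
    weight_init : initialisation scheme id (``"gaussian"``).
    seed : seed making the initialisation deterministic.

    The weight tensor has one ``(in_len, out_len)`` axis pair per fully
    connected axis (in input order), followed by one ``in_len`` axis per
    independent axis (in input order); shared axes contribute no weight axis.
    """

    input_shape: Mapping[str, int]
    axis_roles: Mapping[str, "AxisRole | str"]
    output_lengths: Mapping[str, int] = field(default_factory=dict)
    weight_init: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        in_axes = list(self.input_shape)
        if len(set(in_axes)) != len(in_axes):
            raise ValueError("axis names must be unique")
        roles = {a: _as_role(r) for a, r in self.axis_roles.items()}
        if set(roles) != set(in_axes):
            raise ValueError(
                "every input axis needs exactly one role; got roles for "
                f"{sorted(roles)} but axes {in_axes}"
            )
        object.__setattr__(self, "axis_roles", roles)
        fc = [a for a in in_axes if roles[a] is AxisRole.FULLY_CONNECTED]
        if not fc:
            raise ValueError(
                "at least one axis must be fully_connected; a layer with only "
                "shared/independent axes is a pure broadcast"
            )
        for a in self.output_lengths:
            if a not in roles or roles[a] is not AxisRole.FULLY_CONNECTED:
                raise ValueError(
                    f"output length given for non-fully-connected axis {a!r}"
                )
        for a, n in self.input_shape.items():
            if n < 1:
                raise ValueError(f"axis {a!r} has non-positive length {n}")

    # -- derived views ----------------------------------------------------
    @property
    def fc_axes(self) -> list[str]:
        return [a for a in self.input_shape
                if self.axis_roles[a] is AxisRole.FULLY_CONNECTED]

    @property
    def independent_axes(self) -> list[str]:
        return [a for a in self.input_shape
                if self.axis_roles[a] is AxisRole.INDEPENDENT]

    @property
    def shared_axes(self) -> list[str]:
        return [a for a in self.input_shape
                if self.axis_roles[a] is AxisRole.SHARED]

    def out_length(self, axis: str) -> int:
        return int(self.output_lengths.get(axis, self.input_shape[axis]))

    def weight_shape(self) -> tuple[int, ...]:
        shape: list[int] = []
        for a in self.fc_axes:
            shape.append(int(self.input_shape[a]))
            shape.append(self.out_length(a))
        for a in self.independent_axes:
            shape.append(int(self.input_shape[a]))
        return tuple(shape)

    def output_shape(self) -> dict[str, int]:
        """Output axis-name -> length; fully connected axes resized in place."""
        out = {}
        for a, n in self.input_shape.items():
            if self.axis_roles[a] is AxisRole.FULLY_CONNECTED:
                out[a] = self.out_length(a)
            else:
                out[a] = int(n)
        return out

    def fan_in(self) -> int:
        """Product of contracted (fully connected) input lengths."""
        return int(np.prod([self.input_shape[a] for a in self.fc_axes]))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "axes": {a: int(n) for a, n in self.input_shape.items()},
            "roles": {a: self.axis_roles[a].value for a in self.input_shape},
            "out_lengths": {a: int(n) for a, n in self.output_lengths.items()},
            "init": self.weight_init,
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SFCLayerSpec":
        return cls(
            input_shape=dict(d["axes"]),
            axis_roles=dict(d["roles"]),
            output_lengths=dict(d.get("out_lengths", {})),
            weight_init=d.get("init", "gaussian"),
            seed=int(d.get("seed", 0)),
        )


def build_sfc(spec: SFCLayerSpec) -> np.ndarray:
    """Build the complex weight tensor of an SFC layer.

    Initialisation is a complex Gaussian with each real component drawn from
    N(0, 1/fan_in), where fan_in is the product of the contracted (fully
    connected) input axis lengths. This keeps initial layer outputs O(1) for
    O(1) inputs. Deterministic given ``spec.seed``.
    """
    shape = spec.weight_shape()
    if spec.weight_init == "gaussian":
        rng = np.random.default_rng(spec.seed)
        sd = 1.0 / np.sqrt(spec.fan_in())
        w = rng.normal(0.0, sd, shape) + 1j * rng.normal(0.0, sd, shape)
        return w.astype(np.complex128)
    if spec.weight_init == "zeros":
        return np.zeros(shape, dtype=np.complex128)
    raise ValueError(f"unknown weight_init {spec.weight_init!r}")


def param_count(spec: SFCLayerSpec) -> int:
    """Number of trainable real parameters (complex weights count as two)."""
    return 2 * int(np.prod(spec.weight_shape(), dtype=np.int64))


# ---------------------------------------------------------------------------
# application

_LETTERS = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"


def sfc_subscripts(spec: SFCLayerSpec, batch: bool = False) -> tuple[str, str, str]:
    """einsum subscripts (input, weight, output) realizing the contraction."""
    it = iter(_LETTERS)
    in_sub = {a: next(it) for a in spec.input_shape}
    out_sub = dict(in_sub)
    w_parts: list[str] = []
    for a in spec.fc_axes:
        o = next(it)
        w_parts.append(in_sub[a] + o)
        out_sub[a] = o
    for a in spec.independent_axes:
        w_parts.append(in_sub[a])
    b = next(it) if batch else ""
    x_sub = b + "".join(in_sub[a] for a in spec.input_shape)
    y_sub = b + "".join(out_sub[a] for a in spec.input_shape)
    return x_sub, "".join(w_parts), y_sub


def sfc_apply(x: np.ndarray, w: np.ndarray, spec: SFCLayerSpec) -> np.ndarray:
    """Apply an SFC layer to ``x`` (axes in ``spec.input_shape`` order).

    Fully connected axes are replaced (in place) by their output lengths;
    shared and independent axes pass through unchanged. Linear in ``x``.
    """
    expected = tuple(spec.input_shape.values())
    if tuple(x.shape) != expected:
        raise ValueError(f"input shape {x.shape} does not match spec {expected}")
    if tuple(w.shape) != spec.weight_shape():
        raise ValueError(
            f"weight shape {w.shape} does not match spec {spec.weight_shape()}"
        )
    xs, ws, ys = sfc_subscripts(spec)
    return np.einsum(f"{xs},{ws}->{ys}", x, w, optimize=True)


def sfc_apply_reference(x: np.ndarray, w: np.ndarray, spec: SFCLayerSpec) -> np.ndarray:
    """Slow loop-over-all-index-tuples oracle for :func:`sfc_apply`.

    Only intended for tiny tensors; used to validate the einsum path.
    """
    in_axes = list(spec.input_shape)
    out_shape = tuple(spec.output_shape()[a] for a in in_axes)
    y = np.zeros(out_shape, dtype=np.complex128)
    fc, ind = spec.fc_axes, spec.independent_axes

    for out_idx in np.ndindex(out_shape):
        pos = dict(zip(in_axes, out_idx))
        acc = 0.0 + 0.0j
        # sum over all fully connected input positions
        fc_ranges = [range(spec.input_shape[a]) for a in fc]
        for fc_idx in np.ndindex(tuple(len(r) for r in fc_ranges)):
            in_pos = dict(pos)
            for a, i in zip(fc, fc_idx):
                in_pos[a] = i
            w_idx: list[int] = []
            for a in fc:
                w_idx.append(in_pos[a])
                w_idx.append(pos[a])
            for a in ind:
                w_idx.append(pos[a])
            acc += x[tuple(in_pos[a] for a in in_axes)] * w[tuple(w_idx)]
        y[out_idx] = acc
    return y
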