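"""Training of minimal linear networks.

The recipe is deliberately bare: Adam with a fixed learning rate (default
0.002, beta1 = 0.9), an L1 loss on the complex residual, no bias terms, no
regularization, no learning-rate schedule. Complex weights are optimized as
split real parameters (real and imaginary parts are independent real
variables); because every stage is complex-linear, the gradients computed by
:mod:`mlnrecon.network` are exact.

By default the L1 loss is applied component-wise,
``mean(|Re d| + |Im d|)``; a modulus variant ``mean(|d|)`` is available
behind the ``l1_mode`` switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import LinearNetwork

__all__ = ["TrainConfig", "TrainLog", "l1_loss", "train"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.002
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 8
    max_steps: int = 5000
    loss: str = "l1"
    l1_mode: str = "split"          # "split" | "modulus"
    seed: int = 0
    window: int = 200               # convergence window (steps)
    tol: float = 1e-4               # relative change of windowed mean loss
    eval_every: int = 0             # 0 = no held-out snapshots

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss != "l1":
            raise ValueError("only the L1 loss is supported")


@dataclass
class TrainLog:
    losses: np.ndarray
    steps: int
    converged: bool
    eval_steps: list = field(default_factory=list)
    eval_nrmse: list = field(default_factory=list)

    def windowed_loss(self, window: int = 200) -> float:
        """Mean loss over the final window of steps."""
        w = min(window, len(self.losses))
        return float(np.mean(self.losses[-w:]))


def l1_loss(pred: np.ndarray, target: np.ndarray, mode: str = "split"):
    """L1 loss on a complex residual and its cotangent.

    ``split`` mode: ``mean(|Re d| + |Im d|)`` over all entries, the
    component-wise behaviour of standard frameworks on split-real complex
    parameters. ``modulus`` mode: ``mean(|d|)``. Returns ``(loss, g)`` with
    ``g = dL/dRe(pred) + i dL/dIm(pred)``.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    d = pred - target
    size = d.size
    if mode == "split":
        loss = float(np.mean(np.abs(d.real) + np.abs(d.imag)))
        g = (np.sign(d.real) + 1j * np.sign(d.imag)) / size
    elif mode == "modulus":
        mag = np.abs(d)
        loss = float(np.mean(mag))
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(mag > 0, d / np.where(mag > 0, mag, 1.0), 0.0) / size
    else:
        raise ValueError(f"unknown l1 mode {mode!r}")
    return loss, g.astype(np.complex128)


class _Adam:
    """Adam on the split-real (interleaved float) view of complex arrays."""

    def __init__(self, shapes, cfg: TrainConfig):
        self.cfg = cfg
        self.m = [np.zeros(int(np.prod(s)) * 2) for s in shapes]
        self.v = [np.zeros(int(np.prod(s)) * 2) for s in shapes]
        self.t = 0

    def step(self, ws: list[np.ndarray], gs: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1**self.t
        b2t = 1.0 - c.beta2**self.t
        for w, g, m, v in zip(ws, gs, self.m, self.v):
            gr = np.ascontiguousarray(g).view(np.float64).ravel()
            m *= c.beta1
            m += (1 - c.beta1) * gr
            v *= c.beta2
            gr = gr * gr
            gr *= 1 - c.beta2
            v += gr
            denom = np.sqrt(v)
            denom *= 1.0 / np.sqrt(b2t)
            denom += c.eps
            upd = m / denom
            upd *= c.learning_rate / b1t
            w.reshape(-1).view(np.float64).__isub__(upd)


def train(
    network: LinearNetwork,
    signals: np.ndarray,
    images: np.ndarray,
    cfg: TrainConfig | None = None,
    holdout: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainLog:
    """Optimize the network's weights in place on paired (signal, image) data.

    Deterministic given ``cfg.seed`` and the corpus. Stops at ``max_steps``
    or when the relative change between consecutive windowed mean losses
    drops below ``cfg.tol``. Raises on non-finite loss.
    """
    cfg = cfg or TrainConfig()
    signals = np.asarray(signals, dtype=np.complex128)
    images = np.asarray(images, dtype=np.complex128)
    n = signals.shape[0]
    if images.shape[0] != n:
        raise ValueError("signals and images must pair up")
    rng = np.random.default_rng(cfg.seed)

    ws = [s.w for s in network.trainable_stages]
    opt = _Adam([w.shape for w in ws], cfg)
    losses: list[float] = []
    eval_steps: list[int] = []
    eval_nrmse: list[float] = []
    prev_window: float | None = None
    converged = False
    order = rng.permutation(n)
    pos = 0

    for step in range(cfg.max_steps):
        if pos + cfg.batch_size > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos:pos + cfg.batch_size]
        pos += cfg.batch_size
        pred, caches = network.forward(signals[idx])
        loss, g = l1_loss(pred, images[idx], cfg.l1_mode)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at step {step}: {loss!r}; try a lower "
                f"learning rate (current {cfg.learning_rate})")
        losses.append(loss)
        grads = network.backward(g, caches)
        opt.step(ws, grads)

        if cfg.eval_every and holdout is not None and \
                (step + 1) % cfg.eval_every == 0:
            hp = network.apply(holdout[0])
            err = np.linalg.norm(hp - holdout[1]) / np.linalg.norm(holdout[1])
            eval_steps.append(step + 1)
            eval_nrmse.append(float(err))

        if cfg.window and (step + 1) % cfg.window == 0:
            cur = float(np.mean(losses[-cfg.window:]))
            if prev_window is not None:
                rel = abs(cur - prev_window) / max(abs(prev_window), 1e-30)
                if rel < cfg.tol:
                    converged = True
                    break
            prev_window = cur

    return TrainLog(np.asarray(losses), len(losses), converged,
                    eval_steps, eval_nrmse)
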