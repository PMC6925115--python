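"""Scikit-learn style estimator wrapping topology building and training.

``MLNReconstructor`` is a regressor-shaped estimator: ``fit`` takes paired
(signal, ground-truth complex image) arrays, ``predict`` reconstructs images
from new signals. It composes with sklearn model selection utilities via
``get_params`` / ``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .builder import TopologySpec, build_topology, count_topology_params, network_to_model
from .evaluate import nrmse
from .trainer import TrainConfig, train

__all__ = ["MLNReconstructor"]


class MLNReconstructor(BaseEstimator):
    """Trainable minimal linear network for MR image reconstruction.

    Parameters
    ----------
    topology : topology id (see :data:`mlnrecon.builder.TOPOLOGY_IDS`).
    n : matrix size of the reconstructed image.
    n_ch, n_ts, n_n : channels, time segments, gathered neighbours.
    trajectory : :class:`mlnrecon.physics.Trajectory` for trajectory-based
        topologies (taken from a forward model's ``.traj`` for Cartesian
        sampling).
    learning_rate, beta1, batch_size, max_steps, l1_mode, window, tol :
        training recipe, see :class:`mlnrecon.trainer.TrainConfig`.
    seed : controls weight initialisation and batch order.

    Attributes (after fit)
    ----------------------
    network_ : the trained :class:`mlnrecon.network.LinearNetwork`.
    log_ : the :class:`mlnrecon.trainer.TrainLog`.
    n_params_ : number of trainable real parameters.
    """

    def __init__(self, topology="k_plus_i_mln", n=32, n_ch=1, n_ts=1, n_n=6,
                 n_comp=2, kernel=(3, 3), ts_shared=False, trajectory=None,
                 learning_rate=0.002, beta1=0.9, batch_size=8,
                 max_steps=5000, l1_mode="split", window=200, tol=1e-4,
                 seed=0):
        self.topology = topology
        self.n = n
        self.n_ch = n_ch
        self.n_ts = n_ts
        self.n_n = n_n
        self.n_comp = n_comp
        self.kernel = kernel
        self.ts_shared = ts_shared
        self.trajectory = trajectory
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.l1_mode = l1_mode
        self.window = window
        self.tol = tol
        self.seed = seed

    def _spec(self) -> TopologySpec:
        return TopologySpec(
            id=self.topology, n=self.n, n_ch=self.n_ch, n_ts=self.n_ts,
            n_n=self.n_n, n_comp=self.n_comp, kernel=tuple(self.kernel),
            ts_shared=self.ts_shared, seed=self.seed)

    def fit(self, X, y, holdout=None):
        """Train on signals ``X`` and ground-truth complex images ``y``."""
        X = np.asarray(X, dtype=np.complex128)
        y = np.asarray(y, dtype=np.complex128)
        self.network_ = build_topology(self._spec(), traj=self.trajectory)
        cfg = TrainConfig(
            learning_rate=self.learning_rate, beta1=self.beta1,
            batch_size=self.batch_size, max_steps=self.max_steps,
            l1_mode=self.l1_mode, seed=self.seed, window=self.window,
            tol=self.tol, eval_every=200 if holdout is not None else 0)
        self.log_ = train(self.network_, X, y, cfg, holdout=holdout)
        self.n_params_ = self.network_.n_real_params
        return self

    def predict(self, X):
        """Reconstruct images from a batch of signals."""
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        return self.network_.apply(np.asarray(X, dtype=np.complex128))

    def score(self, X, y):
        """Negative mean NRMSE (higher is better)."""
        pred = self.predict(X)
        y = np.asarray(y)
        return -float(np.mean([nrmse(p, t) for p, t in zip(pred, y)]))

    def count_params(self) -> int:
        """Real-parameter count from the topology formulas (pre-fit safe)."""
        spec = self._spec()
        if self.trajectory is not None:
            spec = TopologySpec(**{**spec.__dict__,
                                   "n_traj": len(self.trajectory)})
        return count_topology_params(spec)

    def model_(self):
        """The (H, M) tensor view of a fitted k+I-family network."""
        return network_to_model(self.network_)
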