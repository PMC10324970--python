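"""Strategy 2 back end: stacked-RBM belief network with an ELM output layer.

A stack of restricted Boltzmann machines is pre-trained greedily by one-step
contrastive divergence (CD-1); the last hidden layer's logistic activations
feed an extreme-learning-machine readout whose output weights are the
minimum-norm least-squares solution (Moore-Penrose pseudo-inverse).  An
optional backpropagation pass fine-tunes all layer weights on squared error,
after which the readout is re-solved.  Particle swarm optimization searches
the hidden-layer topology.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "RBM",
    "rbm_cd1_step",
    "pretrain_bbn",
    "elm_solve",
    "BBNELMClassifier",
    "fit_bbn_elm",
    "PSOConfig",
    "pso_minimize",
    "pso_topology_search",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class RBM:
    """Restricted Boltzmann machine parameters.

    ``w`` couples visible to hidden units; ``b_vis`` is the visible bias
    (the paper's *a*/*b*), ``b_hid`` the hidden bias (*c*); ``lr`` the
    CD learning rate epsilon.
    """

    w: np.ndarray       # (n_visible, n_hidden)
    b_vis: np.ndarray   # (n_visible,)
    b_hid: np.ndarray   # (n_hidden,)
    lr: float = 0.1

    @property
    def n_visible(self) -> int:
        return self.w.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w.shape[1]

    @staticmethod
    def initialize(n_visible: int, n_hidden: int, rng: np.random.Generator,
                   lr: float = 0.1, scale: float = 0.01) -> "RBM":
        return RBM(w=scale * rng.standard_normal((n_visible, n_hidden)),
                   b_vis=np.zeros(n_visible), b_hid=np.zeros(n_hidden), lr=lr)

    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        """P(h=1 | v) = sigma(c + W^T v)."""
        return _sigmoid(self.b_hid + v @ self.w)

    def visible_probs(self, h: np.ndarray) -> np.ndarray:
        """P(v=1 | h) = sigma(b_vis + W h)."""
        return _sigmoid(self.b_vis + h @ self.w.T)


def rbm_cd1_step(rbm: RBM, batch: np.ndarray,
                 rng: np.random.Generator) -> RBM:
    """One CD-1 parameter update on a batch of visible vectors in [0, 1].

    Positive-phase statistics use hidden probabilities; the Gibbs
    reconstruction samples the hidden layer and then the visible layer,
    with hidden probabilities recomputed from the sampled reconstruction
    (so the negative-phase statistics are unbiased for the model
    distribution at the data = model fixed point)::

        dW      = eps (<v h>_data - <v' h'>_recon)
        db_vis  = eps (<v> - <v'>)
        db_hid  = eps (<h> - <h'>)
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.min() < 0.0 or batch.max() > 1.0:
        raise ValueError("batch values must lie in [0, 1]")
    n = batch.shape[0]
    ph = rbm.hidden_probs(batch)
    h_sample = (rng.random(ph.shape) < ph).astype(float)
    pv_recon = rbm.visible_probs(h_sample)
    v_recon = (rng.random(pv_recon.shape) < pv_recon).astype(float)
    ph_recon = rbm.hidden_probs(v_recon)
    dw = (batch.T @ ph - v_recon.T @ ph_recon) / n
    dbv = (batch - v_recon).mean(axis=0)
    dbh = (ph - ph_recon).mean(axis=0)
    return replace(rbm, w=rbm.w + rbm.lr * dw,
                   b_vis=rbm.b_vis + rbm.lr * dbv,
                   b_hid=rbm.b_hid + rbm.lr * dbh)


def pretrain_bbn(X: np.ndarray, topology: list[int], epochs: int = 10,
                 lr: float = 0.1, seed: int = 0,
                 batch_size: int = 32) -> list[RBM]:
    """Greedy layer-wise CD-1 pre-training of a belief network.

    ``topology[0]`` is the input dimension; each subsequent entry is a
    hidden-layer width.  Layer L is trained on the hidden probabilities of
    layer L-1.  ``epochs=0`` returns seeded random initializations.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != topology[0]:
        raise ValueError(
            f"topology[0]={topology[0]} does not match input dim {X.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    stack: list[RBM] = []
    layer_in = X
    for layer, (n_vis, n_hid) in enumerate(zip(topology[:-1], topology[1:])):
        rbm = RBM.initialize(n_vis, n_hid, rng, lr=lr)
        n = layer_in.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                batch = layer_in[order[start:start + batch_size]]
                rbm = rbm_cd1_step(rbm, batch, rng)
        stack.append(rbm)
        layer_in = rbm.hidden_probs(layer_in)
    return stack


def elm_solve(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares readout ``beta = H^+ T``."""
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    return np.linalg.pinv(H) @ T


class BBNELMClassifier(BaseEstimator, ClassifierMixin):
    """Belief-network + ELM hybrid classifier.

    Pipeline: min-max scale inputs to [0, 1] -> greedy CD-1 pre-training of
    the RBM stack -> logistic forward pass -> pseudo-inverse readout ->
    optional backprop fine-tuning of the layer weights (squared error on
    one-hot targets, with step-halving to keep the loss non-increasing)
    -> readout re-solved.  Deterministic given ``random_state``.

    Parameters
    ----------
    hidden_layers : tuple of int
        Hidden-layer widths (the searched topology).
    epochs : int
        CD-1 pre-training epochs per layer.
    lr : float
        CD-1 learning rate.
    bp_epochs : int
        Fine-tuning gradient steps (0 disables fine-tuning).
    bp_lr : float
        Fine-tuning learning rate.
    """

    def __init__(self, hidden_layers: tuple = (64, 32), epochs: int = 5,
                 lr: float = 0.1, bp_epochs: int = 20, bp_lr: float = 0.01,
                 random_state: int = 0):
        self.hidden_layers = hidden_layers
        self.epochs = epochs
        self.lr = lr
        self.bp_epochs = bp_epochs
        self.bp_lr = bp_lr
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.scale_span_ > 0, self.scale_span_, 1.0)
        return np.clip((X - self.scale_min_) / span, 0.0, 1.0)

    def _forward(self, X01: np.ndarray) -> list[np.ndarray]:
        acts = [X01]
        for rbm in self.rbm_stack_:
            acts.append(rbm.hidden_probs(acts[-1]))
        return acts

    def _loss(self, H: np.ndarray, T: np.ndarray) -> float:
        return float(np.mean((T - H @ self.beta_) ** 2))

    def _finetune(self, X01: np.ndarray, T: np.ndarray) -> None:
        """Plain gradient descent on squared error through the stack."""
        lr = self.bp_lr
        weights = [(r.w.copy(), r.b_hid.copy()) for r in self.rbm_stack_]
        acts = self._forward(X01)
        loss = self._loss(acts[-1], T)
        for _ in range(self.bp_epochs):
            # backprop through linear readout and logistic layers
            H = acts[-1]
            delta = 2.0 * (H @ self.beta_ - T) @ self.beta_.T / len(T)
            grads = []
            for li in range(len(weights) - 1, -1, -1):
                a_out = acts[li + 1]
                a_in = acts[li]
                dpre = delta * a_out * (1.0 - a_out)
                grads.append((a_in.T @ dpre, dpre.sum(axis=0)))
                delta = dpre @ weights[li][0].T
            grads.reverse()
            new_weights = [(w - lr * gw, b - lr * gb)
                           for (w, b), (gw, gb) in zip(weights, grads)]
            trial_stack = [replace(r, w=w, b_hid=b)
                           for r, (w, b) in zip(self.rbm_stack_, new_weights)]
            trial_acts = [X01]
            for rbm in trial_stack:
                trial_acts.append(rbm.hidden_probs(trial_acts[-1]))
            new_loss = self._loss(trial_acts[-1], T)
            if new_loss <= loss + 1e-12:
                weights, acts, loss = new_weights, trial_acts, new_loss
                self.rbm_stack_ = trial_stack
            else:
                lr *= 0.5  # step too long; keep the loss non-increasing
                if lr < 1e-8:
                    break

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        counts = np.bincount(y_idx)
        if counts.min() < 1:
            raise ValueError("every class needs at least one sample")
        self.scale_min_ = X.min(axis=0)
        self.scale_span_ = X.max(axis=0) - self.scale_min_
        X01 = self._scale(X)
        topology = [X.shape[1], *self.hidden_layers]
        self.rbm_stack_ = pretrain_bbn(X01, topology, epochs=self.epochs,
                                       lr=self.lr, seed=self.random_state)
        T = np.eye(len(self.classes_))[y_idx]
        H = self._forward(X01)[-1]
        self.beta_ = elm_solve(H, T)
        if self.bp_epochs > 0:
            self._finetune(X01, T)
            H = self._forward(X01)[-1]
            self.beta_ = elm_solve(H, T)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "beta_")
        X01 = self._scale(np.asarray(X, dtype=float))
        return self._forward(X01)[-1] @ self.beta_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        check_is_fitted(self, "beta_")
        arrays = {"beta": self.beta_, "classes": self.classes_,
                  "scale_min": self.scale_min_, "scale_span": self.scale_span_}
        for i, rbm in enumerate(self.rbm_stack_):
            arrays[f"w{i}"] = rbm.w
            arrays[f"bv{i}"] = rbm.b_vis
            arrays[f"bh{i}"] = rbm.b_hid
        meta = json.dumps({"n_layers": len(self.rbm_stack_),
                           "params": {k: (list(v) if isinstance(v, tuple) else v)
                                      for k, v in self.get_params().items()}})
        np.savez(path, _meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "BBNELMClassifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        params = meta["params"]
        params["hidden_layers"] = tuple(params["hidden_layers"])
        model = cls(**params)
        model.beta_ = data["beta"]
        model.classes_ = data["classes"]
        model.scale_min_ = data["scale_min"]
        model.scale_span_ = data["scale_span"]
        model.rbm_stack_ = [RBM(w=data[f"w{i}"], b_vis=data[f"bv{i}"],
                                b_hid=data[f"bh{i}"], lr=params["lr"])
                            for i in range(meta["n_layers"])]
        return model


def fit_bbn_elm(X, y, topology=(64, 32), epochs: int = 5, lr: float = 0.1,
                bp_epochs: int = 20, seed: int = 0) -> BBNELMClassifier:
    """Functional wrapper over :class:`BBNELMClassifier`."""
    return BBNELMClassifier(hidden_layers=tuple(topology), epochs=epochs,
                            lr=lr, bp_epochs=bp_epochs,
                            random_state=seed).fit(X, y)


# ---------------------------------------------------------------------------
# Particle swarm optimization
# ---------------------------------------------------------------------------

@dataclass
class PSOConfig:
    """Global-best PSO settings (swarm of 20 by default; the ``paper_pso``
    preset uses a population of 50)."""

    swarm_size: int = 20
    iterations: int = 100
    inertia: float = 0.5
    cognitive_weight: float = 1.0
    social_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def paper_pso(seed: int = 0) -> PSOConfig:
    return PSOConfig(swarm_size=50, iterations=100, inertia=0.5,
                     cognitive_weight=1.0, social_weight=1.0, seed=seed)


def pso_minimize(objective, bounds, cfg: PSOConfig,
                 x0: np.ndarray | None = None):
    """Global-best particle swarm minimization within box bounds.

    ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``; positions are
    clipped to the bounds; non-finite objective values are rejected
    (logged) rather than fatal.  Returns ``(best_x, best_f, trace)`` with
    a monotone non-increasing best-value trace.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    dim = len(lo)
    rng = np.random.default_rng(cfg.seed)
    X = lo + rng.random((cfg.swarm_size, dim)) * (hi - lo)
    if x0 is not None:
        X[0] = np.clip(x0, lo, hi)
    V = (rng.random((cfg.swarm_size, dim)) - 0.5) * (hi - lo) * 0.1

    def safe_eval(x):
        f = objective(x)
        if not np.isfinite(f):
            logger.warning("objective returned non-finite value; rejected")
            return np.inf
        return float(f)

    pbest = X.copy()
    pbest_f = np.array([safe_eval(x) for x in X])
    g_idx = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g_idx].copy(), pbest_f[g_idx]
    trace = [gbest_f]
    for _ in range(cfg.iterations):
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        V = (cfg.inertia * V
             + cfg.cognitive_weight * r1 * (pbest - X)
             + cfg.social_weight * r2 * (gbest - X))
        X = np.clip(X + V, lo, hi)
        for i in range(cfg.swarm_size):
            f = safe_eval(X[i])
            if f < pbest_f[i]:
                pbest[i], pbest_f[i] = X[i].copy(), f
                if f < gbest_f:
                    gbest, gbest_f = X[i].copy(), f
        trace.append(gbest_f)
    return gbest, gbest_f, np.array(trace)


def pso_topology_search(X, y, candidate_widths, depth_range=(1, 2),
                        cfg: PSOConfig | None = None, epochs: int = 5,
                        bp_epochs: int = 10, val_fraction: float = 0.3):
    """Search the belief-network topology by PSO over integer-encoded
    (depth, width-index) coordinates; the objective is validation error of
    the fitted hybrid.  Returns the best model refit on all data plus a log."""
    candidate_widths = sorted(set(int(w) for w in candidate_widths))
    if not candidate_widths:
        raise ValueError("candidate width set is empty")
    cfg = cfg or PSOConfig(swarm_size=6, iterations=8)
    d_lo, d_hi = depth_range
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=val_fraction, stratify=y, random_state=cfg.seed)

    def decode(z) -> tuple[int, ...]:
        depth = int(np.clip(round(z[0]), d_lo, d_hi))
        widths = []
        for i in range(depth):
            idx = int(np.clip(round(z[1 + i]), 0, len(candidate_widths) - 1))
            widths.append(candidate_widths[idx])
        return tuple(widths)

    log: list[tuple[tuple, float]] = []

    def objective(z) -> float:
        topo = decode(z)
        try:
            model = BBNELMClassifier(hidden_layers=topo, epochs=epochs,
                                     bp_epochs=bp_epochs,
                                     random_state=cfg.seed).fit(X_tr, y_tr)
            err = float(np.mean(model.predict(X_val) != y_val))
        except (ValueError, np.linalg.LinAlgError):
            err = np.inf
        log.append((topo, err))
        return err

    bounds = [(d_lo - 0.49, d_hi + 0.49)]
    bounds += [(-0.49, len(candidate_widths) - 0.51)] * d_hi
    best_z, _, _ = pso_minimize(objective, bounds, cfg)
    best_topo = decode(best_z)
    model = BBNELMClassifier(hidden_layers=best_topo, epochs=epochs,
                             bp_epochs=bp_epochs,
                             random_state=cfg.seed).fit(X, y)
    logger.info("topology search selected %s", best_topo)
    return model, best_topo, log
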