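"""Layer-local training of small rate-layer stacks.

Each layer greedily optimizes the combined predictive/Hebbian/
decorrelation objective on its own inputs and outputs; no gradient flows
between layers.  A toy-scale contrastive baseline (cosine similarity with
in-batch negatives) is provided as a sanity anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from lplnet import metrics
from lplnet.rate_lpl import LPLHyperparams, PairedBatch, RateLayer, lpl_weight_update

__all__ = [
    "LayerStack",
    "layer_forward",
    "layerwise_train_step",
    "contrastive_loss",
    "train_network",
    "TrainDiagnostics",
    "train_contrastive_toy",
    "global_average_pool",
]


def global_average_pool(feature_maps: np.ndarray) -> np.ndarray:
    """Reduce (B, C, H, W) feature maps to (B, C) channel averages.

    Applied before the per-layer objective when layers produce spatial
    feature maps; dense layers do not need it.
    """
    fm = np.asarray(feature_maps, dtype=float)
    if fm.ndim != 4:
        raise ValueError("expected (B, C, H, W) feature maps")
    return fm.mean(axis=(2, 3))

ABLATIONS = ("full", "pred_off", "hebb_off", "decorr_off", "shuffled")


class LayerStack:
    """An ordered stack of dense rate layers trained layer-locally."""

    def __init__(
        self,
        layer_sizes: Sequence[int],
        hyper: Optional[LPLHyperparams] = None,
        activation: str = "softplus0",
        seed: int = 0,
    ) -> None:
        if len(layer_sizes) < 2:
            raise ValueError("need at least an input and an output size")
        rng = np.random.default_rng(seed)
        base = hyper if hyper is not None else LPLHyperparams(lambda2=1.0)
        self.layers: List[RateLayer] = []
        for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            hp = LPLHyperparams(
                eta=base.eta,
                lambda1=base.lambda1,
                lambda2=base.lambda2,
                eta_w=base.eta_w,
                epsilon=base.epsilon,
                delta_t=base.delta_t,
            )
            self.layers.append(
                RateLayer(n_in, n_out, hyper=hp, activation=activation, rng=rng)
            )

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def layer_forward(stack: LayerStack, x: np.ndarray) -> List[np.ndarray]:
    """Activities of every layer for a batch of inputs."""
    acts = []
    h = np.atleast_2d(np.asarray(x, dtype=float))
    for layer in stack.layers:
        if h.shape[1] != layer.n_in:
            raise ValueError(
                f"input of size {h.shape[1]} fed to a layer expecting {layer.n_in}"
            )
        h = layer.forward(h)
        acts.append(h)
    return acts


def layerwise_train_step(
    stack: LayerStack,
    batch: PairedBatch,
    include_pred: bool = True,
    apply: bool = True,
) -> List[np.ndarray]:
    """One greedy update of every layer on its own (input, output) pair.

    Layer ``l`` sees the detached activities of layer ``l-1`` for both
    views; updating a deeper layer never changes a shallower layer's
    update.  Returns the per-layer weight updates.
    """
    h_prev = np.atleast_2d(batch.x_prev)
    h_curr = np.atleast_2d(batch.x_curr)
    updates = []
    for layer in stack.layers:
        local = PairedBatch(x_prev=h_prev, x_curr=h_curr)
        dW = lpl_weight_update(layer, local, include_pred=include_pred)
        h_prev = layer.forward(h_prev)  # computed before the update: both
        h_curr = layer.forward(h_curr)  # views propagate through old weights
        if apply:
            layer.W += dW
        updates.append(dW)
    return updates


def contrastive_loss(v_curr: np.ndarray, v_prev: np.ndarray, eps: float = 0.0) -> float:
    """Cosine-similarity contrastive objective with in-batch negatives.

    ``- sum_b sim(v_b, v_prev_b) + sum_b sum_{b' != b} sim(v_b, v_b')``
    with no gradient through ``v_prev``.  Zero-norm vectors are an error.
    """
    v_curr = np.atleast_2d(np.asarray(v_curr, dtype=float))
    v_prev = np.atleast_2d(np.asarray(v_prev, dtype=float))
    if v_curr.shape != v_prev.shape:
        raise ValueError("projection shape mismatch")
    nc = np.linalg.norm(v_curr, axis=1)
    npv = np.linalg.norm(v_prev, axis=1)
    if np.any(nc == 0) or np.any(npv == 0):
        raise ValueError("zero-norm projection vector")
    u = v_curr / nc[:, None]
    w = v_prev / npv[:, None]
    pos = float(np.sum(u * w))
    sim = u @ u.T
    neg = float(sim.sum() - np.trace(sim))
    return -pos + neg


@dataclass
class TrainDiagnostics:
    """Per-layer diagnostics collected after training a stack."""

    ablation: str
    mean_activity: np.ndarray  # (n_layers,) mean |activity| on the probe set
    participation: np.ndarray  # (n_layers,)
    output_reps: np.ndarray  # probe representations at the top layer
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))


def train_network(
    stack: LayerStack,
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    ablation: str = "full",
    n_epochs: int = 20,
    batch_size: int = 128,
    probe: Optional[np.ndarray] = None,
    view_noise: float = 0.0,
    seed: int = 0,
) -> TrainDiagnostics:
    """Train a stack on paired views under one of the ablations.

    ``shuffled`` breaks temporal contingency by re-pairing the previous
    views at random each epoch; ``pred_off`` drops the predictive term;
    ``hebb_off`` / ``decorr_off`` zero the corresponding loss weights.
    ``view_noise`` adds fresh iid Gaussian noise to both views of every
    batch (a minimal paired-view augmentation: the noise is the
    unpredictable nuisance the predictive term has to bridge).  Returns
    per-layer mean activity and participation ratio over the probe set
    (defaults to ``x_curr``).
    """
    if ablation not in ABLATIONS:
        raise ValueError(f"unknown ablation {ablation!r}; choose from {ABLATIONS}")
    rng = np.random.default_rng(seed)
    x_prev = np.atleast_2d(np.asarray(x_prev, dtype=float))
    x_curr = np.atleast_2d(np.asarray(x_curr, dtype=float))
    n = x_curr.shape[0]

    saved = [(ly.hyper.lambda1, ly.hyper.lambda2) for ly in stack.layers]
    try:
        for ly in stack.layers:
            if ablation == "hebb_off":
                ly.hyper.lambda1 = 0.0
            if ablation == "decorr_off":
                ly.hyper.lambda2 = 0.0
        include_pred = ablation != "pred_off"
        for _ in range(n_epochs):
            order = rng.permutation(n)
            pairing = rng.permutation(n) if ablation == "shuffled" else order
            for start in range(0, n - batch_size + 1, batch_size):
                sel = order[start : start + batch_size]
                sel_prev = pairing[start : start + batch_size]
                xp, xc = x_prev[sel_prev], x_curr[sel]
                if view_noise > 0:
                    xp = xp + rng.normal(0.0, view_noise, xp.shape)
                    xc = xc + rng.normal(0.0, view_noise, xc.shape)
                batch = PairedBatch(x_prev=xp, x_curr=xc)
                layerwise_train_step(stack, batch, include_pred=include_pred)
    finally:
        for ly, (l1, l2) in zip(stack.layers, saved):
            ly.hyper.lambda1, ly.hyper.lambda2 = l1, l2

    probe = x_curr if probe is None else np.atleast_2d(np.asarray(probe, dtype=float))
    acts = layer_forward(stack, probe)
    return TrainDiagnostics(
        ablation=ablation,
        mean_activity=np.array([float(np.mean(np.abs(a))) for a in acts]),
        participation=np.array([metrics.participation_ratio(a) for a in acts]),
        output_reps=acts[-1],
    )


def train_contrastive_toy(
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    n_out: int = 8,
    eta: float = 0.05,
    n_epochs: int = 20,
    batch_size: int = 64,
    seed: int = 0,
) -> np.ndarray:
    """Train a single linear projection with the contrastive loss (toy scale).

    Gradients of the cosine-similarity objective are computed in closed
    form; serves as the negative-sample baseline sanity anchor, not a
    benchmark.  Returns the learned projection matrix (n_out x N).
    """
    rng = np.random.default_rng(seed)
    x_prev = np.atleast_2d(np.asarray(x_prev, dtype=float))
    x_curr = np.atleast_2d(np.asarray(x_curr, dtype=float))
    n, d = x_curr.shape
    W = rng.normal(0.0, 1.0 / np.sqrt(d), size=(n_out, d))

    def cos_grad(u_raw: np.ndarray, v_raw: np.ndarray) -> np.ndarray:
        # d sim(u, v) / d u with v constant
        nu = np.linalg.norm(u_raw)
        nv = np.linalg.norm(v_raw)
        s = float(u_raw @ v_raw) / (nu * nv)
        return v_raw / (nu * nv) - s * u_raw / nu**2

    for _ in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n - batch_size + 1, batch_size):
            sel = order[start : start + batch_size]
            xc, xp = x_curr[sel], x_prev[sel]
            v = xc @ W.T  # (B, n_out)
            vp = xp @ W.T
            B = len(sel)
            gv = np.zeros_like(v)
            for b in range(B):
                gv[b] -= cos_grad(v[b], vp[b])
                for b2 in range(B):
                    if b2 == b:
                        continue
                    # v_b enters sim(v_b, v_b2) and sim(v_b2, v_b); the
                    # cosine is symmetric, so both contribute the same grad
                    gv[b] += 2.0 * cos_grad(v[b], v[b2])
            W -= (eta / B) * gv.T @ xc
    return W
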