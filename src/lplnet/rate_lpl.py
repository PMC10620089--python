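"""Rate-based latent-predictive plasticity.

The learning rule for a layer of rate neurons combines three objective
components evaluated on mini-batches of consecutive input pairs:

* a predictive loss, the mean squared difference between the activity
  evoked by the current input and the (gradient-detached) activity evoked
  by the previous input,
* a Hebbian loss, the negative log variance of each neuron's activity,
  whose gradient yields a BCM-like rule with the running mean acting as a
  plasticity threshold and the variance modulating its strength,
* a decorrelation loss penalizing products of squared deviations between
  different neurons in the same layer.

All weight updates are available in closed form (no autodiff); the closed
form is the exact negative gradient of the combined objective under the
stop-gradient conventions spelled out in the docstrings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "LPLHyperparams",
    "PairedBatch",
    "RateLayer",
    "predictive_loss",
    "hebbian_loss",
    "decorrelation_loss",
    "lpl_weight_update",
    "update_moments",
    "sliding_threshold",
    "lpl_rule_form1",
    "lpl_rule_form2",
    "oja_update",
    "train_single_neuron",
    "SingleNeuronResult",
    "get_activation",
]

_LOG2 = math.log(2.0)


def _softplus0(a: np.ndarray) -> np.ndarray:
    # softplus shifted so that f(0) = 0; smooth rectifier with f' = sigmoid
    return np.logaddexp(0.0, a) - _LOG2


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "linear": (lambda a: np.asarray(a, dtype=float), lambda a: np.ones_like(a, dtype=float)),
    "softplus0": (_softplus0, lambda a: expit(a)),
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2),
}


def get_activation(name: str) -> tuple[Callable, Callable]:
    """Return ``(f, f')`` for a named monotonic activation."""
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


@dataclass
class LPLHyperparams:
    """Hyperparameters of the rate-based rule.

    ``lambda1`` scales the Hebbian component, ``lambda2`` the
    decorrelation component, ``eta_w`` the weight decay.  ``epsilon`` is
    the variance floor added inside the log and in denominators.
    ``delta_t`` is the prediction horizon in discrete steps (only the
    one-step horizon is exercised here; the constant is absorbed into the
    learning rate).
    """

    eta: float = 0.05
    lambda1: float = 1.0
    lambda2: float = 0.0
    eta_w: float = 0.0
    epsilon: float = 1e-6
    delta_t: int = 1

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if min(self.lambda1, self.lambda2, self.eta_w) < 0:
            raise ValueError("lambda1, lambda2 and eta_w must be >= 0")


@dataclass
class PairedBatch:
    """A mini-batch of consecutive input pairs ``(x(t - dt), x(t))``."""

    x_prev: np.ndarray  # (B, N)
    x_curr: np.ndarray  # (B, N)
    labels_prev: Optional[np.ndarray] = None
    labels_curr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x_prev = np.atleast_2d(np.asarray(self.x_prev, dtype=float))
        self.x_curr = np.atleast_2d(np.asarray(self.x_curr, dtype=float))
        if self.x_prev.shape != self.x_curr.shape:
            raise ValueError(
                f"shape mismatch: x_prev {self.x_prev.shape} vs x_curr {self.x_curr.shape}"
            )

    @property
    def batch_size(self) -> int:
        return self.x_curr.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.x_curr.shape[1]


class RateLayer:
    """A layer of rate neurons with running output moments.

    Holds the weight matrix ``W`` (M x N), a monotonic activation and the
    per-neuron running mean / variance estimates that enter the Hebbian
    component.  ``moment_mode`` selects how the moments are refreshed:
    ``"batch"`` (current batch), ``"stale"`` (previous batch) or
    ``"exponential"`` (leaky average with time constant ``moment_tau``
    measured in batches).
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        hyper: Optional[LPLHyperparams] = None,
        activation: str = "linear",
        moment_mode: str = "batch",
        moment_tau: float = 50.0,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        if moment_mode not in ("batch", "stale", "exponential"):
            raise ValueError(f"unknown moment mode {moment_mode!r}")
        rng = np.random.default_rng() if rng is None else rng
        self.n_in = int(n_in)
        self.n_out = int(n_out)
        self.hyper = hyper if hyper is not None else LPLHyperparams()
        self.activation = activation
        self.f, self.fprime = get_activation(activation)
        self.moment_mode = moment_mode
        self.moment_tau = float(moment_tau)
        # zero-mean Gaussian init, std 1/sqrt(N): scale-free starting point
        self.W = rng.normal(0.0, 1.0 / math.sqrt(n_in), size=(n_out, n_in))
        self.z_bar = np.zeros(n_out)
        self.sigma2 = np.ones(n_out)
        self._pending: Optional[tuple[np.ndarray, np.ndarray]] = None

    def pre_activation(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.W.T

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.f(self.pre_activation(x))


def predictive_loss(z_curr: np.ndarray, z_prev: np.ndarray) -> float:
    """Mean squared difference between consecutive activities.

    ``z_prev`` is treated as a constant (no gradient flows through it).
    Returns ``(1 / 2MB) * sum_b ||z_curr^b - z_prev^b||^2``.
    """
    z_curr = np.atleast_2d(z_curr)
    z_prev = np.atleast_2d(z_prev)
    if z_curr.shape != z_prev.shape:
        raise ValueError(f"shape mismatch: {z_curr.shape} vs {z_prev.shape}")
    B, M = z_curr.shape
    return float(np.sum((z_curr - z_prev) ** 2) / (2.0 * M * B))


def _batch_moments(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z_bar = z.mean(axis=0)
    sigma2 = np.sum((z - z_bar) ** 2, axis=0) / (z.shape[0] - 1)
    return z_bar, sigma2


def hebbian_loss(z_curr: np.ndarray, epsilon: float = 0.0) -> float:
    """Negative log variance of activity, averaged over neurons.

    The variance is the (B-1)-normalized sample variance; the mean is
    treated as a constant for gradient purposes (its contribution cancels
    exactly for this loss).
    """
    z_curr = np.atleast_2d(z_curr)
    if z_curr.shape[0] < 2:
        raise ValueError("hebbian_loss requires a batch of at least 2 samples")
    _, sigma2 = _batch_moments(z_curr)
    return float(np.mean(-np.log(sigma2 + epsilon)))


def decorrelation_loss(z_curr: np.ndarray, variant: str = "printed") -> float:
    """Decorrelation penalty between neurons of one layer.

    ``variant="printed"`` implements the sum over ordered pairs ``k != i``
    of products of squared deviations, normalized by ``(B-1)(M^2 - M)``.
    ``variant="covariance"`` instead sums the squared off-diagonal entries
    of the sample covariance matrix (normalized by ``M^2 - M``); it is the
    verbal reading of the same objective and kept behind this flag.
    Returns 0 for a single neuron by convention.
    """
    z_curr = np.atleast_2d(z_curr)
    B, M = z_curr.shape
    if M < 2:
        return 0.0
    d = z_curr - z_curr.mean(axis=0)
    if variant == "printed":
        sq = d**2  # (B, M)
        tot = sq.sum(axis=1)  # (B,)
        # sum over ordered pairs k != i of sq_i * sq_k
        cross = np.sum(sq * (tot[:, None] - sq))
        return float(cross / ((B - 1) * (M**2 - M)))
    if variant == "covariance":
        C = d.T @ d / (B - 1)
        off = C - np.diag(np.diag(C))
        return float(np.sum(off**2) / (M**2 - M))
    raise ValueError(f"unknown decorrelation variant {variant!r}")


def update_moments(layer: RateLayer, z_curr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Refresh the layer's running mean/variance from a batch of activities.

    Returns the ``(z_bar, sigma2)`` pair the *next* weight update should
    use, according to the layer's ``moment_mode``.
    """
    z_curr = np.atleast_2d(z_curr)
    mode = layer.moment_mode
    if mode == "batch":
        layer.z_bar, layer.sigma2 = _batch_moments(z_curr)
    elif mode == "stale":
        if layer._pending is not None:
            layer.z_bar, layer.sigma2 = layer._pending
        layer._pending = _batch_moments(z_curr)
    elif mode == "exponential":
        rho = 1.0 / layer.moment_tau
        z_bar, sigma2 = _batch_moments(z_curr)
        layer.z_bar = (1 - rho) * layer.z_bar + rho * z_bar
        layer.sigma2 = (1 - rho) * layer.sigma2 + rho * sigma2
    else:  # pragma: no cover - guarded in __init__
        raise ValueError(f"unknown moment mode {mode!r}")
    return layer.z_bar, layer.sigma2


def lpl_weight_update(
    layer: RateLayer,
    batch: PairedBatch,
    include_pred: bool = True,
    var_modulation: bool = True,
    refresh_moments: bool = True,
) -> np.ndarray:
    """Closed-form weight update for one paired mini-batch.

    Equals ``-eta * grad_W(L_pred + l1 * L_Hebb + l2 * L_decorr)
    - eta * eta_w * W`` with stop-gradients through the previous-step
    activity, the mean estimate and the variance estimate.

    ``include_pred=False`` drops the predictive component (purely Hebbian
    learning) and ``var_modulation=False`` replaces the variance estimate
    by 1 in the Hebbian denominator (ablation of metaplasticity).  The
    update is returned; the caller applies it.
    """
    hp = layer.hyper
    B = batch.batch_size
    M = layer.n_out
    if B < 2 and refresh_moments and layer.moment_mode == "batch":
        raise ValueError("batch moment estimation needs B >= 2")
    a_curr = layer.pre_activation(batch.x_curr)
    z_curr = layer.f(a_curr)
    z_prev = layer.f(layer.pre_activation(batch.x_prev))  # stop-grad
    if refresh_moments:
        update_moments(layer, z_curr)
    z_bar, sigma2 = layer.z_bar, layer.sigma2

    err = np.zeros_like(z_curr)
    if include_pred:
        err -= z_curr - z_prev
    dev = z_curr - z_bar
    if hp.lambda1 > 0:
        alpha = 2.0 * B / (B - 1) if B > 1 else 2.0
        denom = (sigma2 + hp.epsilon) if var_modulation else 1.0
        err += hp.lambda1 * alpha * dev / denom
    if hp.lambda2 > 0 and M >= 2:
        beta = 4.0 * M * B / ((B - 1) * (M**2 - M))
        sq = dev**2
        err -= hp.lambda2 * beta * dev * (sq.sum(axis=1, keepdims=True) - sq)

    g = err * layer.fprime(a_curr)  # (B, M)
    dW = (hp.eta / (M * B)) * (g.T @ batch.x_curr)
    dW -= hp.eta * hp.eta_w * layer.W
    return dW


def sliding_threshold(
    z_bar: np.ndarray | float,
    sigma2: np.ndarray | float,
    dz_dt: np.ndarray | float,
    lam: float = 1.0,
) -> np.ndarray | float:
    """BCM-style sliding threshold ``Theta = z_bar + (sigma2/lam) dz/dt``."""
    if lam == 0:
        raise ValueError("lam must be nonzero")
    return z_bar + (np.asarray(sigma2) / lam) * dz_dt


def lpl_rule_form1(x, fprime_a, dz_dt, z, z_bar, sigma2, eta=1.0, lam=1.0):
    """Continuous-time rule: eta * x * f'(a) * (-dz/dt + lam/sigma2 (z - z_bar))."""
    return eta * x * fprime_a * (-np.asarray(dz_dt) + (lam / np.asarray(sigma2)) * (z - z_bar))


def lpl_rule_form2(x, fprime_a, dz_dt, z, z_bar, sigma2, eta=1.0, lam=1.0):
    """Sliding-threshold form: eta*lam*x*f'(a)/sigma2 * (z - Theta).

    Algebraically identical to :func:`lpl_rule_form1` for all states.
    """
    theta = sliding_threshold(z_bar, sigma2, dz_dt, lam)
    return eta * lam * x * fprime_a / np.asarray(sigma2) * (z - theta)


def oja_update(w: np.ndarray, x: np.ndarray, eta: float = 0.05) -> np.ndarray:
    """Oja's rule ``dw = eta * z (x - z w)`` with ``z = w.x``, batch-averaged."""
    x = np.atleast_2d(x)
    z = x @ w  # (B,)
    dw = eta * (z[:, None] * (x - z[:, None] * w)).mean(axis=0)
    return dw


@dataclass
class SingleNeuronResult:
    """Trajectories from single-neuron training on the 2D cluster task."""

    rule: str
    weights: np.ndarray  # (n_records, N)
    mean_abs_activity: np.ndarray  # (n_records,)
    activity_variance: np.ndarray  # (n_records,)
    record_steps: np.ndarray
    final_w: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.final_w = self.weights[-1]


_SINGLE_NEURON_RULES = ("lpl", "pred_off", "hebb_off", "no_var_modulation", "oja")


def train_single_neuron(
    config,
    rule: str = "lpl",
    hyper: Optional[LPLHyperparams] = None,
    n_steps: int = 2000,
    batch_size: int = 256,
    seed: int = 0,
    record_every: int = 20,
) -> SingleNeuronResult:
    """Train a single linear neuron on the paired 2D cluster sequence.

    ``config`` is a :class:`lplnet.synthetic_data.ClusterSequenceConfig`;
    a fresh batch of pairs is drawn at every step.  ``rule`` selects the
    full rule or one of its ablations (or Oja's rule as the classic
    Hebbian baseline).
    """
    from lplnet.synthetic_data import gen_cluster_pairs

    if rule not in _SINGLE_NEURON_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {_SINGLE_NEURON_RULES}")
    hyper = hyper if hyper is not None else LPLHyperparams()
    rng = np.random.default_rng(seed)
    layer = RateLayer(2, 1, hyper=hyper, activation="linear", rng=rng)

    weights, m_act, v_act, steps = [], [], [], []
    for step in range(n_steps):
        batch = gen_cluster_pairs(
            config, n_pairs=batch_size, rng=np.random.default_rng(rng.integers(2**63))
        )
        if rule == "oja":
            layer.W[0] += oja_update(layer.W[0], batch.x_curr, eta=hyper.eta)
            z = layer.forward(batch.x_curr)
        else:
            include_pred = rule != "pred_off"
            if rule == "hebb_off":
                saved = hyper.lambda1
                hyper.lambda1 = 0.0
                try:
                    dW = lpl_weight_update(layer, batch, include_pred=True)
                finally:
                    hyper.lambda1 = saved
            else:
                dW = lpl_weight_update(
                    layer,
                    batch,
                    include_pred=include_pred,
                    var_modulation=rule != "no_var_modulation",
                )
            layer.W += dW
            z = layer.forward(batch.x_curr)
        if step % record_every == 0 or step == n_steps - 1:
            weights.append(layer.W[0].copy())
            m_act.append(float(np.mean(np.abs(z))))
            v_act.append(float(np.var(z)))
            steps.append(step)
    return SingleNeuronResult(
        rule=rule,
        weights=np.array(weights),
        mean_abs_activity=np.array(m_act),
        activity_variance=np.array(v_act),
        record_steps=np.array(steps),
    )
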