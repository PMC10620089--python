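"""Conductance-based LIF network with spiking predictive plasticity.

Fixed-step (0.1 ms) forward-Euler simulator of excitatory/inhibitory
populations with dynamic spike thresholds and axonal delay.  Input-to-
excitatory synapses follow the spiking form of the predictive/Hebbian
rule (eligibility traces from a surrogate voltage derivative, online
moment estimates); inhibitory-to-excitatory synapses follow a rate-target
inhibitory STDP rule.

Units: membrane quantities in mV, time constants of the neuron model in
ms, plasticity trace amplitudes in Hz (spike trains enter as delta
functions of weight 1/dt), conductances in units of the leak conductance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from lplnet.synthetic_data import (
    SlowSignalConfig,
    SpikeRaster,
    gen_slow_signal,
    make_shuffled_control,
)

__all__ = [
    "LIFParams",
    "NetworkTopology",
    "SpikingLPLParams",
    "InhSTDPParams",
    "LIFPopulation",
    "LIFNetworkState",
    "build_network",
    "integrate_step",
    "double_exp_filter",
    "DoubleExpTrace",
    "SpikingLPL",
    "InhSTDP",
    "SNNConfig",
    "SNNResult",
    "make_input_rate_traces",
    "run_simulation",
    "mean_afferent_weights",
]

ABLATIONS = ("full", "pred_off", "hebb_off", "inhib_off", "inhib_fixed")


@dataclass
class LIFParams:
    """Conductance-based LIF neuron constants (ms / mV)."""

    tau_mem: float = 20.0
    tau_ampa: float = 5.0
    tau_nmda: float = 100.0
    tau_gaba: float = 10.0
    tau_thr: float = 5.0
    U_leak: float = -70.0
    U_exc: float = 0.0
    U_inh: float = -80.0
    theta_rest: float = -50.0
    delta_theta: float = 100.0
    axonal_delay: float = 0.8
    dt: float = 0.1

    def __post_init__(self) -> None:
        taus = (self.tau_mem, self.tau_ampa, self.tau_nmda, self.tau_gaba, self.tau_thr)
        if min(taus) <= 0:
            raise ValueError("all time constants must be > 0")
        if self.dt >= min(taus):
            raise ValueError("dt must be smaller than the smallest time constant")

    @property
    def delay_steps(self) -> int:
        return max(1, int(round(self.axonal_delay / self.dt)))


@dataclass
class NetworkTopology:
    """Population sizes and pathway connectivity.

    Weights are nonnegative magnitudes within each pathway; the sign of a
    pathway enters through the synaptic reversal potential.  The
    excitatory-to-inhibitory pathway uses a Gaussian connection-
    probability profile ``exp(-(j - c * i)^2 / sigma2_ei)`` mapping the
    excitatory index ``i`` topographically onto the inhibitory index
    ``j``; ``ei_slope=None`` defaults to ``n_inh / n_exc`` (0.25 at the
    full size).
    """

    n_input: int = 500
    n_exc: int = 100
    n_inh: int = 25
    p_in_e: float = 0.5
    w_in_e: float = 0.2
    p_in_i: float = 0.35
    w_in_i: float = 0.2
    p_ie: float = 0.6
    w_ie: float = 0.3
    p_ii: float = 0.3
    w_ii: float = 0.3
    p_ee: float = 0.0
    w_ee: float = 0.0
    w_ei: float = 0.6
    ei_slope: Optional[float] = None
    sigma2_ei: float = 20.0

    def __post_init__(self) -> None:
        for p in (self.p_in_e, self.p_in_i, self.p_ie, self.p_ii, self.p_ee):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must be in [0, 1]")
        if min(self.w_in_e, self.w_in_i, self.w_ie, self.w_ii, self.w_ee, self.w_ei) < 0:
            raise ValueError("weight magnitudes must be >= 0")

    @property
    def ei_c_slope(self) -> float:
        return self.n_inh / self.n_exc if self.ei_slope is None else self.ei_slope


@dataclass
class SpikingLPLParams:
    """Constants of the spiking predictive/Hebbian rule."""

    eta: float = 1e-2
    xi: float = 1e-3
    delta: float = 1e-5
    lam: float = 1.0
    beta_surrogate: float = 1.0  # 1/mV
    pred_delay: float = 0.020  # s
    tau_mean: float = 600.0  # s
    tau_var: float = 20.0  # s
    tau_alpha_rise: float = 0.002
    tau_alpha_fall: float = 0.010
    tau_eps_rise: float = 0.005
    tau_eps_fall: float = 0.020
    # rate-estimate kernel feeding the slow moments (desk choice, see notes)
    tau_rate_rise: float = 0.010
    tau_rate_fall: float = 0.100
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        pos = (
            self.eta, self.xi, self.beta_surrogate, self.pred_delay,
            self.tau_mean, self.tau_var, self.tau_alpha_rise, self.tau_alpha_fall,
            self.tau_eps_rise, self.tau_eps_fall, self.tau_rate_rise, self.tau_rate_fall,
        )
        if min(pos) <= 0 or self.delta < 0:
            raise ValueError("spiking rule constants must be positive")


@dataclass
class InhSTDPParams:
    """Rate-target inhibitory STDP constants."""

    tau_stdp: float = 0.020  # s
    zeta: float = 1e-3
    kappa: float = 10.0  # Hz target rate
    w_min: float = 0.0
    w_max: float = 5.0
    literal_form: bool = False  # printed "+2*kappa*tau" variant (no fixed point)

    def __post_init__(self) -> None:
        if min(self.tau_stdp, self.zeta, self.kappa) <= 0:
            raise ValueError("inhibitory STDP constants must be positive")


# ---------------------------------------------------------------------------
# neuron populations and network state
# ---------------------------------------------------------------------------


class LIFPopulation:
    """State arrays of one population of conductance-based LIF neurons."""

    def __init__(self, n: int, params: LIFParams) -> None:
        self.n = n
        self.p = params
        self.U = np.full(n, params.U_leak)
        self.theta = np.full(n, params.theta_rest)
        self.g_ampa = np.zeros(n)
        self.g_nmda = np.zeros(n)
        self.g_gaba = np.zeros(n)

    def step(self, exc_jump: Optional[np.ndarray], inh_jump: Optional[np.ndarray]) -> np.ndarray:
        """One forward-Euler step; returns the boolean spike vector."""
        p = self.p
        dt = p.dt
        self.g_ampa += dt * (-self.g_ampa / p.tau_ampa)
        if exc_jump is not None:
            self.g_ampa += exc_jump
        self.g_nmda += (dt / p.tau_nmda) * (self.g_ampa - self.g_nmda)
        self.g_gaba += dt * (-self.g_gaba / p.tau_gaba)
        if inh_jump is not None:
            self.g_gaba += inh_jump
        g_exc = 0.5 * (self.g_ampa + self.g_nmda)
        self.U += (dt / p.tau_mem) * (
            (p.U_leak - self.U)
            + g_exc * (p.U_exc - self.U)
            + self.g_gaba * (p.U_inh - self.U)
        )
        if not np.all(np.isfinite(self.U)):
            bad = int(np.flatnonzero(~np.isfinite(self.U))[0])
            raise FloatingPointError(f"non-finite membrane potential in neuron {bad}")
        self.theta += (dt / p.tau_thr) * (p.theta_rest - self.theta)
        spikes = self.U >= self.theta
        if np.any(spikes):
            self.theta[spikes] += p.delta_theta
        return spikes


def _sparse_mask(rng: np.random.Generator, shape, p: float, no_diag: bool = False) -> np.ndarray:
    m = rng.random(shape) < p
    if no_diag and shape[0] == shape[1]:
        np.fill_diagonal(m, False)
    return m


@dataclass
class LIFNetworkState:
    """Weights, masks, population states and the axonal delay queue."""

    params: LIFParams
    topology: NetworkTopology
    exc: LIFPopulation
    inh: LIFPopulation
    W: Dict[str, np.ndarray]  # pathway name -> weight matrix
    mask: Dict[str, np.ndarray]
    _queue: List[Dict[str, np.ndarray]] = field(default_factory=list)
    _qpos: int = 0
    t: float = 0.0

    def __post_init__(self) -> None:
        d = self.params.delay_steps
        empty_in = np.empty(0, dtype=np.int64)
        self._queue = [
            {"in": empty_in, "e": empty_in, "i": empty_in} for _ in range(d)
        ]

    def push_delayed(self, in_idx: np.ndarray, e_idx: np.ndarray, i_idx: np.ndarray) -> None:
        self._queue[self._qpos] = {"in": in_idx, "e": e_idx, "i": i_idx}
        self._qpos = (self._qpos + 1) % len(self._queue)

    def pop_delayed(self) -> Dict[str, np.ndarray]:
        return self._queue[self._qpos]


def build_network(
    topology: NetworkTopology,
    seed: int = 0,
    params: Optional[LIFParams] = None,
) -> LIFNetworkState:
    """Instantiate sparse random connectivity and initial weights.

    All pathways are Bernoulli-sparse except excitatory-to-inhibitory,
    which follows the Gaussian probability profile.  No self-connections
    within a population.
    """
    params = LIFParams() if params is None else params
    rng = np.random.default_rng(seed)
    top = topology
    masks = {
        "in_e": _sparse_mask(rng, (top.n_exc, top.n_input), top.p_in_e),
        "in_i": _sparse_mask(rng, (top.n_inh, top.n_input), top.p_in_i),
        "ie": _sparse_mask(rng, (top.n_exc, top.n_inh), top.p_ie),
        "ii": _sparse_mask(rng, (top.n_inh, top.n_inh), top.p_ii, no_diag=True),
        "ee": _sparse_mask(rng, (top.n_exc, top.n_exc), top.p_ee, no_diag=True),
    }
    # Gaussian profile: pre index i (excitatory) maps to post index j (inhibitory)
    j = np.arange(top.n_inh)[:, None]
    i = np.arange(top.n_exc)[None, :]
    p_ei = np.exp(-((j - top.ei_c_slope * i) ** 2) / top.sigma2_ei)
    masks["ei"] = rng.random((top.n_inh, top.n_exc)) < p_ei

    W = {
        "in_e": masks["in_e"] * top.w_in_e,
        "in_i": masks["in_i"] * top.w_in_i,
        "ie": masks["ie"] * top.w_ie,
        "ii": masks["ii"] * top.w_ii,
        "ee": masks["ee"] * top.w_ee,
        "ei": masks["ei"] * top.w_ei,
    }
    return LIFNetworkState(
        params=params,
        topology=topology,
        exc=LIFPopulation(top.n_exc, params),
        inh=LIFPopulation(top.n_inh, params),
        W=W,
        mask=masks,
    )


def _gather(Wmat: np.ndarray, idx: np.ndarray) -> Optional[np.ndarray]:
    if idx.size == 0:
        return None
    if idx.size == 1:
        return Wmat[:, idx[0]].copy()
    return Wmat[:, idx].sum(axis=1)


def integrate_step(
    state: LIFNetworkState, input_spike_idx: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray]]:
    """Advance the network by one time step.

    ``input_spike_idx`` are indices of input neurons spiking *now*; all
    spikes (input and recurrent) act on postsynaptic conductances only
    after the axonal delay.  Returns ``(e_spikes, i_spikes, delivered)``
    where ``delivered`` holds the presynaptic spike indices that arrived
    at the synapses during this step (useful for plasticity).
    """
    delivered = state.pop_delayed()
    exc_e = _sum_jumps(state, ("in_e", "ee"), (delivered["in"], delivered["e"]))
    inh_e = _gather(state.W["ie"], delivered["i"])
    exc_i = _sum_jumps(state, ("in_i", "ei"), (delivered["in"], delivered["e"]))
    inh_i = _gather(state.W["ii"], delivered["i"])

    e_spk = state.exc.step(exc_e, inh_e)
    i_spk = state.inh.step(exc_i, inh_i)
    state.push_delayed(
        np.asarray(input_spike_idx, dtype=np.int64),
        np.flatnonzero(e_spk),
        np.flatnonzero(i_spk),
    )
    state.t += state.params.dt
    return e_spk, i_spk, delivered


def _sum_jumps(state, pathways, idx_list) -> Optional[np.ndarray]:
    total = None
    for path, idx in zip(pathways, idx_list):
        j = _gather(state.W[path], idx)
        if j is not None:
            total = j if total is None else total + j
    return total


# ---------------------------------------------------------------------------
# double-exponential filters
# ---------------------------------------------------------------------------


class DoubleExpTrace:
    """Online cascade of two leaky integrators (forward Euler)."""

    def __init__(self, shape, tau_rise: float, tau_fall: float, dt: float) -> None:
        if tau_rise <= 0 or tau_fall <= 0:
            raise ValueError("time constants must be positive")
        self.a = np.zeros(shape)
        self.b = np.zeros(shape)
        self.k_rise = dt / tau_rise
        self.k_fall = dt / tau_fall

    def step(self, x) -> np.ndarray:
        self.a += self.k_rise * (x - self.a)
        self.b += self.k_fall * (self.a - self.b)
        return self.b

    def set_value(self, value: float) -> None:
        self.a[...] = value
        self.b[...] = value


def double_exp_filter(signal: np.ndarray, tau_rise: float, tau_fall: float, dt: float) -> np.ndarray:
    """Filter a sampled time series through the two-integrator cascade."""
    signal = np.asarray(signal, dtype=float)
    out = np.empty_like(signal)
    tr = DoubleExpTrace(signal.shape[1:] if signal.ndim > 1 else (), tau_rise, tau_fall, dt)
    for k in range(signal.shape[0]):
        out[k] = tr.step(signal[k])
    return out


# ---------------------------------------------------------------------------
# plasticity rules
# ---------------------------------------------------------------------------


class SpikingLPL:
    """Online spiking predictive/Hebbian rule for one pathway.

    Maintains the presynaptic PSP-shaped trace, the eligibility matrix
    (surrogate voltage derivative times presynaptic trace, filtered), the
    filtered postsynaptic error and the slow moment estimates.  Spike
    trains are treated as sums of delta functions (weight ``1/dt``), all
    filter kernels are normalized to unit time-integral, so trace
    amplitudes are in Hz.

    The slow mean/variance are driven by a smoothed instantaneous rate
    estimate (10/100-ms double-exponential kernel) rather than the raw
    delta train, which keeps the variance on the scale of squared rates.
    """

    def __init__(
        self,
        n_pre: int,
        n_post: int,
        params: SpikingLPLParams,
        dt: float,
        theta_rest: float = -50.0,
        include_pred: bool = True,
        include_hebb: bool = True,
        moments_frozen: bool = False,
        freeze_sigma2: bool = False,
        sbar_init: float = 5.0,
        sigma2_init: float = 10.0,
    ) -> None:
        self.p = params
        self.dt = float(dt)
        self.theta_rest = theta_rest
        self.include_pred = include_pred
        self.include_hebb = include_hebb
        self.freeze_mean = moments_frozen
        self.freeze_var = moments_frozen or freeze_sigma2
        self.pre_trace = DoubleExpTrace(n_pre, params.tau_eps_rise, params.tau_eps_fall, dt)
        self.elig = DoubleExpTrace((n_post, n_pre), params.tau_alpha_rise, params.tau_alpha_fall, dt)
        self.err = DoubleExpTrace(n_post, params.tau_alpha_rise, params.tau_alpha_fall, dt)
        self.rate = DoubleExpTrace(n_post, params.tau_rate_rise, params.tau_rate_fall, dt)
        self.rate.set_value(sbar_init)
        self.sbar = np.full(n_post, float(sbar_init))
        self.sigma2 = np.full(n_post, float(sigma2_init))
        self.delay_steps = max(1, int(round(params.pred_delay / dt)))
        self._hist = np.zeros((self.delay_steps, n_post))
        self._hpos = 0

    def surrogate_fprime(self, U: np.ndarray) -> np.ndarray:
        b = self.p.beta_surrogate
        return b / (1.0 + b * np.abs(U - self.theta_rest)) ** 2

    def step(
        self,
        pre_idx: np.ndarray,
        post_spk: np.ndarray,
        U_post: np.ndarray,
    ) -> np.ndarray:
        """Advance all traces by ``dt`` and return the weight increment."""
        p = self.p
        dt = self.dt
        s_post = post_spk.astype(float) / dt  # delta train in Hz

        pre = np.zeros(self.pre_trace.a.shape)
        if len(pre_idx):
            pre[pre_idx] = 1.0 / dt
        eps = self.pre_trace.step(pre)

        fp = self.surrogate_fprime(U_post)
        elig = self.elig.step(np.multiply.outer(fp, eps))

        s_delayed = self._hist[self._hpos].copy()
        self._hist[self._hpos] = s_post
        self._hpos = (self._hpos + 1) % self.delay_steps

        err_in = np.zeros_like(s_post)
        if self.include_pred:
            err_in -= s_post - s_delayed
        if self.include_hebb:
            err_in += (p.lam / (self.sigma2 + p.xi)) * (s_post - self.sbar)
        err = self.err.step(err_in)

        r = self.rate.step(s_post)
        if not self.freeze_mean:
            self.sbar += (dt / p.tau_mean) * (r - self.sbar)
        if not self.freeze_var:
            self.sigma2 += (dt / p.tau_var) * (-self.sigma2 + (r - self.sbar) ** 2)

        dW = (dt * p.eta) * elig * err[:, None]
        if len(pre_idx):
            dW[:, pre_idx] += p.eta * p.delta  # transmitter-triggered
        return dW


class InhSTDP:
    """Pair-based inhibitory STDP with a postsynaptic rate target.

    On a presynaptic (inhibitory) spike the weight moves by
    ``zeta * (x_post - 2 * kappa * tau)``; on a postsynaptic spike by
    ``zeta * x_pre``.  The pre-spike offset makes the postsynaptic
    excitatory rate ``kappa`` the fixed point.  ``literal_form=True``
    restores the printed all-positive variant for comparison.
    """

    def __init__(self, n_pre: int, n_post: int, params: InhSTDPParams, dt: float) -> None:
        self.p = params
        self.dt = float(dt)
        self.x_pre = np.zeros(n_pre)
        self.x_post = np.zeros(n_post)
        self._decay = 1.0 - dt / params.tau_stdp

    def step(self, pre_spk: np.ndarray, post_spk: np.ndarray, W: np.ndarray, mask: np.ndarray) -> None:
        """Update traces and apply the weight change in place."""
        p = self.p
        self.x_pre *= self._decay
        self.x_post *= self._decay
        pre_idx = np.flatnonzero(pre_spk)
        post_idx = np.flatnonzero(post_spk)
        offset = 2.0 * p.kappa * p.tau_stdp
        if p.literal_form:
            offset = -offset
        if pre_idx.size:
            W[:, pre_idx] += p.zeta * (self.x_post[:, None] - offset)
        if post_idx.size:
            W[post_idx, :] += p.zeta * self.x_pre[None, :]
        if pre_idx.size or post_idx.size:
            W *= mask
            np.clip(W, p.w_min, p.w_max, out=W)
        self.x_pre[pre_idx] += 1.0
        self.x_post[post_idx] += 1.0


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------


def make_input_rate_traces(
    n_per_pop: int = 100,
    base_rate: float = 5.0,
    sample_interval: float = 0.010,
    n_periods: int = 13,
    seed: int = 0,
) -> Dict[str, Tuple[np.ndarray, int]]:
    """Build the five standard input populations.

    P0 is constant at the base rate; P1/P2 follow slow periodic signals
    with periods 3 s and (3 + 1/13) s; the controls repeat the signal for
    ``n_periods`` periods and shuffle it on the 10-ms grid.
    """
    rng = np.random.default_rng(seed)
    cfg1 = SlowSignalConfig(period=3.0, seed=int(rng.integers(2**31)),
                            sample_interval=sample_interval, base_rate=base_rate)
    cfg2 = SlowSignalConfig(period=3.0 + 1.0 / 13.0, seed=int(rng.integers(2**31)),
                            sample_interval=sample_interval, base_rate=base_rate)
    p1 = gen_slow_signal(cfg1, duration=n_periods * cfg1.period)
    p2 = gen_slow_signal(cfg2, duration=n_periods * cfg2.period)
    p1c = make_shuffled_control(p1, n_periods=1, grid=sample_interval,
                               sample_interval=sample_interval, rng=rng)
    p2c = make_shuffled_control(p2, n_periods=1, grid=sample_interval,
                                sample_interval=sample_interval, rng=rng)
    p0 = np.full(len(p1), base_rate)
    return {
        "P0": (p0, n_per_pop),
        "P1": (p1, n_per_pop),
        "P2": (p2, n_per_pop),
        "P1_ctl": (p1c, n_per_pop),
        "P2_ctl": (p2c, n_per_pop),
    }


@dataclass
class SNNConfig:
    """Everything one spiking simulation needs."""

    topology: NetworkTopology = field(default_factory=NetworkTopology)
    lif: LIFParams = field(default_factory=LIFParams)
    lpl: SpikingLPLParams = field(default_factory=SpikingLPLParams)
    istdp: InhSTDPParams = field(default_factory=InhSTDPParams)
    duration: float = 200.0
    ablation: str = "full"
    plastic_input: bool = True
    plastic_inhib: bool = True
    n_per_pop: Optional[int] = None  # defaults to n_input / 5
    base_rate: float = 5.0
    sbar_init: float = 5.0
    sigma2_init: float = 10.0
    # at reduced simulated durations the variance estimate is dominated by
    # the start-up transient; freezing it turns sigma2_init into a fixed
    # metaplastic operating point (same convention as the induction
    # protocols).  The slow mean still evolves online.
    freeze_sigma2: bool = False
    rate_ceiling: float = 200.0
    snapshot_interval: float = 50.0
    record_inputs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; choose from {ABLATIONS}")


@dataclass
class SNNResult:
    """Raster, weight snapshots and diagnostics of one simulation."""

    raster: SpikeRaster  # network spikes, E then I
    input_raster: Optional[SpikeRaster]
    w_in_e: np.ndarray
    w_ie: np.ndarray
    mask_in_e: np.ndarray
    input_slices: Dict[str, slice]
    snapshots: Dict[str, np.ndarray]  # "t" plus per-population mean afferent weights
    exc_rate: float  # mean excitatory rate over the final window
    inh_rate: float
    diagnostics: Dict[str, object]


def mean_afferent_weights(
    w_in_e: np.ndarray, mask: np.ndarray, slices: Dict[str, slice]
) -> Dict[str, np.ndarray]:
    """Per-excitatory-neuron mean connected weight from each input population."""
    out = {}
    for name, sl in slices.items():
        sub_w = w_in_e[:, sl]
        sub_m = mask[:, sl]
        cnt = np.maximum(sub_m.sum(axis=1), 1)
        out[name] = (sub_w * sub_m).sum(axis=1) / cnt
    return out


def _pregen_input_spikes(
    rng: np.random.Generator,
    p_step: np.ndarray,  # (5, n_samples) per-step spike probability
    pop_of: np.ndarray,  # (n_in,) population index per input neuron
    n_steps: int,
    sample_steps: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Bernoulli-thin every (step, neuron) cell; returns sorted event arrays."""
    n_in = len(pop_of)
    chunk = max(sample_steps, (2_000_000 // max(1, n_in)) // sample_steps * sample_steps)
    steps_l, ids_l = [], []
    for start in range(0, n_steps, chunk):
        stop = min(start + chunk, n_steps)
        s_idx = np.arange(start, stop) // sample_steps
        pmat = p_step[:, s_idx].T[:, pop_of]  # (chunk, n_in)
        u = rng.random((stop - start, n_in))
        r, c = np.nonzero(u < pmat)
        if r.size:
            steps_l.append(r + start)
            ids_l.append(c)
    if steps_l:
        return (
            np.concatenate(steps_l).astype(np.int64),
            np.concatenate(ids_l).astype(np.int64),
        )
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)


def run_simulation(config: SNNConfig, backend: str = "numba") -> SNNResult:
    """Run the full loop: integration, delayed delivery, plasticity.

    Input spikes are pregenerated from the per-population rate traces by
    per-step Bernoulli thinning; the loop itself runs either through the
    compiled kernel (default) or the pure-numpy reference path
    (``backend="numpy"``).  Deterministic given ``config.seed``.
    """
    if backend not in ("numba", "numpy"):
        raise ValueError(f"unknown backend {backend!r}")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    top = cfg.topology
    n_per_pop = cfg.n_per_pop or top.n_input // 5
    if n_per_pop * 5 != top.n_input:
        raise ValueError("n_input must be divisible into 5 equal populations")

    traces = make_input_rate_traces(
        n_per_pop=n_per_pop, base_rate=cfg.base_rate, seed=int(rng.integers(2**31))
    )
    state = build_network(top, seed=int(rng.integers(2**31)), params=cfg.lif)
    if cfg.ablation == "inhib_off":
        state.W["ie"][:] = 0.0
        state.W["in_i"][:] = 0.0
        state.W["ei"][:] = 0.0
        state.W["ii"][:] = 0.0

    dt = cfg.lif.dt * 1e-3  # seconds
    n_steps = int(round(cfg.duration / dt))
    sample_steps = int(round(0.010 / dt))

    slices: Dict[str, slice] = {}
    rate_rows = []
    off = 0
    n_samples = n_steps // sample_steps + 1
    for name, (tr, n_neu) in traces.items():
        slices[name] = slice(off, off + n_neu)
        reps = -(-n_samples // len(tr))
        rate_rows.append(np.tile(tr, reps)[:n_samples])
        off += n_neu
    rates = np.stack(rate_rows)  # (5, n_samples)
    pop_of = np.repeat(np.arange(5), n_per_pop)
    in_spk_steps, in_spk_ids = _pregen_input_spikes(
        rng, rates * dt, pop_of, n_steps, sample_steps
    )

    do_lpl = cfg.plastic_input
    include_pred = cfg.ablation != "pred_off"
    include_hebb = cfg.ablation != "hebb_off"
    do_istdp = cfg.plastic_inhib and cfg.ablation not in ("inhib_off", "inhib_fixed")

    window = min(50.0, cfg.duration)
    window_start_step = int(round(max(0.0, cfg.duration - window) / dt))
    sec_steps = int(round(1.0 / dt))
    snap_every = max(1, int(round(cfg.snapshot_interval / dt)))
    snap_steps = np.unique(
        np.concatenate([np.arange(snap_every - 1, n_steps, snap_every), [n_steps - 1]])
    ).astype(np.int64)
    snap_out = np.zeros((len(snap_steps), 5))

    if backend == "numba":
        out = _run_kernel(
            cfg, state, in_spk_steps, in_spk_ids, n_steps, dt,
            do_lpl, include_pred, include_hebb, do_istdp,
            window_start_step, sec_steps, snap_steps, snap_out,
            n_per_pop,
        )
        e_t, e_id, i_t, i_id, e_win, i_win, unstable = out
    else:
        out = _run_numpy(
            cfg, state, in_spk_steps, in_spk_ids, n_steps, dt,
            do_lpl, include_pred, include_hebb, do_istdp,
            window_start_step, sec_steps, snap_steps, snap_out,
            n_per_pop,
        )
        e_t, e_id, i_t, i_id, e_win, i_win, unstable = out

    def _raster(t_parts, id_parts, pops):
        if len(t_parts):
            t = np.concatenate(t_parts)
            nid = np.concatenate(id_parts)
            order = np.argsort(t, kind="stable")
            t, nid = t[order], nid[order]
        else:
            t = np.empty(0)
            nid = np.empty(0, dtype=np.int64)
        return SpikeRaster(t, nid, pops, cfg.duration, dt)

    net_pops = {"E": slice(0, top.n_exc), "I": slice(top.n_exc, top.n_exc + top.n_inh)}
    raster = _raster([e_t, i_t], [e_id, i_id + top.n_exc], net_pops)
    input_raster = None
    if cfg.record_inputs:
        input_raster = _raster([in_spk_steps * dt], [in_spk_ids], slices)

    return SNNResult(
        raster=raster,
        input_raster=input_raster,
        w_in_e=state.W["in_e"].copy(),
        w_ie=state.W["ie"].copy(),
        mask_in_e=state.mask["in_e"].copy(),
        input_slices=slices,
        snapshots={
            "t": (snap_steps + 1) * dt,
            "pop_mean_w": snap_out,
            "pop_names": np.array(list(slices)),
        },
        exc_rate=e_win / (top.n_exc * window),
        inh_rate=i_win / (top.n_inh * window),
        diagnostics={
            "unstable": bool(unstable),
            "ablation": cfg.ablation,
            "duration": cfg.duration,
            "seed": cfg.seed,
            "backend": backend,
        },
    )


def _run_kernel(
    cfg, state, in_spk_steps, in_spk_ids, n_steps, dt,
    do_lpl, include_pred, include_hebb, do_istdp,
    window_start_step, sec_steps, snap_steps, snap_out, n_per_pop,
):
    from lplnet._kernels import sim_loop

    top = cfg.topology
    lif = cfg.lif
    lp = cfg.lpl
    ist = cfg.istdp
    pred_steps = max(1, int(round(lp.pred_delay / dt)))
    cap_e = int(top.n_exc * cfg.duration * min(cfg.rate_ceiling, 150.0)) + 4096
    cap_i = int(top.n_inh * cfg.duration * 400.0) + 4096
    e_spk_step = np.zeros(cap_e, np.int64)
    e_spk_id = np.zeros(cap_e, np.int64)
    i_spk_step = np.zeros(cap_i, np.int64)
    i_spk_id = np.zeros(cap_i, np.int64)

    n_e, n_in, n_i = top.n_exc, top.n_input, top.n_inh
    rt1 = np.full(n_e, float(cfg.sbar_init))
    rt2 = np.full(n_e, float(cfg.sbar_init))
    res = sim_loop(
        n_steps, lif.dt, dt,
        lif.tau_mem, lif.tau_ampa, lif.tau_nmda, lif.tau_gaba, lif.tau_thr,
        lif.U_leak, lif.U_exc, lif.U_inh, lif.theta_rest, lif.delta_theta,
        lif.delay_steps,
        state.exc.U, state.exc.theta, state.exc.g_ampa, state.exc.g_nmda, state.exc.g_gaba,
        state.inh.U, state.inh.theta, state.inh.g_ampa, state.inh.g_nmda, state.inh.g_gaba,
        state.W["in_e"], state.W["in_i"], state.W["ie"], state.W["ii"],
        state.W["ei"], state.W["ee"],
        state.mask["in_e"], state.mask["ie"],
        in_spk_steps, in_spk_ids,
        do_lpl, include_pred, include_hebb, False, cfg.freeze_sigma2,
        lp.eta, lp.xi, lp.delta, lp.lam, lp.beta_surrogate,
        dt / lp.tau_eps_rise, dt / lp.tau_eps_fall,
        dt / lp.tau_alpha_rise, dt / lp.tau_alpha_fall,
        dt / lp.tau_rate_rise, dt / lp.tau_rate_fall,
        dt / lp.tau_mean, dt / lp.tau_var,
        pred_steps, lp.w_min, lp.w_max,
        np.zeros(n_in), np.zeros(n_in),
        np.zeros((n_e, n_in)), np.zeros((n_e, n_in)),
        np.zeros(n_e), np.zeros(n_e),
        rt1, rt2,
        np.full(n_e, float(cfg.sbar_init)), np.full(n_e, float(cfg.sigma2_init)),
        np.zeros((pred_steps, n_e)),
        do_istdp, ist.zeta, 2.0 * ist.kappa * ist.tau_stdp * (-1.0 if ist.literal_form else 1.0),
        1.0 - dt / ist.tau_stdp, ist.w_min, ist.w_max,
        np.zeros(n_i), np.zeros(n_e),
        e_spk_step, e_spk_id, i_spk_step, i_spk_id,
        snap_steps, snap_out, n_per_pop,
        window_start_step, sec_steps, cfg.rate_ceiling,
    )
    n_e_rec, n_i_rec, e_win, i_win, unstable = res
    return (
        e_spk_step[:n_e_rec] * dt, e_spk_id[:n_e_rec],
        i_spk_step[:n_i_rec] * dt, i_spk_id[:n_i_rec],
        e_win, i_win, unstable,
    )


def _run_numpy(
    cfg, state, in_spk_steps, in_spk_ids, n_steps, dt,
    do_lpl, include_pred, include_hebb, do_istdp,
    window_start_step, sec_steps, snap_steps, snap_out, n_per_pop,
):
    """Reference loop built from the documented step primitives."""
    top = cfg.topology
    lpl = None
    if do_lpl:
        lpl = SpikingLPL(
            top.n_input, top.n_exc, cfg.lpl, dt,
            theta_rest=cfg.lif.theta_rest,
            include_pred=include_pred, include_hebb=include_hebb,
            freeze_sigma2=cfg.freeze_sigma2,
            sbar_init=cfg.sbar_init, sigma2_init=cfg.sigma2_init,
        )
    istdp = InhSTDP(top.n_inh, top.n_exc, cfg.istdp, dt) if do_istdp else None

    e_t, e_id, i_t, i_id = [], [], [], []
    e_win = i_win = 0
    e_sec = 0
    unstable = False
    snap_set = {int(s): n for n, s in enumerate(snap_steps)}
    ptr = 0
    for k in range(n_steps):
        idx = []
        while ptr < len(in_spk_steps) and in_spk_steps[ptr] == k:
            idx.append(in_spk_ids[ptr])
            ptr += 1
        in_idx = np.asarray(idx, dtype=np.int64)
        e_spk, i_spk, delivered = integrate_step(state, in_idx)
        if lpl is not None:
            dW = lpl.step(delivered["in"], e_spk, state.exc.U)
            W = state.W["in_e"]
            W += dW
            W *= state.mask["in_e"]
            np.clip(W, cfg.lpl.w_min, cfg.lpl.w_max, out=W)
        if istdp is not None:
            istdp.step(i_spk, e_spk, state.W["ie"], state.mask["ie"])
        eids = np.flatnonzero(e_spk)
        if eids.size:
            e_t.append(np.full(eids.size, k * dt))
            e_id.append(eids)
            e_sec += eids.size
            if k >= window_start_step:
                e_win += eids.size
        iids = np.flatnonzero(i_spk)
        if iids.size:
            i_t.append(np.full(iids.size, k * dt))
            i_id.append(iids)
            if k >= window_start_step:
                i_win += iids.size
        if (k + 1) % sec_steps == 0:
            if e_sec / top.n_exc > cfg.rate_ceiling:
                unstable = True
            e_sec = 0
        if k in snap_set:
            means = mean_afferent_weights(
                state.W["in_e"], state.mask["in_e"],
                {p: slice(p * n_per_pop, (p + 1) * n_per_pop) for p in range(5)},
            )
            snap_out[snap_set[k]] = [means[p].mean() for p in range(5)]

    cat = lambda parts, dtype=None: (
        np.concatenate(parts) if parts else np.empty(0, dtype=dtype or float)
    )
    return (
        cat(e_t), cat(e_id, np.int64), cat(i_t), cat(i_id, np.int64),
        e_win, i_win, unstable,
    )
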