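"""Spike-pairing induction protocols on a voltage-clamped neuron.

A single postsynaptic neuron is held at a fixed membrane voltage between
spikes while prescribed pre/post spike pairs are delivered; the synapse
follows the spiking predictive/Hebbian rule.  Sweeps over pairing delay
and repetition frequency, run from a prescribed initial metaplastic
state (initial slow mean and variance of the postsynaptic activity),
characterize the timing window and its rate dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from lplnet.snn_core import SpikingLPL, SpikingLPLParams

__all__ = [
    "PairingProtocol",
    "STDPCurve",
    "run_pairing_protocol",
    "stdp_window_sweep",
    "frequency_sweep",
]


@dataclass
class PairingProtocol:
    """One spike-pairing induction experiment.

    ``delta_t`` is the post-minus-pre delay in ms (positive: pre leads);
    ``rho`` the pairing repetition frequency in Hz.  The neuron's voltage
    is clamped at ``clamp_voltage`` between spikes.  ``sigma2_init`` and
    ``sbar_init`` set the slow metaplastic state at protocol onset; by
    default they stay frozen during the protocol (their drift over 100
    pairings is negligible given the slow time constants, and freezing
    makes them clean protocol parameters); set ``evolve_moments=True`` to
    let them follow their online dynamics instead.
    """

    n_pairings: int = 100
    delta_t: float = 10.0  # ms
    rho: float = 10.0  # Hz
    clamp_voltage: float = -51.0  # mV
    w_init: float = 0.5
    eta_protocol: float = 5e-3
    sigma2_init: float = 0.1
    sbar_init: float = 20.0  # Hz
    evolve_moments: bool = False
    dt: float = 1e-4  # s
    tail: float = 0.3  # settle time after the last pairing, s

    def __post_init__(self) -> None:
        if self.n_pairings < 0:
            raise ValueError("n_pairings must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if abs(self.delta_t) * 1e-3 >= 1.0 / self.rho:
            raise ValueError("|delta_t| must be smaller than the pairing period")


@dataclass
class STDPCurve:
    """Relative weight change as a function of a swept protocol variable."""

    x: np.ndarray  # delta_t (ms) or rho (Hz)
    dw_rel: np.ndarray  # (w_final - w_init) / w_init
    x_name: str = "delta_t_ms"
    sigma2_init: float = 0.1
    sbar_init: float = 20.0
    rho: Optional[float] = None
    meta: dict = field(default_factory=dict)


def _spike_steps(times_s: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    steps = np.round(times_s / dt).astype(int)
    steps = steps[(steps >= 0) & (steps < n_steps)]
    if len(np.unique(steps)) != len(steps):
        raise ValueError("two forced spikes fall into the same time step")
    return steps


def run_pairing_protocol(protocol: PairingProtocol, backend: str = "numba") -> float:
    """Run one induction protocol; returns ``(w_final - w_init) / w_init``.

    Pre spikes arrive at multiples of the pairing period, post spikes are
    injected ``delta_t`` later (earlier for negative delays); both trains
    are shifted so every spike time is nonnegative.  The run is exactly
    reproducible: there is no randomness once the spike times are fixed.
    ``backend="numpy"`` steps the online-rule object directly (slow
    reference path used for cross-checks).
    """
    prt = protocol
    period = 1.0 / prt.rho
    offset = max(0.0, -prt.delta_t * 1e-3)
    pre_times = offset + period * np.arange(prt.n_pairings)
    post_times = pre_times + prt.delta_t * 1e-3
    duration = (pre_times[-1] if prt.n_pairings else 0.0) + period + prt.tail
    n_steps = int(round(duration / prt.dt))

    pre_arr = _spike_steps(pre_times, prt.dt, n_steps)
    post_arr = np.sort(_spike_steps(post_times, prt.dt, n_steps))
    if prt.delta_t != 0.0 and np.intersect1d(pre_arr, post_arr).size:
        # delta_t = 0 is a legitimate coincident-pairing point; anything
        # else colliding within one step is an ill-posed protocol
        raise ValueError("pre and post forced spikes overlap within one time step")

    params = SpikingLPLParams(eta=prt.eta_protocol)
    if backend == "numba":
        from lplnet._kernels import protocol_loop

        beta = params.beta_surrogate
        fp = beta / (1.0 + beta * abs(prt.clamp_voltage - (-50.0))) ** 2
        w = protocol_loop(
            n_steps, prt.dt, pre_arr, post_arr, fp,
            params.eta, params.xi, params.delta, params.lam,
            prt.dt / params.tau_eps_rise, prt.dt / params.tau_eps_fall,
            prt.dt / params.tau_alpha_rise, prt.dt / params.tau_alpha_fall,
            prt.dt / params.tau_rate_rise, prt.dt / params.tau_rate_fall,
            prt.dt / params.tau_mean, prt.dt / params.tau_var,
            max(1, int(round(params.pred_delay / prt.dt))),
            prt.sbar_init, prt.sigma2_init, not prt.evolve_moments,
            prt.w_init,
        )
        return (w - prt.w_init) / prt.w_init

    pre_steps = set(pre_arr)
    post_steps = set(post_arr)
    rule = SpikingLPL(
        n_pre=1,
        n_post=1,
        params=params,
        dt=prt.dt,
        include_pred=True,
        include_hebb=True,
        moments_frozen=not prt.evolve_moments,
        sbar_init=prt.sbar_init,
        sigma2_init=prt.sigma2_init,
    )
    U = np.array([prt.clamp_voltage])
    w = prt.w_init
    no_pre = np.empty(0, dtype=np.int64)
    one_pre = np.array([0], dtype=np.int64)
    post = np.zeros(1, dtype=bool)
    for k in range(n_steps):
        post[0] = k in post_steps
        dW = rule.step(one_pre if k in pre_steps else no_pre, post, U)
        w += float(dW[0, 0])
        # the voltage is re-clamped immediately after any injected spike
    return (w - prt.w_init) / prt.w_init


def stdp_window_sweep(
    delta_t_grid: Sequence[float],
    sigma2_init: float = 0.1,
    sbar_init: float = 20.0,
    rho: float = 10.0,
    **kwargs,
) -> STDPCurve:
    """Window over pairing delays, one protocol per delay, shared initial state."""
    grid = np.asarray(delta_t_grid, dtype=float)
    dw = np.array(
        [
            run_pairing_protocol(
                PairingProtocol(
                    delta_t=d, rho=rho, sigma2_init=sigma2_init, sbar_init=sbar_init, **kwargs
                )
            )
            for d in grid
        ]
    )
    return STDPCurve(
        x=grid, dw_rel=dw, x_name="delta_t_ms",
        sigma2_init=sigma2_init, sbar_init=sbar_init, rho=rho,
    )


def frequency_sweep(
    delta_t: float,
    rho_list: Sequence[float],
    sigma2_init: float = 0.1,
    sbar_init: float = 20.0,
    **kwargs,
) -> STDPCurve:
    """Rate dependence at fixed pairing delay."""
    rhos = np.asarray(rho_list, dtype=float)
    for rho in rhos:
        if abs(delta_t) * 1e-3 >= 1.0 / rho:
            raise ValueError(f"rho={rho} Hz infeasible for |delta_t|={abs(delta_t)} ms")
    dw = np.array(
        [
            run_pairing_protocol(
                PairingProtocol(
                    delta_t=delta_t, rho=rho, sigma2_init=sigma2_init,
                    sbar_init=sbar_init, **kwargs,
                )
            )
            for rho in rhos
        ]
    )
    return STDPCurve(
        x=rhos, dw_rel=dw, x_name="rho_hz",
        sigma2_init=sigma2_init, sbar_init=sbar_init, rho=None,
        meta={"delta_t_ms": delta_t},
    )
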