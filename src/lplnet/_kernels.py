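"""Compiled inner loop for the spiking simulations.

The numba kernel mirrors the numpy reference path (``integrate_step``
plus the trace objects) step for step; an equivalence test guards the
two implementations against drifting apart.  Everything is explicit
loops over small arrays — that is what numba compiles best.

Per-step ordering (identical to the reference):
1. spikes that were pushed ``delay`` steps ago are delivered to the
   conductances,
2. forward-Euler update of both populations, spike detection, threshold
   jumps,
3. the new spikes (input spikes of this step, network spikes) are pushed
   into the delay ring,
4. input plasticity runs on the *delivered* presynaptic spikes and the
   current postsynaptic spikes/voltages,
5. inhibitory STDP runs on the current network spikes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def protocol_loop(
    n_steps,
    dt_s,
    pre_spike_step,  # sorted int64 array
    post_spike_step,  # sorted int64 array
    fp,  # surrogate derivative at the clamp voltage (constant)
    eta, xi, delta, lam,
    k_eps_r, k_eps_f, k_al_r, k_al_f, k_rt_r, k_rt_f, k_mean, k_var,
    pred_delay_steps,
    sbar0, sig20, moments_frozen,
    w0,
):
    """Scalar-synapse version of the plasticity loop under voltage clamp.

    Mirrors ``SpikingLPL.step`` exactly for one pre and one post neuron
    with a constant surrogate derivative (the membrane is clamped).
    Returns the final weight.
    """
    eps1 = 0.0
    eps2 = 0.0
    el1 = 0.0
    el2 = 0.0
    err1 = 0.0
    err2 = 0.0
    rt1 = sbar0
    rt2 = sbar0
    sbar = sbar0
    sig2 = sig20
    hist = np.zeros(pred_delay_steps)
    hpos = 0
    w = w0
    inv_dt = 1.0 / dt_s
    pp = 0
    qp = 0
    n_pre = pre_spike_step.shape[0]
    n_post = post_spike_step.shape[0]
    for k in range(n_steps):
        pre = 0.0
        if pp < n_pre and pre_spike_step[pp] == k:
            pre = inv_dt
            pp += 1
        post = 0.0
        if qp < n_post and post_spike_step[qp] == k:
            post = inv_dt
            qp += 1
        eps1 += k_eps_r * (pre - eps1)
        eps2 += k_eps_f * (eps1 - eps2)
        el1 += k_al_r * (fp * eps2 - el1)
        el2 += k_al_f * (el1 - el2)
        s_del = hist[hpos]
        hist[hpos] = post
        hpos = (hpos + 1) % pred_delay_steps
        err_in = -(post - s_del) + (lam / (sig2 + xi)) * (post - sbar)
        err1 += k_al_r * (err_in - err1)
        err2 += k_al_f * (err1 - err2)
        rt1 += k_rt_r * (post - rt1)
        rt2 += k_rt_f * (rt1 - rt2)
        if not moments_frozen:
            sbar += k_mean * (rt2 - sbar)
            dev = rt2 - sbar
            sig2 += k_var * (-sig2 + dev * dev)
        w += dt_s * eta * el2 * err2
        if pre > 0.0:
            w += eta * delta
    return w


@njit(cache=True)
def sim_loop(  # noqa: C901 - one big hot loop by design
    n_steps,
    dt_ms,
    dt_s,
    # LIF constants
    tau_mem, tau_ampa, tau_nmda, tau_gaba, tau_thr,
    U_leak, U_exc, U_inh, theta_rest, delta_theta, delay_steps,
    # population state (E then I), modified in place
    U_e, th_e, ga_e, gn_e, gg_e,
    U_i, th_i, ga_i, gn_i, gg_i,
    # weights and plasticity masks
    W_in_e, W_in_i, W_ie, W_ii, W_ei, W_ee,
    mask_in_e, mask_ie,
    # pregenerated input spikes, sorted by step
    in_spk_steps, in_spk_ids,
    # spiking LPL switches and constants
    do_lpl, include_pred, include_hebb, freeze_mean, freeze_var,
    eta, xi, delta, lam, beta_sur,
    k_eps_r, k_eps_f, k_al_r, k_al_f, k_rt_r, k_rt_f, k_mean, k_var,
    pred_delay_steps, w_lo, w_hi,
    eps1, eps2, el1, el2, err1, err2, rt1, rt2, sbar, sig2, hist,
    # inhibitory STDP
    do_istdp, zeta, istdp_offset, stdp_decay, iw_lo, iw_hi,
    x_pre_i, x_post_e,
    # recording buffers
    e_spk_step, e_spk_id, i_spk_step, i_spk_id,
    snap_steps, snap_out, n_per_pop,
    window_start_step, sec_steps, rate_ceiling,
):
    n_e = U_e.shape[0]
    n_i = U_i.shape[0]
    n_in = W_in_e.shape[1]

    ring_in = np.zeros((delay_steps, n_in), np.bool_)
    ring_e = np.zeros((delay_steps, n_e), np.bool_)
    ring_i = np.zeros((delay_steps, n_i), np.bool_)
    qpos = 0
    hpos = 0

    jump_e = np.zeros(n_e)
    jump_i = np.zeros(n_i)
    deliv_in = np.zeros(n_in, np.int64)
    spk_e = np.zeros(n_e, np.bool_)
    spk_i = np.zeros(n_i, np.bool_)
    inv_dt = 1.0 / dt_s

    n_e_rec = 0
    n_i_rec = 0
    e_win = 0.0
    i_win = 0.0
    e_sec = 0.0
    unstable = False
    sp_ptr = 0
    snap_ptr = 0
    cap_e = e_spk_step.shape[0]
    cap_i = i_spk_step.shape[0]

    for k in range(n_steps):
        # ---- 1. conductance jumps from spikes delivered this step ----
        n_deliv = 0
        for i in range(n_e):
            jump_e[i] = 0.0
        for i in range(n_i):
            jump_i[i] = 0.0
        for j in range(n_in):
            if ring_in[qpos, j]:
                deliv_in[n_deliv] = j
                n_deliv += 1
                for i in range(n_e):
                    jump_e[i] += W_in_e[i, j]
                for i in range(n_i):
                    jump_i[i] += W_in_i[i, j]
        for j in range(n_e):
            if ring_e[qpos, j]:
                for i in range(n_e):
                    jump_e[i] += W_ee[i, j]
                for i in range(n_i):
                    jump_i[i] += W_ei[i, j]

        # ---- 2. Euler update, E then I ----
        for i in range(n_e):
            ga_e[i] += dt_ms * (-ga_e[i] / tau_ampa)
            ga_e[i] += jump_e[i]
            gn_e[i] += (dt_ms / tau_nmda) * (ga_e[i] - gn_e[i])
            gg_e[i] += dt_ms * (-gg_e[i] / tau_gaba)
        for j in range(n_i):
            if ring_i[qpos, j]:
                for i in range(n_e):
                    gg_e[i] += W_ie[i, j]
        for i in range(n_e):
            g_exc = 0.5 * (ga_e[i] + gn_e[i])
            U_e[i] += (dt_ms / tau_mem) * (
                (U_leak - U_e[i])
                + g_exc * (U_exc - U_e[i])
                + gg_e[i] * (U_inh - U_e[i])
            )
            th_e[i] += (dt_ms / tau_thr) * (theta_rest - th_e[i])
            spk = U_e[i] >= th_e[i]
            spk_e[i] = spk
            if spk:
                th_e[i] += delta_theta

        for i in range(n_i):
            ga_i[i] += dt_ms * (-ga_i[i] / tau_ampa)
            ga_i[i] += jump_i[i]
            gn_i[i] += (dt_ms / tau_nmda) * (ga_i[i] - gn_i[i])
            gg_i[i] += dt_ms * (-gg_i[i] / tau_gaba)
        for j in range(n_i):
            if ring_i[qpos, j]:
                for i in range(n_i):
                    gg_i[i] += W_ii[i, j]
        for i in range(n_i):
            g_exc = 0.5 * (ga_i[i] + gn_i[i])
            U_i[i] += (dt_ms / tau_mem) * (
                (U_leak - U_i[i])
                + g_exc * (U_exc - U_i[i])
                + gg_i[i] * (U_inh - U_i[i])
            )
            th_i[i] += (dt_ms / tau_thr) * (theta_rest - th_i[i])
            spk = U_i[i] >= th_i[i]
            spk_i[i] = spk
            if spk:
                th_i[i] += delta_theta

        # ---- recording ----
        for i in range(n_e):
            if spk_e[i]:
                if n_e_rec < cap_e:
                    e_spk_step[n_e_rec] = k
                    e_spk_id[n_e_rec] = i
                    n_e_rec += 1
                e_sec += 1.0
                if k >= window_start_step:
                    e_win += 1.0
        for i in range(n_i):
            if spk_i[i]:
                if n_i_rec < cap_i:
                    i_spk_step[n_i_rec] = k
                    i_spk_id[n_i_rec] = i
                    n_i_rec += 1
                if k >= window_start_step:
                    i_win += 1.0

        # ---- 3. push this step's spikes into the (consumed) ring slot ----
        for j in range(n_in):
            ring_in[qpos, j] = False
        while sp_ptr < in_spk_steps.shape[0] and in_spk_steps[sp_ptr] == k:
            ring_in[qpos, in_spk_ids[sp_ptr]] = True
            sp_ptr += 1
        for i in range(n_e):
            ring_e[qpos, i] = spk_e[i]
        for i in range(n_i):
            ring_i[qpos, i] = spk_i[i]
        qpos = (qpos + 1) % delay_steps

        # ---- 4. input plasticity ----
        if do_lpl:
            # presynaptic PSP trace from the spikes delivered this step
            for j in range(n_in):
                pre = 0.0
                eps1[j] += k_eps_r * (pre - eps1[j])
            for m in range(n_deliv):
                j = deliv_in[m]
                eps1[j] += k_eps_r * inv_dt
            for j in range(n_in):
                eps2[j] += k_eps_f * (eps1[j] - eps2[j])

            for i in range(n_e):
                u = U_e[i] - theta_rest
                if u < 0.0:
                    u = -u
                fp = beta_sur / ((1.0 + beta_sur * u) * (1.0 + beta_sur * u))
                for j in range(n_in):
                    el1[i, j] += k_al_r * (fp * eps2[j] - el1[i, j])
                    el2[i, j] += k_al_f * (el1[i, j] - el2[i, j])

            for i in range(n_e):
                s_post = inv_dt if spk_e[i] else 0.0
                s_del = hist[hpos, i]
                hist[hpos, i] = s_post
                err_in = 0.0
                if include_pred:
                    err_in -= s_post - s_del
                if include_hebb:
                    err_in += (lam / (sig2[i] + xi)) * (s_post - sbar[i])
                err1[i] += k_al_r * (err_in - err1[i])
                err2[i] += k_al_f * (err1[i] - err2[i])
                rt1[i] += k_rt_r * (s_post - rt1[i])
                rt2[i] += k_rt_f * (rt1[i] - rt2[i])
                if not freeze_mean:
                    sbar[i] += k_mean * (rt2[i] - sbar[i])
                if not freeze_var:
                    dev = rt2[i] - sbar[i]
                    sig2[i] += k_var * (-sig2[i] + dev * dev)
            hpos = (hpos + 1) % pred_delay_steps

            for i in range(n_e):
                scale = dt_s * eta * err2[i]
                for j in range(n_in):
                    if mask_in_e[i, j]:
                        w = W_in_e[i, j] + scale * el2[i, j]
                        W_in_e[i, j] = w
            for m in range(n_deliv):
                j = deliv_in[m]
                for i in range(n_e):
                    if mask_in_e[i, j]:
                        W_in_e[i, j] += eta * delta
            for i in range(n_e):
                for j in range(n_in):
                    w = W_in_e[i, j]
                    if w < w_lo:
                        W_in_e[i, j] = w_lo
                    elif w > w_hi:
                        W_in_e[i, j] = w_hi

        # ---- 5. inhibitory STDP on the current network spikes ----
        if do_istdp:
            any_spk = False
            for j in range(n_i):
                x_pre_i[j] *= stdp_decay
            for i in range(n_e):
                x_post_e[i] *= stdp_decay
            for j in range(n_i):
                if spk_i[j]:
                    any_spk = True
                    for i in range(n_e):
                        if mask_ie[i, j]:
                            W_ie[i, j] += zeta * (x_post_e[i] - istdp_offset)
            for i in range(n_e):
                if spk_e[i]:
                    any_spk = True
                    for j in range(n_i):
                        if mask_ie[i, j]:
                            W_ie[i, j] += zeta * x_pre_i[j]
            if any_spk:
                for i in range(n_e):
                    for j in range(n_i):
                        w = W_ie[i, j]
                        if w < iw_lo:
                            W_ie[i, j] = iw_lo
                        elif w > iw_hi:
                            W_ie[i, j] = iw_hi
            for j in range(n_i):
                if spk_i[j]:
                    x_pre_i[j] += 1.0
            for i in range(n_e):
                if spk_e[i]:
                    x_post_e[i] += 1.0

        # ---- housekeeping ----
        if (k + 1) % sec_steps == 0:
            if e_sec / n_e > rate_ceiling:
                unstable = True
            e_sec = 0.0
        if snap_ptr < snap_steps.shape[0] and k == snap_steps[snap_ptr]:
            n_pop = snap_out.shape[1]
            for p in range(n_pop):
                tot = 0.0
                cnt = 0.0
                for i in range(n_e):
                    for j in range(p * n_per_pop, (p + 1) * n_per_pop):
                        if mask_in_e[i, j]:
                            tot += W_in_e[i, j]
                            cnt += 1.0
                snap_out[snap_ptr, p] = tot / cnt if cnt > 0 else 0.0
            snap_ptr += 1

    return n_e_rec, n_i_rec, e_win, i_win, unstable
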