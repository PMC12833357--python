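"""Compiled inner loop of the network integrator.

Single fused time-stepping kernel over all cells and synapses.  Gates use
exact-exponential updates with voltage-indexed lookup tables holding
``x_inf(V)`` and ``exp(-dt/tau(V))`` (linear interpolation on a 0.05 mV
grid); the membrane potential uses an explicit update; synaptic open
fractions use the closed-form two-state solution per step, with exact
handling of transmitter-pulse boundaries that fall inside a step.

Everything is deterministic; no random numbers are drawn anywhere.

State arrays are laid out per cell class and padded to the largest
population, so the kernel signature is wide but uniform.  Channel "modes":
0 = voltage-gated or leak, 1 = Kc (conductance scales with min(Ca/sat, 1)),
2 = Kahp (gate driven by intracellular Ca, not voltage).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BLOWUP = 1

SPIKE_THRESHOLD = 0.0  # mV, upward crossing
REFRACTORY = 2.0  # ms merge window


@njit(cache=True, fastmath=True)
def run_kernel(
    counts, Cm, hold_nA, area,
    v, gates, ca,
    n_chan, chan_g, chan_E, chan_N, chan_M, chan_act, chan_inact,
    chan_mode, chan_casrc,
    vmin, dv, xinf_tab, efact_tab,
    ca_tau, ca_gain, kc_sat, kahp_gain, kahp_amax, kahp_beta,
    p_pre, p_post, p_Esyn, p_sinf, p_pfact, p_beta, p_dfact, p_cdur, p_tau,
    s, pulse_end, indptr, e_pre, e_w,
    stim_cls, stim_idx, stim_nA, stim_on, stim_off,
    t0, dt, n_steps, rec_start, rec_every,
    class_offset, v_rec, rec_cls, rec_idx, syn_rec,
    spk_cls, spk_idx, spk_t, spk_count,
    last_spike, syn_acc, rec_cursor,
):
    nA2dens = 1e-3 / area  # nA -> uA/cm^2
    P = p_pre.shape[0]
    n_classes = counts.shape[0]
    NV = xinf_tab.shape[2]
    xmax = NV - 1.000001
    cap = spk_t.shape[0]
    for step in range(n_steps):
        t = t0 + step * dt

        # ---- synaptic open fractions ----------------------------------
        for p in range(P):
            npre = counts[p_pre[p]]
            sinf = p_sinf[p]
            pf = p_pfact[p]
            df = p_dfact[p]
            for j in range(npre):
                pe = pulse_end[p, j]
                sj = s[p, j]
                if t < pe:
                    tend = t + dt
                    if tend <= pe:
                        sj = sinf + (sj - sinf) * pf
                    else:
                        # pulse ends inside this step: exact two-phase update
                        sj = sinf + (sj - sinf) * np.exp(-(pe - t) / p_tau[p])
                        sj = sj * np.exp(-p_beta[p] * (tend - pe))
                else:
                    sj = sj * df
                s[p, j] = sj

        # ---- synaptic currents (nA, positive outward) -----------------
        for c in range(n_classes):
            for i in range(counts[c]):
                syn_acc[c, i] = 0.0
        for p in range(P):
            post_c = p_post[p]
            E = p_Esyn[p]
            for i in range(counts[post_c]):
                g = 0.0
                for e in range(indptr[p, i], indptr[p, i + 1]):
                    g += e_w[e] * s[p, e_pre[e]]
                syn_acc[post_c, i] += g * (v[post_c, i] - E)

        # ---- recording ------------------------------------------------
        if step >= rec_start and (step - rec_start) % rec_every == 0:
            ri = rec_cursor[0]
            if ri < v_rec.shape[0]:
                for c in range(n_classes):
                    off = class_offset[c]
                    for i in range(counts[c]):
                        v_rec[ri, off + i] = v[c, i]
                for r in range(rec_cls.shape[0]):
                    syn_rec[ri, r] = syn_acc[rec_cls[r], rec_idx[r]]
                rec_cursor[0] = ri + 1

        # ---- membrane and gate update ---------------------------------
        stim_active = (t >= stim_on) and (t < stim_off)
        for c in range(n_classes):
            nc = n_chan[c]
            for i in range(counts[c]):
                vi = v[c, i]
                x = (vi - vmin) / dv
                if x < 0.0:
                    x = 0.0
                if x > xmax:
                    x = xmax
                i0 = int(x)
                fr = x - i0
                ion = 0.0
                ca_cur = 0.0
                for k in range(nc):
                    mode = chan_mode[c, k]
                    a = chan_act[c, k]
                    gate_m = 1.0
                    if a >= 0:
                        if mode == 2:
                            al = kahp_gain[c] * ca[c, i]
                            if al > kahp_amax[c]:
                                al = kahp_amax[c]
                            m0 = gates[c, a, i]
                            m0 = m0 + dt * (al * (1.0 - m0) - kahp_beta[c] * m0)
                            if m0 < 0.0:
                                m0 = 0.0
                            elif m0 > 1.0:
                                m0 = 1.0
                        else:
                            xf = xinf_tab[c, a, i0] * (1.0 - fr) + xinf_tab[c, a, i0 + 1] * fr
                            ef = efact_tab[c, a, i0] * (1.0 - fr) + efact_tab[c, a, i0 + 1] * fr
                            m0 = xf + (gates[c, a, i] - xf) * ef
                        gates[c, a, i] = m0
                        gate_m = m0
                    b = chan_inact[c, k]
                    gate_h = 1.0
                    if b >= 0:
                        xf = xinf_tab[c, b, i0] * (1.0 - fr) + xinf_tab[c, b, i0 + 1] * fr
                        ef = efact_tab[c, b, i0] * (1.0 - fr) + efact_tab[c, b, i0 + 1] * fr
                        h0 = xf + (gates[c, b, i] - xf) * ef
                        gates[c, b, i] = h0
                        gate_h = h0
                    gmax = chan_g[c, k]
                    if gmax == 0.0:
                        continue
                    mp = 1.0
                    for _ in range(chan_N[c, k]):
                        mp *= gate_m
                    hp = 1.0
                    for _ in range(chan_M[c, k]):
                        hp *= gate_h
                    cur = gmax * mp * hp * (vi - chan_E[c, k])
                    if mode == 1:
                        sat = ca[c, i] / kc_sat[c]
                        if sat > 1.0:
                            sat = 1.0
                        cur *= sat
                    if chan_casrc[c, k] == 1:
                        ca_cur += cur
                    ion += cur
                if ca_gain[c] > 0.0:
                    cai = ca[c, i]
                    cai += dt * (-cai / ca_tau[c] - ca_gain[c] * ca_cur)
                    if cai < 0.0:
                        cai = 0.0
                    ca[c, i] = cai
                ext = hold_nA[c]
                if stim_active and c == stim_cls:
                    for si in range(stim_idx.shape[0]):
                        if stim_idx[si] == i:
                            ext += stim_nA
                            break
                dvdt = ((ext - syn_acc[c, i]) * nA2dens - ion) / Cm[c]
                vnew = vi + dt * dvdt
                if not (-150.0 <= vnew <= 150.0):
                    return STATUS_BLOWUP, c, i, t
                if vi < SPIKE_THRESHOLD and vnew >= SPIKE_THRESHOLD \
                        and (t - last_spike[c, i]) > REFRACTORY:
                    last_spike[c, i] = t
                    cnt = spk_count[0]
                    if cnt < cap:
                        spk_cls[cnt] = c
                        spk_idx[cnt] = i
                        spk_t[cnt] = t
                        spk_count[0] = cnt + 1
                    for p in range(P):
                        if p_pre[p] == c:
                            pulse_end[p, i] = t + p_cdur[p]
                v[c, i] = vnew
    return STATUS_OK, -1, -1, 0.0
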