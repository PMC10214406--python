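"""Compiled inner loop of the spiking network simulation.

One call advances the whole network by a window of time steps with fixed
stimulus / feedback / dopamine-delivery settings.  The semantics per step
(identical to the composable numpy operations in :mod:`bgexplore.neurons`
and :mod:`bgexplore.plasticity`, which serve as the reference
implementation) are:

1. conductances decay by ``exp(-dt/tau_g)``, then this step's presynaptic
   spike weights are added (noise, feedback drive, cortex, and the spikes
   the network emitted on the previous step - one-step propagation delay);
2. membrane and recovery variables advance one forward-Euler step; neurons
   crossing ``vpeak`` spike and are reset;
3. plasticity traces decay and receive spike increments; spike-triggered
   eligibility / weight events and the continuous dopamine-gated weight
   terms are applied; weights are clipped to their bounds;
4. dopamine traces decay (or are set to R at the delivery step);
5. per-channel saccade integrators decay and accumulate SC spikes; the
   window ends early when an integrator crosses threshold.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_window"]


@njit(cache=True)
def run_window(
    T, dt,
    # membrane state and per-neuron parameters
    V, U, gA, gG,
    invC, n2, n1, n0, a, b, vr, vpk, vreset, dinc, Ibase,
    eA, eG, g_decay,
    # inputs: noise / feedback / cortex spike indicators and weights
    nse, wnx, nsi, wni,
    fb_sp, fb_idx, fb_w,
    ctx_sp,
    spk_prev,
    # connectivity
    Wexc, Winh, Wctx,
    Wsg, sg_gain, stn0, gpe0, n_pc,
    # cortical plasticity state and parameters
    Apre, Apost, E,
    d_pre, d_post, d_E, inc_pre, inc_post,
    alpha_col, sign_col, use_da_col, wmin_col, wmax_col, dnorm_col,
    plastic_ctx_on,
    # homeostatic STN->GPe state and parameters
    Ah, Abh,
    hom_decay, hom_dt_tauAbar, hom_deltaA, hom_eps,
    hom_wmax, hom_lo, hom_hi, hom_dt_tauw,
    plastic_sg_on,
    # dopamine traces [ctx, stn_gpe]
    da, da_decay_ctx, da_decay_sg, da_step, Rval,
    # integrators
    intv, int_decay, int_inc, int_thresh, stop_at_threshold,
    sc0, n_per, n_ch,
    # outputs
    counts, chan_index,
    raster, record_raster,
):
    N = V.shape[0]
    nctx = Wctx.shape[0]
    n_stn = Wsg.shape[0]
    n_gpe = Wsg.shape[1]
    spk_cur = np.zeros(N, dtype=np.uint8)
    sel = -1
    sel_step = -1

    for t in range(T):
        # 1. conductances: decay, then add this step's inputs
        for n in range(N):
            gA[n] *= g_decay
            gG[n] *= g_decay
            if nse[t, n]:
                gA[n] += wnx[n]
            if nsi[t, n]:
                gG[n] += wni[n]
        for k in range(fb_idx.shape[0]):
            if fb_sp[t, k]:
                gA[fb_idx[k]] += fb_w
        for i in range(nctx):
            if ctx_sp[t, i]:
                for n in range(N):
                    gA[n] += Wctx[i, n]
        for j in range(N):
            if spk_prev[j]:
                for n in range(N):
                    gA[n] += Wexc[j, n]
                    gG[n] += Winh[j, n]
        # STN spikes excite GPe through the plastic (nS-scale) matrix
        for s in range(n_stn):
            if spk_prev[stn0 + s]:
                for g in range(n_gpe):
                    gA[gpe0 + g] += Wsg[s, g] * sg_gain

        # 2. membrane step and spike/reset
        for n in range(N):
            Ia = Ibase[n] - gA[n] * (V[n] - eA) - gG[n] * (V[n] - eG)
            v = V[n]
            Vn = v + dt * (n2[n] * v * v + n1[n] * v + n0[n] - U[n] + Ia) * invC[n]
            Un = U[n] + dt * a[n] * (b[n] * (v - vr[n]) - U[n])
            if Vn >= vpk[n]:
                spk_cur[n] = 1
                V[n] = vreset[n]
                U[n] = Un + dinc[n]
                counts[t, chan_index[n]] += 1
                if record_raster:
                    raster[t, n] = 1
            else:
                spk_cur[n] = 0
                V[n] = Vn
                U[n] = Un

        # 3a. cortical STDP traces
        for i in range(nctx):
            Apre[i] *= d_pre
            if ctx_sp[t, i]:
                Apre[i] += inc_pre
        for n in range(N):
            Apost[n] *= d_post
            if spk_cur[n] and alpha_col[n] > 0.0:
                Apost[n] += inc_post
        if plastic_ctx_on:
            for i in range(nctx):
                for n in range(N):
                    E[i, n] *= d_E
            # eligibility events (dopamine-modulated columns) and direct
            # STDP jumps (plain-STDP columns)
            for n in range(N):
                if spk_cur[n] and alpha_col[n] > 0.0:
                    if use_da_col[n]:
                        for i in range(nctx):
                            E[i, n] += Apre[i]
                    else:
                        for i in range(nctx):
                            w = Wctx[i, n] + alpha_col[n] * Apre[i]
                            if w > wmax_col[n]:
                                w = wmax_col[n]
                            Wctx[i, n] = w
            for i in range(nctx):
                if ctx_sp[t, i]:
                    for n in range(N):
                        if alpha_col[n] > 0.0:
                            if use_da_col[n]:
                                E[i, n] -= Apost[n]
                                if dnorm_col[n] > 0.0:
                                    w = Wctx[i, n] - dnorm_col[n]
                                    Wctx[i, n] = w if w > wmin_col[n] else wmin_col[n]
                            else:
                                w = Wctx[i, n] - alpha_col[n] * Apost[n] - dnorm_col[n]
                                Wctx[i, n] = w if w > wmin_col[n] else wmin_col[n]

        # 3b. homeostatic traces (fast trace vs slow running mean)
        for n in range(N):
            Ah[n] *= hom_decay
            if spk_cur[n]:
                Ah[n] += hom_deltaA
            Abh[n] += hom_dt_tauAbar * (Ah[n] - Abh[n])

        # 4. dopamine decay / delivery
        if t == da_step:
            da[0] = Rval
            da[1] = Rval
        else:
            da[0] *= da_decay_ctx
            da[1] *= da_decay_sg

        # 3c. continuous dopamine-gated weight terms
        if plastic_ctx_on and (da[0] > 1e-9 or da[0] < -1e-9):
            for n in range(N):
                if use_da_col[n] and alpha_col[n] > 0.0:
                    coef = alpha_col[n] * sign_col[n] * da[0] * dt
                    for i in range(nctx):
                        w = Wctx[i, n] + coef * E[i, n]
                        if w < wmin_col[n]:
                            w = wmin_col[n]
                        elif w > wmax_col[n]:
                            w = wmax_col[n]
                        Wctx[i, n] = w
        if plastic_sg_on and da[1] > 1e-9:
            for s in range(n_stn):
                rpre = 1.0
                if Abh[stn0 + s] > 1e-12:
                    rpre = Ah[stn0 + s] / Abh[stn0 + s]
                dec_pre = hom_lo - rpre
                if dec_pre < 0.0:
                    dec_pre = 0.0
                inc_pre_h = rpre - hom_hi
                if inc_pre_h < 0.0:
                    inc_pre_h = 0.0
                for g in range(n_gpe):
                    rpost = 1.0
                    if Abh[gpe0 + g] > 1e-12:
                        rpost = Ah[gpe0 + g] / Abh[gpe0 + g]
                    dec_post = hom_lo - rpost
                    if dec_post < 0.0:
                        dec_post = 0.0
                    inc_post_h = rpost - hom_hi
                    if inc_post_h < 0.0:
                        inc_post_h = 0.0
                    ltp = dec_pre + hom_eps * dec_post
                    ltd = inc_pre_h + hom_eps * inc_post_h
                    w = Wsg[s, g]
                    frac = w / hom_wmax
                    w += da[1] * ((1.0 - frac) * ltp - frac * ltd) * hom_dt_tauw
                    if w < 0.0:
                        w = 0.0
                    elif w > hom_wmax:
                        w = hom_wmax
                    Wsg[s, g] = w

        # 5. integrators over SC spikes
        for c in range(n_ch):
            intv[c] *= int_decay
        for c in range(n_ch):
            base = sc0 + c * n_per
            for k in range(n_per):
                if spk_cur[base + k]:
                    intv[c] += int_inc
        if stop_at_threshold:
            for c in range(n_ch):
                if intv[c] >= int_thresh:
                    sel = c
                    sel_step = t
                    break
            if sel >= 0:
                for n in range(N):
                    spk_prev[n] = spk_cur[n]
                return sel, sel_step

        for n in range(N):
            spk_prev[n] = spk_cur[n]

    return sel, sel_step
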