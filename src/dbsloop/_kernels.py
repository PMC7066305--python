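"""Compiled numerical kernels for the network simulation.

All membrane equations are integrated with a fixed-step semi-implicit
scheme: gating variables advance by the exact exponential (Rush–Larsen)
update and the voltage equation by Crank–Nicolson, which for the
single-compartment cells reduces to a scalar linear solve and for the
multi-compartment cortical cell to a per-neuron tridiagonal (Thomas)
solve.  Conductances entering the voltage solve are evaluated at the
step start; synaptic and applied currents are folded in as
conductance/battery pairs so the update stays unconditionally stable
at the default 0.01 ms step.

Units: mV, ms, mS/cm², µA/cm², µF/cm².
"""

from __future__ import annotations

import numpy as np
from numba import njit

SPIKE_THRESHOLD = 0.0  # mV, upward crossing
REFRACTORY_MS = 1.0

# ---------------------------------------------------------------------------
# gating helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _sig(v, theta, k):
    return 1.0 / (1.0 + np.exp(-(v - theta) / k))


@njit(cache=True, inline="always")
def _exprelr(x):
    # x / (exp(x) - 1), stable near 0
    if abs(x) < 1e-7:
        return 1.0 - x / 2.0
    return x / (np.exp(x) - 1.0)


@njit(cache=True, inline="always")
def _rl(x, xinf, tau, dt):
    # Rush-Larsen exponential gating update
    return xinf + (x - xinf) * np.exp(-dt / tau)


@njit(cache=True, inline="always")
def _cn_single(v, g_tot, rhs, iapp, cm, dt):
    # Crank-Nicolson step of C v' = -g_tot v + rhs + iapp
    a = cm / dt
    return ((a - 0.5 * g_tot) * v + rhs + iapp) / (a + 0.5 * g_tot)


# ---------------------------------------------------------------------------
# STN cell (Rubin-Terman lineage; tonic firing, rebound/plateau bursts)
# ---------------------------------------------------------------------------

# parameter vector indices shared by the RT-style cells
# [gL, eL, gNa, eNa, gK, eK, gT, gCa, eCa, gAHP, k1, eps, kca,
#  phi_h, phi_n, phi_r, cm]


@njit(cache=True)
def stn_step(v, n, h, r, ca, gsyn, gesyn, iapp, dt, P, last_spike, t, spk):
    gL, eL, gNa, eNa, gK, eK, gT, gCa, eCa, gAHP, k1, eps, kca = (
        P[0], P[1], P[2], P[3], P[4], P[5], P[6], P[7], P[8], P[9], P[10], P[11], P[12],
    )
    phi_h, phi_n, phi_r, cm = P[13], P[14], P[15], P[16]
    for i in range(v.shape[0]):
        vi = v[i]
        minf = _sig(vi, -30.0, 15.0)
        hinf = _sig(vi, -39.0, -3.1)
        ninf = _sig(vi, -32.0, 8.0)
        rinf = _sig(vi, -67.0, -2.0)
        ainf = _sig(vi, -63.0, 7.8)
        sinf = _sig(vi, -39.0, 8.0)
        tau_h = 1.0 + 500.0 / (1.0 + np.exp((vi + 57.0) / 3.0))
        tau_n = 1.0 + 100.0 / (1.0 + np.exp((vi + 80.0) / 26.0))
        tau_r = 7.1 + 17.5 / (1.0 + np.exp((vi + 68.0) / 2.2))
        n[i] = _rl(n[i], ninf, tau_n / phi_n, dt)
        h[i] = _rl(h[i], hinf, tau_h / phi_h, dt)
        r[i] = _rl(r[i], rinf, tau_r / phi_r, dt)
        binf = _sig(r[i], 0.4, 0.1) - 1.0 / (1.0 + np.exp(4.0))
        if binf < 0.0:
            binf = 0.0
        g_na = gNa * minf * minf * minf * h[i]
        g_k = gK * n[i] ** 4
        g_t = gT * ainf * ainf * ainf * binf * binf
        g_ca = gCa * sinf * sinf
        g_ahp = gAHP * ca[i] / (ca[i] + k1)
        i_ca_like = (g_t + g_ca) * (vi - eCa)
        g_tot = gL + g_na + g_k + g_t + g_ca + g_ahp + gsyn[i]
        rhs = gL * eL + g_na * eNa + g_k * eK + (g_t + g_ca) * eCa + g_ahp * eK + gesyn[i]
        vnew = _cn_single(vi, g_tot, rhs, iapp[i], cm, dt)
        ca[i] += dt * eps * (-i_ca_like - kca * ca[i])
        if ca[i] < 0.0:
            ca[i] = 0.0
        spk[i] = False
        if vi < SPIKE_THRESHOLD <= vnew and t - last_spike[i] > REFRACTORY_MS:
            spk[i] = True
            last_spike[i] = t
        v[i] = vnew


# ---------------------------------------------------------------------------
# GPe / GPi cell (Rubin-Terman)
# ---------------------------------------------------------------------------


@njit(cache=True)
def gp_step(v, n, h, r, ca, gsyn, gesyn, iapp, dt, P, last_spike, t, spk):
    gL, eL, gNa, eNa, gK, eK, gT, gCa, eCa, gAHP, k1, eps, kca = (
        P[0], P[1], P[2], P[3], P[4], P[5], P[6], P[7], P[8], P[9], P[10], P[11], P[12],
    )
    phi_h, phi_n, phi_r, cm = P[13], P[14], P[15], P[16]
    for i in range(v.shape[0]):
        vi = v[i]
        minf = _sig(vi, -37.0, 10.0)
        hinf = _sig(vi, -58.0, -12.0)
        ninf = _sig(vi, -50.0, 14.0)
        rinf = _sig(vi, -70.0, -2.0)
        ainf = _sig(vi, -57.0, 2.0)
        sinf = _sig(vi, -35.0, 2.0)
        tau_hn = 0.05 + 0.27 / (1.0 + np.exp((vi + 40.0) / 12.0))
        n[i] = _rl(n[i], ninf, tau_hn / phi_n, dt)
        h[i] = _rl(h[i], hinf, tau_hn / phi_h, dt)
        r[i] = _rl(r[i], rinf, 30.0 / phi_r, dt)
        g_na = gNa * minf * minf * minf * h[i]
        g_k = gK * n[i] ** 4
        g_t = gT * ainf * ainf * ainf * r[i]
        g_ca = gCa * sinf * sinf
        g_ahp = gAHP * ca[i] / (ca[i] + k1)
        i_ca_like = (g_t + g_ca) * (vi - eCa)
        g_tot = gL + g_na + g_k + g_t + g_ca + g_ahp + gsyn[i]
        rhs = gL * eL + g_na * eNa + g_k * eK + (g_t + g_ca) * eCa + g_ahp * eK + gesyn[i]
        vnew = _cn_single(vi, g_tot, rhs, iapp[i], cm, dt)
        ca[i] += dt * eps * (-i_ca_like - kca * ca[i])
        if ca[i] < 0.0:
            ca[i] = 0.0
        spk[i] = False
        if vi < SPIKE_THRESHOLD <= vnew and t - last_spike[i] > REFRACTORY_MS:
            spk[i] = True
            last_spike[i] = t
        v[i] = vnew


# ---------------------------------------------------------------------------
# Thalamocortical relay cell (Rubin-Terman)
# ---------------------------------------------------------------------------

# P: [gL, eL, gNa, eNa, gK, eK, gT, eCa, cm]


@njit(cache=True)
def tha_step(v, h, r, gsyn, gesyn, iapp, dt, P, last_spike, t, spk):
    gL, eL, gNa, eNa, gK, eK, gT, eCa, cm = (
        P[0], P[1], P[2], P[3], P[4], P[5], P[6], P[7], P[8],
    )
    for i in range(v.shape[0]):
        vi = v[i]
        minf = _sig(vi, -37.0, 7.0)
        ah = 0.128 * np.exp(-(vi + 46.0) / 18.0)
        bh = 4.0 / (1.0 + np.exp(-(vi + 23.0) / 5.0))
        hinf = ah / (ah + bh)
        tau_h = 1.0 / (ah + bh)
        pinf = _sig(vi, -60.0, 6.2)
        rinf = _sig(vi, -84.0, -4.0)
        tau_r = 28.0 + np.exp(-(vi + 25.0) / 10.5)
        h[i] = _rl(h[i], hinf, tau_h, dt)
        r[i] = _rl(r[i], rinf, tau_r, dt)
        nk = 0.75 * (1.0 - h[i])
        g_na = gNa * minf * minf * minf * h[i]
        g_k = gK * nk ** 4
        g_t = gT * pinf * pinf * r[i]
        g_tot = gL + g_na + g_k + g_t + gsyn[i]
        rhs = gL * eL + g_na * eNa + g_k * eK + g_t * eCa + gesyn[i]
        vnew = _cn_single(vi, g_tot, rhs, iapp[i], cm, dt)
        spk[i] = False
        if vi < SPIKE_THRESHOLD <= vnew and t - last_spike[i] > REFRACTORY_MS:
            spk[i] = True
            last_spike[i] = t
        v[i] = vnew


# ---------------------------------------------------------------------------
# Cortical interneuron (fast-spiking, Pospischil lineage: leak + Na + Kd)
# ---------------------------------------------------------------------------

# P: [gL, eL, gNa, eNa, gK, eK, vT, cm]


@njit(cache=True, inline="always")
def _traub_na_k(vi, vT):
    am = 0.32 * 4.0 * _exprelr(-(vi - vT - 13.0) / 4.0)
    bm = 0.28 * 5.0 * _exprelr((vi - vT - 40.0) / 5.0)
    ah = 0.128 * np.exp(-(vi - vT - 17.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(vi - vT - 40.0) / 5.0))
    an = 0.032 * 5.0 * _exprelr(-(vi - vT - 15.0) / 5.0)
    bn = 0.5 * np.exp(-(vi - vT - 10.0) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def intn_step(v, m, h, n, gsyn, gesyn, iapp, dt, P, last_spike, t, spk):
    gL, eL, gNa, eNa, gK, eK, vT, cm = (
        P[0], P[1], P[2], P[3], P[4], P[5], P[6], P[7],
    )
    for i in range(v.shape[0]):
        vi = v[i]
        am, bm, ah, bh, an, bn = _traub_na_k(vi, vT)
        m[i] = _rl(m[i], am / (am + bm), 1.0 / (am + bm), dt)
        h[i] = _rl(h[i], ah / (ah + bh), 1.0 / (ah + bh), dt)
        n[i] = _rl(n[i], an / (an + bn), 1.0 / (an + bn), dt)
        g_na = gNa * m[i] ** 3 * h[i]
        g_k = gK * n[i] ** 4
        g_tot = gL + g_na + g_k + gsyn[i]
        rhs = gL * eL + g_na * eNa + g_k * eK + gesyn[i]
        vnew = _cn_single(vi, g_tot, rhs, iapp[i], cm, dt)
        spk[i] = False
        if vi < SPIKE_THRESHOLD <= vnew and t - last_spike[i] > REFRACTORY_MS:
            spk[i] = True
            last_spike[i] = t
        v[i] = vnew


# ---------------------------------------------------------------------------
# Cortical pyramidal cell: soma - AIS - axon(2) - collateral(3) chain
# ---------------------------------------------------------------------------
# Compartments: 0 soma (Na+Kd+M), 1 AIS, 2-3 main axon, 4-6 collateral
# (axonal compartments: Na + Kd + slowly inactivating D-type K, no M).
# P: [gL_s, eL, gNa_s, eNa, gK_s, eK, gM, tau_max, vT,
#    gL_a, gNa_a, gK_a, gD, cm]
# gax: coupling conductance per interface (6 values, mS/cm²)
# inva: inverse relative area per compartment — a coupling current into
#     compartment j is gax * inva[j] * (v_nb - v_j), so small axonal
#     nodes are driven strongly by the large soma but load it weakly.
# ve: extracellular potential per compartment (mV), coupled through the
#     neighbor differences (activating-function source term).


@njit(cache=True)
def ctx_step(
    v, m, h, n, p, d1, d2, gsyn, gesyn, bias, iapp_extra, ve, gax, inva, dt, P,
    last_soma, last_col, t, spk_soma, spk_col,
):
    gL_s, eL, gNa_s, eNa, gK_s, eK = P[0], P[1], P[2], P[3], P[4], P[5]
    gM, tau_max, vT = P[6], P[7], P[8]
    gL_a, gNa_a, gK_a, gD, cm = P[9], P[10], P[11], P[12], P[13]
    h_slow = P[14]
    ncomp = v.shape[1]
    a_ = np.empty(ncomp)
    b_ = np.empty(ncomp)
    c_ = np.empty(ncomp)
    d_ = np.empty(ncomp)
    for i in range(v.shape[0]):
        for j in range(ncomp):
            vi = v[i, j]
            am, bm, ah, bh, an, bn = _traub_na_k(vi, vT)
            m[i, j] = _rl(m[i, j], am / (am + bm), 1.0 / (am + bm), dt)
            tau_h = 1.0 / (ah + bh)
            if j > 0:
                tau_h *= h_slow  # slower axonal Na recovery: refractory limit
            h[i, j] = _rl(h[i, j], ah / (ah + bh), tau_h, dt)
            n[i, j] = _rl(n[i, j], an / (an + bn), 1.0 / (an + bn), dt)
            if j == 0:
                gna, gk, gl = gNa_s, gK_s, gL_s
            else:
                gna, gk, gl = gNa_a, gK_a, gL_a
            g_na = gna * m[i, j] ** 3 * h[i, j]
            g_k = gk * n[i, j] ** 4
            g_tot = gl + g_na + g_k
            rhs = gl * eL + g_na * eNa + g_k * eK
            if j == 0:
                # slow (M-type) potassium current, soma only
                pinf = 1.0 / (1.0 + np.exp(-(vi + 35.0) / 10.0))
                tp = tau_max / (
                    3.3 * np.exp((vi + 35.0) / 20.0) + np.exp(-(vi + 35.0) / 20.0)
                )
                p[i] = _rl(p[i], pinf, tp, dt)
                g_m = gM * p[i]
                g_tot += g_m + gsyn[i]
                rhs += g_m * eK + gesyn[i] + bias[i]
            else:
                # D-type potassium current, axonal compartments only
                d1inf = 1.0 / (1.0 + np.exp(-(vi + 43.0) / 8.0))
                d2inf = 1.0 / (1.0 + np.exp((vi + 67.0) / 7.3))
                d1[i, j] = _rl(d1[i, j], d1inf, 1.0, dt)
                d2[i, j] = _rl(d2[i, j], d2inf, 100.0, dt)
                g_d = gD * d1[i, j] * d2[i, j]
                g_tot += g_d
                rhs += g_d * eK
            rhs += iapp_extra[i, j]
            # extracellular coupling (explicit source term)
            if j > 0:
                rhs += gax[j - 1] * inva[j] * (ve[i, j - 1] - ve[i, j])
            if j < ncomp - 1:
                rhs += gax[j] * inva[j] * (ve[i, j + 1] - ve[i, j])
            # tridiagonal CN coefficients
            gl_c = gax[j - 1] * inva[j] if j > 0 else 0.0
            gr_c = gax[j] * inva[j] if j < ncomp - 1 else 0.0
            diag = cm / dt + 0.5 * (g_tot + gl_c + gr_c)
            a_[j] = -0.5 * gl_c
            c_[j] = -0.5 * gr_c
            b_[j] = diag
            fexp = -g_tot * vi + rhs
            if j > 0:
                fexp += gl_c * (v[i, j - 1] - vi)
            if j < ncomp - 1:
                fexp += gr_c * (v[i, j + 1] - vi)
            d_[j] = cm / dt * vi + 0.5 * fexp + 0.5 * rhs
        # Thomas solve
        for j in range(1, ncomp):
            w = a_[j] / b_[j - 1]
            b_[j] -= w * c_[j - 1]
            d_[j] -= w * d_[j - 1]
        vnew_last = d_[ncomp - 1] / b_[ncomp - 1]
        vprev = v[i, ncomp - 1]
        v[i, ncomp - 1] = vnew_last
        spk_col[i] = False
        if vprev < SPIKE_THRESHOLD <= vnew_last and t - last_col[i] > REFRACTORY_MS:
            spk_col[i] = True
            last_col[i] = t
        for j in range(ncomp - 2, -1, -1):
            vnew = (d_[j] - c_[j] * v[i, j + 1]) / b_[j]
            vprev = v[i, j]
            if j == 0:
                spk_soma[i] = False
                if vprev < SPIKE_THRESHOLD <= vnew and t - last_soma[i] > REFRACTORY_MS:
                    spk_soma[i] = True
                    last_soma[i] = t
            v[i, j] = vnew


# ---------------------------------------------------------------------------
# synapse kinetics
# ---------------------------------------------------------------------------


@njit(cache=True)
def syn_step(r, pulse_end, t, dt, alpha, beta):
    r_inf = alpha / (alpha + beta)
    tau = 1.0 / (alpha + beta)
    e_open = np.exp(-dt / tau)
    e_closed = np.exp(-beta * dt)
    for s in range(r.shape[0]):
        if t < pulse_end[s]:
            r[s] = r_inf + (r[s] - r_inf) * e_open
        else:
            r[s] *= e_closed


@njit(cache=True)
def syn_accumulate(r, post_idx, w, erev, gs, ges):
    for s in range(r.shape[0]):
        g = w * r[s]
        gs[post_idx[s]] += g
        ges[post_idx[s]] += g * erev


@njit(cache=True)
def syn_deliver(pre_spikes, pre_idx, pulse_end, t, transmitter_ms):
    for s in range(pre_idx.shape[0]):
        if pre_spikes[pre_idx[s]]:
            pulse_end[s] = t + transmitter_ms


# Short-term depression (release-resource) bookkeeping: on each
# arriving spike the transmitter pulse is scaled by the available
# resource x, which is depleted by a fraction u and recovers with
# tau_rec.  u = 0 disables depression for a projection.


# ---------------------------------------------------------------------------
# full-network chunk runner
# ---------------------------------------------------------------------------
# Advances the wired six-population network for n_steps with fixed DBS
# parameters, delivering delayed spikes through per-population ring
# buffers and accumulating the distance-weighted STN synaptic currents
# into the LFP trace.  Projection order and source ids are fixed by
# model.py.


@njit(cache=True)
def run_chunk(
    n_steps, dt, step0,
    # ctx
    vC, mC, hC, nC, pC, d1C, d2C, biasC, ctx_bias_extra, gaxC, invaC, PC,
    lastC, lastCol, ve_unit,
    # intn
    vI, mI, hI, nI, biasI, PI, lastI,
    # stn
    vS, nS, hS, rS, caS, biasS, PS, lastS,
    # gpe
    vG, nG, hG, rG, caG, biasG, PG, lastG, gpe_mask, gpe_pulse,
    # gpi
    vP, nP, hP, rP, caP, biasP, PP, lastP,
    # tha
    vT, hT, rT, biasT, PT, lastT,
    # synapses
    syn_pre, syn_post, syn_r, syn_pulse_end, syn_x, syn_scale,
    proj_off, proj_alpha, proj_beta, proj_erev, proj_w, proj_delay,
    proj_pre_src, proj_post_pop, proj_u_dep, proj_tau_rec, transmitter_ms,
    # inputs
    i_dbs, str_spk,
    # histories (uint8 [hist_len, n])
    h_ctx_soma, h_ctx_col, h_intn, h_stn, h_gpe, h_gpi, h_tha, hist_len,
    # outputs
    o_ctx_soma, o_ctx_col, o_intn, o_stn, o_gpe, o_gpi, o_tha,
    lfp_w, lfp_mono,
):
    n = vS.shape[0]
    nctx = vC.shape[0]
    ncomp = vC.shape[1]
    n_proj = proj_off.shape[0] - 1

    gs_ctx = np.zeros(nctx)
    ges_ctx = np.zeros(nctx)
    gs_intn = np.zeros(n)
    ges_intn = np.zeros(n)
    gs_stn = np.zeros(n)
    ges_stn = np.zeros(n)
    gs_gpe = np.zeros(n)
    ges_gpe = np.zeros(n)
    gs_gpi = np.zeros(n)
    ges_gpi = np.zeros(n)
    gs_tha = np.zeros(n)
    ges_tha = np.zeros(n)

    spkC = np.zeros(nctx, dtype=np.bool_)
    spkCol = np.zeros(nctx, dtype=np.bool_)
    spkI = np.zeros(n, dtype=np.bool_)
    spkS = np.zeros(n, dtype=np.bool_)
    spkG = np.zeros(n, dtype=np.bool_)
    spkP = np.zeros(n, dtype=np.bool_)
    spkT = np.zeros(n, dtype=np.bool_)

    bias_now = np.zeros(nctx)
    iapp_zero_ctx = np.zeros((nctx, ncomp))
    ve_now = np.zeros((nctx, ncomp))
    iapp_gpe = np.zeros(n)
    isyn_stn = np.zeros(n)

    # per-projection kinetic constants
    r_inf = np.empty(n_proj)
    e_open = np.empty(n_proj)
    e_closed = np.empty(n_proj)
    e_rec = np.empty(n_proj)
    for p in range(n_proj):
        a = proj_alpha[p]
        b = proj_beta[p]
        r_inf[p] = a / (a + b)
        e_open[p] = np.exp(-dt * (a + b))
        e_closed[p] = np.exp(-b * dt)
        e_rec[p] = np.exp(-dt / proj_tau_rec[p]) if proj_tau_rec[p] > 0 else 0.0

    for k in range(n_steps):
        g = step0 + k
        t = g * dt
        row_now = g % hist_len

        # 1) deliver delayed presynaptic spikes
        for p in range(n_proj):
            row = (g - proj_delay[p]) % hist_len
            src = proj_pre_src[p]
            for s in range(proj_off[p], proj_off[p + 1]):
                pre = syn_pre[s]
                if src == 0:
                    fired = h_ctx_soma[row, pre]
                elif src == 1:
                    fired = h_ctx_col[row, pre]
                elif src == 2:
                    fired = h_intn[row, pre]
                elif src == 3:
                    fired = h_stn[row, pre]
                elif src == 4:
                    fired = h_gpe[row, pre]
                elif src == 5:
                    fired = h_gpi[row, pre]
                elif src == 6:
                    fired = h_tha[row, pre]
                else:
                    fired = str_spk[k, pre]
                if fired == 1:
                    syn_pulse_end[s] = t + transmitter_ms
                    if proj_u_dep[p] > 0.0:
                        syn_scale[s] = syn_x[s]
                        syn_x[s] *= 1.0 - proj_u_dep[p]

        # 2) synapse kinetics and conductance accumulation
        for i in range(nctx):
            gs_ctx[i] = 0.0
            ges_ctx[i] = 0.0
        for i in range(n):
            gs_intn[i] = 0.0
            ges_intn[i] = 0.0
            gs_stn[i] = 0.0
            ges_stn[i] = 0.0
            gs_gpe[i] = 0.0
            ges_gpe[i] = 0.0
            gs_gpi[i] = 0.0
            ges_gpi[i] = 0.0
            gs_tha[i] = 0.0
            ges_tha[i] = 0.0
        for p in range(n_proj):
            w = proj_w[p]
            erev = proj_erev[p]
            tgt = proj_post_pop[p]
            dep = proj_u_dep[p] > 0.0
            for s in range(proj_off[p], proj_off[p + 1]):
                if t < syn_pulse_end[s]:
                    target = r_inf[p] * (syn_scale[s] if dep else 1.0)
                    syn_r[s] = target + (syn_r[s] - target) * e_open[p]
                else:
                    syn_r[s] *= e_closed[p]
                if dep:
                    syn_x[s] = 1.0 + (syn_x[s] - 1.0) * e_rec[p]
                gg = w * syn_r[s]
                post = syn_post[s]
                if tgt == 0:
                    gs_ctx[post] += gg
                    ges_ctx[post] += gg * erev
                elif tgt == 2:
                    gs_intn[post] += gg
                    ges_intn[post] += gg * erev
                elif tgt == 3:
                    gs_stn[post] += gg
                    ges_stn[post] += gg * erev
                elif tgt == 4:
                    gs_gpe[post] += gg
                    ges_gpe[post] += gg * erev
                elif tgt == 5:
                    gs_gpi[post] += gg
                    ges_gpi[post] += gg * erev
                else:
                    gs_tha[post] += gg
                    ges_tha[post] += gg * erev

        # 3) advance populations
        amp = i_dbs[k]
        for i in range(nctx):
            bias_now[i] = biasC[i] + ctx_bias_extra[k]
            for j in range(ncomp):
                ve_now[i, j] = ve_unit[i, j] * amp
        ctx_step(
            vC, mC, hC, nC, pC, d1C, d2C, gs_ctx, ges_ctx, bias_now,
            iapp_zero_ctx, ve_now, gaxC, invaC, dt, PC, lastC, lastCol, t,
            spkC, spkCol,
        )
        intn_step(vI, mI, hI, nI, gs_intn, ges_intn, biasI, dt, PI, lastI, t, spkI)
        stn_step(vS, nS, hS, rS, caS, gs_stn, ges_stn, biasS, dt, PS, lastS, t, spkS)
        for i in range(n):
            iapp_gpe[i] = biasG[i] + gpe_pulse[k] * gpe_mask[i]
        gp_step(vG, nG, hG, rG, caG, gs_gpe, ges_gpe, iapp_gpe, dt, PG, lastG, t, spkG)
        gp_step(vP, nP, hP, rP, caP, gs_gpi, ges_gpi, biasP, dt, PP, lastP, t, spkP)
        tha_step(vT, hT, rT, gs_tha, ges_tha, biasT, dt, PT, lastT, t, spkT)

        # 4) record spikes into histories and output rasters
        for i in range(nctx):
            h_ctx_soma[row_now, i] = 1 if spkC[i] else 0
            h_ctx_col[row_now, i] = 1 if spkCol[i] else 0
            o_ctx_soma[k, i] = h_ctx_soma[row_now, i]
            o_ctx_col[k, i] = h_ctx_col[row_now, i]
        for i in range(n):
            h_intn[row_now, i] = 1 if spkI[i] else 0
            h_stn[row_now, i] = 1 if spkS[i] else 0
            h_gpe[row_now, i] = 1 if spkG[i] else 0
            h_gpi[row_now, i] = 1 if spkP[i] else 0
            h_tha[row_now, i] = 1 if spkT[i] else 0
            o_intn[k, i] = h_intn[row_now, i]
            o_stn[k, i] = h_stn[row_now, i]
            o_gpe[k, i] = h_gpe[row_now, i]
            o_gpi[k, i] = h_gpi[row_now, i]
            o_tha[k, i] = h_tha[row_now, i]

        # 5) STN synaptic currents -> LFP (projections 0: ctx->stn, 1: gpe->stn)
        for i in range(n):
            isyn_stn[i] = 0.0
        for p in range(2):
            w = proj_w[p]
            erev = proj_erev[p]
            for s in range(proj_off[p], proj_off[p + 1]):
                post = syn_post[s]
                isyn_stn[post] += w * syn_r[s] * (vS[post] - erev)
        for c in range(2):
            acc = 0.0
            for i in range(n):
                acc += lfp_w[c, i] * isyn_stn[i]
            lfp_mono[c, k] = acc
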