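"""Compiled inner loop of the simulator.

One call advances the full coupled system (cable voltages, HH gates, Markov
occupancies, three Ca2+ systems, w/r switches, pump/Na state, synapses) a
given number of 25 us steps, recording sampled traces and full-rate spike
times.  The voltage solve is backward Euler on the (chain) cable with all
ohmic currents conductance-linearised at the new gate values; the GHK and
pump currents enter explicitly at the pre-step voltage.  Units inside the
membrane equation are uA/cm^2 (uF/cm^2 * mV/ms); the slow systems receive
currents converted to mA/cm^2.

This module is deliberately free of Python objects: the engine marshals a
`ModelConfig` into the flat arrays consumed here.
"""

import math

import numpy as np
from numba import njit

from .calcium import chan_influx
from .constants import FARADAY
from .hh_channels import (
    G_BKD_M, G_BKD_Z, G_BKS_H, G_BKS_M, G_BKS_Z, G_CAE_H, G_CAE_M,
    G_CAPD_M, G_CAPS_M, G_CAT_H, G_CAT_M, G_DR_M, G_IHD_M, G_IHS_M,
    G_K2_M, G_K2_Z, G_KA_H, G_KA_M, G_KD_H, G_KD_M, G_KF_H, G_KF_M,
    G_KMID_M, G_KM_M, G_KSLOW_M, G_SK_M,
    gate_inf_tau, gate_update, ghk_flux)
from .resurgent_na import step_occupancy_kernel

# channel-density row indices (order of config.CHANNEL_NAMES)
(C_NAR, C_CAP, C_CAT, C_CAE, C_KA, C_KD, C_KM, C_KDR, C_BK, C_K2,
 C_KFAST, C_KMID, C_KSLOW, C_IH, C_LEAK) = range(15)

SOMA_GATES = np.array([G_KF_M, G_KF_H, G_KMID_M, G_KSLOW_M, G_CAPS_M,
                       G_IHS_M, G_BKS_M, G_BKS_H, G_BKS_Z], dtype=np.int64)
DEND_GATES = np.array([G_CAT_M, G_CAT_H, G_CAE_M, G_CAE_H, G_CAPD_M,
                       G_IHD_M, G_KA_M, G_KA_H, G_KM_M, G_KD_M, G_KD_H,
                       G_DR_M, G_BKD_M, G_BKD_Z, G_K2_M, G_K2_Z, G_SK_M],
                      dtype=np.int64)


@njit(cache=True)
def _dend_rate_scale(gid, k_d_h):
    """Printed channel-specific update factors of the dendritic gates."""
    if gid == G_CAE_M:
        return 4.0
    elif gid == G_CAE_H:
        return 10.0
    elif gid == G_KD_M:
        return 10.0
    elif gid == G_KD_H:
        return k_d_h
    return 1.0


@njit(cache=True)
def init_gates(v, ca, zone, k_d_h):
    """Gate matrix at steady state for the given voltages."""
    n = len(v)
    gates = np.zeros((26, n))
    for i in range(n):
        if zone[i] == 0:
            for g in SOMA_GATES:
                inf, _ = gate_inf_tau(g, v[i], ca[i])
                gates[g, i] = inf
        else:
            for g in DEND_GATES:
                inf, _ = gate_inf_tau(g, v[i], ca[i])
                gates[g, i] = inf
    return gates


@njit(cache=True)
def run_sim(n_steps, dt, t0, soma_idx, smooth_slot,
            # mutable state
            v, gates, markov_p, ca, y, w, r,
            na_i_arr, na_buf, na_head_arr,
            syn_a, syn_b, syn_ptr,
            # morphology / passive
            zone, cm, area, diam, c_lo, c_hi,
            # channels
            gdens, ek, eh, el, eca_dend, e_na, k_d_h,
            # calcium / switches
            depth, soma_beta, soma_floor, kt_smooth, kd_smooth,
            kt_spiny, kd_spiny, tau_r, z_const,
            g_def, g_cf, taum_def, taum_cf, w_thresh, f_w, s_r,
            switch_on, gsk_off, gsk_protocol, y_unit, spiny_y,
            # pump
            pump_density, na_half, na_slope, na_floor, na_scale, d_soma,
            # synapses (may be empty)
            syn_target, syn_weight, syn_is_cf, syn_ev_steps, syn_ev_off,
            dec1, dec2,
            # recording
            sample_stride,
            v_out, ca_out, y_out, na_out, w_out, r_out, gsk_out, ipump_out,
            soma_spikes, dend_spikes, spike_counts,
            spike_thresh, refrac_ms, dend_thresh, dend_comp):
    n = len(v)
    n_syn = len(syn_target)
    n_smooth = len(y)
    e_rev_syn = 0.0

    # scratch
    g_syn_dens = np.zeros(n)       # mS/cm^2
    cf_syn_nA = np.zeros(n)        # nA, CF contacts only
    diag = np.zeros(n)
    rhs = np.zeros(n)
    cprime = np.zeros(n)
    dprime = np.zeros(n)

    si = soma_idx
    head = na_head_arr[0]
    na_i = na_i_arr[0]
    i_pump = pump_density / (1.0 + math.exp((na_half - na_i) / na_slope))

    n_soma_spk = spike_counts[0]
    n_dend_spk = spike_counts[1]
    refrac_steps = int(refrac_ms / dt)
    last_soma_spk = -10 * refrac_steps
    last_dend_spk = -10 * refrac_steps
    # peak tracking for soma spikes
    tracking = False
    track_end = -1
    best_v = -1e9
    best_t = 0.0
    prev_v_soma = v[si]
    prev_v_dend = v[dend_comp]
    dend_above_since = -1000000

    sample_i = 0
    for step in range(n_steps):
        t = t0 + step * dt
        prev_v_soma = v[si]
        prev_v_dend = v[dend_comp]

        # ------------------------------------------------ 1. synapses
        for i in range(n):
            g_syn_dens[i] = 0.0
            cf_syn_nA[i] = 0.0
        for s in range(n_syn):
            syn_a[s] *= dec1
            syn_b[s] *= dec2
            p = syn_ptr[s]
            while p < syn_ev_off[s + 1] and syn_ev_steps[p] <= step:
                if syn_ev_steps[p] == step:
                    syn_a[s] += syn_weight[s]
                    syn_b[s] += syn_weight[s]
                p += 1
            syn_ptr[s] = p
            g_uS = syn_b[s] - syn_a[s]
            if g_uS > 0.0:
                tgt = syn_target[s]
                g_syn_dens[tgt] += g_uS * 1e-3 / area[tgt]
                if syn_is_cf[s]:
                    cf_syn_nA[tgt] += g_uS * (v[tgt] - e_rev_syn)

        # ------------------------------------------------ 2. HH gates
        for i in range(n):
            if zone[i] == 0:
                for g in SOMA_GATES:
                    inf, tau = gate_inf_tau(g, v[i], ca[i])
                    gates[g, i] = gate_update(gates[g, i], inf, tau, dt, 1.0)
            else:
                for g in DEND_GATES:
                    inf, tau = gate_inf_tau(g, v[i], ca[i])
                    sc = _dend_rate_scale(g, k_d_h)
                    gates[g, i] = gate_update(gates[g, i], inf, tau, dt, sc)

        # ------------------------------------------------ 3. Markov step
        pnew = step_occupancy_kernel(markov_p, v[si], dt)
        for i in range(13):
            markov_p[i] = pnew[i]
        o_occ = markov_p[5]

        # ------------------------------------------------ 4. voltage solve
        for i in range(n):
            gt = g_syn_dens[i]                      # mS/cm^2
            ge = g_syn_dens[i] * e_rev_syn
            i_expl = 0.0                            # uA/cm^2, outward +
            if zone[i] == 0:
                gk = (gdens[C_KFAST, i] * gates[G_KF_M, i] ** 3
                      * gates[G_KF_H, i]
                      + gdens[C_KMID, i] * gates[G_KMID_M, i] ** 4
                      + gdens[C_KSLOW, i] * gates[G_KSLOW_M, i] ** 4
                      + gdens[C_BK, i] * gates[G_BKS_M, i] ** 3
                      * gates[G_BKS_Z, i] ** 2 * gates[G_BKS_H, i])
                gt += gk
                ge += gk * ek[i]
                gna = gdens[C_NAR, i] * o_occ
                gt += gna
                ge += gna * e_na
                gh = gdens[C_IH, i] * gates[G_IHS_M, i]
                gt += gh
                ge += gh * eh[i]
                gl = gdens[C_LEAK, i]
                gt += gl
                ge += gl * el[i]
                # GHK P-type Ca (explicit, mA/cm^2 -> uA/cm^2)
                i_expl += gdens[C_CAP, i] * gates[G_CAPS_M, i] \
                    * ghk_flux(v[i]) * 1e3
                # pump (outward, mA/cm^2 -> uA/cm^2)
                i_expl += i_pump * 1e3
            else:
                gca = (gdens[C_CAT, i] * gates[G_CAT_M, i] * gates[G_CAT_H, i]
                       + gdens[C_CAE, i] * gates[G_CAE_M, i]
                       * gates[G_CAE_H, i]
                       + gdens[C_CAP, i] * gates[G_CAPD_M, i])
                gt += gca
                ge += gca * eca_dend
                gk = (gdens[C_KA, i] * gates[G_KA_M, i] ** 4
                      * gates[G_KA_H, i]
                      + gdens[C_KM, i] * gates[G_KM_M, i]
                      + gdens[C_KD, i] * gates[G_KD_M, i] * gates[G_KD_H, i]
                      + gdens[C_KDR, i] * gates[G_DR_M, i] ** 4
                      + gdens[C_BK, i] * gates[G_BKD_M, i]
                      * gates[G_BKD_Z, i] ** 2
                      + gdens[C_K2, i] * gates[G_K2_M, i]
                      * gates[G_K2_Z, i] ** 2)
                if zone[i] == 1:
                    gsk = gsk_protocol if r[smooth_slot[i]] > switch_on \
                        else gsk_off
                    gk += gsk * 1e3 * gates[G_SK_M, i]
                gt += gk
                ge += gk * ek[i]
                gh = gdens[C_IH, i] * gates[G_IHD_M, i]
                gt += gh
                ge += gh * eh[i]
                gl = gdens[C_LEAK, i]
                gt += gl
                ge += gl * el[i]

            diag[i] = cm[i] / dt + gt + c_lo[i] + c_hi[i]
            rhs[i] = cm[i] / dt * v[i] + ge - i_expl

        # Thomas solve of the chain tridiagonal system
        cprime[0] = -c_hi[0] / diag[0]
        dprime[0] = rhs[0] / diag[0]
        for i in range(1, n):
            lower = -c_lo[i]
            denom = diag[i] - lower * cprime[i - 1]
            cprime[i] = -c_hi[i] / denom
            dprime[i] = (rhs[i] - lower * dprime[i - 1]) / denom
        v[n - 1] = dprime[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = dprime[i] - cprime[i] * v[i + 1]

        # ------------------------------------------------ 5. slow systems
        # soma shell (P-type GHK current, mA/cm^2)
        i_cap_soma = gdens[C_CAP, si] * gates[G_CAPS_M, si] * ghk_flux(v[si])
        dca = -(1e4 * i_cap_soma) / (2.0 * FARADAY * depth) \
            - soma_beta * ca[si]
        ca[si] += dt * dca
        if ca[si] < soma_floor:
            ca[si] = soma_floor

        for i in range(n):
            if i == si:
                continue
            ica = (gdens[C_CAT, i] * gates[G_CAT_M, i] * gates[G_CAT_H, i]
                   + gdens[C_CAE, i] * gates[G_CAE_M, i] * gates[G_CAE_H, i]
                   + gdens[C_CAP, i] * gates[G_CAPD_M, i]) \
                * (v[i] - eca_dend) * 1e-3          # mA/cm^2
            if zone[i] == 1:
                j = smooth_slot[i]
                yj = y[j]
                kt = kt_smooth
                kd = kd_smooth
            else:
                yj = spiny_y
                kt = kt_spiny
                kd = kd_spiny
            dca = chan_influx(ica, depth) - kt * ca[i] / (ca[i] + kd) \
                + (yj - ca[i]) / tau_r
            ca[i] += dt * dca
            if ca[i] < 1e-12:
                ca[i] = 1e-12
            if zone[i] == 1:
                j = smooth_slot[i]
                # w switch and live (g, tau_m)
                if ica < 0.0 and -ica > w_thresh:
                    w[j] = 1.0
                else:
                    w[j] *= math.exp(-dt / f_w)
                if w[j] > switch_on:
                    gy = g_cf
                    taumy = taum_cf
                else:
                    gy = g_def
                    taumy = taum_def
                influx = 0.0
                if ica < 0.0:
                    influx = -ica * y_unit / (4.0 * gy * diam[i] * FARADAY)
                y[j] += dt * (influx + (z_const - y[j]) / taumy)
                # r switch from CF synaptic current magnitude
                if abs(cf_syn_nA[i]) > 3.0:
                    r[j] = 1.0
                else:
                    r[j] *= math.exp(-dt / s_r)

        # pump / lagged Na+
        i_na_r = gdens[C_NAR, si] * o_occ * (v[si] - e_na) * 1e-3  # mA/cm^2
        i_pump_na = 3.0 * i_pump
        lagged = na_buf[head]
        na_buf[head] = i_na_r + i_pump_na
        head += 1
        if head == len(na_buf):
            head = 0
        na_i += dt * (-(lagged) * 4e4 * na_scale / (d_soma * FARADAY))
        if na_i < na_floor:
            na_i = na_floor
        i_pump = pump_density / (1.0 + math.exp((na_half - na_i) / na_slope))

        # ------------------------------------------------ 6. recording
        if step % sample_stride == 0 and sample_i < v_out.shape[0]:
            for i in range(n):
                v_out[sample_i, i] = v[i]
                ca_out[sample_i, i] = ca[i]
            for j in range(n_smooth):
                y_out[sample_i, j] = y[j]
                w_out[sample_i, j] = w[j]
                r_out[sample_i, j] = r[j]
            na_out[sample_i] = na_i
            ipump_out[sample_i] = i_pump
            gsk_out[sample_i] = gsk_protocol if r[0] > switch_on else gsk_off
            sample_i += 1

        # soma spikes: upward crossing then peak alignment
        if tracking:
            if v[si] > best_v:
                best_v = v[si]
                best_t = t + dt
            if step >= track_end:
                if n_soma_spk < len(soma_spikes):
                    soma_spikes[n_soma_spk] = best_t
                    n_soma_spk += 1
                tracking = False
        if not tracking and prev_v_soma < spike_thresh <= v[si] \
                and step - last_soma_spk > refrac_steps:
            tracking = True
            track_end = step + int(1.5 / dt)
            best_v = v[si]
            best_t = t + dt
            last_soma_spk = step

        # dendritic Ca spikes on the designated smooth compartment:
        # sustained (>= 3 ms) elevation above threshold, which rejects the
        # brief (< 2 ms) invasion of fast somatic Na spikes
        if v[dend_comp] >= dend_thresh:
            if prev_v_dend < dend_thresh:
                dend_above_since = step
            if (step - dend_above_since) * dt >= 3.0 \
                    and step - last_dend_spk > int(5.0 / dt):
                if n_dend_spk < len(dend_spikes):
                    dend_spikes[n_dend_spk] = t0 + dend_above_since * dt
                    n_dend_spk += 1
                last_dend_spk = step
        elif prev_v_dend >= dend_thresh:
            last_dend_spk = step    # refractory restarts on falling edge

    na_i_arr[0] = na_i
    na_head_arr[0] = head
    spike_counts[0] = n_soma_spk
    spike_counts[1] = n_dend_spk
    return sample_i
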