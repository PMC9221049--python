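"""Compiled simulation kernels.

One explicit-Euler step advances every cell and every coarse-grained calcium
release unit (CRU) of the network; the timestep is chosen adaptively each
step so that (a) the expected fraction of CRUs undergoing a channel
transition stays below the configured bound, (b) no single channel sees a
transition probability above ``pchan_max``, (c) the fastest continuous rate
(gap coupling, Na+ activation gate, subspace relaxation) is resolved, and
(d) the membrane potential moves by at most ~2 mV per step.

Everything here operates on flat float64/int64 arrays packed by
:mod:`cardionet.tissue`; the public modules wrap these kernels.  All
stochastic draws come from the per-unit counter-based streams in
:mod:`cardionet.rng`, so results are bit-reproducible under any update
order.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64, int64, float64, types

from .rng import counter_uniform, stream_ident
from .params import (
    P_C_SC, P_A_M, P_G_NA, P_NA_TAU_SCALE, P_NA_SHIFT, P_G_K1, P_G_KTOF, P_G_KTOS, P_G_KSS,
    P_I_NAK_MAX, P_KM_NAI_NAK, P_KM_KO_NAK,
    P_V_NCX, P_KM_NA_NCX, P_KM_CA_NCX, P_KM_CAI_NCX, P_KSAT_NCX, P_ETA_NCX,
    P_NCX_DYADIC_FRACTION, P_I_PMCA_MAX, P_KM_PMCA,
    P_G_B_CA, P_G_B_NA, P_G_B_K, P_NA_O, P_CA_O, P_K_O,
    P_V_MYO, P_V_NSR, P_V_JSR, P_V_SS, P_N_RYR, P_N_LCC,
    P_CMDN_TOT, P_CMDN_KON, P_CMDN_KOFF, P_TRPN_TOT, P_TRPN_KON, P_TRPN_KOFF,
    P_BULK_TOT, P_BULK_KON, P_BULK_KOFF,
    P_SERCA_VMAX, P_SERCA_KMF, P_SERCA_KMR, P_SERCA_H,
    P_RYR_K_PLUS, P_RYR_ETA, P_RYR_K_MINUS, P_RYR_COUPLING,
    P_RYR_K_OPEN_MAX, P_RYR_JSR_REF,
    P_LCC_G, P_LCC_EREV, P_LCC_TAU_D, P_LCC_VHALF_D, P_LCC_KSLOPE_D,
    P_LCC_TAU_F, P_LCC_VHALF_F, P_LCC_KSLOPE_F,
    P_LCC_K_CAM, P_LCC_K_CAM_MAX, P_LCC_K_CAM_REC,
    P_D_RYR, P_D_EFF, P_D_REFILL,
    P_BSS_TOT, P_BSS_KON, P_BSS_KOFF, P_BJSR_TOT, P_BJSR_KON, P_BJSR_KOFF,
    P_SL_CA_OFF, P_IONIC_OFF, P_CLAMP_NA_K,
    RTF,
)

# amount (uM*um^3/ms) carried per uA/cm^2 of current per cm^2 area per unit charge
_CONV_PER_AREA = 1.0364e7
# amount (uM*um^3/ms) per pA per unit charge
_CONV_PA = 5.1814
_VM_BLOWUP = 200.0  # mV

# diagnostics slots
D_NSTEPS, D_MAXFRAC, D_NCLIP, D_ERROR, D_CROSSTIME, D_MAXDVM, D_IREC, D_EVIDX = range(8)

ERR_NONE = 0.0
ERR_DT_UNDERFLOW = 1.0
ERR_VM_BLOWUP = 2.0


@njit(cache=True, inline="always")
def _safe_expm1_ratio(x):
    """x / (1 - exp(-0.1*x)) singularity-free helper for LR-style rates."""
    if abs(x) < 1e-6:
        return 10.0
    return x / (1.0 - np.exp(-0.1 * x))


@njit(types.Tuple((int64, uint64))(int64, float64, uint64, uint64, uint64),
      cache=True)
def binomial_counter(n, p, seed, ident, ctr):
    """Exact-inversion binomial sampler driven by one counter-based stream.

    Returns (k, advanced_counter).  For means above 50 with n > 128 a
    normal approximation with continuity correction is used (the exact
    path covers every single-cluster configuration).  Draws are skipped
    deterministically when the expected event count is below 1e-12.
    """
    if n <= 0 or p <= 0.0:
        return 0, ctr
    if p >= 1.0:
        return n, ctr
    flip = p > 0.5
    q = 1.0 - p if flip else p
    mean = n * q
    if mean < 1e-12:
        return (n if flip else 0), ctr
    if n <= 128 or mean <= 50.0:
        u = counter_uniform(seed, ident, ctr)
        ctr += uint64(1)
        f = np.exp(n * np.log1p(-q))
        cdf = f
        k = 0
        r = q / (1.0 - q)
        while u > cdf and k < n:
            k += 1
            f *= r * (n - k + 1) / k
            cdf += f
        if flip:
            k = n - k
        return k, ctr
    u1 = counter_uniform(seed, ident, ctr)
    ctr += uint64(1)
    u2 = counter_uniform(seed, ident, ctr)
    ctr += uint64(1)
    z = np.sqrt(-2.0 * np.log(u1 + 1e-300)) * np.cos(6.283185307179586 * u2)
    k = int(np.floor(mean + z * np.sqrt(mean * (1.0 - q)) + 0.5))
    if k < 0:
        k = 0
    elif k > n:
        k = n
    if flip:
        k = n - k
    return k, ctr


@njit(cache=True, inline="always")
def _p_trans(rate, dt):
    x = rate * dt
    if x < 1e-4:
        return x
    return -np.expm1(-x)


@njit(cache=True)
def ryr_rates(ca_ss, ca_jsr, n_open, sens, pp):
    """Per-channel RyR2 opening/closing rates (ms^-1).

    Opening: saturating power law in the effective activating Ca2+
    (cleft Ca2+ x linear lumen factor x phenotype sensitivity) times the
    mean-field coupling factor exp(+a*f_open); closing: base rate times
    exp(-a*f_open).  No Ca2+-dependent inactivation.
    """
    lumen = ca_jsr / pp[P_RYR_JSR_REF]
    if lumen < 0.0:
        lumen = 0.0
    ca_eff = ca_ss * lumen * sens
    eta = pp[P_RYR_ETA]
    if eta == 3.0:
        x = pp[P_RYR_K_PLUS] * ca_eff * ca_eff * ca_eff
    elif eta == 2.0:
        x = pp[P_RYR_K_PLUS] * ca_eff * ca_eff
    else:
        x = pp[P_RYR_K_PLUS] * ca_eff ** eta
    kmax = pp[P_RYR_K_OPEN_MAX]
    k_open = kmax * x / (kmax + x)
    if n_open == 0:
        return k_open, pp[P_RYR_K_MINUS]
    f_open = n_open / pp[P_N_RYR]
    a = pp[P_RYR_COUPLING]
    k_open *= np.exp(a * f_open)
    k_close = pp[P_RYR_K_MINUS] * np.exp(-a * f_open)
    return k_open, k_close


@njit(cache=True)
def lcc_voltage_rates(vm, pp):
    """Voltage-dependent L-type rates: (alpha C->O, beta O->C, kvi ->VI, krec VI->C)."""
    d_inf = 1.0 / (1.0 + np.exp(-(vm - pp[P_LCC_VHALF_D]) / pp[P_LCC_KSLOPE_D]))
    f_inf = 1.0 / (1.0 + np.exp((vm - pp[P_LCC_VHALF_F]) / pp[P_LCC_KSLOPE_F]))
    alpha = d_inf / pp[P_LCC_TAU_D]
    beta = (1.0 - d_inf) / pp[P_LCC_TAU_D]
    kvi = (1.0 - f_inf) / pp[P_LCC_TAU_F]
    krec = f_inf / pp[P_LCC_TAU_F]
    return alpha, beta, kvi, krec


@njit(cache=True)
def lcc_cam_rate(ca_ss, pp):
    """Ca2+-calmodulin inactivation rate of the open L-type channel (ms^-1)."""
    k = pp[P_LCC_K_CAM] * ca_ss
    kmax = pp[P_LCC_K_CAM_MAX]
    return kmax * k / (kmax + k)


@njit(cache=True)
def gate_rates(vm, na_tau_scale=1.0, na_shift=0.0):
    """Deterministic gating-variable rates.

    Returns (am, bm, ah, bh, aj, bj,
             atof_inf, tau_atof, itof_inf, tau_itof,
             atos_inf, tau_atos, itos_inf, tau_itos, akss_inf, tau_akss).
    Fast Na+ kinetics follow the classic cardiac Hodgkin-Huxley m3hj scheme;
    K+ transient-outward kinetics are rodent-like inf/tau formulations.
    """
    vna = vm - na_shift
    am = 0.32 * _safe_expm1_ratio(vna + 47.13)
    bm = 0.08 * np.exp(-vna / 11.0)
    if vna >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(vna + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * vna) / (1.0 + np.exp(-0.1 * (vna + 32.0)))
    else:
        ah = 0.135 * np.exp(-(80.0 + vna) / 6.8)
        bh = 3.56 * np.exp(0.079 * vna) + 3.1e5 * np.exp(0.35 * vna)
        aj = ((-1.2714e5 * np.exp(0.2444 * vna) - 3.474e-5 * np.exp(-0.04391 * vna))
              * (vna + 37.78) / (1.0 + np.exp(0.311 * (vna + 79.23))))
        bj = 0.1212 * np.exp(-0.01052 * vna) / (1.0 + np.exp(-0.1378 * (vna + 40.14)))
    a_inf = 1.0 / (1.0 + np.exp(-(vm + 22.5) / 7.7))
    i_inf = 1.0 / (1.0 + np.exp((vm + 45.2) / 5.7))
    am /= na_tau_scale
    bm /= na_tau_scale
    ah /= na_tau_scale
    bh /= na_tau_scale
    aj /= na_tau_scale
    bj /= na_tau_scale
    tau_atof = 0.493 * np.exp(-0.0629 * vm) + 2.058
    tau_itof = 4.0 + 25.0 / (1.0 + np.exp((vm + 45.2) / 5.7))
    tau_atos = 2.0 * tau_atof
    tau_itos = 270.0 + 1050.0 / (1.0 + np.exp((vm + 45.2) / 5.7))
    tau_akss = 39.3 * np.exp(-0.0862 * vm) + 13.17
    return (am, bm, ah, bh, aj, bj,
            a_inf, tau_atof, i_inf, tau_itof,
            a_inf, tau_atos, i_inf, tau_itos, a_inf, tau_akss)


@njit(cache=True)
def cell_currents(pp, vm, cai, cansr, nai, ki,
                  m, h, j, atof, itof, atos, itos, akss,
                  ca_sensed, sc_ito, sc_ik1, sc_ncx):
    """All deterministic sarcolemmal current densities (uA/cm^2, inward < 0).

    Returns (ina, ik1, iktof, iktos, ikss, inak, incx, ipmca, ibca, ibna, ibk).
    ``ca_sensed`` is the NCX-weighted Ca2+ (dyadic fraction x mean subspace
    Ca2+ plus the bulk remainder).
    """
    ena = RTF * np.log(pp[P_NA_O] / nai)
    ek = RTF * np.log(pp[P_K_O] / ki)
    eca = 0.5 * RTF * np.log(pp[P_CA_O] / max(cai, 1e-6))

    ina = pp[P_G_NA] * m * m * m * h * j * (vm - ena)

    dvk = vm - ek
    ik1 = (sc_ik1 * pp[P_G_K1] * (pp[P_K_O] / (pp[P_K_O] + 0.21))
           * dvk / (1.0 + np.exp(0.0896 * dvk)))
    iktof = sc_ito * pp[P_G_KTOF] * atof ** 3 * itof * dvk
    iktos = sc_ito * pp[P_G_KTOS] * atos * itos * dvk
    ikss = pp[P_G_KSS] * akss * dvk

    sigma = (np.exp(pp[P_NA_O] / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vm / RTF)
                  + 0.0365 * sigma * np.exp(-vm / RTF))
    inak = (pp[P_I_NAK_MAX] * fnak
            / (1.0 + (pp[P_KM_NAI_NAK] / nai) ** 1.5)
            * pp[P_K_O] / (pp[P_K_O] + pp[P_KM_KO_NAK]))

    eta = pp[P_ETA_NCX]
    e1 = np.exp(eta * vm / RTF)
    e2 = np.exp((eta - 1.0) * vm / RTF)
    nao3 = pp[P_NA_O] ** 3
    denom = ((pp[P_KM_NA_NCX] ** 3 + nao3) * (pp[P_KM_CA_NCX] + pp[P_CA_O])
             * (1.0 + pp[P_KSAT_NCX] * e2))
    incx = (sc_ncx * pp[P_V_NCX]
            * (e1 * nai ** 3 * pp[P_CA_O] - e2 * nao3 * ca_sensed) / denom)

    ipmca = pp[P_I_PMCA_MAX] * cai / (cai + pp[P_KM_PMCA])

    ibca = pp[P_G_B_CA] * (vm - eca)
    ibna = pp[P_G_B_NA] * (vm - ena)
    ibk = pp[P_G_B_K] * (vm - ek)
    if pp[P_SL_CA_OFF] != 0.0:
        incx = 0.0
        ipmca = 0.0
        ibca = 0.0
    return ina, ik1, iktof, iktos, ikss, inak, incx, ipmca, ibca, ibna, ibk


@njit(cache=True)
def serca_flux(cai, cansr, scale, pp):
    """Reversible SERCA2a uptake (uM/ms referenced to myoplasmic volume)."""
    f = (cai / pp[P_SERCA_KMF]) ** pp[P_SERCA_H]
    r = (cansr / pp[P_SERCA_KMR]) ** pp[P_SERCA_H]
    return scale * pp[P_SERCA_VMAX] * (f - r) / (1.0 + f + r)


@njit(cache=True)
def advance(pp, sc, mult,
            vm, cai, cansr, nai, ki, gates, bufm,
            ryr_o, lcc, cass, cajsr, bss, bjsr, vssf, ctr,
            e0, e1, gg, gsum,
            stim_cell, stim_amp, stim_on, stim_off,
            ev_time, ev_cell, ev_cru, ev_nch,
            bounds,
            seed, t_start, t_end, dt_min, dt_max, frac_max, pchan_max,
            rec_dt, rec_t, rec_vm, rec_cai, rec_cansr, rec_ryrf, rec_casm,
            act_t, watch_cell, stop_grace, fail_t0, fail_window,
            sc_dvm, sc_cder, sc_gr, sc_ko, sc_kc, sc_kcam, sc_lccr,
            sc_coup, sc_iapp, sc_qeff, sc_qref, sc_mcass, sc_nlcc,
            diag):
    """Advance the network from t_start until t_end (or early stop).

    Mutates all state arrays in place.  ``diag`` carries step counts, the
    maximum expected CRU-transition fraction over accepted steps, clip
    counts, error codes, the watch-cell crossing time, and the recording /
    event cursors (so the integration can be resumed seamlessly).
    """
    n = vm.shape[0]
    K = ryr_o.shape[1]
    n_units = n * K if K > 0 else 1
    n_ryr = int(pp[P_N_RYR])
    n_lcc_ch = int(pp[P_N_LCC])
    ionic_off = pp[P_IONIC_OFF] != 0.0
    sl_ca_off = pp[P_SL_CA_OFF] != 0.0
    clamp_nak = pp[P_CLAMP_NA_K] != 0.0
    fdyad = pp[P_NCX_DYADIC_FRACTION]
    conv = pp[P_A_M] * _CONV_PER_AREA  # amount per (uA/cm^2) per unit charge
    inv_csc = 1.0 / pp[P_C_SC]
    couple_fac = 1.0e-6 / pp[P_A_M]  # nS*mV -> uA/cm^2
    v_myo = pp[P_V_MYO]
    v_nsr = pp[P_V_NSR]
    v_jsr = pp[P_V_JSR]
    v_ss0 = pp[P_V_SS]
    krec_cam = pp[P_LCC_K_CAM_REC]
    # constant continuous-rate ceiling: subspace relaxation + buffer on-rates
    r_const = pp[P_D_EFF] / v_ss0 + pp[P_BSS_KON] * pp[P_BSS_TOT] \
        + pp[P_BULK_KON] * pp[P_BULK_TOT]
    kd_jsr = pp[P_BJSR_KOFF] / pp[P_BJSR_KON]
    bjsr_tot = pp[P_BJSR_TOT]
    max_gsum_rate = 0.0
    for c in range(n):
        r = couple_fac * gsum[c] * inv_csc
        if r > max_gsum_rate:
            max_gsum_rate = r

    t = t_start
    last_act = fail_t0
    irec = int(diag[D_IREC])
    ev_idx = int(diag[D_EVIDX])
    n_rec_max = rec_t.shape[0]
    n_bounds = bounds.shape[0]
    cross_t = diag[D_CROSSTIME]
    eps = 1e-9

    # record the initial sample if it is already due (run start / resume)
    if irec < n_rec_max and t >= rec_t[irec] - eps:
        for c in range(n):
            rec_vm[irec, c] = vm[c]
            rec_cai[irec, c] = cai[c]
            rec_cansr[irec, c] = cansr[c]
            sro = 0.0
            scs = 0.0
            for u in range(K):
                sro += ryr_o[c, u]
                scs += cass[c, u]
            if K > 0:
                rec_ryrf[irec, c] = sro / (K * n_ryr)
                rec_casm[irec, c] = scs / K
            else:
                rec_ryrf[irec, c] = 0.0
                rec_casm[irec, c] = 0.0
        irec += 1

    while t < t_end - eps:
        # --- phase A: rates, currents, derivatives (read-only) ---
        for c in range(n):
            sc_coup[c] = 0.0
            sc_iapp[c] = 0.0
            sc_qeff[c] = 0.0
            sc_qref[c] = 0.0
            sc_mcass[c] = 0.0
            sc_nlcc[c] = 0.0
        for e in range(e0.shape[0]):
            a = e0[e]
            b = e1[e]
            w = gg[e] * (vm[b] - vm[a])
            sc_coup[a] += w
            sc_coup[b] -= w
        for s in range(stim_cell.shape[0]):
            if t >= stim_on[s] - eps and t < stim_off[s] - eps:
                sc_iapp[stim_cell[s]] += stim_amp[s]

        r_exit_sum = 0.0
        r_chan_max = 0.0
        max_gate_rate = 0.0
        max_abs_dvm = 0.0
        for c in range(n):
            # unit-level rates and accumulators
            for u in range(K):
                no = ryr_o[c, u]
                ko, kc = ryr_rates(cass[c, u], cajsr[c, u], no, sc[c, 4], pp)
                kcam = lcc_cam_rate(cass[c, u], pp)
                sc_ko[c, u] = ko
                sc_kc[c, u] = kc
                sc_kcam[c, u] = kcam
                sc_mcass[c] += cass[c, u] / (1.0 + cass[c, u] / pp[P_KM_CAI_NCX])
                sc_qeff[c] += pp[P_D_EFF] * (cass[c, u] - cai[c])
                sc_qref[c] += pp[P_D_REFILL] * (cansr[c] - cajsr[c, u])
                sc_nlcc[c] += lcc[c, u, 1]
            al, be, kvi, krec = lcc_voltage_rates(vm[c], pp)
            sc_lccr[c, 0] = al
            sc_lccr[c, 1] = be
            sc_lccr[c, 2] = kvi
            sc_lccr[c, 3] = krec
            for u in range(K):
                no = ryr_o[c, u]
                r_u = ((n_ryr - no) * sc_ko[c, u] + no * sc_kc[c, u]
                       + lcc[c, u, 0] * (al + kvi)
                       + lcc[c, u, 1] * (be + kvi + sc_kcam[c, u])
                       + lcc[c, u, 2] * krec
                       + lcc[c, u, 3] * krec_cam)
                r_exit_sum += r_u
                rcm = sc_ko[c, u]
                if sc_kc[c, u] > rcm:
                    rcm = sc_kc[c, u]
                oc = be + kvi + sc_kcam[c, u]
                if oc > rcm:
                    rcm = oc
                cc = al + kvi
                if cc > rcm:
                    rcm = cc
                if rcm > r_chan_max:
                    r_chan_max = rcm

            mcass = sc_mcass[c] / K if K > 0 else cai[c]
            coup_dens = couple_fac * sc_coup[c]

            if ionic_off:
                dvm = (-sc_iapp[c]) * inv_csc + coup_dens * inv_csc
                for q in range(7):
                    sc_cder[c, q] = 0.0
            else:
                g = gates[c]
                cai_sat = cai[c] / (1.0 + cai[c] / pp[P_KM_CAI_NCX])
                ca_sensed = fdyad * mcass + (1.0 - fdyad) * cai_sat
                (ina, ik1, iktof, iktos, ikss, inak, incx, ipmca,
                 ibca, ibna, ibk) = cell_currents(
                    pp, vm[c], cai[c], cansr[c], nai[c], ki[c],
                    g[0], g[1], g[2], g[3], g[4], g[5], g[6], g[7],
                    ca_sensed, sc[c, 0], sc[c, 1], sc[c, 2])
                i_dhpr = 0.0
                if not sl_ca_off:
                    i_dhpr = (sc_nlcc[c] * mult * pp[P_LCC_G]
                              * (vm[c] - pp[P_LCC_EREV]) * 1.0e-6 / pp[P_A_M])
                i_ion = (ina + ik1 + iktof + iktos + ikss + inak + incx
                         + ipmca + ibca + ibna + ibk + i_dhpr)
                dvm = (-(i_ion + sc_iapp[c]) + coup_dens) * inv_csc

                gr = gate_rates(vm[c], pp[P_NA_TAU_SCALE], pp[P_NA_SHIFT])
                for q in range(16):
                    sc_gr[c, q] = gr[q]
                if gr[0] + gr[1] > max_gate_rate:
                    max_gate_rate = gr[0] + gr[1]

                jser = serca_flux(cai[c], cansr[c], sc[c, 3], pp)
                amt_ca = (incx * conv - 0.5 * ipmca * conv - 0.5 * ibca * conv)
                dcmdn = pp[P_CMDN_KON] * cai[c] * (pp[P_CMDN_TOT] - bufm[c, 0]) \
                    - pp[P_CMDN_KOFF] * bufm[c, 0]
                dtrpn = pp[P_TRPN_KON] * cai[c] * (pp[P_TRPN_TOT] - bufm[c, 1]) \
                    - pp[P_TRPN_KOFF] * bufm[c, 1]
                dbulk = pp[P_BULK_KON] * cai[c] * (pp[P_BULK_TOT] - bufm[c, 2]) \
                    - pp[P_BULK_KOFF] * bufm[c, 2]
                dcai = ((mult * sc_qeff[c] + amt_ca) / v_myo - jser
                        - dcmdn - dtrpn - dbulk)
                dcansr = (jser * v_myo - mult * sc_qref[c]) / v_nsr
                if clamp_nak:
                    dnai = 0.0
                    dki = 0.0
                else:
                    dnai = (-(ina + ibna) * conv - 3.0 * incx * conv
                            - 3.0 * inak * conv) / v_myo / 1000.0
                    dki = (-(ik1 + iktof + iktos + ikss + ibk) * conv
                           + 2.0 * inak * conv) / v_myo / 1000.0
                sc_cder[c, 0] = dcai
                sc_cder[c, 1] = dcansr
                sc_cder[c, 2] = dnai
                sc_cder[c, 3] = dki
                sc_cder[c, 4] = dcmdn
                sc_cder[c, 5] = dtrpn
                sc_cder[c, 6] = dbulk
            sc_dvm[c] = dvm
            av = abs(dvm)
            if av > max_abs_dvm:
                av, max_abs_dvm = max_abs_dvm, av

        # --- timestep selection ---
        dt = dt_max
        if r_exit_sum > 0.0:
            d = frac_max * n_units / r_exit_sum
            if d < dt:
                dt = d
        if r_chan_max > 0.0:
            d = pchan_max / r_chan_max
            if d < dt:
                dt = d
        r_cont = r_const
        if max_gate_rate > r_cont:
            r_cont = max_gate_rate
        if max_gsum_rate > r_cont:
            r_cont = max_gsum_rate
        if r_cont > 0.0:
            d = 0.5 / r_cont
            if d < dt:
                dt = d
        if max_abs_dvm > 0.0:
            d = 2.0 / max_abs_dvm
            if d < dt:
                dt = d
        if dt < dt_min:
            diag[D_ERROR] = ERR_DT_UNDERFLOW
            break
        # clamp to the next boundary (records, events, stimulus edges, t_end)
        t_next = t_end
        if irec < n_rec_max and rec_t[irec] < t_next:
            t_next = rec_t[irec]
        if ev_idx < ev_time.shape[0] and ev_time[ev_idx] < t_next:
            t_next = ev_time[ev_idx]
        for q in range(n_bounds):
            if bounds[q] > t + eps:
                if bounds[q] < t_next:
                    t_next = bounds[q]
                break
        if t + dt > t_next - eps:
            dt = t_next - t
            if dt <= 0.0:
                dt = eps
        frac = r_exit_sum * dt / n_units
        if frac > diag[D_MAXFRAC]:
            diag[D_MAXFRAC] = frac
        if max_abs_dvm * inv_csc > diag[D_MAXDVM]:
            diag[D_MAXDVM] = max_abs_dvm * inv_csc

        # --- phase B: apply updates ---
        # units first: their fluxes must see the same pre-update cell state
        # that the cell derivatives were computed from (exact conservation)
        vm_step_max = -1e30
        ryr_open_sum = 0.0
        for c in range(n):
            al = sc_lccr[c, 0]
            be = sc_lccr[c, 1]
            kvi = sc_lccr[c, 2]
            krec = sc_lccr[c, 3]
            for u in range(K):
                ident = stream_ident(uint64(c), uint64(u), uint64(0))
                cc = ctr[c, u]
                # continuous dyad update (reads state at step start)
                no = ryr_o[c, u]
                v_ss_u = v_ss0 * vssf[c, u]
                q_ryr = pp[P_D_RYR] * no * (cajsr[c, u] - cass[c, u])
                q_lcc = 0.0
                if not sl_ca_off:
                    q_lcc = -(pp[P_LCC_G] * (vm[c] - pp[P_LCC_EREV])) \
                        * _CONV_PA * 0.5 * lcc[c, u, 1]
                q_eff = pp[P_D_EFF] * (cass[c, u] - cai[c])
                q_ref = pp[P_D_REFILL] * (cansr[c] - cajsr[c, u])
                dbss = pp[P_BSS_KON] * cass[c, u] * (pp[P_BSS_TOT] - bss[c, u]) \
                    - pp[P_BSS_KOFF] * bss[c, u]
                cass[c, u] += dt * ((q_ryr + q_lcc - q_eff) / v_ss_u - dbss)
                bss[c, u] += dt * dbss
                # junctional SR: buffer in rapid equilibrium on the total
                tj = cajsr[c, u] + bjsr[c, u] + dt * (q_ref - q_ryr) / v_jsr
                if tj < 0.0:
                    tj = 0.0
                    diag[D_NCLIP] += 1.0
                bb = bjsr_tot + kd_jsr - tj
                disc = np.sqrt(bb * bb + 4.0 * kd_jsr * tj)
                if bb > 0.0:
                    fj = 2.0 * kd_jsr * tj / (bb + disc)
                else:
                    fj = 0.5 * (disc - bb)
                cajsr[c, u] = fj
                bjsr[c, u] = tj - fj
                if cass[c, u] < 0.0:
                    cass[c, u] = 0.0
                    diag[D_NCLIP] += 1.0
                # stochastic transitions (tau-leap with exact per-channel prob)
                ko = sc_ko[c, u]
                kc = sc_kc[c, u]
                p_open = _p_trans(ko, dt)
                p_close = _p_trans(kc, dt)
                n_opened, cc = binomial_counter(n_ryr - no, p_open, seed, ident, cc)
                n_closed, cc = binomial_counter(no, p_close, seed, ident, cc)
                ryr_o[c, u] = no + n_opened - n_closed
                ryr_open_sum += ryr_o[c, u]
                # LCC: C exits (alpha -> O, kvi -> VI)
                kcam = sc_kcam[c, u]
                nC = lcc[c, u, 0]
                nO = lcc[c, u, 1]
                nVI = lcc[c, u, 2]
                nCaI = lcc[c, u, 3]
                rC = al + kvi
                dC_O = 0
                dC_VI = 0
                if nC > 0 and rC > 0.0:
                    nx, cc = binomial_counter(nC, _p_trans(rC, dt), seed, ident, cc)
                    if nx > 0:
                        dC_O, cc = binomial_counter(nx, al / rC, seed, ident, cc)
                        dC_VI = nx - dC_O
                rO = be + kvi + kcam
                dO_C = 0
                dO_VI = 0
                dO_CaI = 0
                if nO > 0 and rO > 0.0:
                    nx, cc = binomial_counter(nO, _p_trans(rO, dt), seed, ident, cc)
                    if nx > 0:
                        dO_C, cc = binomial_counter(nx, be / rO, seed, ident, cc)
                        rem = nx - dO_C
                        if rem > 0 and kvi + kcam > 0.0:
                            dO_VI, cc = binomial_counter(
                                rem, kvi / (kvi + kcam), seed, ident, cc)
                            dO_CaI = rem - dO_VI
                dVI_C = 0
                if nVI > 0 and krec > 0.0:
                    dVI_C, cc = binomial_counter(
                        nVI, _p_trans(krec, dt), seed, ident, cc)
                dCaI_C = 0
                if nCaI > 0 and krec_cam > 0.0:
                    dCaI_C, cc = binomial_counter(
                        nCaI, _p_trans(krec_cam, dt), seed, ident, cc)
                lcc[c, u, 0] = nC - dC_O - dC_VI + dO_C + dVI_C + dCaI_C
                lcc[c, u, 1] = nO + dC_O - dO_C - dO_VI - dO_CaI
                lcc[c, u, 2] = nVI + dC_VI + dO_VI - dVI_C
                lcc[c, u, 3] = nCaI + dO_CaI - dCaI_C
                ctr[c, u] = cc

            vold = vm[c]
            vm[c] = vold + dt * sc_dvm[c]
            if vm[c] > vm_step_max:
                vm_step_max = vm[c]
            if act_t[c] < 0.0 and vold <= 0.0 < vm[c]:
                act_t[c] = t + dt * (0.0 - vold) / (vm[c] - vold)
                last_act = t + dt
            if abs(vm[c]) > _VM_BLOWUP:
                diag[D_ERROR] = ERR_VM_BLOWUP
            if not ionic_off:
                cai[c] += dt * sc_cder[c, 0]
                cansr[c] += dt * sc_cder[c, 1]
                nai[c] += dt * sc_cder[c, 2]
                ki[c] += dt * sc_cder[c, 3]
                bufm[c, 0] += dt * sc_cder[c, 4]
                bufm[c, 1] += dt * sc_cder[c, 5]
                bufm[c, 2] += dt * sc_cder[c, 6]
                if cai[c] < 0.0:
                    cai[c] = 0.0
                    diag[D_NCLIP] += 1.0
                if cansr[c] < 0.0:
                    cansr[c] = 0.0
                    diag[D_NCLIP] += 1.0
                # gates: explicit Euler on alpha/beta or inf/tau forms
                g = gates[c]
                g[0] += dt * (sc_gr[c, 0] * (1.0 - g[0]) - sc_gr[c, 1] * g[0])
                g[1] += dt * (sc_gr[c, 2] * (1.0 - g[1]) - sc_gr[c, 3] * g[1])
                g[2] += dt * (sc_gr[c, 4] * (1.0 - g[2]) - sc_gr[c, 5] * g[2])
                for q in range(5):
                    gi = 3 + q
                    inf = sc_gr[c, 6 + 2 * q]
                    tau = sc_gr[c, 7 + 2 * q]
                    g[gi] += dt * (inf - g[gi]) / tau
                for q in range(8):
                    if g[q] < 0.0:
                        g[q] = 0.0
                    elif g[q] > 1.0:
                        g[q] = 1.0

        t += dt
        diag[D_NSTEPS] += 1.0
        if diag[D_ERROR] != ERR_NONE:
            break

        # --- events: forced RyR2 openings ---
        while ev_idx < ev_time.shape[0] and ev_time[ev_idx] <= t + eps:
            c = ev_cell[ev_idx]
            u = ev_cru[ev_idx]
            if ryr_o[c, u] < ev_nch[ev_idx]:
                ryr_o[c, u] = ev_nch[ev_idx]
            ev_idx += 1

        # --- recording ---
        if irec < n_rec_max and t >= rec_t[irec] - eps:
            for c in range(n):
                rec_vm[irec, c] = vm[c]
                rec_cai[irec, c] = cai[c]
                rec_cansr[irec, c] = cansr[c]
                sro = 0.0
                scs = 0.0
                for u in range(K):
                    sro += ryr_o[c, u]
                    scs += cass[c, u]
                if K > 0:
                    rec_ryrf[irec, c] = sro / (K * n_ryr)
                    rec_casm[irec, c] = scs / K
                else:
                    rec_ryrf[irec, c] = 0.0
                    rec_casm[irec, c] = 0.0
            irec += 1

        # --- early stop when the network is quiescent and nothing fired ---
        if fail_window > 0.0 and t > fail_t0 + fail_window \
                and t - last_act > fail_window and vm_step_max < -40.0 \
                and ryr_open_sum < 0.002 * n_ryr * n_units:
            break

        # --- early stop on watched-cell activation ---
        if watch_cell >= 0 and cross_t < 0.0 and act_t[watch_cell] >= 0.0:
            cross_t = act_t[watch_cell]
            diag[D_CROSSTIME] = cross_t
            te = cross_t + stop_grace
            if te < t_end:
                t_end = te

    diag[D_IREC] = irec
    diag[D_EVIDX] = ev_idx
    return t
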