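"""Calibration of the whole-cell model to its physiological contract.

The ionic-current formulations are standard Hodgkin-Huxley-style rat
ventricular components; what pins the free maximal conductances is a small
contract rather than any single published rate constant:

* resting potential near -80 mV with zero net current and zero net
  species flux (quiescent leak balance),
* a rapid-upstroke, rat-like (short) action potential,
* 1-D conduction velocity 0.36 m/s at 2500 nS gap conductance and
  100 um cell length,
* the printed 1-D excitation facts: seven end-cells suffice for the slow
  equal-charge stimulus while five do not.

:func:`resting_balance` solves the quiescent balance in closed form;
:func:`calibrate_conduction` tunes the Na+ conductance to the velocity
target.  The shipped defaults in :mod:`cardionet.params` are the output of
``cardionet calibrate`` (see scripts in the CLI).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import _engine
from .params import ModelParams, pack_params, RTF
from .tissue import NetworkState, TimestepPolicy, build_lattice, run_network
from .myocyte import initialize_quiescent
from .protocols import (make_stimulus, stimulus_rows, detect_propagation,
                        measure_conduction_velocity)

__all__ = ["resting_balance", "measure_cv", "single_cell_ap",
           "calibrate_conduction", "run_calibration"]


def _rest_currents(params: ModelParams, vm: float, cai: float, nai: float,
                   ki: float, cansr: float):
    pp = pack_params(params)
    gr = _engine.gate_rates(vm)
    m = gr[0] / (gr[0] + gr[1])
    h = gr[2] / (gr[2] + gr[3])
    jg = gr[4] / (gr[4] + gr[5])
    gates = (m, h, jg, gr[6], gr[8], gr[10], gr[12], gr[14])
    cai_sat = cai / (1.0 + cai / params.membrane.km_cai_ncx)
    return _engine.cell_currents(pp, vm, cai, cansr, nai, ki, *gates,
                                 cai_sat, 1.0, 1.0, 1.0)


def resting_balance(params: ModelParams, vm_rest: float = -80.0,
                    cai_rest: float = 0.1, nai_rest: float = 10.0,
                    ki_rest: float = 140.0,
                    cansr_rest: float = 1000.0) -> ModelParams:
    """Solve (g_b_ca, g_b_na, i_nak_max) so the target rest is a fixed point.

    Zeroing the Na+, K+ and Ca2+ species balances at the target state also
    zeroes the total membrane current (the species decomposition is exact),
    so Vm, the bulk concentrations and the SR load are all stationary up to
    the stochastic RyR2 leak.
    """
    mp = params.membrane
    (ina, ik1, iktof, iktos, ikss, inak_u, incx, ipmca,
     _, _, _) = _rest_currents(
        replace(params, membrane=replace(mp, i_nak_max=1.0)),
        vm_rest, cai_rest, nai_rest, ki_rest, cansr_rest)
    eca = 0.5 * RTF * np.log(mp.ca_o / cai_rest)
    ena = RTF * np.log(mp.na_o / nai_rest)
    ek = RTF * np.log(mp.k_o / ki_rest)
    # Ca: NCX influx (per unit charge, one Ca) balances PMCA + background
    g_b_ca = 2.0 * (incx - 0.5 * ipmca) / (vm_rest - eca)
    # K: 2 K in per pump cycle balances the K-current efflux
    ibk = mp.g_b_k * (vm_rest - ek)
    inak_req = (ik1 + iktof + iktos + ikss + ibk) / 2.0
    i_nak_max = inak_req / inak_u
    # Na: background influx balances pump + NCX-coupled + fast-Na efflux
    g_b_na = (-ina - 3.0 * incx - 3.0 * inak_req) / (vm_rest - ena)
    if g_b_ca <= 0 or g_b_na <= 0 or i_nak_max <= 0:
        raise ValueError(
            f"no physical rest solution: g_b_ca={g_b_ca:.3g}, "
            f"g_b_na={g_b_na:.3g}, i_nak_max={i_nak_max:.3g}")
    return replace(params, membrane=replace(
        mp, g_b_ca=float(g_b_ca), g_b_na=float(g_b_na),
        i_nak_max=float(i_nak_max)))


def single_cell_ap(params: ModelParams, seed: int = 3, n_cru: int = 100,
                   multiplicity: int = 200, settle_ms: float = 500.0,
                   t_end: float = 150.0):
    """One stimulated beat of a settled cell; returns (times, vm, metrics)."""
    st = initialize_quiescent(params, seed=seed, n_cru=n_cru,
                              multiplicity=multiplicity, settle_ms=settle_ms,
                              check=False)
    nw = st.network
    t0 = nw.t
    res = run_network(nw, None, TimestepPolicy(), t0 + t_end,
                      stim_rows=[(0, -16.3, t0 + 5.0, t0 + 7.0)],
                      record_dt=0.25)
    vm = res.vm[:, 0]
    t = res.time - t0
    v_rest = vm[0]
    v_peak = float(vm.max())
    apd90 = float("nan")
    if v_peak > 0:
        v90 = v_peak - 0.9 * (v_peak - v_rest)
        above = np.nonzero(vm > v90)[0]
        if above.size:
            apd90 = float(t[above[-1]] - t[above[0]])
    dvdt_max = float(np.max(np.diff(vm) / np.diff(t)))
    return t, vm, {"v_rest": float(v_rest), "v_peak": v_peak,
                   "apd90": apd90, "dvdt_max": dvdt_max}


def measure_cv(params: ModelParams, n_cells: int = 80, g_gap: float = 2500.0,
               n_stim: int = 10, seed: int = 7, n_cru: int = 50,
               multiplicity: int = 400, settle_ms: float = 500.0,
               cell_length_um: float = 100.0, t_end: float = 60.0):
    """Conduction velocity (m/s) on a cable with a suprathreshold end stimulus."""
    geom = build_lattice((n_cells,), g_long=g_gap,
                         cell_length_um=cell_length_um)
    tpl = initialize_quiescent(params, seed=11, n_cru=n_cru,
                               multiplicity=multiplicity, settle_ms=settle_ms,
                               check=False).network
    nw = NetworkState(n_cells, params, seed, n_cru=n_cru,
                      multiplicity=multiplicity)
    nw.broadcast_cell(tpl)
    proto = make_stimulus("instantaneous", range(n_stim), onset=2.0)
    res = run_network(nw, geom, TimestepPolicy(), t_end,
                      stim_rows=stimulus_rows(proto), record_dt=1.0,
                      watch_cell=n_cells - 1, stop_grace=5.0)
    out = detect_propagation(res, geom, stim_cells=proto.target_cells)
    if not out.success:
        return None
    return measure_conduction_velocity(res, geom)


def calibrate_conduction(params: ModelParams, target_cv: float = 0.36,
                         tol: float = 0.01, max_iter: int = 8,
                         verbose: bool = False) -> ModelParams:
    """Tune g_na (secant steps) until the cable velocity meets the target."""
    p = params
    g = p.membrane.g_na
    cv = measure_cv(p)
    if cv is None:
        raise RuntimeError("cable did not propagate at the starting g_na")
    if verbose:
        print(f"g_na={g:.3f} -> CV={cv:.4f}")
    if abs(cv - target_cv) <= tol:
        return p
    g_prev, cv_prev = g, cv
    g = g * (target_cv / cv) ** 2
    best = (abs(cv - target_cv), p)
    for _ in range(max_iter):
        cand = replace(p, membrane=replace(p.membrane, g_na=float(g)))
        cv = measure_cv(cand)
        if cv is None:
            # lost propagation: back off toward the last working conductance
            g = 0.5 * (g + g_prev)
            continue
        if verbose:
            print(f"g_na={g:.3f} -> CV={cv:.4f}")
        if abs(cv - target_cv) < best[0]:
            best = (abs(cv - target_cv), cand)
        if abs(cv - target_cv) <= tol:
            return cand
        if abs(cv - cv_prev) > 1e-6:
            g_new = g + (target_cv - cv) * (g - g_prev) / (cv - cv_prev)
        else:
            g_new = g
        g_prev, cv_prev = g, cv
        g = float(np.clip(g_new, 0.25 * g, 4.0 * g))
    return best[1]


def run_calibration(params: ModelParams | None = None,
                    verbose: bool = True) -> ModelParams:
    """Full calibration pass: quiescent balance, then conduction velocity."""
    p = params or ModelParams()
    p = resting_balance(p)
    if verbose:
        mp = p.membrane
        print(f"rest solve: g_b_ca={mp.g_b_ca:.4g} g_b_na={mp.g_b_na:.4g} "
              f"i_nak_max={mp.i_nak_max:.4g}")
    p = calibrate_conduction(p, verbose=verbose)
    if verbose:
        print(f"calibrated g_na={p.membrane.g_na:.4g}")
    return p
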