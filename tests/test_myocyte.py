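"""Whole-cell model: currents, SERCA, coupling, phenotype, quiescence."""

import math

import numpy as np
import pytest
from dataclasses import replace

from cardionet.params import (ModelParams, MembraneParams, Phenotype,
                              CONTROL_PHENOTYPE, HF_PHENOTYPE, RTF)
from cardionet.myocyte import (MyocyteState, compute_currents, serca_flux,
                               membrane_derivative, step_myocyte,
                               apply_phenotype, initialize_quiescent)
from cardionet.tissue import NetworkState, TimestepPolicy, run_network


def _quiet_cell(params=None, n_cru=20, mult=1000, seed=4):
    nw = NetworkState(1, params or ModelParams(), seed, n_cru=n_cru,
                      multiplicity=mult)
    return MyocyteState(nw)


# --- currents ---------------------------------------------------------------

def test_k_currents_vanish_at_reversal():
    st = _quiet_cell()
    ek = RTF * math.log(5.4 / 140.0)
    st.network.vm[0] = ek
    st.network.gates[0, 3:] = 1.0       # K gates open
    cur = compute_currents(st)
    assert cur.i_k1 == pytest.approx(0.0, abs=1e-12)
    assert cur.i_kss == pytest.approx(0.0, abs=1e-12)
    assert cur.i_ktof == pytest.approx(0.0, abs=1e-12)


def test_background_currents_are_ohmic():
    st = _quiet_cell()
    p = st.network.params.membrane
    ena = RTF * math.log(p.na_o / st.na_i)
    c1 = compute_currents(st)
    st.network.vm[0] += 10.0
    c2 = compute_currents(st)
    g_eff = (c2.i_bg_na - c1.i_bg_na) / 10.0
    assert g_eff == pytest.approx(p.g_b_na, rel=1e-9)
    assert c1.i_bg_na == pytest.approx(p.g_b_na * (-80.0 - ena), rel=1e-9)


def test_ncx_forward_mode_with_elevated_subspace_ca():
    """Active release at resting Vm drives a large inward NCX current."""
    st = _quiet_cell()
    rest = compute_currents(st).i_ncx
    st.network.cass[0, :] = 200.0        # release active in every unit
    active = compute_currents(st).i_ncx
    assert active < rest < 0.1
    assert active < -1.0                 # strongly inward (forward mode)


def test_ncx_dyadic_split_weighted_sum():
    st = _quiet_cell()
    st.network.cass[0, :] = 150.0
    cur = compute_currents(st)
    f = st.network.params.membrane.ncx_dyadic_fraction
    # the split reassembles into the configured weighting
    assert cur.i_ncx == pytest.approx(cur.i_ncx_dyad + cur.i_ncx_bulk)
    assert cur.i_ncx_dyad / f < 0       # dyadic part inward when Ca is high


def test_resting_current_balance():
    """At the calibrated rest the net membrane current is ~0 (<0.05 uA/cm2)."""
    st = _quiet_cell()
    nw = st.network
    nw.vm[0] = -80.0
    nw.cai[0] = 0.1
    nw.cansr[0] = 1000.0
    nw.nai[0] = 10.0
    nw.ki[0] = 140.0
    nw.cass[0, :] = 0.1
    cur = compute_currents(st)
    assert abs(cur.total()) < 0.05


def test_nonfinite_state_rejected():
    st = _quiet_cell()
    st.network.vm[0] = float("nan")
    with pytest.raises(ValueError):
        compute_currents(st)


# --- SERCA ------------------------------------------------------------------

def test_serca_equilibrium_point(params):
    c = params.cell
    ratio = c.serca_kmr / c.serca_kmf
    assert serca_flux(0.1, 0.1 * ratio) == pytest.approx(0.0, abs=1e-15)


def test_serca_monotone_and_reversible(params):
    assert serca_flux(1.0, 500.0) > serca_flux(0.3, 500.0) > 0
    assert serca_flux(0.3, 500.0) > serca_flux(0.3, 900.0)
    assert serca_flux(0.05, 2000.0) < 0  # reverse (leak) mode


def test_serca_scales_linearly(params):
    j1 = serca_flux(0.5, 800.0, scale=1.0)
    assert serca_flux(0.5, 800.0, scale=0.7) == pytest.approx(0.7 * j1)


# --- membrane derivative ----------------------------------------------------

def test_derivative_zero_without_currents():
    st = _quiet_cell()
    from cardionet.myocyte import CurrentSet
    assert membrane_derivative(st, CurrentSet()) == 0.0


def test_coupling_sign_and_mismatch():
    st = _quiet_cell()
    from cardionet.myocyte import CurrentSet
    d = membrane_derivative(st, CurrentSet(), [0.0], [2500.0])
    assert d > 0  # a depolarized neighbour depolarizes the resting cell
    with pytest.raises(ValueError):
        membrane_derivative(st, CurrentSet(), [0.0], [2500.0, 100.0])


def test_two_cell_passive_exponential_decay():
    """Coupled passive cells equilibrate as exp(-t/tau), tau = Csc*Am/2G."""
    p = replace(ModelParams(), ionic_currents_off=True)
    nw = NetworkState(2, p, 1, n_cru=0, multiplicity=1)
    nw.vm[0], nw.vm[1] = -60.0, -80.0
    from cardionet.tissue import build_lattice
    geom = build_lattice((2,), g_long=2500.0)
    mp = p.membrane
    tau = mp.c_sc * mp.a_m / (2.0 * 2500.0 * 1e-6)  # ms
    t_end = 3.0 * tau
    pol = TimestepPolicy(dt_max=min(5e-3, tau / 200.0))
    res = run_network(nw, geom, pol, t_end, record_dt=t_end)
    dv0, dv1 = 20.0, nw.vm[0] - nw.vm[1]
    expected = dv0 * math.exp(-t_end / tau)
    assert dv1 == pytest.approx(expected, rel=0.01)
    # total charge is conserved by antisymmetric gap currents
    assert nw.vm.sum() == pytest.approx(-140.0, abs=1e-9)


# --- stepping ---------------------------------------------------------------

def test_step_zero_dt_is_identity():
    st = _quiet_cell()
    vm0 = st.vm
    out = step_myocyte(st, 0.0)
    assert out.vm == vm0


def test_gates_stay_in_unit_interval():
    st = _quiet_cell()
    step_myocyte(st, 5.0)
    g = st.gating
    assert np.all(g >= 0.0) and np.all(g <= 1.0)


def test_step_convergence_in_dt():
    """Halving dt_max changes the Vm trajectory by < 0.5 mV RMS.

    Channel gating is frozen (zero transition rates, zero unitary flux) so
    the comparison isolates the Euler error of the continuous subsystem;
    with live gating a different step sequence draws different spark
    realizations, which is reproducibility, not convergence.
    """
    from cardionet.params import GatingRateParams
    g = GatingRateParams(ryr_k_plus=0.0, ryr_k_minus=0.0, lcc_g=0.0)
    p = ModelParams(gating=g)
    traces = []
    for dtm in (5e-3, 2.5e-3):
        nw = NetworkState(1, p, 6, n_cru=20, multiplicity=1000)
        pol = TimestepPolicy(dt_max=dtm)
        res = run_network(nw, None, pol, 40.0,
                          stim_rows=[(0, -16.3, 2.0, 4.0)], record_dt=0.5,
                          config=None)
        traces.append(res.vm[:, 0])
    n = min(len(traces[0]), len(traces[1]))
    rms = float(np.sqrt(np.mean((traces[0][:n] - traces[1][:n]) ** 2)))
    assert rms < 0.5, f"dt-halving RMS {rms:.3f} mV"


# --- phenotype --------------------------------------------------------------

def test_control_phenotype_is_identity():
    nw = NetworkState(3, ModelParams(), 2, n_cru=40, multiplicity=500)
    apply_phenotype(nw, CONTROL_PHENOTYPE)
    assert np.allclose(nw.scales, 1.0)
    assert np.all(nw.vssf == 1.0)


def test_hf_phenotype_orphans_exact_quarter():
    nw = NetworkState(2, ModelParams(), 2, n_cru=200, multiplicity=100)
    apply_phenotype(nw, HF_PHENOTYPE)
    for c in range(2):
        assert int((nw.vssf[c] > 1.0).sum()) == 50   # 25% of 200
        assert np.all(nw.vssf[c][nw.vssf[c] > 1.0] == 30.0)
    assert np.allclose(nw.scales[:, 0], 0.8)   # I_to
    assert np.allclose(nw.scales[:, 1], 0.8)   # I_K1
    assert np.allclose(nw.scales[:, 2], 2.0)   # NCX
    assert np.allclose(nw.scales[:, 3], 0.7)   # SERCA
    assert np.allclose(nw.scales[:, 4], 1.5)   # RyR2 sensitivity


def test_orphan_selection_seed_reproducible():
    a = NetworkState(1, ModelParams(), 7, n_cru=200, multiplicity=100)
    b = NetworkState(1, ModelParams(), 7, n_cru=200, multiplicity=100)
    c = NetworkState(1, ModelParams(), 8, n_cru=200, multiplicity=100)
    for nw in (a, b, c):
        apply_phenotype(nw, HF_PHENOTYPE)
    assert np.array_equal(a.vssf, b.vssf)
    assert not np.array_equal(a.vssf, c.vssf)


def test_invalid_orphan_fraction():
    with pytest.raises(ValueError):
        Phenotype(orphan_fraction=1.5)


# --- quiescent initialisation ----------------------------------------------

def test_initialize_quiescent_resting_range():
    st = initialize_quiescent(seed=2, n_cru=30, multiplicity=667,
                              settle_ms=600.0)
    assert -85.0 <= st.vm <= -75.0
    assert 0.03 <= st.ca_myo <= 0.3


def test_quiescent_all_conductances_zero_holds_vm():
    mp = MembraneParams(g_na=0, g_k1=0, g_ktof=0, g_ktos=0, g_kss=0,
                        i_nak_max=0, v_ncx=0, i_pmca_max=0, g_b_ca=0,
                        g_b_na=0, g_b_k=0)
    p = replace(ModelParams(), membrane=mp)
    nw = NetworkState(1, p, 3, n_cru=0, multiplicity=1)
    nw.vm[0] = -73.0
    run_network(nw, None, TimestepPolicy(), 20.0, record_dt=20.0)
    assert nw.vm[0] == pytest.approx(-73.0, abs=1e-6)
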