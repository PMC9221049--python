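"""Geometry construction, adaptive timestep, network integration."""

import numpy as np
import pytest
from dataclasses import replace

import networkx as nx

from cardionet.params import ModelParams
from cardionet.tissue import (build_lattice, build_trabecula, NetworkState,
                              TimestepPolicy, select_adaptive_dt, step_tissue,
                              run_network, total_calcium, SimulationError)


# --- lattice construction ---------------------------------------------------

def test_cable_edges():
    g = build_lattice((200,), g_long=2500.0)
    assert g.n_cells == 200
    assert g.n_edges == 199
    assert np.all(g.g_gap == 2500.0)
    assert np.all(g.neighbor_counts() <= 2)


def test_single_cell_lattice_has_no_edges():
    g = build_lattice((1, 1))
    assert g.n_edges == 0


def test_sheet_edge_counts_and_anisotropy():
    g = build_lattice((100, 100), g_long=2500.0, g_trans=800.0)
    assert g.n_edges == 2 * 100 * 99
    assert int((g.axis == 0).sum()) == 9900
    assert int((g.axis == 1).sum()) == 9900
    assert np.all(g.g_gap[g.axis == 0] == 2500.0)
    assert np.all(g.g_gap[g.axis == 1] == 800.0)
    assert np.all(g.neighbor_counts() <= 4)


def test_block_neighbor_bound():
    g = build_lattice((5, 5, 5))
    assert np.all(g.neighbor_counts() <= 6)


def test_invalid_dims():
    with pytest.raises(ValueError):
        build_lattice((0,))
    with pytest.raises(ValueError):
        build_lattice(())


def test_edges_unique_and_no_self_loops():
    g = build_lattice((4, 3))
    pairs = {tuple(sorted(e)) for e in zip(g.e0, g.e1)}
    assert len(pairs) == g.n_edges
    assert np.all(g.e0 != g.e1)


# --- trabecula ---------------------------------------------------------------

def test_trabecula_published_dimensions():
    g = build_trabecula()
    assert g.n_cells == 20 ** 3 + 6 * 6 * 7 + 4 * 4 * 6 + 2 * 2 * 5 == 8368


def test_trabecula_connected():
    g = build_trabecula()
    G = nx.Graph()
    G.add_nodes_from(range(g.n_cells))
    G.add_edges_from(zip(g.e0.tolist(), g.e1.tolist()))
    assert nx.is_connected(G)


def test_trabecula_empty_segments_is_cube():
    g = build_trabecula(segment_dims_list=())
    cube = build_lattice((20, 20, 20))
    assert g.n_cells == cube.n_cells
    assert g.n_edges == cube.n_edges


def test_trabecula_overhang_rejected():
    with pytest.raises(ValueError):
        build_trabecula(cube_dims=(4, 4, 4), segment_dims_list=((6, 6, 3),))


# --- adaptive timestep -------------------------------------------------------

def test_quiescent_network_takes_dt_max():
    nw = NetworkState(4, ModelParams(), 1, n_cru=10, multiplicity=2000)
    pol = TimestepPolicy(dt_max=2.0e-3)   # below the stability ceiling
    geom = build_lattice((4,))
    assert select_adaptive_dt(nw, pol, geom) == pol.dt_max


def test_transition_rule_binds_and_scales():
    """dt halves when every CRU exit rate doubles (fraction rule regime)."""
    nw = NetworkState(1, ModelParams(), 1, n_cru=50, multiplicity=400)
    # put every cluster mid-burst so gating rates dominate
    nw.cass[0, :] = 40.0
    nw.cajsr[0, :] = 1000.0
    nw.ryr_o[0, :] = 10
    pol = TimestepPolicy(pchan_max=1e9)   # expose the 10% rule only
    dt1 = select_adaptive_dt(nw, pol)
    nw2 = NetworkState(1, ModelParams(), 1, n_cru=50, multiplicity=400)
    nw2.cass[0, :] = 40.0
    nw2.cajsr[0, :] = 1000.0
    nw2.ryr_o[0, :] = 10
    nw2.scales[0, 4] = 2.0 ** (1.0 / 3.0)  # doubles the opening rate (eta=3)
    dt2 = select_adaptive_dt(nw2, pol)
    assert dt1 < TimestepPolicy().dt_max
    # opening dominates the exit-rate sum here, so dt shrinks close to 2x
    assert dt2 < dt1
    assert dt2 / dt1 == pytest.approx(0.5, rel=0.25)


def test_dt_min_violation_raises():
    nw = NetworkState(1, ModelParams(), 1, n_cru=50, multiplicity=400)
    nw.cass[0, :] = 400.0
    nw.ryr_o[0, :] = 25
    pol = TimestepPolicy(dt_min=4.9e-3, dt_max=5e-3)
    with pytest.raises(SimulationError):
        select_adaptive_dt(nw, pol)


def test_fraction_rule_holds_over_full_run():
    """Instrumented bound: expected transitioning-CRU fraction <= 10%."""
    nw = NetworkState(2, ModelParams(), 5, n_cru=30, multiplicity=667)
    geom = build_lattice((2,))
    res = run_network(nw, geom, TimestepPolicy(), 60.0,
                      stim_rows=[(0, -16.3, 2.0, 4.0), (1, -16.3, 2.0, 4.0)],
                      record_dt=5.0)
    frac = res.diagnostics["max_cru_transition_fraction"]
    assert 0.0 < frac <= 0.10 * (1.0 + 1e-9)


# --- stepping / conservation -------------------------------------------------

def test_identical_cells_stay_identical():
    """With equal states the gap currents vanish and cells evolve alike."""
    p = replace(ModelParams(), ionic_currents_off=True)
    nw = NetworkState(3, p, 1, n_cru=0, multiplicity=1)
    nw.vm[:] = -70.0
    geom = build_lattice((3,), g_long=2500.0)
    run_network(nw, geom, TimestepPolicy(), 5.0, record_dt=5.0)
    assert np.allclose(nw.vm, -70.0)


def test_gap_current_antisymmetry_conserves_charge():
    """Sum over cells of coupling contributions is zero at every step."""
    p = replace(ModelParams(), ionic_currents_off=True)
    nw = NetworkState(5, p, 1, n_cru=0, multiplicity=1)
    nw.vm[:] = [-80.0, -20.0, -60.0, -75.0, -40.0]
    s0 = nw.vm.sum()
    geom = build_lattice((5,), g_long=1800.0)
    run_network(nw, geom, TimestepPolicy(), 10.0, record_dt=10.0)
    assert nw.vm.sum() == pytest.approx(s0, abs=1e-8)
    assert nw.vm.std() < 1.0  # relaxed toward the common mean


def test_closed_system_calcium_conserved():
    """Sarcolemmal Ca2+ off: total Ca constant to 1e-6 relative over 100 ms."""
    p = replace(ModelParams(), sarcolemmal_ca_off=True, clamp_na_k=True)
    nw = NetworkState(1, p, 11, n_cru=20, multiplicity=1000)
    nw.ryr_o[0, :10] = 10      # active release makes every flux leg nonzero
    c0 = total_calcium(nw)
    res = run_network(nw, None, TimestepPolicy(), 100.0, record_dt=50.0)
    assert abs(total_calcium(nw) - c0) / c0 < 1e-6
    assert res.diagnostics["n_clip_events"] == 0


def test_run_determinism():
    """Same configuration and seed give bit-identical outputs."""
    outs = []
    for _ in range(2):
        nw = NetworkState(3, ModelParams(), 77, n_cru=10, multiplicity=2000)
        geom = build_lattice((3,))
        res = run_network(nw, geom, TimestepPolicy(), 30.0,
                          stim_rows=[(0, -16.3, 2.0, 4.0)], record_dt=1.0)
        outs.append((res.vm.copy(), res.ca_myo.copy(), nw.ctr.copy()))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])
    assert np.array_equal(outs[0][2], outs[1][2])


def test_checkpoint_equivalence():
    """A run split at a checkpoint matches the single uninterrupted run."""
    def fresh():
        return NetworkState(2, ModelParams(), 13, n_cru=10, multiplicity=2000)
    geom = build_lattice((2,))
    stim = [(0, -16.3, 2.0, 4.0)]
    a = fresh()
    run_network(a, geom, TimestepPolicy(), 30.0, stim_rows=stim, record_dt=1.0)
    b = fresh()
    run_network(b, geom, TimestepPolicy(), 14.0, stim_rows=stim, record_dt=1.0)
    c = b.copy()
    run_network(c, geom, TimestepPolicy(), 30.0, stim_rows=stim, record_dt=1.0)
    assert np.array_equal(a.vm, c.vm)
    assert np.array_equal(a.cass, c.cass)
    assert np.array_equal(a.ctr, c.ctr)


def test_zero_duration_run_returns_initial_snapshot():
    nw = NetworkState(2, ModelParams(), 1, n_cru=5, multiplicity=4000)
    geom = build_lattice((2,))
    res = run_network(nw, geom, TimestepPolicy(), 0.0, record_dt=1.0)
    assert res.time.size <= 1
    assert nw.t == 0.0


def test_step_tissue_advances_clock():
    nw = NetworkState(2, ModelParams(), 1, n_cru=5, multiplicity=4000)
    geom = build_lattice((2,))
    dt = step_tissue(nw, geom, TimestepPolicy(dt_max=2e-3))
    assert dt > 0
    assert nw.t == pytest.approx(dt)
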