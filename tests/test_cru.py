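"""Single calcium-release-unit gating: rate laws, sampling, oracles.

The Monte Carlo channel sampler is validated against the exact stationary
distribution of the cluster birth-death chain (product form) and of the
four-state L-type channel (matrix solve), both at clamped Ca2+.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardionet.cru_dynamics import (
    CRUnit, RyRClusterState, LCCComplexState, DyadState,
    ryr_transition_rates, lcc_transition_rates, sample_transitions,
    dyad_fluxes, force_open_ryrs, cluster_stationary_open_fraction,
    lcc_stationary_distribution, LCC_OPEN)
from cardionet.params import GatingRateParams
from cardionet.rng import derive_stream


# --- RyR2 rate law ---------------------------------------------------------

def test_zero_cleft_ca_gives_zero_opening(gating):
    ko, kc = ryr_transition_rates(0.0, 1000.0, 0, RyRClusterState(), gating)
    assert ko == 0.0
    assert kc > 0.0


def test_opening_rate_monotone_in_ca_and_lumen(gating):
    ryr = RyRClusterState()
    kos = [ryr_transition_rates(ca, 1000.0, 0, ryr, gating)[0]
           for ca in (0.1, 1.0, 5.0, 20.0, 100.0)]
    assert all(b > a for a, b in zip(kos, kos[1:]))
    klum = [ryr_transition_rates(5.0, j, 0, ryr, gating)[0]
            for j in (100.0, 500.0, 1000.0, 1500.0)]
    assert all(b > a for a, b in zip(klum, klum[1:]))


def test_mean_field_coupling_direction(gating):
    ryr = RyRClusterState()
    ko0, kc0 = ryr_transition_rates(5.0, 1000.0, 0, ryr, gating)
    ko1, kc1 = ryr_transition_rates(5.0, 1000.0, 25, ryr, gating)
    assert ko1 > ko0
    assert kc1 < kc0


def test_hf_sensitivity_scales_effective_ca(gating):
    """Sensitivity 1.5 acts on the ligand axis: rates match Ca x 1.5."""
    hf = RyRClusterState(sensitivity_scale=1.5)
    ctrl = RyRClusterState()
    ko_hf, _ = ryr_transition_rates(2.0, 1000.0, 0, hf, gating)
    ko_scaled, _ = ryr_transition_rates(3.0, 1000.0, 0, ctrl, gating)
    assert ko_hf == pytest.approx(ko_scaled, rel=1e-12)


def test_negative_concentration_rejected(gating):
    with pytest.raises(ValueError):
        ryr_transition_rates(-1.0, 1000.0, 0, RyRClusterState(), gating)


# --- stationary oracle vs Monte Carlo --------------------------------------

def _mc_open_fraction(ca_ss, ca_jsr, gating, n_total=49, n_chains=12,
                      n_steps=22_000, dt=2e-3, seed=5, sens=1.0):
    """Monte Carlo open fraction from independent replicate chains.

    Each chain is an independent stream; the standard error comes from the
    spread of the chain means, which is honest even when within-chain
    mixing is slow (bursty low-open-probability regimes).
    """
    burn = n_steps // 5
    means = []
    for ch in range(n_chains):
        cru = CRUnit(ryr=RyRClusterState(n_total=n_total,
                                         sensitivity_scale=sens),
                     dyad=DyadState(ca_ss=ca_ss, ca_jsr=ca_jsr))
        rng = derive_stream(seed, cell=0, cru=ch)
        total = 0.0
        for i in range(n_steps):
            cru = sample_transitions(cru, dt, rng, gating)
            if i >= burn:
                total += cru.ryr.n_open
        means.append(total / (n_steps - burn) / n_total)
    means = np.asarray(means)
    return float(means.mean()), float(means.std(ddof=1) / math.sqrt(n_chains))


@pytest.mark.parametrize("ca_ss,ca_jsr", [
    (2.0, 1000.0), (4.0, 1000.0), (6.0, 800.0), (10.0, 500.0), (20.0, 300.0),
])
def test_monte_carlo_matches_birth_death_stationary(gating, ca_ss, ca_jsr):
    """Clamped-Ca gating reproduces the exact stationary open fraction."""
    exact = cluster_stationary_open_fraction(ca_ss, ca_jsr, gating)
    mc, se = _mc_open_fraction(ca_ss, ca_jsr, gating)
    assert abs(mc - exact) <= 3.0 * max(se, 2e-5), \
        f"MC {mc:.5f} vs exact {exact:.5f} (3 SE = {3 * se:.5f})"


def test_stationary_trivial_limits():
    g0 = GatingRateParams(ryr_k_plus=0.0)
    assert cluster_stationary_open_fraction(5.0, 1000.0, g0) == 0.0
    # symmetric per-channel rates, no coupling -> open fraction 1/2
    gsym = GatingRateParams(ryr_k_plus=0.3, ryr_eta=0.0, ryr_k_minus=0.3,
                            ryr_coupling=0.0, ryr_k_open_max=1e12)
    frac = cluster_stationary_open_fraction(5.0, 1000.0, gsym)
    assert frac == pytest.approx(0.5, abs=1e-9)


def test_two_state_single_channel_analytic(gating):
    """n_total = 1, no coupling: P_open = k_open/(k_open + k_close)."""
    g = GatingRateParams(ryr_coupling=0.0)
    ko, kc = ryr_transition_rates(6.0, 1000.0, 0, RyRClusterState(n_total=1),
                                  g)
    expected = ko / (ko + kc)
    assert cluster_stationary_open_fraction(6.0, 1000.0, g, n_total=1) == \
        pytest.approx(expected, rel=1e-9)


def test_stationary_monotone_in_drivers(gating):
    fr = [cluster_stationary_open_fraction(c, 1000.0, gating)
          for c in (1.0, 3.0, 6.0, 12.0)]
    assert all(b >= a for a, b in zip(fr, fr[1:]))
    fs = [cluster_stationary_open_fraction(4.0, 1000.0, gating,
                                           sensitivity_scale=s)
          for s in (0.8, 1.0, 1.5)]
    assert all(b >= a for a, b in zip(fs, fs[1:]))


# --- L-type channel --------------------------------------------------------

def test_lcc_deep_closed_at_rest(gating):
    """Long clamp far below threshold leaves the channel shut."""
    pi = lcc_stationary_distribution(-85.0, 0.1, gating)
    assert pi[LCC_OPEN] < 1e-3


def test_lcc_activation_increases_with_voltage(gating):
    r1 = lcc_transition_rates(-40.0, 0.1, LCCComplexState(), gating)
    r2 = lcc_transition_rates(0.0, 0.1, LCCComplexState(), gating)
    assert r2["activation"] > r1["activation"]
    assert all(v >= 0 for v in r2.values())


def test_lcc_cam_inactivation_monotone_in_ca(gating):
    """Steady open fraction at 0 mV decreases as cleft Ca2+ rises."""
    po = [lcc_stationary_distribution(0.0, ca, gating)[LCC_OPEN]
          for ca in (0.1, 10.0, 100.0, 400.0)]
    assert all(b < a for a, b in zip(po, po[1:]))


def test_lcc_mc_matches_stationary():
    """Single-channel occupancy matches the CTMC stationary solve (3 SE).

    The inactivation recovery constants are compressed so the chain mixes
    within a chain length (the physiological values put the slowest
    recovery near 1 s); sampler and matrix oracle share the same rates, so
    this validates the identical code path.
    """
    g = GatingRateParams(lcc_k_cam_rec=0.2, lcc_tau_f=8.0, lcc_k_cam=0.05)
    vm, ca = -30.0, 10.0
    pi = lcc_stationary_distribution(vm, ca, g)
    n_chains, n_steps, dt = 8, 30_000, 5e-3
    burn = n_steps // 5
    chain_occ = np.zeros((n_chains, 4))
    for ch in range(n_chains):
        cru = CRUnit(lcc=LCCComplexState(counts=np.array([1, 0, 0, 0])),
                     dyad=DyadState(ca_ss=ca))
        rng = derive_stream(17, cell=0, cru=ch)
        for i in range(n_steps):
            cru = sample_transitions(cru, dt, rng, g, vm=vm)
            if i >= burn:
                chain_occ[ch] += cru.lcc.counts
        chain_occ[ch] /= chain_occ[ch].sum()
    occ = chain_occ.mean(axis=0)
    se = chain_occ.std(axis=0, ddof=1) / math.sqrt(n_chains)
    for s in range(4):
        assert abs(occ[s] - pi[s]) <= 3.0 * max(se[s], 2e-3), \
            f"state {s}: MC {occ[s]:.4f} vs exact {pi[s]:.4f}"


# --- sampling behaviour ----------------------------------------------------

def test_no_transitions_for_vanishing_dt(gating):
    cru = CRUnit(dyad=DyadState(ca_ss=5.0))
    out = sample_transitions(cru, 1e-12, derive_stream(1), gating)
    assert out.ryr.n_open == cru.ryr.n_open
    assert np.array_equal(out.lcc.counts, cru.lcc.counts)


def test_zero_rates_absorbing(gating):
    g = GatingRateParams(ryr_k_plus=0.0, ryr_k_minus=0.0, lcc_k_cam=0.0,
                         lcc_k_cam_rec=0.0)
    cru = CRUnit(ryr=RyRClusterState(n_open=12),
                 dyad=DyadState(ca_ss=0.0))
    out = sample_transitions(cru, 1.0, derive_stream(3), g, vm=-200.0)
    assert out.ryr.n_open == 12


def test_dt_validation(gating):
    with pytest.raises(ValueError):
        sample_transitions(CRUnit(), 0.0, derive_stream(1), gating)
    with pytest.raises(ValueError):
        # rate*dt > 1 signals a timestep-control failure
        sample_transitions(CRUnit(dyad=DyadState(ca_ss=300.0)), 10.0,
                           derive_stream(1), gating)


def test_sampling_reproducible(gating):
    cru = CRUnit(dyad=DyadState(ca_ss=8.0))
    seqs = []
    for _ in range(2):
        rng = derive_stream(99, cell=2, cru=5)
        c = cru
        seq = []
        for _ in range(200):
            c = sample_transitions(c, 2e-3, rng, gating)
            seq.append(c.ryr.n_open)
        seqs.append(seq)
    assert seqs[0] == seqs[1]


@given(n_open=st.integers(0, 49), seed=st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_channel_count_conservation(n_open, seed):
    """n_open stays within [0, n_total] under any sampled transition."""
    g = GatingRateParams()
    cru = CRUnit(ryr=RyRClusterState(n_open=n_open),
                 dyad=DyadState(ca_ss=10.0, ca_jsr=800.0))
    rng = derive_stream(seed)
    for _ in range(20):
        cru = sample_transitions(cru, 2e-3, rng, g)
        assert 0 <= cru.ryr.n_open <= cru.ryr.n_total
        assert cru.lcc.counts.sum() == 7
        assert (cru.lcc.counts >= 0).all()


# --- forced openings and fluxes --------------------------------------------

def test_force_open_ryrs():
    cru = CRUnit()
    out = force_open_ryrs(cru, 10)
    assert out.ryr.n_open == 10
    assert force_open_ryrs(out, 0).ryr.n_open == 10      # no-op, keeps max
    assert force_open_ryrs(cru, 49).ryr.n_open == 49     # saturation
    with pytest.raises(ValueError):
        force_open_ryrs(cru, 50)


def test_dyad_fluxes_zero_gradient(gating):
    cru = CRUnit(ryr=RyRClusterState(n_open=20),
                 dyad=DyadState(ca_ss=500.0, ca_jsr=500.0))
    fl = dyad_fluxes(cru, 0.1, 500.0, gating)
    assert fl["J_release"] == 0.0


def test_dyad_fluxes_global_equilibrium(gating):
    ca = 0.25
    beq = gating.bss_tot * ca / (ca + gating.bss_koff / gating.bss_kon)
    cru = CRUnit(dyad=DyadState(ca_ss=ca, ca_jsr=ca, buffer_ss=beq))
    fl = dyad_fluxes(cru, ca, ca, gating)
    for v in fl.values():
        assert v == pytest.approx(0.0, abs=1e-12)


def test_dyad_release_sign(gating):
    cru = CRUnit(ryr=RyRClusterState(n_open=49),
                 dyad=DyadState(ca_ss=1.0, ca_jsr=1000.0))
    fl = dyad_fluxes(cru, 0.1, 1000.0, gating)
    assert fl["J_release"] > 0
    assert fl["J_efflux"] > 0
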