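"""Compartmental whole-cell myocyte model.

Membrane potential follows the charge balance over the fast Na+ current,
four K+ currents (inward rectifier, fast/slow transient outward,
steady-state), Na+/K+ pump, NCX (with a dyadic fraction sensing subspace
Ca2+), plasma-membrane Ca2+ pump, three linear background currents, the
stochastic L-type trigger flux, applied current, and gap-junction coupling.
Bulk compartments: myoplasmic and network-SR Ca2+ (with calmodulin/troponin
buffering and a thermodynamically reversible SERCA2a), intracellular Na+
and K+.

Heart-failure remodeling is applied as multiplicative transforms: transient
outward and inward-rectifier K+ conductances x0.8, NCX x2, SERCA2a x0.7,
RyR2 Ca2+ sensitivity x1.5, and orphaning of a fixed fraction of release
units through a 30-fold dyadic subspace volume increase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

from . import _engine
from .params import (ModelParams, MembraneParams, Phenotype, pack_params,
                     CONTROL_PHENOTYPE, HF_PHENOTYPE)
from .cru_dynamics import CRUnit, RyRClusterState, LCCComplexState, DyadState
from .rng import RNGStream, derive_stream
from .tissue import NetworkState, TimestepPolicy, _run_engine, SimulationError

__all__ = [
    "CurrentSet", "MyocyteState", "compute_currents", "serca_flux",
    "membrane_derivative", "step_myocyte", "apply_phenotype",
    "phenotype_scale_row", "initialize_quiescent", "pace_myocyte",
]

_PURPOSE_ORPHAN = 101


@dataclass(frozen=True)
class CurrentSet:
    """Membrane current densities, uA/cm^2, inward negative."""

    i_dhpr_trigger: float = 0.0
    i_dhpr_nj: float = 0.0
    i_na: float = 0.0
    i_ncx_dyad: float = 0.0
    i_ncx_bulk: float = 0.0
    i_nak: float = 0.0
    i_pmca: float = 0.0
    i_k1: float = 0.0
    i_kss: float = 0.0
    i_ktof: float = 0.0
    i_ktos: float = 0.0
    i_bg_ca: float = 0.0
    i_bg_na: float = 0.0
    i_bg_k: float = 0.0
    i_app: float = 0.0

    @property
    def i_ncx(self) -> float:
        return self.i_ncx_dyad + self.i_ncx_bulk

    def total(self) -> float:
        """Sum of all ionic current densities plus the applied current."""
        return (self.i_dhpr_trigger + self.i_dhpr_nj + self.i_na + self.i_ncx
                + self.i_nak + self.i_pmca + self.i_k1 + self.i_kss
                + self.i_ktof + self.i_ktos + self.i_bg_ca + self.i_bg_na
                + self.i_bg_k + self.i_app)


class MyocyteState:
    """Single-cell state: a one-cell network plus convenience accessors."""

    def __init__(self, network: NetworkState):
        if network.n != 1:
            raise ValueError("MyocyteState wraps a one-cell network")
        self.network = network

    # -- scalar accessors ---------------------------------------------------
    @property
    def vm(self) -> float:
        return float(self.network.vm[0])

    @vm.setter
    def vm(self, v: float):
        self.network.vm[0] = v

    @property
    def ca_myo(self) -> float:
        return float(self.network.cai[0])

    @property
    def ca_nsr(self) -> float:
        return float(self.network.cansr[0])

    @property
    def na_i(self) -> float:
        return float(self.network.nai[0])

    @property
    def k_i(self) -> float:
        return float(self.network.ki[0])

    @property
    def gating(self) -> np.ndarray:
        """Deterministic gates (m, h, j, a_tof, i_tof, a_tos, i_tos, a_kss)."""
        return self.network.gates[0]

    @property
    def phenotype(self) -> str:
        return self.network.phenotype_names[0]

    @property
    def t(self) -> float:
        return self.network.t

    @property
    def mean_ca_ss(self) -> float:
        return float(self.network.cass[0].mean()) if self.network.K else self.ca_myo

    @property
    def ryr_open_fraction(self) -> float:
        K = self.network.K
        if K == 0:
            return 0.0
        return float(self.network.ryr_o[0].sum()
                     / (K * self.network.params.cell.n_ryr))

    @property
    def crus(self) -> list[CRUnit]:
        """Snapshot of every coarse release unit as a CRUnit object."""
        nw = self.network
        g = nw.params
        out = []
        for u in range(nw.K):
            out.append(CRUnit(
                ryr=RyRClusterState(
                    n_open=int(nw.ryr_o[0, u]), n_total=g.cell.n_ryr,
                    coupling_energy=g.gating.ryr_coupling,
                    sensitivity_scale=float(nw.scales[0, 4])),
                lcc=LCCComplexState(counts=nw.lcc[0, u].copy()),
                dyad=DyadState(ca_ss=float(nw.cass[0, u]),
                               ca_jsr=float(nw.cajsr[0, u]),
                               v_ss=g.cell.v_ss * float(nw.vssf[0, u]),
                               buffer_ss=float(nw.bss[0, u]),
                               buffer_jsr=float(nw.bjsr[0, u])),
                orphaned=bool(nw.vssf[0, u] > 1.0),
                multiplicity=nw.mult))
        return out

    def copy(self) -> "MyocyteState":
        return MyocyteState(self.network.copy())


def _check_finite(state: MyocyteState):
    nw = state.network
    vals = [nw.vm[0], nw.cai[0], nw.cansr[0], nw.nai[0], nw.ki[0]]
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite state values: {vals}")


def compute_currents(state: MyocyteState, params: ModelParams | None = None,
                     i_app: float = 0.0) -> CurrentSet:
    """All deterministic membrane currents plus the stochastic L-type trigger.

    The NCX is reported as the weighted dyadic/bulk split: the dyadic
    fraction senses the mean subspace Ca2+ and the remainder the bulk
    myoplasmic Ca2+ (the formulation is linear in the sensed Ca2+, so the
    split is exact).
    """
    _check_finite(state)
    nw = state.network
    params = params or nw.params
    pp = pack_params(params)
    g = nw.gates[0]
    sc = nw.scales[0]
    args = (pp, nw.vm[0], nw.cai[0], nw.cansr[0], nw.nai[0], nw.ki[0],
            g[0], g[1], g[2], g[3], g[4], g[5], g[6], g[7])
    f = params.membrane.ncx_dyadic_fraction
    km = params.membrane.km_cai_ncx
    if nw.K:
        cass = nw.cass[0]
        sensed_dyad = float(np.mean(cass / (1.0 + cass / km)))
    else:
        sensed_dyad = nw.cai[0] / (1.0 + nw.cai[0] / km)
    sensed_bulk = nw.cai[0] / (1.0 + nw.cai[0] / km)
    out_d = _engine.cell_currents(*args, sensed_dyad, sc[0], sc[1], sc[2])
    out_b = _engine.cell_currents(*args, sensed_bulk, sc[0], sc[1], sc[2])
    (ina, ik1, iktof, iktos, ikss, inak, incx_d, ipmca, ibca, ibna, ibk) = out_d
    incx_b = out_b[6]
    n_lcc_open = int(nw.lcc[0, :, 1].sum()) if nw.K else 0
    i_dhpr = 0.0
    if not params.sarcolemmal_ca_off:
        i_dhpr = (n_lcc_open * nw.mult * params.gating.lcc_g
                  * (nw.vm[0] - params.gating.lcc_erev) * 1e-6
                  / params.membrane.a_m)
    return CurrentSet(
        i_dhpr_trigger=float(i_dhpr), i_dhpr_nj=0.0, i_na=float(ina),
        i_ncx_dyad=float(f * incx_d), i_ncx_bulk=float((1 - f) * incx_b),
        i_nak=float(inak), i_pmca=float(ipmca), i_k1=float(ik1),
        i_kss=float(ikss), i_ktof=float(iktof), i_ktos=float(iktos),
        i_bg_ca=float(ibca), i_bg_na=float(ibna), i_bg_k=float(ibk),
        i_app=float(i_app))


def serca_flux(ca_myo: float, ca_nsr: float, scale: float = 1.0,
               params: ModelParams | None = None) -> float:
    """Reversible SERCA2a uptake, uM/ms referenced to the myoplasmic volume.

    Positive = uptake into the SR; reverses sign at the thermodynamic
    equilibrium ratio ca_nsr/ca_myo = serca_kmr/serca_kmf; scales linearly
    with the phenotype SERCA expression factor.
    """
    if ca_myo < 0 or ca_nsr < 0:
        raise ValueError("concentrations must be >= 0")
    pp = pack_params(params or ModelParams())
    return float(_engine.serca_flux(float(ca_myo), float(ca_nsr),
                                    float(scale), pp))


def membrane_derivative(state: MyocyteState, currents: CurrentSet,
                        neighbor_vms=(), edge_ggaps=(),
                        params: ModelParams | None = None) -> float:
    """dVm/dt (mV/ms): -(sum of current densities)/C_sc plus gap coupling.

    The gap term is +sum_k G_k (Vm_k - Vm) / (C_sc * A_m) with nS*mV
    converted to uA; coupling relaxes Vm toward the neighbours.
    """
    neighbor_vms = list(neighbor_vms)
    edge_ggaps = list(edge_ggaps)
    if len(neighbor_vms) != len(edge_ggaps):
        raise ValueError("neighbor_vms and edge_ggaps must have equal length")
    params = params or state.network.params
    mp = params.membrane
    coup = sum(g * (vk - state.vm) for vk, g in zip(neighbor_vms, edge_ggaps))
    coup_dens = 1e-6 * coup / mp.a_m
    return (-currents.total() + coup_dens) / mp.c_sc


def step_myocyte(state: MyocyteState, dt: float,
                 policy: TimestepPolicy | None = None) -> MyocyteState:
    """Advance a single myocyte by dt (ms) in place; dt = 0 is the identity.

    Continuous variables take explicit-Euler updates; every CRU's channels
    are advanced by the counter-based Monte Carlo sampler.  The step is
    internally subdivided whenever the adaptive rules require it.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0.0:
        return state
    policy = policy or TimestepPolicy()
    _run_engine(state.network, None, policy, state.network.t + dt,
                record_dt=max(dt, 1.0))
    return state


def phenotype_scale_row(ph: Phenotype) -> np.ndarray:
    """(ito, ik1, ncx, serca, ryr_sensitivity) multiplier row for the kernels."""
    return np.array([ph.scale_ito, ph.scale_ik1, ph.scale_ncx,
                     ph.scale_serca, ph.ryr_sensitivity])


def apply_phenotype(network: NetworkState, ph: Phenotype,
                    cells=None, seed: int | None = None) -> NetworkState:
    """Apply a phenotype's transforms to (a subset of) a network's cells.

    Conductance/pump scalings become per-cell multipliers; exactly
    round(orphan_fraction * n_cru) release units per cell are flagged
    orphaned (subspace volume x orphan_vss_factor).  The orphan subset is
    drawn from the per-cell counter-based stream, so it is seed-reproducible
    and order-independent.
    """
    cells = range(network.n) if cells is None else cells
    seed = network.seed if seed is None else seed
    row = phenotype_scale_row(ph)
    n_orphan = int(round(ph.orphan_fraction * network.K))
    for c in cells:
        network.scales[c] = row
        network.phenotype_names[c] = ph.name
        network.vssf[c] = 1.0
        if n_orphan:
            rng = derive_stream(seed, cell=c, purpose=_PURPOSE_ORPHAN)
            idx = rng.choice_without_replacement(network.K, n_orphan)
            network.vssf[c, idx] = ph.orphan_vss_factor
    return network


def initialize_quiescent(params: ModelParams | None = None, seed: int = 0,
                         phenotype: Phenotype = CONTROL_PHENOTYPE,
                         n_cru: int | None = None,
                         multiplicity: int | None = None,
                         settle_ms: float = 2000.0,
                         policy: TimestepPolicy | None = None,
                         check: bool = True) -> MyocyteState:
    """Build a resting myocyte: settle an unstimulated cell and verify rest.

    After the settle the time-averaged |dVm/dt| over the final quarter must
    stay below 1 mV/s and the SR load within 2%; otherwise the drifting
    variable is named in the error.
    """
    params = params or ModelParams()
    nw = NetworkState(1, params, seed, n_cru=n_cru, multiplicity=multiplicity)
    apply_phenotype(nw, phenotype)
    policy = policy or TimestepPolicy()
    state = MyocyteState(nw)
    if settle_ms <= 0:
        return state
    times, traces, _, _ = _run_engine(nw, None, policy, settle_ms,
                                      record_dt=max(settle_ms / 200.0, 1.0))
    if check:
        q = max(len(times) // 4, 2)
        vm_tail = traces["vm"][-q:, 0]
        dt_tail = float(times[-1] - times[-q])
        drift = abs(vm_tail[-1] - vm_tail[0]) / max(dt_tail, 1e-9) * 1000.0
        if drift > 1.0:
            raise SimulationError(
                f"failed to settle: Vm drifting at {drift:.2f} mV/s")
        sr_tail = traces["ca_nsr"][-q:, 0]
        sr_rel = abs(sr_tail[-1] - sr_tail[0]) / max(sr_tail[-1], 1e-9)
        if sr_rel > 0.02:
            raise SimulationError(
                f"failed to settle: SR Ca2+ drifted {100 * sr_rel:.1f}% "
                "over the settle tail")
    return state


def pace_myocyte(state: MyocyteState, n_beats: int = 20,
                 cycle_ms: float = 1000.0, stim_amp: float = -16.3,
                 stim_dur: float = 2.0, record_dt: float = 1.0,
                 policy: TimestepPolicy | None = None):
    """Pace a single myocyte with a periodic current and record the traces.

    Returns (times, traces) where traces carry vm, ca_myo, ca_nsr,
    ryr_open_frac, ca_ss_mean as (samples, 1) arrays.
    """
    policy = policy or TimestepPolicy()
    nw = state.network
    t0 = nw.t
    stim_rows = [(0, stim_amp, t0 + k * cycle_ms, t0 + k * cycle_ms + stim_dur)
                 for k in range(n_beats)]
    t_end = t0 + n_beats * cycle_ms
    times, traces, _, _ = _run_engine(nw, None, policy, t_end,
                                      stim_rows=stim_rows, record_dt=record_dt)
    return times, traces
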