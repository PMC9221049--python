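"""Single calcium release unit (dyad): stochastic gating and local Ca2+ fluxes.

A release unit couples a cluster of RyR2 channels on the junctional SR to a
small cluster of L-type Ca2+ channels across a femtolitre-scale dyadic
subspace.  RyR2 channels are two-state (closed/open) with a saturating
power-law opening rate in the effective activating Ca2+ — cleft Ca2+ scaled
by a linear junctional-SR lumen factor and a phenotype sensitivity — plus an
Ising-type mean-field coupling across the cluster; there is no
Ca2+-dependent inactivation, so release terminates by lumen depletion.
L-type channels occupy four states: closed, open, voltage-inactivated and
Ca2+-calmodulin-inactivated.

The module exposes object-level operations used by tests and protocols; the
network integrator in :mod:`cardionet.tissue` runs the same compiled rate
functions over flat arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

from .params import GatingRateParams, CellGeometryParams, ModelParams, pack_params
from .rng import RNGStream
from . import _engine

__all__ = [
    "RyRClusterState", "LCCComplexState", "DyadState", "CRUnit",
    "LCC_CLOSED", "LCC_OPEN", "LCC_VINACT", "LCC_CAINACT",
    "ryr_transition_rates", "lcc_transition_rates", "sample_transitions",
    "dyad_fluxes", "force_open_ryrs", "cluster_stationary_open_fraction",
    "lcc_rate_matrix", "lcc_stationary_distribution",
]

LCC_CLOSED, LCC_OPEN, LCC_VINACT, LCC_CAINACT = 0, 1, 2, 3


@dataclass
class RyRClusterState:
    """State of one RyR2 cluster."""

    n_open: int = 0
    n_total: int = 49
    coupling_energy: float = 1.0     # mean-field coupling strength a
    sensitivity_scale: float = 1.0   # 1.0 control, 1.5 heart failure

    def __post_init__(self):
        if not 0 <= self.n_open <= self.n_total:
            raise ValueError("n_open must lie in [0, n_total]")
        if self.sensitivity_scale <= 0:
            raise ValueError("sensitivity_scale must be > 0")


@dataclass
class LCCComplexState:
    """Per-state channel counts of the L-type cluster (C, O, VI, CaI)."""

    counts: np.ndarray = field(default_factory=lambda: np.array([7, 0, 0, 0]))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4,) or (self.counts < 0).any():
            raise ValueError("counts must be 4 non-negative integers")

    @property
    def n_lcc(self) -> int:
        return int(self.counts.sum())

    @property
    def n_open(self) -> int:
        return int(self.counts[LCC_OPEN])


@dataclass
class DyadState:
    """Dyadic subspace and junctional SR compartments of one unit."""

    ca_ss: float = 0.1       # uM
    ca_jsr: float = 1000.0   # uM
    v_ss: float = 1.0e-3     # um^3
    buffer_ss: float = 0.0   # uM bound subspace buffer
    buffer_jsr: float = 0.0  # uM bound junctional-SR buffer

    def __post_init__(self):
        if self.ca_ss < 0 or self.ca_jsr < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass
class CRUnit:
    """One coarse-grained calcium release unit.

    ``multiplicity`` is the number of identical physical CRUs this unit
    represents; its fluxes into the bulk compartments are scaled by it.
    """

    ryr: RyRClusterState = field(default_factory=RyRClusterState)
    lcc: LCCComplexState = field(default_factory=LCCComplexState)
    dyad: DyadState = field(default_factory=DyadState)
    orphaned: bool = False
    multiplicity: int = 100

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


def _pp(params: GatingRateParams, sens: float = 1.0,
        cell: CellGeometryParams | None = None) -> np.ndarray:
    mp = ModelParams(gating=params, cell=cell or CellGeometryParams())
    return pack_params(mp)


def ryr_transition_rates(ca_ss: float, ca_jsr: float, n_open: int,
                         ryr: RyRClusterState,
                         params: GatingRateParams) -> tuple[float, float]:
    """Per-channel RyR2 (opening, closing) rates in ms^-1 at clamped Ca2+.

    Opening increases with cleft Ca2+, lumen Ca2+ and the number of open
    neighbours; closing decreases with open neighbours.
    """
    if ca_ss < 0 or ca_jsr < 0:
        raise ValueError("concentrations must be >= 0")
    pp = _pp(params)
    pp[_np_idx("N_RYR")] = ryr.n_total
    pp[_np_idx("RYR_COUPLING")] = ryr.coupling_energy
    ko, kc = _engine.ryr_rates(float(ca_ss), float(ca_jsr), int(n_open),
                               float(ryr.sensitivity_scale), pp)
    return float(ko), float(kc)


def _np_idx(name: str) -> int:
    from . import params as _p
    return getattr(_p, "P_" + name)


def lcc_transition_rates(vm: float, ca_ss: float, lcc: LCCComplexState,
                         params: GatingRateParams) -> dict[str, float]:
    """L-type per-channel transition rates (ms^-1) at voltage vm and cleft Ca."""
    if not math.isfinite(vm):
        raise ValueError("vm must be finite")
    if ca_ss < 0:
        raise ValueError("ca_ss must be >= 0")
    pp = _pp(params)
    alpha, beta, kvi, krec = _engine.lcc_voltage_rates(float(vm), pp)
    kcam = _engine.lcc_cam_rate(float(ca_ss), pp)
    return {"activation": float(alpha), "deactivation": float(beta),
            "v_inactivation": float(kvi), "v_recovery": float(krec),
            "ca_cam_inactivation": float(kcam),
            "ca_cam_recovery": float(params.lcc_k_cam_rec)}


def lcc_rate_matrix(vm: float, ca_ss: float,
                    params: GatingRateParams) -> np.ndarray:
    """4x4 generator matrix Q (rows = from-state C,O,VI,CaI) of one channel."""
    r = lcc_transition_rates(vm, ca_ss, LCCComplexState(), params)
    Q = np.zeros((4, 4))
    Q[LCC_CLOSED, LCC_OPEN] = r["activation"]
    Q[LCC_CLOSED, LCC_VINACT] = r["v_inactivation"]
    Q[LCC_OPEN, LCC_CLOSED] = r["deactivation"]
    Q[LCC_OPEN, LCC_VINACT] = r["v_inactivation"]
    Q[LCC_OPEN, LCC_CAINACT] = r["ca_cam_inactivation"]
    Q[LCC_VINACT, LCC_CLOSED] = r["v_recovery"]
    Q[LCC_CAINACT, LCC_CLOSED] = r["ca_cam_recovery"]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def lcc_stationary_distribution(vm: float, ca_ss: float,
                                params: GatingRateParams) -> np.ndarray:
    """Stationary distribution of the single-channel L-type CTMC (exact solve)."""
    Q = lcc_rate_matrix(vm, ca_ss, params)
    A = np.vstack([Q.T, np.ones(4)])
    b = np.zeros(5)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if not np.all(np.isfinite(pi)):
        raise RuntimeError("stationary solve did not converge")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def sample_transitions(cru: CRUnit, dt: float, rng: RNGStream,
                       params: GatingRateParams | None = None,
                       vm: float = -80.0) -> CRUnit:
    """Sample one tau-leap of channel transitions for a single unit.

    Channel counts move by binomially sampled events at the current rates
    (L-type voltage rates evaluated at ``vm``); per-channel transition
    probabilities must stay below ~0.2 (the adaptive timestep enforces this
    in network runs; here rate*dt > 1 raises).
    """
    params = params or GatingRateParams()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    pp = _pp(params)
    pp[_np_idx("N_RYR")] = cru.ryr.n_total
    pp[_np_idx("RYR_COUPLING")] = cru.ryr.coupling_energy
    ko, kc = _engine.ryr_rates(cru.dyad.ca_ss, cru.dyad.ca_jsr,
                               cru.ryr.n_open, cru.ryr.sensitivity_scale, pp)
    rates = lcc_transition_rates(vm, cru.dyad.ca_ss, cru.lcc, params)
    maxr = max(ko, kc, *rates.values())
    if maxr * dt > 1.0:
        raise ValueError(
            f"rate*dt = {maxr * dt:.3g} > 1: adaptive timestep control failed")
    seed = np.uint64(rng.seed)
    ident = np.uint64(rng._ident)
    cc = np.uint64(rng.counter)

    no = cru.ryr.n_open
    p_open = -math.expm1(-ko * dt)
    p_close = -math.expm1(-kc * dt)
    n_up, cc = _engine.binomial_counter(cru.ryr.n_total - no, p_open, seed, ident, cc)
    n_dn, cc = _engine.binomial_counter(no, p_close, seed, ident, cc)
    new_ryr = replace(cru.ryr, n_open=no + int(n_up) - int(n_dn))

    al, be = rates["activation"], rates["deactivation"]
    kvi, krec = rates["v_inactivation"], rates["v_recovery"]
    kcam, krec_cam = rates["ca_cam_inactivation"], rates["ca_cam_recovery"]
    nC, nO, nVI, nCaI = (int(x) for x in cru.lcc.counts)
    dC_O = dC_VI = dO_C = dO_VI = dO_CaI = dVI_C = dCaI_C = 0
    rC = al + kvi
    if nC and rC > 0:
        nx, cc = _engine.binomial_counter(nC, -math.expm1(-rC * dt), seed, ident, cc)
        if nx:
            dC_O, cc = _engine.binomial_counter(int(nx), al / rC, seed, ident, cc)
            dC_VI = int(nx) - int(dC_O)
    rO = be + kvi + kcam
    if nO and rO > 0:
        nx, cc = _engine.binomial_counter(nO, -math.expm1(-rO * dt), seed, ident, cc)
        if nx:
            dO_C, cc = _engine.binomial_counter(int(nx), be / rO, seed, ident, cc)
            rem = int(nx) - int(dO_C)
            if rem and kvi + kcam > 0:
                dO_VI, cc = _engine.binomial_counter(rem, kvi / (kvi + kcam),
                                                     seed, ident, cc)
                dO_CaI = rem - int(dO_VI)
    if nVI and krec > 0:
        dVI_C, cc = _engine.binomial_counter(nVI, -math.expm1(-krec * dt),
                                             seed, ident, cc)
    if nCaI and krec_cam > 0:
        dCaI_C, cc = _engine.binomial_counter(nCaI, -math.expm1(-krec_cam * dt),
                                              seed, ident, cc)
    counts = np.array([nC - dC_O - dC_VI + dO_C + dVI_C + dCaI_C,
                       nO + dC_O - dO_C - dO_VI - dO_CaI,
                       nVI + dC_VI + dO_VI - dVI_C,
                       nCaI + dO_CaI - dCaI_C], dtype=np.int64)
    rng.counter = int(cc)
    return replace(cru, ryr=new_ryr, lcc=LCCComplexState(counts=counts))


def dyad_fluxes(cru: CRUnit, ca_myo: float, ca_nsr: float,
                params: GatingRateParams | None = None,
                cell: CellGeometryParams | None = None) -> dict[str, float]:
    """Local Ca2+ fluxes of one unit, as uM/ms in the destination compartment.

    J_release: JSR -> subspace through open RyR2s; J_refill: NSR -> JSR;
    J_efflux: subspace -> myoplasm; J_buffer: net binding to the subspace
    buffer (uM/ms removed from free subspace Ca2+).  Every flux appears with
    opposite sign, volume-weighted, in its source compartment.
    """
    if ca_myo < 0 or ca_nsr < 0:
        raise ValueError("concentrations must be >= 0")
    g = params or GatingRateParams()
    cgeo = cell or CellGeometryParams()
    v_ss = cru.dyad.v_ss
    q_release = g.d_ryr * cru.ryr.n_open * (cru.dyad.ca_jsr - cru.dyad.ca_ss)
    q_refill = g.d_refill * (ca_nsr - cru.dyad.ca_jsr)
    q_efflux = g.d_eff * (cru.dyad.ca_ss - ca_myo)
    j_buffer = (g.bss_kon * cru.dyad.ca_ss * (g.bss_tot - cru.dyad.buffer_ss)
                - g.bss_koff * cru.dyad.buffer_ss)
    return {
        "J_release": q_release / v_ss,
        "J_refill": q_refill / cgeo.v_jsr,
        "J_efflux": q_efflux / cgeo.v_myo,
        "J_buffer": j_buffer,
    }


def force_open_ryrs(cru: CRUnit, n: int) -> CRUnit:
    """Force at least n RyR2 channels open (spontaneous-release trigger).

    The opened channels are not clamped: they close again through the normal
    stochastic gating.
    """
    if not 0 <= n <= cru.ryr.n_total:
        raise ValueError(f"n must lie in [0, {cru.ryr.n_total}]")
    return replace(cru, ryr=replace(cru.ryr, n_open=max(cru.ryr.n_open, n)))


def cluster_stationary_open_fraction(ca_ss: float, ca_jsr: float,
                                     params: GatingRateParams,
                                     n_total: int = 49,
                                     sensitivity_scale: float = 1.0) -> float:
    """Exact stationary expected open fraction of the cluster at clamped Ca2+.

    The cluster is a birth-death chain on n_open = 0..n_total; the stationary
    vector has the product form pi(n+1)/pi(n) = b(n)/d(n+1) and is evaluated
    in log space.  Used as the independent oracle for the Monte Carlo gating.
    """
    ryr = RyRClusterState(n_total=n_total, coupling_energy=params.ryr_coupling,
                          sensitivity_scale=sensitivity_scale)
    log_pi = np.zeros(n_total + 1)
    for n in range(n_total):
        ko, _ = ryr_transition_rates(ca_ss, ca_jsr, n, ryr, params)
        _, kc = ryr_transition_rates(ca_ss, ca_jsr, n + 1, ryr, params)
        birth = (n_total - n) * ko
        death = (n + 1) * kc
        if birth == 0.0:
            # absorbing at n: chain cannot move up; all mass stays below
            log_pi[n + 1:] = -np.inf
            break
        log_pi[n + 1] = log_pi[n] + math.log(birth) - math.log(death)
    log_pi -= log_pi[np.isfinite(log_pi)].max()
    pi = np.exp(log_pi)
    pi /= pi.sum()
    if not np.all(np.isfinite(pi)):
        raise RuntimeError("stationary solve did not converge")
    return float((pi * np.arange(n_total + 1)).sum() / n_total)
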