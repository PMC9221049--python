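"""Tissue geometry, gap-junction coupling and network integration.

Cells are abstract lattice nodes joined by nearest-neighbour gap junctions
with axis-dependent conductance (anisotropic tissue); boundaries are no-flux
(a boundary cell simply has fewer neighbours).  Geometries: 1-D cable, 2-D
sheet, 3-D block, and a trabecula (stacked boxes on a wall block).

The network state lives in flat arrays advanced by the compiled kernels in
:mod:`cardionet._engine` under an adaptive explicit-Euler scheme: the step
is bounded so that at most a configured fraction of calcium release units
is expected to undergo a channel transition, no single channel sees a
transition probability above ``pchan_max``, and the fastest continuous
rates stay resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import copy as _copy

import numpy as np

from . import _engine
from .params import ModelParams, Phenotype, pack_params
from ._engine import (D_NSTEPS, D_MAXFRAC, D_NCLIP, D_ERROR, D_CROSSTIME,
                      D_MAXDVM, D_IREC, D_EVIDX, ERR_DT_UNDERFLOW, ERR_VM_BLOWUP)

__all__ = [
    "TissueGeometry", "TimestepPolicy", "NetworkState", "SimResult",
    "SimulationError", "build_lattice", "build_trabecula",
    "select_adaptive_dt", "step_tissue", "run_network", "run_simulation",
    "total_calcium",
]

AXIS_LONG, AXIS_TRANS, AXIS_SHEET = 0, 1, 2


class SimulationError(RuntimeError):
    """Raised when the integrator detects instability or timestep failure."""


@dataclass(frozen=True)
class TissueGeometry:
    """Cell lattice with per-edge gap conductances (nS) and no-flux boundary."""

    kind: str
    dims: tuple
    coords: np.ndarray          # (n, 3) int lattice coordinates
    e0: np.ndarray              # (m,) int edge endpoint a
    e1: np.ndarray              # (m,) int edge endpoint b
    g_gap: np.ndarray           # (m,) float conductance nS
    axis: np.ndarray            # (m,) int axis label of each edge
    cell_length_um: float = 100.0

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.e0.shape[0]

    def index_of(self, coord) -> int:
        """Cell index of a lattice coordinate."""
        c = np.asarray(coord, dtype=np.int64)
        hit = np.nonzero((self.coords == c).all(axis=1))[0]
        if hit.size == 0:
            raise KeyError(f"no cell at {tuple(c)}")
        return int(hit[0])

    def neighbor_counts(self) -> np.ndarray:
        cnt = np.zeros(self.n_cells, dtype=np.int64)
        np.add.at(cnt, self.e0, 1)
        np.add.at(cnt, self.e1, 1)
        return cnt

    def gsum(self) -> np.ndarray:
        """Total gap conductance incident on each cell (nS)."""
        g = np.zeros(self.n_cells)
        np.add.at(g, self.e0, self.g_gap)
        np.add.at(g, self.e1, self.g_gap)
        return g


@dataclass(frozen=True)
class TimestepPolicy:
    """Adaptive-timestep bounds (ms) and the CRU-transition fraction rule.

    Desk-scale defaults: dt_max 5e-3 ms with the <=10 % expected-transition
    rule; the native fine-grained bounds (1e-5 to 1e-4 ms) remain selectable
    for convergence studies.
    """

    dt_min: float = 1.0e-5
    dt_max: float = 5.0e-3
    max_cru_transition_fraction: float = 0.10
    pchan_max: float = 0.2

    def __post_init__(self):
        if not 0 < self.dt_min <= self.dt_max:
            raise ValueError("require 0 < dt_min <= dt_max")
        if not 0 < self.max_cru_transition_fraction <= 1:
            raise ValueError("max_cru_transition_fraction must lie in (0, 1]")


def _edges_from_coords(coords: np.ndarray, g_axis: tuple[float, float, float]):
    """Nearest-neighbour edges among `coords` with axis-labelled conductances."""
    index = {tuple(c): i for i, c in enumerate(coords.tolist())}
    e0, e1, gg, ax = [], [], [], []
    for i, c in enumerate(coords.tolist()):
        for axis in range(3):
            nb = list(c)
            nb[axis] += 1
            j = index.get(tuple(nb))
            if j is not None:
                e0.append(i)
                e1.append(j)
                gg.append(g_axis[axis])
                ax.append(axis)
    return (np.asarray(e0, dtype=np.int64), np.asarray(e1, dtype=np.int64),
            np.asarray(gg, dtype=np.float64), np.asarray(ax, dtype=np.int64))


def build_lattice(dims, g_long: float = 2500.0, g_trans: float = 800.0,
                  g_sheet: float | None = None,
                  cell_length_um: float = 100.0) -> TissueGeometry:
    """Build a 1-D cable, 2-D sheet or 3-D block of gap-coupled myocytes.

    Axis 0 is longitudinal (conductance ``g_long``), axis 1 transverse,
    axis 2 the sheet-normal direction (defaults to ``g_trans``).
    """
    dims = tuple(int(d) for d in np.atleast_1d(dims))
    if len(dims) == 0 or any(d <= 0 for d in dims):
        raise ValueError(f"lattice dims must be positive, got {dims}")
    if len(dims) > 3:
        raise ValueError("at most 3 dimensions")
    full = dims + (1,) * (3 - len(dims))
    coords = np.stack(np.meshgrid(*[np.arange(d) for d in full],
                                  indexing="ij"), axis=-1).reshape(-1, 3)
    g_sheet = g_trans if g_sheet is None else g_sheet
    e0, e1, gg, ax = _edges_from_coords(coords, (g_long, g_trans, g_sheet))
    kind = {1: "cable", 2: "sheet", 3: "block"}[len(dims)]
    return TissueGeometry(kind=kind, dims=dims, coords=coords, e0=e0, e1=e1,
                          g_gap=gg, axis=ax, cell_length_um=cell_length_um)


def build_trabecula(cube_dims=(20, 20, 20),
                    segment_dims_list=((6, 6, 7), (4, 4, 6), (2, 2, 5)),
                    g_long: float = 2500.0, g_trans: float = 800.0,
                    g_sheet: float | None = None,
                    cell_length_um: float = 100.0) -> TissueGeometry:
    """A trabecula: successively narrower boxes stacked on a wall block.

    Each segment is centred on the top face of the structure below it and
    joined face-to-face; the longitudinal (high-conductance) axis is the
    stacking axis z.  The default dimensions give 20^3 + 6*6*7 + 4*4*6 +
    2*2*5 = 8368 cells.
    """
    cube = tuple(int(d) for d in cube_dims)
    if any(d <= 0 for d in cube):
        raise ValueError("cube dims must be positive")
    coords = []
    for x in range(cube[0]):
        for y in range(cube[1]):
            for z in range(cube[2]):
                coords.append((x, y, z))
    base_x0, base_y0 = 0, 0
    base_dx, base_dy = cube[0], cube[1]
    z0 = cube[2]
    for seg in segment_dims_list:
        sx, sy, sz = (int(d) for d in seg)
        if sx <= 0 or sy <= 0 or sz <= 0:
            raise ValueError("segment dims must be positive")
        x0 = base_x0 + (base_dx - sx) // 2
        y0 = base_y0 + (base_dy - sy) // 2
        if x0 < base_x0 or y0 < base_y0 or x0 + sx > base_x0 + base_dx \
                or y0 + sy > base_y0 + base_dy:
            raise ValueError(f"segment {seg} overhangs the face below it")
        for x in range(x0, x0 + sx):
            for y in range(y0, y0 + sy):
                for z in range(z0, z0 + sz):
                    coords.append((x, y, z))
        base_x0, base_y0, base_dx, base_dy = x0, y0, sx, sy
        z0 += sz
    coords = np.asarray(coords, dtype=np.int64)
    g_sheet = g_trans if g_sheet is None else g_sheet
    # stacking axis z is longitudinal for a strand
    e0, e1, gg, ax = _edges_from_coords(coords, (g_trans, g_sheet, g_long))
    return TissueGeometry(kind="trabecula", dims=cube, coords=coords,
                          e0=e0, e1=e1, g_gap=gg, axis=ax,
                          cell_length_um=cell_length_um)


# --------------------------------------------------------------------------

class NetworkState:
    """Flat-array state of every cell and coarse-grained CRU in a network."""

    def __init__(self, n_cells: int, params: ModelParams, seed: int,
                 n_cru: int | None = None, multiplicity: int | None = None):
        self.params = params
        self.pp = pack_params(params)
        self.seed = int(seed)
        self.n = int(n_cells)
        self.K = params.cell.n_cru if n_cru is None else int(n_cru)
        self.mult = (params.cell.multiplicity if multiplicity is None
                     else int(multiplicity))
        n, K = self.n, self.K
        g = params.gating
        c = params.cell
        self.t = 0.0
        self.vm = np.full(n, -80.0)
        self.cai = np.full(n, 0.1)
        self.cansr = np.full(n, 1000.0)
        self.nai = np.full(n, 10.0)
        self.ki = np.full(n, 140.0)
        self.gates = np.zeros((n, 8))
        gr = _engine.gate_rates(-80.0)
        ss = [gr[0] / (gr[0] + gr[1]), gr[2] / (gr[2] + gr[3]),
              gr[4] / (gr[4] + gr[5]), gr[6], gr[8], gr[10], gr[12], gr[14]]
        self.gates[:] = np.asarray(ss)
        self.bufm = np.zeros((n, 3))
        self.bufm[:, 0] = c.cmdn_tot * 0.1 / (0.1 + c.cmdn_koff / c.cmdn_kon)
        self.bufm[:, 1] = c.trpn_tot * 0.1 / (0.1 + c.trpn_koff / c.trpn_kon)
        self.bufm[:, 2] = c.bulk_tot * 0.1 / (0.1 + c.bulk_koff / c.bulk_kon)
        self.ryr_o = np.zeros((n, K), dtype=np.int64)
        self.lcc = np.zeros((n, K, 4), dtype=np.int64)
        self.lcc[:, :, 0] = c.n_lcc
        self.cass = np.full((n, K), 0.1)
        self.cajsr = np.full((n, K), 1000.0)
        self.bss = np.full((n, K), g.bss_tot * 0.1 / (0.1 + g.bss_koff / g.bss_kon))
        self.bjsr = np.full((n, K), g.bjsr_tot * 1000.0
                            / (1000.0 + g.bjsr_koff / g.bjsr_kon))
        self.vssf = np.ones((n, K))
        self.ctr = np.zeros((n, K), dtype=np.uint64)
        self.scales = np.ones((n, 5))  # ito, ik1, ncx, serca, ryr_sens
        self.phenotype_names = ["control"] * n
        self._scratch = None

    def copy(self) -> "NetworkState":
        """Deep copy (checkpoint); resuming from it reproduces the original run."""
        new = _copy.copy(self)
        for nm in ("vm", "cai", "cansr", "nai", "ki", "gates", "bufm",
                   "ryr_o", "lcc", "cass", "cajsr", "bss", "bjsr", "vssf",
                   "ctr", "scales"):
            setattr(new, nm, getattr(self, nm).copy())
        new.phenotype_names = list(self.phenotype_names)
        new._scratch = None
        return new

    def broadcast_cell(self, src: "NetworkState", cells=None, src_cell: int = 0):
        """Copy one settled cell's state onto (a subset of) this network's cells."""
        if src.K != self.K:
            raise ValueError("CRU counts differ")
        cells = range(self.n) if cells is None else cells
        for c in cells:
            self.vm[c] = src.vm[src_cell]
            self.cai[c] = src.cai[src_cell]
            self.cansr[c] = src.cansr[src_cell]
            self.nai[c] = src.nai[src_cell]
            self.ki[c] = src.ki[src_cell]
            self.gates[c] = src.gates[src_cell]
            self.bufm[c] = src.bufm[src_cell]
            self.ryr_o[c] = src.ryr_o[src_cell]
            self.lcc[c] = src.lcc[src_cell]
            self.cass[c] = src.cass[src_cell]
            self.cajsr[c] = src.cajsr[src_cell]
            self.bss[c] = src.bss[src_cell]
            self.bjsr[c] = src.bjsr[src_cell]
            self.vssf[c] = src.vssf[src_cell]
            self.scales[c] = src.scales[src_cell]
            self.phenotype_names[c] = src.phenotype_names[src_cell]

    def scratch(self):
        if self._scratch is None:
            n, K = self.n, max(self.K, 1)
            self._scratch = dict(
                sc_dvm=np.zeros(self.n), sc_cder=np.zeros((n, 7)),
                sc_gr=np.zeros((n, 16)), sc_ko=np.zeros((n, K)),
                sc_kc=np.zeros((n, K)), sc_kcam=np.zeros((n, K)),
                sc_lccr=np.zeros((n, 4)), sc_coup=np.zeros(n),
                sc_iapp=np.zeros(n), sc_qeff=np.zeros(n),
                sc_qref=np.zeros(n), sc_mcass=np.zeros(n), sc_nlcc=np.zeros(n),
            )
        return self._scratch


def total_calcium(state: NetworkState) -> float:
    """Total Ca2+ amount (uM*um^3): free + buffered over every compartment.

    The conservation audit quantity: constant when sarcolemmal Ca2+ fluxes
    are disabled.
    """
    c = state.params.cell
    amt = (c.v_myo * (state.cai + state.bufm.sum(axis=1))
           + c.v_nsr * state.cansr).sum()
    v_ss_u = c.v_ss * state.vssf
    amt += state.mult * (v_ss_u * (state.cass + state.bss)
                         + c.v_jsr * (state.cajsr + state.bjsr)).sum()
    return float(amt)


# --------------------------------------------------------------------------

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


@dataclass
class SimResult:
    """Recorded traces and provenance of one network simulation."""

    time: np.ndarray            # (s,) ms
    vm: np.ndarray              # (s, n) mV
    ca_myo: np.ndarray          # (s, n) uM
    ca_nsr: np.ndarray          # (s, n) uM
    ryr_open_frac: np.ndarray   # (s, n)
    ca_ss_mean: np.ndarray      # (s, n) uM
    activation_time: np.ndarray  # (n,) ms, -1 if never crossed 0 mV
    events: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0


def _network_rates(state: NetworkState) -> tuple[float, float, float]:
    """(sum of CRU exit rates, max per-channel rate, max gate rate) right now."""
    pp = state.pp
    r_sum = 0.0
    r_chan = 0.0
    r_gate = 0.0
    for c in range(state.n):
        al, be, kvi, krec = _engine.lcc_voltage_rates(state.vm[c], pp)
        gr = _engine.gate_rates(state.vm[c])
        r_gate = max(r_gate, gr[0] + gr[1])
        for u in range(state.K):
            ko, kc = _engine.ryr_rates(state.cass[c, u], state.cajsr[c, u],
                                       state.ryr_o[c, u], state.scales[c, 4], pp)
            kcam = _engine.lcc_cam_rate(state.cass[c, u], pp)
            no = state.ryr_o[c, u]
            nC, nO, nVI, nCaI = state.lcc[c, u]
            r_sum += ((state.params.cell.n_ryr - no) * ko + no * kc
                      + nC * (al + kvi) + nO * (be + kvi + kcam)
                      + nVI * krec + nCaI * state.params.gating.lcc_k_cam_rec)
            r_chan = max(r_chan, ko, kc, al + kvi, be + kvi + kcam)
    return r_sum, r_chan, r_gate


def select_adaptive_dt(state: NetworkState, policy: TimestepPolicy,
                       geometry: TissueGeometry | None = None) -> float:
    """Choose the next timestep under the CRU-transition and stability rules.

    The expected number of CRUs with at least one channel transition within
    the returned dt is at most ``max_cru_transition_fraction`` of all CRUs
    (via the linear bound sum(rates)*dt), no per-channel transition
    probability exceeds ``pchan_max``, and the fastest continuous rate
    (gap coupling, Na+ gate, subspace relaxation) is resolved with margin.
    """
    r_sum, r_chan, r_gate = _network_rates(state)
    n_units = max(state.n * state.K, 1)
    pp = state.pp
    g = state.params.gating
    c = state.params.cell
    from .params import P_A_M, P_C_SC
    r_const = g.d_eff / c.v_ss + g.bss_kon * g.bss_tot + c.bulk_kon * c.bulk_tot
    if geometry is not None and geometry.n_edges > 0:
        r_couple = 1e-6 * geometry.gsum().max() / (pp[P_A_M] * pp[P_C_SC])
        r_const = max(r_const, r_couple)
    dt = policy.dt_max
    if r_sum > 0:
        dt = min(dt, policy.max_cru_transition_fraction * n_units / r_sum)
    if r_chan > 0:
        dt = min(dt, policy.pchan_max / r_chan)
    r_cont = max(r_const, r_gate)
    if r_cont > 0:
        dt = min(dt, 0.5 / r_cont)
    if dt < policy.dt_min:
        raise SimulationError(
            f"required dt {dt:.3g} ms below dt_min {policy.dt_min:.3g} ms")
    return float(dt)


def _diag_dict(diag: np.ndarray) -> dict:
    return {
        "n_steps": int(diag[D_NSTEPS]),
        "max_cru_transition_fraction": float(diag[D_MAXFRAC]),
        "n_clip_events": int(diag[D_NCLIP]),
        "max_dvm": float(diag[D_MAXDVM]),
    }


def _run_engine(state: NetworkState, geometry: TissueGeometry | None,
                policy: TimestepPolicy, t_end: float,
                stim_rows=None, events=None, record_dt: float = 0.5,
                act_t: np.ndarray | None = None,
                watch_cell: int = -1, stop_grace: float = 5.0,
                fail_window: float = -1.0,
                rec_from: float | None = None):
    """Low-level driver: advance `state` to t_end, recording at `record_dt`.

    Returns (times, traces dict, act_t, diagnostics dict).
    """
    n = state.n
    if geometry is None:
        e0, e1, gg = _EMPTY_I, _EMPTY_I, _EMPTY_F
        gsum = np.zeros(n)
    else:
        e0, e1, gg = geometry.e0, geometry.e1, geometry.g_gap
        gsum = geometry.gsum()
    if stim_rows:
        s_cell = np.asarray([r[0] for r in stim_rows], dtype=np.int64)
        s_amp = np.asarray([r[1] for r in stim_rows], dtype=np.float64)
        s_on = np.asarray([r[2] for r in stim_rows], dtype=np.float64)
        s_off = np.asarray([r[3] for r in stim_rows], dtype=np.float64)
    else:
        s_cell, s_amp, s_on, s_off = _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F
    if events:
        ev = sorted(events)
        ev_t = np.asarray([e[0] for e in ev], dtype=np.float64)
        ev_c = np.asarray([e[1] for e in ev], dtype=np.int64)
        ev_u = np.asarray([e[2] for e in ev], dtype=np.int64)
        ev_n = np.asarray([e[3] for e in ev], dtype=np.int64)
    else:
        ev_t, ev_c, ev_u, ev_n = _EMPTY_F, _EMPTY_I, _EMPTY_I, _EMPTY_I
    bounds = np.unique(np.concatenate([s_on, s_off]))

    t0 = state.t
    rec_from = t0 if rec_from is None else rec_from
    n_rec = max(int(np.floor((t_end - rec_from) / record_dt + 1e-9)) + 1, 1)
    rec_t = rec_from + np.arange(n_rec) * record_dt
    rec_vm = np.zeros((n_rec, n))
    rec_cai = np.zeros((n_rec, n))
    rec_cansr = np.zeros((n_rec, n))
    rec_ryrf = np.zeros((n_rec, n))
    rec_casm = np.zeros((n_rec, n))
    if act_t is None:
        act_t = np.full(n, -1.0)

    diag = np.zeros(8)
    diag[D_CROSSTIME] = -1.0
    fail_t0 = t0
    if s_off.size:
        fail_t0 = max(fail_t0, float(s_off.max()))
    if ev_t.size:
        fail_t0 = max(fail_t0, float(ev_t.max()))
    sc = state.scratch()
    # record the initial sample if it falls on the grid
    t_final = _engine.advance(
        state.pp, state.scales, float(state.mult),
        state.vm, state.cai, state.cansr, state.nai, state.ki,
        state.gates, state.bufm,
        state.ryr_o, state.lcc, state.cass, state.cajsr, state.bss,
        state.bjsr, state.vssf, state.ctr,
        e0, e1, gg, gsum,
        s_cell, s_amp, s_on, s_off,
        ev_t, ev_c, ev_u, ev_n,
        bounds,
        np.uint64(state.seed), t0, float(t_end),
        policy.dt_min, policy.dt_max,
        policy.max_cru_transition_fraction, policy.pchan_max,
        float(record_dt), rec_t, rec_vm, rec_cai, rec_cansr, rec_ryrf, rec_casm,
        act_t, int(watch_cell), float(stop_grace),
        float(fail_t0), float(fail_window),
        sc["sc_dvm"], sc["sc_cder"], sc["sc_gr"], sc["sc_ko"], sc["sc_kc"],
        sc["sc_kcam"], sc["sc_lccr"], sc["sc_coup"], sc["sc_iapp"],
        sc["sc_qeff"], sc["sc_qref"], sc["sc_mcass"], sc["sc_nlcc"],
        diag)
    state.t = float(t_final)
    err = diag[D_ERROR]
    if err == ERR_DT_UNDERFLOW:
        raise SimulationError("adaptive timestep fell below dt_min "
                              "(stability failure)")
    if err == ERR_VM_BLOWUP:
        raise SimulationError("membrane potential left [-200, 200] mV "
                              "(unstable step)")
    irec = int(diag[D_IREC])
    traces = {"vm": rec_vm[:irec], "ca_myo": rec_cai[:irec],
              "ca_nsr": rec_cansr[:irec], "ryr_open_frac": rec_ryrf[:irec],
              "ca_ss_mean": rec_casm[:irec]}
    d = _diag_dict(diag)
    d["watch_cross_time"] = float(diag[D_CROSSTIME])
    return rec_t[:irec], traces, act_t, d


def step_tissue(state: NetworkState, geometry: TissueGeometry,
                policy: TimestepPolicy) -> float:
    """Advance the whole network by one adaptive step; returns the dt taken."""
    dt = select_adaptive_dt(state, policy, geometry)
    t0 = state.t
    _run_engine(state, geometry, policy, t0 + dt, record_dt=max(2 * dt, 1e-6))
    return state.t - t0


def run_network(state: NetworkState, geometry: TissueGeometry | None,
                policy: TimestepPolicy, t_end: float,
                stim_rows=None, events=None, record_dt: float = 0.5,
                watch_cell: int = -1, stop_grace: float = 5.0,
                fail_window: float = -1.0,
                config: dict | None = None) -> SimResult:
    """Run protocol events on a network and collect traces.

    ``stim_rows``: iterable of (cell, amplitude uA/cm^2, t_on, t_off).
    ``events``: iterable of (t, cell, cru, n_channels) forced RyR2 openings.
    ``watch_cell``: optional early stop shortly after this cell activates.
    Deterministic for a given (state, seed, arguments).
    """
    times, traces, act_t, diags = _run_engine(
        state, geometry, policy, t_end, stim_rows=stim_rows, events=events,
        record_dt=record_dt, watch_cell=watch_cell, stop_grace=stop_grace,
        fail_window=fail_window)
    ev_log = [{"t": float(e[0]), "cell": int(e[1]), "cru": int(e[2]),
               "n_channels": int(e[3])} for e in (events or [])]
    for r in (stim_rows or []):
        ev_log.append({"t": float(r[2]), "cell": int(r[0]),
                       "stimulus_uA_cm2": float(r[1]),
                       "duration_ms": float(r[3] - r[2])})
    ev_log.sort(key=lambda e: e["t"])
    return SimResult(time=times, vm=traces["vm"], ca_myo=traces["ca_myo"],
                     ca_nsr=traces["ca_nsr"],
                     ryr_open_frac=traces["ryr_open_frac"],
                     ca_ss_mean=traces["ca_ss_mean"],
                     activation_time=act_t, events=ev_log,
                     diagnostics=diags, config=config or {}, seed=state.seed)


def run_simulation(config) -> SimResult:
    """Run one fully configured simulation (see :mod:`cardionet.config`).

    Builds the geometry, settles and broadcasts the initial cell state,
    applies phenotype and protocol, integrates to ``run.t_end_ms`` and
    returns the recorded traces.  Deterministic for a given (config, seed);
    if ``run.output`` is set the results and the resolved config are written
    there.
    """
    from .config import SimulationConfig
    from .myocyte import initialize_quiescent, apply_phenotype
    from .protocols import (make_stimulus, stimulus_rows, target_family,
                            SpontaneousReleaseProtocol, StimulusProtocol,
                            spontaneous_release_events)
    from .params import CONTROL_PHENOTYPE

    cfg = config
    params = cfg.model_params()
    geom = cfg.build_geometry()
    policy = cfg.timestep_policy()
    seed = int(cfg.run["seed"])
    n_cru = int(cfg.cell["n_cru"])
    mult = int(cfg.cell["multiplicity"])
    settle = float(cfg.cell["settle_ms"])
    ph = cfg.phenotype_obj()

    proto = cfg.protocol
    if proto.get("target_cells"):
        targets = tuple(int(c) for c in proto["target_cells"])
    elif proto["kind"] == "none":
        targets = ()
    else:
        fam = target_family(geom, spacing=int(proto.get("spacing", 0) or 0),
                            end_block=int(proto.get("end_block", 0) or 0))
        targets = fam(int(proto["n_target_cells"]))

    nw = NetworkState(geom.n_cells, params, seed, n_cru=n_cru,
                      multiplicity=mult)
    ctrl = initialize_quiescent(params, seed=seed + 101, n_cru=n_cru,
                                multiplicity=mult, settle_ms=settle,
                                policy=policy, check=False).network
    nw.broadcast_cell(ctrl)
    ph_cells_mode = cfg.phenotype.get("cells", "targets")
    if ph.name != "control" and ph_cells_mode != "none":
        ph_tpl = initialize_quiescent(params, seed=seed + 102, phenotype=ph,
                                      n_cru=n_cru, multiplicity=mult,
                                      settle_ms=settle, policy=policy,
                                      check=False).network
        cells = range(nw.n) if ph_cells_mode == "all" else list(targets)
        nw.broadcast_cell(ph_tpl, cells=cells)
        apply_phenotype(nw, ph, cells=cells, seed=seed)

    stim, events = [], []
    onset = float(proto.get("onset", 5.0))
    if proto["kind"] == "stimulus" and targets:
        if proto.get("amplitude") is not None:
            sp = StimulusProtocol(target_cells=targets,
                                  amplitude=float(proto["amplitude"]),
                                  duration=float(proto["duration"]),
                                  onset=onset)
        else:
            sp = make_stimulus(proto["stimulus"], targets, onset=onset)
        stim = stimulus_rows(sp)
    elif proto["kind"] == "spontaneous" and targets:
        sp = SpontaneousReleaseProtocol(
            target_cells=targets, cru_fraction=float(proto["cru_fraction"]),
            channels_opened=int(proto["channels_opened"]), onset=onset)
        events = spontaneous_release_events(nw, sp, seed=seed)

    res = run_network(nw, geom, policy, float(cfg.run["t_end_ms"]),
                      stim_rows=stim, events=events,
                      record_dt=float(cfg.run["record_dt_ms"]),
                      config=cfg.to_dict())
    out = cfg.run.get("output")
    if out:
        from .results import write_results
        write_results(res, out)
    return res
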