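"""Experiment protocols: stimuli, spontaneous release, thresholds.

The central question: what is the minimal number of myocytes whose
activation — by current injection at fixed charge mass, or by spontaneous
RyR2 openings in a fraction of their release units — launches a sustained
propagating action potential through the rest of the tissue?

Success of a trial is judged from the voltage traces: a cell counts as
activated when its membrane potential first crosses 0 mV; propagation
succeeds when at least 95% of the non-stimulated cells activate and the
most distal cells activate.  Because gating is stochastic, the minimal cell
count is defined by a majority rule over repeated trials with logged seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Phenotype, ModelParams, CONTROL_PHENOTYPE
from .rng import derive_stream
from .tissue import (TissueGeometry, TimestepPolicy, NetworkState, SimResult,
                     run_network)
from .myocyte import apply_phenotype, initialize_quiescent

__all__ = [
    "StimulusProtocol", "SpontaneousReleaseProtocol", "PropagationOutcome",
    "ThresholdResult", "make_stimulus", "stimulus_rows",
    "spontaneous_release_events", "apply_spontaneous_release",
    "detect_propagation", "find_min_cells", "make_noncontiguous_pattern",
    "ThresholdSetup", "measure_conduction_velocity", "target_family",
]

#: Equal-charge stimulus pair: slow 5 ms and fast 2 ms injections, both
#: carrying -32.60 uA/cm^2*ms.
GRADUAL_AMPLITUDE, GRADUAL_DURATION = -6.52, 5.0
INSTANT_AMPLITUDE, INSTANT_DURATION = -16.30, 2.0

_PURPOSE_SPONT = 202


@dataclass(frozen=True)
class StimulusProtocol:
    """Applied-current description for a set of target cells."""

    target_cells: tuple
    amplitude: float            # uA/cm^2, negative = depolarizing
    duration: float             # ms
    onset: float = 0.0          # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if len(self.target_cells) == 0:
            raise ValueError("target set must be non-empty")

    @property
    def charge_mass(self) -> float:
        """Total current mass, uA/cm^2 * ms."""
        return self.amplitude * self.duration


@dataclass(frozen=True)
class SpontaneousReleaseProtocol:
    """Forced RyR2 openings in a random subset of each target cell's CRUs."""

    target_cells: tuple
    cru_fraction: float = 0.5
    channels_opened: int = 10
    onset: float = 0.0

    def __post_init__(self):
        if not 0 < self.cru_fraction <= 1:
            raise ValueError("cru_fraction must lie in (0, 1]")
        if self.channels_opened < 0:
            raise ValueError("channels_opened must be >= 0")


@dataclass(frozen=True)
class PropagationOutcome:
    """Verdict of one trial."""

    success: bool
    activation_time: np.ndarray     # ms per cell, nan if never
    conduction_velocity: float | None
    fraction_activated: float


@dataclass
class ThresholdResult:
    """Minimal activated-cell count under the majority success rule."""

    n_min: int
    outcomes: dict = field(default_factory=dict)  # N -> list of (seed, bool)
    p_threshold: float = 0.5
    trials: int = 5
    seeds: dict = field(default_factory=dict)      # N -> list of seeds

    def success_rate(self, n: int) -> float:
        o = self.outcomes[n]
        return sum(1 for _, s in o if s) / len(o)


def make_stimulus(kind: str, target_cells, onset: float = 0.0) -> StimulusProtocol:
    """The equal-charge-mass stimulus pair.

    ``gradual``: -6.52 uA/cm^2 for 5 ms; ``instantaneous``: -16.30 uA/cm^2
    for 2 ms — both deliver -32.60 uA/cm^2*ms.
    """
    if kind == "gradual":
        amp, dur = GRADUAL_AMPLITUDE, GRADUAL_DURATION
    elif kind == "instantaneous":
        amp, dur = INSTANT_AMPLITUDE, INSTANT_DURATION
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    return StimulusProtocol(target_cells=tuple(int(c) for c in target_cells),
                            amplitude=amp, duration=dur, onset=float(onset))


def stimulus_rows(proto: StimulusProtocol) -> list:
    """(cell, amplitude, t_on, t_off) rows for the integrator."""
    return [(c, proto.amplitude, proto.onset, proto.onset + proto.duration)
            for c in proto.target_cells]


def _spont_unit_subset(network: NetworkState, cell: int,
                       proto: SpontaneousReleaseProtocol,
                       seed: int | None) -> np.ndarray:
    n_units = int(round(proto.cru_fraction * network.K))
    rng = derive_stream(network.seed if seed is None else seed,
                        cell=cell, purpose=_PURPOSE_SPONT)
    return rng.choice_without_replacement(network.K, n_units)


def spontaneous_release_events(network: NetworkState,
                               proto: SpontaneousReleaseProtocol,
                               seed: int | None = None) -> list:
    """Scheduled forced-opening events (t, cell, cru, n_channels).

    Each target cell receives forced openings of ``channels_opened`` RyR2s
    in a seed-reproducible random subset of exactly
    round(cru_fraction * n_cru) coarse units at the protocol onset.
    """
    n_ryr = network.params.cell.n_ryr
    if proto.channels_opened > n_ryr:
        raise ValueError(f"channels_opened exceeds cluster size {n_ryr}")
    events = []
    for c in proto.target_cells:
        if not 0 <= c < network.n:
            raise ValueError(f"target cell {c} outside network")
        for u in _spont_unit_subset(network, int(c), proto, seed):
            events.append((proto.onset, int(c), int(u), proto.channels_opened))
    return events


def apply_spontaneous_release(network: NetworkState,
                              proto: SpontaneousReleaseProtocol,
                              seed: int | None = None) -> NetworkState:
    """Apply the forced openings to the network state immediately."""
    for t, c, u, nch in spontaneous_release_events(network, proto, seed):
        if network.ryr_o[c, u] < nch:
            network.ryr_o[c, u] = nch
    return network


def _distal_set(geometry: TissueGeometry, stim_cells: np.ndarray) -> np.ndarray:
    """Indices of the cells farthest (lattice distance) from the stimulus."""
    coords = geometry.coords.astype(float)
    if stim_cells.size:
        ref = coords[stim_cells]
        d = np.min(np.linalg.norm(coords[:, None, :] - ref[None, :, :], axis=2),
                   axis=1)
    else:
        d = np.linalg.norm(coords - coords[0], axis=1)
    dmax = d.max()
    return np.nonzero(d >= dmax - 1e-9)[0]


def detect_propagation(result: SimResult, geometry: TissueGeometry,
                       stim_cells=None, activation_vm: float = 0.0,
                       min_fraction: float = 0.95) -> PropagationOutcome:
    """Judge a trial from its traces and activation times.

    A cell's activation time is its first upward crossing of
    ``activation_vm`` (0 mV by default, recorded exactly by the
    integrator).  Success requires >= ``min_fraction`` of non-stimulated
    cells to activate and every most-distal cell to activate.  Conduction
    velocity is cell_length over the median consecutive-cell delay in the
    central half of the longitudinal path (stimulus and boundary zones
    excluded).
    """
    if result.time.size == 0:
        raise ValueError("traces shorter than the stimulus window")
    act = result.activation_time.copy()
    act_ok = act >= 0.0
    stim_cells = np.asarray(sorted(stim_cells or []), dtype=np.int64)
    non_stim = np.setdiff1d(np.arange(geometry.n_cells), stim_cells)
    frac = float(act_ok[non_stim].mean()) if non_stim.size else 0.0
    distal = _distal_set(geometry, stim_cells)
    success = frac >= min_fraction and bool(act_ok[distal].all())

    cv = None
    if success:
        cv = _conduction_velocity_from_activation(act, geometry)
    act_out = np.where(act_ok, act, np.nan)
    return PropagationOutcome(success=success, activation_time=act_out,
                              conduction_velocity=cv,
                              fraction_activated=frac)


def _conduction_velocity_from_activation(act: np.ndarray,
                                         geometry: TissueGeometry) -> float | None:
    """Median-delay conduction velocity (m/s) along the longitudinal axis."""
    # order cells along the longitudinal coordinate of the first lattice line
    long_axis = 2 if geometry.kind == "trabecula" else 0
    line = geometry.coords.copy()
    other = [a for a in range(3) if a != long_axis]
    on_line = (line[:, other[0]] == line[:, other[0]].min()) \
        & (line[:, other[1]] == line[:, other[1]].min())
    idx = np.nonzero(on_line)[0]
    order = np.argsort(line[idx, long_axis])
    path = idx[order]
    if path.size < 8:
        return None
    q = path.size // 4
    central = path[q:path.size - q]
    t_c = act[central]
    if np.any(t_c < 0):
        return None
    delays = np.diff(t_c)
    med = float(np.median(delays))
    if med <= 0:
        return None
    return geometry.cell_length_um / med * 1e-3  # um/ms -> m/s


def measure_conduction_velocity(result: SimResult,
                                geometry: TissueGeometry) -> float | None:
    """Conduction velocity (m/s) of a successful run's wavefront."""
    return _conduction_velocity_from_activation(result.activation_time, geometry)


def target_family(geometry: TissueGeometry, spacing: int = 0,
                  end_block: int = 0):
    """Default N -> target-cell-set family for a geometry.

    Cable: the first N cells (optionally a non-contiguous pattern);
    sheet/block: a compact square patch in the corner; trabecula: cells
    taken from the strand tip downward (2 x 2 columns for the published
    tip).
    """
    if geometry.kind == "cable":
        if spacing > 0 or end_block > 0:
            n_len = geometry.n_cells

            def build(n):
                return make_noncontiguous_pattern(n, spacing, end_block, n_len)
        else:
            def build(n):
                return tuple(range(n))
        return build
    if geometry.kind in ("sheet", "block"):
        coords = geometry.coords
        # row-major distance from the corner, then lexicographic
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0],
                            coords.max(axis=1)))

        def build(n):
            return tuple(int(i) for i in order[:n])
        return build
    if geometry.kind == "trabecula":
        coords = geometry.coords
        order = np.lexsort((coords[:, 0], coords[:, 1], -coords[:, 2]))

        def build(n):
            return tuple(int(i) for i in order[:n])
        return build
    raise ValueError(f"no default family for geometry kind {geometry.kind!r}")


def make_noncontiguous_pattern(n_stimulated: int, spacing: int,
                               end_block: int, cable_length: int) -> tuple:
    """Deterministic non-contiguous stimulation pattern on a cable.

    ``end_block`` contiguous cells at the cable end, then stimulated cells
    separated by ``spacing`` unstimulated cells.  With spacing 0 and no end
    block this reduces to the standard contiguous pattern.
    """
    if n_stimulated < end_block:
        raise ValueError("n_stimulated must be >= end_block")
    cells = list(range(end_block))
    pos = end_block + spacing
    while len(cells) < n_stimulated:
        cells.append(pos)
        pos += 1 + spacing
    if cells and cells[-1] >= cable_length:
        raise ValueError(
            f"pattern (last index {cells[-1]}) exceeds cable length {cable_length}")
    return tuple(cells)


# --------------------------------------------------------------------------

@dataclass
class ThresholdSetup:
    """Everything needed to run one minimal-cell-count search on a geometry.

    ``protocol_family`` maps a cell count N to the concrete target set;
    built-ins: contiguous end cells on a cable, 2 x 2 columns from a
    trabecula tip, square patches on sheets/blocks.
    """

    geometry: TissueGeometry
    params: ModelParams
    phenotype: Phenotype = CONTROL_PHENOTYPE
    stimulus_kind: str | None = "gradual"      # None for spontaneous release
    spont: SpontaneousReleaseProtocol | None = None
    n_cru: int = 50
    multiplicity: int = 400
    settle_ms: float = 1000.0
    t_end: float = 120.0
    onset: float = 5.0
    record_dt: float = 1.0
    fail_window: float = 50.0
    policy: TimestepPolicy = field(default_factory=TimestepPolicy)
    target_builder: object = None               # callable N -> cell indices
    phenotype_cells: str = "targets"            # "targets" | "all" | "none"

    def targets(self, n: int) -> tuple:
        if self.target_builder is not None:
            return tuple(self.target_builder(n))
        return tuple(range(n))


def _settled_template(setup: ThresholdSetup, phenotype: Phenotype, seed: int):
    return initialize_quiescent(
        setup.params, seed=seed, phenotype=phenotype, n_cru=setup.n_cru,
        multiplicity=setup.multiplicity, settle_ms=setup.settle_ms,
        policy=setup.policy, check=False).network


def build_trial_runner(setup: ThresholdSetup):
    """Return runner(N, seed) -> (success, SimResult) for one trial.

    A control cell (and, if needed, a phenotype cell) is settled once and
    broadcast over the geometry; each trial perturbs only the seed of the
    stochastic gating streams.
    """
    geom = setup.geometry
    ctrl_tpl = _settled_template(setup, CONTROL_PHENOTYPE, seed=12345)
    ph_tpl = None
    if setup.phenotype.name != "control" and setup.phenotype_cells != "none":
        ph_tpl = _settled_template(setup, setup.phenotype, seed=12346)

    def runner(n_cells: int, seed: int):
        targets = setup.targets(n_cells)
        nw = NetworkState(geom.n_cells, setup.params, seed,
                          n_cru=setup.n_cru, multiplicity=setup.multiplicity)
        nw.broadcast_cell(ctrl_tpl)
        if ph_tpl is not None:
            cells = (range(nw.n) if setup.phenotype_cells == "all"
                     else list(targets))
            nw.broadcast_cell(ph_tpl, cells=cells)
            apply_phenotype(nw, setup.phenotype, cells=cells, seed=seed)
        stim, events = [], []
        if setup.stimulus_kind is not None:
            proto = make_stimulus(setup.stimulus_kind, targets,
                                  onset=setup.onset)
            stim = stimulus_rows(proto)
        if setup.spont is not None:
            sp = SpontaneousReleaseProtocol(
                target_cells=targets, cru_fraction=setup.spont.cru_fraction,
                channels_opened=setup.spont.channels_opened, onset=setup.onset)
            events = spontaneous_release_events(nw, sp, seed=seed)
        distal = _distal_set(geom, np.asarray(targets, dtype=np.int64))
        res = run_network(nw, geom, setup.policy, setup.t_end,
                          stim_rows=stim, events=events,
                          record_dt=setup.record_dt,
                          watch_cell=int(distal[-1]), stop_grace=10.0,
                          fail_window=setup.fail_window)
        out = detect_propagation(res, geom, stim_cells=targets)
        return out.success, res

    return runner


def find_min_cells(runner, n_max: int, trials: int = 5,
                   p_threshold: float = 0.5, seed: int = 0,
                   n_start: int = 1) -> ThresholdResult:
    """Smallest N whose success rate over `trials` is >= `p_threshold`.

    Linear scan upward from ``n_start`` (thresholds are small and success
    need not be monotone on single trials); per-N trials stop early once the
    majority verdict is decided.  The failure at n_min - 1 is part of the
    recorded outcomes.  Seeds are logged for exact replay.
    """
    need = int(np.ceil(p_threshold * trials))
    result = ThresholdResult(n_min=-1, p_threshold=p_threshold, trials=trials)
    for n in range(n_start, n_max + 1):
        outcomes = []
        seeds = []
        succ = fail = 0
        for r in range(trials):
            s = seed + 1000 * n + r
            ok, _ = runner(n, s)
            outcomes.append((s, bool(ok)))
            seeds.append(s)
            succ += ok
            fail += not ok
            if succ >= need or fail > trials - need:
                break
        result.outcomes[n] = outcomes
        result.seeds[n] = seeds
        if succ >= need:
            result.n_min = n
            return result
    raise RuntimeError(
        f"no threshold found up to N = {n_max}; outcomes: "
        f"{ {k: [o[1] for o in v] for k, v in result.outcomes.items()} }")
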