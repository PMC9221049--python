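"""Model parameters: membrane, calcium release unit, and phenotype blocks.

All rates are ms^-1, voltages mV, Ca2+ in uM, Na+/K+ in mM, volumes um^3,
conductances for membrane currents mS/cm^2 (densities), gap junctions nS,
membrane currents uA/cm^2 with inward negative.

The dataclasses are the public surface; :func:`pack_params` flattens them
into a float64 vector consumed by the compiled kernels.  Index constants
``P_<NAME>`` are generated from ``PARAM_FIELDS`` so the two views cannot
drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import numpy as np

__all__ = [
    "GatingRateParams", "MembraneParams", "CellGeometryParams", "Phenotype",
    "ModelParams", "pack_params", "unpack_params", "default_params",
    "CONTROL_PHENOTYPE", "HF_PHENOTYPE", "FARADAY", "RTF",
]

FARADAY = 96.485  # C/mmol
RTF = 26.712  # mV at 37 C


@dataclass(frozen=True)
class GatingRateParams:
    """Stochastic channel gating rates for one calcium release unit.

    RyR2 cluster: two-state channels whose opening rate follows a saturating
    power law in the effective activating Ca2+ (cleft Ca2+ scaled by a linear
    junctional-SR lumen factor and the phenotype sensitivity), with an
    Ising-type mean-field coupling across the cluster and no Ca2+-dependent
    inactivation.  L-type channels: four states (closed, open,
    voltage-inactivated, Ca2+-calmodulin-inactivated).
    """

    # RyR2
    ryr_k_plus: float = 3.0e-5      # ms^-1 uM^-eta, opening prefactor
    ryr_eta: float = 3.0            # Ca activation exponent
    ryr_k_minus: float = 0.4        # ms^-1, closing base rate
    ryr_coupling: float = 1.0       # mean-field coupling strength a
    ryr_k_open_max: float = 30.0    # ms^-1, saturating ceiling of opening rate
    ryr_jsr_ref: float = 1000.0     # uM, lumen Ca at which the lumen factor is 1
    # L-type (LCC)
    lcc_g: float = 2.0e-3           # pA/mV single-channel slope conductance
    lcc_erev: float = 60.0          # mV effective reversal
    lcc_tau_d: float = 2.0          # ms activation time constant
    lcc_vhalf_d: float = -10.0      # mV activation midpoint
    lcc_kslope_d: float = 6.24      # mV activation slope
    lcc_tau_f: float = 30.0         # ms voltage-inactivation time constant
    lcc_vhalf_f: float = -23.0      # mV inactivation midpoint
    lcc_kslope_f: float = 6.0       # mV inactivation slope
    lcc_k_cam: float = 0.01         # ms^-1 uM^-1 Ca-CaM inactivation slope
    lcc_k_cam_max: float = 5.0      # ms^-1 ceiling of Ca-CaM inactivation
    lcc_k_cam_rec: float = 0.01     # ms^-1 recovery from Ca-CaM inactivation
    # Dyad fluxes (um^3/ms unless noted)
    d_ryr: float = 1.5e-3           # per open RyR2, JSR -> subspace
    d_eff: float = 0.1              # subspace -> myoplasm efflux
    d_refill: float = 1.0e-3        # NSR -> JSR refill
    # Subspace / JSR buffers (uM, ms^-1 uM^-1, ms^-1)
    bss_tot: float = 47.0
    bss_kon: float = 0.1
    bss_koff: float = 1.0
    bjsr_tot: float = 13500.0
    bjsr_kon: float = 0.1
    bjsr_koff: float = 63.0


@dataclass(frozen=True)
class MembraneParams:
    """Sarcolemmal current densities and ion-handling parameters (Eq.-1 set)."""

    c_sc: float = 1.0               # uF/cm^2 specific capacitance
    a_m: float = 5.0e-4             # cm^2 effective membrane area (incl. t-tubules)
    g_na: float = 8.0               # mS/cm^2 fast Na+ (conduction-calibrated)
    na_tau_scale: float = 1.0       # scales all fast-Na gate time constants
    na_shift: float = 0.0           # mV depolarizing shift of Na activation
    g_k1: float = 0.7               # mS/cm^2 inward rectifier scale
    g_ktof: float = 0.40            # mS/cm^2 fast transient outward K+
    g_ktos: float = 0.05            # mS/cm^2 slow transient outward K+
    g_kss: float = 0.05             # mS/cm^2 steady-state K+
    i_nak_max: float = 8.05553      # uA/cm^2 Na/K pump ceiling (rest-balance solve)
    km_nai_nak: float = 21.0        # mM
    km_ko_nak: float = 1.5          # mM
    v_ncx: float = 250.0            # uA/cm^2 NCX scale (see calibration)
    km_na_ncx: float = 87.5         # mM
    km_ca_ncx: float = 1380.0       # uM external Ca half-saturation
    km_cai_ncx: float = 150.0       # uM internal (sensed) Ca saturation
    ksat_ncx: float = 0.1
    eta_ncx: float = 0.35
    ncx_dyadic_fraction: float = 0.20  # fraction of NCX sensing subspace Ca
    i_pmca_max: float = 0.05        # uA/cm^2
    km_pmca: float = 0.5            # uM
    g_b_ca: float = 2.05208e-04     # mS/cm^2 background Ca (rest-balance solve)
    g_b_na: float = 1.60276e-02     # mS/cm^2 background Na (rest-balance solve)
    g_b_k: float = 1.0e-3           # mS/cm^2 background K
    
    na_o: float = 140.0             # mM
    ca_o: float = 1800.0            # uM
    k_o: float = 5.4                # mM


@dataclass(frozen=True)
class CellGeometryParams:
    """Compartment volumes, CRU architecture and myoplasmic buffers."""

    v_myo: float = 20000.0          # um^3 myoplasm
    v_nsr: float = 1000.0           # um^3 network SR
    v_jsr: float = 0.02             # um^3 junctional SR per physical CRU
    v_ss: float = 1.0e-3            # um^3 dyadic subspace per physical CRU
    n_ryr: int = 49                 # RyR2 channels per cluster
    n_lcc: int = 7                  # L-type channels per cluster
    n_cru: int = 200                # coarse-grained release units per cell
    multiplicity: int = 100         # physical CRUs per coarse unit
    orphan_vss_factor: float = 30.0
    # Myoplasmic buffers
    cmdn_tot: float = 24.0          # uM calmodulin
    cmdn_kon: float = 0.1
    cmdn_koff: float = 0.238
    trpn_tot: float = 70.0          # uM troponin
    trpn_kon: float = 0.0327
    trpn_koff: float = 0.0196
    bulk_tot: float = 400.0         # uM low-affinity pool (ATP, SL, myofilament)
    bulk_kon: float = 0.05
    bulk_koff: float = 1.0          # Kd 20 uM
    # SERCA2a (thermodynamically reversible)
    serca_vmax: float = 0.9         # uM/ms referenced to v_myo
    serca_kmf: float = 0.25         # uM forward half-saturation
    serca_kmr: float = 2500.0       # uM reverse half-saturation
    serca_h: float = 1.787          # Hill exponent


@dataclass(frozen=True)
class Phenotype:
    """Multiplicative remodeling transforms (control = all ones)."""

    name: str = "control"
    scale_ito: float = 1.0
    scale_ik1: float = 1.0
    scale_ncx: float = 1.0
    scale_serca: float = 1.0
    ryr_sensitivity: float = 1.0
    orphan_fraction: float = 0.0
    orphan_vss_factor: float = 30.0

    def __post_init__(self):
        for f in ("scale_ito", "scale_ik1", "scale_ncx", "scale_serca",
                  "ryr_sensitivity"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        if not 0.0 <= self.orphan_fraction <= 1.0:
            raise ValueError("orphan_fraction must lie in [0, 1]")


#: Heart-failure remodeling: I_to and I_K1 down 20%, NCX expression doubled,
#: SERCA2a down 30%, RyR2 Ca sensitivity up 50%, 25% of CRUs orphaned through
#: a 30-fold subspace volume increase.
HF_PHENOTYPE = Phenotype(name="hf", scale_ito=0.8, scale_ik1=0.8, scale_ncx=2.0,
                         scale_serca=0.7, ryr_sensitivity=1.5,
                         orphan_fraction=0.25, orphan_vss_factor=30.0)
CONTROL_PHENOTYPE = Phenotype()


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of one myocyte model."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    gating: GatingRateParams = field(default_factory=GatingRateParams)
    cell: CellGeometryParams = field(default_factory=CellGeometryParams)
    # Global switches used by conservation audits and passive-membrane tests
    sarcolemmal_ca_off: bool = False
    ionic_currents_off: bool = False
    clamp_na_k: bool = False

    def to_dict(self) -> dict:
        d = {"membrane": asdict(self.membrane), "gating": asdict(self.gating),
             "cell": asdict(self.cell),
             "sarcolemmal_ca_off": self.sarcolemmal_ca_off,
             "ionic_currents_off": self.ionic_currents_off,
             "clamp_na_k": self.clamp_na_k}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(membrane=MembraneParams(**d.get("membrane", {})),
                   gating=GatingRateParams(**d.get("gating", {})),
                   cell=CellGeometryParams(**d.get("cell", {})),
                   sarcolemmal_ca_off=bool(d.get("sarcolemmal_ca_off", False)),
                   ionic_currents_off=bool(d.get("ionic_currents_off", False)),
                   clamp_na_k=bool(d.get("clamp_na_k", False)))


# --- flat packing for the compiled kernels ---------------------------------

PARAM_FIELDS = (
    # membrane
    "c_sc", "a_m", "g_na", "na_tau_scale", "na_shift", "g_k1", "g_ktof", "g_ktos", "g_kss",
    "i_nak_max", "km_nai_nak", "km_ko_nak",
    "v_ncx", "km_na_ncx", "km_ca_ncx", "km_cai_ncx", "ksat_ncx", "eta_ncx",
    "ncx_dyadic_fraction", "i_pmca_max", "km_pmca",
    "g_b_ca", "g_b_na", "g_b_k", "na_o", "ca_o", "k_o",
    # cell geometry / buffers / serca
    "v_myo", "v_nsr", "v_jsr", "v_ss", "n_ryr", "n_lcc",
    "cmdn_tot", "cmdn_kon", "cmdn_koff", "trpn_tot", "trpn_kon", "trpn_koff",
    "bulk_tot", "bulk_kon", "bulk_koff",
    "serca_vmax", "serca_kmf", "serca_kmr", "serca_h",
    # gating
    "ryr_k_plus", "ryr_eta", "ryr_k_minus", "ryr_coupling",
    "ryr_k_open_max", "ryr_jsr_ref",
    "lcc_g", "lcc_erev", "lcc_tau_d", "lcc_vhalf_d", "lcc_kslope_d",
    "lcc_tau_f", "lcc_vhalf_f", "lcc_kslope_f",
    "lcc_k_cam", "lcc_k_cam_max", "lcc_k_cam_rec",
    "d_ryr", "d_eff", "d_refill",
    "bss_tot", "bss_kon", "bss_koff", "bjsr_tot", "bjsr_kon", "bjsr_koff",
    # switches
    "sl_ca_off", "ionic_off", "clamp_na_k",
)

_g = globals()
for _i, _nm in enumerate(PARAM_FIELDS):
    _g["P_" + _nm.upper()] = _i
N_PARAMS = len(PARAM_FIELDS)


def pack_params(p: ModelParams) -> np.ndarray:
    """Flatten a ModelParams into the float64 vector the kernels consume."""
    src = {}
    src.update(asdict(p.membrane))
    src.update(asdict(p.cell))
    src.update(asdict(p.gating))
    src["sl_ca_off"] = 1.0 if p.sarcolemmal_ca_off else 0.0
    src["ionic_off"] = 1.0 if p.ionic_currents_off else 0.0
    src["clamp_na_k"] = 1.0 if p.clamp_na_k else 0.0
    out = np.empty(N_PARAMS, dtype=np.float64)
    for i, nm in enumerate(PARAM_FIELDS):
        out[i] = float(src[nm])
    return out


def unpack_params(v: np.ndarray) -> dict:
    """Inverse view of :func:`pack_params` (name -> value)."""
    return {nm: float(v[i]) for i, nm in enumerate(PARAM_FIELDS)}


def default_params(**overrides) -> ModelParams:
    """Calibrated control-cell defaults (see docs/methods.md, calibration)."""
    p = ModelParams()
    if overrides:
        p = replace(p, **overrides)
    return p
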