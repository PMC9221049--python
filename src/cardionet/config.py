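"""Simulation configuration: strict schema, loading, and fixture builders.

A configuration file (YAML) fully determines a run: geometry, phenotype,
protocol, numerics, cell discretisation, and run control.  Loading is
strict — unknown keys are errors and every default is made explicit in the
resolved config, because threshold counts are sensitive to parameters and a
silently defaulted value would make results irreproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import copy

import yaml

from .params import ModelParams, Phenotype, CONTROL_PHENOTYPE, HF_PHENOTYPE

__all__ = ["SimulationConfig", "load_config", "dump_config", "resolve_config",
           "make_fixture", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violated the schema."""


_GEOMETRY_KEYS = {"kind", "dims", "g_long", "g_trans", "g_sheet",
                  "cell_length_um", "cube_dims", "segments"}
_PROTOCOL_KEYS = {"kind", "stimulus", "amplitude", "duration", "onset",
                  "n_target_cells", "target_cells", "cru_fraction",
                  "channels_opened", "spacing", "end_block"}
_PHENOTYPE_KEYS = {"name", "cells", "scale_ito", "scale_ik1", "scale_ncx",
                   "scale_serca", "ryr_sensitivity", "orphan_fraction",
                   "orphan_vss_factor"}
_NUMERICS_KEYS = {"dt_min", "dt_max", "max_cru_transition_fraction",
                  "pchan_max"}
_CELL_KEYS = {"n_cru", "multiplicity", "settle_ms"}
_RUN_KEYS = {"t_end_ms", "record_dt_ms", "seed", "output"}
_TOP_KEYS = {"geometry", "phenotype", "protocol", "numerics", "cell", "run",
             "params"}


def _check_keys(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{where}': {sorted(unknown)}")


@dataclass
class SimulationConfig:
    """Fully resolved simulation description (all defaults explicit)."""

    geometry: dict = field(default_factory=lambda: {
        "kind": "cable", "dims": [100], "g_long": 2500.0, "g_trans": 800.0,
        "g_sheet": 800.0, "cell_length_um": 100.0,
        "cube_dims": [20, 20, 20],
        "segments": [[6, 6, 7], [4, 4, 6], [2, 2, 5]]})
    phenotype: dict = field(default_factory=lambda: {
        "name": "control", "cells": "targets"})
    protocol: dict = field(default_factory=lambda: {
        "kind": "stimulus", "stimulus": "gradual", "amplitude": None,
        "duration": None, "onset": 5.0, "n_target_cells": 7,
        "target_cells": None, "cru_fraction": 0.5, "channels_opened": 10,
        "spacing": 0, "end_block": 0})
    numerics: dict = field(default_factory=lambda: {
        "dt_min": 1.0e-5, "dt_max": 5.0e-3,
        "max_cru_transition_fraction": 0.10, "pchan_max": 0.2})
    cell: dict = field(default_factory=lambda: {
        "n_cru": 50, "multiplicity": 400, "settle_ms": 1000.0})
    run: dict = field(default_factory=lambda: {
        "t_end_ms": 120.0, "record_dt_ms": 1.0, "seed": 1, "output": None})
    params: dict = field(default_factory=dict)   # nested ModelParams overrides

    def to_dict(self) -> dict:
        return copy.deepcopy(asdict(self))

    def model_params(self) -> ModelParams:
        base = ModelParams().to_dict()
        for sect, vals in self.params.items():
            if sect not in base:
                raise ConfigError(f"unknown params section '{sect}'")
            if isinstance(base[sect], dict):
                for k, v in vals.items():
                    if k not in base[sect]:
                        raise ConfigError(f"unknown parameter '{sect}.{k}'")
                    base[sect][k] = v
            else:
                base[sect] = vals
        return ModelParams.from_dict(base)

    def phenotype_obj(self) -> Phenotype:
        ph = dict(self.phenotype)
        ph.pop("cells", None)
        name = ph.pop("name", "control")
        if name == "control" and not ph:
            return CONTROL_PHENOTYPE
        if name == "hf" and not ph:
            return HF_PHENOTYPE
        base = asdict(HF_PHENOTYPE if name == "hf" else CONTROL_PHENOTYPE)
        base.update(ph)
        base["name"] = name
        return Phenotype(**base)

    def build_geometry(self):
        from .tissue import build_lattice, build_trabecula
        g = self.geometry
        if g["kind"] in ("cable", "sheet", "block"):
            return build_lattice(tuple(g["dims"]), g_long=g["g_long"],
                                 g_trans=g["g_trans"], g_sheet=g["g_sheet"],
                                 cell_length_um=g["cell_length_um"])
        if g["kind"] == "trabecula":
            return build_trabecula(tuple(g["cube_dims"]),
                                   [tuple(s) for s in g["segments"]],
                                   g_long=g["g_long"], g_trans=g["g_trans"],
                                   g_sheet=g["g_sheet"],
                                   cell_length_um=g["cell_length_um"])
        raise ConfigError(f"unknown geometry kind {g['kind']!r}")

    def timestep_policy(self):
        from .tissue import TimestepPolicy
        return TimestepPolicy(**self.numerics)


def resolve_config(raw: dict) -> SimulationConfig:
    """Validate a raw mapping against the schema and fill every default."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    cfg = SimulationConfig()
    for name, allowed in (("geometry", _GEOMETRY_KEYS),
                          ("phenotype", _PHENOTYPE_KEYS),
                          ("protocol", _PROTOCOL_KEYS),
                          ("numerics", _NUMERICS_KEYS),
                          ("cell", _CELL_KEYS), ("run", _RUN_KEYS)):
        block = raw.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"'{name}' must be a mapping")
        _check_keys(block, allowed, name)
        getattr(cfg, name).update(block)
    cfg.params = copy.deepcopy(raw.get("params", {}))

    g = cfg.geometry
    if g["kind"] in ("cable", "sheet", "block"):
        dims = g["dims"]
        if not dims or any(int(d) <= 0 for d in dims):
            raise ConfigError(f"geometry.dims must be positive, got {dims}")
    for key in ("dt_min", "dt_max"):
        if cfg.numerics[key] <= 0:
            raise ConfigError(f"numerics.{key} must be > 0")
    if cfg.cell["n_cru"] < 0 or cfg.cell["multiplicity"] < 1:
        raise ConfigError("cell.n_cru must be >= 0 and multiplicity >= 1")
    if cfg.run["seed"] < 0:
        raise ConfigError("run.seed must be non-negative")
    cfg.model_params()       # validates the params overrides
    cfg.phenotype_obj()      # validates phenotype fields
    return cfg


def load_config(path) -> SimulationConfig:
    """Load and strictly validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return resolve_config(raw)


def dump_config(cfg: SimulationConfig, path) -> None:
    """Write the fully resolved configuration next to the outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def make_fixture(kind: str) -> SimulationConfig:
    """Self-contained tiny configurations used by the test suite.

    ``single_cru``: one cell with one coarse unit; ``single_cell``: a full
    myocyte; ``cable_small``: 30 cells at reduced CRU count; ``sheet_small``:
    a 20 x 20 sheet; ``trabecula_paper``: the published trabecula geometry
    (8368 cells).
    """
    if kind == "single_cru":
        raw = {"geometry": {"kind": "cable", "dims": [1]},
               "cell": {"n_cru": 1, "multiplicity": 20000, "settle_ms": 0.0},
               "protocol": {"kind": "none"},
               "run": {"t_end_ms": 10.0, "record_dt_ms": 0.5}}
    elif kind == "single_cell":
        raw = {"geometry": {"kind": "cable", "dims": [1]},
               "cell": {"n_cru": 200, "multiplicity": 100,
                        "settle_ms": 500.0},
               "protocol": {"kind": "stimulus", "stimulus": "instantaneous",
                            "n_target_cells": 1},
               "run": {"t_end_ms": 150.0, "record_dt_ms": 0.5}}
    elif kind == "cable_small":
        raw = {"geometry": {"kind": "cable", "dims": [30]},
               "cell": {"n_cru": 20, "multiplicity": 1000,
                        "settle_ms": 400.0},
               "protocol": {"kind": "stimulus", "stimulus": "gradual",
                            "n_target_cells": 7},
               "run": {"t_end_ms": 60.0, "record_dt_ms": 1.0}}
    elif kind == "sheet_small":
        raw = {"geometry": {"kind": "sheet", "dims": [20, 20]},
               "cell": {"n_cru": 20, "multiplicity": 1000,
                        "settle_ms": 400.0},
               "protocol": {"kind": "stimulus", "stimulus": "gradual",
                            "n_target_cells": 9},
               "run": {"t_end_ms": 80.0, "record_dt_ms": 1.0}}
    elif kind == "trabecula_paper":
        raw = {"geometry": {"kind": "trabecula"},
               "cell": {"n_cru": 10, "multiplicity": 2000,
                        "settle_ms": 200.0},
               "protocol": {"kind": "stimulus", "stimulus": "gradual",
                            "n_target_cells": 20, "onset": 2.0},
               "run": {"t_end_ms": 80.0, "record_dt_ms": 1.0}}
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    return resolve_config(raw)
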