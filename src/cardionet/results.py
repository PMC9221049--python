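"""Result serialization: HDF5 containers and CSV export.

A simulation's traces, activation times, event log, resolved configuration,
seed and package version are stored in one HDF5 file; small runs can also
be exported as CSV for quick inspection.  Threshold sweeps are written as
flat CSV tables (one row per geometry/protocol/phenotype combination).
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .tissue import SimResult

__all__ = ["write_results", "read_results", "export_csv",
           "threshold_table", "write_threshold_csv"]

_CSV_MAX_SAMPLES = 10_000


def write_results(result: SimResult, path) -> str:
    """Write one simulation result as an HDF5 container.

    Datasets: time, vm, ca_myo, ca_nsr, ryr_open_frac, ca_ss_mean,
    activation_time; attributes carry the event log, resolved config, seed
    and package version as JSON.  Small runs additionally get a CSV next to
    the container.
    """
    from . import __version__
    path = str(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=result.time)
        fh.create_dataset("vm", data=result.vm)
        fh.create_dataset("ca_myo", data=result.ca_myo)
        fh.create_dataset("ca_nsr", data=result.ca_nsr)
        fh.create_dataset("ryr_open_frac", data=result.ryr_open_frac)
        fh.create_dataset("ca_ss_mean", data=result.ca_ss_mean)
        fh.create_dataset("activation_time", data=result.activation_time)
        fh.attrs["events"] = json.dumps(result.events)
        fh.attrs["config"] = json.dumps(result.config)
        fh.attrs["diagnostics"] = json.dumps(result.diagnostics)
        fh.attrs["seed"] = result.seed
        fh.attrs["version"] = __version__
    if result.time.size * max(result.vm.shape[1], 1) <= _CSV_MAX_SAMPLES:
        export_csv(result, path + ".csv")
    return path


def read_results(path) -> SimResult:
    """Read back a container written by :func:`write_results`."""
    with h5py.File(str(path), "r") as fh:
        return SimResult(
            time=fh["time"][:], vm=fh["vm"][:], ca_myo=fh["ca_myo"][:],
            ca_nsr=fh["ca_nsr"][:], ryr_open_frac=fh["ryr_open_frac"][:],
            ca_ss_mean=fh["ca_ss_mean"][:],
            activation_time=fh["activation_time"][:],
            events=json.loads(fh.attrs["events"]),
            diagnostics=json.loads(fh.attrs["diagnostics"]),
            config=json.loads(fh.attrs["config"]),
            seed=int(fh.attrs["seed"]))


def export_csv(result: SimResult, path) -> str:
    """Flat CSV of the voltage and Ca2+ traces (small runs only)."""
    n = result.vm.shape[1]
    cols = {"time_ms": result.time}
    for c in range(n):
        cols[f"vm_{c}"] = result.vm[:, c]
        cols[f"ca_myo_{c}"] = result.ca_myo[:, c]
    pd.DataFrame(cols).to_csv(str(path), index=False)
    return str(path)


def threshold_table(entries) -> pd.DataFrame:
    """Tabulate threshold-search results.

    ``entries``: iterable of dicts with keys dimensionality, protocol,
    phenotype, n_min, n_cells (total cells in the geometry).  The percentage
    column mirrors the published table layout.
    """
    rows = []
    for e in entries:
        pct = 100.0 * e["n_min"] / e["n_cells"]
        rows.append({"dimensionality": e["dimensionality"],
                     "protocol": e["protocol"],
                     "phenotype": e["phenotype"],
                     "n_min": int(e["n_min"]),
                     "pct": round(pct, 3)})
    return pd.DataFrame(rows, columns=["dimensionality", "protocol",
                                       "phenotype", "n_min", "pct"])


def write_threshold_csv(entries, path) -> str:
    threshold_table(entries).to_csv(str(path), index=False)
    return str(path)
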