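"""Delimited-text and structured-text serialization for every pipeline stage.

Interchange formats are deliberately plain: comma-delimited tables with an
explicit header plus a leading ``# units:`` comment line, and YAML for
parameter sets and fit reports.  All numbers are written at full precision;
rounding is a display concern.  Reports carry a schema version.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .amplification import NeuronCurrentSet
from .calibration import DoseResponseCurve
from .model import GatingParams
from .surface import TitrationSurface

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "read_curve",
    "write_curve",
    "read_surface",
    "write_surface",
    "read_neuron_currents",
    "write_neuron_currents",
    "read_params",
    "write_params",
    "write_report",
    "read_report",
    "file_checksum",
]

REPORT_SCHEMA_VERSION = 1


def _read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    units: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            if line.lstrip("# ").startswith("units:"):
                spec = line.split("units:", 1)[1].strip()
                for item in spec.split():
                    if "=" in item:
                        key, val = item.split("=", 1)
                        units[key] = val
            body_start = k + 1
        else:
            break
    df = pd.read_csv(
        _io.StringIO("\n".join(lines[body_start:])), float_precision="round_trip"
    )
    return df, units


def write_curve(curve: DoseResponseCurve, path) -> None:
    path = Path(path)
    d = {"dose": curve.dose, "response": curve.response}
    d["sem"] = curve.sem if curve.sem is not None else np.full(len(curve), np.nan)
    d["n"] = curve.n if curve.n is not None else np.full(len(curve), np.nan)
    df = pd.DataFrame(d)
    with open(path, "w") as fh:
        fh.write(
            f"# units: dose={curve.dose_units or 'unknown'} "
            f"response={curve.response_units or 'unknown'} label={curve.label or '-'}\n"
        )
        df.to_csv(fh, index=False)


def read_curve(path) -> DoseResponseCurve:
    df, units = _read_table(path)
    sem = df["sem"].to_numpy() if "sem" in df and df["sem"].notna().all() else None
    n = df["n"].to_numpy() if "n" in df and df["n"].notna().all() else None
    return DoseResponseCurve(
        dose=df["dose"].to_numpy(),
        response=df["response"].to_numpy(),
        sem=sem,
        n=n,
        dose_units=units.get("dose", ""),
        response_units=units.get("response", ""),
        label=units.get("label", "").replace("-", "") or "",
    )


def write_surface(surface: TitrationSurface, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units: nta_mole_fraction=mole_fraction na_mM=mM norm_current=normalized\n")
        surface.to_frame().to_csv(fh, index=False)


def read_surface(path) -> TitrationSurface:
    df, _ = _read_table(path)
    return TitrationSurface.from_frame(df)


def write_neuron_currents(sets: list[NeuronCurrentSet], path) -> None:
    rows = []
    cell = 0
    for s in sets:
        for c in s.currents_pA:
            rows.append({"cell_id": f"c{cell:03d}", "na_internal_mM": s.na_internal_mM,
                         "current_pA": c})
            cell += 1
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# units: na_internal_mM=mM current_pA=pA\n")
        df.to_csv(fh, index=False)


def read_neuron_currents(path) -> dict[float, NeuronCurrentSet]:
    """Returns one NeuronCurrentSet per internal Na+ level, keyed by mM."""
    df, _ = _read_table(path)
    out = {}
    for na, grp in df.groupby("na_internal_mM"):
        out[float(na)] = NeuronCurrentSet(
            currents_pA=grp["current_pA"].to_numpy(), na_internal_mM=float(na)
        )
    return out


def write_params(params: GatingParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def read_params(path) -> GatingParams:
    with open(path) as fh:
        return GatingParams.from_dict(yaml.safe_load(fh))


def _pyify(obj):
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_pyify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_report(report: dict, path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **_pyify(report)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_report(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_checksum(path) -> str:
    """SHA-256 of a file, for stage-boundary reproducibility logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
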