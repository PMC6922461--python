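"""CSV and JSON input/output with unit normalisation.

The long-form titration dialect has columns
``series_id, role, x_value, x_unit, y_value, y_unit, replicate``;
concentrations are normalised to molar and times to minutes on read.
Dose-response experiments use their own dialect:
``experiment_id, dose_value, dose_type, response_value, response_unit,
is_control``.  Bead tables: ``bead_id, MFI, capacity``.

Results serialise to schema-versioned JSON records carrying parameters,
standard errors, sse, n, convergence flags, seed and software version,
so a run is auditable without rerunning it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import TitrationSeries, EquilibriumSeries, ROLES

SCHEMA_VERSION = "1.0"

#: Multipliers to the canonical unit (molar for concentration, minutes
#: for time; AU/RU pass through).
CONCENTRATION_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
                       "nM": 1e-9, "pM": 1e-12}
TIME_UNITS = {"min": 1.0, "s": 1.0 / 60.0, "h": 60.0}
PASSTHROUGH_UNITS = {"AU", "RU", "count", "normalized"}

TITRATION_COLUMNS = ["series_id", "role", "x_value", "x_unit",
                     "y_value", "y_unit", "replicate"]
DOSE_RESPONSE_COLUMNS = ["experiment_id", "dose_value", "dose_type",
                         "response_value", "response_unit", "is_control"]


class CSVFormatError(ValueError):
    """Malformed input table; the message lists offending rows."""


def _normalize_x(values, units, role, path):
    out = np.empty(len(values), dtype=float)
    bad = []
    for i, (v, u) in enumerate(zip(values, units)):
        if role == "decay":
            factor = TIME_UNITS.get(u)
        elif role in ("dose_response", "bead"):
            factor = 1.0 if u in PASSTHROUGH_UNITS | {"ligands_per_cell"} else None
        else:
            factor = CONCENTRATION_UNITS.get(u)
        if factor is None:
            bad.append((i + 2, u))  # +2: header + 1-based
            continue
        out[i] = v * factor
    if bad:
        rows = ", ".join(f"line {ln} (unit {u!r})" for ln, u in bad[:10])
        raise CSVFormatError(f"{path}: unknown x_unit in rows: {rows}")
    return out


def read_titration_csv(path, role: str | None = None) -> list:
    """Read a long-form titration CSV into validated, unit-normalised series.

    Returns one :class:`TitrationSeries` (or :class:`EquilibriumSeries` for
    role ``spr``) per distinct ``series_id``, sorted by series_id.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise CSVFormatError(f"{path}: missing columns {missing}")
    for col in ("x_value", "y_value"):
        nonnum = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if nonnum.any():
            lines = (df.index[nonnum] + 2).tolist()[:10]
            raise CSVFormatError(f"{path}: non-numeric {col} at lines {lines}")
        df[col] = pd.to_numeric(df[col])
    if df[["x_value", "y_value"]].isna().any().any():
        lines = (df.index[df[["x_value", "y_value"]].isna().any(axis=1)] + 2).tolist()
        raise CSVFormatError(f"{path}: empty numeric cells at lines {lines[:10]}")
    dup = df.duplicated(subset=["series_id", "x_value", "replicate"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:10]
        raise CSVFormatError(
            f"{path}: duplicate (series_id, x, replicate) at lines {lines}")
    out = []
    for sid, grp in df.groupby("series_id", sort=True):
        roles = grp["role"].unique()
        if len(roles) != 1:
            raise CSVFormatError(f"{path}: series {sid!r} mixes roles {roles}")
        r = roles[0]
        if r not in ROLES:
            raise CSVFormatError(f"{path}: unknown role {r!r} for series {sid!r}")
        if role is not None and r != role:
            continue
        x = _normalize_x(grp["x_value"].to_numpy(), grp["x_unit"].tolist(), r, path)
        kwargs = dict(role=r, series_id=str(sid),
                      x_unit="min" if r == "decay" else
                      ("AU" if r in ("dose_response", "bead") else "M"),
                      y_unit=str(grp["y_unit"].iloc[0]),
                      replicate=grp["replicate"].to_numpy())
        if r == "spr":
            kwargs.pop("role")
            out.append(EquilibriumSeries(x, grp["y_value"].to_numpy(float), **kwargs))
        else:
            out.append(TitrationSeries(x, grp["y_value"].to_numpy(float), **kwargs))
    return out


def write_titration_csv(series_list, path) -> Path:
    """Write series back to the long-form dialect (round-trips with read)."""
    path = Path(path)
    frames = [s.to_dataframe() for s in series_list]
    pd.concat(frames, ignore_index=True)[TITRATION_COLUMNS].to_csv(path, index=False)
    return path


def read_dose_response_csv(path):
    """Read the dose-response dialect into per-experiment DataFrames."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise CSVFormatError(f"{path}: missing columns {missing}")
    df["is_control"] = df["is_control"].astype(bool)
    return {str(eid): grp.reset_index(drop=True)
            for eid, grp in df.groupby("experiment_id", sort=True)}


def read_bead_csv(path):
    """Read a bead standard table (bead_id, MFI, capacity)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("bead_id", "MFI", "capacity"):
        if col not in df.columns:
            raise CSVFormatError(f"{path}: missing column {col!r}")
    return df


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    raise TypeError(f"cannot serialise {type(obj).__name__} to results JSON")


def write_results_json(results, path, seed=None) -> Path:
    """Write fit results as schema-versioned JSON.

    ``results`` may be a dict or a list of result dataclasses/dicts; each
    entry is serialised with every numeric field intact.
    """
    from . import __version__
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "software": {"name": "ligandquant", "version": __version__},
        "seed": seed,
        "results": _jsonable(results),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, allow_nan=True))
    return path


def read_results_json(path) -> dict:
    return json.loads(Path(path).read_text())
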