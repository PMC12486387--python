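"""File formats: run tables, feed schedules, configs, results.

All artefacts are plain text. Run and feed tables are CSV with
unit-bearing column names (``glc_gL``, ``glu_mM``, ...) so the gram/molar
ambiguity of mixed-unit assays cannot leak into files; blank cells mean
missing. Configuration (model constants, parameter bounds) is YAML, with
the shipped defaults in ``mckm/data/defaults.yaml``. Results are JSON.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    KineticParameters,
    MCKMError,
    ModelConstants,
    N_VARIABLES,
    PARAM_NAMES,
    ParameterBounds,
    VARIABLE_NAMES,
)
from .regression import CultureRun, RegressionResult, estimate_mu_from_vcc
from .simulate import FeedSchedule

__all__ = [
    "SchemaError",
    "RUN_COLUMNS",
    "read_run",
    "write_run",
    "read_feeds",
    "write_feeds",
    "load_constants",
    "load_bounds",
    "default_config",
    "write_result",
    "read_result",
    "result_row",
]

SCHEMA_VERSION = 1

#: Run CSV schema: sampling time plus the 7 measured quantities.
RUN_COLUMNS = (
    "time_h",
    "Xv",
    "P_gL",
    "glc_gL",
    "glu_mM",
    "gln_mM",
    "amm_mM",
    "lac_gL",
)

# run-CSV column -> state-vector variable
_COLUMN_TO_VARIABLE = {
    "Xv": "Xv",
    "P_gL": "P",
    "glc_gL": "glc",
    "glu_mM": "glu",
    "gln_mM": "gln",
    "amm_mM": "amm",
    "lac_gL": "lac",
}


class SchemaError(MCKMError, ValueError):
    """A file does not match the expected schema."""


def read_run(
    path: str | Path,
    schedule: FeedSchedule | None = None,
    campaign: str = "",
    clone: str = "",
    passage: int = 1,
    replicate: int = 1,
) -> CultureRun:
    """Load a run CSV; the mu_est column is derived from the cell counts."""
    frame = pd.read_csv(path)
    unknown = set(frame.columns) - set(RUN_COLUMNS)
    if unknown:
        raise SchemaError(f"{path}: unknown columns {sorted(unknown)}")
    missing = set(RUN_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    times = frame["time_h"].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise SchemaError(f"{path}: sampling times must all be present")
    if len(np.unique(times)) != len(times):
        raise SchemaError(f"{path}: duplicate sampling times")
    if np.any(np.diff(times) <= 0):
        raise SchemaError(f"{path}: sampling times must be strictly increasing")
    observations = np.full((len(times), N_VARIABLES), np.nan)
    for column, variable in _COLUMN_TO_VARIABLE.items():
        observations[:, VARIABLE_NAMES.index(variable)] = frame[column].to_numpy(
            dtype=float
        )
    observations[:, -1] = estimate_mu_from_vcc(times, observations[:, 0])
    return CultureRun(
        sample_times=times,
        observations=observations,
        schedule=schedule or FeedSchedule(),
        campaign=campaign,
        clone=clone,
        passage=passage,
        replicate=replicate,
    )


def write_run(run: CultureRun, path: str | Path) -> None:
    frame = pd.DataFrame({"time_h": run.sample_times})
    for column, variable in _COLUMN_TO_VARIABLE.items():
        frame[column] = run.observations[:, VARIABLE_NAMES.index(variable)]
    frame.to_csv(path, index=False)


def read_feeds(path: str | Path) -> FeedSchedule:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return FeedSchedule.from_json(path)
    return FeedSchedule.from_csv(path)


def write_feeds(schedule: FeedSchedule, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        schedule.to_json(path)
    else:
        schedule.to_csv(path)


# --- configuration -----------------------------------------------------------


def default_config() -> dict:
    """The shipped defaults (model constants and bounds table)."""
    text = resources.files("mckm").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _load_yaml(path: str | Path | None) -> dict:
    if path is None:
        return default_config()
    return yaml.safe_load(Path(path).read_text())


def load_constants(path: str | Path | None = None) -> ModelConstants:
    config = _load_yaml(path)
    section = config.get("constants", config)
    known = {"alpha_glc", "glc_F_in", "glu_F_in", "V0", "lactate_switch_as_printed"}
    unknown = set(section) - known
    if unknown:
        raise SchemaError(f"unknown constants keys: {sorted(unknown)}")
    return ModelConstants(**section)


def load_bounds(path: str | Path | None = None) -> ParameterBounds:
    config = _load_yaml(path)
    section = config.get("bounds", config)
    try:
        lb = [section[n]["lb"] for n in PARAM_NAMES]
        ig = [section[n]["ig"] for n in PARAM_NAMES]
        ub = [section[n]["ub"] for n in PARAM_NAMES]
    except KeyError as exc:
        raise SchemaError(f"bounds config is missing entry {exc}") from exc
    return ParameterBounds(lb=np.array(lb), ub=np.array(ub), ig=np.array(ig))


# --- results -----------------------------------------------------------------


def write_result(result: RegressionResult, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "mode": result.mode,
        "theta": result.theta_hat.to_dict(),
        "theta_ig": result.theta_ig.to_dict(),
        "r2": {k: _json_float(v) for k, v in result.r2.items()},
        "nrmse": {k: _json_float(v) for k, v in result.nrmse.items()},
        "objective": _json_float(result.objective_value),
        "solver_status": result.solver_status,
        "nfev": result.nfev,
        "bounds": {
            "lb": result.bounds.lb.tolist(),
            "ub": result.bounds.ub.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_result(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def result_row(result: RegressionResult, **metadata) -> dict:
    """Flat dict for cohort concatenation (one CSV row per run)."""
    row = dict(metadata)
    row["mode"] = result.mode
    row.update(result.theta_hat.to_dict())
    row.update({f"r2_{k}": v for k, v in result.r2.items()})
    row.update({f"nrmse_{k}": v for k, v in result.nrmse.items()})
    row["objective"] = result.objective_value
    row["solver_status"] = result.solver_status
    return row


def _json_float(value: float):
    value = float(value)
    return value if np.isfinite(value) else None
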