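"""Reading model specifications and writing reports and timeseries.

JSON is the canonical model-specification dialect; YAML is accepted on
input as a convenience. Reports are JSON with full-precision floats;
matrices and trajectories go to CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .model import LineageModel, ModelValidationError, build_model
from .simulate import TrajectorySet

__all__ = ["load_spec", "load_model", "save_model", "write_report",
           "write_matrix_csv", "write_trajectory_csv"]

SCHEMA_VERSION = 1


def load_spec(path: str | Path) -> dict[str, Any]:
    """Parse a model specification file (JSON, or YAML by extension).

    Returns the plain-dict specification ready for
    :func:`lineagecalc.model.build_model`; raises
    :class:`ModelValidationError` naming the offending key on schema
    problems.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        spec = yaml.safe_load(text)
    else:
        try:
            spec = json.loads(text)
        except json.JSONDecodeError:
            spec = yaml.safe_load(text)
    if not isinstance(spec, Mapping):
        raise ModelValidationError(f"{path}: specification must be a mapping")
    for key in ("compartments", "processes"):
        if key not in spec:
            raise ModelValidationError(f"{path}: missing key '{key}'")
    return dict(spec)


def load_model(path: str | Path) -> LineageModel:
    return build_model(load_spec(path))


def save_model(model: LineageModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(model.to_json() + "\n")
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(result: Mapping[str, Any], path: str | Path) -> Path:
    """Write a JSON report with a schema version stamp."""
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION, **_jsonable(result)}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_matrix_csv(matrix: np.ndarray, names: tuple[str, ...],
                     path: str | Path) -> Path:
    """Square matrix to CSV with a header row/column of names."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["", *names])
        for name, row in zip(names, np.asarray(matrix)):
            w.writerow([name, *(repr(float(v)) for v in row)])
    return path


def write_trajectory_csv(traj: TrajectorySet, path: str | Path) -> Path:
    """Trajectory to CSV: time, one column per compartment, event label.

    The first row is the initial state (no triggering event). The file
    embeds the seed and mode in a comment line for reproducibility.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# seed={traj.seed} mode={traj.mode} "
                 f"absorbed={traj.absorbed}\n")
        w = csv.writer(fh)
        w.writerow(["time", *traj.compartment_names, "event"])
        labels = ["", *traj.events]
        for t, row, ev in zip(traj.times, traj.counts, labels):
            w.writerow([repr(float(t)), *(int(v) for v in row), ev])
    return path
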