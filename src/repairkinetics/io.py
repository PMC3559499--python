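"""Reading and writing measurement tables, fit results and trajectories.

Measurements travel as tidy CSV (header ``condition,time_h,replicate,
observable,value``); fit results as JSON documents that round-trip the full
estimate, confidence intervals, multistart trace and provenance (seed,
package version); trajectories as wide CSV with one column per compartment.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .data import MeasurementTable
from .exceptions import ValidationError
from .kinetics import COMPARTMENTS, Trajectory

__all__ = [
    "read_measurements",
    "write_measurements",
    "write_results",
    "read_results",
    "trajectory_to_frame",
    "write_trajectory",
]


def read_measurements(path) -> MeasurementTable:
    """Load and validate a measurement CSV; errors name the offending row."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"measurement file not found: {path}")
    return MeasurementTable.from_csv(path)


def write_measurements(table: MeasurementTable, path, force: bool = False) -> None:
    _guard_overwrite(path, force)
    table.to_csv(path)


def write_results(results, path, force: bool = False) -> dict:
    """Serialise a :class:`RepairResults` to JSON; returns the document.

    The document carries the estimates, fitted initial state(s), SSR,
    flags, derived half-times (ln 2 / k, minutes), the full multistart
    trace, the seed and the package version, and round-trips losslessly.
    """
    _guard_overwrite(path, force)
    doc = results.to_dict()
    doc["package"] = "repairkinetics"
    doc["version"] = __version__
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return doc


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    df = pd.DataFrame(traj.states, columns=list(COMPARTMENTS))
    df.insert(0, "time_h", traj.times)
    return df


def write_trajectory(traj: Trajectory, path, force: bool = False) -> None:
    _guard_overwrite(path, force)
    trajectory_to_frame(traj).to_csv(path, index=False)


def _guard_overwrite(path, force: bool) -> None:
    if Path(path).exists() and not force:
        raise ValidationError(
            f"refusing to overwrite existing file {path} (use force/--force)"
        )
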