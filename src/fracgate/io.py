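"""Trajectory/field serialization and run summaries.

CSV conventions: comma separator, ``.`` decimal, UTF-8, LF line endings,
15-significant-digit values (full float64 round-trip at that precision).
Each CSV gets a sibling ``<name>.json`` run summary embedding the package
version, the resolved configuration and diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from fracgate.gme import ProbabilityField
from fracgate.kinetics import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_fields",
    "read_fields",
    "write_summary",
]

_FLOAT_FMT = "%.15g"


def _summary_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_summary(path, payload: dict[str, Any]) -> Path:
    """Write the JSON run summary next to a CSV output file."""
    from fracgate import __version__

    out = _summary_path(Path(path))
    doc = {"version": __version__, **payload}
    try:
        out.write_text(json.dumps(doc, indent=2, default=_jsonify) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write summary {out}: {exc}") from exc
    return out


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_trajectory(
    traj: Trajectory, path, *, state_column: str = "x"
) -> Path:
    """Write a trajectory as CSV (header ``t,<state_column>``) + JSON summary.

    Values round-trip through :func:`read_trajectory` to 15 significant
    digits, which recovers float64 exactly in practice.
    """
    path = Path(path)
    try:
        traj.to_frame(state_column).to_csv(
            path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
        )
    except OSError as exc:
        raise OSError(f"cannot write trajectory {path}: {exc}") from exc
    write_summary(path, {
        "output": str(path),
        "config": traj.meta,
        "final_state": float(traj.states[-1]),
        "n_points": int(len(traj.times)),
    })
    return path


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    df = pd.read_csv(path)
    state_col = [c for c in df.columns if c != "t"][0]
    meta: dict[str, Any] = {}
    spath = _summary_path(Path(path))
    if spath.exists():
        meta = json.loads(spath.read_text()).get("config", {})
    return Trajectory(times=df["t"].to_numpy(), states=df[state_col].to_numpy(),
                      meta=meta)


def write_fields(
    fields: Sequence[ProbabilityField], path, *, extra: dict | None = None
) -> Path:
    """Write a probability-field sequence: one row per time, columns
    ``t,x_1,...,x_N``; JSON summary alongside."""
    path = Path(path)
    n = len(fields[0].values)
    cols = ["t"] + [f"x_{i + 1}" for i in range(n)]
    data = np.column_stack(
        [[f.t for f in fields]] + [np.array([f.values[i] for f in fields])
                                   for i in range(n)]
    )
    try:
        pd.DataFrame(data, columns=cols).to_csv(
            path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
        )
    except OSError as exc:
        raise OSError(f"cannot write fields {path}: {exc}") from exc
    write_summary(path, {
        "output": str(path),
        "n_times": len(fields),
        "n_lattice": n,
        **(extra or {}),
    })
    return path


def read_fields(path) -> list[ProbabilityField]:
    """Read a field-sequence CSV written by :func:`write_fields`."""
    df = pd.read_csv(path)
    xcols = [c for c in df.columns if c != "t"]
    return [
        ProbabilityField(values=row[xcols].to_numpy(dtype=float), t=float(row["t"]))
        for _, row in df.iterrows()
    ]
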