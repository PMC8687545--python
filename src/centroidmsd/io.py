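"""Trajectory persistence: CSV records plus a JSON metadata sidecar.

The CSV holds one row per binding event with header
``event,kind,fa,attached,cx,cy``; centroid coordinates are written with 17
significant digits so the round trip is lossless at float64 precision.  The
sidecar ``<path>.meta.json`` carries the model parameters, the outreach
distribution, the initialization mode and the post-burn-in centroid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ModelParams, OutreachDistribution, Trajectory

__all__ = ["write_trajectory", "read_trajectory", "TrajectoryFormatError"]

_COLUMNS = ["event", "kind", "fa", "attached", "cx", "cy"]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file: bad header, indices or attachment counts."""


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    traj.records.to_csv(path, index=False, float_format="%.17g", columns=_COLUMNS)
    meta: dict = {}
    if traj.params is not None:
        p = traj.params
        meta["params"] = {
            "n": p.n, "r": p.r, "events": p.events,
            "burn_in": p.burn_in, "seed": p.seed,
        }
    if traj.dist is not None:
        meta["distribution"] = traj.dist.to_config()
    if traj.init_mode is not None:
        meta["init"] = traj.init_mode
    if traj.initial_centroid is not None:
        meta["initial_centroid"] = [float(v) for v in traj.initial_centroid]
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def _validate(records: pd.DataFrame) -> None:
    if list(records.columns) != _COLUMNS:
        raise TrajectoryFormatError(
            f"expected header {','.join(_COLUMNS)}, got {','.join(map(str, records.columns))}"
        )
    if len(records) == 0:
        return
    if not records["kind"].isin(["attach", "detach"]).all():
        raise TrajectoryFormatError("kind must be 'attach' or 'detach'")
    ev = records["event"].to_numpy()
    if np.any(np.diff(ev) <= 0):
        raise TrajectoryFormatError("event index must be strictly increasing")
    att = records["attached"].to_numpy()
    if np.any((att < 0)):
        raise TrajectoryFormatError("attached count must be nonnegative")
    d = np.diff(att)
    if np.any(np.abs(d) != 1):
        raise TrajectoryFormatError("attached count must change by exactly 1 per event")
    step = np.where(records["kind"].to_numpy()[1:] == "attach", 1, -1)
    if np.any(d != step):
        raise TrajectoryFormatError("attached count inconsistent with event kind")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV (and its sidecar, if present) back into memory."""
    path = Path(path)
    records = pd.read_csv(path, dtype={"kind": str}, float_precision="round_trip")
    _validate(records)
    initial = params = dist = init_mode = None
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        if "initial_centroid" in meta:
            initial = np.asarray(meta["initial_centroid"], dtype=float)
        if "params" in meta:
            params = ModelParams(**meta["params"])
        if "distribution" in meta:
            dist = OutreachDistribution.from_config(meta["distribution"])
        init_mode = meta.get("init")
    return Trajectory(
        records=records,
        initial_centroid=initial,
        params=params,
        dist=dist,
        init_mode=init_mode,
    )
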