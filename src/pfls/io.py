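"""Session serialization: JSON manifest + delimited-text data files.

On-disk layout (one directory per session)::

    manifest.json        session id, scale, maze parameters, units, events
    positions.csv        t,x,y (seconds, pixels)
    spikes/<unit>.csv    one spike-time column, header "t"

Floats are written with ``repr`` (shortest round-tripping form), so
write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import (PositionSeries, Session, SpikeTrain, TrialEvent,
                   drop_out_of_bounds_spikes)
from .geometry import build_maze

MANIFEST_NAME = "manifest.json"


class SessionIOError(IOError):
    """A session file is missing or malformed."""


def _fmt(v: float) -> str:
    return repr(float(v))


def _parse_table(path: Path, n_cols: int) -> np.ndarray:
    """Parse a headered CSV of floats, reporting file and line on errors."""
    if not path.exists():
        raise SessionIOError(f"missing data file: {path}")
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise SessionIOError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != n_cols:
                raise SessionIOError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise SessionIOError(f"{path}:{lineno}: non-numeric field ({exc})")
    return np.array(rows, dtype=float).reshape(-1, n_cols)


def write_session(session: Session, out_dir) -> Path:
    """Write a session to ``out_dir``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "spikes").mkdir(exist_ok=True)

    pos = session.positions
    with open(out_dir / "positions.csv", "w") as fh:
        fh.write("t,x,y\n")
        for t, x, y in zip(pos.t, pos.x, pos.y):
            fh.write(f"{_fmt(t)},{_fmt(x)},{_fmt(y)}\n")

    units = []
    for tr in session.trains:
        rel = f"spikes/{tr.unit_id}.csv"
        with open(out_dir / rel, "w") as fh:
            fh.write("t\n")
            for t in tr.spike_times:
                fh.write(_fmt(t) + "\n")
        units.append({"unit_id": tr.unit_id, "region": tr.region, "file": rel})

    manifest = {
        "session_id": session.session_id,
        "px_per_cm": pos.px_per_cm,
        "nominal_rate": pos.nominal_rate,
        "maze": {"arm_length": session.maze.arm_length,
                 "stem_length": session.maze.stem_length},
        "positions_file": "positions.csv",
        "units": units,
        "events": [{"kind": e.kind, "time": e.time, "side": e.side,
                    "correct": e.correct} for e in session.events],
    }
    mpath = out_dir / MANIFEST_NAME
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return mpath


def read_session(manifest_path, clip_spikes: bool = False) -> Session:
    """Read a session from a manifest path (or its directory).

    With ``clip_spikes`` spikes outside the position-time bounds are dropped
    (with a logged count) instead of raising a validation error.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise SessionIOError(f"missing manifest: {manifest_path}")
    root = manifest_path.parent
    try:
        with open(manifest_path) as fh:
            man = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SessionIOError(f"{manifest_path}: invalid JSON ({exc})")

    tab = _parse_table(root / man["positions_file"], 3)
    positions = PositionSeries(t=tab[:, 0], x=tab[:, 1], y=tab[:, 2],
                               px_per_cm=man["px_per_cm"],
                               nominal_rate=man.get("nominal_rate", 30.0))
    t0, t1 = float(positions.t[0]), float(positions.t[-1])

    trains = []
    for u in man["units"]:
        spikes = _parse_table(root / u["file"], 1)[:, 0]
        if clip_spikes:
            spikes = drop_out_of_bounds_spikes(spikes, t0, t1, u["unit_id"])
        trains.append(SpikeTrain(unit_id=u["unit_id"], region=u["region"],
                                 spike_times=spikes,
                                 session_id=man["session_id"]))

    maze = build_maze(man["maze"]["arm_length"], man["maze"]["stem_length"])
    events = [TrialEvent(kind=e["kind"], time=e["time"], side=e.get("side", ""),
                         correct=e.get("correct", True)) for e in man["events"]]
    return Session(session_id=man["session_id"], positions=positions,
                   trains=trains, maze=maze, events=events)


def sessions_equal(a: Session, b: Session) -> bool:
    """Field-by-field equality of two sessions (exact float comparison)."""
    if a.session_id != b.session_id:
        return False
    pa, pb = a.positions, b.positions
    if not (np.array_equal(pa.t, pb.t) and np.array_equal(pa.x, pb.x)
            and np.array_equal(pa.y, pb.y) and pa.px_per_cm == pb.px_per_cm):
        return False
    if len(a.trains) != len(b.trains):
        return False
    for ta, tb in zip(a.trains, b.trains):
        if (ta.unit_id, ta.region) != (tb.unit_id, tb.region):
            return False
        if not np.array_equal(ta.spike_times, tb.spike_times):
            return False
    if (a.maze.arm_length, a.maze.stem_length) != (b.maze.arm_length,
                                                   b.maze.stem_length):
        return False
    return [(e.kind, e.time, e.side, e.correct) for e in a.events] == \
           [(e.kind, e.time, e.side, e.correct) for e in b.events]
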