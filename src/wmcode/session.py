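"""Session data contract: in-memory container, on-disk layout, validation.

A session is one recording experiment: a trials table, a unit table with mean
spike waveforms, a spike-event table, gaze tables (fixations and saccades),
per-trial navigation trajectories, and metadata (condition, injection time).

Conventions
-----------
* Time base: milliseconds from session start, 0-based.
* Epoch intervals are half-open ``[on, off)``; cue lasts 3000 ms, delay
  2000 ms, and the analysed response window is the first 2000 ms after
  navigation onset.
* Target locations 1-9 form a 3 x 3 grid centred at the arena origin with
  290 arena-units spacing; columns are indexed left-to-right, rows
  near-to-far.
* Injection periods: ``pre`` (trial start before injection), ``early_post``
  (start within 30 min of injection), ``late_post`` (30-60 min). Assignment
  is by trial start time.

On disk a session is either a directory of CSV tables plus a
``session.json`` metadata sidecar, or a single HDF5 file with the same
tables as groups plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Epoch durations, ms.
CUE_MS = 3000.0
DELAY_MS = 2000.0
RESPONSE_MS = 2000.0

#: Grid geometry (arena units).
GRID_SPACING = 290.0

#: Injection-period boundaries relative to injection time, ms.
EARLY_POST_MS = 30.0 * 60.0 * 1000.0
LATE_POST_MS = 60.0 * 60.0 * 1000.0

PERIODS = ("pre", "early_post", "late_post")
EPOCHS = ("cue", "delay", "response")
CONDITIONS = ("ketamine_wm", "saline_wm", "ketamine_perception")

#: Screen geometry for gaze tables (pixels).
SCREEN_W = 1024
SCREEN_H = 768

_TABLE_NAMES = ("trials", "units", "waveforms", "spikes",
                "fixations", "saccades", "trajectories")

_TRIAL_COLUMNS = [
    "trial_id", "target_location", "target_x", "target_y", "target_column",
    "target_side", "outcome", "cue_on", "delay_on", "response_on",
    "trial_end", "period", "response_time",
]


class SessionValidationError(ValueError):
    """A session violates the data contract; the message lists offenders."""


class MissingTableError(FileNotFoundError):
    """An expected session table is absent on disk."""


def target_xy(location: int) -> tuple[float, float]:
    """Arena coordinates of a target location (1-9, centred 3x3 grid)."""
    if not 1 <= int(location) <= 9:
        raise ValueError(f"target location must be 1..9, got {location}")
    col = (int(location) - 1) % 3
    row = (int(location) - 1) // 3
    return (col - 1) * GRID_SPACING, (row - 1) * GRID_SPACING


def target_column(location: int) -> str:
    """Grid column (``left``/``center``/``right``) of a target location."""
    return ("left", "center", "right")[(int(location) - 1) % 3]


def screen_target_xy(location: int) -> tuple[float, float]:
    """Projection of an arena target onto the screen (pixels).

    The 3x3 arena grid maps to a 3x3 grid of screen points centred on the
    screen, spaced a quarter of the screen per step.
    """
    col = (int(location) - 1) % 3
    row = (int(location) - 1) // 3
    return SCREEN_W / 2.0 + (col - 1) * SCREEN_W / 4.0, \
        SCREEN_H / 2.0 + (row - 1) * SCREEN_H / 4.0


def screen_cell_bounds(location: int,
                       grid: int = 4) -> tuple[float, float, float, float]:
    """Bounds (x0, x1, y0, y1) of the screen-grid cell holding a target's
    projection; the default 4x4 grid gives the 16-cell analysis grid."""
    x, y = screen_target_xy(location)
    cw, ch = SCREEN_W / grid, SCREEN_H / grid
    cx = min(int(x // cw), grid - 1)
    cy = min(int(y // ch), grid - 1)
    return cx * cw, (cx + 1) * cw, cy * ch, (cy + 1) * ch


def period_label(trial_start: float, injection_time: float) -> str:
    """Injection-period label from trial start time (ms)."""
    if trial_start < injection_time:
        return "pre"
    if trial_start < injection_time + EARLY_POST_MS:
        return "early_post"
    if trial_start < injection_time + LATE_POST_MS:
        return "late_post"
    return "late_post"


def epoch_window(trial: pd.Series, epoch: str) -> tuple[float, float]:
    """Half-open ``[on, off)`` window of an epoch within a trial, ms."""
    if epoch == "cue":
        return float(trial["cue_on"]), float(trial["delay_on"])
    if epoch == "delay":
        return float(trial["delay_on"]), float(trial["response_on"])
    if epoch == "response":
        on = float(trial["response_on"])
        return on, min(on + RESPONSE_MS, float(trial["trial_end"]))
    raise ValueError(f"unknown epoch {epoch!r}")


@dataclass
class SessionRecording:
    """One experiment: trials, units, spikes, gaze, trajectories, metadata.

    All tables are pandas DataFrames; see the module docstring for the
    time-base and geometry conventions.
    """

    session_id: str
    condition: str
    injection_time: float
    trials: pd.DataFrame
    units: pd.DataFrame
    waveforms: pd.DataFrame
    spikes: pd.DataFrame
    fixations: pd.DataFrame
    saccades: pd.DataFrame
    trajectories: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "SessionRecording":
        return replace(
            self,
            **{n: self.table(n).copy() for n in _TABLE_NAMES},
            meta=dict(self.meta),
        )

    def unit_spikes(self, unit_id: int) -> np.ndarray:
        """Spike times (ms) of one unit, sorted ascending."""
        t = self.spikes.loc[self.spikes["unit_id"] == unit_id, "time_ms"]
        return np.sort(t.to_numpy(dtype=float))


def validate_session(rec: SessionRecording) -> None:
    """Check the data-contract invariants; raise on the first violation.

    Checks: condition label; spike unit references and per-unit time
    ordering; period labels consistent with the injection time; epoch
    ordering and the stated cue/delay durations; target geometry columns.
    """
    problems: list[str] = []

    if rec.condition not in CONDITIONS:
        problems.append(f"unknown condition {rec.condition!r}")

    known_units = set(rec.units["unit_id"].tolist())
    bad_ref = rec.spikes.loc[~rec.spikes["unit_id"].isin(known_units)]
    if len(bad_ref):
        problems.append(
            f"{len(bad_ref)} spikes reference unknown unit_ids "
            f"{sorted(set(bad_ref['unit_id'].tolist()))[:5]}"
        )
    if len(rec.spikes) and (rec.spikes["time_ms"] < 0).any():
        problems.append("negative spike times present")

    tr = rec.trials
    if len(tr):
        expected = tr["cue_on"].map(
            lambda t: period_label(float(t), rec.injection_time))
        mism = tr.loc[tr["period"] != expected]
        if len(mism):
            problems.append(
                f"{len(mism)} trials have period labels inconsistent with "
                f"injection_time (trial_ids {mism['trial_id'].tolist()[:5]})"
            )
        bad_period = tr.loc[~tr["period"].isin(PERIODS)]
        if len(bad_period):
            problems.append(
                f"{len(bad_period)} trials carry unknown period labels")

        order_ok = (
            (tr["cue_on"] < tr["delay_on"])
            & (tr["delay_on"] < tr["response_on"])
            & (tr["response_on"] < tr["trial_end"])
        )
        if not order_ok.all():
            problems.append(
                f"epoch boundaries out of order for trial_ids "
                f"{tr.loc[~order_ok, 'trial_id'].tolist()[:5]}"
            )
        cue_span = tr["delay_on"] - tr["cue_on"]
        delay_span = tr["response_on"] - tr["delay_on"]
        if not np.allclose(cue_span, CUE_MS):
            problems.append("cue epoch span differs from 3000 ms")
        if not np.allclose(delay_span, DELAY_MS):
            problems.append("delay epoch span differs from 2000 ms")

        expect_col = tr["target_location"].map(target_column)
        if not (tr["target_column"] == expect_col).all():
            problems.append("target_column inconsistent with target_location")

    if problems:
        raise SessionValidationError("; ".join(problems))


# ---------------------------------------------------------------------------
# On-disk layout


def write_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write a session to ``path``.

    ``path`` ending in ``.h5``/``.hdf5`` selects the single-file HDF5 layout
    (tables as groups, JSON metadata sidecar next to the file); otherwise a
    directory of CSV tables plus ``session.json`` is written.
    """
    path = Path(path)
    meta = {
        "session_id": rec.session_id,
        "condition": rec.condition,
        "injection_time": rec.injection_time,
        **rec.meta,
    }
    if path.suffix in (".h5", ".hdf5"):
        path.parent.mkdir(parents=True, exist_ok=True)
        with pd.HDFStore(path, mode="w") as store:
            for name in _TABLE_NAMES:
                store.put(name, rec.table(name), format="table")
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name in _TABLE_NAMES:
            rec.table(name).to_csv(path / f"{name}.csv", index=False)
        (path / "session.json").write_text(json.dumps(meta, indent=2))
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read and validate a session written by :func:`write_session`."""
    path = Path(path)
    tables: dict[str, pd.DataFrame] = {}
    if path.suffix in (".h5", ".hdf5"):
        if not path.exists():
            raise MissingTableError(f"no session file at {path}")
        with pd.HDFStore(path, mode="r") as store:
            for name in _TABLE_NAMES:
                key = f"/{name}"
                if key not in store.keys():
                    raise MissingTableError(f"table {name!r} missing in {path}")
                tables[name] = store.get(name).reset_index(drop=True)
        meta = json.loads(path.with_suffix(".json").read_text())
    else:
        if not path.is_dir():
            raise MissingTableError(f"no session directory at {path}")
        for name in _TABLE_NAMES:
            fp = path / f"{name}.csv"
            if not fp.exists():
                raise MissingTableError(f"table {name!r} missing in {path}")
            tables[name] = pd.read_csv(fp)
        meta = json.loads((path / "session.json").read_text())

    meta = dict(meta)
    rec = SessionRecording(
        session_id=str(meta.pop("session_id")),
        condition=str(meta.pop("condition")),
        injection_time=float(meta.pop("injection_time")),
        meta=meta,
        **tables,
    )
    # Empty CSV tables come back with object dtype; normalise numerics.
    for name in _TABLE_NAMES:
        df = rec.table(name)
        for col in df.columns:
            if df[col].dtype == object:
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError):
                    pass
    validate_session(rec)
    return rec
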