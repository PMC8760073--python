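"""Behavioral performance, response time, and trajectory-dispersion analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .session import GRID_SPACING, PERIODS, SessionRecording, target_xy
from .synth import ENCLAVE_LINE_Y

#: Chance probability of reaching the correct one of nine targets.
CHANCE_P = 1.0 / 9.0

GRID_N = 5


def percent_correct(
    trials: pd.DataFrame,
    by: str = "period",
    chance: float = CHANCE_P,
    n_bins: int = 0,
) -> pd.DataFrame:
    """Percent correct per group with an exact binomial test against chance.

    One row per group (default: injection period): n_trials, n_correct,
    percent_correct and the upper-tail exact binomial p-value against the
    9-target chance level. Set ``n_bins`` > 0 to append a within-group time
    course over equally sized trial bins (columns group, bin, percent).
    Empty groups are omitted.
    """
    rows = []
    for key, grp in trials.groupby(by, sort=False):
        n = len(grp)
        if n == 0:
            continue
        k = int((grp["outcome"] == "correct").sum())
        p = binomtest(k, n, chance, alternative="greater").pvalue
        rows.append({by: key, "n_trials": n, "n_correct": k,
                     "percent_correct": 100.0 * k / n, "binomial_p": p})
    out = pd.DataFrame(rows, columns=[by, "n_trials", "n_correct",
                                      "percent_correct", "binomial_p"])
    if n_bins > 0:
        tc_rows = []
        for key, grp in trials.groupby(by, sort=False):
            grp = grp.sort_values("cue_on")
            bins = np.array_split(np.arange(len(grp)), n_bins)
            for b, idx in enumerate(bins):
                if len(idx) == 0:
                    continue
                sub = grp.iloc[idx]
                tc_rows.append({
                    by: key, "bin": b,
                    "percent": 100.0 * (sub["outcome"] == "correct").mean(),
                })
        out.attrs["timecourse"] = pd.DataFrame(tc_rows)
    return out


def response_times(trials: pd.DataFrame, by: str = "period") -> pd.DataFrame:
    """Mean +/- SEM response time (s) of correct trials per group.

    Response time is navigation onset to trial end. Groups with a single
    trial report SEM 0 with ``sem_undefined`` set; groups with no correct
    trials are omitted.
    """
    correct = trials.loc[trials["outcome"] == "correct"]
    rows = []
    for key, grp in correct.groupby(by, sort=False):
        rt = grp["response_time"].dropna().to_numpy(dtype=float)
        if rt.size == 0:
            continue
        sem = float(rt.std(ddof=1) / np.sqrt(rt.size)) if rt.size > 1 else 0.0
        rows.append({by: key, "n_trials": rt.size,
                     "mean_s": float(rt.mean()), "sem_s": sem,
                     "sem_undefined": rt.size == 1})
    return pd.DataFrame(rows, columns=[by, "n_trials", "mean_s", "sem_s",
                                       "sem_undefined"])


@dataclass
class TrajectoryGrid:
    """5x5 occupancy analysis of navigation trajectories.

    ``per_trial``: long table (trial_id, cell_row, cell_col, entered).
    ``percent``: per target-location condition percent of trials entering
    each cell (25 cells x 9 conditions = 225 values for a full session).
    """

    per_trial: pd.DataFrame
    percent: pd.DataFrame
    grid_edges_x: np.ndarray
    grid_edges_y: np.ndarray
    n_trials_used: int
    n_trials_excluded: int


def _grid_edges(n: int = GRID_N) -> tuple[np.ndarray, np.ndarray]:
    """Grid bounding the nine targets, padded by half the target spacing."""
    xy = np.array([target_xy(loc) for loc in range(1, 10)])
    pad = GRID_SPACING / 2.0
    ex = np.linspace(xy[:, 0].min() - pad, xy[:, 0].max() + pad, n + 1)
    ey = np.linspace(xy[:, 1].min() - pad, xy[:, 1].max() + pad, n + 1)
    return ex, ey


def _cells_entered(x: np.ndarray, y: np.ndarray,
                   ex: np.ndarray, ey: np.ndarray) -> np.ndarray:
    """Boolean (row, col) entry matrix; segments between samples count.

    Segments are interpolated at a quarter of the cell size so coarse
    trajectory sampling cannot skip a traversed cell.
    """
    n = len(ex) - 1
    entered = np.zeros((n, n), dtype=bool)
    if x.size == 0:
        return entered
    step = min(ex[1] - ex[0], ey[1] - ey[0]) / 4.0
    xs, ys = [x[:1]], [y[:1]]
    for k in range(x.size - 1):
        seg = float(np.hypot(x[k + 1] - x[k], y[k + 1] - y[k]))
        m = max(int(np.ceil(seg / step)), 1)
        t = np.linspace(0.0, 1.0, m + 1)[1:]
        xs.append(x[k] + t * (x[k + 1] - x[k]))
        ys.append(y[k] + t * (y[k + 1] - y[k]))
    px = np.concatenate(xs)
    py = np.concatenate(ys)
    # half-open cells [edge_i, edge_{i+1})
    ci = np.searchsorted(ex, px, side="right") - 1
    cj = np.searchsorted(ey, py, side="right") - 1
    ok = (ci >= 0) & (ci < n) & (cj >= 0) & (cj < n)
    entered[cj[ok], ci[ok]] = True  # row = y cell, col = x cell
    return entered


def grid_occupancy(
    rec: SessionRecording,
    period: str | None = None,
    enclave_line_y: float = ENCLAVE_LINE_Y,
    n: int = GRID_N,
) -> TrajectoryGrid:
    """Per-trial 5x5 cell-entry indicators and per-condition percentages.

    Only trials whose trajectory crosses the line separating the start
    enclave from the arena body are scored; trials with empty trajectories
    are excluded. Entering a cell once or many times both score 1.
    """
    trials = rec.trials
    if period is not None:
        trials = trials.loc[trials["period"] == period]
    ex, ey = _grid_edges(n)
    traj = rec.trajectories
    rows = []
    used, excluded = 0, 0
    for tr in trials.itertuples():
        sub = traj.loc[traj["trial_id"] == tr.trial_id].sort_values("time_ms")
        if len(sub) == 0:
            excluded += 1
            continue
        y = sub["y"].to_numpy(dtype=float)
        if y.max() < enclave_line_y:
            excluded += 1  # never left the start enclave
            continue
        entered = _cells_entered(sub["x"].to_numpy(dtype=float), y, ex, ey)
        used += 1
        for r in range(n):
            for c in range(n):
                rows.append({
                    "trial_id": tr.trial_id,
                    "target_location": tr.target_location,
                    "cell_row": r, "cell_col": c,
                    "entered": int(entered[r, c]),
                })
    per_trial = pd.DataFrame(rows, columns=[
        "trial_id", "target_location", "cell_row", "cell_col", "entered"])
    if len(per_trial):
        percent = (per_trial.groupby(
            ["target_location", "cell_row", "cell_col"])["entered"]
            .mean().mul(100.0).rename("percent").reset_index())
    else:
        percent = pd.DataFrame(columns=["target_location", "cell_row",
                                        "cell_col", "percent"])
    return TrajectoryGrid(per_trial=per_trial, percent=percent,
                          grid_edges_x=ex, grid_edges_y=ey,
                          n_trials_used=used, n_trials_excluded=excluded)


def occupancy_increase(percent_a: pd.DataFrame,
                       percent_b: pd.DataFrame) -> pd.DataFrame:
    """Between-period difference map keeping increases only (a - b, >= 0)."""
    key = ["target_location", "cell_row", "cell_col"]
    merged = percent_a.merge(percent_b, on=key, suffixes=("_a", "_b"))
    merged["increase"] = np.clip(
        merged["percent_a"] - merged["percent_b"], 0.0, None)
    return merged[key + ["increase"]]


def dispersion_summary(rec: SessionRecording) -> pd.DataFrame:
    """Mean number of entered cells per trial, per injection period."""
    rows = []
    for period in PERIODS:
        grid = grid_occupancy(rec, period=period)
        if grid.n_trials_used == 0:
            continue
        per = grid.per_trial.groupby("trial_id")["entered"].sum()
        rows.append({"period": period,
                     "mean_cells_entered": float(per.mean()),
                     "n_trials": grid.n_trials_used})
    return pd.DataFrame(rows, columns=["period", "mean_cells_entered",
                                       "n_trials"])
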