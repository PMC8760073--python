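"""Single-unit spatial selectivity and tuning-shape statistics.

Covers epoch-averaged firing rates, the one-way-ANOVA selectivity test with
its 50x balanced-subsample median procedure, preferred / least-preferred
location extraction, ranked-tuning slopes, Gaussian-kernel spike density
functions (SD 150 ms), and the second-order polynomial surface fit used to
visualise tuning over the arena.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_for
from .session import (
    EPOCHS,
    PERIODS,
    SessionRecording,
    epoch_window,
    target_xy,
)

#: Spike-density-function kernel SD, ms.
SDF_SD_MS = 150.0


def epoch_rates(
    rec: SessionRecording,
    epoch: str,
    unit_ids: np.ndarray | list | None = None,
    trial_ids: np.ndarray | list | None = None,
) -> pd.DataFrame:
    """Epoch-averaged firing rates, one row per (trial, unit).

    Rate = spike count in the half-open epoch window / window duration (s).
    Returns columns: trial_id, unit_id, location, period, outcome, rate_hz.
    """
    if epoch not in EPOCHS:
        raise ValueError(f"epoch must be one of {EPOCHS}, got {epoch!r}")
    trials = rec.trials
    if trial_ids is not None:
        trials = trials.loc[trials["trial_id"].isin(set(trial_ids))]
    uids = (list(unit_ids) if unit_ids is not None
            else rec.units["unit_id"].tolist())

    spike_by_unit = {
        uid: rec.unit_spikes(uid) for uid in uids
    }
    rows = []
    for tr in trials.itertuples():
        on, off = epoch_window(
            pd.Series({"cue_on": tr.cue_on, "delay_on": tr.delay_on,
                       "response_on": tr.response_on,
                       "trial_end": tr.trial_end}), epoch)
        dur_s = (off - on) / 1000.0
        if dur_s <= 0:
            raise ValueError(
                f"zero-length {epoch} window in trial {tr.trial_id}")
        for uid in uids:
            ts = spike_by_unit[uid]
            count = int(np.searchsorted(ts, off, side="left")
                        - np.searchsorted(ts, on, side="left"))
            rows.append({
                "trial_id": tr.trial_id, "unit_id": uid,
                "location": tr.target_location, "period": tr.period,
                "outcome": tr.outcome, "rate_hz": count / dur_s,
            })
    cols = ["trial_id", "unit_id", "location", "period", "outcome", "rate_hz"]
    return pd.DataFrame(rows, columns=cols)


def rate_matrix(rates: pd.DataFrame,
                unit_ids: list | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Pivot a long rate table to (trials x units) plus the trial metadata."""
    wide = rates.pivot_table(index="trial_id", columns="unit_id",
                             values="rate_hz")
    if unit_ids is not None:
        wide = wide[unit_ids]
    info = (rates[["trial_id", "location", "period", "outcome"]]
            .drop_duplicates("trial_id").set_index("trial_id")
            .loc[wide.index].reset_index())
    from .session import target_column as _tc
    info["target_column"] = info["location"].map(_tc)
    return wide.to_numpy(dtype=float), info


def _anova_p(groups: list[np.ndarray]) -> float:
    if np.ptp(np.concatenate(groups)) == 0:
        return np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        return float(stats.f_oneway(*groups).pvalue)


def anova_selectivity(
    rates: pd.DataFrame,
    alpha: float = 0.05,
    n_subsample: int = 50,
    subsample_to: dict | int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-unit spatial-selectivity test on epoch-averaged rates.

    For each unit, a one-way fixed-effects ANOVA of rate on target location
    is run on ``n_subsample`` balanced subsamples (each location drawn
    without replacement down to ``subsample_to`` trials; default the unit's
    minimum per-location count) and the median p-value is kept. When the
    subsample size equals every location's count the procedure reduces to a
    single full-data ANOVA.

    Returns one row per unit: anova_p, selective (median p < alpha),
    preferred/least-preferred location (ties broken toward the lowest
    location index and flagged), and the per-location mean rates as
    ``mean_rate_loc1`` .. ``mean_rate_loc9``.
    """
    out = []
    for uid, df in rates.groupby("unit_id"):
        groups = {loc: sub["rate_hz"].to_numpy(dtype=float)
                  for loc, sub in df.groupby("location")}
        if len(groups) < 2:
            continue
        counts = {loc: len(g) for loc, g in groups.items()}
        if isinstance(subsample_to, dict):
            m = int(subsample_to.get(uid, min(counts.values())))
        elif subsample_to is not None:
            m = int(subsample_to)
        else:
            m = min(counts.values())
        if m < 2 or min(counts.values()) < m:
            continue  # cannot balance this unit; skipped
        pooled = df["rate_hz"].to_numpy(dtype=float)
        if np.ptp(pooled) == 0:
            continue  # constant rates: test undefined, unit skipped

        rng = rng_for(seed, "anova_subsample", uid)
        if all(c == m for c in counts.values()):
            pvals = [_anova_p(list(groups.values()))]
        else:
            pvals = []
            for _ in range(n_subsample):
                sub = [g[rng.choice(len(g), size=m, replace=False)]
                       for g in groups.values()]
                pvals.append(_anova_p(sub))
        p_med = float(np.nanmedian(pvals))

        means = {loc: float(g.mean()) for loc, g in sorted(groups.items())}
        locs = np.array(sorted(means))
        vals = np.array([means[loc] for loc in locs])
        pref = int(locs[int(np.argmax(vals))])
        least = int(locs[int(np.argmin(vals))])
        tied = bool((vals == vals.max()).sum() > 1
                    or (vals == vals.min()).sum() > 1)
        row = {
            "unit_id": uid, "anova_p": p_med,
            "selective": bool(p_med < alpha),
            "preferred_location": pref,
            "least_preferred_location": least,
            "tied": tied, "n_trials_per_location": m,
        }
        for loc in range(1, 10):
            row[f"mean_rate_loc{loc}"] = means.get(loc, np.nan)
        out.append(row)
    cols = (["unit_id", "anova_p", "selective", "preferred_location",
             "least_preferred_location", "tied", "n_trials_per_location"]
            + [f"mean_rate_loc{loc}" for loc in range(1, 10)])
    return pd.DataFrame(out, columns=cols)


def tuning_census(
    rec: SessionRecording,
    epoch: str = "delay",
    alpha: float = 0.05,
    n_subsample: int = 50,
    seed: int = 0,
    single_units_only: bool = True,
) -> pd.DataFrame:
    """Selectivity per unit per injection period with matched trial counts.

    The subsample size for each unit is its minimum per-location trial count
    across the three injection periods, so the selective proportions are
    comparable between periods.
    """
    uids = rec.units.loc[rec.units["is_single"], "unit_id"].tolist() \
        if single_units_only else rec.units["unit_id"].tolist()
    rates = epoch_rates(rec, epoch, unit_ids=uids)
    min_counts: dict[int, int] = {}
    for uid, df in rates.groupby("unit_id"):
        per = df.groupby(["period", "location"]).size()
        min_counts[uid] = int(per.min()) if len(per) else 0
    frames = []
    for period in PERIODS:
        sub = rates.loc[rates["period"] == period]
        if not len(sub):
            continue
        res = anova_selectivity(sub, alpha=alpha, n_subsample=n_subsample,
                                subsample_to=min_counts,
                                seed=seed)
        res.insert(1, "period", period)
        res.insert(2, "epoch", epoch)
        frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


@dataclass
class RankedSlope:
    """Session-level ranked tuning curve and its fitted slope (Hz/rank)."""

    period: str
    ranked_rates: np.ndarray  # rank 1 (preferred) .. 9 (least preferred)
    slope: float


def ranked_slope(rates: pd.DataFrame, period: str | None = None,
                 normalize: bool = True) -> RankedSlope:
    """Slope of a line fitted to rank-ordered mean rates, pooled over units.

    Each unit's nine per-location mean rates are sorted from preferred to
    least preferred, optionally normalised by the unit's maximum, averaged
    across units, and a least-squares line is fitted against rank 1..9. A
    more negative slope means sharper tuning.
    """
    if period is not None:
        rates = rates.loc[rates["period"] == period]
    curves = []
    for _, df in rates.groupby("unit_id"):
        means = df.groupby("location")["rate_hz"].mean()
        if len(means) < 9:
            raise ValueError("ranked_slope requires all 9 locations per unit")
        vals = np.sort(means.to_numpy(dtype=float))[::-1]
        if normalize:
            if vals[0] > 0:
                vals = vals / vals[0]
            else:
                continue
        curves.append(vals)
    if not curves:
        raise ValueError("no usable units for ranked_slope")
    avg = np.mean(curves, axis=0)
    ranks = np.arange(1, 10, dtype=float)
    slope = float(np.polyfit(ranks, avg, 1)[0])
    return RankedSlope(period=period or "all", ranked_rates=avg, slope=slope)


def sdf(
    spike_times_ms: np.ndarray,
    t_grid_ms: np.ndarray,
    sd_ms: float = SDF_SD_MS,
) -> np.ndarray:
    """Spike density function: Gaussian-kernel rate estimate in Hz.

    Plain convolution with an untruncated Gaussian kernel (no edge
    renormalisation); a single spike contributes a unit-mass bump whose
    peak is ``1000 / (sd_ms * sqrt(2*pi))`` Hz.
    """
    t_grid_ms = np.asarray(t_grid_ms, dtype=float)
    out = np.zeros_like(t_grid_ms)
    ts = np.asarray(spike_times_ms, dtype=float)
    if ts.size == 0:
        return out
    norm = 1000.0 / (sd_ms * np.sqrt(2.0 * np.pi))
    for t in ts:  # spike counts per window are small; direct sum is exact
        out += norm * np.exp(-((t_grid_ms - t) ** 2) / (2.0 * sd_ms ** 2))
    return out


@dataclass
class PlaneFit:
    """Coefficients of f(x,y) = p00 + p10 x + p01 y + p20 x^2 + p02 y^2 + p11 xy."""

    p00: float
    p10: float
    p01: float
    p20: float
    p02: float
    p11: float

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (self.p00 + self.p10 * x + self.p01 * y
                + self.p20 * x * x + self.p02 * y * y + self.p11 * x * y)


def plane_fit(mean_rates: np.ndarray,
              xy: np.ndarray | None = None) -> PlaneFit:
    """Least-squares second-order polynomial surface over target coordinates.

    ``mean_rates`` are the nine per-location (normalised) mean rates ordered
    by location 1..9; ``xy`` defaults to the standard grid coordinates.
    Display aid only.
    """
    r = np.asarray(mean_rates, dtype=float)
    if xy is None:
        xy = np.array([target_xy(loc) for loc in range(1, 10)])
    xy = np.asarray(xy, dtype=float)
    if r.shape[0] != xy.shape[0]:
        raise ValueError("mean_rates and xy must have matching length")
    x, y = xy[:, 0], xy[:, 1]
    design = np.column_stack([np.ones_like(x), x, y, x * x, y * y, x * y])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("rank-deficient design: degenerate coordinates")
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    return PlaneFit(*map(float, coef))
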