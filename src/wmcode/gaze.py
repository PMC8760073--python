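"""Gaze control analyses separating memory codes from eye-position signals.

The session format carries pre-labelled fixations and saccades (eye-movement
classification is upstream of this package). Four analyses: the proportion
of delay-epoch fixation time spent on the target; decoding the target from
16-cell fixation-count maps; decoding the eye's screen region from neural
activity during fixations; and saccade-tuning tests in retinocentric vs
spatiocentric reference frames with cross-frame power matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import child_seed, rng_for
from .decoding import decode_cv
from .session import (
    SCREEN_H,
    SCREEN_W,
    SessionRecording,
    screen_cell_bounds,
)
from .tuning import epoch_rates

#: Fixations shorter than this are dropped (ms).
MIN_FIXATION_MS = 6.0

#: Screen grid for fixation-map decoding: 16 cells (4 x 4).
FIX_GRID = 4


def _clean_fixations(fixations: pd.DataFrame) -> pd.DataFrame:
    dur = fixations["end_ms"] - fixations["start_ms"]
    return fixations.loc[dur >= MIN_FIXATION_MS]


def fixation_on_target_proportion(
    rec: SessionRecording,
    epoch: str = "delay",
    period: str | None = None,
    correct_only: bool = True,
) -> float:
    """Summed on-target fixation time over summed fixation time.

    A fixation is on target when it falls in the screen-grid cell containing
    the target's screen projection (the same 16-cell grid used by the
    fixation-map decoder). Returns ``nan`` when there is no fixation time.
    """
    trials = rec.trials
    if period is not None:
        trials = trials.loc[trials["period"] == period]
    if correct_only:
        trials = trials.loc[trials["outcome"] == "correct"]
    fx = _clean_fixations(rec.fixations)
    fx = fx.loc[fx["epoch"] == epoch]
    fx = fx.merge(trials[["trial_id", "target_location"]], on="trial_id")
    if not len(fx):
        return float("nan")
    dur = (fx["end_ms"] - fx["start_ms"]).to_numpy(dtype=float)
    on = np.zeros(len(fx), dtype=bool)
    for loc, idx in fx.groupby("target_location").groups.items():
        x0, x1, y0, y1 = screen_cell_bounds(int(loc))
        sub = fx.loc[idx]
        on[fx.index.get_indexer(idx)] = (
            (sub["x_px"] >= x0) & (sub["x_px"] < x1)
            & (sub["y_px"] >= y0) & (sub["y_px"] < y1)
        ).to_numpy()
    total = dur.sum()
    return float(dur[on].sum() / total) if total > 0 else float("nan")


def fixation_count_maps(
    rec: SessionRecording,
    epoch: str,
    trials: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-trial 16-cell fixation-count vectors (4 x 4 screen grid)."""
    if trials is None:
        trials = rec.trials
    fx = _clean_fixations(rec.fixations)
    fx = fx.loc[fx["epoch"] == epoch]
    cw, ch = SCREEN_W / FIX_GRID, SCREEN_H / FIX_GRID
    maps = np.zeros((len(trials), FIX_GRID * FIX_GRID))
    trial_pos = {tid: k for k, tid in enumerate(trials["trial_id"])}
    for row in fx.itertuples():
        k = trial_pos.get(row.trial_id)
        if k is None:
            continue
        ci = min(int(row.x_px // cw), FIX_GRID - 1)
        cj = min(int(row.y_px // ch), FIX_GRID - 1)
        maps[k, cj * FIX_GRID + ci] += 1
    return maps, trials.reset_index(drop=True)


def decode_target_from_fixations(
    rec: SessionRecording,
    epoch: str = "delay",
    period: str | None = None,
    label: str = "target_column",
    k_folds: int = 5,
    n_balance: int = 20,
    seed: int = 0,
):
    """Decode target location from where the animal fixated on screen.

    Linear SVM with ``k_folds``-fold cross-validation on the 16-cell
    fixation-count vectors. Returns a :class:`~wmcode.decoding.DecodingResult`.
    """
    trials = rec.trials
    if period is not None:
        trials = trials.loc[trials["period"] == period]
    maps, info = fixation_count_maps(rec, epoch, trials)
    return decode_cv(maps, info[label].to_numpy(), k_folds=k_folds,
                     n_balance=n_balance, seed=seed)


def neural_decoder_matched_features(
    rec: SessionRecording,
    epoch: str = "delay",
    period: str | None = None,
    label: str = "target_column",
    n_features: int = 16,
    k_folds: int = 5,
    n_balance: int = 20,
    seed: int = 0,
):
    """Neural decoder restricted to ``n_features`` units, for the paired
    comparison against the fixation-map decoder (identical trial sets)."""
    trials = rec.trials
    if period is not None:
        trials = trials.loc[trials["period"] == period]
    rng = rng_for(seed, "feature_pick")
    uids = rec.units["unit_id"].to_numpy()
    if len(uids) > n_features:
        uids = np.sort(rng.choice(uids, size=n_features, replace=False))
    rates = epoch_rates(rec, epoch, unit_ids=uids,
                        trial_ids=trials["trial_id"].to_numpy())
    wide = rates.pivot_table(index="trial_id", columns="unit_id",
                             values="rate_hz").loc[trials["trial_id"]]
    return decode_cv(wide.to_numpy(), trials[label].to_numpy(),
                     k_folds=k_folds, n_balance=n_balance,
                     seed=child_seed(seed, "neural"))


def eye_regions(n_regions: int = 4) -> list[tuple[float, float, float, float]]:
    """Default screen regions for eye-region decoding: the four screen
    quadrants (config-replaceable)."""
    if n_regions != 4:
        raise ValueError("only the 4-quadrant default is built in")
    hw, hh = SCREEN_W / 2.0, SCREEN_H / 2.0
    return [(0, hw, 0, hh), (hw, SCREEN_W, 0, hh),
            (0, hw, hh, SCREEN_H), (hw, SCREEN_W, hh, SCREEN_H)]


class MissingRegionError(ValueError):
    """A session lacks fixations in one or more screen regions."""


def decode_eye_region_from_neurons(
    rec: SessionRecording,
    epochs: tuple = ("cue", "delay"),
    regions: list | None = None,
    k_folds: int = 4,
    seed: int = 0,
):
    """Decode which screen region the eyes fixate from firing rates.

    Firing rate of every unit is computed within each fixation window,
    z-scored inside the cross-validated SVM pipeline, and classified into
    the fixation's region (4 classes, chance 25%). Sessions missing a
    region entirely raise :class:`MissingRegionError` (excluded upstream).
    """
    regions = regions if regions is not None else eye_regions()
    fx = _clean_fixations(rec.fixations)
    fx = fx.loc[fx["epoch"].isin(epochs)].reset_index(drop=True)
    labels = np.full(len(fx), -1)
    for r, (x0, x1, y0, y1) in enumerate(regions):
        inside = ((fx["x_px"] >= x0) & (fx["x_px"] < x1)
                  & (fx["y_px"] >= y0) & (fx["y_px"] < y1)).to_numpy()
        labels[inside & (labels < 0)] = r
    keep = labels >= 0
    fx, labels = fx.loc[keep].reset_index(drop=True), labels[keep]
    present = np.unique(labels)
    if len(present) < len(regions):
        raise MissingRegionError(
            f"regions {sorted(set(range(len(regions))) - set(present))} "
            "have no fixations")

    uids = rec.units["unit_id"].tolist()
    spike_by_unit = {uid: rec.unit_spikes(uid) for uid in uids}
    X = np.zeros((len(fx), len(uids)))
    for i, row in enumerate(fx.itertuples()):
        dur_s = (row.end_ms - row.start_ms) / 1000.0
        for j, uid in enumerate(uids):
            ts = spike_by_unit[uid]
            c = (np.searchsorted(ts, row.end_ms)
                 - np.searchsorted(ts, row.start_ms))
            X[i, j] = c / dur_s if dur_s > 0 else 0.0
    return decode_cv(X, labels, k_folds=k_folds, n_balance=5, seed=seed)


# ---------------------------------------------------------------------------
# Saccade reference-frame tuning


@dataclass
class SaccadeFrameBins:
    """Quadrant-binned saccades per reference frame after power matching."""

    table: pd.DataFrame  # saccade_idx, frame, bin, kept
    acceptable_bins: dict  # frame -> list of bin ids with >= min_count


def _quadrant(x: np.ndarray, y: np.ndarray, cx: float, cy: float) -> np.ndarray:
    return (x >= cx).astype(int) + 2 * (y >= cy).astype(int)


def bin_saccades(
    saccades: pd.DataFrame,
    seed: int = 0,
    min_count: int = 10,
) -> SaccadeFrameBins:
    """Quadrant binning in both reference frames with power matching.

    Retinocentric: saccade displacement (end - start) binned by the sign of
    its components. Spatiocentric: landing position binned into screen
    quadrants. To match statistical power across frames, bins are ordered by
    count within each frame, paired by rank across frames, and saccades are
    dropped at random from the larger bin of each pair so paired counts are
    equal. Bins below ``min_count`` (after matching) are unacceptable.
    """
    sx = saccades["start_x_px"].to_numpy(dtype=float)
    sy = saccades["start_y_px"].to_numpy(dtype=float)
    ex = saccades["end_x_px"].to_numpy(dtype=float)
    ey = saccades["end_y_px"].to_numpy(dtype=float)
    retino = _quadrant(ex - sx, ey - sy, 0.0, 0.0)
    spatio = _quadrant(ex, ey, SCREEN_W / 2.0, SCREEN_H / 2.0)

    rows = []
    for idx in range(len(saccades)):
        rows.append({"saccade_idx": idx, "frame": "retinocentric",
                     "bin": int(retino[idx]), "kept": True})
        rows.append({"saccade_idx": idx, "frame": "spatiocentric",
                     "bin": int(spatio[idx]), "kept": True})
    table = pd.DataFrame(rows)

    rng = rng_for(seed, "power_match")
    counts = {
        frame: table.loc[(table["frame"] == frame)]
        .groupby("bin").size().sort_values(ascending=False)
        for frame in ("retinocentric", "spatiocentric")
    }
    ranked = {f: list(c.items()) for f, c in counts.items()}
    n_pairs = min(len(ranked["retinocentric"]), len(ranked["spatiocentric"]))
    for k in range(n_pairs):
        (bin_r, n_r) = ranked["retinocentric"][k]
        (bin_s, n_s) = ranked["spatiocentric"][k]
        target = min(n_r, n_s)
        for frame, b, cnt in (("retinocentric", bin_r, n_r),
                              ("spatiocentric", bin_s, n_s)):
            if cnt > target:
                members = table.index[(table["frame"] == frame)
                                      & (table["bin"] == b)].to_numpy()
                drop = rng.choice(members, size=cnt - target, replace=False)
                table.loc[drop, "kept"] = False
    kept = table.loc[table["kept"]]
    acceptable = {
        frame: sorted(
            b for b, c in kept.loc[kept["frame"] == frame]
            .groupby("bin").size().items() if c >= min_count)
        for frame in ("retinocentric", "spatiocentric")
    }
    return SaccadeFrameBins(table=table, acceptable_bins=acceptable)


def saccade_frame_tuning(
    rec: SessionRecording,
    alpha: float = 0.05,
    rate_window_ms: float = 200.0,
    min_bins: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-unit Kruskal-Wallis saccade tuning in each reference frame.

    For every saccade, each unit's firing rate is taken in a fixed window
    from saccade onset; rates are compared across the frame's acceptable
    quadrant bins (power-matched across frames). Units (here, sessions)
    with fewer than ``min_bins`` acceptable bins in a frame are excluded
    for that frame. Returns unit_id, frame, kw_p, tuned.
    """
    bins = bin_saccades(rec.saccades, seed=seed)
    sacc = rec.saccades.reset_index(drop=True)
    uids = rec.units["unit_id"].tolist()
    spike_by_unit = {uid: rec.unit_spikes(uid) for uid in uids}
    onset = sacc["start_ms"].to_numpy(dtype=float)

    rate = np.zeros((len(sacc), len(uids)))
    for j, uid in enumerate(uids):
        ts = spike_by_unit[uid]
        c = (np.searchsorted(ts, onset + rate_window_ms)
             - np.searchsorted(ts, onset))
        rate[:, j] = c / (rate_window_ms / 1000.0)

    out = []
    for frame in ("retinocentric", "spatiocentric"):
        ok_bins = bins.acceptable_bins[frame]
        sub = bins.table.loc[(bins.table["frame"] == frame)
                             & bins.table["kept"]
                             & bins.table["bin"].isin(ok_bins)]
        if len(ok_bins) < min_bins:
            continue  # frame excluded for all units
        for j, uid in enumerate(uids):
            groups = [rate[sub.loc[sub["bin"] == b, "saccade_idx"]
                           .to_numpy(), j] for b in ok_bins]
            if any(len(g) < 2 for g in groups):
                continue
            flat = np.concatenate(groups)
            if np.ptp(flat) == 0:
                continue
            p = float(stats.kruskal(*groups).pvalue)
            out.append({"unit_id": uid, "frame": frame, "kw_p": p,
                        "tuned": bool(p < alpha)})
    return pd.DataFrame(out, columns=["unit_id", "frame", "kw_p", "tuned"])


def tuning_overlap(
    saccade_table: pd.DataFrame,
    delay_tuned_ids: set,
) -> pd.DataFrame:
    """Overlap of saccade-frame tuning with delay-epoch target tuning."""
    rows = []
    for frame, grp in saccade_table.groupby("frame"):
        n = len(grp)
        tuned = grp.loc[grp["tuned"], "unit_id"]
        both = sum(1 for u in tuned if u in delay_tuned_ids)
        rows.append({
            "frame": frame, "n_units": n,
            "prop_saccade_tuned": float(grp["tuned"].mean()) if n else np.nan,
            "prop_both_tuned": both / n if n else np.nan,
        })
    return pd.DataFrame(rows, columns=["frame", "n_units",
                                       "prop_saccade_tuned",
                                       "prop_both_tuned"])
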