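import numpy as np
import pandas as pd
import pytest

from wmcode.session import SCREEN_H, SCREEN_W, screen_cell_bounds
from wmcode.gaze import (
    MissingRegionError,
    bin_saccades,
    decode_eye_region_from_neurons,
    decode_target_from_fixations,
    fixation_on_target_proportion,
    neural_decoder_matched_features,
    saccade_frame_tuning,
)
from wmcode.synth import GeneratorConfig, generate_session

from conftest import make_manual_session, trial_row


def _fixation(trial_id, x, y, start, dur=150.0, epoch="delay"):
    return {"trial_id": trial_id, "x_px": x, "y_px": y,
            "start_ms": start, "end_ms": start + dur, "epoch": epoch}


def _session_with_fixations(fix_rows, n_trials=4):
    rec = make_manual_session(
        [trial_row(i, 5, cue_on=500.0 + i * 20000.0) for i in
         range(n_trials)],
        spikes=[(0, 1.0)])
    rec.fixations = pd.DataFrame(fix_rows)
    return rec


def test_fixation_proportion_extremes():
    x0, x1, y0, y1 = screen_cell_bounds(5)
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    on = _session_with_fixations(
        [_fixation(i, cx, cy, 4000.0 + i * 20000.0) for i in range(4)])
    assert fixation_on_target_proportion(on) == pytest.approx(1.0)
    off = _session_with_fixations(
        [_fixation(i, 5.0, 5.0, 4000.0 + i * 20000.0) for i in range(4)])
    assert fixation_on_target_proportion(off) == pytest.approx(0.0)
    # sub-6-ms fixations are discarded entirely
    tiny = _session_with_fixations(
        [_fixation(0, cx, cy, 4000.0, dur=3.0)])
    assert np.isnan(fixation_on_target_proportion(tiny))


def test_fixation_proportion_matches_generator_bias(default_session):
    rec, _ = default_session
    cfg = GeneratorConfig()
    prop = fixation_on_target_proportion(rec, period="pre")
    # biased fixations land in the target cell; unbiased ones land there
    # with probability 1/16
    expected = cfg.on_target_bias + (1 - cfg.on_target_bias) / 16.0
    n_fix = len(rec.fixations.query("epoch == 'delay'"))
    assert prop == pytest.approx(expected, abs=4 * np.sqrt(
        expected * (1 - expected) / max(n_fix // 3, 1)))


def test_fixation_map_decoder_perfect_when_cells_are_class_specific():
    # fixations deterministically in a class-specific cell
    rows, trials = [], []
    cells = {1: (100.0, 100.0), 5: (500.0, 400.0), 9: (900.0, 700.0)}
    for i in range(45):
        loc = [1, 5, 9][i % 3]
        trials.append(trial_row(i, loc, cue_on=500.0 + i * 20000.0))
        x, y = cells[loc]
        rows.append(_fixation(i, x, y, 4000.0 + i * 20000.0))
    rec = make_manual_session(trials, spikes=[(0, 1.0)])
    rec.fixations = pd.DataFrame(rows)
    res = decode_target_from_fixations(rec, n_balance=2, seed=0)
    assert res.accuracy == 1.0


def test_fixation_map_decoder_at_chance_with_identical_maps():
    rows, trials = [], []
    for i in range(60):
        loc = [1, 5, 9][i % 3]
        trials.append(trial_row(i, loc, cue_on=500.0 + i * 20000.0))
        rows.append(_fixation(i, 500.0, 400.0, 4000.0 + i * 20000.0))
    rec = make_manual_session(trials, spikes=[(0, 1.0)])
    rec.fixations = pd.DataFrame(rows)
    res = decode_target_from_fixations(rec, n_balance=3, seed=0)
    assert abs(res.accuracy - 1 / 3) < 0.25


def test_gaze_bias_dissociation(default_session):
    # the dissociation logic: fixation-map decoding is far weaker than
    # neural decoding on the same pre-injection trials
    rec, _ = default_session
    fix = decode_target_from_fixations(rec, period="pre", n_balance=3,
                                       seed=0)
    neural = neural_decoder_matched_features(rec, period="pre",
                                             n_balance=3, seed=0)
    assert neural.accuracy > fix.accuracy


def test_eye_region_decoder_chance_and_keyed_unit():
    rng = np.random.default_rng(0)
    n_fix = 240
    quadrant_centers = [(256, 192), (768, 192), (256, 576), (768, 576)]
    trials = [trial_row(0, 5, cue_on=500.0)]
    fix_rows, spikes = [], []
    t = 600.0
    for i in range(n_fix):
        q = i % 4
        x, y = quadrant_centers[q]
        fix_rows.append(_fixation(0, x + rng.normal(0, 30),
                                  y + rng.normal(0, 30), t, dur=100.0,
                                  epoch="cue" if i % 2 else "delay"))
        # unit 0's rate is a distinct level per quadrant; unit 1 is random
        spikes += [(0, t + u) for u in
                   sorted(rng.uniform(0, 100, (0, 6, 14, 25)[q]))]
        spikes += [(1, t + u) for u in sorted(rng.uniform(0, 100, 3))]
        t += 150.0
    trials[0]["delay_on"] = trials[0]["cue_on"] + 3000.0
    trials[0]["trial_end"] = t + 5000.0
    rec = make_manual_session(trials, spikes=spikes)
    rec.fixations = pd.DataFrame(fix_rows)
    res = decode_eye_region_from_neurons(rec, seed=0)
    assert res.accuracy > 0.9  # keyed unit separates one region perfectly

    # rates independent of region: accuracy ~ 25%
    spikes_flat = [(0, u) for u in np.sort(rng.uniform(600.0, t, 2000))]
    rec2 = make_manual_session(trials, spikes=spikes_flat)
    rec2.fixations = pd.DataFrame(fix_rows)
    res2 = decode_eye_region_from_neurons(rec2, seed=0)
    assert abs(res2.accuracy - 0.25) < 0.12


def test_eye_region_decoder_missing_region_excluded():
    trials = [trial_row(0, 5, cue_on=500.0)]
    fix_rows = [_fixation(0, 100.0, 100.0, 600.0 + 200 * i)
                for i in range(20)]  # all in one quadrant
    rec = make_manual_session(trials, spikes=[(0, 1.0)])
    rec.fixations = pd.DataFrame(fix_rows)
    with pytest.raises(MissingRegionError):
        decode_eye_region_from_neurons(rec, seed=0)


def _saccade_table(rng, n, retino_bias=None):
    rows = []
    for i in range(n):
        sx, sy = rng.uniform(0, SCREEN_W), rng.uniform(0, SCREEN_H)
        dx, dy = rng.normal(0, 150), rng.normal(0, 120)
        rows.append({"trial_id": 0, "start_x_px": sx, "start_y_px": sy,
                     "end_x_px": np.clip(sx + dx, 0, SCREEN_W),
                     "end_y_px": np.clip(sy + dy, 0, SCREEN_H),
                     "start_ms": 500.0 + 300.0 * i,
                     "end_ms": 540.0 + 300.0 * i})
    return pd.DataFrame(rows)


def test_power_matching_equalises_and_never_increases():
    rng = np.random.default_rng(3)
    sacc = _saccade_table(rng, 400)
    bins = bin_saccades(sacc, seed=0)
    raw = bins.table.groupby(["frame", "bin"]).size()
    kept = (bins.table.loc[bins.table["kept"]]
            .groupby(["frame", "bin"]).size())
    for key in kept.index:
        assert kept[key] <= raw[key]  # matching only ever drops saccades
    r = kept["retinocentric"].sort_values(ascending=False).to_numpy()
    s = kept["spatiocentric"].sort_values(ascending=False).to_numpy()
    np.testing.assert_array_equal(r, s)  # rank-paired bins are equal


def test_saccade_tuning_detects_retinocentric_drive():
    rng = np.random.default_rng(5)
    sacc = _saccade_table(rng, 360)
    trials = [trial_row(0, 5, cue_on=500.0)]
    trials[0]["trial_end"] = float(sacc["end_ms"].max() + 10000.0)
    # unit 0 rate keyed to the retinocentric quadrant of each saccade
    dx = sacc["end_x_px"] - sacc["start_x_px"]
    dy = sacc["end_y_px"] - sacc["start_y_px"]
    quad = (dx >= 0).astype(int) + 2 * (dy >= 0).astype(int)
    spikes = []
    for i, row in sacc.iterrows():
        lam = [1, 4, 8, 14][quad[i]] * 0.2
        n_sp = rng.poisson(lam)
        spikes += [(0, row["start_ms"] + u)
                   for u in sorted(rng.uniform(0, 200, n_sp))]
        spikes += [(1, row["start_ms"] + u)
                   for u in sorted(rng.uniform(0, 200, rng.poisson(1.0)))]
    rec = make_manual_session(trials, spikes=spikes)
    rec.saccades = sacc
    res = saccade_frame_tuning(rec, seed=0).set_index(["unit_id", "frame"])
    assert bool(res.loc[(0, "retinocentric"), "tuned"])
    # untuned unit stays untuned in that frame at alpha = 0.05 most runs
    assert res.loc[(1, "retinocentric"), "kw_p"] > 0.01
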