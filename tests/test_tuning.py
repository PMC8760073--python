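import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmcode.synth import generate_null_units
from wmcode.tuning import (
    PlaneFit,
    anova_selectivity,
    epoch_rates,
    plane_fit,
    ranked_slope,
    sdf,
)
from wmcode.session import target_xy

from conftest import make_manual_session, trial_row


def _rates_df(per_unit_loc_rates, n_trials=5, jitter=None, seed=0):
    """Long rate table from {unit: {loc: rate}} with optional noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for uid, locs in per_unit_loc_rates.items():
        for loc, r in locs.items():
            for t in range(n_trials):
                val = r + (rng.normal(0, jitter) if jitter else 0.0)
                rows.append({"unit_id": uid, "location": loc,
                             "rate_hz": val,
                             "trial_id": len(rows), "period": "pre",
                             "outcome": "correct"})
    return pd.DataFrame(rows)


def test_epoch_rates_counts_in_window():
    trials = [trial_row(0, 1, cue_on=500.0)]
    # 6 spikes inside the 2000-ms delay -> 3 Hz; delay is [3500, 5500)
    spikes = [(0, t) for t in (3600, 3700, 4000, 4500, 5000, 5499.9)]
    spikes += [(0, 5500.0), (0, 100.0)]  # outside the half-open window
    rec = make_manual_session(trials, spikes)
    rates = epoch_rates(rec, "delay")
    assert rates.loc[0, "rate_hz"] == pytest.approx(3.0)
    # a unit with no spikes reads 0 Hz
    rec2 = make_manual_session(trials, [(0, 100.0)])
    assert epoch_rates(rec2, "delay").loc[0, "rate_hz"] == 0.0


def test_anova_detects_strong_tuning():
    df = _rates_df({0: {loc: (50.0 if loc == 4 else 5.0)
                        for loc in range(1, 10)}},
                   n_trials=20, jitter=2.0)
    res = anova_selectivity(df, alpha=0.05)
    assert res.loc[0, "anova_p"] < 1e-10
    assert bool(res.loc[0, "selective"])
    assert res.loc[0, "preferred_location"] == 4
    # F-statistic oracle on the same grouped data
    groups = [df.loc[df["location"] == loc, "rate_hz"] for loc in
              range(1, 10)]
    assert res.loc[0, "anova_p"] == pytest.approx(
        stats.f_oneway(*groups).pvalue)


def test_anova_constant_rates_skipped():
    df = _rates_df({0: {loc: 0.0 for loc in range(1, 10)}}, n_trials=5)
    assert len(anova_selectivity(df)) == 0


def test_subsample_median_is_noop_at_equal_counts():
    df = _rates_df({0: {loc: float(loc) for loc in range(1, 10)}},
                   n_trials=8, jitter=3.0, seed=3)
    res = anova_selectivity(df, n_subsample=50, seed=1)
    groups = [df.loc[df["location"] == loc, "rate_hz"]
              for loc in range(1, 10)]
    assert res.loc[0, "anova_p"] == pytest.approx(
        stats.f_oneway(*groups).pvalue)


def test_type_one_error_calibrated_on_null_units():
    n = 300
    df = generate_null_units(n, rate=5.0, seed=9, trials_per_location=15)
    df = df.loc[~df["degenerate"]]
    res = anova_selectivity(df, alpha=0.05, seed=0)
    frac = res["selective"].mean()
    se = np.sqrt(0.05 * 0.95 / len(res))
    assert abs(frac - 0.05) < 3 * se


def test_ranked_slope_closed_form():
    # session-mean ranked rates 9..1 Hz -> least-squares slope is -1 Hz/rank
    df = _rates_df({0: {loc: float(10 - loc) for loc in range(1, 10)}},
                   n_trials=3)
    rs = ranked_slope(df, normalize=False)
    assert rs.slope == pytest.approx(-1.0)
    np.testing.assert_allclose(rs.ranked_rates, np.arange(9, 0, -1.0))
    flat = _rates_df({0: {loc: 4.0 for loc in range(1, 10)}}, n_trials=3)
    assert ranked_slope(flat, normalize=False).slope == pytest.approx(0.0)


def test_ranked_slope_requires_all_locations():
    df = _rates_df({0: {loc: 1.0 * loc for loc in range(1, 9)}}, n_trials=3)
    with pytest.raises(ValueError, match="9 locations"):
        ranked_slope(df, normalize=False)


def test_sdf_peak_height_and_linearity():
    grid = np.arange(-1000.0, 1000.0, 1.0)
    one = sdf(np.array([0.0]), grid)
    peak = 1000.0 / (150.0 * np.sqrt(2 * np.pi))
    assert one.max() == pytest.approx(peak, rel=1e-6)  # ~2.66 Hz
    assert grid[np.argmax(one)] == pytest.approx(0.0)
    two = sdf(np.array([0.0, 50.0]), grid)
    np.testing.assert_allclose(two, one + sdf(np.array([50.0]), grid),
                               rtol=1e-12)
    assert not sdf(np.array([]), grid).any()


def test_sdf_mass_conservation():
    grid = np.arange(-2000.0, 7000.0, 1.0)
    spikes = np.array([0.0, 1000.0, 2500.0, 4999.0])
    est = sdf(spikes, grid)
    # integral (in spikes: Hz * s) equals the spike count within 0.1%
    integral = np.trapezoid(est, grid / 1000.0)
    assert integral == pytest.approx(len(spikes), rel=1e-3)


def test_plane_fit_exact_surfaces():
    xy = np.array([target_xy(loc) for loc in range(1, 10)]) / 290.0
    fit = plane_fit(2.0 * xy[:, 0], xy)
    assert fit.p10 == pytest.approx(2.0, abs=1e-10)
    for name in ("p00", "p01", "p20", "p02", "p11"):
        assert getattr(fit, name) == pytest.approx(0.0, abs=1e-10)
    fit2 = plane_fit(xy[:, 0] ** 2, xy)
    assert fit2.p20 == pytest.approx(1.0, abs=1e-10)
    assert fit2.p10 == pytest.approx(0.0, abs=1e-10)


def test_plane_fit_matches_pseudoinverse_oracle():
    rng = np.random.default_rng(0)
    xy = np.array([target_xy(loc) for loc in range(1, 10)]) / 290.0
    r = rng.normal(size=9)
    fit = plane_fit(r, xy)
    x, y = xy[:, 0], xy[:, 1]
    design = np.column_stack([np.ones(9), x, y, x * x, y * y, x * y])
    oracle = np.linalg.pinv(design) @ r
    got = [fit.p00, fit.p10, fit.p01, fit.p20, fit.p02, fit.p11]
    np.testing.assert_allclose(got, oracle, atol=1e-10)


def test_plane_fit_degenerate_coordinates_raise():
    xy = np.zeros((9, 2))
    with pytest.raises(ValueError, match="rank"):
        plane_fit(np.arange(9.0), xy)
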