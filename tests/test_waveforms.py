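import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

from wmcode.synth import GeneratorConfig, generate_session
from wmcode.waveforms import (
    WaveformClassifier,
    cell_type_contrast,
    classify_session_units,
    fit_width_mixture,
    gaussian_crossing,
    waveform_width,
    widths_table,
)

DT_US = 1e6 / 30000.0


def _template(trough_us, peak_us, n=48, dt=DT_US, peak_amp=0.6):
    t = np.arange(n) * dt
    s = 40.0
    return (-np.exp(-((t - trough_us) ** 2) / (2 * s * s))
            + peak_amp * np.exp(-((t - peak_us) ** 2) / (2 * s * s)))


def test_width_from_constructed_template():
    # trough at 300 us, peak at 650 us -> width 350 us (within one fine step)
    v = _template(300.0, 650.0)
    w = waveform_width(v, DT_US)
    assert w == pytest.approx(350.0, abs=DT_US / 100 + 1.5)


def test_width_invariant_to_polarity_and_affine_scaling():
    v = _template(300.0, 650.0)
    w = waveform_width(v, DT_US)
    assert waveform_width(-v, DT_US) == pytest.approx(w, abs=1e-9)
    assert waveform_width(3.5 * v + 0.2, DT_US) == pytest.approx(w, abs=1e-6)


def test_width_matches_brute_force_grid_search():
    v = _template(280.0, 700.0, peak_amp=0.4)
    t = np.arange(v.size) * DT_US
    fine_t = np.linspace(t[0], t[-1], (v.size - 1) * 100 + 1)
    fine_v = CubicSpline(t, v - v.mean())(fine_t)
    oracle = abs(fine_t[np.argmax(fine_v)] - fine_t[np.argmin(fine_v)])
    assert waveform_width(v, DT_US) == pytest.approx(oracle, abs=1e-9)


def test_monotone_waveform_excluded():
    assert np.isnan(waveform_width(np.linspace(0, 1, 48), DT_US))
    assert np.isnan(waveform_width(np.ones(48), DT_US))


def test_session_widths_recover_drawn_widths(small_session):
    rec, gt = small_session
    table = widths_table(rec).set_index("unit_id")
    truth = gt.units.set_index("unit_id")
    for uid in truth.index:
        if table.loc[uid, "excluded"]:
            continue
        assert table.loc[uid, "width_us"] == pytest.approx(
            truth.loc[uid, "width_us"], abs=25.0)


def test_gaussian_crossing_analytic_case():
    # equal SDs and weights: crossing is the midpoint of the means
    assert gaussian_crossing(200.0, 40.0, 0.5, 400.0, 40.0, 0.5) == \
        pytest.approx(300.0, abs=1e-6)
    assert gaussian_crossing(300.0, 40.0, 0.5, 300.0, 40.0, 0.5) is None


def test_mixture_recovers_threshold_near_analytic_crossing():
    rng = np.random.default_rng(0)
    cfg = GeneratorConfig()
    n = 2000
    n_ns = int(n * 0.25)
    widths = np.concatenate([
        rng.normal(cfg.ns_width_mean, cfg.width_sd, n_ns),
        rng.normal(cfg.bs_width_mean, cfg.width_sd, n - n_ns),
    ])
    fit = fit_width_mixture(widths, seed=0)
    assert fit.bimodal
    truth = gaussian_crossing(cfg.ns_width_mean, cfg.width_sd, 0.25,
                              cfg.bs_width_mean, cfg.width_sd, 0.75)
    assert abs(fit.threshold - truth) < 15.0


def test_unimodal_widths_select_single_gaussian():
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        widths = rng.normal(350.0, 60.0, size=1500)
        widths = widths[(widths > 0) & (widths < 675.0)]
        fit = fit_width_mixture(widths, seed=seed)
        wins += int(not fit.bimodal)
    assert wins >= 9  # 1-Gaussian AIC wins in >= 90% of seeds


def test_classifier_labels_and_outlier_exclusion():
    rng = np.random.default_rng(1)
    widths = np.concatenate([rng.normal(220, 40, 400),
                             rng.normal(420, 40, 1200)])
    clf = WaveformClassifier(seed=0).fit(widths)
    labels = clf.predict(np.array([150.0, clf.threshold_, 600.0, 700.0,
                                   np.nan]))
    assert list(labels) == ["NS", "BS", "BS", "excluded", "excluded"]


def test_cell_type_contrast_detects_generator_effects():
    cfg = GeneratorConfig()
    rec, gt = generate_session(cfg, seed=21)
    # classify with the truth-free width pipeline, pooled boundary known
    # to need more units than one session holds -> prefit on drawn mixture
    rng = np.random.default_rng(2)
    pool = np.concatenate([rng.normal(cfg.ns_width_mean, cfg.width_sd, 300),
                           rng.normal(cfg.bs_width_mean, cfg.width_sd, 900)])
    clf = WaveformClassifier(seed=0).fit(pool)
    table, _ = classify_session_units(rec, clf=clf)
    # labels agree with ground truth for nearly all units
    merged = table.merge(gt.units[["unit_id", "cell_class"]], on="unit_id",
                         suffixes=("", "_true"))
    usable = merged.loc[merged["cell_class"] != "excluded"]
    agree = (usable["cell_class"] == usable["cell_class_true"]).mean()
    assert agree > 0.9

    from wmcode.waveforms import preferred_rate_table
    rates_tbl = preferred_rate_table(rec, table, alpha=0.1, seed=0)
    res = cell_type_contrast(rates_tbl)
    assert res["n_ns"] >= 2 and res["n_bs"] >= 2
    # directional effects present in a drug-on session
    assert res["ns_pref_decrease_p"] < 0.2
    assert res["bs_least_increase_p"] < 0.2
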