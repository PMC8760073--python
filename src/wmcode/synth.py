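"""Synthetic session generator.

Emulates the statistical structure the analysis stages assume: two
waveform-defined unit classes (narrow- and broad-spiking) with smooth
9-location spatial tuning, doubly-stochastic trial-to-trial count
variability with a shared gain latent, epoch structure (cue 3000 ms, delay
2000 ms, response 2000 ms), navigation trajectories whose lateral dispersion
varies by injection period, fixations with a small on-target bias, and a
perturbation ("drug-on") mode that suppresses narrow-spiking tuning
multiplicatively and adds rate at broad-spiking units' non-preferred
locations in the early post-injection period, relaxing in the late period.

Ground truth (true tuning curves, class labels, widths, latent gains) is
emitted alongside every session and is never consumed by analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from ._utils import rng_for
from .session import (
    CUE_MS,
    DELAY_MS,
    GRID_SPACING,
    PERIODS,
    SCREEN_H,
    SCREEN_W,
    SessionRecording,
    period_label,
    screen_cell_bounds,
    target_column,
    target_xy,
    validate_session,
)

#: Arena start point (centre of the start enclave) and the boundary line
#: separating the enclave from the grid region.
START_XY = (0.0, -600.0)
ENCLAVE_LINE_Y = -435.0

_PRE_CUE_MS = 500.0
_ITI_MS = 1500.0
_NAV_LIMIT_S = 10.0


class GeneratorConfigError(ValueError):
    """Configuration produces invalid rates or timelines."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Rates are in Hz, times in ms unless noted; widths in microseconds.
    Defaults are the study conditions used throughout the test suite:
    modest session sizes (32 units, 12 trials per location per period) with
    drug effects strong enough that single-session contrasts are detectable.
    """

    # Unit population
    n_ns: int = 8
    n_bs: int = 24
    multiunit_fraction: float = 0.25

    # Trial structure
    trials_per_location_per_period: int = 12

    # Tuning model: baseline + amplitude * Gaussian bump over grid coords
    baseline_rate_hz: float = 3.0
    peak_rate_hz: float = 8.0
    tuning_bandwidth: float = GRID_SPACING  # arena units

    # Noise model
    rho: float = 0.2              # shared-gain latent strength
    private_gain_sd: float = 0.25  # per-unit multiplicative dispersion

    # Drug effect (early post-injection; late post relaxes toward baseline)
    g_ns: float = 0.5        # NS tuning-amplitude multiplier (< 1)
    delta_bs: float = 4.0    # BS additive rate at least-preferred (Hz, > 0)
    late_relaxation: float = 0.35  # fraction of the early effect remaining

    # Behaviour
    p_correct: dict = field(default_factory=lambda: {
        "pre": 0.80, "early_post": 0.50, "late_post": 0.70})
    response_time_mean_s: dict = field(default_factory=lambda: {
        "pre": 4.0, "early_post": 5.5, "late_post": 4.5})
    response_time_sd_s: float = 0.8
    dispersion: dict = field(default_factory=lambda: {
        "pre": 25.0, "early_post": 80.0, "late_post": 40.0})

    # Waveform-width mixture (microseconds)
    ns_width_mean: float = 220.0
    bs_width_mean: float = 420.0
    width_sd: float = 40.0
    waveform_sampling_interval_us: float = 1e6 / 30000.0

    # Gaze
    fixation_rate_hz: float = 3.0
    on_target_bias: float = 0.15
    fixation_duration_ms: tuple = (100.0, 300.0)

    # Mode switches
    condition: str = "ketamine_wm"
    perception_mode: bool = False  # period-independent behaviour parameters

    def validate(self) -> None:
        if not 0 < min(self.p_correct.values()) <= 1 or \
                max(self.p_correct.values()) > 1:
            raise GeneratorConfigError("p_correct must lie in (0, 1]")
        if self.ns_width_mean >= self.bs_width_mean:
            raise GeneratorConfigError(
                "width mixture means must be ordered NS < BS")
        if self.g_ns < 0 or self.delta_bs < 0:
            raise GeneratorConfigError("g_ns and delta_bs must be >= 0")
        if self.baseline_rate_hz < 0 or self.peak_rate_hz < 0:
            raise GeneratorConfigError("rates must be non-negative")


@dataclass
class GroundTruth:
    """True generator state for one session; never read by analysis stages.

    ``units``: unit_id, cell_class, width_us, pref_location, is_single.
    ``tuning``: long table (unit_id, period, location, rate_hz) of the true
    delay-epoch tuning curves. ``trial_gain``: per-trial shared latent gain.
    ``separation``: per-period norm of the true left-vs-right rate
    difference vector over all units (the decodable separation).
    """

    units: pd.DataFrame
    tuning: pd.DataFrame
    trial_gain: pd.DataFrame
    separation: pd.DataFrame


def _grid_coords() -> np.ndarray:
    return np.array([target_xy(loc) for loc in range(1, 10)])


def _true_curves(cfg: GeneratorConfig, pref_locs: np.ndarray,
                 classes: np.ndarray) -> dict[str, np.ndarray]:
    """Delay-epoch tuning curves, shape (n_units, 9), per period."""
    xy = _grid_coords()
    amp = cfg.peak_rate_hz - cfg.baseline_rate_hz
    bumps = np.empty((len(pref_locs), 9))
    for i, pref in enumerate(pref_locs):
        d2 = np.sum((xy - xy[pref - 1]) ** 2, axis=1)
        bumps[i] = np.exp(-d2 / (2.0 * cfg.tuning_bandwidth ** 2))

    base = cfg.baseline_rate_hz + amp * bumps  # pre-injection curves

    curves = {"pre": base}
    for period, strength in (("early_post", 1.0),
                             ("late_post", cfg.late_relaxation)):
        g = 1.0 - strength * (1.0 - cfg.g_ns)
        delta = strength * cfg.delta_bs
        cur = base.copy()
        ns = classes == "NS"
        bs = classes == "BS"
        # NS: multiplicative suppression of the tuned component
        cur[ns] = cfg.baseline_rate_hz + g * amp * bumps[ns]
        # BS: additive gain concentrated at non-preferred locations
        cur[bs] = base[bs] + delta * (1.0 - bumps[bs])
        if (cur < 0).any():
            raise GeneratorConfigError(
                "drug-effect parameters drive a rate below zero")
        curves[period] = cur
    return curves


def _epoch_rate(curve_rate: float, baseline: float, epoch: str) -> float:
    """Rate for an epoch given the unit's delay tuning-curve value."""
    if epoch in ("cue", "delay"):
        return curve_rate
    if epoch == "response":
        return baseline + 0.7 * (curve_rate - baseline)
    return baseline  # pre-cue


def _make_waveform(width_us: float, dt_us: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Biphasic template with trough-to-peak interval ``width_us``."""
    n = 48
    t = np.arange(n) * dt_us
    t_trough = 400.0
    t_peak = t_trough + width_us
    s = 40.0
    v = (-np.exp(-((t - t_trough) ** 2) / (2 * s * s))
         + 0.55 * np.exp(-((t - t_peak) ** 2) / (2 * s * s)))
    v += rng.normal(0.0, 0.003, size=n)
    return v


def _bridge_noise(n: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Brownian-bridge lateral noise, zero at both endpoints.

    ``scale`` is the standard deviation of the lateral excursion at the
    path midpoint (arena units).
    """
    if n < 3 or scale <= 0:
        return np.zeros(n)
    steps = rng.normal(0.0, 1.0, size=n - 1)
    w = np.concatenate([[0.0], np.cumsum(steps)])
    u = np.linspace(0.0, 1.0, n)
    bridge = w - u * w[-1]
    # midpoint variance of the raw bridge is (n-1)/4
    return 2.0 * scale * bridge / np.sqrt(n - 1)


def generate_session(
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[SessionRecording, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Spike counts per epoch are conditionally Poisson given a per-trial
    shared gain: ``rate = tuning(location) * gain``, with
    ``gain = max(0.05, 1 + rho * z_trial + private_sd * z_unit_trial)``.
    Spike times are placed uniformly within each epoch.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = rng_for(seed, "session")

    n_units = cfg.n_ns + cfg.n_bs
    classes = np.array(["NS"] * cfg.n_ns + ["BS"] * cfg.n_bs)
    widths = np.where(
        classes == "NS",
        rng.normal(cfg.ns_width_mean, cfg.width_sd, n_units),
        rng.normal(cfg.bs_width_mean, cfg.width_sd, n_units),
    )
    widths = np.clip(widths, 80.0, 660.0)
    pref_locs = rng.integers(1, 10, size=n_units)
    is_single = rng.random(n_units) >= cfg.multiunit_fraction
    curves = _true_curves(cfg, pref_locs, classes)

    # --- trial timeline -------------------------------------------------
    # Trials are laid out sequentially with their actual navigation
    # durations; each post-injection block must fit its 30-min window.
    nav_limit_ms = _NAV_LIMIT_S * 1000.0
    period_ms = 30.0 * 60e3

    trial_rows = []
    trial_id = 0
    period_start = 0.0
    injection_time = None
    for period in PERIODS:
        locs = np.repeat(np.arange(1, 10), cfg.trials_per_location_per_period)
        rng.shuffle(locs)
        t0 = period_start
        behav_period = "pre" if cfg.perception_mode else period
        for loc in locs:
            cue_on = t0 + _PRE_CUE_MS
            delay_on = cue_on + CUE_MS
            response_on = delay_on + DELAY_MS
            correct = rng.random() < cfg.p_correct[behav_period]
            rt = float(np.clip(
                rng.normal(cfg.response_time_mean_s[behav_period],
                           cfg.response_time_sd_s),
                1.0, _NAV_LIMIT_S - 0.2))
            nav_ms = rt * 1000.0 if correct else nav_limit_ms
            trial_end = response_on + nav_ms
            x, y = target_xy(int(loc))
            trial_rows.append({
                "trial_id": trial_id,
                "target_location": int(loc),
                "target_x": x, "target_y": y,
                "target_column": target_column(int(loc)),
                "target_side": target_column(int(loc)),
                "outcome": "correct" if correct else "incorrect",
                "cue_on": cue_on, "delay_on": delay_on,
                "response_on": response_on, "trial_end": trial_end,
                "period": period,
                "response_time": rt if correct else np.nan,
            })
            t0 = trial_end + _ITI_MS
            trial_id += 1
        if period == "pre":
            injection_time = t0 + 1000.0
            period_start = injection_time
        else:
            if t0 - period_start > period_ms:
                raise GeneratorConfigError(
                    "trials_per_location_per_period does not fit in a "
                    "30-min injection period")
            period_start += period_ms
    trials = pd.DataFrame(trial_rows)
    # labels must match the boundary rule exactly
    assert all(period_label(r["cue_on"], injection_time) == r["period"]
               for r in trial_rows)

    # --- units and waveforms -------------------------------------------
    unit_rows, wf_rows = [], []
    for uid in range(n_units):
        unit_rows.append({
            "unit_id": uid,
            "is_single": bool(is_single[uid]),
            "array_id": uid % 2,
            "sampling_interval_us": cfg.waveform_sampling_interval_us,
        })
        wf = _make_waveform(widths[uid], cfg.waveform_sampling_interval_us,
                            rng)
        for k, v in enumerate(wf):
            wf_rows.append({"unit_id": uid, "sample_idx": k, "voltage": v})
    units = pd.DataFrame(unit_rows)
    waveforms = pd.DataFrame(wf_rows)

    # --- spikes ----------------------------------------------------------
    gain_rows = []
    spike_unit, spike_time = [], []
    for tr in trials.itertuples():
        loc = tr.target_location
        z = rng.normal()
        gain_rows.append({"trial_id": tr.trial_id, "gain": z})
        private = rng.normal(0.0, 1.0, size=n_units)
        gains = np.maximum(
            0.05, 1.0 + cfg.rho * z + cfg.private_gain_sd * private)
        curve = curves[tr.period][:, loc - 1]
        windows = (
            ("precue", tr.cue_on - _PRE_CUE_MS, tr.cue_on),
            ("cue", tr.cue_on, tr.delay_on),
            ("delay", tr.delay_on, tr.response_on),
            ("response", tr.response_on,
             min(tr.response_on + 2000.0, tr.trial_end)),
        )
        for uid in range(n_units):
            for epoch, on, off in windows:
                rate = _epoch_rate(curve[uid], cfg.baseline_rate_hz, epoch)
                lam = rate * gains[uid] * (off - on) / 1000.0
                count = rng.poisson(lam) if lam > 0 else 0
                if count:
                    ts = np.sort(rng.uniform(on, off, size=count))
                    spike_unit.extend([uid] * count)
                    spike_time.extend(ts.tolist())
    spikes = pd.DataFrame({
        "unit_id": np.array(spike_unit, dtype=int),
        "time_ms": np.array(spike_time, dtype=float),
    }).sort_values(["unit_id", "time_ms"], kind="stable",
                   ignore_index=True)

    # --- trajectories ----------------------------------------------------
    traj_rows = []
    for tr in trials.itertuples():
        behav_period = "pre" if cfg.perception_mode else tr.period
        disp = cfg.dispersion[behav_period]
        goal = (tr.target_x, tr.target_y)
        if tr.outcome == "incorrect":
            wrong = int(rng.integers(1, 10))
            while wrong == tr.target_location:
                wrong = int(rng.integers(1, 10))
            goal = target_xy(wrong)
        dur = tr.trial_end - tr.response_on
        n_pts = max(int(dur // 100.0) + 1, 3)
        u = np.linspace(0.0, 1.0, n_pts)
        px = START_XY[0] + u * (goal[0] - START_XY[0])
        py = START_XY[1] + u * (goal[1] - START_XY[1])
        direction = np.array([goal[0] - START_XY[0], goal[1] - START_XY[1]])
        norm = np.hypot(*direction) or 1.0
        perp = np.array([-direction[1], direction[0]]) / norm
        lateral = _bridge_noise(n_pts, disp, rng)
        for k in range(n_pts):
            traj_rows.append({
                "trial_id": tr.trial_id,
                "time_ms": tr.response_on + u[k] * dur,
                "x": px[k] + lateral[k] * perp[0],
                "y": py[k] + lateral[k] * perp[1],
            })
    trajectories = pd.DataFrame(traj_rows)

    # --- gaze ------------------------------------------------------------
    fix_rows, sac_rows = [], []
    lo_d, hi_d = cfg.fixation_duration_ms
    for tr in trials.itertuples():
        bounds = screen_cell_bounds(tr.target_location)
        for epoch, on, off in (("cue", tr.cue_on, tr.delay_on),
                               ("delay", tr.delay_on, tr.response_on)):
            n_fix = rng.poisson(cfg.fixation_rate_hz * (off - on) / 1000.0)
            starts = np.sort(rng.uniform(on, off, size=n_fix))
            prev = None
            for s in starts:
                if rng.random() < cfg.on_target_bias:
                    x = rng.uniform(bounds[0], bounds[1])
                    y = rng.uniform(bounds[2], bounds[3])
                else:
                    x = rng.uniform(0, SCREEN_W)
                    y = rng.uniform(0, SCREEN_H)
                dur = min(rng.uniform(lo_d, hi_d), off - s)
                fix_rows.append({
                    "trial_id": tr.trial_id, "x_px": x, "y_px": y,
                    "start_ms": s, "end_ms": s + dur, "epoch": epoch,
                })
                if prev is not None:
                    sac_rows.append({
                        "trial_id": tr.trial_id,
                        "start_x_px": prev[0], "start_y_px": prev[1],
                        "end_x_px": x, "end_y_px": y,
                        "start_ms": max(prev[2], s - 30.0), "end_ms": s,
                    })
                prev = (x, y, s + dur)
    fix_cols = ["trial_id", "x_px", "y_px", "start_ms", "end_ms", "epoch"]
    sac_cols = ["trial_id", "start_x_px", "start_y_px", "end_x_px",
                "end_y_px", "start_ms", "end_ms"]
    fixations = pd.DataFrame(fix_rows, columns=fix_cols)
    saccades = pd.DataFrame(sac_rows, columns=sac_cols)

    rec = SessionRecording(
        session_id=f"synthetic-{seed}",
        condition=cfg.condition,
        injection_time=injection_time,
        trials=trials,
        units=units,
        waveforms=waveforms,
        spikes=spikes,
        fixations=fixations,
        saccades=saccades,
        trajectories=trajectories,
        meta={"generator_seed": seed, "synthetic": True},
    )
    validate_session(rec)

    tuning_rows = []
    for period in PERIODS:
        for uid in range(n_units):
            for loc in range(1, 10):
                tuning_rows.append({
                    "unit_id": uid, "period": period, "location": loc,
                    "rate_hz": curves[period][uid, loc - 1],
                })
    tuning = pd.DataFrame(tuning_rows)
    sep_rows = []
    left = [loc for loc in range(1, 10) if target_column(loc) == "left"]
    right = [loc for loc in range(1, 10) if target_column(loc) == "right"]
    for period in PERIODS:
        c = curves[period]
        dfv = (c[:, [l - 1 for l in left]].mean(axis=1)
               - c[:, [r - 1 for r in right]].mean(axis=1))
        sep_rows.append({"period": period,
                         "separation": float(np.linalg.norm(dfv))})
    gt = GroundTruth(
        units=pd.DataFrame({
            "unit_id": np.arange(n_units),
            "cell_class": classes,
            "width_us": widths,
            "pref_location": pref_locs,
            "is_single": is_single,
        }),
        tuning=tuning,
        trial_gain=pd.DataFrame(gain_rows),
        separation=pd.DataFrame(sep_rows),
    )
    return rec, gt


def generate_null_units(
    n: int,
    rate: float,
    seed: int = 0,
    trials_per_location: int = 20,
    duration_ms: float = DELAY_MS,
) -> pd.DataFrame:
    """Units with location-independent Poisson rates, for type-I calibration.

    Returns a long table (unit_id, location, rate_hz) of epoch-averaged
    rates; all 9 location means are equal in expectation. Units whose counts
    are all zero are flagged via ``degenerate`` for exclusion from ANOVA.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = rng_for(seed, "null_units")
    rows = []
    dur_s = duration_ms / 1000.0
    for uid in range(int(n)):
        counts = rng.poisson(rate * dur_s, size=(9, trials_per_location))
        degenerate = counts.sum() == 0
        for loc in range(1, 10):
            for c in counts[loc - 1]:
                rows.append({
                    "unit_id": uid, "location": loc,
                    "rate_hz": c / dur_s, "degenerate": degenerate,
                })
    cols = ["unit_id", "location", "rate_hz", "degenerate"]
    return pd.DataFrame(rows, columns=cols)
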