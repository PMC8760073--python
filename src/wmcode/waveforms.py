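"""Cell-type classification from spike-waveform peak-to-trough width.

Mean waveforms are upsampled x100 with a cubic spline; width is the time
between the voltage minimum and maximum. After removing outlier widths
(> 675 µs), the width histogram is fitted with a 1-Gaussian and a
2-Gaussian model by maximum likelihood (EM with restarts); the Akaike
information criterion selects the model. When the 2-Gaussian model wins,
the boundary between narrow-spiking (NS) and broad-spiking (BS) units is
the crossing point of the two weighted component densities between the two
means — the valley of the bimodal histogram. Units with width below the
boundary are NS; at or above, BS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .session import SessionRecording

#: Widths above this are dropped as outliers before mixture fitting (µs).
OUTLIER_CUT_US = 675.0

_MIN_WIDTHS = 50


def waveform_width(
    voltage: np.ndarray,
    sampling_interval_us: float,
    upsample: int = 100,
) -> float:
    """Peak-to-trough width (µs) from a cubic-spline upsampled waveform.

    Returns ``nan`` for non-biphasic (monotone or single-signed) waveforms,
    which are excluded from width analysis. The width is the absolute time
    difference between the global minimum and maximum of the upsampled
    trace, so it is invariant to polarity and to affine voltage scaling.
    """
    v = np.asarray(voltage, dtype=float)
    if v.size < 4 or np.ptp(v) == 0:
        return float("nan")
    v = v - v.mean()
    if v.min() >= 0 or v.max() <= 0:
        return float("nan")  # not biphasic
    t = np.arange(v.size) * float(sampling_interval_us)
    fine_t = np.linspace(t[0], t[-1], (v.size - 1) * upsample + 1)
    fine_v = CubicSpline(t, v)(fine_t)
    imin, imax = int(np.argmin(fine_v)), int(np.argmax(fine_v))
    # trough and peak must be genuine (interior) extrema; a monotone
    # waveform puts both at the trace endpoints
    if {imin, imax} & {0, fine_v.size - 1}:
        return float("nan")
    return float(abs(fine_t[imax] - fine_t[imin]))


def widths_table(rec: SessionRecording) -> pd.DataFrame:
    """Per-unit widths from a session's mean waveforms.

    Columns: unit_id, width_us, excluded, reason (non-biphasic waveforms
    and outlier widths are marked excluded).
    """
    rows = []
    for tr in rec.units.itertuples():
        wf = rec.waveforms.loc[rec.waveforms["unit_id"] == tr.unit_id]
        wf = wf.sort_values("sample_idx")
        w = waveform_width(wf["voltage"].to_numpy(),
                           tr.sampling_interval_us)
        if np.isnan(w):
            rows.append({"unit_id": tr.unit_id, "width_us": np.nan,
                         "excluded": True, "reason": "non-biphasic"})
        elif w > OUTLIER_CUT_US:
            rows.append({"unit_id": tr.unit_id, "width_us": w,
                         "excluded": True, "reason": "outlier"})
        else:
            rows.append({"unit_id": tr.unit_id, "width_us": w,
                         "excluded": False, "reason": ""})
    return pd.DataFrame(rows, columns=["unit_id", "width_us", "excluded",
                                       "reason"])


@dataclass
class MixtureFit:
    """1- vs 2-Gaussian width-mixture fit and the resulting boundary."""

    means: np.ndarray      # sorted ascending (NS mean first when bimodal)
    sds: np.ndarray
    weights: np.ndarray
    aic_1g: float
    aic_2g: float
    bimodal: bool          # 2-Gaussian model selected by AIC
    threshold: float | None  # µs; None when unimodal or degenerate
    degenerate: bool = False


def gaussian_crossing(m1: float, s1: float, w1: float,
                      m2: float, s2: float, w2: float) -> float | None:
    """Crossing of two weighted normal densities between their means."""
    if m1 > m2:
        m1, s1, w1, m2, s2, w2 = m2, s2, w2, m1, s1, w1
    if m2 - m1 < 1e-9:
        return None

    def diff(x: float) -> float:
        return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

    lo, hi = m1, m2
    if diff(lo) * diff(hi) > 0:
        return None
    return float(brentq(diff, lo, hi))


def fit_width_mixture(
    widths: np.ndarray,
    seed: int = 0,
    outlier_cut_us: float = OUTLIER_CUT_US,
    n_restarts: int = 10,
    min_widths: int = _MIN_WIDTHS,
) -> MixtureFit:
    """Model-select a 1- vs 2-Gaussian width distribution and set the boundary.

    Both models are fitted by maximum likelihood (the 2-Gaussian by EM with
    ``n_restarts`` seeded restarts, best likelihood kept); the lower AIC
    wins. The NS/BS threshold is the between-means crossing of the weighted
    component densities; identical components yield a degenerate fit with
    no threshold.
    """
    w = np.asarray(widths, dtype=float)
    w = w[np.isfinite(w)]
    w = w[w <= outlier_cut_us]
    if w.size < min_widths:
        raise ValueError(
            f"need at least {min_widths} widths after outlier removal, "
            f"got {w.size}")
    X = w[:, None]
    gm1 = GaussianMixture(1, random_state=seed).fit(X)
    gm2 = GaussianMixture(2, n_init=n_restarts, random_state=seed,
                          init_params="k-means++").fit(X)
    if not (gm1.converged_ and gm2.converged_):
        raise RuntimeError("width-mixture EM failed to converge")
    aic1, aic2 = float(gm1.aic(X)), float(gm2.aic(X))
    order = np.argsort(gm2.means_.ravel())
    means = gm2.means_.ravel()[order]
    sds = np.sqrt(gm2.covariances_.ravel()[order])
    weights = gm2.weights_[order]
    bimodal = aic2 < aic1
    threshold = None
    degenerate = False
    if bimodal:
        threshold = gaussian_crossing(means[0], sds[0], weights[0],
                                      means[1], sds[1], weights[1])
        if threshold is None:
            degenerate = True
    return MixtureFit(means=means, sds=sds, weights=weights,
                      aic_1g=aic1, aic_2g=aic2, bimodal=bimodal,
                      threshold=threshold, degenerate=degenerate)


class WaveformClassifier(BaseEstimator):
    """NS/BS width classifier, sklearn-estimator shaped.

    ``fit`` takes the width sample (µs), fits the mixture and stores
    ``threshold_``; ``predict`` labels widths ``"NS"`` below the threshold
    and ``"BS"`` at or above it (boundary ties go to BS). When the
    1-Gaussian model wins, or the fit is degenerate, every unit is labelled
    ``"BS"`` and ``bimodal_`` is False.
    """

    def __init__(self, seed: int = 0,
                 outlier_cut_us: float = OUTLIER_CUT_US,
                 min_widths: int = _MIN_WIDTHS):
        self.seed = seed
        self.outlier_cut_us = outlier_cut_us
        self.min_widths = min_widths

    def fit(self, widths, y=None):
        self.fit_ = fit_width_mixture(widths, seed=self.seed,
                                      outlier_cut_us=self.outlier_cut_us,
                                      min_widths=self.min_widths)
        self.bimodal_ = self.fit_.bimodal and not self.fit_.degenerate
        self.threshold_ = self.fit_.threshold if self.bimodal_ else None
        return self

    def predict(self, widths):
        w = np.asarray(widths, dtype=float)
        labels = np.full(w.shape, "BS", dtype=object)
        labels[~np.isfinite(w) | (w > self.outlier_cut_us)] = "excluded"
        if self.bimodal_:
            labels[(w < self.threshold_) & np.isfinite(w)
                   & (w <= self.outlier_cut_us)] = "NS"
        return labels


def classify_session_units(
    rec: SessionRecording,
    seed: int = 0,
    clf: WaveformClassifier | None = None,
    min_widths: int = _MIN_WIDTHS,
) -> tuple[pd.DataFrame, MixtureFit]:
    """Width, class label, and mixture diagnostics for a session's units.

    Pass a prefit ``clf`` to classify with a boundary fitted on widths
    pooled across sessions (the recommended use at small unit counts).
    """
    table = widths_table(rec)
    if clf is None:
        clf = WaveformClassifier(seed=seed, min_widths=min_widths).fit(
            table.loc[~table["excluded"], "width_us"].to_numpy())
    table = table.copy()
    table["cell_class"] = clf.predict(table["width_us"].to_numpy())
    table.loc[table["excluded"], "cell_class"] = "excluded"
    return table, clf.fit_


# ---------------------------------------------------------------------------
# Downstream cell-type contrast: preferred / least-preferred rate changes


def preferred_rate_table(
    rec: SessionRecording,
    class_table: pd.DataFrame,
    alpha: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Delay-epoch rates at each tuned unit's preferred and least-preferred
    location, before and after injection.

    Units are delay-tuned at the (lenient) ``alpha`` on pre-injection
    trials; preferred and least-preferred locations are fixed from the
    pre-injection tuning. Returns one row per tuned NS/BS unit with the
    mean rate at each location in the pre and early post-injection periods.
    """
    from .tuning import anova_selectivity, epoch_rates

    rates = epoch_rates(rec, "delay")
    pre = rates.loc[rates["period"] == "pre"]
    sel = anova_selectivity(pre, alpha=alpha, seed=seed)
    tuned = sel.loc[sel["selective"]]
    cls = class_table.set_index("unit_id")["cell_class"]

    rows = []
    for unit in tuned.itertuples():
        label = cls.get(unit.unit_id)
        if label not in ("NS", "BS"):
            continue
        per_loc = (rates.loc[rates["unit_id"] == unit.unit_id]
                   .groupby(["period", "location"])["rate_hz"].mean())
        row = {"unit_id": unit.unit_id, "cell_class": label}
        for tag, loc in (("pref", unit.preferred_location),
                         ("least", unit.least_preferred_location)):
            for period in ("pre", "early_post"):
                row[f"{tag}_{period}"] = float(
                    per_loc.get((period, loc), np.nan))
        rows.append(row)
    return pd.DataFrame(rows, columns=["unit_id", "cell_class",
                                       "pref_pre", "pref_early_post",
                                       "least_pre", "least_early_post"])


def cell_type_contrast(table: pd.DataFrame) -> dict:
    """1-tailed rank-sum tests of the cell-type-specific rate changes.

    Tests the two directional effects: NS units decrease their rate at
    preferred locations after injection, and BS units increase their rate
    at least-preferred locations. Returns the one-sided p-values
    ``ns_pref_decrease_p`` and ``bs_least_increase_p`` (nan when a class is
    absent).
    """
    from scipy.stats import ranksums

    out = {"ns_pref_decrease_p": float("nan"),
           "bs_least_increase_p": float("nan"),
           "n_ns": 0, "n_bs": 0}
    ns = table.loc[table["cell_class"] == "NS"].dropna(
        subset=["pref_pre", "pref_early_post"])
    bs = table.loc[table["cell_class"] == "BS"].dropna(
        subset=["least_pre", "least_early_post"])
    out["n_ns"], out["n_bs"] = len(ns), len(bs)
    if len(ns) >= 2:
        out["ns_pref_decrease_p"] = float(ranksums(
            ns["pref_pre"], ns["pref_early_post"],
            alternative="greater").pvalue)
    if len(bs) >= 2:
        out["bs_least_increase_p"] = float(ranksums(
            bs["least_pre"], bs["least_early_post"],
            alternative="less").pvalue)
    return out
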