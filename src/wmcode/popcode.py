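"""Population signal, projected precision, and decodable information.

For a binary discrimination (left vs right remembered locations) by an
ensemble of N units, the decodability of the two conditions from trial
firing-rate vectors decomposes into

* the population signal ``PS = |Δf|`` — the Euclidean norm of the vector of
  per-unit mean-rate differences between the two conditions (population
  tuning), and
* the projected precision ``PP = sqrt(Σ_i cos²θ̂_i / σ̂_i²)`` — where σ̂_i²
  and θ̂_i are the i-th eigenvalue of the within-condition covariance Σ and
  the angle between the i-th eigenvector and the signal direction
  ``u_Δf = Δf/|Δf|`` (trial-to-trial reliability along the signal).

Under equal-covariance Gaussian conditions the optimal linear classifier
achieves the theoretical decoding accuracy ``DPt = Φ(PS·PP/2)`` with Φ the
standard normal CDF. Its empirical counterpart ``DPe`` is the
cross-validated accuracy of a linear discriminant that uses the same
shrinkage-regularised covariance estimate, so the two are directly
comparable.

The covariance estimator is the pooled within-condition sample covariance
with analytic shrinkage of the off-diagonal entries toward zero
(Schäfer–Strimmer rule), which keeps per-unit variances intact and the
matrix well conditioned at small trial counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from ._utils import child_seed, rng_for

#: Units with mean rate at or below this (Hz) are excluded from ensembles.
RATE_FLOOR_HZ = 0.5

ENSEMBLE_SIZES = (2, 3, 5)
TOP_PERCENTILE = 75.0


def shrinkage_covariance(residuals: np.ndarray) -> tuple[np.ndarray, float]:
    """Sample covariance with analytic off-diagonal shrinkage toward zero.

    ``residuals`` are mean-centred observations (rows) of the units
    (columns). The shrinkage intensity is the Schäfer–Strimmer estimate
    ``λ* = Σ_{i≠j} Var̂(s_ij) / Σ_{i≠j} s_ij²`` clipped to [0, 1]; the
    returned matrix is ``(1-λ)S + λ diag(S)``.
    """
    X = np.asarray(residuals, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations for a covariance")
    S = X.T @ X / (n - 1)
    if p == 1:
        return S, 0.0
    # Var of each off-diagonal covariance entry
    W = X[:, :, None] * X[:, None, :]          # n x p x p products
    w_bar = W.mean(axis=0)
    var_s = n / (n - 1) ** 3 * ((W - w_bar) ** 2).sum(axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = (S[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom,
                                               0.0, 1.0))
    sigma = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    return sigma, lam


def pooled_within_class_cov(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, float]:
    """Shrinkage covariance of class-mean-centred trial rate vectors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    resid = np.empty_like(X)
    for c in np.unique(y):
        mask = y == c
        resid[mask] = X[mask] - X[mask].mean(axis=0)
    return shrinkage_covariance(resid)


def population_signal(
    mean_a: np.ndarray, mean_b: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Δf, its norm PS, and the unit signal direction u_Δf.

    ``u_Δf`` is ``None`` when PS = 0 (direction undefined).
    """
    delta_f = np.asarray(mean_a, dtype=float) - np.asarray(mean_b,
                                                           dtype=float)
    ps = float(np.linalg.norm(delta_f))
    u = delta_f / ps if ps > 0 else None
    return delta_f, ps, u


def projected_precision(sigma: np.ndarray, u_delta_f: np.ndarray) -> float:
    """PP = sqrt(Σ_i cos²θ̂_i / σ̂_i²) from the eigendecomposition of Σ."""
    sigma = np.asarray(sigma, dtype=float)
    if not np.all(np.isfinite(sigma)):
        raise ValueError("covariance contains non-finite entries")
    evals, evecs = np.linalg.eigh(sigma)
    if np.any(evals <= 0):
        raise ValueError("covariance must be positive definite "
                         "(regularise before calling)")
    cosines = evecs.T @ np.asarray(u_delta_f, dtype=float)
    return float(np.sqrt(np.sum(cosines**2 / evals)))


def theoretical_accuracy(ps: float, pp: float) -> float:
    """DPt = Φ(PS · PP / 2); 0.5 at PS = 0, approaching 1 as PS·PP grows."""
    if ps < 0:
        raise ValueError("PS is a norm and cannot be negative")
    return float(norm.cdf(0.5 * ps * pp))


class ShrinkageLDA(ClassifierMixin, BaseEstimator):
    """Binary linear discriminant with the shared shrinkage covariance.

    fit computes class means and the pooled within-class
    shrinkage-regularised covariance; predict projects onto
    ``w = Σ⁻¹ Δf`` and thresholds at the projected midpoint (equal priors,
    as classes are balanced upstream).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ShrinkageLDA is a binary classifier")
        m1 = X[y == self.classes_[1]].mean(axis=0)
        m0 = X[y == self.classes_[0]].mean(axis=0)
        sigma, self.shrinkage_ = pooled_within_class_cov(X, y)
        self.sigma_ = sigma
        self.coef_ = np.linalg.solve(sigma, m1 - m0)
        self.intercept_ = -0.5 * float(self.coef_ @ (m1 + m0))
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        return np.where(self.decision_function(X) > 0,
                        self.classes_[1], self.classes_[0])


def empirical_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    n_balance: int = 1,
    seed: int = 0,
) -> float:
    """DPe: cross-validated accuracy of the shrinkage LDA.

    Classes are balanced by subsampling without replacement before each of
    ``n_balance`` stratified ``k_folds``-fold cross-validations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("empirical decoding uses binary labels")
    if counts.min() < k_folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has fewer than "
            f"{k_folds} trials")
    m = counts.min()
    accs = []
    for rep in range(n_balance):
        rng = rng_for(seed, "lda_balance", rep)
        idx = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=m, replace=False)
            for c in classes
        ])
        Xb, yb = X[idx], y[idx]
        skf = StratifiedKFold(k_folds, shuffle=True,
                              random_state=child_seed(seed, "lda_fold", rep))
        fold_acc = []
        for tr_idx, te_idx in skf.split(Xb, yb):
            clf = ShrinkageLDA().fit(Xb[tr_idx], yb[tr_idx])
            fold_acc.append(np.mean(clf.predict(Xb[te_idx]) == yb[te_idx]))
        accs.append(float(np.mean(fold_acc)))
    return float(np.mean(accs))


@dataclass
class PopulationCodeStats:
    """The decomposition for one ensemble: Δf, PS, PP, DPt, DPe."""

    unit_ids: tuple
    delta_f: np.ndarray
    ps: float
    pp: float | None      # None when PS = 0 (direction undefined)
    dpt: float
    dpe: float
    shrinkage: float


def ensemble_stats(
    X: np.ndarray,
    y: np.ndarray,
    unit_ids: tuple | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> PopulationCodeStats:
    """PS/PP/DPt/DPe for one ensemble's trial-by-unit rate matrix.

    Class means, the shrinkage covariance (shared between PP and the LDA),
    and the cross-validated empirical accuracy are computed on the same
    balanced trial set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("population-code stats require binary classes")
    rng = rng_for(seed, "stats_balance")
    m = min(int((y == c).sum()) for c in classes)
    if m < 2:
        raise ValueError("need at least 2 trials per class")
    idx = np.concatenate([
        rng.choice(np.flatnonzero(y == c), size=m, replace=False)
        for c in classes
    ])
    Xb, yb = X[idx], y[idx]

    mean_a = Xb[yb == classes[0]].mean(axis=0)
    mean_b = Xb[yb == classes[1]].mean(axis=0)
    delta_f, ps, u = population_signal(mean_a, mean_b)
    sigma, lam = pooled_within_class_cov(Xb, yb)
    if u is None:
        pp, dpt = None, 0.5
    else:
        pp = projected_precision(sigma, u)
        dpt = theoretical_accuracy(ps, pp)
    dpe = empirical_accuracy(Xb, yb, k_folds=k_folds,
                             seed=child_seed(seed, "dpe"))
    return PopulationCodeStats(
        unit_ids=tuple(unit_ids) if unit_ids is not None else tuple(),
        delta_f=delta_f, ps=ps, pp=pp, dpt=dpt, dpe=dpe, shrinkage=lam)


def draw_ensembles(
    eligible: list,
    size: int,
    n: int,
    seed: int = 0,
) -> list[tuple]:
    """Random unit ensembles without replacement within an ensemble.

    When the combinatorial space has at most ``n`` members all unique
    combinations are returned; otherwise ``n`` distinct combinations are
    sampled.
    """
    eligible = sorted(eligible)
    if size > len(eligible):
        raise ValueError(f"ensemble size {size} exceeds "
                         f"{len(eligible)} eligible units")
    total = comb(len(eligible), size)
    if total <= n:
        return [tuple(c) for c in combinations(eligible, size)]
    rng = rng_for(seed, "ensembles", size)
    seen: set[tuple] = set()
    while len(seen) < n:
        pick = tuple(sorted(rng.choice(len(eligible), size=size,
                                       replace=False).tolist()))
        seen.add(tuple(eligible[i] for i in pick))
    return sorted(seen)


def random_ensemble_sweep(
    X: np.ndarray,
    y: np.ndarray,
    unit_ids: list,
    sizes: tuple = ENSEMBLE_SIZES,
    n: int = 1000,
    seed: int = 0,
    k_folds: int = 5,
    rate_floor_hz: float = RATE_FLOOR_HZ,
    top_percentile: float = TOP_PERCENTILE,
) -> pd.DataFrame:
    """PS/PP/DPt/DPe over random ensembles, with the top-quartile flag.

    Units whose overall mean rate is at or below ``rate_floor_hz`` are
    excluded. For each requested size, ``n`` random ensembles are evaluated
    (all unique combinations when fewer exist); ensembles whose DPe reaches
    the ``top_percentile`` within their size form the top subset. Sizes
    larger than the eligible pool are skipped with a warning column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    unit_ids = list(unit_ids)
    mean_rates = X.mean(axis=0)
    eligible_cols = [j for j in range(X.shape[1])
                     if mean_rates[j] > rate_floor_hz]
    col_of = {unit_ids[j]: j for j in range(len(unit_ids))}
    eligible_ids = [unit_ids[j] for j in eligible_cols]

    rows = []
    eid = 0
    for size in sizes:
        if size > len(eligible_ids):
            continue  # size skipped: not enough eligible units
        for ens in draw_ensembles(eligible_ids, size, n,
                                  seed=child_seed(seed, "draw", size)):
            cols = [col_of[u] for u in ens]
            st = ensemble_stats(X[:, cols], y, unit_ids=ens,
                                k_folds=k_folds,
                                seed=child_seed(seed, "ens", eid))
            rows.append({
                "ensemble_id": eid, "size": size,
                "unit_ids": ",".join(map(str, ens)),
                "ps": st.ps, "pp": st.pp if st.pp is not None else np.nan,
                "dpt": st.dpt, "dpe": st.dpe, "shrinkage": st.shrinkage,
            })
            eid += 1
    out = pd.DataFrame(rows, columns=[
        "ensemble_id", "size", "unit_ids", "ps", "pp", "dpt", "dpe",
        "shrinkage"])
    if len(out):
        out["top75"] = False
        for size, grp in out.groupby("size"):
            cut = np.percentile(grp["dpe"], top_percentile)
            out.loc[grp.index[grp["dpe"] >= cut], "top75"] = True
    return out
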