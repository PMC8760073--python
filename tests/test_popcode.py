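import numpy as np
import pytest
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from wmcode.popcode import (
    ShrinkageLDA,
    draw_ensembles,
    empirical_accuracy,
    ensemble_stats,
    pooled_within_class_cov,
    population_signal,
    projected_precision,
    random_ensemble_sweep,
    shrinkage_covariance,
    theoretical_accuracy,
)


def _gaussian_classes(rng, n_per_class, mean_a, mean_b, cov):
    a = rng.multivariate_normal(mean_a, cov, size=n_per_class)
    b = rng.multivariate_normal(mean_b, cov, size=n_per_class)
    X = np.vstack([a, b])
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return X, y


def test_population_signal_examples():
    df, ps, u = population_signal([5.0, 5.0], [5.0, 5.0])
    assert ps == 0.0 and u is None
    df, ps, u = population_signal([3.0, 0.0], [0.0, 4.0])
    np.testing.assert_allclose(df, [3.0, -4.0])
    assert ps == pytest.approx(5.0)  # 3-4-5 triangle
    np.testing.assert_allclose(np.linalg.norm(u), 1.0)


@pytest.mark.parametrize("sigma,u,expected", [
    (np.eye(2) * 4.0, [1.0, 0.0], 0.5),        # isotropic: PP = 1/sigma
    (np.diag([1.0, 4.0]), [1.0, 0.0], 1.0),    # aligned with tight axis
    (np.diag([1.0, 4.0]), [0.0, 1.0], 0.5),    # aligned with loose axis
])
def test_projected_precision_diagonal_cases(sigma, u, expected):
    assert projected_precision(sigma, np.array(u)) == pytest.approx(expected)


def test_projected_precision_cosine_partition():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(4, 4))
    sigma = A @ A.T + 4 * np.eye(4)
    u = rng.normal(size=4)
    u /= np.linalg.norm(u)
    evals, evecs = np.linalg.eigh(sigma)
    cos2 = (evecs.T @ u) ** 2
    assert cos2.sum() == pytest.approx(1.0, abs=1e-10)
    pp = projected_precision(sigma, u)
    assert np.sqrt(1.0 / evals.max()) <= pp <= np.sqrt(1.0 / evals.min())


def test_theoretical_accuracy_spot_values():
    assert theoretical_accuracy(0.0, 1.0) == 0.5
    # PS = 2, isotropic unit covariance: accuracy = Phi(1)
    assert theoretical_accuracy(2.0, 1.0) == pytest.approx(
        norm.cdf(1.0), abs=1e-9)
    assert theoretical_accuracy(2.0, 1.0) == pytest.approx(0.8413, abs=5e-5)


def test_dpt_matches_monte_carlo_bayes_oracle():
    # optimal linear classifier accuracy simulated from the true model
    rng = np.random.default_rng(7)
    n = 100_000
    for dist in (1.0, 2.0, 4.0):
        mean_a, mean_b = np.array([dist / 2, 0]), np.array([-dist / 2, 0])
        w = mean_a - mean_b  # Bayes rule for equal isotropic covariance
        x_a = rng.multivariate_normal(mean_a, np.eye(2), size=n)
        x_b = rng.multivariate_normal(mean_b, np.eye(2), size=n)
        acc = 0.5 * ((x_a @ w > 0).mean() + (x_b @ w <= 0).mean())
        dpt = theoretical_accuracy(dist, 1.0)
        se = np.sqrt(acc * (1 - acc) / (2 * n))
        assert abs(dpt - acc) < 3 * max(se, 1e-4)


def test_dpt_invariances():
    rng = np.random.default_rng(3)
    X, y = _gaussian_classes(rng, 300, [1.0, 2.0, 0.5], [0.0, 0.0, 0.0],
                             np.diag([1.0, 2.0, 0.5]))
    base = ensemble_stats(X, y, seed=0)
    # global rate rescaling: PS scales by c, PP by 1/c, DPt unchanged
    scaled = ensemble_stats(4.0 * X, y, seed=0)
    assert scaled.ps == pytest.approx(4.0 * base.ps, rel=1e-9)
    assert scaled.pp == pytest.approx(base.pp / 4.0, rel=1e-9)
    assert scaled.dpt == pytest.approx(base.dpt, rel=1e-9)
    # simultaneous unit permutation leaves DPt unchanged
    perm = [2, 0, 1]
    permuted = ensemble_stats(X[:, perm], y, seed=0)
    assert permuted.dpt == pytest.approx(base.dpt, rel=1e-9)
    assert permuted.ps == pytest.approx(base.ps, rel=1e-9)


def test_shrinkage_covariance_preserves_diagonal():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 3)) @ np.diag([1.0, 2.0, 0.5])
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (len(X) - 1)
    sigma, lam = shrinkage_covariance(Xc)
    assert 0.0 <= lam <= 1.0
    np.testing.assert_allclose(np.diag(sigma), np.diag(S), rtol=1e-12)
    assert np.all(np.abs(sigma[~np.eye(3, dtype=bool)])
                  <= np.abs(S[~np.eye(3, dtype=bool)]) + 1e-12)


def test_shrinkage_lda_agrees_with_reference_lda():
    # well-conditioned data: shrinkage ~ small, decisions match sklearn LDA
    rng = np.random.default_rng(11)
    X, y = _gaussian_classes(rng, 400, [1.0, 0.5], [0.0, 0.0], np.eye(2))
    ours = ShrinkageLDA().fit(X, y)
    ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
    Xt, yt = _gaussian_classes(rng, 500, [1.0, 0.5], [0.0, 0.0], np.eye(2))
    agree = np.mean(ours.predict(Xt) == ref.predict(Xt))
    assert agree > 0.99


def test_empirical_accuracy_trivial_cases():
    rng = np.random.default_rng(2)
    X, y = _gaussian_classes(rng, 50, [10.0, 10.0], [0.0, 0.0],
                             0.01 * np.eye(2))
    assert empirical_accuracy(X, y, seed=0) == pytest.approx(1.0)
    y_shuf = np.random.default_rng(0).permutation(y)
    Xn = rng.normal(size=(100, 2))
    acc = empirical_accuracy(Xn, y_shuf, n_balance=5, seed=0)
    assert abs(acc - 0.5) < 0.15


def test_dpe_consistent_with_dpt_at_large_n():
    rng = np.random.default_rng(13)
    cov = np.diag([1.0, 1.5, 0.7])
    mean_a = np.array([0.3, 0.2, 0.1])
    X, y = _gaussian_classes(rng, 2000, mean_a, -mean_a, cov)
    st = ensemble_stats(X, y, seed=0)
    assert st.dpe == pytest.approx(st.dpt, abs=0.02)
    # empirical decoding cannot systematically beat the optimum
    assert st.dpe <= st.dpt + 0.03


def test_draw_ensembles_combinatorics_and_determinism():
    assert len(draw_ensembles([1, 2, 3, 4], size=3, n=1000)) == 4  # C(4,3)
    a = draw_ensembles(list(range(20)), size=3, n=50, seed=5)
    b = draw_ensembles(list(range(20)), size=3, n=50, seed=5)
    assert a == b
    assert len(set(a)) == 50  # no duplicate ensembles
    with pytest.raises(ValueError, match="exceeds"):
        draw_ensembles([1, 2], size=3, n=10)


def test_random_ensemble_sweep_filters_low_rate_units():
    rng = np.random.default_rng(4)
    X = np.abs(rng.normal(3.0, 1.0, size=(80, 5)))
    X[:, 2] = 0.01  # below the 0.5 Hz eligibility floor
    y = np.array(["L", "R"] * 40)
    X[y == "L", 0] += 2.0
    sweep = random_ensemble_sweep(X, y, unit_ids=[10, 11, 12, 13, 14],
                                  sizes=(2,), n=20, seed=0)
    assert len(sweep)
    assert not sweep["unit_ids"].str.contains("12").any()
    assert sweep["top75"].any()
    assert (sweep.loc[sweep["top75"], "dpe"].min()
            >= np.percentile(sweep["dpe"], 75) - 1e-12)
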