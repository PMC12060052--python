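"""Inference engines: paired t, RM-ANOVA, cluster-mass permutation test,
skipped correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from expviol.stats import (cluster_permutation_test, paired_t, rm_anova_2way,
                           skipped_pearson)


# ------------------------------------------------------------------ paired t

def test_paired_t_identical_samples():
    with pytest.warns(UserWarning):
        out = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert out["t"] == 0.0
    assert out["p"] == 1.0
    assert out["df"] == 2


def test_paired_t_constant_differences_flagged():
    with pytest.warns(UserWarning):
        out = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
    assert np.isinf(out["t"]) and out["t"] > 0
    assert out["df"] == 3
    assert out["p"] == 0.0


def test_paired_t_matches_scipy(rng):
    x, y = rng.normal(size=(2, 30))
    out = paired_t(x, y, tail="greater")
    ref = sps.ttest_rel(x, y, alternative="greater")
    assert out["t"] == pytest.approx(ref.statistic)
    assert out["p"] == pytest.approx(ref.pvalue)


def test_paired_t_type_one_error_calibrated():
    rng = np.random.default_rng(2024)
    n_rep, n = 10_000, 52
    d = rng.normal(size=(n_rep, n))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    crit = sps.t.ppf(0.975, n - 1)
    rate = np.mean(np.abs(t) > crit)
    assert rate == pytest.approx(0.05, abs=0.01)
    # spot-check the vectorised oracle against paired_t itself
    out = paired_t(d[0], np.zeros(n))
    assert out["t"] == pytest.approx(t[0])


# ----------------------------------------------------------------- RM-ANOVA

def toy_table(rng, n_sub=3, a=2, b=4, effects=True):
    rows = []
    for s in range(n_sub):
        for ai in range(a):
            for bi in range(b):
                v = rng.normal()
                if effects:
                    v += 0.8 * ai + 0.3 * bi + 0.4 * ai * bi + 0.5 * s
                rows.append({"sub": s, "A": ai, "B": bi, "v": v})
    return pd.DataFrame(rows)


def test_rm_anova_all_equal_cells_give_zero_f():
    df = toy_table(np.random.default_rng(0), effects=False)
    df["v"] = 5.0
    out = rm_anova_2way(df, "v", "sub", ("A", "B"))
    assert all(out[k]["F"] == 0.0 for k in ("A", "B", "A:B"))


def test_rm_anova_matches_hand_partition():
    """F values match a hand-computed sums-of-squares partition on a
    3-observer toy table."""
    rng = np.random.default_rng(42)
    df = toy_table(rng)
    out = rm_anova_2way(df, "v", "sub", ("A", "B"))

    y = df.pivot_table(index="sub", columns=["A", "B"], values="v").to_numpy()
    n, a, b = 3, 2, 4
    y = y.reshape(n, a, b)
    gm = y.mean()
    # independent re-derivation via explicit loops
    ss_a = sum(n * b * (y[:, i, :].mean() - gm) ** 2 for i in range(a))
    ss_as = sum(b * (y[s, i, :].mean() - y[:, i, :].mean()
                     - y[s].mean() + gm) ** 2
                for s in range(n) for i in range(a))
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    assert out["A"]["F"] == pytest.approx(f_a, rel=1e-10)
    ss_ab = sum(n * (y[:, i, j].mean() - y[:, i, :].mean()
                     - y[:, :, j].mean() + gm) ** 2
                for i in range(a) for j in range(b))
    ss_abs = sum((y[s, i, j] - y[s, i, :].mean() - y[s, :, j].mean()
                  - y[:, i, j].mean() + y[:, i, :].mean() + y[:, :, j].mean()
                  + y[s].mean() - gm) ** 2
                 for s in range(n) for i in range(a) for j in range(b))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    assert out["A:B"]["F"] == pytest.approx(f_ab, rel=1e-10)


def test_rm_anova_matches_statsmodels():
    from statsmodels.stats.anova import AnovaRM
    rng = np.random.default_rng(7)
    df = toy_table(rng, n_sub=8, b=8)
    out = rm_anova_2way(df, "v", "sub", ("A", "B"))
    ref = AnovaRM(df, "v", "sub", within=["A", "B"]).fit().anova_table
    assert out["A"]["F"] == pytest.approx(ref.loc["A", "F Value"], rel=1e-9)
    assert out["B"]["F"] == pytest.approx(ref.loc["B", "F Value"], rel=1e-9)
    assert out["A:B"]["F"] == pytest.approx(ref.loc["A:B", "F Value"], rel=1e-9)
    assert out["A:B"]["p"] == pytest.approx(ref.loc["A:B", "Pr > F"], rel=1e-9)


def test_rm_anova_listwise_deletion():
    rng = np.random.default_rng(1)
    df = toy_table(rng, n_sub=5)
    df = df[~((df["sub"] == 4) & (df["A"] == 1) & (df["B"] == 0))]
    with pytest.warns(UserWarning, match="listwise"):
        out = rm_anova_2way(df, "v", "sub", ("A", "B"))
    assert out["A"]["df2"] == 3.0  # 4 remaining subjects - 1


def test_rm_anova_null_calibration():
    rng = np.random.default_rng(5)
    rejections = 0
    n_rep = 300
    for _ in range(n_rep):
        df = toy_table(rng, n_sub=8, b=4, effects=False)
        out = rm_anova_2way(df, "v", "sub", ("A", "B"))
        rejections += out["A:B"]["p"] < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.035)


# ------------------------------------------------------------- cluster test

def test_cluster_identical_conditions_no_clusters(rng):
    a = rng.normal(size=(10, 60))
    res = cluster_permutation_test(a, a.copy(), n_perm=200, seed=0)
    assert res.clusters == []


def test_cluster_determinism(rng):
    d = rng.normal(size=(12, 80))
    r1 = cluster_permutation_test(d, n_perm=300, seed=42)
    r2 = cluster_permutation_test(d, n_perm=300, seed=42)
    assert r1.threshold_mass == r2.threshold_mass
    assert np.array_equal(r1.null_masses, r2.null_masses)
    assert r1.clusters == r2.clusters


def test_cluster_two_tailed_sign_symmetry(rng):
    """Flipping every difference series flips cluster signs but leaves the
    two-tailed permutation threshold unchanged."""
    d = rng.normal(0.3, 1.0, size=(15, 100))
    r1 = cluster_permutation_test(d, n_perm=400, seed=9, tail="two")
    r2 = cluster_permutation_test(-d, n_perm=400, seed=9, tail="two")
    assert r1.threshold_mass == pytest.approx(r2.threshold_mass)
    masses1 = sorted(c["mass"] for c in r1.clusters)
    masses2 = sorted(-c["mass"] for c in r2.clusters)
    assert np.allclose(masses1, masses2)


def test_cluster_monte_carlo_close_to_exhaustive(rng):
    """n=8 observers: the Monte-Carlo null threshold is within 5% of the
    exhaustive 2^8 sign-flip enumeration."""
    d = rng.normal(0.0, 1.0, size=(8, 50)) + 0.6
    exact = cluster_permutation_test(d, method="exhaustive", tail="two")
    assert exact.n_perm == 256
    mc = cluster_permutation_test(d, n_perm=1000, seed=3, tail="two")
    assert mc.threshold_mass == pytest.approx(exact.threshold_mass, rel=0.05)


def test_cluster_detects_injected_boxcar(rng):
    """A d~1 boxcar effect at samples 600-1000 (of 0..1499 ms at 1 ms) is
    detected and localised."""
    n_obs, n_t = 30, 300
    times = np.arange(n_t) * 5.0
    effect = (times >= 600) & (times <= 1000)
    d = rng.normal(0, 1, size=(n_obs, n_t)) + effect * 1.0
    res = cluster_permutation_test(d, times=times, n_perm=500, seed=1,
                                   tail="greater")
    sig = res.significant_clusters
    assert len(sig) >= 1
    main = max(sig, key=lambda c: c["mass"])
    overlap = (min(main["end_ms"], 1000) - max(main["start_ms"], 600)) / 400.0
    assert overlap >= 0.8


def test_cluster_input_validation(rng):
    with pytest.raises(ValueError):
        cluster_permutation_test(rng.normal(size=(1, 10)))
    with pytest.raises(ValueError):
        cluster_permutation_test(rng.normal(size=(5, 10)), tail="less")
    with pytest.warns(UserWarning):
        cluster_permutation_test(rng.normal(size=(5, 10)), n_perm=50, seed=0)


def test_cluster_familywise_error_quick(rng):
    """Null familywise error near 0.05 (small version; the full calibration
    runs in the acceptance suite)."""
    hits = 0
    n_rep = 150
    for i in range(n_rep):
        d = rng.normal(size=(20, 100))
        res = cluster_permutation_test(d, n_perm=500, seed=i, tail="two")
        hits += bool(res.significant_clusters)
    assert hits / n_rep < 0.11


# ------------------------------------------------------- skipped correlation

def test_skipped_perfect_line():
    x = np.linspace(0, 1, 20)
    est = skipped_pearson(x, 2 * x + 1)
    assert est.r == pytest.approx(1.0)
    assert est.n_outliers == 0


def test_skipped_reduces_to_pearson_when_clean(rng):
    cov = [[1.0, 0.5], [0.5, 1.0]]
    xy = rng.multivariate_normal([0, 0], cov, size=500)
    est = skipped_pearson(xy[:, 0], xy[:, 1])
    r_plain = sps.pearsonr(xy[:, 0], xy[:, 1]).statistic
    assert abs(est.r - r_plain) < 0.05
    if est.n_outliers == 0:
        assert est.r == pytest.approx(r_plain)


def test_skipped_recovers_r_with_planted_leverage_points(rng):
    cov = [[1.0, 0.5], [0.5, 1.0]]
    n, n_out = 500, 25
    xy = rng.multivariate_normal([0, 0], cov, size=n)
    xy[:n_out] = [10.0, -10.0] + 0.1 * rng.normal(size=(n_out, 2))
    est = skipped_pearson(xy[:, 0], xy[:, 1])
    flagged_planted = np.intersect1d(est.outlier_ids, np.arange(n_out))
    assert len(flagged_planted) >= 0.9 * n_out
    assert abs(est.r - 0.5) < 0.1


def test_skipped_agrees_with_pingouin_on_clean_data(rng):
    pingouin = pytest.importorskip("pingouin")
    xy = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=200)
    est = skipped_pearson(xy[:, 0], xy[:, 1])
    ref = pingouin.corr(xy[:, 0], xy[:, 1], method="skipped")
    assert est.r == pytest.approx(float(ref["r"].iloc[0]), abs=0.05)


def test_skipped_refuses_majority_outliers(rng):
    """A cross-shaped cloud (tight arms far from a tight centre) flags most
    points on some projection; the estimator must refuse rather than
    correlate the leftovers."""
    arms = np.array([[10.0, 0.0], [-10.0, 0.0], [0.0, 10.0], [0.0, -10.0]])
    pts = np.vstack([np.repeat(arms, 4, axis=0), np.zeros((4, 2))])
    pts += 0.01 * rng.normal(size=pts.shape)
    with pytest.raises(ValueError, match="refused"):
        skipped_pearson(pts[:, 0], pts[:, 1])


def test_skipped_validation():
    with pytest.raises(ValueError):
        skipped_pearson([1, 2, 3], [1, 2, 3])
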