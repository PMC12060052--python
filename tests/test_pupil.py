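"""Pupillometry preprocessing: normalization, baselining, interpolation,
outlier exclusion, condition differences."""

import numpy as np
import pandas as pd
import pytest

from expviol.pupil import (EpochSet, PupilTrace, condition_difference_course,
                           epoch_and_baseline, exclude_pupil_outlier_observers,
                           interpolate_missing, normalize_to_observer_mean,
                           preprocess_epoch_set, window_average)


def make_trace(d, onset=500.0, missing=None, t0=-500.0):
    t = t0 + np.arange(len(d), dtype=float)
    if missing is None:
        missing = np.zeros(len(d), dtype=bool)
    return PupilTrace(0, 0, t, np.asarray(d, float), missing,
                      target_onset_ms=onset)


def epoch_grid(onset=500.0):
    """A trace covering exactly the -500..1500 ms epoch around `onset`."""
    return np.arange(-500.0, 1500.0 + 0.5) + onset


# ---------------------------------------------------------------------- norm

def test_normalize_constant_trace_to_unity():
    tr = make_trace(np.full(2001, 7.3))
    out, mean = normalize_to_observer_mean([tr])
    assert mean == pytest.approx(7.3)
    assert np.allclose(out[0].d, 1.0)


def test_normalize_scale_invariance(rng):
    d = rng.uniform(2000, 4000, 2001)
    a, _ = normalize_to_observer_mean([make_trace(d)])
    b, _ = normalize_to_observer_mean([make_trace(3.0 * d)])
    assert np.allclose(a[0].d, b[0].d)


def test_normalized_observer_mean_is_one(rng):
    traces = [make_trace(rng.uniform(1000, 5000, 500)) for _ in range(5)]
    out, _ = normalize_to_observer_mean(traces)
    pooled = np.concatenate([tr.d for tr in out])
    assert pooled.mean() == pytest.approx(1.0, abs=1e-12)


def test_normalize_all_missing_errors():
    missing = np.ones(100, dtype=bool)
    tr = make_trace(np.full(100, np.nan), missing=missing)
    with pytest.raises(ValueError):
        normalize_to_observer_mean([tr])


# ------------------------------------------------------------------ baseline

def test_linear_ramp_baselines_to_zero():
    t = epoch_grid()
    tr = make_trace(5.0 + 0.003 * t, onset=500.0, t0=0.0)
    ep = epoch_and_baseline(tr)
    assert ep.valid
    assert len(ep.t_rel) == 2001
    assert np.allclose(ep.d_norm, 0.0, atol=1e-9)


def test_constant_input_baselines_to_zero():
    ep = epoch_and_baseline(make_trace(np.full(2001, 4.2), onset=0.0))
    assert np.allclose(ep.d_norm, 0.0, atol=1e-9)


def test_ramp_plus_boxcar_recovers_boxcar():
    t = epoch_grid(onset=0.0)
    h = 0.8
    box = ((t >= 300) & (t < 900)) * h
    tr = make_trace(2.0 + 0.001 * t + box, onset=0.0, t0=-500.0)
    ep = epoch_and_baseline(tr)
    box_rel = ((ep.t_rel >= 300) & (ep.t_rel < 900)) * h
    assert np.allclose(ep.d_norm, box_rel, atol=1e-9)


def test_prestimulus_residuals_vanish(rng):
    """After baselining, the pre-onset mean and OLS slope are ~0 by
    construction, even for noisy drifting input."""
    d = 3000 + np.cumsum(rng.normal(0, 1, 2001)) + rng.normal(0, 5, 2001)
    ep = epoch_and_baseline(make_trace(d, onset=0.0))
    pre = ep.t_rel < 0
    assert abs(ep.d_norm[pre].mean()) < 1e-9
    slope = np.polyfit(ep.t_rel[pre], ep.d_norm[pre], 1)[0]
    assert abs(slope) < 1e-12


def test_baseline_idempotent(rng):
    d = 3000 + np.cumsum(rng.normal(0, 1, 2001))
    ep = epoch_and_baseline(make_trace(d, onset=0.0))
    tr2 = make_trace(ep.d_norm, onset=0.0)
    ep2 = epoch_and_baseline(tr2)
    assert abs(ep2.baseline_fit["intercept"]) < 1e-9
    assert abs(ep2.baseline_fit["slope"]) < 1e-12


def test_insufficient_baseline_flags_invalid():
    missing = np.zeros(2001, dtype=bool)
    missing[:499] = True  # leaves a single pre-onset sample
    ep = epoch_and_baseline(make_trace(np.ones(2001), onset=0.0,
                                       missing=missing))
    assert not ep.valid


def test_epoch_requires_coverage():
    tr = make_trace(np.ones(300), onset=0.0, t0=-100.0)
    with pytest.raises(ValueError):
        epoch_and_baseline(tr)


# --------------------------------------------------------------- interpolate

def test_interpolation_fills_midpoint():
    d = np.array([1.0, np.nan, 2.0])
    missing = np.isnan(d)
    from expviol.pupil import PupilEpoch
    epo = PupilEpoch(0, 0, np.arange(3.0), d, missing=missing)
    out = interpolate_missing(epo)
    assert out.d_norm[1] == pytest.approx(1.5)
    assert out.interpolated_mask.tolist() == [False, True, False]


def test_interpolation_identity_without_gaps(rng):
    from expviol.pupil import PupilEpoch
    d = rng.normal(size=50)
    epo = PupilEpoch(0, 0, np.arange(50.0), d.copy(),
                     missing=np.zeros(50, bool))
    out = interpolate_missing(epo)
    assert np.array_equal(out.d_norm, d)
    assert not out.interpolated_mask.any()


def test_interpolation_edge_gaps_held():
    from expviol.pupil import PupilEpoch
    d = np.array([np.nan, np.nan, 3.0, 4.0, np.nan])
    epo = PupilEpoch(0, 0, np.arange(5.0), d, missing=np.isnan(d))
    out = interpolate_missing(epo)
    assert np.allclose(out.d_norm, [3.0, 3.0, 3.0, 4.0, 4.0])


def test_blink_interpolation_error_taylor_bound():
    """Filling a 100-ms gap in a smooth kernel errs by at most
    max|f''| * (half-gap)^2 / 2."""
    from expviol.pupil import PupilEpoch
    from expviol.simulate import _gamma_kernel
    t = np.arange(0.0, 2000.0)
    f = _gamma_kernel(t, 930.0, 400.0)
    gap = (t >= 850) & (t < 950)
    d = np.where(gap, np.nan, f)
    epo = PupilEpoch(0, 0, t, d, missing=gap)
    out = interpolate_missing(epo)
    err = np.max(np.abs(out.d_norm[gap] - f[gap]))
    curvature = np.max(np.abs(np.diff(f, 2)))  # per ms^2
    assert err <= curvature * 50.0 ** 2 / 2 + 1e-12


# ----------------------------------------------------------------- exclusion

def test_identical_observers_none_excluded():
    with pytest.warns(UserWarning):
        keep = exclude_pupil_outlier_observers(np.full(10, 3000.0))
    assert keep.all()


def test_planted_outlier_is_excluded(rng):
    x = rng.normal(3000, 100, 30)
    base_sd = x.std(ddof=1)
    x = np.append(x, x.mean() + 10 * base_sd)
    keep = exclude_pupil_outlier_observers(x)
    assert not keep[-1]
    assert keep[:-1].all()


def test_exactly_three_sd_is_kept():
    """The exclusion rule is strict: an observer at exactly 3.0 group SDs
    stays in."""
    base = np.array([-1.0, 1.0] * 8, dtype=float)

    def z_of(c):
        x = np.append(base, c)
        return (c - x.mean()) / x.std(ddof=1)

    lo, hi = 1.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if z_of(mid) < 3.0:
            lo = mid
        else:
            hi = mid
    c3 = (lo + hi) / 2
    assert z_of(c3) == pytest.approx(3.0, abs=1e-6)
    assert exclude_pupil_outlier_observers(np.append(base, c3 - 1e-3))[-1]
    assert not exclude_pupil_outlier_observers(np.append(base, c3 + 1e-3))[-1]


def test_exclusion_needs_three_observers():
    with pytest.raises(ValueError):
        exclude_pupil_outlier_observers([1.0, 2.0])


# ---------------------------------------------------- condition differences

def make_epoch_set(obs, d_seq, d_rnd, violations_seq=None, violations_rnd=None):
    n_s, n_t = d_seq.shape
    n_r = d_rnd.shape[0]
    d = np.vstack([d_seq, d_rnd])
    conds = np.array(["sequential"] * n_s + ["random"] * n_r)
    v = np.concatenate([
        np.full(n_s, 60.0) if violations_seq is None else violations_seq,
        np.full(n_r, 60.0) if violations_rnd is None else violations_rnd,
    ])
    return EpochSet(obs, np.arange(n_t, dtype=float), d,
                    np.zeros_like(d, dtype=bool), conds, v,
                    np.arange(n_s + n_r))


def test_identical_conditions_give_zero_difference(rng):
    d = rng.normal(size=(4, 50))
    es = make_epoch_set(0, d, d.copy())
    diff = condition_difference_course([es])
    assert np.allclose(diff.to_numpy(), 0.0)


def test_split_selects_violation_subsets(rng):
    d_seq = np.vstack([np.ones((3, 20)), np.zeros((3, 20))])
    v_seq = np.array([60.0] * 3 + [10.0] * 3)
    d_rnd = np.zeros((6, 20))
    es = make_epoch_set(0, d_seq, d_rnd, violations_seq=v_seq,
                        violations_rnd=v_seq)
    large = condition_difference_course([es], split="large")
    small = condition_difference_course([es], split="small")
    assert np.allclose(large.to_numpy(), 1.0)
    assert np.allclose(small.to_numpy(), 0.0)


def test_missing_condition_drops_observer(rng):
    d = rng.normal(size=(4, 30))
    es_ok = make_epoch_set(0, d, d + 1)
    bad = EpochSet(1, np.arange(30.0), d, np.zeros_like(d, bool),
                   np.array(["sequential"] * 4), np.full(4, 60.0),
                   np.arange(4))
    with pytest.warns(UserWarning):
        diff = condition_difference_course([es_ok, bad])
    assert list(diff.index) == [0]


def test_preprocess_epoch_set_end_to_end(rng):
    t_rel = np.arange(-500.0, 1501.0)
    n = 8
    d = 3000 + rng.normal(0, 5, (n, len(t_rel)))
    missing = rng.random((n, len(t_rel))) < 0.01
    es = EpochSet(0, t_rel, np.where(missing, np.nan, d), missing,
                  np.array(["sequential", "random"] * 4),
                  rng.uniform(-90, 90, n), np.arange(n))
    out, mean, keep = preprocess_epoch_set(es)
    assert mean == pytest.approx(3000, rel=0.01)
    assert keep.all()
    pre = out.t_rel < 0
    resid = out.d[:, pre]
    # baseline used measured samples only, interpolation came after
    assert np.all(np.abs(resid.mean(axis=1)) < 1e-3)
    assert not np.isnan(out.d).any()


# ------------------------------------------------------------ window average

def test_window_average_constant_and_single_sample():
    t = np.arange(0.0, 100.0)
    df = pd.DataFrame(np.full((3, 100), 2.5), columns=t)
    out = window_average(df, (10, 50))
    assert np.allclose(out, 2.5)
    single = window_average(df, (42, 42))
    assert np.allclose(single, 2.5)


def test_window_average_boxcar_closed_form():
    t = np.arange(0.0, 1500.0)
    h = 1.7
    series = pd.Series(np.where((t >= 600) & (t < 1100), h, 0.0), index=t)
    got = window_average(series, (563, 1100))
    in_window = (t >= 563) & (t <= 1100)
    expected = series.to_numpy()[in_window].mean()  # direct integration
    assert got == pytest.approx(expected)
    assert expected == pytest.approx(h * 500 / 538, rel=1e-9)


def test_window_average_validation():
    t = np.arange(0.0, 10.0)
    series = pd.Series(np.ones(10), index=t)
    with pytest.raises(ValueError):
        window_average(series, (5, 2))
    with pytest.raises(ValueError):
        window_average(series, (100, 200))
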