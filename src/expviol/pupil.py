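"""Pupillometry preprocessing and condition-difference extraction.

The processing chain mirrors standard practice for event-locked pupil
analyses:

1. divisive normalization of each observer's diameter samples by their
   grand mean across the experiment (dimensionless, mean ~ 1);
2. epoching from -500 to +1500 ms around target onset (inclusive grid:
   2001 samples at 1 kHz);
3. baseline correction by an ordinary-least-squares line fit to the 500 ms
   pre-onset period, extrapolated across the whole epoch and subtracted
   (removes both level and slow drift slope);
4. linear interpolation of missing samples (blinks), done last so the
   baseline fit uses only measured samples;
5. exclusion of observers whose average raw diameter lies more than 3
   group SDs from the group mean (single pass);
6. per-observer sequential-minus-random difference time courses, optionally
   restricted to trials with large (> 30 deg) or small (<= 30 deg)
   expectation violations, and window averages over a significant period.

Two parallel APIs are provided: scalar functions on single traces/epochs
(:class:`PupilTrace`, :class:`PupilEpoch`) and vectorised functions on
per-observer epoch matrices (:class:`EpochSet`) used by the cohort
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PupilTrace",
    "PupilEpoch",
    "EpochSet",
    "normalize_to_observer_mean",
    "epoch_and_baseline",
    "interpolate_missing",
    "exclude_pupil_outlier_observers",
    "condition_difference_course",
    "window_average",
    "preprocess_epoch_set",
]

EPOCH_START_MS = -500.0
EPOCH_END_MS = 1500.0


@dataclass
class PupilTrace:
    """Raw diameter series for one trial (arbitrary units, 1 kHz default)."""

    observer_id: int
    trial_id: int
    t: np.ndarray           # ms, strictly increasing, uniform step
    d: np.ndarray           # diameter, NaN where missing
    missing: np.ndarray     # bool mask
    target_onset_ms: float = 0.0

    def __post_init__(self):
        if not (len(self.t) == len(self.d) == len(self.missing)):
            raise ValueError("t, d and missing must have equal length")
        steps = np.diff(self.t)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("t must be strictly increasing with a uniform step")

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 1.0


@dataclass
class PupilEpoch:
    """Event-locked, baseline-corrected epoch for one trial."""

    observer_id: int
    trial_id: int
    t_rel: np.ndarray
    d_norm: np.ndarray
    baseline_fit: dict = field(default_factory=dict)   # {"intercept", "slope"}
    interpolated_mask: Optional[np.ndarray] = None
    missing: Optional[np.ndarray] = None
    valid: bool = True


@dataclass
class EpochSet:
    """All epochs of one observer as a (trials x time) matrix."""

    observer_id: int
    t_rel: np.ndarray          # ms grid, shared across trials
    d: np.ndarray              # (n_trials, n_time)
    missing: np.ndarray        # bool, same shape
    conditions: np.ndarray     # "sequential" | "random" per trial
    violations: np.ndarray     # signed deg per trial
    trial_ids: np.ndarray

    def __post_init__(self):
        n, m = self.d.shape
        if self.missing.shape != (n, m) or len(self.t_rel) != m:
            raise ValueError("inconsistent EpochSet shapes")


# ---------------------------------------------------------------------------
# normalization

def normalize_to_observer_mean(traces):
    """Divide every sample by the observer's grand mean diameter.

    ``traces`` is a sequence of :class:`PupilTrace` (one observer).  Returns
    ``(normalized_traces, grand_mean)``.  The grand mean is computed over
    all non-missing samples pooled across traces.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    total, count = 0.0, 0
    for tr in traces:
        good = ~tr.missing
        total += np.nansum(tr.d[good])
        count += int(good.sum())
    if count == 0:
        raise ValueError("observer has no non-missing pupil samples")
    mean = total / count
    out = [replace(tr, d=tr.d / mean) for tr in traces]
    return out, float(mean)


def _normalize_matrix(d, missing):
    good = ~missing
    if not good.any():
        raise ValueError("observer has no non-missing pupil samples")
    mean = float(np.nansum(np.where(good, d, 0.0)) / good.sum())
    return d / mean, mean


# ---------------------------------------------------------------------------
# epoching + baseline

def _baseline_line(t_pre, d_pre, missing_pre):
    """OLS (intercept, slope) of the pre-onset samples, missing excluded."""
    good = ~missing_pre & np.isfinite(d_pre)
    if good.sum() < 2:
        return None
    slope, intercept = np.polyfit(t_pre[good], d_pre[good], 1)
    return float(intercept), float(slope)


def epoch_and_baseline(trace: PupilTrace, target_onset_ms=None,
                       t_start=EPOCH_START_MS, t_end=EPOCH_END_MS):
    """Cut an epoch around target onset and subtract the pre-onset line.

    The epoch grid is inclusive of both endpoints (2001 samples at 1 kHz).
    An OLS line is fit to the non-missing samples in ``[t_start, 0)`` and
    extrapolated across the whole epoch before subtraction, so a purely
    linear input becomes identically zero.  Epochs with fewer than two
    non-missing baseline samples are flagged invalid.
    """
    onset = trace.target_onset_ms if target_onset_ms is None else target_onset_ms
    t_rel = trace.t - onset
    dt = trace.dt_ms
    sel = (t_rel >= t_start - dt / 2) & (t_rel <= t_end + dt / 2)
    if t_rel[sel].min() > t_start + dt / 2 or t_rel[sel].max() < t_end - dt / 2:
        raise ValueError("trace does not cover the requested epoch window")
    t_rel = t_rel[sel]
    d = trace.d[sel].astype(float).copy()
    missing = trace.missing[sel].copy()

    pre = t_rel < 0
    fit = _baseline_line(t_rel[pre], d[pre], missing[pre])
    if fit is None:
        return PupilEpoch(trace.observer_id, trace.trial_id, t_rel, d,
                          baseline_fit={}, missing=missing, valid=False)
    intercept, slope = fit
    d = d - (intercept + slope * t_rel)
    return PupilEpoch(trace.observer_id, trace.trial_id, t_rel, d,
                      baseline_fit={"intercept": intercept, "slope": slope},
                      missing=missing, valid=True)


def _baseline_matrix(t_rel, d, missing):
    """Row-wise pre-onset OLS subtraction; returns (corrected, valid_mask)."""
    pre = t_rel < 0
    tp = t_rel[pre]
    dp = np.where(missing[:, pre], np.nan, d[:, pre])
    w = (~missing[:, pre]).astype(float)
    n = w.sum(axis=1)
    valid = n >= 2
    # closed-form weighted OLS per row (weights 0/1)
    sx = (w * tp).sum(axis=1)
    sy = np.nansum(np.where(w > 0, dp, 0.0), axis=1)
    sxx = (w * tp * tp).sum(axis=1)
    sxy = np.nansum(np.where(w > 0, dp * tp, 0.0), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx * sx
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
    slope = np.where(valid, slope, 0.0)
    intercept = np.where(valid, intercept, 0.0)
    corrected = d - (intercept[:, None] + slope[:, None] * t_rel[None, :])
    return corrected, valid


# ---------------------------------------------------------------------------
# interpolation

def interpolate_missing(epoch: PupilEpoch) -> PupilEpoch:
    """Linearly interpolate missing samples; edge gaps held at nearest value."""
    if epoch.missing is None or not epoch.missing.any():
        return replace(epoch, interpolated_mask=np.zeros(len(epoch.t_rel), bool))
    good = ~epoch.missing
    if not good.any():
        return replace(epoch, valid=False,
                       interpolated_mask=epoch.missing.copy())
    filled = epoch.d_norm.copy()
    filled[epoch.missing] = np.interp(
        epoch.t_rel[epoch.missing], epoch.t_rel[good], epoch.d_norm[good]
    )
    return replace(epoch, d_norm=filled, interpolated_mask=epoch.missing.copy(),
                   missing=np.zeros_like(epoch.missing))


def _interpolate_matrix(t_rel, d, missing):
    out = d.copy()
    rows = np.flatnonzero(missing.any(axis=1))
    dead = np.zeros(d.shape[0], bool)
    for i in rows:
        good = ~missing[i]
        if not good.any():
            dead[i] = True
            continue
        out[i, missing[i]] = np.interp(t_rel[missing[i]], t_rel[good], d[i, good])
    return out, dead


# ---------------------------------------------------------------------------
# observer exclusion

def exclude_pupil_outlier_observers(mean_diameters, threshold=3.0):
    """Keep-mask for observers by average raw pupil diameter.

    Observers strictly more than ``threshold`` group standard deviations
    (ddof=1) from the group mean are excluded.  A single pass is made: the
    mean and SD are computed once on all observers, never re-estimated.
    """
    x = np.asarray(mean_diameters, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observers")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero group SD: no pupil-outlier exclusions possible")
        return np.ones(x.size, dtype=bool)
    return np.abs(x - mu) <= threshold * sd


# ---------------------------------------------------------------------------
# condition differences

def preprocess_epoch_set(es: EpochSet, normalize=True, subtractive=False):
    """normalize -> baseline -> interpolate one observer's epoch matrix.

    Returns ``(processed EpochSet, raw_grand_mean, valid_trial_mask)``.
    ``subtractive=True`` normalizes by subtracting (rather than dividing by)
    the observer's grand mean.
    """
    d, missing = es.d.astype(float), es.missing
    if normalize:
        if subtractive:
            good = ~missing
            mean = float(np.nansum(np.where(good, d, 0.0)) / good.sum())
            d = d - mean
        else:
            d, mean = _normalize_matrix(d, missing)
    else:
        mean = float("nan")
    d, valid = _baseline_matrix(es.t_rel, d, missing)
    d, dead = _interpolate_matrix(es.t_rel, d, missing)
    keep = valid & ~dead
    out = EpochSet(es.observer_id, es.t_rel, d[keep],
                   np.zeros_like(missing[keep]), es.conditions[keep],
                   es.violations[keep], es.trial_ids[keep])
    return out, mean, keep


def condition_difference_course(epoch_sets, split=None, large_threshold=30.0):
    """Per-observer sequential-minus-random mean epoch difference.

    Parameters
    ----------
    epoch_sets : iterable of EpochSet
        Preprocessed epochs, one set per observer.
    split : {None, "large", "small"}
        Restrict to trials with absolute expectation violation strictly
        greater than (``"large"``) or at most (``"small"``)
        ``large_threshold`` degrees.

    Returns
    -------
    DataFrame indexed by observer_id, columns = t_rel (ms).  Observers
    missing either condition after the split are dropped with a warning.
    """
    rows, index, t_ref = [], [], None
    for es in epoch_sets:
        if t_ref is None:
            t_ref = es.t_rel
        sel = np.ones(len(es.conditions), bool)
        if split == "large":
            sel = np.abs(es.violations) > large_threshold
        elif split == "small":
            sel = np.abs(es.violations) <= large_threshold
        elif split is not None:
            raise ValueError(f"unknown split {split!r}")
        seq = sel & (es.conditions == "sequential")
        rnd = sel & (es.conditions == "random")
        if not seq.any() or not rnd.any():
            warnings.warn(f"observer {es.observer_id}: missing a condition "
                          "after split; dropped")
            continue
        rows.append(es.d[seq].mean(axis=0) - es.d[rnd].mean(axis=0))
        index.append(es.observer_id)
    if not rows:
        raise ValueError("no observer had both conditions")
    return pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="observer_id"),
                        columns=np.asarray(t_ref))


def window_average(difference, window):
    """Time-mean of a difference course over ``window=(lo_ms, hi_ms)``, inclusive.

    Accepts the DataFrame from :func:`condition_difference_course` (returns a
    per-observer Series) or a single 1-D Series.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("empty window")
    if isinstance(difference, pd.DataFrame):
        t = difference.columns.to_numpy(dtype=float)
        sel = (t >= lo) & (t <= hi)
        if not sel.any():
            raise ValueError("window contains no samples")
        return difference.loc[:, sel].mean(axis=1)
    t = difference.index.to_numpy(dtype=float)
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise ValueError("window contains no samples")
    return float(difference.iloc[sel].mean())
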