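"""Behavioral analysis pipeline: exclusions, condition summaries,
violation-magnitude tuning curves, bias curves, and the sequence-length
median split.

All functions operate on the package's long-format behavioral table (one
row per trial; see ``simulate.simulate_behavior_frame`` for the schema).
Trials with no speeded response inside the 2-s window (``missed``) are
dropped before the accuracy denominator is formed.  Observers with
proportion correct strictly below 0.75 across all scored trials are
excluded; precision/bias/RT statistics then use correct-choice trials only
(a config flag reinstates all trials).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .circstats import UndefinedMeanError, angular_sd, axial_mean

__all__ = [
    "exclude_by_accuracy",
    "correct_trials_only",
    "condition_summaries",
    "tuning_by_violation",
    "bias_by_violation",
    "median_split_by_length",
    "violation_bin_edges",
]

log = logging.getLogger(__name__)

ACCURACY_THRESHOLD = 0.75


def exclude_by_accuracy(data: pd.DataFrame, threshold=ACCURACY_THRESHOLD):
    """Drop observers scoring strictly below ``threshold`` proportion correct.

    Missed trials are removed from both numerator and denominator first.
    Returns ``(kept_data, exclusions)`` where ``exclusions`` is a per-observer
    frame with columns prop_correct, n_scored, excluded.
    """
    if data.empty:
        raise ValueError("empty dataset")
    scored = data.loc[~data["missed"].astype(bool)]
    acc = (scored.groupby("observer_id")["choice_correct"]
           .agg(prop_correct="mean", n_scored="size").reset_index())
    acc["excluded"] = acc["prop_correct"] < threshold
    bad = set(acc.loc[acc["excluded"], "observer_id"])
    if bad:
        log.info("accuracy exclusion (<%.2f): observers %s", threshold, sorted(bad))
    kept = scored.loc[~scored["observer_id"].isin(bad)].reset_index(drop=True)
    return kept, acc


def correct_trials_only(data: pd.DataFrame):
    """Retain correct-choice trials; returns ``(subset, retained_fraction)``."""
    if data.empty:
        return data, float("nan")
    keep = data["choice_correct"].astype(bool)
    frac = float(keep.mean())
    log.info("correct-trial filter retained %.1f%% of trials", 100 * frac)
    out = data.loc[keep].reset_index(drop=True)
    lost = set(data["observer_id"].unique()) - set(out["observer_id"].unique())
    for obs in sorted(lost):
        warnings.warn(f"observer {obs} has no correct trials")
    return out, frac


def _precision(errors):
    errors = np.asarray(errors, float)
    errors = errors[np.isfinite(errors)]
    if len(errors) < 2:
        warnings.warn("fewer than 2 reproduction errors: precision undefined")
        return float("nan")
    return angular_sd(errors)


def condition_summaries(data: pd.DataFrame) -> pd.DataFrame:
    """Per observer x condition: mean RT (ms) and reproduction precision
    (angular SD, deg; lower = more precise).

    Expects exclusions/filters already applied.  A missing condition yields
    NaN cells and a warning.
    """
    rows = []
    conditions = ("random", "sequential")
    for obs, grp in data.groupby("observer_id"):
        row = {"observer_id": obs}
        for cond in conditions:
            sub = grp.loc[grp["condition"] == cond]
            if sub.empty:
                warnings.warn(f"observer {obs}: no {cond} trials")
                row[f"mean_rt_{cond}"] = np.nan
                row[f"precision_{cond}"] = np.nan
                row[f"n_{cond}"] = 0
                continue
            row[f"mean_rt_{cond}"] = float(sub["rt"].mean())
            row[f"precision_{cond}"] = _precision(sub["repro_error"])
            row[f"n_{cond}"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows)


def violation_bin_edges(n_bins=8, signed=True):
    """Equal-width violation bins: signed over (-90, 90], or folded |v| over [0, 90]."""
    if signed:
        return np.linspace(-90.0, 90.0, n_bins + 1)
    return np.linspace(0.0, 90.0, n_bins + 1)


def _assign_bins(violation, n_bins, signed):
    edges = violation_bin_edges(n_bins, signed)
    v = np.asarray(violation, float)
    if signed:
        if np.any(v <= -90.0) or np.any(v > 90.0):
            raise ValueError("signed violations must lie in (-90, 90]")
        idx = np.searchsorted(edges, v, side="left") - 1
    else:
        v = np.abs(v)
        idx = np.searchsorted(edges, v, side="left") - 1
        idx = np.where(v == 0.0, 0, idx)     # first bin closed at 0
    idx = np.clip(idx, 0, n_bins - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return idx, centers


def tuning_by_violation(data: pd.DataFrame, n_bins=8, signed=True) -> pd.DataFrame:
    """Violation-magnitude tuning curves of RT and precision.

    Signed violations in (-90, 90] are partitioned into ``n_bins``
    equal-width half-open bins (lo, hi]; ``signed=False`` folds onto
    |violation| in [0, 90] with the first bin closed at zero.  Returns a
    long frame (observer_id, condition, bin, bin_center, mean_rt,
    precision, n_trials); empty cells are absent (the RM-ANOVA layer
    handles them by listwise deletion).
    """
    idx, centers = _assign_bins(data["violation"], n_bins, signed)
    df = data.assign(_bin=idx)
    rows = []
    for (obs, cond, b), grp in df.groupby(["observer_id", "condition", "_bin"]):
        rows.append({
            "observer_id": obs, "condition": cond, "bin": int(b),
            "bin_center": float(centers[int(b)]),
            "mean_rt": float(grp["rt"].mean()),
            "precision": _precision(grp["repro_error"]),
            "n_trials": len(grp),
        })
    out = pd.DataFrame(rows)
    assert out["n_trials"].sum() == len(data), "bin assignment lost trials"
    return out


def bias_by_violation(data: pd.DataFrame, n_bins=8, signed=True) -> pd.DataFrame:
    """Per-bin axial mean of signed reproduction error ("bias", deg).

    A repulsive bias away from the expected orientation appears as bias
    sharing the sign of the bin centre near zero violation.
    """
    idx, centers = _assign_bins(data["violation"], n_bins, signed)
    df = data.assign(_bin=idx)
    rows = []
    for (obs, cond, b), grp in df.groupby(["observer_id", "condition", "_bin"]):
        errs = grp["repro_error"].to_numpy(float)
        errs = errs[np.isfinite(errs)]
        try:
            bias = axial_mean(errs) if len(errs) else float("nan")
        except UndefinedMeanError:
            bias = float("nan")
        rows.append({
            "observer_id": obs, "condition": cond, "bin": int(b),
            "bin_center": float(centers[int(b)]), "bias": bias,
            "n_trials": len(grp),
        })
    return pd.DataFrame(rows)


def median_split_by_length(data: pd.DataFrame) -> pd.DataFrame:
    """Split each observer's trials at their median sequence length.

    Trials with ``n_initial`` at or below the observer's median go to the
    "short" half (ties short).  Returns per observer x half x condition
    mean RT and precision.  Raises if any observer has constant
    ``n_initial`` (no split possible).
    """
    rows = []
    for obs, grp in data.groupby("observer_id"):
        lengths = grp["n_initial"].to_numpy()
        if lengths.min() == lengths.max():
            raise ValueError(f"observer {obs}: constant sequence length, "
                             "median split impossible")
        med = float(np.median(lengths))
        half = np.where(lengths <= med, "short", "long")
        sub = grp.assign(_half=half)
        for (h, cond), cell in sub.groupby(["_half", "condition"]):
            rows.append({
                "observer_id": obs, "half": h, "condition": cond,
                "mean_rt": float(cell["rt"].mean()),
                "precision": _precision(cell["repro_error"]),
                "n_trials": len(cell),
            })
    return pd.DataFrame(rows)
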