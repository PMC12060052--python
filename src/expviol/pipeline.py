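"""End-to-end orchestration: simulate (or load) -> behavior -> pupil ->
stats -> machine-readable results manifest.

The headline analysis of an Experiment-1-style dataset comprises:

1. accuracy exclusion (< 0.75 correct) and correct-trial filtering;
2. paired t-tests on per-observer mean RT and reproduction precision
   (sequential vs. random);
3. two-way repeated-measures ANOVAs (condition x violation bin) on the
   8-bin tuning curves of RT and precision;
4. the signed-error bias curve and the sequence-length median split;
5. pupil preprocessing, the large-violation sequential-minus-random
   difference course, a one-tailed cluster-mass permutation test across
   the epoch, and the per-observer window average over the significant
   cluster;
6. skipped Pearson correlations: RT vs. precision within each condition,
   the condition differences against each other, and the pupil window
   average against the RT and precision condition differences.

Every analysis decision (bins, tails, n_perm, thresholds, seed) lives in
:class:`RunConfig` and is echoed into the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import pupil as pup
from . import stats as st
from .design import generate_session_exp1, generate_session_exp2
from .simulate import CohortData, ObserverParams, simulate_cohort

__all__ = [
    "RunConfig",
    "run_pipeline",
    "analyze_cohort",
    "load_osf_deposit",
    "write_behavior_table",
    "read_behavior_table",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "expviol-behavior-v1"
BEHAVIOR_COLUMNS = [
    "observer_id", "trial_id", "block", "condition", "n_initial", "violation",
    "delta_pt", "target", "choice", "choice_correct", "missed", "rt",
    "reproduction", "repro_error",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    experiment: str = "exp1"          # "exp1" | "exp2"
    seed: int = 0
    n_observers: int = 60
    n_blocks: Optional[int] = None    # default: 16 (exp1) / 48 (exp2)
    trials_per_block: int = 24
    # analysis toggles
    n_bins: int = 8
    signed_bins: bool = True
    accuracy_threshold: float = 0.75
    correct_only: bool = True
    pupil_enabled: bool = True
    pupil_dt_ms: float = 1.0
    pupil_outlier_sd: float = 3.0
    violation_split_deg: float = 30.0
    n_perm: int = 1000
    pupil_tail: str = "greater"
    alpha_pointwise: float = 0.05
    out_dir: Optional[str] = None
    population_means: dict = field(default_factory=dict)
    population_sds: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self):
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# tabular IO

def write_behavior_table(data: pd.DataFrame, path, seed=None):
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n# seed={seed}\n")
        data.to_csv(fh, sep="\t", index=False)


def read_behavior_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


#: Default mapping from our canonical columns to themselves; a deposit
#: mapping file (YAML: {canonical: deposit_column}) overrides entries.
def load_osf_deposit(path, mapping=None) -> pd.DataFrame:
    """Load an externally deposited long-format behavioral table.

    ``mapping`` is an optional YAML file (or dict) giving
    ``canonical_column: deposit_column`` pairs for columns whose names
    differ from the package schema.  Missing required columns raise a
    field-by-field diagnostic; unmapped extra columns are logged and kept.
    """
    if mapping is None:
        mapping = {}
    elif not isinstance(mapping, dict):
        with open(mapping) as fh:
            mapping = yaml.safe_load(fh) or {}
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, comment="#")
    rename = {v: k for k, v in mapping.items()}
    df = raw.rename(columns=rename)
    required = ["observer_id", "condition", "violation", "choice_correct", "rt",
                "repro_error"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        available = sorted(df.columns)
        raise ValueError(
            "deposit schema mismatch; missing required columns:\n"
            + "\n".join(f"  - {c}: not found (mapped names available: "
                        f"{available})" for c in missing))
    if "missed" not in df.columns:
        df["missed"] = df["rt"].isna()
    extra = [c for c in df.columns if c not in BEHAVIOR_COLUMNS]
    if extra:
        log.info("deposit columns kept unmapped: %s", extra)
    return df


# ---------------------------------------------------------------------------
# analysis

def _corr(x, y):
    try:
        est = st.skipped_pearson(x, y)
        return {"r": est.r, "p": est.p_value, "n": est.n_used,
                "n_outliers": est.n_outliers}
    except ValueError as exc:
        return {"r": float("nan"), "p": float("nan"), "n": 0,
                "error": str(exc)}


def analyze_behavior(data: pd.DataFrame, config: RunConfig):
    """Behavioral stage: exclusions, summaries, tuning, bias, median split."""
    kept, acc = bhv.exclude_by_accuracy(data, config.accuracy_threshold)
    if config.correct_only:
        kept, retained = bhv.correct_trials_only(kept)
    else:
        retained = 1.0
    summaries = bhv.condition_summaries(kept)
    tuning = bhv.tuning_by_violation(kept, config.n_bins, config.signed_bins)
    bias = bhv.bias_by_violation(kept, config.n_bins, config.signed_bins)
    try:
        split = bhv.median_split_by_length(kept)
    except ValueError:
        split = pd.DataFrame()
    results = {
        "n_observers_in": int(data["observer_id"].nunique()),
        "n_excluded_accuracy": int(acc["excluded"].sum()),
        "prop_correct_mean": float(acc.loc[~acc["excluded"], "prop_correct"].mean()),
        "retained_correct_fraction": float(retained),
        "rt_t": st.paired_t(summaries["mean_rt_sequential"],
                            summaries["mean_rt_random"]),
        "precision_t": st.paired_t(summaries["precision_sequential"],
                                   summaries["precision_random"]),
    }
    for dv in ("mean_rt", "precision"):
        try:
            eff = st.rm_anova_2way(tuning.rename(columns={dv: "value"}),
                                   "value", "observer_id",
                                   ("condition", "bin"))
            results[f"anova_{dv}"] = {"condition": eff["A"], "bin": eff["B"],
                                      "interaction": eff["A:B"]}
        except ValueError as exc:
            results[f"anova_{dv}"] = {"error": str(exc)}
    results["corr_rt_precision_random"] = _corr(
        summaries["mean_rt_random"], summaries["precision_random"])
    results["corr_rt_precision_sequential"] = _corr(
        summaries["mean_rt_sequential"], summaries["precision_sequential"])
    results["corr_diff_rt_precision"] = _corr(
        summaries["mean_rt_random"] - summaries["mean_rt_sequential"],
        summaries["precision_random"] - summaries["precision_sequential"])
    return {"data": kept, "accuracy": acc, "summaries": summaries,
            "tuning": tuning, "bias": bias, "median_split": split,
            "results": results}


def analyze_pupil(epoch_sets: dict, included_observers, config: RunConfig,
                  seed=None):
    """Pupil stage: preprocess, exclude outlier observers, cluster test."""
    processed, raw_means, obs_ids = [], [], []
    for obs, es in epoch_sets.items():
        if obs not in included_observers:
            continue
        out, mean, _ = pup.preprocess_epoch_set(es)
        processed.append(out)
        raw_means.append(mean)
        obs_ids.append(obs)
    if len(processed) < 3:
        raise ValueError("too few observers with pupil data")
    keep = pup.exclude_pupil_outlier_observers(raw_means,
                                               config.pupil_outlier_sd)
    kept_sets = [es for es, k in zip(processed, keep) if k]
    diff = pup.condition_difference_course(kept_sets, split="large",
                                           large_threshold=config.violation_split_deg)
    result = st.cluster_permutation_test(
        diff.to_numpy(), times=diff.columns.to_numpy(float),
        alpha_pointwise=config.alpha_pointwise, n_perm=config.n_perm,
        tail=config.pupil_tail, seed=seed)
    sig = result.significant_clusters
    window = None
    window_means = None
    if sig:
        main = max(sig, key=lambda c: abs(c["mass"]))
        window = (main["start_ms"], main["end_ms"])
        window_means = pup.window_average(diff, window)
    return {"difference": diff, "cluster": result, "window": window,
            "window_means": window_means,
            "n_pupil_excluded": int((~keep).sum()),
            "observers": [o for o, k in zip(obs_ids, keep) if k]}


def analyze_cohort(cohort: CohortData, config: RunConfig, seed=None):
    """Full behavioral + pupil analysis of one cohort; returns a manifest-
    shaped dict plus intermediate tables."""
    beh = analyze_behavior(cohort.behavior, config)
    results = dict(beh["results"])
    pupil_out = None
    if config.pupil_enabled and cohort.epoch_sets:
        included = set(beh["data"]["observer_id"].unique())
        try:
            pupil_out = analyze_pupil(cohort.epoch_sets, included, config,
                                      seed=seed)
        except ValueError as exc:
            results["pupil_error"] = str(exc)
        if pupil_out is not None:
            results["n_pupil_excluded"] = pupil_out["n_pupil_excluded"]
            results["cluster_window_ms"] = pupil_out["window"]
            results["cluster_threshold_mass"] = pupil_out["cluster"].threshold_mass
            if pupil_out["window_means"] is not None:
                wm = pupil_out["window_means"]
                summ = beh["summaries"].set_index("observer_id").loc[wm.index]
                results["corr_pupil_rt"] = _corr(
                    wm.to_numpy(),
                    (summ["mean_rt_random"] - summ["mean_rt_sequential"]).to_numpy())
                results["corr_pupil_precision"] = _corr(
                    wm.to_numpy(),
                    (summ["precision_random"] - summ["precision_sequential"]).to_numpy())
    return {"results": results, "behavior": beh, "pupil": pupil_out}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig):
    """Simulate a cohort per ``config``, analyze it, and (optionally) write
    the report bundle to ``config.out_dir``.  Returns the manifest dict."""
    rng = np.random.default_rng(config.seed)
    if config.experiment == "exp1":
        factory = generate_session_exp1
        n_blocks = config.n_blocks or 16
    elif config.experiment == "exp2":
        factory = generate_session_exp2
        n_blocks = config.n_blocks or 48
    else:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    means = ObserverParams(**config.population_means)
    cohort = simulate_cohort(
        config.n_observers, rng=rng, design_factory=factory,
        design_kwargs={"n_blocks": n_blocks,
                       "trials_per_block": config.trials_per_block},
        population_means=means, population_sds=config.population_sds,
        pupil=config.pupil_enabled, dt_ms=config.pupil_dt_ms)
    out = analyze_cohort(cohort, config, seed=config.seed)
    manifest = {"config": config.to_dict(), "results": out["results"]}

    if config.experiment == "exp2":
        manifest["results"]["cue_validity"] = _exp2_cue_analysis(
            out["behavior"]["data"])

    if config.out_dir:
        d = Path(config.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        write_behavior_table(cohort.behavior, d / "behavior.tsv",
                             seed=config.seed)
        out["behavior"]["summaries"].to_csv(d / "summaries.tsv", sep="\t",
                                            index=False)
        out["behavior"]["tuning"].to_csv(d / "tuning.tsv", sep="\t", index=False)
        out["behavior"]["bias"].to_csv(d / "bias.tsv", sep="\t", index=False)
        if len(out["behavior"]["median_split"]):
            out["behavior"]["median_split"].to_csv(
                d / "median_split.tsv", sep="\t", index=False)
        if out["pupil"] is not None:
            out["pupil"]["difference"].to_csv(d / "pupil_difference.tsv",
                                              sep="\t")
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True,
                      default=_json_default)
    return manifest


def _exp2_cue_analysis(data: pd.DataFrame):
    """2x2 (sequence condition x cue validity) analysis of RT and precision."""
    if "cue_valid" not in data.columns:
        return {"error": "no cue_valid column"}
    out = {}
    for dv, agg in (("rt", "mean_rt"), ("repro_error", "precision")):
        rows = []
        for (obs, cond, valid), grp in data.groupby(
                ["observer_id", "condition", "cue_valid"]):
            val = (float(grp["rt"].mean()) if dv == "rt"
                   else bhv._precision(grp["repro_error"]))
            rows.append({"observer_id": obs, "condition": cond,
                         "cue_valid": str(bool(valid)), "value": val})
        cells = pd.DataFrame(rows)
        try:
            eff = st.rm_anova_2way(cells, "value", "observer_id",
                                   ("condition", "cue_valid"))
            out[agg] = {"sequence": eff["A"], "cue_validity": eff["B"],
                        "interaction": eff["A:B"]}
        except ValueError as exc:
            out[agg] = {"error": str(exc)}
        # paired t per validity level (sequential vs random)
        for valid in ("True", "False"):
            sub = cells[cells["cue_valid"] == valid].pivot(
                index="observer_id", columns="condition", values="value").dropna()
            if len(sub) >= 2:
                key = "valid" if valid == "True" else "invalid"
                out[f"{agg}_t_{key}"] = st.paired_t(sub["sequential"],
                                                    sub["random"])
    return out
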