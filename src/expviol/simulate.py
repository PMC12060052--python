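"""Generative observer model for the expectation-violation task.

Every analysis stage in this package is validated against data from this
simulator, whose effect structure mirrors the phenomena the behavioral and
pupillometric analyses are designed to detect:

* **Suppressive prediction tuning** (sequential condition): responses are
  slowest and least precise when the target matches the expected
  orientation (violation ~ 0) and improve as the violation grows.  This is
  modelled as a unit-height Gaussian penalty ``G(violation; width)`` plus a
  complementary "surprise benefit" ``1 - G`` so that, aggregated over the
  uniform violation distribution, sequential trials come out faster and
  more precise than random trials while remaining worse at violation 0.
* **Temporal integration** (both conditions): faster/more precise responses
  when the penultimate and target orientations are similar, because the two
  briefly presented gratings blend into a cleaner orientation signal.
* **Motor priming**: RT decreases linearly with the number of preceding
  gratings (longer foreperiod).
* **Repulsive bias**: reproduction errors are pushed away from the expected
  orientation, modelled as a derivative-of-Gaussian of the violation
  (unit peak at ``violation = bias_width``), sequential trials only.
* **Surprise-locked pupil dilation**: each grating evokes a gamma-shaped
  dilation kernel; the target additionally evokes a dilation proportional
  to the absolute expectation violation (sequential only), peaking
  ``pupil_latency_ms`` after target onset.  Traces carry slow random-walk
  drift, white measurement noise and Poisson-process blinks.

Reproduction noise is wrapped normal on the axial circle (angles doubled),
so the generating SD is directly comparable to the angular-SD precision
measure used downstream.  RT noise is lognormal; responses slower than the
2-second deadline are recorded as missed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .circstats import axial_wrap, wrap_orientation
from .design import SessionDesign, TrialSpec, TrialTiming, generate_session_exp1, session_to_frame
from .pupil import EpochSet, PupilTrace

__all__ = [
    "ObserverParams",
    "BehavioralRecord",
    "DEFAULT_POPULATION_SDS",
    "simulate_behavior",
    "simulate_behavior_frame",
    "simulate_pupil",
    "simulate_pupil_epochs",
    "simulate_cohort",
    "CohortData",
    "null_params",
]


@dataclass
class ObserverParams:
    """Tunable parameters of one simulated observer.

    Times in ms, angles in degrees, pupil diameter in arbitrary tracker
    units.  Amplitudes of zero switch the corresponding effect off.
    """

    # speeded response
    rt_base: float = 500.0            # deterministic RT floor
    rt_sigma: float = 150.0           # lognormal noise scale (median extra ms)
    rt_shape: float = 0.6             # lognormal shape (log-SD)
    rt_pred_amp: float = 50.0         # slowing at violation 0 (sequential)
    rt_pred_width: float = 25.0
    rt_surprise_amp: float = 50.0     # speeding for large violations (sequential)
    rt_integration_amp: float = 30.0  # speeding for small |target - penultimate|
    rt_integration_width: float = 25.0
    rt_len_slope: float = 6.0         # ms faster per extra preceding grating
    # reproduction
    repro_sd_base: float = 7.0
    repro_sd_pred_amp: float = 2.0       # precision loss at violation 0 (sequential)
    repro_sd_pred_width: float = 25.0
    repro_sd_surprise_amp: float = 2.5   # precision gain at large violations
    repro_sd_integration_amp: float = 1.5
    bias_amp: float = 2.0                # repulsion peak (deg)
    bias_width: float = 25.0
    # binary choice
    lapse_rate: float = 0.08
    choice_noise_sd: float = 8.0
    # pupil
    pupil_base: float = 3000.0
    pupil_drift_sd: float = 30.0      # random-walk SD accumulated per second
    pupil_noise_sd: float = 10.0
    pupil_event_amp: float = 30.0     # per-grating dilation kernel peak
    pupil_surprise_gain: float = 1.2  # a.u. per degree of |violation| (sequential)
    pupil_latency_ms: float = 930.0   # surprise-kernel peak latency
    pupil_width_ms: float = 400.0     # surprise-kernel SD
    blink_rate: float = 0.15          # Hz
    blink_dur_ms: float = 120.0

    def __post_init__(self):
        nonneg = [f.name for f in dataclasses.fields(self)
                  if f.name not in ("lapse_rate",)]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.lapse_rate <= 0.5):
            raise ValueError("lapse_rate must be in [0, 0.5]")


def null_params(**overrides) -> ObserverParams:
    """Parameters with every condition/tuning effect switched off."""
    base = ObserverParams(
        rt_pred_amp=0.0, rt_surprise_amp=0.0, rt_integration_amp=0.0,
        rt_len_slope=0.0, repro_sd_pred_amp=0.0, repro_sd_surprise_amp=0.0,
        repro_sd_integration_amp=0.0, bias_amp=0.0, pupil_surprise_gain=0.0,
    )
    return dataclasses.replace(base, **overrides)


@dataclass
class BehavioralRecord:
    observer_id: int
    trial_id: int
    choice: str              # "cw" | "ccw"
    choice_correct: bool
    rt: float                # ms; NaN if missed
    missed: bool
    reproduction: float      # deg, [0, 180)
    repro_error: float       # signed deg, (-90, 90]


def _gauss(x, width):
    """Unit-height Gaussian tuning profile."""
    if width <= 0:
        return np.zeros_like(np.asarray(x, float))
    return np.exp(-np.square(x) / (2.0 * width ** 2))


def _dog(x, width):
    """Derivative-of-Gaussian with unit peak at x = width; sign(x) preserved."""
    if width <= 0:
        return np.zeros_like(np.asarray(x, float))
    z = np.asarray(x, float) / width
    return z * np.exp(0.5 * (1.0 - z * z))


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior_frame(design_frame: pd.DataFrame, p: ObserverParams,
                            rng, observer_id=0,
                            speeded_window_ms=2000.0) -> pd.DataFrame:
    """Vectorised behavioral simulation for a session table."""
    df = design_frame
    n = len(df)
    seq = (df["condition"] == "sequential").to_numpy()
    violation = df["violation"].to_numpy(dtype=float)
    target = df["target"].to_numpy(dtype=float)
    delta_pt = axial_wrap(target - df["penultimate"].to_numpy(dtype=float))
    n_initial = df["n_initial"].to_numpy(dtype=float)

    g_pred = _gauss(violation, p.rt_pred_width)
    rt_det = (p.rt_base
              - p.rt_len_slope * (n_initial - 5.0)
              + seq * (p.rt_pred_amp * g_pred
                       - p.rt_surprise_amp * (1.0 - g_pred))
              - p.rt_integration_amp * _gauss(delta_pt, p.rt_integration_width))
    rt = rt_det + rng.lognormal(np.log(max(p.rt_sigma, 1e-9)), p.rt_shape, size=n)
    missed = rt > speeded_window_ms
    rt = np.where(missed, np.nan, rt)

    g_prec = _gauss(violation, p.repro_sd_pred_width)
    sd = (p.repro_sd_base
          + seq * (p.repro_sd_pred_amp * g_prec
                   - p.repro_sd_surprise_amp * (1.0 - g_prec))
          - p.repro_sd_integration_amp * _gauss(delta_pt, p.rt_integration_width))
    sd = np.maximum(sd, 1.0)
    bias = seq * p.bias_amp * _dog(violation, p.bias_width)
    reproduction = wrap_orientation(target + bias + rng.normal(0.0, sd))
    repro_error = axial_wrap(reproduction - target)

    signed_target = axial_wrap(target)
    percept = signed_target + rng.normal(0.0, p.choice_noise_sd, size=n)
    choice_cw = percept > 0
    lapse = rng.random(n) < p.lapse_rate
    choice_cw = np.where(lapse, ~choice_cw, choice_cw)
    true_cw = signed_target > 0
    correct = choice_cw == true_cw

    out = pd.DataFrame({
        "observer_id": observer_id,
        "trial_id": df["trial_id"].to_numpy(),
        "block": df["block"].to_numpy(),
        "condition": df["condition"].to_numpy(),
        "n_initial": df["n_initial"].to_numpy(),
        "violation": violation,
        "delta_pt": delta_pt,
        "target": target,
        "choice": np.where(choice_cw, "cw", "ccw"),
        "choice_correct": correct,
        "missed": missed,
        "rt": rt,
        "reproduction": reproduction,
        "repro_error": repro_error,
    })
    if "cue_valid" in df.columns:
        out["cue_valid"] = df["cue_valid"].to_numpy()
    return out


def simulate_behavior(trial: TrialSpec, p: ObserverParams, rng,
                      observer_id=0) -> BehavioralRecord:
    """Single-trial behavioral simulation (scalar convenience wrapper)."""
    frame = session_to_frame(SessionDesign([trial], 1, 1))
    row = simulate_behavior_frame(frame, p, rng, observer_id).iloc[0]
    return BehavioralRecord(
        observer_id=observer_id, trial_id=trial.trial_id,
        choice=row["choice"], choice_correct=bool(row["choice_correct"]),
        rt=float(row["rt"]), missed=bool(row["missed"]),
        reproduction=float(row["reproduction"]),
        repro_error=float(row["repro_error"]),
    )


# ---------------------------------------------------------------------------
# pupil

def _gamma_kernel(t_ms, peak_ms, width_ms):
    """Unit-peak gamma-shaped impulse response (mode = peak_ms, SD ~ width_ms)."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    if peak_ms <= 0:
        return out
    r = peak_ms / max(width_ms, 1e-9)
    shape = (r * r + 2.0 + r * np.sqrt(r * r + 4.0)) / 2.0
    theta = peak_ms / (shape - 1.0)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1.0) * np.log(tp / peak_ms) + (peak_ms - tp) / theta)
    return out


def _insert_blinks(missing, rng, p, dt_ms, duration_ms):
    n_blinks = rng.poisson(p.blink_rate * duration_ms / 1000.0)
    n_samp = missing.shape[-1]
    for _ in range(n_blinks):
        start = int(rng.integers(0, n_samp))
        stop = min(n_samp, start + max(1, int(round(p.blink_dur_ms / dt_ms))))
        missing[start:stop] = True
    return missing


def simulate_pupil(trial: TrialSpec, p: ObserverParams, rng, observer_id=0,
                   dt_ms=1.0, lead_in_ms=500.0, tail_ms=2000.0,
                   timing: TrialTiming = TrialTiming()) -> PupilTrace:
    """Simulate the full 1 kHz pupil trace of one trial.

    The trace runs from ``lead_in_ms`` before the first grating to
    ``tail_ms`` after target onset.  Every grating (including penultimate
    and target) adds a dilation kernel; sequential targets add a surprise
    kernel scaled by ``pupil_surprise_gain * |violation|``.
    """
    soa = timing.soa_ms
    target_onset = (trial.n_gratings - 1) * soa
    t = np.arange(-lead_in_ms, target_onset + tail_ms + dt_ms / 2, dt_ms)
    n = len(t)
    drift = np.cumsum(rng.normal(0.0, p.pupil_drift_sd * np.sqrt(dt_ms / 1000.0), n))
    d = p.pupil_base + drift + rng.normal(0.0, p.pupil_noise_sd, n)
    for k in range(trial.n_gratings):
        d += p.pupil_event_amp * _gamma_kernel(t - k * soa, p.pupil_latency_ms,
                                               p.pupil_width_ms)
    if trial.condition == "sequential" and p.pupil_surprise_gain > 0:
        amp = p.pupil_surprise_gain * abs(trial.violation)
        d += amp * _gamma_kernel(t - target_onset, p.pupil_latency_ms,
                                 p.pupil_width_ms)
    missing = np.zeros(n, dtype=bool)
    _insert_blinks(missing, rng, p, dt_ms, t[-1] - t[0])
    d = np.where(missing, np.nan, d)
    return PupilTrace(observer_id, trial.trial_id, t, d, missing,
                      target_onset_ms=float(target_onset))


def simulate_pupil_epochs(design_frame: pd.DataFrame, p: ObserverParams, rng,
                          observer_id=0, dt_ms=1.0, t_start=-500.0,
                          t_end=1500.0,
                          timing: TrialTiming = TrialTiming()) -> EpochSet:
    """Vectorised epoch-window pupil simulation for a whole session.

    Generates only the target-locked window (default -500..1500 ms) for
    every trial at once — the signal content is identical to cutting the
    same window out of :func:`simulate_pupil` traces, with the random-walk
    drift re-anchored at the epoch start (the pre-onset baseline regression
    downstream removes the anchoring difference).
    """
    soa = timing.soa_ms
    t_rel = np.arange(t_start, t_end + dt_ms / 2, dt_ms)
    n_t = len(t_rel)
    df = design_frame
    n_trials = len(df)
    n_gratings = df["n_initial"].to_numpy() + 2
    seq = (df["condition"] == "sequential").to_numpy()
    violation = df["violation"].to_numpy(dtype=float)

    d = np.full((n_trials, n_t), p.pupil_base)
    d += np.cumsum(rng.normal(0.0, p.pupil_drift_sd * np.sqrt(dt_ms / 1000.0),
                              (n_trials, n_t)), axis=1)
    d += rng.normal(0.0, p.pupil_noise_sd, (n_trials, n_t))
    # grating events at -soa*k relative to target onset (k=0 is the target);
    # kernels from gratings before the window still rise into it
    kernel_span = p.pupil_latency_ms + 6.0 * p.pupil_width_ms
    max_k = int(np.ceil((kernel_span - t_start) / soa)) + 1
    for k in range(min(max_k, int(n_gratings.max()))):
        active = n_gratings > k
        kern = p.pupil_event_amp * _gamma_kernel(t_rel + k * soa,
                                                 p.pupil_latency_ms,
                                                 p.pupil_width_ms)
        if kern.any():
            d[active] += kern
    surprise = _gamma_kernel(t_rel, p.pupil_latency_ms, p.pupil_width_ms)
    amps = np.where(seq, p.pupil_surprise_gain * np.abs(violation), 0.0)
    d += amps[:, None] * surprise[None, :]

    missing = np.zeros((n_trials, n_t), dtype=bool)
    if p.blink_rate > 0:
        for i in range(n_trials):
            _insert_blinks(missing[i], rng, p, dt_ms, t_end - t_start)
    d = np.where(missing, np.nan, d)
    return EpochSet(observer_id, t_rel, d, missing,
                    conditions=df["condition"].to_numpy().astype(str),
                    violations=violation,
                    trial_ids=df["trial_id"].to_numpy())


# ---------------------------------------------------------------------------
# cohorts

#: Between-observer population SDs for each ObserverParams field.
DEFAULT_POPULATION_SDS = {
    "rt_base": 60.0, "rt_sigma": 30.0, "rt_shape": 0.05,
    "rt_pred_amp": 15.0, "rt_pred_width": 4.0, "rt_surprise_amp": 15.0,
    "rt_integration_amp": 10.0, "rt_integration_width": 4.0,
    "rt_len_slope": 2.0,
    "repro_sd_base": 1.5, "repro_sd_pred_amp": 0.7, "repro_sd_pred_width": 4.0,
    "repro_sd_surprise_amp": 0.7, "repro_sd_integration_amp": 0.5,
    "bias_amp": 0.7, "bias_width": 4.0,
    "lapse_rate": 0.09, "choice_noise_sd": 1.5,
    "pupil_base": 400.0, "pupil_drift_sd": 8.0, "pupil_noise_sd": 3.0,
    "pupil_event_amp": 8.0, "pupil_surprise_gain": 0.4,
    "pupil_latency_ms": 60.0, "pupil_width_ms": 60.0,
    "blink_rate": 0.05, "blink_dur_ms": 20.0,
}


#: Loadings of observer parameters on two latent individual-difference
#: factors: "g" (general performance: slow observers are also imprecise)
#: and "s" (prediction/surprise sensitivity: the behavioral and pupillary
#: consequences of expectation share a mechanism).  A loading L puts
#: fraction L of a parameter's population SD on the factor, inducing
#: between-observer correlations ~ L_i * L_j across measures.
LATENT_LOADINGS = {
    "rt_base": ("g", 0.8), "repro_sd_base": ("g", 0.8),
    "rt_surprise_amp": ("s", 0.7), "repro_sd_surprise_amp": ("s", 0.7),
    "pupil_surprise_gain": ("s", 0.7),
}


def _draw_observer_params(means: ObserverParams, sds: dict, rng,
                          latent=None) -> ObserverParams:
    """Truncated-normal draw of one observer's parameters.

    Each field is drawn from N(mean + loading*sd*factor, sd*sqrt(1-L^2))
    truncated to its admissible range (nonnegative; lapse_rate in
    [0, 0.5]) by rejection sampling; ``latent`` maps factor names to the
    observer's standard-normal factor scores (see LATENT_LOADINGS).
    """
    latent = latent or {}
    values = {}
    for f in dataclasses.fields(ObserverParams):
        mu = getattr(means, f.name)
        sd = float(sds.get(f.name, 0.0))
        if sd < 0:
            raise ValueError(f"population SD for {f.name} must be >= 0")
        lo, hi = (0.0, 0.5) if f.name == "lapse_rate" else (0.0, np.inf)
        factor, loading = LATENT_LOADINGS.get(f.name, (None, 0.0))
        if factor in latent:
            mu = mu + loading * sd * latent[factor]
            sd = sd * np.sqrt(1.0 - loading ** 2)
        if sd == 0:
            values[f.name] = float(np.clip(mu, lo, hi))
            continue
        for _ in range(1000):
            v = rng.normal(mu, sd)
            if lo <= v <= hi:
                break
        else:
            v = float(np.clip(mu, lo, hi))
        values[f.name] = float(v)
    return ObserverParams(**values)


@dataclass
class CohortData:
    """A simulated cohort: behavior table, pupil epochs, generating params."""

    behavior: pd.DataFrame
    epoch_sets: dict                 # observer_id -> EpochSet (raw), or {}
    params: pd.DataFrame             # generating parameters per observer
    seed: Optional[int] = None


def simulate_cohort(n_observers, seed=None, rng=None, design_factory=None,
                    design_kwargs=None, population_means=None,
                    population_sds=None, pupil=True, dt_ms=1.0,
                    t_start=-500.0, t_end=1500.0) -> CohortData:
    """Simulate a cohort of observers, each with a fresh session design.

    Per-observer parameters are drawn from a truncated-normal population
    around ``population_means`` (an :class:`ObserverParams`) with
    ``population_sds`` (dict; defaults :data:`DEFAULT_POPULATION_SDS`).
    Pupil data are generated as target-locked epoch matrices.
    """
    if n_observers < 2:
        raise ValueError("need at least 2 observers")
    if rng is None:
        rng = np.random.default_rng(seed)
    if design_factory is None:
        design_factory = generate_session_exp1
    design_kwargs = dict(design_kwargs or {})
    means = population_means or ObserverParams()
    sds = DEFAULT_POPULATION_SDS if population_sds is None else population_sds

    behav_frames, epoch_sets, param_rows = [], {}, []
    for obs in range(n_observers):
        latent = {"g": rng.standard_normal(), "s": rng.standard_normal()}
        p = _draw_observer_params(means, sds, rng, latent=latent)
        design = design_factory(rng=rng, **design_kwargs)
        frame = session_to_frame(design)
        behav_frames.append(simulate_behavior_frame(frame, p, rng, observer_id=obs))
        if pupil:
            epoch_sets[obs] = simulate_pupil_epochs(
                frame, p, rng, observer_id=obs, dt_ms=dt_ms,
                t_start=t_start, t_end=t_end, timing=design.timing)
        param_rows.append({"observer_id": obs, **dataclasses.asdict(p)})
    return CohortData(
        behavior=pd.concat(behav_frames, ignore_index=True),
        epoch_sets=epoch_sets,
        params=pd.DataFrame(param_rows),
        seed=seed,
    )
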