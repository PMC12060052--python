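"""Trial and session construction for the orientation expectation task.

A trial presents a rapid stream of gratings (250 ms each, 32 ms blank ISI):
an *initial sequence* of 5-12 gratings, then a *penultimate* grating, then
the *target*.  In the sequential condition the stream rotates consistently
by +-30 degrees per grating, establishing an expectation for the target
orientation (penultimate + 30 * direction); the randomly drawn target then
violates that expectation by a signed angle in (-90, 90].  In the random
condition every pre-target orientation is drawn independently and the
"expected" orientation is defined as the penultimate orientation, so that
both conditions can be binned on the same axis.

Sessions pair every sequential trial with a random trial sharing the same
penultimate and target orientations, so condition contrasts are not
confounded by the stimuli actually judged.

Experiment 2 adds spatial dynamics: the stream traverses an imaginary
circle (radius 6 deg of visual angle, 12.85 deg of polar angle per step),
and on half of the trials the target lands on a pre-cued cardinal axis
(valid cue) while on the other half it appears before reaching it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .circstats import axial_wrap, wrap_orientation

__all__ = [
    "ROTATION_STEP_DEG",
    "TrialTiming",
    "TrialSpec",
    "SessionDesign",
    "generate_trial",
    "generate_session_exp1",
    "generate_session_exp2",
    "session_to_frame",
    "write_session",
    "read_session",
]

ROTATION_STEP_DEG = 30.0
EXP2_STEP_DEG = 12.85
EXP2_RADIUS_DEG = 6.0
N_INITIAL_RANGE = (5, 12)

#: Cardinal cue axes mapped to polar angle (0 = right, counterclockwise +).
CUE_AXIS_POLAR = {"right": 0.0, "up": 90.0, "left": 180.0, "down": 270.0}


@dataclass(frozen=True)
class TrialTiming:
    grating_ms: int = 250
    isi_ms: int = 32
    speeded_window_ms: int = 2000

    @property
    def soa_ms(self) -> int:
        """Stimulus-onset asynchrony between successive gratings."""
        return self.grating_ms + self.isi_ms


@dataclass
class TrialSpec:
    """Full stimulus description of one trial."""

    trial_id: int
    condition: str  # "sequential" | "random"
    initial_orientations: list
    n_initial: int
    rotation_dir: int  # +1 / -1; 0 for random condition
    penultimate: float
    target: float
    expected: float
    violation: float  # signed, (-90, 90]
    block: int = 0
    # Experiment 2 fields (None for Experiment 1)
    positions: Optional[list] = None
    direction: Optional[int] = None
    cue_axis: Optional[str] = None
    cue_valid: Optional[bool] = None

    def __post_init__(self):
        if self.condition not in ("sequential", "random"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not (N_INITIAL_RANGE[0] <= self.n_initial <= N_INITIAL_RANGE[1]):
            raise ValueError(f"n_initial {self.n_initial} outside {N_INITIAL_RANGE}")
        if len(self.initial_orientations) != self.n_initial:
            raise ValueError("initial_orientations length mismatch")

    @property
    def n_gratings(self) -> int:
        """Total gratings shown: initial sequence + penultimate + target."""
        return self.n_initial + 2


@dataclass
class SessionDesign:
    trials: list
    n_blocks: int
    trials_per_block: int
    seed: Optional[int] = None
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __len__(self):
        return len(self.trials)


def _sequential_orientations(start: float, n: int, direction: int):
    """A +-30 deg staircase of n orientations from `start`."""
    return [wrap_orientation(start + direction * ROTATION_STEP_DEG * k) for k in range(n)]


def generate_trial(condition, n_initial, rotation_dir, rng, *,
                   trial_id=0, block=0, start=None, target=None,
                   penultimate=None, initial_orientations=None,
                   integer_degrees=False):
    """Build one :class:`TrialSpec`.

    Sequential trials form a ``rotation_dir * 30`` degree staircase from a
    random start; the penultimate grating continues the rotation and the
    expected target is one further step.  Random trials draw every
    orientation independently and define ``expected = penultimate``.

    ``start``, ``target``, ``penultimate`` and ``initial_orientations``
    override the random draws (used for matched-pair construction and
    tests).  ``integer_degrees`` snaps the target to the 1-180 degree grid.
    """
    n_initial = int(n_initial)
    if not (N_INITIAL_RANGE[0] <= n_initial <= N_INITIAL_RANGE[1]):
        raise ValueError(f"n_initial must be in {N_INITIAL_RANGE}, got {n_initial}")

    def draw_orientation():
        if integer_degrees:
            return float(rng.integers(1, 181)) % 180.0
        return float(rng.uniform(0.0, 180.0))

    if condition == "sequential":
        if rotation_dir not in (1, -1):
            raise ValueError("sequential trials need rotation_dir in {+1, -1}")
        if initial_orientations is None:
            s = draw_orientation() if start is None else wrap_orientation(start)
            initial_orientations = _sequential_orientations(s, n_initial, rotation_dir)
        if penultimate is None:
            penultimate = wrap_orientation(
                initial_orientations[-1] + rotation_dir * ROTATION_STEP_DEG
            )
        expected = wrap_orientation(penultimate + rotation_dir * ROTATION_STEP_DEG)
    elif condition == "random":
        rotation_dir = 0
        if initial_orientations is None:
            initial_orientations = [draw_orientation() for _ in range(n_initial)]
        if penultimate is None:
            penultimate = draw_orientation()
        expected = float(penultimate)
    else:
        raise ValueError(f"unknown condition {condition!r}")

    if target is None:
        target = draw_orientation()
    target = wrap_orientation(target)
    violation = axial_wrap(target - expected)
    return TrialSpec(
        trial_id=trial_id, condition=condition,
        initial_orientations=list(initial_orientations), n_initial=n_initial,
        rotation_dir=rotation_dir, penultimate=float(penultimate),
        target=float(target), expected=float(expected),
        violation=float(violation), block=block,
    )


def _counterbalanced_cells(n_trials, rng):
    """(n_initial, rotation_dir) cells repeated to cover n_trials, shuffled."""
    lengths = range(N_INITIAL_RANGE[0], N_INITIAL_RANGE[1] + 1)
    cells = [(n, d) for n in lengths for d in (1, -1)]
    if n_trials % len(cells) != 0:
        raise ValueError(
            f"cannot counterbalance {n_trials} sequential trials over "
            f"{len(cells)} (length x direction) cells"
        )
    reps = n_trials // len(cells)
    out = cells * reps
    rng.shuffle(out)
    return out


def generate_session_exp1(n_blocks=16, trials_per_block=24, seed=None, rng=None,
                          integer_degrees=False):
    """Generate an Experiment-1 session.

    Defaults give 384 trials (24 x 16), 192 per condition, sequence length
    (5-12) and rotation direction (+-) counterbalanced over the sequential
    trials, and every sequential trial matched by a random trial with the
    same penultimate and target orientations.  Condition order is
    pseudorandom (shuffled) within each block.
    """
    if trials_per_block % 2 != 0:
        raise ValueError("trials_per_block must be even (half per condition)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_trials = n_blocks * trials_per_block
    n_pairs = n_trials // 2
    cells = _counterbalanced_cells(n_pairs, rng)
    # random-condition sequence lengths get their own counterbalanced set
    rand_cells = _counterbalanced_cells(n_pairs, rng)

    pairs = []
    for (n_init, rot), (n_init_r, _) in zip(cells, rand_cells):
        seq = generate_trial("sequential", n_init, rot, rng,
                             integer_degrees=integer_degrees)
        rnd = generate_trial("random", n_init_r, 0, rng,
                             penultimate=seq.penultimate, target=seq.target,
                             integer_degrees=integer_degrees)
        pairs.append((seq, rnd))

    # interleave pseudorandomly: half of each block's slots per condition
    trials = []
    per_cond = trials_per_block // 2
    order_pool = [t for pair in pairs for t in pair]
    rng.shuffle(order_pool)
    seq_pool = [t for t in order_pool if t.condition == "sequential"]
    rnd_pool = [t for t in order_pool if t.condition == "random"]
    tid = 0
    for b in range(n_blocks):
        block_trials = (seq_pool[b * per_cond:(b + 1) * per_cond]
                        + rnd_pool[b * per_cond:(b + 1) * per_cond])
        rng.shuffle(block_trials)
        for t in block_trials:
            t.trial_id = tid
            t.block = b
            tid += 1
            trials.append(t)
    return SessionDesign(trials=trials, n_blocks=n_blocks,
                         trials_per_block=trials_per_block, seed=seed)


def _exp2_positions(n_gratings, target_polar, direction, step=EXP2_STEP_DEG):
    """Polar angles of the gratings, ending at target_polar, stepping by
    `direction * step` per grating."""
    idx = np.arange(n_gratings)
    angles = target_polar - direction * step * (n_gratings - 1 - idx)
    return [float(a % 360.0) for a in angles]


def generate_session_exp2(n_blocks=48, trials_per_block=24, seed=None, rng=None,
                          integer_degrees=False):
    """Generate an Experiment-2 session (spatially dynamic streams).

    Per block: the cue axis is one cardinal direction (fixed within block,
    randomised between blocks); half of the trials are validly cued (target
    lands on the cue axis), half invalidly cued (target appears 1-4 steps
    before the stream reaches the axis).  Condition structure, matching and
    counterbalancing follow Experiment 1.
    """
    if not (48 <= n_blocks <= 60):
        raise ValueError("Experiment 2 uses between 48 and 60 blocks")
    if trials_per_block % 4 != 0:
        raise ValueError("trials_per_block must be divisible by 4 "
                         "(condition x cue-validity split)")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_pairs = n_blocks * trials_per_block // 2
    lengths = range(N_INITIAL_RANGE[0], N_INITIAL_RANGE[1] + 1)
    cells = [(n, d) for n in lengths for d in (1, -1)]
    cell_seq = (cells * (n_pairs // len(cells) + 1))[:n_pairs]
    rng.shuffle(cell_seq)

    trials = []
    tid = 0
    pair_idx = 0
    per_quarter = trials_per_block // 4
    for b in range(n_blocks):
        cue_axis = str(rng.choice(list(CUE_AXIS_POLAR)))
        cue_polar = CUE_AXIS_POLAR[cue_axis]
        block_trials = []
        for valid in (True, False):
            for _ in range(per_quarter):
                n_init, rot = cell_seq[pair_idx]
                pair_idx += 1
                direction = int(rng.choice([1, -1]))
                seq = generate_trial("sequential", n_init, rot, rng,
                                     integer_degrees=integer_degrees)
                rnd = generate_trial("random", n_init, 0, rng,
                                     penultimate=seq.penultimate,
                                     target=seq.target,
                                     integer_degrees=integer_degrees)
                for t in (seq, rnd):
                    if valid:
                        target_polar = cue_polar
                    else:
                        # target shown 1-4 steps before reaching the cue axis
                        steps_short = int(rng.integers(1, 5))
                        target_polar = (cue_polar
                                        - direction * EXP2_STEP_DEG * steps_short) % 360.0
                    t.positions = _exp2_positions(t.n_gratings, target_polar, direction)
                    t.direction = direction
                    t.cue_axis = cue_axis
                    t.cue_valid = valid
                    block_trials.append(t)
        rng.shuffle(block_trials)
        for t in block_trials:
            t.trial_id = tid
            t.block = b
            tid += 1
            trials.append(t)
    return SessionDesign(trials=trials, n_blocks=n_blocks,
                         trials_per_block=trials_per_block, seed=seed)


# ---------------------------------------------------------------------------
# serialization: long-format delimited tables, one row per trial


def _join(values):
    return ";".join(f"{v:.6f}" for v in values)


def session_to_frame(design: SessionDesign) -> pd.DataFrame:
    rows = []
    for t in design.trials:
        row = {
            "trial_id": t.trial_id,
            "block": t.block,
            "condition": t.condition,
            "n_initial": t.n_initial,
            "rotation_dir": t.rotation_dir,
            "initial_orientations": _join(t.initial_orientations),
            "penultimate": t.penultimate,
            "target": t.target,
            "expected": t.expected,
            "violation": t.violation,
        }
        if t.positions is not None:
            row.update(positions=_join(t.positions), direction=t.direction,
                       cue_axis=t.cue_axis, cue_valid=t.cue_valid)
        rows.append(row)
    return pd.DataFrame(rows)


def write_session(design: SessionDesign, path):
    """Write a session as a commented-header TSV (seed + timing recorded)."""
    frame = session_to_frame(design)
    timing = design.timing
    header = (
        f"# expviol session v1\n"
        f"# seed={design.seed}\n"
        f"# n_blocks={design.n_blocks} trials_per_block={design.trials_per_block}\n"
        f"# grating_ms={timing.grating_ms} isi_ms={timing.isi_ms} "
        f"speeded_window_ms={timing.speeded_window_ms}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)


def read_session(path) -> SessionDesign:
    meta = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
            else:
                lines.append(line)
    frame = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
    trials = []
    for _, r in frame.iterrows():
        has_exp2 = "positions" in frame.columns and pd.notna(r.get("positions"))
        trials.append(TrialSpec(
            trial_id=int(r.trial_id), condition=r.condition,
            initial_orientations=[float(x) for x in str(r.initial_orientations).split(";")],
            n_initial=int(r.n_initial), rotation_dir=int(r.rotation_dir),
            penultimate=float(r.penultimate), target=float(r.target),
            expected=float(r.expected), violation=float(r.violation),
            block=int(r.block),
            positions=([float(x) for x in str(r.positions).split(";")] if has_exp2 else None),
            direction=(int(r.direction) if has_exp2 else None),
            cue_axis=(r.cue_axis if has_exp2 else None),
            cue_valid=(bool(r.cue_valid) if has_exp2 else None),
        ))
    seed = meta.get("seed")
    return SessionDesign(
        trials=trials,
        n_blocks=int(meta.get("n_blocks", 0)),
        trials_per_block=int(meta.get("trials_per_block", 0)),
        seed=None if seed in (None, "None") else int(seed),
    )
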