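"""Behavioral task schedules for the three saccade paradigms.

Task 1 is a slow event-related pro/antisaccade task: each trial presents a
central fixation dot, a colored cue 3 s later instructing a pro- or
antisaccade, a peripheral target 3 s after the cue (at 3.8 deg or 14.8 deg,
left or right), and a step back to center 6 s after the target.  Every
nominal event time receives an independent uniform jitter of +/-500 ms to
reduce predictability.  Trials run back to back with no rest, giving a mean
inter-saccade interval of about 6 s.

Task 2 alternates 20 s blocks of rapid visual stimulation (under fixation)
with 20 s rest blocks, 12 cycles, for an 8 minute run.

Task 3 cycles 20 s blocks of self-paced horizontal saccades, vertical
saccades and fixation, in darkness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sides and amplitudes of the peripheral target.  The side letter encodes
#: the *saccade direction*: for antisaccades the target appears in the
#: opposite hemifield, so ``target_L_small_anti`` means a leftward
#: antisaccade to a target shown on the right.
SIDES = ("L", "R")
AMPLITUDES = ("small", "large")
TASKS = ("pro", "anti")

#: Visual angles (degrees) of the two target amplitudes.
AMPLITUDE_DEG = {"small": 3.8, "large": 14.8}

#: Nominal within-trial epochs (seconds): fixation -> cue -> target -> return.
FIX_TO_CUE = 3.0
CUE_TO_TARGET = 3.0
TARGET_TO_RETURN = 6.0
TRIAL_LENGTH = FIX_TO_CUE + CUE_TO_TARGET + TARGET_TO_RETURN

#: Block length (seconds) shared by tasks 2 and 3.
BLOCK_S = 20.0

EVENT_VOCABULARY = (
    ["fix", "cue_pro", "cue_anti"]
    + [f"target_{s}_{a}_{t}" for t in TASKS for s in SIDES for a in AMPLITUDES]
    + [f"return_{s}_{a}" for s in SIDES for a in AMPLITUDES]
)


@dataclass
class EventSchedule:
    """Timed, labeled events for one event-related run."""

    events: pd.DataFrame  # columns: onset, nominal_onset, duration, trial_type, jitter
    run_duration: float

    def __post_init__(self) -> None:
        bad = set(self.events["trial_type"]) - set(EVENT_VOCABULARY)
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")
        if np.any(np.abs(self.events["jitter"].to_numpy()) > 0.5 + 1e-12):
            raise ValueError("event jitter exceeds +/-0.5 s")

    def onsets(self, labels) -> np.ndarray:
        """Realized onsets (s) of all events whose label is in *labels*."""
        if isinstance(labels, str):
            labels = [labels]
        m = self.events["trial_type"].isin(labels)
        return self.events.loc[m, "onset"].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, run_duration: float | None = None) -> "EventSchedule":
        df = pd.read_csv(path, sep="\t")
        if run_duration is None:
            run_duration = float(df["onset"].max()) + TARGET_TO_RETURN
        return cls(events=df, run_duration=run_duration)


@dataclass
class BlockSchedule:
    """Contiguous, non-overlapping blocks for a blocked run."""

    blocks: pd.DataFrame  # columns: onset, duration, trial_type
    run_duration: float

    def __post_init__(self) -> None:
        b = self.blocks
        if np.any(b["duration"].to_numpy() <= 0):
            raise ValueError("block durations must be positive")
        ends = b["onset"].to_numpy() + b["duration"].to_numpy()
        if not np.allclose(ends[:-1], b["onset"].to_numpy()[1:]):
            raise ValueError("blocks must be contiguous and non-overlapping")

    def to_tsv(self, path) -> None:
        self.blocks.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BlockSchedule":
        df = pd.read_csv(path, sep="\t")
        dur = float(df["onset"].iloc[-1] + df["duration"].iloc[-1])
        return cls(blocks=df, run_duration=dur)


# Prefix order for the trial-condition factors (anti?, right?, large?) such
# that every prefix keeps each factor's level counts within 1 of balance.
_BALANCED_PREFIX = [
    (0, 0, 0), (1, 1, 1), (0, 1, 1), (1, 0, 0),
    (1, 0, 1), (0, 1, 0), (1, 1, 0), (0, 0, 1),
]


def _trial_conditions(n_trials: int, rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Balanced, shuffled (task, side, amplitude) triples."""
    full, rem = divmod(n_trials, 8)
    combos = _BALANCED_PREFIX * full + _BALANCED_PREFIX[:rem]
    conds = [(TASKS[a], SIDES[r], AMPLITUDES[l]) for a, r, l in combos]
    rng.shuffle(conds)
    return conds


def build_task1_schedule(
    n_trials: int,
    seed: int,
    jitter: bool = True,
    jitter_half_width: float = 0.5,
) -> EventSchedule:
    """Event-related pro/antisaccade schedule (task 1).

    Each 12 s trial is fixation (0 s), cue (+3 s), peripheral target
    (+6 s) and return step (+12 s == next trial's fixation - the return
    event is the reappearing fixation dot).  Every nominal time gets an
    independent uniform jitter on [-jitter_half_width, +jitter_half_width]
    when *jitter* is enabled.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    conds = _trial_conditions(n_trials, rng)
    rows = []
    for i, (task, side, amp) in enumerate(conds):
        t0 = i * TRIAL_LENGTH
        nominal = {
            "fix": t0,
            f"cue_{task}": t0 + FIX_TO_CUE,
            f"target_{side}_{amp}_{task}": t0 + FIX_TO_CUE + CUE_TO_TARGET,
            f"return_{side}_{amp}": t0 + TRIAL_LENGTH,
        }
        for label, t_nom in nominal.items():
            j = rng.uniform(-jitter_half_width, jitter_half_width) if jitter else 0.0
            rows.append(
                {"onset": t_nom + j, "nominal_onset": t_nom, "duration": 0.0,
                 "trial_type": label, "jitter": j}
            )
    df = pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)
    return EventSchedule(events=df, run_duration=n_trials * TRIAL_LENGTH)


def build_task2_schedule(n_cycles: int = 12, block_s: float = BLOCK_S) -> BlockSchedule:
    """Blocked visual-stimulation task: n_cycles x (20 s stim + 20 s rest)."""
    rows = []
    for i in range(n_cycles):
        rows.append({"onset": i * 2 * block_s, "duration": block_s, "trial_type": "stim"})
        rows.append({"onset": i * 2 * block_s + block_s, "duration": block_s, "trial_type": "rest"})
    return BlockSchedule(blocks=pd.DataFrame(rows), run_duration=n_cycles * 2 * block_s)


def build_task3_schedule(total_duration: float = 900.0, block_s: float = BLOCK_S) -> BlockSchedule:
    """Saccades-in-darkness task: cycles of horizontal / vertical / fixation."""
    cycle = 3 * block_s
    if total_duration <= 0 or abs(total_duration / cycle - round(total_duration / cycle)) > 1e-9:
        raise ValueError(f"total_duration must be a positive multiple of {cycle:.0f} s")
    n_cycles = int(round(total_duration / cycle))
    rows = []
    for i in range(n_cycles):
        for k, label in enumerate(("horizontal", "vertical", "fixation")):
            rows.append({"onset": i * cycle + k * block_s, "duration": block_s, "trial_type": label})
    return BlockSchedule(blocks=pd.DataFrame(rows), run_duration=total_duration)
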