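"""n-back paradigm timing: blocks, trials, letters, targets.

The task is a letter n-back with three load conditions (0-back, 1-back,
2-back), each presented in two blocks of 100 trials.  A trial shows one
consonant for 500 ms, followed by a blank inter-trial interval drawn
uniformly from 1000-2000 ms.  Half the trials in every block are targets:
in 0-back the target is the letter 'x', in 1-back a letter equal to the
previous one, in 2-back a letter equal to the one two trials back (case
is ignored throughout).  The same schedule drives both the simulator and
the GLM design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("0back", "1back", "2back")

#: 18 Dutch consonants used as stimuli (alphabet minus vowels, Q, Y and J).
LETTERS = tuple("BCDFGHKLMNPRSTVWXZ")

ZERO_BACK_TARGET = "X"


@dataclass(frozen=True)
class Trial:
    onset: float          # seconds from run start
    letter: str           # upper-case identity
    case: str             # "upper" | "lower"
    is_target: bool
    condition: str
    duration: float = 0.5


@dataclass(frozen=True)
class Block:
    condition: str
    onset: float
    trials: tuple[Trial, ...]


@dataclass(frozen=True)
class TaskSchedule:
    blocks: tuple[Block, ...]
    tr_seconds: float
    n_scans: int

    @property
    def trials(self) -> tuple[Trial, ...]:
        return tuple(t for b in self.blocks for t in b.trials)

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr_seconds

    def to_events_frame(self) -> pd.DataFrame:
        """Events table with columns onset, duration, trial_type."""
        rows = [(t.onset, t.duration, t.condition) for t in self.trials]
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


def _nback_letters(rng: np.random.Generator, n_trials: int, n: int,
                   target_idx: set[int]) -> list[tuple[str, bool]]:
    """Letter stream for an n-back block with ground-truth targets.

    Targets copy the referent letter; non-targets are constrained to
    differ from their referent so is_target is the unique truth.
    """
    letters: list[str] = []
    for i in range(n_trials):
        if n == 0:
            if i in target_idx:
                letters.append(ZERO_BACK_TARGET)
            else:
                pool = [c for c in LETTERS if c != ZERO_BACK_TARGET]
                letters.append(pool[rng.integers(len(pool))])
        else:
            referent = letters[i - n] if i >= n else None
            if i in target_idx:
                assert referent is not None
                letters.append(referent)
            else:
                pool = [c for c in LETTERS if c != referent]
                letters.append(pool[rng.integers(len(pool))])
    return [(ltr, i in target_idx) for i, ltr in enumerate(letters)]


def _make_block(rng: np.random.Generator, condition: str, onset: float,
                n_trials: int, target_fraction: float,
                stim_duration: float, iti_range: tuple[float, float]) -> Block:
    n = int(condition[0])
    n_targets = round(n_trials * target_fraction)
    eligible = list(range(n, n_trials))  # first n trials have no referent
    if n_targets > len(eligible):
        raise ValueError(
            f"cannot place {n_targets} targets in a {n_trials}-trial "
            f"{condition} block (only {len(eligible)} eligible positions)"
        )
    target_idx = set(rng.choice(eligible, size=n_targets, replace=False).tolist())
    stream = _nback_letters(rng, n_trials, n, target_idx)

    trials = []
    t = onset
    for letter, is_target in stream:
        case = "upper" if rng.random() < 0.5 else "lower"
        trials.append(Trial(onset=round(t, 6), letter=letter, case=case,
                            is_target=is_target, condition=condition,
                            duration=stim_duration))
        iti = rng.uniform(*iti_range)
        t += stim_duration + iti
    return Block(condition=condition, onset=onset, trials=tuple(trials))


def build_schedule(
    seed: int,
    *,
    trials_per_block: int = 100,
    target_fraction: float = 0.5,
    stim_duration: float = 0.5,
    iti_range: tuple[float, float] = (1.0, 2.0),
    rest_duration: float = 20.0,
    tr_seconds: float = 2.0,
) -> TaskSchedule:
    """Build a full six-block schedule.

    Block order is semi-randomized: each condition appears exactly once in
    the first three blocks and once in the last three.  Blocks are
    separated by ``rest_duration`` seconds of instruction/rest, which is
    the implicit baseline the task regressors are contrasted against.
    Targets occupy exactly ``target_fraction`` of each block's trials.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if iti_range[0] > iti_range[1] or iti_range[0] < 0:
        raise ValueError("invalid ITI range")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(CONDITIONS)) + list(rng.permutation(CONDITIONS))

    blocks = []
    t = rest_duration
    for condition in order:
        block = _make_block(rng, condition, t, trials_per_block,
                            target_fraction, stim_duration, iti_range)
        blocks.append(block)
        last = block.trials[-1]
        t = last.onset + last.duration + rng.uniform(*iti_range) + rest_duration
    n_scans = int(np.ceil(t / tr_seconds))
    return TaskSchedule(blocks=tuple(blocks), tr_seconds=tr_seconds,
                        n_scans=n_scans)


def condition_onsets(schedule: TaskSchedule) -> dict[str, np.ndarray]:
    """Per-condition trial onsets (seconds) for design construction.

    Every trial event is included — incorrect responses are not excluded
    from the regressors.
    """
    out: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for trial in schedule.trials:
        out[trial.condition].append(trial.onset)
    return {c: np.asarray(v, dtype=float) for c, v in out.items()}


def verify_nback_rule(schedule: TaskSchedule) -> bool:
    """Replay the n-back rule over every block's letter stream.

    Returns True iff the is_target flags agree with the rule everywhere
    (targets match their referent, non-targets do not).
    """
    for block in schedule.blocks:
        n = int(block.condition[0])
        letters = [t.letter.upper() for t in block.trials]
        for i, trial in enumerate(block.trials):
            if n == 0:
                rule = letters[i] == ZERO_BACK_TARGET
            else:
                rule = i >= n and letters[i] == letters[i - n]
            if rule != trial.is_target:
                return False
    return True
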