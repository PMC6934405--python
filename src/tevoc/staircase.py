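"""Adaptive 3I-3AFC staircase tracks and session schedules.

Each track adjusts a task-specific difficulty level multiplicatively:

* **AMD** (amplitude-modulation detection): level is the modulation
  depth ``m``, starting at 1.0 (full modulation, which is also the cap).
  Phase-1 step factor 1.58 (4 dB), phase-2 factor 1.26 (2 dB).
* **AMRD** (AM-rate discrimination): level is the rate increment
  ``Δfm`` in Hz above the block's standard rate, starting at 50 % of the
  standard (4 Hz for an 8-Hz standard).  Steps 1.4 then √1.4.
* **FD** (frequency discrimination): level is ``Δf`` as a percentage of
  the 800-Hz standard, starting at 50 %.  Steps 2 then √2.

All tracks begin with a one-down/one-up rule (phase 1).  The first
incorrect response permanently switches the track to a three-down/one-up
rule with the smaller step (phase 2), which converges on the level where
the psychometric function passes through 0.5^(1/3) ≈ 79.4 % correct.
Levels are clamped to [floor, cap]; tracks never terminate early.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "StaircaseConfig",
    "Trial",
    "Track",
    "Schedule",
    "ScheduleBlock",
    "next_level",
    "run_trial",
    "run_track",
    "count_reversals",
    "build_schedule",
    "converged_performance",
    "TRAINING_FM_SET",
]

TRAINING_FM_SET = (4.0, 8.0, 16.0)

# 3-down/1-up tracks the level where p(correct) = 0.5^(1/3)
TARGET_P = 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class StaircaseConfig:
    """Rules of one adaptive track.

    ``phase2_down`` is the number of consecutive correct responses
    required for a level decrease in phase 2 (3 in the standard
    procedure; 1 gives a plain one-down/one-up track for comparison with
    up-down theory).  ``start_phase=2`` begins directly in phase 2, which
    is useful for steady-state analyses.
    """

    task: str = "AMD"
    start_level: float = 1.0
    phase1_step: float = 1.58
    phase2_step: float = 1.26
    phase2_down: int = 3
    n_trials: int = 30
    level_floor: float = 1e-3
    level_cap: float = 1.0
    n_intervals: int = 3
    n_practice: int = 0
    start_phase: int = 1
    fm_standard: float = 8.0  # Hz; AM tasks' standard modulation rate

    def __post_init__(self) -> None:
        if self.phase1_step <= 1 or self.phase2_step <= 1:
            raise ValueError("step factors must exceed 1")
        if not 0 < self.level_floor < self.level_cap:
            raise ValueError("require 0 < level_floor < level_cap")
        if self.n_trials < 1 or self.phase2_down < 1:
            raise ValueError("n_trials and phase2_down must be >= 1")
        if self.start_phase not in (1, 2):
            raise ValueError("start_phase must be 1 or 2")

    @classmethod
    def for_task(cls, task: str, n_trials: int = 30, fm_standard: float = 8.0,
                 n_practice: int = 0) -> "StaircaseConfig":
        """Canonical configuration for AMD, AMRD or FD.

        AMRD's level is Δfm in Hz: start = 50 % of the standard, cap =
        the standard itself.  FD's level is Δf in percent of 800 Hz:
        start = 50 %, cap = 100 %.
        """
        task = task.upper()
        if task == "AMD":
            return cls(task="AMD", start_level=1.0, phase1_step=1.58,
                       phase2_step=1.26, level_floor=1e-3, level_cap=1.0,
                       n_trials=n_trials, n_practice=n_practice,
                       fm_standard=fm_standard)
        if task == "AMRD":
            return cls(task="AMRD", start_level=0.5 * fm_standard,
                       phase1_step=1.4, phase2_step=math.sqrt(1.4),
                       level_floor=1e-3 * fm_standard, level_cap=fm_standard,
                       n_trials=n_trials, n_practice=n_practice,
                       fm_standard=fm_standard)
        if task == "FD":
            return cls(task="FD", start_level=50.0, phase1_step=2.0,
                       phase2_step=math.sqrt(2.0), level_floor=0.05,
                       level_cap=100.0, n_trials=n_trials,
                       n_practice=n_practice, fm_standard=fm_standard)
        raise ValueError(f"unknown task: {task!r}")


@dataclass(frozen=True)
class Trial:
    index: int
    level: float
    target_interval: int
    response_interval: int
    correct: bool
    phase: int
    direction: str  # "up" | "down" | "hold"
    reversal: bool = False
    practice: bool = False

    def __post_init__(self) -> None:
        if self.target_interval not in (1, 2, 3) or self.response_interval not in (1, 2, 3):
            raise ValueError("intervals must be 1..3")


@dataclass(frozen=True)
class Track:
    """An adaptive track: its rules, trial records, and seed."""

    config: StaircaseConfig
    trials: tuple[Trial, ...]
    seed: int | None = None

    @property
    def n_reversals(self) -> int:
        return count_reversals(self)

    def levels(self, include_practice: bool = False) -> np.ndarray:
        return np.array([t.level for t in self.trials
                         if include_practice or not t.practice])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": [t.index for t in self.trials],
            "level": [t.level for t in self.trials],
            "phase": [t.phase for t in self.trials],
            "target": [t.target_interval for t in self.trials],
            "response": [t.response_interval for t in self.trials],
            "correct": [int(t.correct) for t in self.trials],
            "reversal": [int(t.reversal) for t in self.trials],
            "practice": [int(t.practice) for t in self.trials],
        })


def _clamp(level: float, cfg: StaircaseConfig) -> float:
    return min(max(level, cfg.level_floor), cfg.level_cap)


def _trailing_correct_run(trials) -> int:
    """Consecutive correct phase-2 responses at the end of the track."""
    run = 0
    for t in reversed(trials):
        if t.phase != 2 or not t.correct:
            break
        run += 1
    return run


def _decide_move(trials, cfg: StaircaseConfig) -> tuple[str, float]:
    """Direction and step factor implied by the last (adaptive) trial.

    Phase 1 is one-down/one-up with the large step; the incorrect
    response that triggers the phase switch still moves by the phase-1
    factor.  Phase 2 decreases the level only after ``phase2_down``
    consecutive correct responses (the counter restarts after every level
    change, so a decrease happens exactly when the trailing correct run
    is a positive multiple of ``phase2_down``), and increases it on any
    incorrect response.
    """
    last = trials[-1]
    if last.phase == 1:
        return ("down" if last.correct else "up"), cfg.phase1_step
    if not last.correct:
        return "up", cfg.phase2_step
    run = _trailing_correct_run(trials)
    if run > 0 and run % cfg.phase2_down == 0:
        return "down", cfg.phase2_step
    return "hold", cfg.phase2_step


def next_level(track: Track, cfg: StaircaseConfig | None = None) -> float:
    """Level for the next trial implied by the track so far (clamped)."""
    cfg = cfg or track.config
    trials = [t for t in track.trials if not t.practice]
    if not trials:
        return _clamp(cfg.start_level, cfg)
    direction, step = _decide_move(trials, cfg)
    level = trials[-1].level
    if direction == "down":
        level /= step
    elif direction == "up":
        level *= step
    return _clamp(level, cfg)


def run_trial(level: float, observer, rng: np.random.Generator,
              n_intervals: int = 3) -> tuple[int, int, bool]:
    """Simulate one oddball trial: returns (target, response, correct).

    The target interval is uniform over 1..n_intervals; the observer
    answers correctly with its psychometric probability at *level*,
    otherwise picks one of the remaining intervals uniformly.  Draw
    order (target, correctness, distractor) is fixed for reproducibility.
    """
    target = int(rng.integers(1, n_intervals + 1))
    p = observer.p_correct(level)
    correct = bool(rng.random() < p)
    if correct:
        response = target
    else:
        others = [i for i in range(1, n_intervals + 1) if i != target]
        response = int(others[rng.integers(0, len(others))])
    return target, response, correct


def run_track(cfg: StaircaseConfig, observer, seed: int | None = None,
              rng: np.random.Generator | None = None) -> Track:
    """Run a full adaptive track against a simulated observer.

    Practice trials (``cfg.n_practice``), if any, precede the adaptive
    run at fixed levels — "easy" at the start level and "impossible" at
    the floor, in a 3-easy/2-impossible pattern for the canonical 5 —
    and are flagged ``practice`` (excluded from analysis and stepping).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trials: list[Trial] = []

    for i in range(cfg.n_practice):
        easy = i < math.ceil(cfg.n_practice * 3 / 5)
        lvl = _clamp(cfg.start_level, cfg) if easy else cfg.level_floor
        target, response, correct = run_trial(lvl, observer, rng, cfg.n_intervals)
        trials.append(Trial(index=len(trials), level=lvl, target_interval=target,
                            response_interval=response, correct=correct,
                            phase=0, direction="hold", practice=True))

    phase = cfg.start_phase
    level = _clamp(cfg.start_level, cfg)
    adaptive: list[Trial] = []
    last_move: str | None = None
    for i in range(cfg.n_trials):
        target, response, correct = run_trial(level, observer, rng, cfg.n_intervals)
        adaptive.append(Trial(index=len(trials) + i, level=level,
                              target_interval=target, response_interval=response,
                              correct=correct, phase=phase, direction="hold"))
        direction, step = _decide_move(adaptive, cfg)
        reversal = direction != "hold" and last_move is not None and direction != last_move
        adaptive[-1] = replace(adaptive[-1], direction=direction, reversal=reversal)
        if direction == "down":
            level = _clamp(level / step, cfg)
            last_move = "down"
        elif direction == "up":
            level = _clamp(level * step, cfg)
            last_move = "up"
        if phase == 1 and not correct:
            phase = 2
    return Track(config=cfg, trials=tuple(trials + adaptive), seed=seed)


def count_reversals(track: Track) -> int:
    """Number of direction changes among level moves (holds ignored)."""
    moves = [t.direction for t in track.trials
             if not t.practice and t.direction != "hold"]
    return sum(1 for a, b in zip(moves, moves[1:]) if a != b)


@dataclass(frozen=True)
class ScheduleBlock:
    day: int
    task: str           # AMD | AMRD | FD | VCV
    fm_standard: float | None
    block: int          # 1-based within the protocol
    n_trials: int
    feedback: bool = True


@dataclass(frozen=True)
class Schedule:
    protocol: str
    blocks: tuple[ScheduleBlock, ...]

    @property
    def total_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def fm_sequence(self) -> list[float]:
        return [b.fm_standard for b in self.blocks if b.fm_standard is not None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.blocks])


def _latin_row(row_index: int) -> tuple[float, ...]:
    """One row of the cyclic 3x3 Latin square over the training rates."""
    k = row_index % 3
    return tuple(TRAINING_FM_SET[(k + j) % 3] for j in range(3))


def build_schedule(protocol: str, fm_row: int = 0) -> Schedule:
    """Block schedule for one protocol phase.

    * ``pretraining`` — 2 blocks x 60 vocoded-VCV identification trials
      with feedback (day 1).
    * ``pretest`` / ``posttest`` — 1 block x 60 VCV without feedback plus
      2 blocks x 30 adaptive trials on each of AMD, AMRD (8-Hz standard)
      and FD (days 2 and 4).
    * ``training_AMD`` / ``training_AMRD`` — 21 blocks x 60 trials, 9 on
      day 2 and 12 on day 3; the standard modulation rate rotates
      through 4, 8 and 16 Hz block by block following the Latin-square
      row selected by ``fm_row`` (each participant gets one row, cycled,
      so every 3 consecutive blocks cover each rate once).
    """
    blocks: list[ScheduleBlock] = []
    if protocol == "pretraining":
        for b in range(2):
            blocks.append(ScheduleBlock(day=1, task="VCV", fm_standard=None,
                                        block=b + 1, n_trials=60, feedback=True))
    elif protocol in ("pretest", "posttest"):
        day = 2 if protocol == "pretest" else 4
        blocks.append(ScheduleBlock(day=day, task="VCV", fm_standard=None,
                                    block=1, n_trials=60, feedback=False))
        i = 1
        for task in ("AMD", "AMRD", "FD"):
            fm = 8.0 if task in ("AMD", "AMRD") else None
            for _ in range(2):
                i += 1
                blocks.append(ScheduleBlock(day=day, task=task, fm_standard=fm,
                                            block=i, n_trials=30, feedback=True))
    elif protocol in ("training_AMD", "training_AMRD"):
        task = "AMD" if protocol.endswith("AMD") else "AMRD"
        row = _latin_row(fm_row)
        for b in range(21):
            day = 2 if b < 9 else 3
            blocks.append(ScheduleBlock(day=day, task=task,
                                        fm_standard=row[b % 3],
                                        block=b + 1, n_trials=60, feedback=True))
    else:
        raise ValueError(f"unknown protocol: {protocol!r}")
    return Schedule(protocol=protocol, blocks=tuple(blocks))


def converged_performance(cfg: StaircaseConfig, observer, n_tracks: int = 500,
                          seed: int = 0, tail: int = 20) -> tuple[float, float]:
    """Asymptotic proportion correct tracked by the staircase.

    Runs *n_tracks* independent tracks and evaluates the observer's true
    psychometric probability at the levels visited in the final *tail*
    trials of each; returns (mean, standard error over tracks).  For a
    three-down/one-up phase 2 with small steps this approaches
    0.5^(1/3) ≈ 0.794; for a one-down/one-up rule it approaches 0.5.
    """
    if cfg.n_trials < 2 * tail:
        import warnings
        warnings.warn("few trials relative to the evaluation tail; "
                      "converged-performance estimate may be biased by burn-in",
                      stacklevel=2)
    seeds = np.random.SeedSequence(seed).spawn(n_tracks)
    track_means = np.empty(n_tracks)
    for k, ss in enumerate(seeds):
        track = run_track(cfg, observer, rng=np.random.default_rng(ss))
        levels = track.levels()[-tail:]
        track_means[k] = float(np.mean([observer.p_correct(lv) for lv in levels]))
    return float(track_means.mean()), float(track_means.std(ddof=1) / np.sqrt(n_tracks))
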