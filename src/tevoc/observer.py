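"""Simulated observers and synthetic study generation.

This module stands in for the human listeners: it provides (a) a
parametric psychometric observer for the adaptive tasks, (b) a
vowel-consonant-vowel (VCV) identification simulator whose per-feature
transmission probabilities are known ground truth, and (c) a whole-study
generator (three groups, pre/post tests) emitting the trial tables the
analysis pipeline consumes.

The observer answers a 3I-3AFC trial correctly with probability

    p(level) = gamma + (1 - gamma - lambda) * Phi(beta * (log10(level) - alpha)),

a cumulative-Gaussian psychometric function on the log10 task axis with
guess rate ``gamma`` (1/3 for three alternatives) and lapse rate
``lambda``.  Working in log10 units makes the multiplicative staircase
steps additive on the observer's axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .confusion import CONSONANTS, VOWELS, FEATURES, FeatureMap, load_feature_map
from .staircase import StaircaseConfig, run_track

__all__ = [
    "ObserverModel",
    "FeatureTransmission",
    "GroupEffects",
    "StudyDesign",
    "StudyData",
    "simulate_vcv_trials",
    "generate_study",
    "GROUPS",
    "TEST_SESSIONS",
]

GROUPS = ("control", "AMD-trained", "AMR-trained")
TEST_SESSIONS = ("pretest", "posttest")
TARGET_P = 0.5 ** (1.0 / 3.0)  # 3-down/1-up convergence point


@dataclass(frozen=True)
class ObserverModel:
    """Cumulative-Gaussian psychometric observer on the log10 task axis.

    ``alpha`` is the function's midpoint in log10 task units (log10 m for
    AMD, log10 Δfm for AMRD, log10 Δf% for FD); ``beta`` its slope per
    log10 unit; ``gamma`` the guess rate and ``lapse`` the lapse rate.
    """

    alpha: float
    beta: float = 8.0
    gamma: float = 1.0 / 3.0
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.gamma < 1:
            raise ValueError("guess rate must be in [0, 1)")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse rate must be in [0, 0.1]")
        if self.beta <= 0:
            raise ValueError("slope must be positive")

    def p_correct(self, level: float) -> float:
        """True probability of a correct response at *level* (> 0)."""
        if level <= 0:
            raise ValueError("level must be positive")
        f = norm.cdf(self.beta * (np.log10(level) - self.alpha))
        return float(self.gamma + (1.0 - self.gamma - self.lapse) * f)

    def threshold_at(self, p: float = TARGET_P) -> float:
        """Level (task units) where the psychometric function crosses *p*."""
        q = (p - self.gamma) / (1.0 - self.gamma - self.lapse)
        if not 0 < q < 1:
            raise ValueError(f"target {p} outside the function's range")
        return float(10.0 ** (self.alpha + norm.ppf(q) / self.beta))

    @classmethod
    def with_threshold(cls, threshold: float, p: float = TARGET_P,
                       beta: float = 8.0, gamma: float = 1.0 / 3.0,
                       lapse: float = 0.02) -> "ObserverModel":
        """Observer whose *p*-correct point sits at *threshold* (task units)."""
        q = (p - gamma) / (1.0 - gamma - lapse)
        alpha = np.log10(threshold) - norm.ppf(q) / beta
        return cls(alpha=float(alpha), beta=beta, gamma=gamma, lapse=lapse)


@dataclass(frozen=True)
class FeatureTransmission:
    """Per-feature probability that the phonetic feature survives intact."""

    t_voice: float = 0.96
    t_manner: float = 0.95
    t_place: float = 0.75

    def __post_init__(self) -> None:
        for name, t in self.as_dict().items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {t}")

    def as_dict(self) -> dict[str, float]:
        return {"voice": self.t_voice, "manner": self.t_manner, "place": self.t_place}

    def shifted(self, delta: float) -> "FeatureTransmission":
        """All three probabilities shifted by *delta*, clipped to [0, 1]."""
        c = lambda t: float(np.clip(t + delta, 0.0, 1.0))
        return FeatureTransmission(c(self.t_voice), c(self.t_manner), c(self.t_place))


def simulate_vcv_trials(ft: FeatureTransmission, fmap: FeatureMap | None = None,
                        n_per_token: int = 1,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate VCV identification with known feature transmission.

    Each of the 60 consonant-vowel tokens is presented *n_per_token*
    times.  On each trial every feature of the stimulus consonant is
    independently kept with its transmission probability, otherwise
    resampled uniformly from that feature's *other* categories.  If all
    three features survive, the consonant itself is perceived (so perfect
    transmission yields a diagonal confusion matrix); otherwise the
    response is drawn uniformly from the consonants matching the
    perturbed (voice, manner, place) triple, or uniformly from all 20 if
    no consonant matches.  Features are perturbed independently — real
    confusions correlate features; see the methods note.

    Returns a trial table with columns stimulus, vowel, response, correct.
    """
    if fmap is None:
        fmap = load_feature_map()
    if rng is None:
        rng = np.random.default_rng()
    t = ft.as_dict()
    records = []
    for c in CONSONANTS:
        triple = dict(zip(FEATURES, fmap.triple(c)))
        for v in VOWELS:
            for _ in range(n_per_token):
                perceived = {}
                intact = True
                for feat in FEATURES:
                    if rng.random() < t[feat]:
                        perceived[feat] = triple[feat]
                    else:
                        intact = False
                        others = [cat for cat in fmap.categories(feat)
                                  if cat != triple[feat]]
                        perceived[feat] = others[rng.integers(0, len(others))]
                if intact:
                    response = c
                else:
                    matches = fmap.consonants_matching(
                        perceived["voice"], perceived["manner"], perceived["place"])
                    pool = matches if matches else list(CONSONANTS)
                    response = pool[rng.integers(0, len(pool))]
                records.append({"stimulus": c, "vowel": v, "response": response,
                                "correct": int(response == c)})
    return pd.DataFrame(records)


@dataclass(frozen=True)
class GroupEffects:
    """Pre→post improvements injected for one group.

    ``threshold_gain`` maps task → drop in log10 threshold from pretest
    to posttest (positive = improvement).  ``vcv_gain`` is the additive
    shift applied to all three feature-transmission probabilities at
    posttest.
    """

    threshold_gain: dict = field(default_factory=dict)  # task -> log10 drop
    vcv_gain: float = 0.0


def _default_effects() -> dict[str, GroupEffects]:
    # Improvements of the size reported for each group on each task
    # (log10 threshold units).  The VCV transmission gains translate, via
    # the feature-channel model, into ~4-6 percentage-point relative-IT
    # improvements — the magnitude the emulated study observed.
    return {
        "control": GroupEffects(
            threshold_gain={"AMD": 0.08, "AMRD": 0.10, "FD": 0.18}, vcv_gain=0.012),
        "AMD-trained": GroupEffects(
            threshold_gain={"AMD": 0.21, "AMRD": 0.09, "FD": 0.08}, vcv_gain=0.018),
        "AMR-trained": GroupEffects(
            threshold_gain={"AMD": 0.07, "AMRD": 0.23, "FD": 0.07}, vcv_gain=0.016),
    }


def _default_baselines() -> dict[str, float]:
    # Mean pretest thresholds at the 79.4 % point, in task units:
    # AMD depth m ≈ 0.1 (-20 dB), AMRD Δfm ≈ 1.6 Hz (20 % of 8 Hz),
    # FD Δf ≈ 1.5 % of 800 Hz — representative of normal-hearing adults.
    return {"AMD": 0.10, "AMRD": 1.6, "FD": 1.5}


@dataclass(frozen=True)
class StudyDesign:
    """Ground-truth configuration of a synthetic training study.

    ``between_sd`` is the between-subject SD of log10 threshold;
    ``vcv_between_sd`` that of the per-subject shift applied to the
    feature-transmission probabilities.  ``session_schedule`` fixes the
    VCV sessions generated; pretraining blocks carry lower transmissions
    (rapid early learning) than the tests.  All effects default to the
    study conditions this toolkit emulates.
    """

    n_per_group: int = 18
    groups: tuple[str, ...] = GROUPS
    baseline_thresholds: dict = field(default_factory=_default_baselines)
    observer_beta: float = 8.0
    observer_lapse: float = 0.02
    between_sd: float = 0.20
    effects: dict = field(default_factory=_default_effects)
    pretest_transmission: FeatureTransmission = FeatureTransmission()
    pretraining_drop: tuple[float, float] = (0.08, 0.02)  # pretraining1/2 deficits
    vcv_between_sd: float = 0.03
    blocks_per_test: int = 2
    trials_per_block: int = 30
    vcv_trials_per_session: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for name in ("between_sd", "vcv_between_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StudyData:
    """Synthetic study output: trial-level tables plus the ground truth."""

    subjects: pd.DataFrame    # subject, group, per-task true log10 thresholds
    tracks: pd.DataFrame      # staircase trial records, all tasks/sessions/blocks
    vcv_trials: pd.DataFrame  # VCV identification trials, all sessions
    design: StudyDesign

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.tracks.to_csv(out / "tracks.csv", index=False)
        self.vcv_trials.to_csv(out / "vcv_trials.csv", index=False)


def generate_study(design: StudyDesign = StudyDesign()) -> StudyData:
    """Generate a full synthetic study, reproducible from ``design.seed``.

    Per subject, each task's true log10 threshold is the group baseline
    plus Gaussian between-subject noise; the posttest threshold is
    lowered by the group's injected gain.  Staircase tracks
    (``blocks_per_test`` blocks per task and session) are then run
    against the subject's observer, and VCV identification trials are
    simulated for the two pretraining blocks and both tests.
    """
    rng = np.random.default_rng(design.seed)
    fmap = load_feature_map()
    tasks = tuple(design.baseline_thresholds)

    subject_rows = []
    track_rows = []
    vcv_rows = []
    subject_id = 0
    for group in design.groups:
        eff = design.effects.get(group, GroupEffects())
        for _ in range(design.n_per_group):
            subject_id += 1
            sid = f"S{subject_id:02d}"
            sub_offset = rng.normal(0.0, design.between_sd) if design.between_sd else 0.0
            vcv_offset = rng.normal(0.0, design.vcv_between_sd) if design.vcv_between_sd else 0.0
            row = {"subject": sid, "group": group}

            for task in tasks:
                base_log = np.log10(design.baseline_thresholds[task]) + sub_offset
                for session in TEST_SESSIONS:
                    gain = eff.threshold_gain.get(task, 0.0) if session == "posttest" else 0.0
                    true_log = base_log - gain
                    row[f"true_log10_{task}_{session}"] = true_log
                    obs = ObserverModel.with_threshold(
                        10.0 ** true_log, beta=design.observer_beta,
                        lapse=design.observer_lapse)
                    cfg = StaircaseConfig.for_task(task, n_trials=design.trials_per_block)
                    for block in range(1, design.blocks_per_test + 1):
                        track = run_track(cfg, obs, rng=rng)
                        frame = track.to_frame()
                        frame.insert(0, "subject", sid)
                        frame.insert(1, "group", group)
                        frame.insert(2, "task", task)
                        frame.insert(3, "session", session)
                        frame.insert(4, "block", block)
                        track_rows.append(frame)

            sessions = {
                "pretraining1": design.pretest_transmission.shifted(
                    -design.pretraining_drop[0] + vcv_offset),
                "pretraining2": design.pretest_transmission.shifted(
                    -design.pretraining_drop[1] + vcv_offset),
                "pretest": design.pretest_transmission.shifted(vcv_offset),
                "posttest": design.pretest_transmission.shifted(vcv_offset + eff.vcv_gain),
            }
            n_rep = max(design.vcv_trials_per_session // 60, 1)
            for session, ft in sessions.items():
                trials = simulate_vcv_trials(ft, fmap, n_per_token=n_rep, rng=rng)
                trials = trials.sample(frac=1.0, random_state=int(rng.integers(2**31)))
                trials = trials.reset_index(drop=True)
                trials.insert(0, "subject", sid)
                trials.insert(1, "group", group)
                trials.insert(2, "session", session)
                trials["trial_order"] = np.arange(1, len(trials) + 1)
                vcv_rows.append(trials)
            subject_rows.append(row)

    return StudyData(
        subjects=pd.DataFrame(subject_rows),
        tracks=pd.concat(track_rows, ignore_index=True),
        vcv_trials=pd.concat(vcv_rows, ignore_index=True),
        design=design,
    )
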