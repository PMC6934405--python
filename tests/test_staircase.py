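"""Adaptive-track stepping rules, reversal counting, schedules, convergence.

The steady-state checks compare simulation against transformed up-down
theory: a three-down/one-up rule converges where p(correct)^3 = 1/2,
i.e. p ≈ 0.794, and a one-down/one-up rule where p = 1/2.  The
Markov-chain test builds the exact stationary distribution of the
discretised staircase and compares simulated level-visit frequencies
against it.
"""

import numpy as np
import pytest

from tevoc import (
    ObserverModel,
    StaircaseConfig,
    Track,
    build_schedule,
    converged_performance,
    count_reversals,
    next_level,
    run_track,
    run_trial,
)
from tevoc.staircase import TRAINING_FM_SET, Trial


def make_track(cfg, levels, corrects, phases, directions):
    trials = tuple(
        Trial(index=i, level=lv, target_interval=1, response_interval=1 if c else 2,
              correct=c, phase=ph, direction=d)
        for i, (lv, c, ph, d) in enumerate(zip(levels, corrects, phases, directions))
    )
    return Track(config=cfg, trials=trials)


class TestNextLevel:
    def setup_method(self):
        self.cfg = StaircaseConfig.for_task("AMD")

    def test_phase1_correct_divides_by_large_step(self):
        track = make_track(self.cfg, [1.0], [True], [1], ["down"])
        assert next_level(track) == pytest.approx(1.0 / 1.58)

    def test_phase1_incorrect_at_cap_clamps(self):
        track = make_track(self.cfg, [1.0], [False], [1], ["up"])
        assert next_level(track) == 1.0  # cap

    def test_phase2_three_down_rule(self):
        cfg = self.cfg
        # two corrects then a third: level moves down by the small step
        track = make_track(cfg, [0.5, 0.5, 0.5], [True, True, True],
                           [2, 2, 2], ["hold", "hold", "down"])
        assert next_level(track) == pytest.approx(0.5 / 1.26)
        # two corrects then an incorrect: up by the small step
        track = make_track(cfg, [0.5, 0.5, 0.5], [True, True, False],
                           [2, 2, 2], ["hold", "hold", "up"])
        assert next_level(track) == pytest.approx(0.5 * 1.26)

    def test_phase2_counter_restarts_after_move(self):
        cfg = self.cfg
        # 4 consecutive corrects: 3rd triggered a move, so only 1 toward the next
        track = make_track(cfg, [0.5] * 4, [True] * 4, [2] * 4,
                           ["hold", "hold", "down", "hold"])
        assert next_level(track) == pytest.approx(0.5)  # hold, not another down

    def test_floor_clamp(self):
        cfg = self.cfg
        track = make_track(cfg, [cfg.level_floor], [True, ], [1], ["down"])
        assert next_level(track) == cfg.level_floor

    def test_empty_track_returns_start(self):
        track = Track(config=self.cfg, trials=())
        assert next_level(track) == self.cfg.start_level


class TestRunTrial:
    def test_perfect_observer_always_correct(self, perfect_observer, rng):
        for _ in range(20):
            target, response, correct = run_trial(0.5, perfect_observer, rng)
            assert correct and response == target

    def test_guessing_observer_near_chance(self, guessing_observer, rng):
        n = 3000
        hits = sum(run_trial(0.5, guessing_observer, rng)[2] for _ in range(n))
        assert hits / n == pytest.approx(1 / 3, abs=0.03)

    def test_seeded_run_is_reproducible(self, amd_observer, amd_config):
        a = run_track(amd_config, amd_observer, seed=42)
        b = run_track(amd_config, amd_observer, seed=42)
        assert a.to_frame().equals(b.to_frame())


class TestRunTrack:
    def test_perfect_observer_descends_monotonically(self, perfect_observer, amd_config):
        track = run_track(amd_config, perfect_observer, seed=1)
        levels = track.levels()
        assert np.all(np.diff(levels) < 0) or np.all(
            np.diff(levels)[levels[1:] > amd_config.level_floor] < 0)
        assert track.n_reversals == 0

    def test_guessing_observer_pinned_near_cap(self, guessing_observer, amd_config):
        track = run_track(amd_config, guessing_observer, seed=1)
        # chance performance drives levels up; late trials sit at the cap
        late = track.levels()[-10:]
        assert np.median(late) == pytest.approx(amd_config.level_cap, rel=0.3)

    def test_realistic_observer_reversal_count(self, amd_observer):
        cfg = StaircaseConfig.for_task("AMD", n_trials=60)
        counts = [run_track(cfg, amd_observer, seed=s).n_reversals for s in range(20)]
        assert np.mean(counts) >= 4.0

    def test_levels_stay_in_bounds(self, amd_observer, amd_config):
        for seed in range(5):
            levels = run_track(amd_config, amd_observer, seed=seed).levels()
            assert np.all(levels >= amd_config.level_floor)
            assert np.all(levels <= amd_config.level_cap)

    def test_phase_switch_once_and_irreversible(self, amd_observer, amd_config):
        for seed in range(5):
            track = run_track(amd_config, amd_observer, seed=seed)
            phases = [t.phase for t in track.trials if not t.practice]
            assert sorted(phases) == phases  # 1...1 then 2...2
            if 2 in phases:
                first2 = phases.index(2)
                incorrects = [i for i, t in enumerate(track.trials) if not t.correct]
                assert incorrects[0] == first2 - 1

    def test_practice_trials_flagged_and_non_adaptive(self, amd_observer):
        cfg = StaircaseConfig.for_task("AMD", n_trials=30, n_practice=5)
        track = run_track(cfg, amd_observer, seed=0)
        practice = [t for t in track.trials if t.practice]
        assert len(practice) == 5
        assert len(track.trials) == 35
        assert {t.level for t in practice[:3]} == {cfg.start_level}
        assert {t.level for t in practice[3:]} == {cfg.level_floor}
        assert len(track.levels(include_practice=False)) == 30


class TestCountReversals:
    def test_monotone_track_zero(self):
        cfg = StaircaseConfig.for_task("AMD")
        track = make_track(cfg, [1.0, 0.6, 0.4], [True] * 3, [1] * 3, ["down"] * 3)
        assert count_reversals(track) == 0

    def test_strict_zigzag(self):
        cfg = StaircaseConfig.for_task("AMD")
        dirs = ["down", "up", "down", "up", "down", "up"]
        track = make_track(cfg, [0.5] * 6, [True] * 6, [2] * 6, dirs)
        assert count_reversals(track) == 5

    def test_hand_counted_fixture(self):
        # moves: down down up hold up down hold down -> reversals at
        # 3rd (d->u), 6th (u->d): holds skipped, consecutive ups are one run
        cfg = StaircaseConfig.for_task("AMD")
        dirs = ["down", "down", "up", "hold", "up", "down", "hold", "down"]
        track = make_track(cfg, [0.5] * 8, [True] * 8, [2] * 8, dirs)
        assert count_reversals(track) == 2


class TestSchedule:
    def test_training_totals(self):
        sched = build_schedule("training_AMD")
        assert sched.total_trials == 1260
        assert len(sched.blocks) == 21
        days = [b.day for b in sched.blocks]
        assert days.count(2) == 9 and days.count(3) == 12

    def test_pretest_psychophysics_blocks(self):
        sched = build_schedule("pretest")
        amd_blocks = [b for b in sched.blocks if b.task == "AMD"]
        assert len(amd_blocks) == 2
        assert all(b.n_trials == 30 for b in amd_blocks)
        vcv = [b for b in sched.blocks if b.task == "VCV"]
        assert len(vcv) == 1 and vcv[0].n_trials == 60 and not vcv[0].feedback

    @pytest.mark.parametrize("fm_row", [0, 1, 2])
    def test_any_three_block_window_covers_all_rates(self, fm_row):
        seq = build_schedule("training_AMRD", fm_row=fm_row).fm_sequence()
        assert len(seq) == 21
        for i in range(len(seq) - 2):
            assert set(seq[i:i + 3]) == set(TRAINING_FM_SET)

    def test_rates_balanced(self):
        seq = build_schedule("training_AMD").fm_sequence()
        for fm in TRAINING_FM_SET:
            assert seq.count(fm) == 7

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            build_schedule("weekend")


class TestStepBookkeeping:
    def test_db_values_match_printed(self):
        assert round(20 * np.log10(1.58)) == 4
        assert round(20 * np.log10(1.26)) == 2


class TestConvergedPerformance:
    def test_three_down_one_up_tracks_79_percent(self):
        obs = ObserverModel.with_threshold(0.1, beta=4.0, lapse=0.0)
        cfg = StaircaseConfig.for_task("AMD", n_trials=100)
        mean, se = converged_performance(cfg, obs, n_tracks=150, seed=11)
        assert mean == pytest.approx(0.794, abs=0.02)

    def test_one_down_one_up_tracks_50_percent(self):
        obs = ObserverModel.with_threshold(0.1, beta=4.0, lapse=0.0)
        cfg = StaircaseConfig(task="AMD", start_level=1.0, phase1_step=1.58,
                              phase2_step=1.26, phase2_down=1, n_trials=100,
                              level_floor=1e-4, level_cap=1.0)
        mean, se = converged_performance(cfg, obs, n_tracks=150, seed=11)
        assert mean == pytest.approx(0.50, abs=0.03)


def updown_stationary(p_levels, n_down):
    """Brute-force stationary distribution of the transformed up-down chain.

    States are (level index, consecutive-correct count); a correct
    response advances the counter, the n_down-th consecutive correct
    moves one level harder (index + 1), any incorrect moves one easier
    (index - 1); both moves reset the counter; ends clamp.
    """
    K = len(p_levels)
    n_states = K * n_down
    P = np.zeros((n_states, n_states))

    def sid(k, c):
        return k * n_down + c

    for k in range(K):
        p = p_levels[k]
        for c in range(n_down):
            if c < n_down - 1:
                P[sid(k, c), sid(k, c + 1)] += p
            else:
                P[sid(k, c), sid(min(k + 1, K - 1), 0)] += p
            P[sid(k, c), sid(max(k - 1, 0), 0)] += 1 - p
    evals, evecs = np.linalg.eig(P.T)
    i = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    return pi.reshape(K, n_down).sum(axis=1)


class TestMarkovOracle:
    def test_visit_frequencies_match_stationary_distribution(self):
        from scipy.stats import chisquare

        obs = ObserverModel.with_threshold(0.1, beta=4.0, lapse=0.0)
        step = 1.26
        cap = 1.0
        K = 40
        cfg = StaircaseConfig(task="AMD", start_level=cap, phase1_step=1.58,
                              phase2_step=step, phase2_down=3,
                              n_trials=100_000, level_floor=cap * step**-(K - 1),
                              level_cap=cap, start_phase=2)
        track = run_track(cfg, obs, seed=99)
        levels = track.levels()
        # map visited levels onto the multiplicative grid (cap * step^-k);
        # levels harder than the start are index k > 0
        k_idx = np.clip(np.round(np.log(cap / levels) / np.log(step)).astype(int), 0, K - 1)
        # the chain's level autocorrelation is ~0 beyond lag 40, so thin by
        # that stride to make the multinomial chi-square assumption valid
        counts = np.bincount(k_idx[500::40], minlength=K)

        grid = cap * step ** -np.arange(K)
        pi = updown_stationary([obs.p_correct(lv) for lv in grid], n_down=3)
        n = counts.sum()
        keep = pi * n >= 5  # chi-square validity
        chi2 = chisquare(
            np.append(counts[keep], counts[~keep].sum()),
            np.append(pi[keep] * n, pi[~keep].sum() * n),
        )
        assert chi2.pvalue > 0.01
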