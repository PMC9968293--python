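"""Cohort generator: agent dynamics, tapping rules, SRT, dataset IO."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from coreg.cohort import (
    AgentParams,
    CohortConfig,
    SchemaError,
    read_dataset,
    simulate_cohort,
    simulate_decision,
    simulate_srt_block,
    simulate_tapping,
    write_dataset,
)
from coreg.task import FrameSequence, TaskDesign, generate_frame_sequence


def _agent(**overrides):
    base = dict(
        bound={"fast": 5.0, "slow": 5.0},
        motor_delay_mean={"fast": 400.0, "slow": 400.0, "none": 400.0},
        tap_interval_mean={"fast": 174.0, "slow": 186.0, "none": 180.0},
        accum_noise_sd=0.0,
        motor_delay_sd=0.0,
        tap_interval_sd=0.0,
        lapse_prob=0.0,
        premature_prob=0.0,
        frame_drop_prob=0.0,
    )
    base.update(overrides)
    return AgentParams(**base)


def test_noiseless_accumulator_commits_at_first_crossing(rng):
    seq = FrameSequence(steps=np.ones(179, int), trial_type="obvious", winner="right")
    choice, commit, rt = simulate_decision(_agent(), seq, "slow", rng)
    assert choice == "right" and commit == 5
    assert rt == pytest.approx(5 * 1000 / 60 + 400)


def test_noiseless_commit_matches_manual_crossing(rng):
    agent = _agent(bound={"fast": 12.0, "slow": 12.0})
    for _ in range(5):
        seq = generate_frame_sequence("random", rng=rng)
        choice, commit, rt = simulate_decision(agent, seq, "slow", rng)
        x = np.cumsum(seq.steps.astype(float))
        frames = np.arange(1, 180)
        bound = 12.0 * np.maximum(1 - frames / 179, 0.0)
        expected = int(np.argmax(np.abs(x) >= bound)) + 1
        assert commit == expected


def test_unreachable_bound_gives_no_response(rng):
    seq = FrameSequence(steps=np.ones(179, int), trial_type="obvious", winner="right")
    agent = _agent(bound={"fast": np.inf, "slow": np.inf})
    choice, commit, rt = simulate_decision(agent, seq, "slow", rng)
    assert choice == "none" and commit is None and rt is None


def test_choice_symmetry_on_random_sequences(rng):
    agent = _agent(accum_noise_sd=0.4, bound={"fast": 10.0, "slow": 10.0})
    rights = 0
    n = 1500
    seqs = [generate_frame_sequence("random", rng=rng) for _ in range(200)]
    for i in range(n):
        choice, _, _ = simulate_decision(agent, seqs[i % len(seqs)], "slow", rng)
        rights += choice == "right"
    # mirrored sequence population is symmetric; 4 SE envelope
    assert abs(rights / n - 0.5) < 4 * 0.5 / np.sqrt(n)


def test_generated_rts_respect_timeout(small_cohort):
    rt = small_cohort.trials["rt"].dropna()
    assert (rt > 0).all() and (rt <= 3000).all()
    none_rows = small_cohort.trials[small_cohort.trials["choice"] == "none"]
    assert none_rows["rt"].isna().all()


def test_tapping_decision_session_timeout(rng):
    agent = _agent(tap_interval_mean={"fast": 174.0, "slow": 900.0, "none": 500.0})
    taps, ok = simulate_tapping(agent, "fast", "decision", rng)
    assert ok and np.allclose(taps, 174.0)
    taps, ok = simulate_tapping(agent, "slow", "decision", rng)
    assert not ok  # 4 x 900 ms exceeds the 3000-ms movement phase


def test_fast_tapping_collision_at_closed_form_tap(rng):
    # snake interval = 1000 / (0.85 * max speed); constant slower tapping
    # collides exactly when the first cumulative tap time exceeds it
    agent = _agent(max_tap_speed=6.0)
    snake_ms = 1000 / (0.85 * 6.0)
    slow = dict(agent.tap_interval_mean)
    slow["fast"] = snake_ms + 10.0
    agent = dataclasses.replace(agent, tap_interval_mean=slow)
    _, ok = simulate_tapping(agent, "fast", "movement", rng)
    assert not ok
    fast = dict(agent.tap_interval_mean)
    fast["fast"] = snake_ms - 10.0
    agent = dataclasses.replace(agent, tap_interval_mean=fast)
    _, ok = simulate_tapping(agent, "fast", "movement", rng)
    assert ok


def test_slow_tapping_overtake_fails(rng):
    agent = _agent(max_tap_speed=6.0)
    snake_ms = 1000 / (0.595 * 6.0)
    fast_taps = dict(agent.tap_interval_mean)
    fast_taps["slow"] = snake_ms * 0.5  # tapping twice as fast as the snake
    agent = dataclasses.replace(agent, tap_interval_mean=fast_taps)
    _, ok = simulate_tapping(agent, "slow", "movement", rng)
    assert not ok


def test_slow_condition_movement_accuracy_at_least_fast(rng):
    """Collision risk is one-sided: with equal interval SDs the slow
    condition fails no more often than the fast one."""
    agent = _agent(
        tap_interval_mean={"fast": 160.0, "slow": 260.0, "none": 200.0},
        tap_interval_sd=30.0, max_tap_speed=6.3,
    )
    oks = {c: np.mean([simulate_tapping(agent, c, "movement", rng)[1]
                       for _ in range(1200)]) for c in ("fast", "slow")}
    assert oks["slow"] >= oks["fast"]


def test_srt_block_deterministic_and_lapse_free(rng):
    agent = _agent(motor_delay_sd=0.0, detection_latency_ms=0.0)
    block = simulate_srt_block(agent, "none", 50, rng)
    assert (block["rt"] == 400.0).all()
    assert not block["premature"].any()


def test_srt_mean_matches_configuration(rng):
    agent = _agent(motor_delay_sd=60.0, detection_latency_ms=180.0, lapse_prob=0.0)
    block = simulate_srt_block(agent, "none", 5000, rng)
    se = 60.0 / np.sqrt(5000)
    assert abs(block["rt"].mean() - 580.0) < 3 * se


def test_cohort_bookkeeping(tiny_cohort):
    trials = tiny_cohort.trials
    assert len(trials) == 2 * 2 * 2 * 20
    counts = trials.groupby(["participant_id", "session", "condition"]).size()
    assert (counts == 20).all()
    srt = tiny_cohort.srt
    assert set(srt[srt.session == "decision"].condition) == {"none"}
    assert set(srt[srt.session == "movement"].condition) == {"fast", "slow"}


def test_ground_truth_reproduces_planted_differences(small_cohort):
    cfg = small_cohort.meta["config"]
    truth = small_cohort.meta["ground_truth"]
    diffs = [t["decision"]["tap_interval_mean"]["fast"] - t["decision"]["tap_interval_mean"]["slow"]
             for t in truth.values()]
    se = cfg["tap_diff_sd"] / np.sqrt(len(diffs))
    assert abs(np.mean(diffs) - cfg["tap_decision_diff"]) < 4 * se


def test_null_planting_gives_null_tap_difference():
    cfg = CohortConfig(n_participants=8, trials_per_condition=40, seed=11,
                       tap_decision_diff=0.0, tap_diff_sd=0.0)
    ds = simulate_cohort(cfg)
    tr = ds.trials[(ds.trials.session == "decision") & (ds.trials.choice != "none")]
    taps = tr.groupby(["participant_id", "condition"])[["tap1", "tap2", "tap3", "tap4"]] \
             .mean().mean(axis=1).unstack()
    diff = (taps["fast"] - taps["slow"]).mean()
    assert abs(diff) < 6.0  # within-trial sampling noise only


def test_dataset_roundtrip(tmp_path, tiny_cohort):
    write_dataset(tiny_cohort, tmp_path / "d")
    back = read_dataset(tmp_path / "d")
    pd.testing.assert_frame_equal(back.trials, tiny_cohort.trials, check_dtype=False)
    pd.testing.assert_frame_equal(back.srt, tiny_cohort.srt, check_dtype=False)
    assert back.meta["seed"] == tiny_cohort.meta["seed"]


def test_schema_error_names_missing_column(tmp_path, tiny_cohort):
    write_dataset(tiny_cohort, tmp_path / "d")
    trials = pd.read_csv(tmp_path / "d" / "trials.csv").drop(columns=["winner"])
    trials.to_csv(tmp_path / "d" / "trials.csv", index=False)
    with pytest.raises(SchemaError, match="winner"):
        read_dataset(tmp_path / "d")


def test_cohort_reproducible_from_seed():
    a = simulate_cohort(CohortConfig(n_participants=2, trials_per_condition=20, seed=5))
    b = simulate_cohort(CohortConfig(n_participants=2, trials_per_condition=20, seed=5))
    pd.testing.assert_frame_equal(a.trials, b.trials)
    pd.testing.assert_frame_equal(a.srt, b.srt)


def test_agent_params_validation():
    with pytest.raises(ValueError, match="bounds"):
        _agent(bound={"fast": -1.0, "slow": 2.0})
    with pytest.raises(ValueError, match="lapse"):
        _agent(lapse_prob=0.5)
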