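"""Synthetic cohort: simulated participants performing both sessions.

Each participant is an evidence-accumulating agent.  In the decision phase
the agent integrates the actual frame sequence (gain * step + Gaussian
noise per frame) and commits when the accumulator reaches a linearly
collapsing bound; commitment plus a condition-specific motor delay gives
the reaction time.  Tapping, simple-reaction-time (SRT) blocks, lapses and
frame-rate dropouts are simulated so that every downstream analysis stage
(exclusion rules, endpoint measures, diffusion-model fits, psychophysical
kernels) can be exercised against known ground truth.

The generator is deliberately *not* a drift-diffusion model: it sees the
frame-wise evidence, which is what gives psychophysical kernels their
shape; the diffusion model of :mod:`coreg.ddm` is the analysis-side
approximation, fitted to the simulated reaction times.

Default parameters are calibrated to the published condition magnitudes
(decision-duration medians ~1774/1006 ms in slow/fast decision blocks,
~1584/1522 ms in slow/fast tapping blocks; tap-interval medians 186/174
and 263/146 ms; movement accuracy ~100%/93%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .task import (
    CompositionError,
    FrameSequence,
    TaskDesign,
    make_trial_list,
    steps_to_str,
)

__all__ = [
    "AgentParams",
    "CohortConfig",
    "Dataset",
    "SchemaError",
    "simulate_decision",
    "simulate_tapping",
    "simulate_srt_block",
    "simulate_cohort",
    "write_dataset",
    "read_dataset",
]

SCHEMA_VERSION = "1"

TRIAL_COLUMNS = [
    "participant_id", "session", "condition", "block_index", "trial_id",
    "trial_type", "winner", "steps", "rt", "choice", "decision_correct",
    "commit_frame", "tap1", "tap2", "tap3", "tap4", "movement_correct",
    "frame_rate_ok", "premature_press",
]
SRT_COLUMNS = ["participant_id", "session", "condition", "rt", "premature"]


class SchemaError(ValueError):
    """Dataset on disk does not match the expected schema."""


@dataclass
class AgentParams:
    """Generative parameters of one simulated participant in one session.

    Per-condition dictionaries are keyed by 'fast'/'slow' (and 'none' for
    the snake-free SRT block of the decision session).  ``bound`` is the
    commitment threshold at trial onset in accumulator units; it collapses
    linearly to ``(1 - bound_collapse) * bound`` at the final frame, which
    forces commitment by the deadline when ``bound_collapse`` is 1.
    """

    bound: Mapping[str, float]
    motor_delay_mean: Mapping[str, float]
    tap_interval_mean: Mapping[str, float]
    gain: float = 1.0
    accum_noise_sd: float = 0.4
    bound_collapse: float = 1.0
    motor_delay_sd: float = 60.0
    tap_interval_sd: float = 25.0
    lapse_prob: float = 0.04
    premature_prob: float = 0.01
    frame_drop_prob: float = 0.02
    max_tap_speed: float = 6.3
    detection_latency_ms: float = 180.0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bound.values()):
            raise ValueError("bounds must be positive")
        if not (0 <= self.lapse_prob < 0.2):
            raise ValueError("lapse_prob must lie in [0, 0.2)")
        if any(m <= 0 for m in self.tap_interval_mean.values()):
            raise ValueError("tap interval means must be positive")
        for sd in (self.accum_noise_sd, self.motor_delay_sd, self.tap_interval_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


_MIN_MOTOR_DELAY = 50.0
_MIN_TAP_INTERVAL = 60.0


def _trunc_normal(mean: float, sd: float, lo: float, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Normal draws truncated below at ``lo`` (resampling, clip fallback)."""
    if sd == 0:
        return np.full(size, max(mean, lo))
    out = rng.normal(mean, sd, size)
    for _ in range(50):
        bad = out < lo
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(out, lo)


def simulate_decision(
    agent: AgentParams,
    seq: FrameSequence,
    condition: str,
    rng: np.random.Generator,
    design: TaskDesign | None = None,
) -> tuple[str, int | None, float | None]:
    """One decision-phase pass of the accumulator agent.

    Returns ``(choice, commit_frame, rt_ms)``; choice is 'none' (with None
    for the other fields) when the agent fails to commit in time or the
    reaction time would exceed the decision timeout.
    """
    design = design or TaskDesign()
    n = design.n_frames
    drift = agent.gain * seq.steps.astype(float)
    if agent.accum_noise_sd > 0:
        drift = drift + rng.normal(0.0, agent.accum_noise_sd, n)
    x = np.cumsum(drift)
    frames = np.arange(1, n + 1)
    frac = np.maximum(1.0 - agent.bound_collapse * frames / n, 0.0)
    b = agent.bound[condition]
    with np.errstate(invalid="ignore"):
        bound = np.where(frac > 0, b * frac, 0.0)
    hit = np.abs(x) >= bound
    if not hit.any():
        return "none", None, None
    k = int(np.argmax(hit)) + 1
    choice = "right" if x[k - 1] >= 0 else "left"
    delay = float(
        _trunc_normal(agent.motor_delay_mean[condition], agent.motor_delay_sd,
                      _MIN_MOTOR_DELAY, 1, rng)[0]
    )
    rt = k * design.frame_ms + delay
    if rt > design.decision_timeout_ms:
        return "none", None, None
    return choice, k, float(rt)


def simulate_tapping(
    agent: AgentParams,
    condition: str,
    session: str,
    rng: np.random.Generator,
    design: TaskDesign | None = None,
) -> tuple[np.ndarray, bool]:
    """Four inter-tap intervals plus the movement-correctness verdict.

    Decision session: correct when the four taps finish inside the 3000-ms
    movement phase.  Movement session: the caterpillar head (advancing one
    36-degree segment per tap) must additionally stay ahead of a chasing
    snake at 85% of the maximum tapping speed (fast) or behind a retreating
    snake at 59.5% of it (slow); collisions are checked tap by tap.
    """
    design = design or TaskDesign()
    intervals = _trunc_normal(
        agent.tap_interval_mean[condition], agent.tap_interval_sd,
        _MIN_TAP_INTERVAL, design.n_taps_after_decision, rng,
    )
    t = np.cumsum(intervals)
    ok = bool(t[-1] <= design.movement_timeout_ms)
    if session == "movement" and ok:
        if condition == "fast":
            # snake starts one tap-segment behind the caterpillar head and
            # reaches segment k at k * snake_interval
            snake_ms = 1000.0 / (design.snake_fast_fraction * agent.max_tap_speed)
            ok = bool(np.all(t <= np.arange(1, len(t) + 1) * snake_ms))
        elif condition == "slow":
            # snake starts one segment ahead; the head collides when the
            # caterpillar overtakes it
            snake_ms = 1000.0 / (design.snake_slow_fraction * agent.max_tap_speed)
            ok = bool(np.all(t >= np.arange(0, len(t)) * snake_ms))
    return intervals, ok


def simulate_srt_block(
    agent: AgentParams,
    condition: str,
    n_trials: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simple-reaction-time block: detection latency plus the motor delay."""
    rows = []
    for _ in range(n_trials):
        if rng.uniform() < agent.lapse_prob:
            rows.append({"condition": condition,
                         "rt": float(rng.uniform(1.0, 49.0)), "premature": True})
            continue
        delay = float(
            _trunc_normal(agent.motor_delay_mean[condition], agent.motor_delay_sd,
                          _MIN_MOTOR_DELAY, 1, rng)[0]
        )
        rows.append({"condition": condition,
                     "rt": agent.detection_latency_ms + delay, "premature": False})
    return pd.DataFrame(rows)


@dataclass
class CohortConfig:
    """Cohort size, seeds, and the planted fast/slow condition effects.

    Condition effects are parameterised as a slow-condition intercept plus
    a fast-condition difference, mirroring how the within-subject effects
    are reported.  Between-participant spread applies to intercepts and
    (more tightly) to the differences, so planted effects are directionally
    consistent across most participants.
    """

    n_participants: int = 40
    trials_per_condition: int = 160
    srt_trials_per_block: int = 40
    seed: int = 0

    # accumulator
    gain: float = 1.0
    accum_noise_sd: float = 0.4
    bound_collapse: float = 1.0

    # decision session: planted threshold + motor-delay + tap effects
    bound_decision_slow: float = 25.0
    bound_decision_diff: float = -11.0
    motor_delay_decision_slow: float = 480.0
    motor_delay_decision_diff: float = -300.0
    tap_decision_slow: float = 186.0
    tap_decision_diff: float = -16.0

    # movement session
    bound_movement_slow: float = 22.5
    bound_movement_diff: float = -2.5
    motor_delay_movement_slow: float = 360.0
    motor_delay_movement_diff: float = -30.0
    tap_movement_slow: float = 263.0
    tap_movement_diff: float = -117.0

    # between-participant spread
    bound_between_sd: float = 2.5
    bound_diff_sd: float = 1.5
    motor_delay_between_sd: float = 60.0
    motor_delay_diff_sd: float = 30.0
    tap_between_sd: float = 25.0
    tap_diff_sd: float = 8.0

    # within-trial noise and nuisance rates
    motor_delay_sd: float = 60.0
    tap_interval_sd: float = 25.0
    lapse_prob: float = 0.04
    premature_prob: float = 0.01
    frame_drop_prob: float = 0.02
    max_tap_speed: float = 6.3
    detection_latency_ms: float = 180.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        self.blocks_per_condition  # validates composition

    @property
    def blocks_per_condition(self) -> int:
        """Largest block count <= 4 that yields mixture-legal block sizes."""
        for nb in (4, 2, 1):
            if self.trials_per_condition % nb == 0 and (self.trials_per_condition // nb) % 10 == 0:
                return nb
        raise CompositionError(
            f"trials_per_condition={self.trials_per_condition} cannot be split "
            "into blocks whose size is a multiple of 10"
        )


@dataclass
class Dataset:
    """Simulated cohort: main-task trials, SRT trials, and metadata."""

    trials: pd.DataFrame
    srt: pd.DataFrame
    meta: dict


def _draw_agent(cfg: CohortConfig, session: str, rng: np.random.Generator) -> AgentParams:
    if session == "decision":
        b0, db = cfg.bound_decision_slow, cfg.bound_decision_diff
        m0, dm = cfg.motor_delay_decision_slow, cfg.motor_delay_decision_diff
        t0, dt = cfg.tap_decision_slow, cfg.tap_decision_diff
    else:
        b0, db = cfg.bound_movement_slow, cfg.bound_movement_diff
        m0, dm = cfg.motor_delay_movement_slow, cfg.motor_delay_movement_diff
        t0, dt = cfg.tap_movement_slow, cfg.tap_movement_diff

    b_slow = max(3.0, rng.normal(b0, cfg.bound_between_sd))
    b_fast = max(2.0, b_slow + rng.normal(db, cfg.bound_diff_sd))
    m_slow = max(_MIN_MOTOR_DELAY + 10, rng.normal(m0, cfg.motor_delay_between_sd))
    m_fast = max(_MIN_MOTOR_DELAY + 10, m_slow + rng.normal(dm, cfg.motor_delay_diff_sd))
    t_slow = max(_MIN_TAP_INTERVAL + 10, rng.normal(t0, cfg.tap_between_sd))
    t_fast = max(_MIN_TAP_INTERVAL + 10, t_slow + rng.normal(dt, cfg.tap_diff_sd))

    return AgentParams(
        bound={"fast": b_fast, "slow": b_slow},
        motor_delay_mean={"fast": m_fast, "slow": m_slow, "none": 0.5 * (m_fast + m_slow)},
        tap_interval_mean={"fast": t_fast, "slow": t_slow, "none": 0.5 * (t_fast + t_slow)},
        gain=cfg.gain,
        accum_noise_sd=cfg.accum_noise_sd,
        bound_collapse=cfg.bound_collapse,
        motor_delay_sd=cfg.motor_delay_sd,
        tap_interval_sd=cfg.tap_interval_sd,
        lapse_prob=cfg.lapse_prob,
        premature_prob=cfg.premature_prob,
        frame_drop_prob=cfg.frame_drop_prob,
        max_tap_speed=cfg.max_tap_speed,
        detection_latency_ms=cfg.detection_latency_ms,
    )


def _simulate_trial(
    agent: AgentParams,
    seq: FrameSequence,
    condition: str,
    session: str,
    rng: np.random.Generator,
    design: TaskDesign,
) -> dict:
    row = {
        "trial_type": seq.trial_type,
        "winner": seq.winner,
        "steps": steps_to_str(seq.steps),
        "rt": np.nan,
        "choice": "none",
        "decision_correct": False,
        "commit_frame": np.nan,
        "tap1": np.nan, "tap2": np.nan, "tap3": np.nan, "tap4": np.nan,
        "movement_correct": False,
        "frame_rate_ok": bool(rng.uniform() >= agent.frame_drop_prob),
        "premature_press": False,
    }
    u = rng.uniform()
    if u < agent.premature_prob:
        row["premature_press"] = True
        return row
    if u < agent.premature_prob + agent.lapse_prob / 2:
        return row  # attentional lapse: no response at all
    if u < agent.premature_prob + agent.lapse_prob:
        # anticipation: a guess well before evidence could matter
        row["rt"] = float(rng.uniform(1.0, 140.0))
        row["choice"] = "left" if rng.uniform() < 0.5 else "right"
        row["commit_frame"] = 1
    else:
        choice, k, rt = simulate_decision(agent, seq, condition, rng, design)
        if choice == "none":
            return row
        row["choice"], row["commit_frame"], row["rt"] = choice, k, rt
    row["decision_correct"] = bool(row["choice"] == seq.winner)
    taps, ok = simulate_tapping(agent, condition, session, rng, design)
    row.update({f"tap{i + 1}": float(v) for i, v in enumerate(taps)})
    row["movement_correct"] = ok
    return row


def simulate_cohort(config: CohortConfig, design: TaskDesign | None = None) -> Dataset:
    """Simulate every participant's decision and movement session plus SRT.

    Per-participant random streams are derived deterministically from the
    dataset seed (seed + participant index), so the cohort is reproducible
    trial-for-trial.  Ground-truth agent parameters are stored in the
    metadata for recovery tests.
    """
    design = design or TaskDesign()
    trial_rows, srt_rows, truth = [], [], {}
    nb = config.blocks_per_condition
    tpb = config.trials_per_condition // nb

    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        rng = np.random.default_rng(config.seed + p)
        truth[pid] = {}
        for session in ("decision", "movement"):
            agent = _draw_agent(config, session, rng)
            truth[pid][session] = {
                "bound": dict(agent.bound),
                "motor_delay_mean": dict(agent.motor_delay_mean),
                "tap_interval_mean": dict(agent.tap_interval_mean),
            }
            block_order = list(rng.permutation(["fast"] * nb + ["slow"] * nb))
            trial_id = 0
            for b_ix, condition in enumerate(block_order):
                for seq in make_trial_list(tpb, design, rng):
                    row = _simulate_trial(agent, seq, condition, session, rng, design)
                    row.update(
                        participant_id=pid, session=session, condition=condition,
                        block_index=b_ix, trial_id=trial_id,
                    )
                    trial_rows.append(row)
                    trial_id += 1
            srt_conditions = ["none"] if session == "decision" else \
                list(rng.permutation(["fast", "slow"]))
            for cond in srt_conditions:
                block = simulate_srt_block(agent, cond, config.srt_trials_per_block, rng)
                block["participant_id"] = pid
                block["session"] = session
                srt_rows.append(block)

    trials = pd.DataFrame(trial_rows)[TRIAL_COLUMNS]
    srt = pd.concat(srt_rows, ignore_index=True)[SRT_COLUMNS]
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": asdict(config),
        "ground_truth": truth,
    }
    return Dataset(trials=trials, srt=srt, meta=meta)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Persist a cohort as trials.csv + srt.csv + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.trials.to_csv(path / "trials.csv", index=False)
    dataset.srt.to_csv(path / "srt.csv", index=False)
    (path / "meta.json").write_text(json.dumps(dataset.meta, indent=2))


def read_dataset(path: str | Path) -> Dataset:
    """Load a cohort written by :func:`write_dataset`, validating the schema."""
    path = Path(path)
    for name in ("trials.csv", "srt.csv", "meta.json"):
        if not (path / name).exists():
            raise SchemaError(f"missing dataset file: {name}")
    trials = pd.read_csv(path / "trials.csv")
    srt = pd.read_csv(path / "srt.csv")
    meta = json.loads((path / "meta.json").read_text())
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise SchemaError(f"trials.csv is missing column {col!r}")
    for col in SRT_COLUMNS:
        if col not in srt.columns:
            raise SchemaError(f"srt.csv is missing column {col!r}")
    if str(meta.get("schema_version")) != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version {meta.get('schema_version')!r} != {SCHEMA_VERSION!r}"
        )
    return Dataset(trials=trials, srt=srt, meta=meta)
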