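"""Stimulus engine for the two-banana Tokens task.

Two bananas grow around a circular track; on every screen refresh (60 Hz)
exactly one of them is extended by 2 degrees.  A trial presents 179 such
frames, so one banana always ends up strictly longer.  The participant has
to commit to the banana that will win before the frames run out.

This module generates and classifies the frame-wise evidence sequences and
computes the objective *success probability*: the probability that a given
evidence lead survives the remaining frames when each remaining frame
extends either banana independently with probability one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FRAME_MS",
    "TRIAL_TYPES",
    "TaskDesign",
    "EvidenceState",
    "FrameSequence",
    "InvalidStateError",
    "NoWinnerError",
    "GenerationError",
    "CompositionError",
    "success_probability",
    "success_probability_oracle",
    "running_winner_probability",
    "classify_trial_type",
    "generate_frame_sequence",
    "make_trial_list",
    "steps_to_str",
    "str_to_steps",
    "rt_to_frame",
]

#: Duration of one stimulus frame in milliseconds (60 Hz refresh).
FRAME_MS = 1000.0 / 60.0

#: Closed set of trial-type labels.
TRIAL_TYPES = ("obvious", "ambiguous", "misleading", "random")


class InvalidStateError(ValueError):
    """Evidence state violates its invariants (e.g. negative remaining)."""


class NoWinnerError(ValueError):
    """A frame sequence whose evidence sums to zero has no winner."""


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its draw budget for a trial type."""


class CompositionError(ValueError):
    """Requested trial count is incompatible with the type mixture."""


@dataclass(frozen=True)
class TaskDesign:
    """Fixed constants of the task and of the trial-type operationalisation.

    The trial-type thresholds (``burn_in_frames``, ``early_frames`` and the
    probability band) turn the qualitative type descriptions ("one banana
    grew larger early on", "in competition for about halfway") into testable
    rules on the running success probability of the eventual winner.
    """

    frame_rate: float = 60.0
    n_frames: int = 179
    degrees_per_frame: float = 2.0
    decision_timeout_ms: float = 3000.0
    movement_timeout_ms: float = 3000.0
    n_taps_after_decision: int = 4
    degrees_per_tap: float = 36.0
    type_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "obvious": 0.30,
            "ambiguous": 0.30,
            "misleading": 0.20,
            "random": 0.20,
        }
    )
    snake_fast_fraction: float = 0.85
    snake_slow_fraction: float = 0.595
    # Trial-type operationalisation constants (probability band on the
    # running winner probability; "early" ~ first half of the trial).
    burn_in_frames: int = 30
    early_frames: int = 90
    band_lo: float = 0.4
    band_hi: float = 0.6

    def __post_init__(self) -> None:
        if self.n_frames % 2 == 0:
            raise ValueError("n_frames must be odd so that one banana always wins")
        if abs(sum(self.type_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("type_mixture must sum to 1")
        if set(self.type_mixture) != set(TRIAL_TYPES):
            raise ValueError(f"type_mixture keys must be {TRIAL_TYPES}")

    @property
    def total_degrees(self) -> float:
        """Angle covered by the winning growth path (179 * 2 = 358)."""
        return self.n_frames * self.degrees_per_frame

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.frame_rate


@dataclass(frozen=True)
class EvidenceState:
    """Signed frame-count lead of a designated banana plus frames to come."""

    delta: int
    remaining: int

    def __post_init__(self) -> None:
        if self.remaining < 0:
            raise InvalidStateError(f"remaining must be >= 0, got {self.remaining}")


@dataclass
class FrameSequence:
    """One trial's frame-wise evidence steps plus its label and winner.

    ``steps`` holds -1 where the left banana is extended and +1 where the
    right banana is extended.
    """

    steps: np.ndarray
    trial_type: str
    winner: str

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int8)
        if not np.isin(self.steps, (-1, 1)).all():
            raise ValueError("steps must contain only -1 and +1")
        total = int(self.steps.sum())
        if total == 0:
            raise NoWinnerError("frame sequence sums to zero: no winner")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        expected = "right" if total > 0 else "left"
        if self.winner != expected:
            raise ValueError(f"winner {self.winner!r} inconsistent with steps (sum={total})")

    def __len__(self) -> int:
        return len(self.steps)

    def mirrored(self) -> "FrameSequence":
        """Left/right mirror image; trial type is invariant under mirroring."""
        return FrameSequence(
            steps=-self.steps,
            trial_type=self.trial_type,
            winner="left" if self.winner == "right" else "right",
        )


def _as_state(state) -> tuple[int, int]:
    if isinstance(state, EvidenceState):
        return state.delta, state.remaining
    delta, remaining = state
    if remaining < 0:
        raise InvalidStateError(f"remaining must be >= 0, got {remaining}")
    return int(delta), int(remaining)


def success_probability(state) -> float:
    """P(designated banana finishes strictly longer).

    Each of the ``remaining`` frames independently extends the designated
    banana with probability 1/2, so with K ~ Binomial(remaining, 1/2) the
    final lead is ``delta + 2K - remaining`` and the returned value is
    P(delta + 2K - remaining > 0).  A tied finish counts as failure (ties
    are impossible for full-length trials because 179 is odd).
    """
    delta, remaining = _as_state(state)
    if remaining == 0:
        return 1.0 if delta > 0 else 0.0
    k = math.floor((remaining - delta) / 2)
    if k < 0:
        return 1.0
    return float(stats.binom.sf(k, remaining, 0.5))


def success_probability_oracle(state) -> float:
    """Exhaustive-enumeration reference for :func:`success_probability`.

    Enumerates all 2**remaining assignments of the remaining frames; refuses
    remaining > 20 to keep the enumeration tractable.
    """
    delta, remaining = _as_state(state)
    if remaining > 20:
        raise ValueError("oracle refuses remaining > 20 (combinatorial blow-up)")
    wins = 0
    for assignment in range(2 ** remaining):
        k = assignment.bit_count()
        if delta + 2 * k - remaining > 0:
            wins += 1
    return wins / 2 ** remaining


@lru_cache(maxsize=4)
def _success_table(n_frames: int) -> np.ndarray:
    """Lookup table P[delta + n_frames, remaining] of success probabilities."""
    delta = np.arange(-n_frames, n_frames + 1)
    remaining = np.arange(0, n_frames + 1)
    k = np.floor((remaining[None, :] - delta[:, None]) / 2.0)
    table = stats.binom.sf(np.maximum(k, -1.0), remaining[None, :], 0.5)
    # remaining == 0 column: sf() handles it, but make the lead rule explicit
    table[:, 0] = (delta > 0).astype(float)
    return table


def running_winner_probability(steps: Sequence[int], design: TaskDesign | None = None) -> np.ndarray:
    """Running success probability of the eventual winner, one value per frame."""
    design = design or TaskDesign()
    steps = np.asarray(steps, dtype=np.int64)
    if len(steps) != design.n_frames:
        raise ValueError(f"expected {design.n_frames} frames, got {len(steps)}")
    total = int(steps.sum())
    if total == 0:
        raise NoWinnerError("frame sequence sums to zero: no winner")
    w = 1 if total > 0 else -1
    lead = np.cumsum(steps) * w
    remaining = design.n_frames - np.arange(1, design.n_frames + 1)
    table = _success_table(design.n_frames)
    return table[lead + design.n_frames, remaining]


def _classify_from_pw(p_w: np.ndarray, design: TaskDesign) -> str:
    after = p_w[design.burn_in_frames:]
    early = p_w[: design.early_frames]
    if (after >= design.band_hi).all() and (after >= 0.5).all():
        return "obvious"
    if (early <= design.band_lo).any():
        return "misleading"
    if ((early > design.band_lo) & (early < design.band_hi)).all():
        return "ambiguous"
    return "random"


def classify_trial_type(steps: Sequence[int], design: TaskDesign | None = None) -> str:
    """Deterministic trial-type label from the winner's running probability.

    obvious:    the winner's success probability stays >= band_hi on every
                frame after the burn-in.
    misleading: the winner's probability drops to <= band_lo at some early
                frame (the winner still prevails by construction).
    ambiguous:  the probability stays strictly inside the band on every
                early frame.
    random:     anything else.
    """
    design = design or TaskDesign()
    return _classify_from_pw(running_winner_probability(steps, design), design)


def _classify_batch(steps_matrix: np.ndarray, design: TaskDesign) -> np.ndarray:
    """Vectorised classification of a (n_seq, n_frames) matrix of +/-1 steps."""
    n = design.n_frames
    totals = steps_matrix.sum(axis=1)
    w = np.where(totals > 0, 1, -1)[:, None]
    lead = np.cumsum(steps_matrix, axis=1) * w
    remaining = n - np.arange(1, n + 1)
    table = _success_table(n)
    p_w = table[lead + n, remaining[None, :]]

    after = p_w[:, design.burn_in_frames:]
    early = p_w[:, : design.early_frames]
    is_obvious = (after >= design.band_hi).all(axis=1)
    is_misleading = (early <= design.band_lo).any(axis=1) & ~is_obvious
    is_ambiguous = (
        ((early > design.band_lo) & (early < design.band_hi)).all(axis=1)
        & ~is_obvious
        & ~is_misleading
    )
    labels = np.full(len(steps_matrix), "random", dtype=object)
    labels[is_obvious] = "obvious"
    labels[is_misleading] = "misleading"
    labels[is_ambiguous] = "ambiguous"
    # ties have no winner; mark invalid (cannot happen for odd n_frames)
    labels[totals == 0] = "invalid"
    return labels


_REJECTION_BUDGET = 100_000
_BATCH = 512


def _propose_ambiguous(batch: int, design: TaskDesign, rng: np.random.Generator) -> np.ndarray:
    """Guided proposal for 'ambiguous' sequences.

    A uniform proposal lands inside the 0.4-0.6 probability band on every
    early frame with probability ~2e-5, which makes plain rejection sampling
    intractable.  Here the early steps are drawn uniformly but reflected
    whenever they would carry the running probability of a designated side
    out of the band; the remaining frames stay uniform.  The classifier
    still arbitrates acceptance, so every returned sequence that survives
    rejection satisfies the exact same band rule as a uniform draw would.
    """
    n = design.n_frames
    steps = rng.choice(np.array([-1, 1], dtype=np.int8), size=(batch, n))
    table = _success_table(n)
    lead = np.zeros(batch, dtype=np.int64)
    for t in range(design.early_frames):
        rem = n - (t + 1)
        p = table[lead + steps[:, t] + n, rem]
        exits = (p >= design.band_hi) | (p <= design.band_lo)
        steps[exits, t] *= -1
        lead = lead + steps[:, t]
    return steps


def _sample_sequences(
    trial_type: str,
    n_needed: int,
    design: TaskDesign,
    rng: np.random.Generator,
    budget: int = _REJECTION_BUDGET,
) -> list[np.ndarray]:
    """Rejection-sample +/-1 sequences until n_needed match trial_type.

    Proposals are uniform except for 'ambiguous' (see
    :func:`_propose_ambiguous`); 'random' accepts every draw.
    """
    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"unknown trial type {trial_type!r}")
    out: list[np.ndarray] = []
    drawn = 0
    while len(out) < n_needed:
        if drawn >= budget * max(n_needed, 1):
            raise GenerationError(
                f"rejection budget exceeded while generating {trial_type!r} trials"
            )
        batch = min(_BATCH, budget)
        if trial_type == "ambiguous":
            steps = _propose_ambiguous(batch, design, rng)
        else:
            steps = rng.choice(np.array([-1, 1], dtype=np.int8), size=(batch, design.n_frames))
        drawn += batch
        if trial_type == "random":
            # every legal draw is accepted: 'random' means any growth pattern
            take = steps
        else:
            labels = _classify_batch(steps, design)
            take = steps[labels == trial_type]
        for row in take[: n_needed - len(out)]:
            out.append(row)
    return out


def generate_frame_sequence(
    trial_type: str,
    design: TaskDesign | None = None,
    rng: np.random.Generator | None = None,
) -> FrameSequence:
    """Draw one frame sequence of the requested type by rejection sampling."""
    design = design or TaskDesign()
    rng = rng if rng is not None else np.random.default_rng()
    steps = _sample_sequences(trial_type, 1, design, rng)[0]
    winner = "right" if steps.sum() > 0 else "left"
    return FrameSequence(steps=steps, trial_type=trial_type, winner=winner)


def make_trial_list(
    n_trials: int,
    design: TaskDesign | None = None,
    rng: np.random.Generator | None = None,
) -> list[FrameSequence]:
    """Ordered trial list with the exact design mixture, winners balanced.

    Type counts are the deterministic composition of the mixture (e.g. 160
    trials -> 48 obvious, 48 ambiguous, 32 misleading, 32 random); the order
    is shuffled and winning sides are counterbalanced to within one trial by
    mirroring sequences in place.
    """
    design = design or TaskDesign()
    rng = rng if rng is not None else np.random.default_rng()
    counts: dict[str, int] = {}
    for label, prop in design.type_mixture.items():
        exact = n_trials * prop
        if abs(exact - round(exact)) > 1e-9:
            raise CompositionError(
                f"{n_trials} trials cannot realise the {prop:.0%} share of "
                f"{label!r} trials exactly; use a multiple of 10"
            )
        counts[label] = round(exact)

    sequences: list[FrameSequence] = []
    for label in TRIAL_TYPES:
        for steps in _sample_sequences(label, counts[label], design, rng):
            winner = "right" if steps.sum() > 0 else "left"
            sequences.append(FrameSequence(steps=steps, trial_type=label, winner=winner))

    order = rng.permutation(len(sequences))
    shuffled = [sequences[i] for i in order]
    # Counterbalance winners by mirroring: alternate the desired side down
    # the shuffled list; mirroring preserves the trial type exactly.
    for i, seq in enumerate(shuffled):
        desired = "left" if i % 2 == 0 else "right"
        if seq.winner != desired:
            shuffled[i] = seq.mirrored()
    return shuffled


def steps_to_str(steps: Sequence[int]) -> str:
    """Serialise steps as a string of 'L'/'R' characters."""
    return "".join("R" if s > 0 else "L" for s in steps)


def str_to_steps(text: str) -> np.ndarray:
    if set(text) - {"L", "R"}:
        raise ValueError("steps string may contain only 'L' and 'R'")
    return np.fromiter((1 if c == "R" else -1 for c in text), dtype=np.int8, count=len(text))


def rt_to_frame(rt_ms: float, design: TaskDesign | None = None) -> int:
    """Map a reaction time to its containing frame (1-based, by ceiling).

    Frame k spans ((k-1)/60, k/60] seconds from decision-phase onset.
    """
    design = design or TaskDesign()
    frame = math.ceil(rt_ms / design.frame_ms)
    return int(min(max(frame, 1), design.n_frames))
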