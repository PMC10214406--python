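"""The 5-choice reversal-learning environment.

One of five positions is rewarded for a whole block of trials; at an
unannounced reversal a different position becomes rewarded.  Three positions
are "frequent" candidates; the remaining two are never rewarded, rarely
rewarded, or equally rewarded depending on the experiment version.

The environment delivers a scalar reward-prediction-error signal R built
from a reward constant ``r`` and a learned reward prediction: rewarded
response i yields ``r - P_i``, any unrewarded response yields ``-r`` and a
missing response ``-r/2``.  R is written into a transient dopamine trace
that decays exponentially and gates synaptic plasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POSITIONS",
    "FREQUENT",
    "OTHER",
    "Outcome",
    "RewardModel",
    "DopamineState",
    "Block",
    "BlockSchedule",
    "TrialRecord",
    "TrialTiming",
    "Agent",
    "reward_signal",
    "update_prediction",
    "dopamine_step",
    "generate_block_schedule",
    "run_trial",
    "run_experiment",
    "trials_to_frame",
]

POSITIONS: tuple[int, ...] = (1, 2, 3, 4, 5)
FREQUENT: tuple[int, ...] = (2, 3, 4)
OTHER: tuple[int, ...] = (1, 5)


@dataclass(frozen=True)
class Outcome:
    """Result of one trial: the selected position (or None) and reward flag."""

    selected: int | None
    rewarded: bool

    @property
    def missing(self) -> bool:
        return self.selected is None


@dataclass
class RewardModel:
    """Reward constant and learned reward-prediction signal.

    ``mode="specific"`` keeps one prediction P_i per response, updated by
    ``+-r/tau_P`` and clamped to ``[-r, 0.8 r]``.  ``mode="legacy"`` keeps a
    single scalar prediction that relaxes toward ``r`` on rewarded responses
    and resets to zero on unrewarded ones.
    """

    r: float = 0.25
    tau_P: float = 50.0
    tau_P_legacy: float = 60.0
    mode: str = "specific"
    P: np.ndarray = field(default_factory=lambda: np.zeros(len(POSITIONS)))
    P_legacy: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("specific", "legacy"):
            raise ValueError(f"unknown reward-model mode {self.mode!r}")
        self.P = np.asarray(self.P, dtype=float).copy()

    def prediction_for(self, position: int) -> float:
        if self.mode == "legacy":
            return self.P_legacy
        return float(self.P[position - 1])


def reward_signal(outcome: Outcome, model: RewardModel) -> float:
    """Scalar reward signal R for one trial outcome (uses pre-update P)."""
    if outcome.missing:
        return -model.r / 2.0
    if outcome.rewarded:
        return model.r - model.prediction_for(outcome.selected)
    return -model.r


def update_prediction(model: RewardModel, outcome: Outcome) -> RewardModel:
    """Return a model with the prediction updated for this outcome."""
    if outcome.missing:
        return model
    if model.mode == "legacy":
        if outcome.rewarded:
            new = model.P_legacy + (model.r - model.P_legacy) / model.tau_P_legacy
        else:
            new = 0.0
        return replace(model, P=model.P.copy(), P_legacy=new)
    P = model.P.copy()
    i = outcome.selected - 1
    step = model.r / model.tau_P
    P[i] += step if outcome.rewarded else -step
    P[i] = min(max(P[i], -model.r), 0.8 * model.r)
    return replace(model, P=P)


@dataclass
class DopamineState:
    """Transient dopamine deviation from baseline, one trace per projection
    group, each decaying exponentially with its own time constant (ms)."""

    tau: dict[str, float]
    DA: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.tau:
            self.DA.setdefault(name, 0.0)


def dopamine_step(
    state: DopamineState, dt: float, deliver: float | None = None
) -> DopamineState:
    """Advance the dopamine traces by ``dt`` ms; optionally deliver R first.

    On delivery every trace is set to R; otherwise each decays as
    ``DA <- DA * exp(-dt / tau)``.
    """
    DA = {}
    for name, tau in state.tau.items():
        if deliver is not None:
            DA[name] = deliver
        else:
            DA[name] = state.DA[name] * math.exp(-dt / tau)
    return DopamineState(tau=dict(state.tau), DA=DA)


# ---------------------------------------------------------------------------
# Block schedules


@dataclass(frozen=True)
class Block:
    index: int
    rewarded: int
    consecutive_target: int
    max_trials: int
    familiarization: bool = False
    after_break: bool = False


@dataclass
class BlockSchedule:
    version: str
    blocks: list[Block]
    frequent: tuple[int, ...] = FREQUENT
    other: tuple[int, ...] = OTHER

    def __len__(self) -> int:
        return len(self.blocks)

    def main_blocks(self) -> list[Block]:
        return [b for b in self.blocks if not b.familiarization]

    def validate(self) -> None:
        prev = None
        for b in self.blocks:
            if prev is not None and b.rewarded == prev:
                raise AssertionError("same position rewarded in consecutive blocks")
            prev = b.rewarded

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "version": self.version,
                "frequent": list(self.frequent),
                "other": list(self.other),
                "blocks": [
                    {
                        "index": b.index, "rewarded": b.rewarded,
                        "consecutive_target": b.consecutive_target,
                        "max_trials": b.max_trials,
                        "familiarization": b.familiarization,
                        "after_break": b.after_break,
                    }
                    for b in self.blocks
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BlockSchedule":
        import json

        data = json.loads(text)
        return cls(
            version=data["version"],
            blocks=[Block(**b) for b in data["blocks"]],
            frequent=tuple(data["frequent"]),
            other=tuple(data["other"]),
        )


def _no_repeat_shuffle(
    pool: Sequence[int], rng: np.random.Generator, first_forbidden: int | None
) -> list[int]:
    """Random permutation of ``pool`` with no two adjacent equal entries and
    a forbidden first entry (rejection sampling)."""
    pool = list(pool)
    for _ in range(10_000):
        perm = list(rng.permutation(pool))
        if first_forbidden is not None and perm[0] == first_forbidden:
            continue
        if any(a == b for a, b in zip(perm, perm[1:])):
            continue
        return perm
    raise RuntimeError("could not satisfy schedule constraints")


def _sample_sequence(
    choices: Sequence[int],
    n_blocks: int,
    rng: np.random.Generator,
) -> list[int]:
    seq: list[int] = []
    for _ in range(n_blocks):
        opts = [c for c in choices if not seq or c != seq[-1]]
        seq.append(int(rng.choice(opts)))
    return seq


def generate_block_schedule(
    version: str,
    n_blocks: int | None = None,
    rng: np.random.Generator | None = None,
    *,
    frequent: tuple[int, ...] = FREQUENT,
    other: tuple[int, ...] = OTHER,
    consecutive_target: int = 15,
    max_trials: int = 30,
) -> BlockSchedule:
    """Build the rewarded-position sequence for one experiment.

    Model versions (``never``/``rarely``/``all``) terminate each block after
    15 consecutive rewarded trials or 30 trials.  ``never``: 60 blocks drawn
    from the three frequent positions; ``rarely``: 70 blocks where every
    14-block part rewards each frequent position four times and each rare
    position once; ``all``: 60 blocks over all five positions.  The same
    position is never rewarded in two consecutive blocks.

    Human variants (``human_never``/``human_rarely``) prepend familiarization
    parts, draw the per-block termination rule uniformly from 7-9 consecutive
    / 12-14 maximum trials, and mark the block after each between-part break.
    """
    rng = np.random.default_rng() if rng is None else rng
    blocks: list[Block] = []

    def add(rewarded: int, fam: bool, after_break: bool, ct: int, mt: int) -> None:
        blocks.append(
            Block(len(blocks) + 1, rewarded, ct, mt, fam, after_break)
        )

    if version == "never":
        n = 60 if n_blocks is None else n_blocks
        seq = _sample_sequence(frequent, n, rng)
        for pos in seq:
            add(pos, False, False, consecutive_target, max_trials)
    elif version == "all":
        n = 60 if n_blocks is None else n_blocks
        seq = _sample_sequence(frequent + other, n, rng)
        for pos in seq:
            add(pos, False, False, consecutive_target, max_trials)
    elif version == "rarely":
        n = 70 if n_blocks is None else n_blocks
        if n % 14:
            raise ValueError("rarely-rewarded schedules come in 14-block parts")
        part = [p for p in frequent for _ in range(4)] + list(other)
        seq: list[int] = []
        for _ in range(n // 14):
            prev = seq[-1] if seq else None
            seq.extend(_no_repeat_shuffle(part, rng, prev))
        for pos in seq:
            add(pos, False, False, consecutive_target, max_trials)
    elif version in ("human_never", "human_rarely"):
        def human_block(pos: int, fam: bool, after_break: bool) -> None:
            ct = int(rng.integers(7, 10))
            mt = int(rng.integers(12, 15))
            add(pos, fam, after_break, ct, mt)

        all_pos = frequent + other
        if version == "human_never":
            # familiarization: two 12-block parts, four positions rewarded in
            # five blocks each and one random position in four
            short = int(rng.choice(all_pos))
            fam_pool = [p for p in all_pos for _ in range(4)] + [
                p for p in all_pos if p != short
            ]
            fam_seq = _no_repeat_shuffle(fam_pool, rng, None)
            parts = [fam_seq[:12], fam_seq[12:]]
            fam_flags = [True, True]
            for _ in range(4):
                prev = parts[-1][-1]
                parts.append(
                    _no_repeat_shuffle([p for p in frequent for _ in range(4)], rng, prev)
                )
                fam_flags.append(False)
        else:
            fam_pool = [p for p in all_pos for _ in range(3)]
            parts = [_no_repeat_shuffle(fam_pool, rng, None)]
            fam_flags = [True]
            for _ in range(5):
                prev = parts[-1][-1]
                parts.append(
                    _no_repeat_shuffle(
                        [p for p in frequent for _ in range(4)] + list(other), rng, prev
                    )
                )
                fam_flags.append(False)
        for part_seq, fam in zip(parts, fam_flags):
            for j, pos in enumerate(part_seq):
                human_block(pos, fam, after_break=(j == 0 and len(blocks) > 0))
    else:
        raise ValueError(f"unknown schedule version {version!r}")

    schedule = BlockSchedule(version=version, blocks=blocks, frequent=frequent, other=other)
    schedule.validate()
    return schedule


# ---------------------------------------------------------------------------
# Trial loop


@dataclass(frozen=True)
class TrialTiming:
    """Trial phase durations in ms."""

    rest_ms: float = 1700.0
    max_stimulus_ms: float = 1000.0
    reward_delay_ms: float = 130.0
    feedback_ms: float = 300.0  # post-delivery window simulated each trial


@dataclass(frozen=True)
class TrialRecord:
    block: int
    trial: int
    selected: int | None
    rewarded: bool
    latency_ms: float
    R: float


class Agent(Protocol):
    """Anything that can act in the task.

    The spiking network implements this by simulating membrane dynamics;
    scripted test doubles implement it directly.
    """

    def select(self, rng: np.random.Generator) -> tuple[int | None, float]:
        """Simulate rest + stimulus; return (selected position | None, latency ms)."""

    def deliver_outcome(
        self, outcome: Outcome, R: float, rng: np.random.Generator
    ) -> None:
        """Simulate the post-response window: delay, dopamine delivery, plasticity."""


def run_trial(
    agent: Agent,
    block: Block,
    model: RewardModel,
    trial_index: int,
    rng: np.random.Generator,
) -> tuple[TrialRecord, RewardModel]:
    """One trial: response, reward computation, prediction update, delivery."""
    selected, latency = agent.select(rng)
    rewarded = selected is not None and selected == block.rewarded
    outcome = Outcome(selected, rewarded)
    R = reward_signal(outcome, model)
    model = update_prediction(model, outcome)
    agent.deliver_outcome(outcome, R, rng)
    record = TrialRecord(block.index, trial_index, selected, rewarded, latency, R)
    return record, model


def run_block(
    agent: Agent,
    block: Block,
    model: RewardModel,
    rng: np.random.Generator,
) -> tuple[list[TrialRecord], RewardModel]:
    """Trials until ``consecutive_target`` rewarded in a row or ``max_trials``."""
    records: list[TrialRecord] = []
    consecutive = 0
    for t in range(1, block.max_trials + 1):
        record, model = run_trial(agent, block, model, t, rng)
        records.append(record)
        consecutive = consecutive + 1 if record.rewarded else 0
        if consecutive >= block.consecutive_target:
            break
    return records, model


def run_experiment(
    agent: Agent,
    schedule: BlockSchedule,
    rng: np.random.Generator,
    model: RewardModel | None = None,
    block_callback=None,
) -> pd.DataFrame:
    """Run a full multi-block experiment; returns the trial table.

    Predictions are never reset between blocks: the agent learns
    continuously.  ``block_callback(block, records)`` runs after each block
    (used for weight snapshots).
    """
    model = RewardModel() if model is None else model
    all_records: list[TrialRecord] = []
    for block in schedule.blocks:
        records, model = run_block(agent, block, model, rng)
        all_records.extend(records)
        if block_callback is not None:
            block_callback(block, records)
    return trials_to_frame(all_records)


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Trial records as the standard tabular schema."""
    return pd.DataFrame(
        {
            "block": [r.block for r in records],
            "trial": [r.trial for r in records],
            "selected": [0 if r.selected is None else r.selected for r in records],
            "rewarded": [bool(r.rewarded) for r in records],
            "latency_ms": [r.latency_ms for r in records],
            "R": [r.R for r in records],
        }
    )
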