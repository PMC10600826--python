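"""Three-arm bandit environment: reward schedules and agent-environment sessions.

The task is a block-structured multi-armed bandit. Each arm pays off with a
fixed probability within a block; at every block boundary the assignment of
probabilities to arms is re-drawn as a fresh permutation of the same
probability set, constrained to differ from the previous block so that every
switch is behaviorally detectable. Outcomes are symmetric win/loss payoffs;
the value used by the learning rule is a configurable coding of the outcome
(default +1 win / -1 loss).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError, InputError

TRIAL_COLUMNS = ["subject", "trial", "block", "arm", "outcome", "win", "p_arm", "payoff"]


@dataclass(frozen=True)
class TaskConfig:
    """Structure of the bandit task.

    Attributes
    ----------
    n_arms, n_trials, block_length
        Task geometry; ``n_trials`` must be divisible by ``block_length``.
    prob_set
        Reward probabilities assigned to the arms within each block; one entry
        per arm, each strictly inside (0, 1) except in explicitly degenerate
        test configurations where 0/1 are permitted.
    win_payoff, loss_payoff
        Net currency change recorded on winning / losing trials.
    outcome_coding
        ``(win_value, loss_value)`` pair fed to the learning rule as ``r``.
    """

    n_arms: int = 3
    n_trials: int = 90
    block_length: int = 30
    prob_set: tuple[float, ...] = (0.8, 0.5, 0.2)
    win_payoff: float = 10.0
    loss_payoff: float = -10.0
    outcome_coding: tuple[float, float] = (1.0, -1.0)

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ConfigError(f"need at least 2 arms, got {self.n_arms}")
        if self.n_trials <= 0 or self.block_length <= 0:
            raise ConfigError("n_trials and block_length must be positive")
        if self.n_trials % self.block_length != 0:
            raise ConfigError(
                f"n_trials={self.n_trials} not divisible by block_length={self.block_length}"
            )
        if len(self.prob_set) != self.n_arms:
            raise ConfigError(
                f"prob_set has {len(self.prob_set)} entries for {self.n_arms} arms"
            )
        for p in self.prob_set:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"reward probability {p} outside [0, 1]")
        if len(self.outcome_coding) != 2:
            raise ConfigError("outcome_coding must be a (win, loss) pair")

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_length


@dataclass(frozen=True)
class Schedule:
    """Per-trial arm->probability map with block bookkeeping.

    ``probs`` has shape (n_trials, n_arms); ``block`` has shape (n_trials,).
    Within a block all rows are identical and each row is a permutation of the
    config's probability set; consecutive blocks differ.
    """

    probs: np.ndarray
    block: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    @property
    def n_arms(self) -> int:
        return self.probs.shape[1]

    def block_assignments(self) -> np.ndarray:
        """One probability row per block, shape (n_blocks, n_arms)."""
        _, first = np.unique(self.block, return_index=True)
        return self.probs[np.sort(first)]

    def to_json(self) -> str:
        return json.dumps(
            {"probs": self.probs.tolist(), "block": self.block.tolist()}
        )

    @classmethod
    def from_json(cls, s: str) -> "Schedule":
        d = json.loads(s)
        return cls(
            probs=np.asarray(d["probs"], dtype=float),
            block=np.asarray(d["block"], dtype=int),
        )


@dataclass(frozen=True)
class TrialRecord:
    """One bandit trial: who chose what, and what came back."""

    subject: int
    trial: int
    block: int
    arm: int
    outcome: float  # outcome_coding value fed to the learning rule
    win: bool
    p_arm: float  # scheduled reward probability of the chosen arm
    payoff: float  # net currency change


def make_schedule(config: TaskConfig, seed: int | np.random.Generator) -> Schedule:
    """Draw a block-permuted reward schedule.

    Each block's arm->probability assignment is sampled uniformly from the
    permutations of ``config.prob_set`` that differ from the previous block's
    assignment (the first block is uniform over all permutations).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    perms = [np.asarray(p, dtype=float) for p in itertools.permutations(config.prob_set)]
    probs = np.empty((config.n_trials, config.n_arms), dtype=float)
    block = np.empty(config.n_trials, dtype=int)
    prev: np.ndarray | None = None
    for b in range(config.n_blocks):
        if prev is None:
            choices = perms
        else:
            choices = [p for p in perms if not np.array_equal(p, prev)]
            if not choices:  # degenerate prob_set (all entries equal)
                choices = perms
        assignment = choices[rng.integers(len(choices))]
        sl = slice(b * config.block_length, (b + 1) * config.block_length)
        probs[sl] = assignment
        block[sl] = b
        prev = assignment
    return Schedule(probs=probs, block=block)


def sample_outcome(
    schedule: Schedule,
    trial: int,
    arm: int,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
) -> tuple[float, bool]:
    """Bernoulli outcome draw for (trial, arm), mapped through outcome coding.

    Returns ``(r, win)`` where ``r`` is the outcome-coding value.
    """
    if not (0 <= trial < schedule.n_trials):
        raise IndexError(f"trial {trial} out of range [0, {schedule.n_trials})")
    if not (0 <= arm < schedule.n_arms):
        raise IndexError(f"arm {arm} out of range [0, {schedule.n_arms})")
    coding = config.outcome_coding if config is not None else (1.0, -1.0)
    win = bool(rng.random() < schedule.probs[trial, arm])
    return (coding[0] if win else coding[1], win)


def run_session(
    params,
    spec,
    config: TaskConfig = TaskConfig(),
    seed: int | np.random.Generator = 0,
    subject: int = 0,
    schedule: Schedule | None = None,
) -> list[TrialRecord]:
    """Run one agent-environment session and return its trial records.

    The agent chooses by softmax over its running expected values and learns
    with the Rescorla-Wagner variant given by ``spec``; the environment
    supplies Bernoulli outcomes from a (freshly drawn, unless provided)
    block-permuted schedule. Reproducible given ``seed``.
    """
    from .rl_models import softmax_probs, rw_update  # deferred: avoid cycle

    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = make_schedule(config, rng)
    if schedule.n_trials != config.n_trials or schedule.n_arms != config.n_arms:
        raise InputError("schedule shape does not match config")

    V = np.zeros(config.n_arms)
    records: list[TrialRecord] = []
    for t in range(config.n_trials):
        p = softmax_probs(V, params.beta)
        arm = int(rng.choice(config.n_arms, p=p))
        r, win = sample_outcome(schedule, t, arm, rng, config)
        records.append(
            TrialRecord(
                subject=subject,
                trial=t,
                block=int(schedule.block[t]),
                arm=arm,
                outcome=r,
                win=win,
                p_arm=float(schedule.probs[t, arm]),
                payoff=config.win_payoff if win else config.loss_payoff,
            )
        )
        V = rw_update(V, arm, r, params, spec)
    return records


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records -> long-format table (one row per trial)."""
    return pd.DataFrame([asdict(r) for r in records], columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame` for a single- or multi-subject table."""
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"trial table missing columns: {sorted(missing)}")
    return [
        TrialRecord(
            subject=int(row.subject),
            trial=int(row.trial),
            block=int(row.block),
            arm=int(row.arm),
            outcome=float(row.outcome),
            win=bool(row.win),
            p_arm=float(row.p_arm),
            payoff=float(row.payoff),
        )
        for row in df.itertuples(index=False)
    ]
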