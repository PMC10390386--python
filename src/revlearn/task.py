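"""Probabilistic reversal-learning task: session generation and behavioral summaries.

A session is a sequence of binary-choice trials.  A hidden "preferred" side
``z_t`` determines where the reward is more likely to be (``x_t = z_t`` with
probability ``p_reward``).  The preferred side reverses either after the
agent picks it on ``k`` consecutive trials (response-contingent rule) or
independently with a fixed per-trial probability (stochastic rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReversalRule",
    "PhaseTiming",
    "TaskConfig",
    "SessionRecord",
    "EXP1",
    "EXP2A",
    "EXP2B",
    "named_condition",
    "generate_session",
    "summarize_behavior",
    "reversal_aligned_curves",
    "session_to_tsv",
    "read_session_tsv",
]

MISSING = -1  # choice code for a missed (non-responded) trial


@dataclass(frozen=True)
class ReversalRule:
    """Either ``response_contingent`` (k consecutive preferred choices) or
    ``stochastic`` (independent per-trial switch probability ``h``)."""

    kind: str
    k_consecutive: int = 8
    h: float = 0.06

    def __post_init__(self) -> None:
        if self.kind not in ("response_contingent", "stochastic"):
            raise ValueError(f"unknown reversal rule {self.kind!r}")
        if self.kind == "response_contingent" and self.k_consecutive < 1:
            raise ValueError("k_consecutive must be >= 1")
        if self.kind == "stochastic" and not (0.0 <= self.h < 1.0):
            raise ValueError("h must be in [0, 1)")


@dataclass(frozen=True)
class PhaseTiming:
    """Per-phase durations (seconds) used to place feedback onsets."""

    fixation: tuple[float, float] = (1.5, 2.0)
    choice_max: float = 2.0
    wait: tuple[float, float] = (1.5, 2.0)
    feedback: float = 3.0  # two 1.5 s subphases
    response_time: float = 0.7  # nominal simulated reaction time


@dataclass(frozen=True)
class TaskConfig:
    n_trials: int
    p_reward: float
    reversal_rule: ReversalRule
    start_points: int = 100
    timing: PhaseTiming = field(default_factory=PhaseTiming)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.5 < self.p_reward <= 1.0):
            raise ValueError("p_reward must be in (0.5, 1]")


EXP1 = TaskConfig(n_trials=150, p_reward=0.75, reversal_rule=ReversalRule("response_contingent", k_consecutive=8))
EXP2A = TaskConfig(n_trials=100, p_reward=0.85, reversal_rule=ReversalRule("stochastic", h=0.06))
EXP2B = TaskConfig(n_trials=100, p_reward=0.65, reversal_rule=ReversalRule("stochastic", h=0.06))

_CONDITIONS = {"exp1": EXP1, "exp2a": EXP2A, "exp2b": EXP2B}


def named_condition(name: str) -> TaskConfig:
    try:
        return _CONDITIONS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown condition {name!r}; expected one of {sorted(_CONDITIONS)}")


@dataclass
class SessionRecord:
    """Per-trial record of one session.

    ``y`` uses -1 for missed trials (reward 0 on those).  ``reversal`` marks
    trials on which the hidden side differs from the previous trial.
    """

    z: np.ndarray
    x: np.ndarray
    y: np.ndarray
    reward: np.ndarray
    reversal: np.ndarray
    feedback_onset_s: np.ndarray
    score: np.ndarray
    config: TaskConfig | None = None

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    @property
    def responded(self) -> np.ndarray:
        return self.y != MISSING

    @property
    def binary_reward(self) -> np.ndarray:
        """Model-facing reward coding: 1 if the choice matched the rewarded side."""
        return ((self.y == self.x) & self.responded).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "z": self.z,
                "x": self.x,
                "y": self.y,
                "reward": self.reward,
                "reversal": self.reversal.astype(int),
                "feedback_onset_s": self.feedback_onset_s,
                "score": self.score,
            }
        )


class ScriptedAgent:
    """Plays a fixed choice sequence; used by tests and as a missing-data stub."""

    def __init__(self, script: Sequence[int]):
        self.script = [int(v) for v in script]
        self._i = 0

    def reset(self) -> None:
        self._i = 0

    def choose(self, rng: np.random.Generator) -> int:
        if self._i >= len(self.script):
            raise ValueError("script shorter than the session")
        y = self.script[self._i]
        self._i += 1
        return y

    def observe(self, y: int, x: int, rewarded: int) -> None:  # noqa: ARG002
        pass


def generate_session(
    config: TaskConfig,
    agent,
    seed: int | np.random.Generator,
    initial_side: int | None = None,
) -> SessionRecord:
    """Simulate one session driven by ``agent``.

    The agent must expose ``reset()``, ``choose(rng) -> side`` (may return -1
    for a miss) and ``observe(y, x, rewarded)``.  Under the
    response-contingent rule the reversal takes effect on the trial following
    the k-th consecutive preferred choice; missed trials neither extend nor
    reset the streak.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_trials
    rule = config.reversal_rule
    timing = config.timing

    agent.reset()
    z = np.empty(n, dtype=np.int64)
    x = np.empty(n, dtype=np.int64)
    y = np.empty(n, dtype=np.int64)
    reward = np.zeros(n, dtype=np.int64)
    onsets = np.empty(n, dtype=np.float64)

    z_cur = int(rng.integers(2)) if initial_side is None else int(initial_side)
    streak = 0
    clock = 0.0
    score_cur = config.start_points
    score = np.empty(n, dtype=np.int64)

    for t in range(n):
        z[t] = z_cur
        x[t] = z_cur if rng.random() < config.p_reward else 1 - z_cur
        y_t = int(agent.choose(rng))
        y[t] = y_t
        responded = y_t != MISSING

        fixation = rng.uniform(*timing.fixation)
        if responded:
            wait = rng.uniform(*timing.wait)
            clock += fixation + timing.response_time + wait
        else:
            clock += fixation + timing.choice_max
        onsets[t] = clock
        clock += timing.feedback

        if responded:
            rewarded = int(y_t == x[t])
            reward[t] = 1 if rewarded else -1
            score_cur += reward[t]
            agent.observe(y_t, int(x[t]), rewarded)
        score[t] = score_cur

        # hidden-side update for the next trial
        if rule.kind == "response_contingent":
            if responded:
                streak = streak + 1 if y_t == z_cur else 0
            if streak >= rule.k_consecutive:
                z_cur = 1 - z_cur
                streak = 0
        else:
            if rng.random() < rule.h:
                z_cur = 1 - z_cur

    reversal = np.zeros(n, dtype=bool)
    reversal[1:] = z[1:] != z[:-1]
    return SessionRecord(
        z=z, x=x, y=y, reward=reward, reversal=reversal,
        feedback_onset_s=onsets, score=score, config=config,
    )


@dataclass(frozen=True)
class BehaviorSummary:
    preferred_pct: float
    rewarded_pct: float
    switch_pct: float


def summarize_behavior(session: SessionRecord) -> BehaviorSummary:
    """Percent preferred choices, rewarded choices and response switches.

    Switches are counted over consecutive pairs of responded trials.
    """
    resp = session.responded
    if resp.sum() < 2:
        raise ValueError("need at least two responded trials")
    y, z, x = session.y[resp], session.z[resp], session.x[resp]
    pair_ok = resp[1:] & resp[:-1]
    switches = (session.y[1:] != session.y[:-1])[pair_ok]
    return BehaviorSummary(
        preferred_pct=100.0 * float(np.mean(y == z)),
        rewarded_pct=100.0 * float(np.mean(y == x)),
        switch_pct=100.0 * float(np.mean(switches)) if switches.size else float("nan"),
    )


def reversal_aligned_curves(
    sessions: Iterable[SessionRecord],
    window: Sequence[int] = range(-2, 4),
) -> pd.DataFrame:
    """Mean behavioral measures around reversals, per trial offset.

    Offset 0 is the first trial governed by the new contingency.  Returns one
    row per offset with columns ``preferred_pct``, ``rewarded_pct``,
    ``switch_pct`` and sample counts; offsets with no data carry NaN and
    ``n == 0``.
    """
    window = list(window)
    if not window:
        raise ValueError("empty window")
    sessions = list(sessions)
    acc: dict[int, dict[str, list]] = {o: {"pref": [], "rew": [], "sw": []} for o in window}
    n_reversals = 0
    for s in sessions:
        rev_idx = np.flatnonzero(s.reversal)
        n_reversals += rev_idx.size
        for t0 in rev_idx:
            for o in window:
                t = t0 + o
                if not (0 <= t < s.n_trials):
                    continue
                if s.y[t] != MISSING:
                    acc[o]["pref"].append(s.y[t] == s.z[t])
                    acc[o]["rew"].append(s.y[t] == s.x[t])
                if t >= 1 and s.y[t] != MISSING and s.y[t - 1] != MISSING:
                    acc[o]["sw"].append(s.y[t] != s.y[t - 1])
    if n_reversals == 0:
        raise ValueError("no reversals in the provided sessions")
    rows = []
    for o in window:
        pref, rew, sw = acc[o]["pref"], acc[o]["rew"], acc[o]["sw"]
        rows.append(
            {
                "offset": o,
                "preferred_pct": 100.0 * np.mean(pref) if pref else np.nan,
                "rewarded_pct": 100.0 * np.mean(rew) if rew else np.nan,
                "switch_pct": 100.0 * np.mean(sw) if sw else np.nan,
                "n": len(pref),
            }
        )
    return pd.DataFrame(rows)


def session_to_tsv(session: SessionRecord, path) -> None:
    session.to_frame().to_csv(path, sep="\t", index=False)


def read_session_tsv(path, config: TaskConfig | None = None) -> SessionRecord:
    df = pd.read_csv(path, sep="\t")
    return SessionRecord(
        z=df["z"].to_numpy(np.int64),
        x=df["x"].to_numpy(np.int64),
        y=df["y"].to_numpy(np.int64),
        reward=df["reward"].to_numpy(np.int64),
        reversal=df["reversal"].to_numpy(bool),
        feedback_onset_s=df["feedback_onset_s"].to_numpy(np.float64),
        score=df["score"].to_numpy(np.int64),
        config=config,
    )
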