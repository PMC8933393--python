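"""Synthetic agent populations for the restless four-armed bandit.

The analysis pipeline needs behavioural data whose statistical structure is
known by construction: reward-oriented learners (Q-learning with softmax
choice), reward-oblivious pattern followers (constant / alternating / cycle
motor patterns), hybrids that fall back on a pattern whenever no option
clearly dominates in value, and uniform-random noise agents. Every record
carries full provenance so recovery analyses can condition on the true
generating policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import N_OPTIONS, EpisodeConfig, PayoffStructure, run_episode

Q_INIT = 50.0

AGENT_KINDS = ("q_learning", "pattern", "hybrid", "random")
PATTERN_TYPES = ("constant", "alternating", "cycle")

#: default generative parameter ranges. On a 1-98 point reward scale a
#: softmax inverse temperature of ~0.1 already discriminates a 10-point
#: value gap fairly sharply, so beta is kept well below 1.
DEFAULT_ALPHA_RANGE = (0.1, 0.6)
DEFAULT_BETA_RANGE = (0.05, 0.3)
DEFAULT_GAP_THRESHOLD = 20.0

DEFAULT_MIXTURE = {"q_learning": 0.5, "pattern": 0.3, "hybrid": 0.2}


@dataclass(frozen=True)
class AgentSpec:
    """Generative description of one synthetic participant."""

    kind: str
    alpha: float | None = None
    beta: float | None = None
    pattern_type: str | None = None
    pattern_options: tuple[int, ...] | None = None
    value_gap_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.kind in ("q_learning", "hybrid"):
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValueError("alpha must be in [0, 1] for value-learning agents")
            if self.beta is None or self.beta <= 0:
                raise ValueError("beta must be > 0 for value-learning agents")
        if self.kind in ("pattern", "hybrid"):
            if self.pattern_type not in PATTERN_TYPES:
                raise ValueError(f"pattern_type must be one of {PATTERN_TYPES}")
        if self.kind == "hybrid" and self.value_gap_threshold is None:
            raise ValueError("hybrid agents need a value_gap_threshold")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "seed": self.seed}
        for k in ("alpha", "beta", "pattern_type", "value_gap_threshold"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.pattern_options is not None:
            d["pattern_options"] = list(self.pattern_options)
        return d


@dataclass
class BehaviouralRecord:
    """One participant's actions, rewards and missed flags on one structure.

    ``actions`` uses -1 and ``rewards`` uses NaN on missed trials.
    """

    participant_id: str
    structure_id: int
    actions: np.ndarray
    rewards: np.ndarray
    missed: np.ndarray
    agent_spec: AgentSpec | None = None

    def __post_init__(self) -> None:
        self.actions = np.asarray(self.actions, dtype=int)
        self.rewards = np.asarray(self.rewards, dtype=float)
        self.missed = np.asarray(self.missed, dtype=bool)
        n = len(self.actions)
        if not (len(self.rewards) == n and len(self.missed) == n):
            raise ValueError("actions, rewards, missed must have equal length")
        if np.any(self.missed != (self.actions < 0)):
            raise ValueError("missed flags must match missing actions")
        if np.any(self.missed != np.isnan(self.rewards)):
            raise ValueError("missed flags must match missing rewards")
        ok = ~self.missed
        if np.any((self.actions[ok] < 1) | (self.actions[ok] > N_OPTIONS)):
            raise ValueError("actions must be in 1..4 on non-missed trials")

    @property
    def n_trials(self) -> int:
        return len(self.actions)

    @property
    def n_observed(self) -> int:
        return int((~self.missed).sum())


# ---------------------------------------------------------------------------
# agent step functions
# ---------------------------------------------------------------------------

def softmax(values: np.ndarray, beta: float) -> np.ndarray:
    z = beta * np.asarray(values, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def q_agent_step(
    q_values: np.ndarray,
    alpha: float,
    beta: float,
    last_outcome: tuple[int, float] | None,
    rng: np.random.Generator,
) -> int:
    """One step of a softmax Q-learner; updates ``q_values`` in place.

    If ``last_outcome`` is present, the previous trial's prediction error
    first updates the chosen option's value (delta rule with learning rate
    ``alpha``); the next action is then sampled from a softmax over the
    updated values with inverse temperature ``beta``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not np.all(np.isfinite(q_values)):
        raise ValueError("q_values must be finite")
    if last_outcome is not None:
        a, r = last_outcome
        q_values[a - 1] += alpha * (r - q_values[a - 1])
    p = softmax(q_values, beta)
    return int(rng.choice(N_OPTIONS, p=p)) + 1


def pattern_agent_step(
    action_history: list[int],
    pattern_type: str,
    options: tuple[int, ...],
    rng: np.random.Generator | None = None,
) -> int:
    """Deterministic next action of a motor-pattern follower.

    constant: always ``options[0]``. alternating: swaps between
    ``options[0]`` and ``options[1]``. cycle: walks the fixed permutation
    ``options`` (length 4) and wraps around.
    """
    if pattern_type == "constant":
        return options[0]
    if pattern_type == "alternating":
        a, b = options[0], options[1]
        if not action_history:
            return a
        return b if action_history[-1] == a else a
    if pattern_type == "cycle":
        cycle = list(options)
        if not action_history:
            return cycle[0]
        last = action_history[-1]
        idx = cycle.index(last) if last in cycle else -1
        return cycle[(idx + 1) % len(cycle)]
    raise ValueError(f"unknown pattern_type {pattern_type!r}")


def hybrid_agent_step(
    q_values: np.ndarray,
    action_history: list[int],
    spec: AgentSpec,
    last_outcome: tuple[int, float] | None,
    rng: np.random.Generator,
) -> tuple[int, str]:
    """Value-gap switching agent: reward-oriented when one option clearly
    dominates, pattern-following otherwise.

    Returns ``(action, mode)`` with mode in {"reward", "pattern"} so
    simulations can log which policy produced each choice. The Q-update from
    the previous outcome is always applied (values track rewards even while
    the agent acts on a pattern).
    """
    if spec.kind != "hybrid":
        raise ValueError("spec.kind must be 'hybrid'")
    if last_outcome is not None:
        a, r = last_outcome
        q_values[a - 1] += spec.alpha * (r - q_values[a - 1])
    top2 = np.partition(q_values, -2)[-2:]
    gap = top2[1] - top2[0]
    if gap >= spec.value_gap_threshold:
        p = softmax(q_values, spec.beta)
        return int(rng.choice(N_OPTIONS, p=p)) + 1, "reward"
    return (
        pattern_agent_step(action_history, spec.pattern_type, spec.pattern_options),
        "pattern",
    )


def make_policy(spec: AgentSpec):
    """Wrap an AgentSpec as an episode step-function with internal state."""
    q = np.full(N_OPTIONS, Q_INIT)
    history: list[int] = []

    def policy(t: int, last_outcome, rng) -> int:
        if spec.kind == "q_learning":
            a = q_agent_step(q, spec.alpha, spec.beta, last_outcome, rng)
        elif spec.kind == "pattern":
            a = pattern_agent_step(history, spec.pattern_type, spec.pattern_options)
        elif spec.kind == "hybrid":
            a, _mode = hybrid_agent_step(q, history, spec, last_outcome, rng)
        elif spec.kind == "random":
            a = int(rng.integers(1, N_OPTIONS + 1))
        else:  # pragma: no cover
            raise ValueError(spec.kind)
        history.append(a)
        return a

    return policy


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def _draw_spec(kind: str, rng: np.random.Generator, ranges: dict) -> AgentSpec:
    alpha = beta = None
    pattern_type = None
    pattern_options = None
    threshold = None
    if kind in ("q_learning", "hybrid"):
        alpha = float(rng.uniform(*ranges["alpha"]))
        beta = float(rng.uniform(*ranges["beta"]))
    if kind in ("pattern", "hybrid"):
        pattern_type = str(rng.choice(PATTERN_TYPES))
        perm = tuple(int(x) for x in rng.permutation(N_OPTIONS) + 1)
        if pattern_type == "constant":
            pattern_options = perm[:1]
        elif pattern_type == "alternating":
            pattern_options = perm[:2]
        else:
            pattern_options = perm
    if kind == "hybrid":
        threshold = float(ranges["gap_threshold"])
    return AgentSpec(
        kind=kind,
        alpha=alpha,
        beta=beta,
        pattern_type=pattern_type,
        pattern_options=pattern_options,
        value_gap_threshold=threshold,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_population(
    n_participants: int,
    mixture: dict[str, float] | None = None,
    payoffs: list[PayoffStructure] | None = None,
    episode_config: EpisodeConfig | None = None,
    seed: int = 0,
    parameter_ranges: dict | None = None,
) -> list[BehaviouralRecord]:
    """Simulate a heterogeneous population of bandit players.

    Participants are assigned payoff structures round-robin and agent kinds
    by sampling the mixture; per-kind parameters are drawn from
    ``parameter_ranges`` (defaults above). Fully reproducible by ``seed``.
    """
    if payoffs is None or len(payoffs) == 0:
        raise ValueError("need at least one payoff structure")
    mixture = dict(DEFAULT_MIXTURE if mixture is None else mixture)
    total = sum(mixture.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"mixture proportions must sum to 1, got {total}")
    for k in mixture:
        if k not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {k!r} in mixture")
    episode_config = episode_config or EpisodeConfig()
    ranges = {
        "alpha": DEFAULT_ALPHA_RANGE,
        "beta": DEFAULT_BETA_RANGE,
        "gap_threshold": DEFAULT_GAP_THRESHOLD,
    }
    if parameter_ranges:
        ranges.update(parameter_ranges)

    rng = np.random.default_rng(seed)
    kinds = list(mixture.keys())
    probs = np.array([mixture[k] for k in kinds], dtype=float)
    probs /= probs.sum()

    records = []
    for i in range(n_participants):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        spec = _draw_spec(kind, rng, ranges)
        payoff = payoffs[i % len(payoffs)]
        cfg = EpisodeConfig(
            n_trials=episode_config.n_trials,
            miss_probability=episode_config.miss_probability,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = run_episode(make_policy(spec), payoff, cfg)
        rec.participant_id = f"p{i:04d}"
        rec.structure_id = payoff.structure_id
        rec.agent_spec = spec
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# persistence: long CSV + JSON provenance manifest
# ---------------------------------------------------------------------------

def population_to_frame(records: list[BehaviouralRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for t in range(rec.n_trials):
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "trial": t + 1,
                    "action": rec.actions[t] if not rec.missed[t] else np.nan,
                    "reward": rec.rewards[t],
                    "missed": bool(rec.missed[t]),
                    "structure_id": rec.structure_id,
                }
            )
    return pd.DataFrame(rows)


def save_population(records: list[BehaviouralRecord], csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    population_to_frame(records).to_csv(csv_path, index=False)
    manifest = {
        rec.participant_id: (rec.agent_spec.to_dict() if rec.agent_spec else None)
        for rec in records
    }
    csv_path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
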