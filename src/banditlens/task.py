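"""Restless four-armed bandit task: drifting payoff structures and episode loops.

Each of the four options carries a reward value that performs an independent
Gaussian random walk over trials (per-step standard deviation ``drift_sd``,
default 2.8 points), reflected at the bounds of the reward range so that
every value stays inside ``[reward_min, reward_max]`` (default [1, 98]).
Participants (or synthetic agents) pick one option per trial and receive
the current value of that option; a trial may also be missed, in which case
no action and no reward are recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_OPTIONS = 4
DEFAULT_BOUNDS = (1.0, 98.0)
DEFAULT_DRIFT_SD = 2.8

#: seeds of the three default payoff structures used throughout the analysis
DEFAULT_STRUCTURE_SEEDS = (101, 202, 303)


@dataclass(frozen=True)
class PayoffStructure:
    """A T x 4 grid of drifting reward values, one column per option."""

    structure_id: int
    rewards: np.ndarray  # shape (T, 4), float points
    drift_sd: float
    bounds: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        r = np.asarray(self.rewards, dtype=float)
        if r.ndim != 2 or r.shape[1] != N_OPTIONS:
            raise ValueError(f"rewards must be (T, {N_OPTIONS}), got {r.shape}")
        if r.shape[0] < 5:
            raise ValueError("payoff structure needs at least 5 trials")
        lo, hi = self.bounds
        if r.min() < lo or r.max() > hi:
            raise ValueError("rewards fall outside the declared bounds")
        object.__setattr__(self, "rewards", r)

    @property
    def n_trials(self) -> int:
        return int(self.rewards.shape[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rewards, columns=[f"option_{i + 1}" for i in range(N_OPTIONS)]
        )
        df.insert(0, "trial", np.arange(1, self.n_trials + 1))
        return df


@dataclass(frozen=True)
class EpisodeConfig:
    """How one participant's episode is run."""

    n_trials: int = 150
    miss_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 5:
            raise ValueError("n_trials must be >= 5")
        if not 0.0 <= self.miss_probability < 1.0:
            raise ValueError("miss_probability must be in [0, 1)")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] by reflection at the boundaries."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return y + lo


def generate_payoff_structure(
    n_trials: int = 150,
    drift_sd: float = DEFAULT_DRIFT_SD,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    seed: int = 0,
    structure_id: int = 0,
    n_options: int = N_OPTIONS,
) -> PayoffStructure:
    """Generate one payoff structure as independent reflected Gaussian walks.

    Each option's series starts uniformly within ``bounds`` and takes
    Gaussian steps of standard deviation ``drift_sd``; steps that would
    leave the range are reflected at the boundary, which preserves the
    per-step spread away from the edges (clipping would not).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if n_trials < 5:
        raise ValueError("n_trials must be >= 5")
    if drift_sd < 0:
        raise ValueError("drift_sd must be non-negative")
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must be ordered (lo < hi)")

    rng = np.random.default_rng(seed)
    rewards = np.empty((n_trials, n_options), dtype=float)
    rewards[0] = rng.uniform(lo, hi, size=n_options)
    steps = rng.normal(0.0, drift_sd, size=(n_trials - 1, n_options))
    for t in range(1, n_trials):
        rewards[t] = _reflect(rewards[t - 1] + steps[t - 1], lo, hi)

    if n_options == N_OPTIONS:
        structure = PayoffStructure(structure_id, rewards, drift_sd, bounds, seed)
    else:
        # internal calibration use (e.g. single-option long walks) bypasses
        # the 4-column invariant
        structure = PayoffStructure.__new__(PayoffStructure)
        object.__setattr__(structure, "structure_id", structure_id)
        object.__setattr__(structure, "rewards", rewards)
        object.__setattr__(structure, "drift_sd", drift_sd)
        object.__setattr__(structure, "bounds", bounds)
        object.__setattr__(structure, "seed", seed)
    return structure


def default_payoff_structures(
    n_trials: int = 150,
    drift_sd: float = DEFAULT_DRIFT_SD,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> list[PayoffStructure]:
    """The three documented default payoff structures."""
    return [
        generate_payoff_structure(
            n_trials, drift_sd, bounds, seed=s, structure_id=i + 1
        )
        for i, s in enumerate(DEFAULT_STRUCTURE_SEEDS)
    ]


def run_episode(policy, payoff: PayoffStructure, config: EpisodeConfig):
    """Run one agent through ``config.n_trials`` trials of ``payoff``.

    ``policy`` is a step function ``policy(trial_index, last_outcome, rng)
    -> action in {1..4}`` where ``last_outcome`` is the previous
    ``(action, reward)`` pair or ``None`` (first trial or after a miss the
    previous outcome is still the last *observed* one).

    Returns a :class:`~banditlens.agents.BehaviouralRecord`-compatible dict of
    arrays; the agents module wraps it. With probability
    ``miss_probability`` a trial is marked missed: no action, no reward.
    """
    from .agents import BehaviouralRecord  # avoid import cycle at module load

    if payoff.n_trials < config.n_trials:
        raise ValueError("payoff structure shorter than the episode")

    rng = np.random.default_rng(config.seed)
    actions = np.full(config.n_trials, -1, dtype=int)
    rewards = np.full(config.n_trials, np.nan, dtype=float)
    missed = np.zeros(config.n_trials, dtype=bool)

    last_outcome: tuple[int, float] | None = None
    for t in range(config.n_trials):
        if rng.random() < config.miss_probability:
            missed[t] = True
            continue
        action = int(policy(t, last_outcome, rng))
        if not 1 <= action <= N_OPTIONS:
            raise ValueError(f"policy returned action {action}, outside 1..{N_OPTIONS}")
        reward = float(payoff.rewards[t, action - 1])
        actions[t] = action
        rewards[t] = reward
        last_outcome = (action, reward)

    return BehaviouralRecord(
        participant_id="episode",
        structure_id=payoff.structure_id,
        actions=actions,
        rewards=rewards,
        missed=missed,
    )


def save_payoff_structure(structure: PayoffStructure, csv_path: str | Path) -> None:
    """Write the reward grid as CSV with a JSON config sidecar."""
    csv_path = Path(csv_path)
    structure.to_frame().to_csv(csv_path, index=False)
    sidecar = {
        "structure_id": structure.structure_id,
        "drift_sd": structure.drift_sd,
        "bounds": list(structure.bounds),
        "seed": structure.seed,
        "n_trials": structure.n_trials,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_payoff_structure(csv_path: str | Path) -> PayoffStructure:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    rewards = df[[f"option_{i + 1}" for i in range(N_OPTIONS)]].to_numpy(float)
    return PayoffStructure(
        structure_id=int(meta["structure_id"]),
        rewards=rewards,
        drift_sd=float(meta["drift_sd"]),
        bounds=tuple(meta["bounds"]),
        seed=int(meta["seed"]),
    )
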