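"""Context-window datasets and participant-wise cross-validation folds.

A behavioural record is turned into K-step (action, reward) context windows
each paired with the next observed action as the prediction target. Missed
trials are removed from the stream first, so a window can span a gap; such
windows are kept but flagged. Training uses a sliding window (stride 1);
held-out evaluation uses non-overlapping K+1 blocks so each observed choice
is predicted at most once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import BehaviouralRecord

DEFAULT_K = 4


@dataclass(frozen=True)
class SequenceSample:
    participant_id: str
    context_actions: tuple[int, ...]   # length K
    context_rewards: tuple[float, ...]  # length K
    target_action: int
    target_trial: int                  # 1-based original trial index
    has_gap: bool

    @property
    def k(self) -> int:
        return len(self.context_actions)


@dataclass(frozen=True)
class FoldAssignment:
    fold_id: int
    train_participants: frozenset[str]
    test_participants: frozenset[str]

    def __post_init__(self) -> None:
        if self.train_participants & self.test_participants:
            raise ValueError("train and test participants overlap")


def make_windows(
    record: BehaviouralRecord,
    k: int = DEFAULT_K,
    mode: str = "sliding",
    max_gap: int | None = None,
) -> list[SequenceSample]:
    """Extract K-step context windows with next-action targets.

    Missed trials are dropped from the action stream; windows are consecutive
    over the remaining trials, and ``has_gap`` marks windows whose context or
    target spans one or more removed trials. ``mode='sliding'`` advances by
    one observed trial; ``mode='non_overlapping'`` advances by k+1 so no
    trial is reused between windows. ``max_gap`` (observed-trial windows
    spanning more than this many missed trials are dropped) is off by
    default.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("sliding", "non_overlapping"):
        raise ValueError(f"unknown mode {mode!r}")

    keep = ~record.missed
    trials = np.flatnonzero(keep) + 1  # 1-based original indices
    actions = record.actions[keep]
    rewards = record.rewards[keep]
    n = len(actions)
    if n < k + 1:
        return []

    stride = 1 if mode == "sliding" else k + 1
    samples = []
    for start in range(0, n - k, stride):
        idx = slice(start, start + k)
        span_trials = trials[start : start + k + 1]
        n_missing = int(span_trials[-1] - span_trials[0]) - k
        if max_gap is not None and n_missing > max_gap:
            continue
        samples.append(
            SequenceSample(
                participant_id=record.participant_id,
                context_actions=tuple(int(a) for a in actions[idx]),
                context_rewards=tuple(float(r) for r in rewards[idx]),
                target_action=int(actions[start + k]),
                target_trial=int(trials[start + k]),
                has_gap=n_missing > 0,
            )
        )
    return samples


def split_by_participant(
    records: list[BehaviouralRecord], k: int = 5, seed: int = 0
) -> list[FoldAssignment]:
    """Shuffle participants and partition them into k near-equal test sets."""
    ids = [rec.participant_id for rec in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(ids) < k:
        raise ValueError("fewer participants than folds")

    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_sets = [order[i::k] for i in range(k)]
    all_ids = frozenset(ids)
    folds = []
    for fold_id, test in enumerate(test_sets, start=1):
        test_set = frozenset(test)
        folds.append(
            FoldAssignment(
                fold_id=fold_id,
                train_participants=all_ids - test_set,
                test_participants=test_set,
            )
        )
    return folds


def shuffle_samples(samples: list[SequenceSample], seed: int = 0) -> list[SequenceSample]:
    """Permutation of the pooled samples, reproducible by seed."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


def windows_for_population(
    records: list[BehaviouralRecord],
    k: int = DEFAULT_K,
    mode: str = "sliding",
    participants: set[str] | frozenset[str] | None = None,
    shuffle_seed: int | None = None,
    max_gap: int | None = None,
) -> list[SequenceSample]:
    """Pool windows over (a subset of) a population; optionally shuffle."""
    samples: list[SequenceSample] = []
    for rec in records:
        if participants is not None and rec.participant_id not in participants:
            continue
        samples.extend(make_windows(rec, k=k, mode=mode, max_gap=max_gap))
    if shuffle_seed is not None:
        samples = shuffle_samples(samples, seed=shuffle_seed)
    return samples


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def samples_to_frame(samples: list[SequenceSample]) -> pd.DataFrame:
    k = samples[0].k if samples else DEFAULT_K
    rows = []
    for s in samples:
        row = {"participant_id": s.participant_id, "target_trial": s.target_trial}
        for j in range(k):
            row[f"a{j + 1}"] = s.context_actions[j]
            row[f"r{j + 1}"] = s.context_rewards[j]
        row["target_action"] = s.target_action
        row["has_gap"] = s.has_gap
        rows.append(row)
    return pd.DataFrame(rows)


def save_folds(folds: list[FoldAssignment], path: str | Path) -> None:
    payload = [
        {
            "fold_id": f.fold_id,
            "train": sorted(f.train_participants),
            "test": sorted(f.test_participants),
        }
        for f in folds
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
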