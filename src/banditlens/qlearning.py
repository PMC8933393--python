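"""Explicit reward-oriented model: Q-learning with a softmax choice rule.

The chosen option's expected value is updated by a delta rule,

    Q[a] <- Q[a] + alpha * (r - Q[a]),

with all four values initialised at 50 (the middle of the 1-98 point reward
range), and choice probabilities follow a softmax with inverse temperature
beta over the current values. A single (alpha, beta) pair is fitted for the
whole population by maximum likelihood (L-BFGS-B with random multi-starts).
The model's behavioural prediction on each trial is the argmax of the
pre-choice Q-values, with ties broken toward the lowest option index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .agents import BehaviouralRecord, Q_INIT, softmax
from .task import N_OPTIONS

DEFAULT_BOUNDS = ((0.0, 1.0), (1e-4, 1.0))  # (alpha, beta); beta > 0


@dataclass(frozen=True)
class QParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("parameters must be finite")


@dataclass
class QTrace:
    """Per-trial pre-choice Q-values, choice probabilities and predictions."""

    q_values: np.ndarray       # (T, 4), values *before* each trial's update
    choice_probs: np.ndarray   # (T, 4)
    predictions: np.ndarray    # (T,) argmax action, ties -> lowest index

    def __post_init__(self) -> None:
        if not np.allclose(self.choice_probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("choice probabilities must sum to 1 per trial")


@dataclass
class QFitResult:
    params: QParams
    nll: float
    n_trials: int
    n_starts: int
    converged: bool
    starts: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "alpha": self.params.alpha,
                    "beta": self.params.beta,
                    "nll": self.nll,
                    "n_trials": self.n_trials,
                    "n_starts": self.n_starts,
                    "converged": self.converged,
                },
                indent=2,
            )
        )


def q_update(q: np.ndarray, action: int, reward: float, alpha: float) -> np.ndarray:
    """Delta-rule update of the chosen option; returns a new array."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not 1 <= action <= N_OPTIONS:
        raise ValueError("action must be in 1..4")
    out = np.array(q, dtype=float)
    out[action - 1] += alpha * (reward - out[action - 1])
    return out


def action_probs(q: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities with inverse temperature beta."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("q-values must be finite")
    return softmax(q, beta)


def trace(record: BehaviouralRecord, params: QParams) -> QTrace:
    """Trial-by-trial Q-values, choice probabilities and argmax predictions.

    Values start at 50, the update is applied only on observed trials, and
    each trial's probabilities/prediction use the pre-choice values (missed
    trials carry the values through unchanged).
    """
    T = record.n_trials
    q = np.full(N_OPTIONS, Q_INIT)
    q_values = np.empty((T, N_OPTIONS))
    probs = np.empty((T, N_OPTIONS))
    preds = np.empty(T, dtype=int)
    for t in range(T):
        q_values[t] = q
        probs[t] = softmax(q, params.beta)
        preds[t] = int(np.argmax(q)) + 1  # np.argmax ties -> lowest index
        if not record.missed[t]:
            q = q_update(q, int(record.actions[t]), float(record.rewards[t]), params.alpha)
    return QTrace(q_values=q_values, choice_probs=probs, predictions=preds)


def _stack_records(records: list[BehaviouralRecord]):
    """Pad records to a common length: actions (R, T) with -1 beyond the end
    or on missed trials, rewards (R, T) with 0 placeholders."""
    T = max(rec.n_trials for rec in records)
    actions = np.full((len(records), T), -1, dtype=int)
    rewards = np.zeros((len(records), T))
    for i, rec in enumerate(records):
        actions[i, : rec.n_trials] = rec.actions
        rewards[i, : rec.n_trials] = np.where(rec.missed, 0.0, rec.rewards)
    return actions, rewards


def negative_log_likelihood(
    records: list[BehaviouralRecord], params: QParams
) -> float:
    """Summed -log p(observed action) over all non-missed trials.

    Vectorised over participants: the Q recursion runs once per trial for
    the whole stack of records.
    """
    if not records:
        raise ValueError("records must be non-empty")
    actions, rewards = _stack_records(records)
    R, T = actions.shape
    q = np.full((R, 4), Q_INIT)
    rows = np.arange(R)
    total = 0.0
    for t in range(T):
        a = actions[:, t]
        ok = a > 0
        z = params.beta * q
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        logp = z - np.log(e.sum(axis=1, keepdims=True))
        total -= float(logp[rows[ok], a[ok] - 1].sum())
        chosen = q[rows[ok], a[ok] - 1]
        q[rows[ok], a[ok] - 1] = chosen + params.alpha * (rewards[ok, t] - chosen)
    if not np.isfinite(total):
        return np.inf
    return total


def fit(
    records: list[BehaviouralRecord],
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    n_starts: int = 5,
    seed: int = 0,
) -> QFitResult:
    """Group-level maximum-likelihood fit of (alpha, beta) by L-BFGS-B.

    The likelihood is pooled over every participant's observed trials, and
    the bounded minimisation is restarted from ``n_starts`` random points
    inside the search box; the best converged solution wins.
    """
    if not records:
        raise ValueError("records must be non-empty")
    (a_lo, a_hi), (b_lo, b_hi) = bounds
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        try:
            return negative_log_likelihood(records, QParams(float(x[0]), float(x[1])))
        except ValueError:
            return np.inf

    best = None
    starts_log = []
    for _ in range(n_starts):
        x0 = np.array([rng.uniform(a_lo, a_hi), rng.uniform(max(b_lo, 1e-3), b_hi)])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=[(a_lo, a_hi), (b_lo, b_hi)])
        starts_log.append({"x0": x0.tolist(), "fun": float(res.fun), "success": bool(res.success)})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} L-BFGS-B starts failed: {starts_log}")

    n_trials = int(sum(rec.n_observed for rec in records))
    return QFitResult(
        params=QParams(float(best.x[0]), float(best.x[1])),
        nll=float(best.fun),
        n_trials=n_trials,
        n_starts=n_starts,
        converged=True,
        starts=starts_log,
    )


def fit_per_participant(
    records: list[BehaviouralRecord], **kwargs
) -> dict[str, QFitResult]:
    """Independent fit per participant (non-default alternative to the pooled fit)."""
    return {rec.participant_id: fit([rec], **kwargs) for rec in records}


def predict_and_score(
    records: list[BehaviouralRecord], params: QParams
) -> "QScore":
    """Argmax predictions and accuracy over non-missed trials.

    The first trial's prediction is the tie-broken argmax of the all-50
    initialisation; it is included but flagged via ``first_trial`` so
    reports can drop it.
    """
    rows = []
    for rec in records:
        tr = trace(rec, params)
        for t in range(rec.n_trials):
            if rec.missed[t]:
                continue
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "trial": t + 1,
                    "prediction": int(tr.predictions[t]),
                    "observed": int(rec.actions[t]),
                    "correct": bool(tr.predictions[t] == rec.actions[t]),
                    "first_trial": t == 0,
                }
            )
    return QScore(rows)


class QScore:
    """Per-trial predictions with participant-wise and trial-wise aggregates."""

    def __init__(self, rows: list[dict]):
        import pandas as pd

        self.table = pd.DataFrame(
            rows,
            columns=[
                "participant_id", "trial", "prediction", "observed",
                "correct", "first_trial",
            ],
        )

    @property
    def accuracy(self) -> float | None:
        if self.table.empty:
            return None
        return float(self.table["correct"].mean())

    def accuracy_by_participant(self):
        return self.table.groupby("participant_id")["correct"].agg(["size", "sum", "mean"])

    def accuracy_by_trial(self):
        return self.table.groupby("trial")["correct"].agg(["size", "sum", "mean"])


def simulate_probe(
    actions: tuple[int, int, int, int],
    rewards: tuple[float, float, float, float],
    params: QParams,
) -> np.ndarray:
    """Fifth-choice softmax distribution after a fresh 4-step context.

    Values start at 50, the four (action, reward) updates are applied in
    order, and the returned vector is the softmax over the resulting values.
    """
    if len(actions) != 4 or len(rewards) != 4:
        raise ValueError("probe needs exactly 4 action-reward pairs")
    q = np.full(N_OPTIONS, Q_INIT)
    for a, r in zip(actions, rewards):
        q = q_update(q, int(a), float(r), params.alpha)
    return softmax(q, params.beta)
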