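"""End-to-end orchestration: population -> datasets -> three models ->
comparison -> probes, with a reproducible report bundle.

All randomness flows from one global seed through named substreams, so each
stage is independently reproducible. The three models are wrapped in a
common probe interface (``probe_proba(actions, rewards)``) so the probe
module never needs to know what kind of model it is scoring.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agents, compare, dataset, lstm, probes, qlearning, task

logger = logging.getLogger("banditlens")

MODEL_NAMES = ("exploratory", "reward_oblivious", "q_model")


def substream(seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the global seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one full desk-scale study run depends on."""

    n_participants: int = 240
    mixture: dict = field(default_factory=lambda: dict(agents.DEFAULT_MIXTURE))
    n_trials: int = 150
    drift_sd: float = task.DEFAULT_DRIFT_SD
    bounds: tuple = task.DEFAULT_BOUNDS
    miss_probability: float = 0.01
    n_structures: int = 3
    k: int = 4
    n_folds: int = 5
    epochs: int = 300  # faithful recipe; reduce for quick smoke runs
    batch_size: int = 2048
    hidden_units: int = 64
    learning_rate: float = 0.001
    q_n_starts: int = 5
    variants_per_cell: int = 8
    seed: int = 0
    out_dir: str = "runs/default"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["bounds"] = list(d["bounds"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["bounds"] = tuple(d["bounds"])
        return cls(**d)


# ---------------------------------------------------------------------------
# probe adapters: a uniform fifth-choice interface over the three models
# ---------------------------------------------------------------------------

class RecurrentAdapter:
    def __init__(self, model: lstm.RecurrentPolicyModel):
        self.model = model

    def probe_proba(self, actions, rewards) -> np.ndarray:
        return self.model.predict_proba(list(zip(actions, rewards)))


class QAdapter:
    def __init__(self, params: qlearning.QParams):
        self.params = params

    def probe_proba(self, actions, rewards) -> np.ndarray:
        return qlearning.simulate_probe(tuple(actions), tuple(rewards), self.params)


def model_adapters(
    exploratory: lstm.RecurrentPolicyModel,
    reward_oblivious: lstm.RecurrentPolicyModel,
    q_params: qlearning.QParams,
) -> dict:
    return {
        "exploratory": RecurrentAdapter(exploratory),
        "reward_oblivious": RecurrentAdapter(reward_oblivious),
        "q_model": QAdapter(q_params),
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig) -> list[agents.BehaviouralRecord]:
    payoffs = [
        task.generate_payoff_structure(
            config.n_trials,
            config.drift_sd,
            config.bounds,
            seed=substream(config.seed, f"payoff{i}"),
            structure_id=i + 1,
        )
        for i in range(config.n_structures)
    ]
    return agents.generate_population(
        config.n_participants,
        mixture=config.mixture,
        payoffs=payoffs,
        episode_config=task.EpisodeConfig(
            n_trials=config.n_trials, miss_probability=config.miss_probability
        ),
        seed=substream(config.seed, "population"),
    )


def train_models_on_split(
    records: list[agents.BehaviouralRecord],
    fold: dataset.FoldAssignment,
    config: RunConfig,
) -> dict:
    """Fit all three models on one fold's training participants."""
    train_samples = dataset.windows_for_population(
        records,
        k=config.k,
        mode="sliding",
        participants=fold.train_participants,
        shuffle_seed=substream(config.seed, f"shuffle{fold.fold_id}"),
    )
    tc = lstm.TrainingConfig(
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=substream(config.seed, f"weights{fold.fold_id}"),
    )
    exploratory = lstm.train(train_samples, "action_reward", tc, config.hidden_units)
    reward_oblivious = lstm.train(train_samples, "action_only", tc, config.hidden_units)
    train_records = [r for r in records if r.participant_id in fold.train_participants]
    q_fit = qlearning.fit(
        train_records,
        n_starts=config.q_n_starts,
        seed=substream(config.seed, f"qfit{fold.fold_id}"),
    )
    return {
        "exploratory": exploratory,
        "reward_oblivious": reward_oblivious,
        "q_fit": q_fit,
        "train_samples": train_samples,
    }


def evaluate_split(
    records: list[agents.BehaviouralRecord],
    fold: dataset.FoldAssignment,
    models: dict,
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Score all three models on the fold's held-out participants.

    Evaluation windows are non-overlapping (each observed choice predicted
    at most once); the Q-model is scored on exactly the same
    (participant, target trial) pairs for a fair comparison.
    """
    test_samples = dataset.windows_for_population(
        records, k=config.k, mode="non_overlapping",
        participants=fold.test_participants,
    )
    preds = {
        name: lstm.evaluate(models[name], test_samples)
        for name in ("exploratory", "reward_oblivious")
    }
    test_records = [r for r in records if r.participant_id in fold.test_participants]
    q_score = qlearning.predict_and_score(test_records, models["q_fit"].params)
    q_table = q_score.table.rename(columns={"trial": "target_trial"})
    keys = preds["exploratory"][["participant_id", "target_trial"]]
    q_aligned = keys.merge(q_table, on=["participant_id", "target_trial"], how="left")
    if q_aligned["correct"].isna().any():
        raise RuntimeError("Q-model missing predictions on the shared set")
    preds["q_model"] = q_aligned[
        ["participant_id", "target_trial", "prediction", "observed", "correct"]
    ]
    return preds


def cross_validated_predictions(
    records: list[agents.BehaviouralRecord], config: RunConfig
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Full k-fold CV: per-fold training, single evaluation per participant."""
    folds = dataset.split_by_participant(
        records, k=config.n_folds, seed=substream(config.seed, "folds")
    )
    all_preds: dict[str, list[pd.DataFrame]] = {n: [] for n in MODEL_NAMES}
    fold_models = []
    for fold in folds:
        models = train_models_on_split(records, fold, config)
        preds = evaluate_split(records, fold, models, config)
        for name in MODEL_NAMES:
            all_preds[name].append(preds[name])
        fold_models.append(models)
    merged = {n: pd.concat(ps, ignore_index=True) for n, ps in all_preds.items()}
    return merged, fold_models


# ---------------------------------------------------------------------------
# real-data loading (long CSV: participant, trial, action, reward)
# ---------------------------------------------------------------------------

def load_real_records(path: str | Path) -> list[agents.BehaviouralRecord]:
    """Load behavioural data in long format into validated records.

    Rows with missing action/reward are treated as missed trials;
    out-of-range actions or rewards are rejected with their row numbers.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "trial", "action", "reward"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    bad = df.index[
        df["action"].notna() & ~df["action"].isin([1, 2, 3, 4])
    ].tolist()
    if bad:
        raise ValueError(f"{path}: invalid action at rows {bad[:10]}")
    bad_r = df.index[df["reward"].notna() & ((df["reward"] < 1) | (df["reward"] > 98))]
    if len(bad_r):
        raise ValueError(f"{path}: reward out of [1, 98] at rows {bad_r.tolist()[:10]}")

    records = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial")
        n = int(grp["trial"].max())
        actions = np.full(n, -1, dtype=int)
        rewards = np.full(n, np.nan)
        missed = np.ones(n, dtype=bool)
        for _, row in grp.iterrows():
            t = int(row["trial"]) - 1
            if pd.notna(row["action"]) and pd.notna(row["reward"]):
                actions[t] = int(row["action"])
                rewards[t] = float(row["reward"])
                missed[t] = False
        records.append(
            agents.BehaviouralRecord(
                participant_id=str(pid),
                structure_id=int(grp["structure_id"].iloc[0])
                if "structure_id" in grp
                else 0,
                actions=actions,
                rewards=rewards,
                missed=missed,
            )
        )
    return records


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage and emit a report bundle under config.out_dir.

    Returns the machine-readable summary (also written as summary.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    timings = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.time()
        return name

    stage("simulate")
    records = simulate_stage(config)
    agents.save_population(records, out / "population.csv")

    stage("cv")
    folds = dataset.split_by_participant(
        records, k=config.n_folds, seed=substream(config.seed, "folds")
    )
    dataset.save_folds(folds, out / "folds.json")
    predictions, fold_models = cross_validated_predictions(records, config)
    for name, table in predictions.items():
        table.to_csv(out / f"predictions_{name}.csv", index=False)

    stage("compare")
    acc_part = compare.accuracy_by_participant(predictions)
    acc_time = compare.accuracy_by_time(predictions)
    acc_part.to_csv(out / "accuracy_by_participant.csv", index=False)
    acc_time.to_csv(out / "accuracy_by_time.csv", index=False)
    sim = compare.similarity_over_time(
        predictions["q_model"], predictions["reward_oblivious"]
    )
    sim.to_csv(out / "similarity_q_vs_oblivious.csv", index=False)

    stage("probes")
    # probe scoring uses the first fold's trained models
    m0 = fold_models[0]
    adapters = model_adapters(
        m0["exploratory"], m0["reward_oblivious"], m0["q_fit"].params
    )
    probe_list = probes.enumerate_probes(
        variants_per_cell=config.variants_per_cell,
        seed=substream(config.seed, "probes"),
    )
    probe_preds = probes.collect_predictions(probe_list, adapters)
    cells, per_probe = probes.distance_matrix(probe_preds)
    labels = probes.classify_convergence(cells)
    probe_preds.to_csv(out / "probe_predictions.csv", index=False)
    cells.to_csv(out / "probe_distance_cells.csv", index=False)
    per_probe.to_csv(out / "probe_distances.csv", index=False)
    labels.to_csv(out / "probe_convergence_labels.csv", index=False)

    stage("report")
    pooled = {n: compare.pooled_accuracy(t) for n, t in predictions.items()}
    m0["q_fit"].to_json(out / "q_fit.json")
    lstm.save_model(m0["exploratory"], out / "exploratory.npz")
    lstm.save_model(m0["reward_oblivious"], out / "reward_oblivious.npz")
    summary = {
        "config": json.loads(config.to_json()),
        "n_records": len(records),
        "pooled_accuracy": pooled,
        "q_fit": {"alpha": m0["q_fit"].params.alpha, "beta": m0["q_fit"].params.beta},
        "convergence_labels": labels.to_dict(orient="records"),
        "files": {},
    }
    for f in sorted(out.glob("*")):
        if f.name != "summary.json" and f.is_file():
            summary["files"][f.name] = _hash_file(f)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
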