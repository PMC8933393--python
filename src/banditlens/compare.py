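"""Model comparison on a shared prediction set.

All models are scored on identical (participant, target_trial) pairs; the
comparison surfaces are accuracy by participant, accuracy by trial, and a
trial-wise similarity statistic: the fraction of participants on which two
models agree in correctness (both right or both wrong) at that trial. The
similarity of a model with itself is 1 everywhere; complementary models
score 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

KEY = ["participant_id", "target_trial"]


def _check_aligned(predictions: dict[str, pd.DataFrame]) -> None:
    names = list(predictions)
    ref = set(map(tuple, predictions[names[0]][KEY].itertuples(index=False)))
    for name in names[1:]:
        other = set(map(tuple, predictions[name][KEY].itertuples(index=False)))
        if other != ref:
            raise ValueError(
                f"prediction sets differ between {names[0]!r} and {name!r} "
                f"({len(ref ^ other)} mismatched keys)"
            )


def accuracy_by_participant(predictions: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-participant accuracy per model, plus pairwise difference columns.

    ``predictions`` maps model name to a table with participant_id,
    target_trial and a boolean ``correct`` column (as produced by the
    models' evaluate/score functions), all on the same prediction set.
    """
    _check_aligned(predictions)
    parts = []
    for name, table in predictions.items():
        g = table.groupby("participant_id")["correct"].agg(
            n_predictions="size", n_correct="sum", accuracy="mean"
        )
        g["model_name"] = name
        parts.append(g.reset_index())
    long = pd.concat(parts, ignore_index=True)

    wide = long.pivot(index="participant_id", columns="model_name", values="accuracy")
    names = list(predictions)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            wide[f"{a}_minus_{b}"] = wide[a] - wide[b]
    return wide.reset_index().merge(
        long.pivot(index="participant_id", columns="model_name", values="n_predictions")
        .add_prefix("n_")
        .reset_index(),
        on="participant_id",
    )


def pooled_accuracy(table: pd.DataFrame) -> float:
    return float(table["correct"].mean())


def accuracy_by_time(predictions: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-target-trial accuracy curve for each model (long format)."""
    _check_aligned(predictions)
    parts = []
    for name, table in predictions.items():
        g = table.groupby("target_trial")["correct"].agg(
            n_predictions="size", n_correct="sum", accuracy="mean"
        )
        g["model_name"] = name
        parts.append(g.reset_index())
    return pd.concat(parts, ignore_index=True)


def similarity_over_time(
    correct_a: pd.DataFrame, correct_b: pd.DataFrame
) -> pd.DataFrame:
    """Trial-wise agreement in correctness between two models.

    For each target trial with M jointly-scored participants, similarity is
    the fraction on which the models are both correct or both wrong
    (agreement = 1 - XOR of the correctness flags). Trials with M = 0 are
    absent from the output.
    """
    a = correct_a.set_index(KEY)["correct"]
    b = correct_b.set_index(KEY)["correct"]
    joined = pd.concat({"a": a, "b": b}, axis=1, join="inner").reset_index()
    if joined.empty:
        return pd.DataFrame(columns=["target_trial", "similarity", "m"])
    joined["agree"] = joined["a"] == joined["b"]
    out = joined.groupby("target_trial")["agree"].agg(similarity="mean", m="size")
    return out.reset_index()
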