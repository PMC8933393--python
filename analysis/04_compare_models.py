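#!/usr/bin/env python
"""Compare the three models on the shared held-out prediction set.

Produces accuracy by participant (with pairwise differences), accuracy by
trial, and the trial-wise similarity (correctness agreement) between the
Q-learning and reward-oblivious models. Run 03_train_and_evaluate.py first.
"""

from pathlib import Path

import pandas as pd

import banditlens as bl

OUT = Path("results/study")
MODELS = ("exploratory", "reward_oblivious", "q_model")


def main() -> None:
    predictions = {
        name: pd.read_csv(OUT / f"predictions_{name}.csv") for name in MODELS
    }
    for name, table in predictions.items():
        print(f"{name}: pooled held-out accuracy {table['correct'].mean():.3f}")

    by_participant = bl.compare.accuracy_by_participant(predictions)
    by_participant.to_csv(OUT / "accuracy_by_participant.csv", index=False)
    by_time = bl.compare.accuracy_by_time(predictions)
    by_time.to_csv(OUT / "accuracy_by_time.csv", index=False)

    sim = bl.compare.similarity_over_time(
        predictions["q_model"], predictions["reward_oblivious"]
    )
    sim.to_csv(OUT / "similarity_q_vs_oblivious.csv", index=False)
    print(
        "Q vs reward-oblivious similarity: "
        f"median {sim['similarity'].median():.3f} over {len(sim)} trials"
    )
    gap = by_participant["exploratory_minus_q_model"]
    print(
        f"exploratory - q_model accuracy gap: mean {gap.mean():+.3f} "
        f"({(gap > 0).mean():.0%} of participants favour the black box)"
    )


if __name__ == "__main__":
    main()
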