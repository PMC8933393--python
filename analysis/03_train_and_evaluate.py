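#!/usr/bin/env python
"""Train the two recurrent models and evaluate all three on held-out data.

Splits participants into five folds, trains the exploratory
(action + reward) and reward-oblivious (action only) LSTMs and fits the
Q-model on each fold's training 80%, then scores all three on the held-out
20% with non-overlapping windows so every choice is predicted exactly once.
Pass --single-fold to train on the first fold only (a few minutes instead
of ~15).
"""

import argparse
from pathlib import Path

import banditlens as bl
from banditlens import pipeline as pl

OUT = Path("results/study")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--single-fold", action="store_true")
    args = parser.parse_args()

    cfg = pl.RunConfig.from_json((OUT / "config.json").read_text())
    records = pl.load_real_records(OUT / "population.csv")

    if args.single_fold:
        folds = bl.dataset.split_by_participant(
            records, k=cfg.n_folds, seed=pl.substream(cfg.seed, "folds")
        )[:1]
        bl.dataset.save_folds(folds, OUT / "folds.json")
        models = pl.train_models_on_split(records, folds[0], cfg)
        predictions = pl.evaluate_split(records, folds[0], models, cfg)
        keep = models
    else:
        predictions, fold_models = pl.cross_validated_predictions(records, cfg)
        keep = fold_models[0]

    for name, table in predictions.items():
        table.to_csv(OUT / f"predictions_{name}.csv", index=False)
        print(f"{name}: held-out accuracy {table['correct'].mean():.3f} "
              f"({len(table)} predictions)")
    bl.lstm.save_model(keep["exploratory"], OUT / "exploratory.npz")
    bl.lstm.save_model(keep["reward_oblivious"], OUT / "reward_oblivious.npz")
    keep["q_fit"].to_json(OUT / "q_fit.json")
    print(f"saved model checkpoints and predictions under {OUT}")


if __name__ == "__main__":
    main()
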