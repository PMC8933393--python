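#!/usr/bin/env python
"""Probe the trained models with hand-designed action-reward sequences.

Feeds every probe (3 action patterns x 3 reward patterns, 8 variants per
cell) to the three models, scores pairwise symmetric KL distances between
their fifth-choice distributions, aggregates by category cell, and labels
each cell by which explicit model the black-box model converges with.
Run 03_train_and_evaluate.py first.
"""

import json
from pathlib import Path

import banditlens as bl
from banditlens import pipeline as pl

OUT = Path("results/study")


def main() -> None:
    cfg = pl.RunConfig.from_json((OUT / "config.json").read_text())
    exploratory = bl.lstm.load_model(OUT / "exploratory.npz")
    reward_oblivious = bl.lstm.load_model(OUT / "reward_oblivious.npz")
    q_meta = json.loads((OUT / "q_fit.json").read_text())
    q_params = bl.qlearning.QParams(q_meta["alpha"], q_meta["beta"])

    adapters = pl.model_adapters(exploratory, reward_oblivious, q_params)
    probes = bl.probes.enumerate_probes(
        variants_per_cell=cfg.variants_per_cell, seed=pl.substream(cfg.seed, "probes")
    )
    preds = bl.probes.collect_predictions(probes, adapters)
    preds.to_csv(OUT / "probe_predictions.csv", index=False)

    ro = preds[preds["model_name"] == "reward_oblivious"]
    rate = (ro["argmax_action"] == ro["pattern_completion"]).mean()
    print(f"{len(probes)} probes; reward-oblivious pattern completion {rate:.1%}")

    cells, per_probe = bl.probes.distance_matrix(preds)
    cells.to_csv(OUT / "probe_distance_cells.csv", index=False)
    per_probe.to_csv(OUT / "probe_distances.csv", index=False)
    labels = bl.probes.classify_convergence(cells)
    labels.to_csv(OUT / "probe_convergence_labels.csv", index=False)
    for _, row in labels.iterrows():
        print(
            f"  {row['action_category']:>13} actions x {row['reward_category']:>10} "
            f"rewards: d(exp,Q) = {row['d_exploratory_q']:.3f}, "
            f"d(exp,RO) = {row['d_exploratory_oblivious']:.3f} -> {row['label']}"
        )


if __name__ == "__main__":
    main()
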