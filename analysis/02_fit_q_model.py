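#!/usr/bin/env python
"""Fit the reward-oriented Q-learning model at the group level.

Pools every participant's observed trials into one likelihood and fits
(learning rate alpha, inverse temperature beta) by L-BFGS-B with random
multi-starts. Run 01_simulate_population.py first.
"""

from pathlib import Path

import banditlens as bl
from banditlens import pipeline as pl

OUT = Path("results/study")


def main() -> None:
    cfg = pl.RunConfig.from_json((OUT / "config.json").read_text())
    records = pl.load_real_records(OUT / "population.csv")
    result = bl.qlearning.fit(
        records, n_starts=cfg.q_n_starts, seed=pl.substream(cfg.seed, "qfit-pooled")
    )
    result.to_json(OUT / "q_fit_population.json")
    print(
        f"group fit over {result.n_trials} trials: "
        f"alpha = {result.params.alpha:.3f}, beta = {result.params.beta:.3f}, "
        f"NLL = {result.nll:.1f}"
    )
    score = bl.qlearning.predict_and_score(records, result.params)
    print(f"argmax accuracy on all observed trials: {score.accuracy:.3f}")


if __name__ == "__main__":
    main()
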