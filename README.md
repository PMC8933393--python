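# banditlens

Black-box sequence models predict human choices in restless bandit tasks
well — but what did they learn? `banditlens` builds the full
characterisation pipeline for a four-armed restless bandit: it trains a
recurrent next-action model on behavioural sequences and then *explains*
it by comparison with two transparent cognitive models, using held-out
accuracy, a trial-wise similarity statistic, and probe experiments scored
with a symmetric Kullback–Leibler distance. Everything runs on synthetic
agent populations with known generating policies, so every claim in the
pipeline can be validated against ground truth. It is aimed at
computational cognitive modellers who want a tested, reproducible harness
for this style of model-explanation analysis (a loader for real long-format
behavioural data is included).

## The models

**Task.** On each of 150 rounds a player picks one of four options and
receives a reward r ∈ [1, 98] points; each option's payoff drifts as a
bounded Gaussian random walk with σ = 2.8 points/trial.

**Reward-oriented (Q-learning).** Expected values Q(a), initialised at 50,
update only for the chosen action:

    Q_{t+1}(a_t) = Q_t(a_t) + α (r_t − Q_t(a_t)),

with choices softmax-distributed, p_t(a) ∝ exp(β Q_t(a)). A single (α, β)
is fitted to the whole population by maximum likelihood (L-BFGS-B,
multi-start). Its behavioural prediction each trial is argmax Q.

**Reward-oblivious.** A single-layer LSTM (64 hidden units, 4-way softmax
head) that sees only the last K = 4 *actions* — it can complete choice
patterns (constant a–a–a–a, alternating a–b–a–b, cycling a–b–c–d) but
cannot use rewards.

**Exploratory (the black box).** The same LSTM given (action, reward)
pairs. Both networks are trained with Adam (lr 0.001, β₁ 0.9, β₂ 0.99,
batch 2048, 300 epochs) on 4-step sliding windows, with cross-validation
split by participant; the LSTM and its backpropagation are implemented in
numpy and verified against numerical gradients.

**Comparison.** Per-trial similarity between two models is the fraction of
participants on which they are both correct or both wrong. Probe
experiments feed hand-designed 4-step action×reward contexts (3 action
patterns × 3 reward patterns, several variants per cell) to all three
models and score pairwise distances between their fifth-choice
distributions with SymKL(P, Q) = ½KL(P‖Q) + ½KL(Q‖P); cell-averaged
distances show where the black box converges with each explicit model.

## Worked example

Probe the fitted reward-oriented model with a fresh 4-step context
(α = 0.3, β = 0.15):

```python
>>> import numpy as np
>>> from banditlens.qlearning import QParams, simulate_probe
>>> from banditlens.probes import sym_kl
>>> p = QParams(alpha=0.3, beta=0.15)
>>> np.round(simulate_probe((1, 2, 3, 4), (40, 40, 40, 40), p), 3)
array([0.25, 0.25, 0.25, 0.25])
>>> np.round(simulate_probe((1, 2, 3, 4), (20, 30, 70, 80), p), 3)
array([0.037, 0.058, 0.352, 0.552])
>>> np.round(simulate_probe((1, 2, 3, 4), (80, 60, 40, 20), p), 3)
array([0.61 , 0.248, 0.101, 0.041])
```

Trying each option once at the same reward leaves the values tied — the
fifth choice is exactly uniform for *any* (α, β). Ascending rewards put
the mode on the last-chosen option 4 (p = 0.552); descending rewards on
the first (p = 0.610). A reward-oblivious pattern completer instead picks
the action that continues the cycle (option 1) in all three cases, which
is what makes these probes diagnostic. The two reward-pattern predictions
sit 1.76 nats apart in symmetric KL:

```python
>>> a = simulate_probe((1, 2, 3, 4), (20, 30, 70, 80), p)
>>> d = simulate_probe((1, 2, 3, 4), (80, 60, 40, 20), p)
>>> round(sym_kl(a, d), 4)
1.7617
```

The full synthetic study is the sequence of drivers under `analysis/`
(simulate → fit Q → train/evaluate networks → compare → probes), each of
which prints what it found and writes its tables under `results/study/`.
On the default 240-participant mixture population (50% Q-learners, 30%
pattern followers, 20% hybrids), held-out accuracy orders exploratory
0.912 ≥ reward-oblivious 0.908 ≥ Q-model 0.646, and the reward-oblivious
net completes 100% of probe action patterns. The same pipeline is exposed
as a CLI (`banditlens simulate|fit-q|train-rnn|run-all|report`).

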