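# Methods

## The task and what the package studies

Participants in a restless four-armed bandit choose one of four options on
each of 150 rounds and receive a reward in points. Each option's payoff
performs an independent Gaussian random walk (per-step sd σ = 2.8 points)
bounded in [1, 98], so the best option changes over time and the player has
to keep tracking outcomes. A response deadline means some rounds are
missed: no choice, no reward.

The package asks how far a high-capacity black-box sequence model that
predicts the next choice can be *explained* by two transparent cognitive
models:

- a **reward-oriented** model — Q-learning with a softmax choice rule,
  which assumes choices maximise learned expected reward;
- a **reward-oblivious** model — a sequence model that sees only past
  actions and can therefore only complete motor/choice patterns.

Three comparison surfaces are computed: held-out prediction accuracy, a
trial-wise similarity statistic (do two models succeed and fail on the same
participants?), and probe experiments in which hand-designed 4-step
action–reward contexts are fed to all models and their fifth-choice
distributions are compared with a symmetric Kullback–Leibler (KL) distance.

Everything runs on synthetic populations whose generating policies are
known, so each claim can be checked against ground truth.

## Task generator

Each option's reward series starts uniformly in the bounds and takes
Gaussian steps of sd `drift_sd` (default 2.8). The boundary behaviour of
the walk is not prescribed anywhere, so a choice was needed: values are
**reflected** at the bounds rather than clipped, because clipping
accumulates probability mass at the edges and shrinks the realised
per-step sd, while reflection preserves it away from the boundaries (the
calibration check measures sd over 10⁵ steps with bounds widened so
reflection never triggers, and requires 2.8 ± 0.05). Rewards are kept as
real numbers internally and rounded only on CSV export.

Three default payoff structures are generated from three fixed, documented
seeds (101, 202, 303). Missed trials are a Bernoulli process per trial; the
default rate of 1% per trial makes ≈ 4% of extracted 4-step windows span a
gap, the rate reported for the reference human dataset.

## Synthetic population

The generator emulates a population in which reward learning and motor
patterns coexist:

| kind        | share | behaviour |
|-------------|-------|-----------|
| q_learning  | 0.50  | softmax Q-learner, α ~ U[0.1, 0.6], β ~ U[0.05, 0.3] |
| pattern     | 0.30  | deterministic constant / alternating / cycle pattern |
| hybrid      | 0.20  | Q-learner that falls back on its pattern when no option clearly dominates |

β is kept well below 1 because rewards live on a 1–98 scale: β ≈ 0.1
already discriminates a 10-point value gap fairly sharply. Q-values (for
agents and for the fitted model alike) initialise at 50, the midpoint of
the reward range.

Cycle agents walk a **per-agent fixed permutation** of the four options,
not only 1→2→3→4. This is the generative counterpart of varying "which
options play the roles a, b, c, d" in the probe set, and it makes the
pattern completion of an all-different window a–b–c–d its first action a
(the cycle wraps), for any permutation.

Hybrid agents are a construct of this package: they always update Q-values,
but act on their pattern whenever the gap between the best and second-best
value is below a threshold (default 20 points), switching to softmax
reward-seeking when one option clearly dominates. This is the simplest
mechanism that produces "pattern use when values are uninformative", the
qualitative behaviour the analysis is designed to detect. No claim is made
that humans implement this rule.

What the generator does **not** emulate: reaction times, learning across
sessions, forgetting/decay, individual drift in strategy over the session,
and any reward sensitivity inside the pattern policies (a pattern agent
never abandons its pattern, however bad the rewards — see *Known
limitations* below, where this matters).

## Datasets and cross-validation

Records are cut into K = 4-step (action, reward) windows with the next
observed action as the target; the first prediction is therefore for round
5. Missed trials are removed from the stream first; a window that spans a
removed trial is kept but flagged (`has_gap`), and a maximum-gap filter is
available but off by default. Training extraction slides by one trial;
held-out evaluation uses non-overlapping K+1 blocks so every choice is
predicted at most once. Cross-validation splits at the **participant**
level (default five folds, 80/20), so networks are always evaluated on
unseen individuals; pooled samples are shuffled before batching since no
continuity beyond a window is assumed.

## The recurrent models

Both networks are single-layer LSTMs with 64 hidden units and a dense
4-way softmax head. The exploratory model's input per step is the action
one-hot plus reward/98 (5 features); the reward-oblivious model gets the
one-hot only (4 features). Training minimises mean categorical
cross-entropy with Adam (learning rate 0.001, β₁ = 0.9, β₂ = 0.99), batch
size 2048, 300 epochs in the faithful configuration.

The network is implemented directly in numpy — forward pass and
backpropagation through time — which keeps runs bit-reproducible on one
CPU. The gradients are validated against central finite differences in the
test suite (agreement to ~1e-7 relative). Initialisation: Glorot-uniform
input kernel, orthogonal recurrent kernel (one block per gate),
forget-gate bias 1. Argmax predictions break ties toward the lowest option
index, a deterministic and testable rule.

Desk-scale runs (test suite, analysis scripts) use 240 participants and
the configuration above; the expensive LSTM fixtures are trained once per
session and shared across checks. Training-loss traces show the nets learn
the pattern structure within the first ~30 epochs, while reward
sensitivity in the exploratory model keeps developing for hundreds of
epochs; checks that depend on the reward channel therefore use the
faithful 300-epoch recipe rather than a truncated one.

## The Q-learning model

Update Q(a) ← Q(a) + α(r − Q(a)) on the chosen option only; choice
probabilities softmax(βQ) with max-subtraction for numerical stability;
values initialised at 50 and frozen across missed trials. A single (α, β)
is fitted for the whole population by maximising the pooled log-likelihood
of observed actions with L-BFGS-B under bounds α ∈ [0, 1], β ∈ (0, 1],
restarted from 5 random points (per-participant fitting is available but
non-default). The β upper bound of 1 is generous on this reward scale
(β = 1 over a 10-point gap is already near-deterministic). Behavioural
predictions use the argmax of the pre-choice values; the first trial's
prediction (all values 50, tie-broken to option 1) is included but flagged
so reports can drop it. Accuracy is computed over non-missed trials only.

Probe simulations start from a fresh all-50 initialisation, apply the four
probe updates, and return the softmax distribution for the fifth choice.
Two analytic anchors follow directly: trying each option once at the same
reward leaves all values tied, so the distribution is exactly uniform for
any (α, β); and with all-different actions the probe's best-rewarded action
carries the mode for any parameters in the search box.

## Similarity statistic

For each trial t, over the M participants with predictions from both
models, similarity is the fraction on which the two models agree in
correctness — both right or both wrong. The statistic as originally
printed sums an XOR of the two correctness flags, which would make
identical models score 0; the surrounding text unambiguously describes
agreement, so the package implements the complement (XNOR). Trials with
M = 0 are reported absent, and participants lacking a prediction from
either model are excluded pairwise with M adjusted per trial.

## Probe experiments

Probes cross three action patterns (constant a–a–a–a, alternating a–b–a–b,
all-different a–b–c–d) with three reward patterns (constant, strictly
ascending, strictly descending) — nine category cells. Variants within a
cell rotate which options play the roles and vary the concrete reward
levels (constant cells include levels below and above the value
initialisation of 50; default 8 variants per cell drawn deterministically
from the level × rotation pool). Distances between fifth-choice
distributions use symmetric KL, ½KL(p‖q) + ½KL(q‖p), in nats, with
components floored at 1e-10 before logs — a safety net only, since softmax
outputs are never exactly zero. Cells aggregate by the arithmetic mean of
per-probe distances. A cell is labelled by which explicit model the
black box is nearer to, `both` if the two explicit models are within 0.05
nats of each other, `neither` if the black box is farther than 1.0 nats
from both; thresholds configurable and reported with results.

The probe taxonomy mentions varying "timing in the one-different
patterns"; the phrase is ambiguous (possibly a fourth, partially-varied
pattern family) and is not implemented.

## What passing desk-scale checks do and do not show

Passing checks establish that the pipeline's statistics behave as designed
on a population with known structure: the reward-oblivious net completes
patterns near-perfectly, the exploratory net's held-out accuracy weakly
dominates both explicit models, the group fit recovers generating (α, β)
on homogeneous data, and probe distances separate cells where the explicit
models disagree. They do **not** show that human choice data has the
mixture structure assumed here, nor do they reproduce dataset-bound
accuracy values from the reference study of 965 human players (72.3% /
69.9% / 68.2%); those require the original data, and only their ordering
is asserted on synthetic populations.

## Known limitations

- **Perseveration dominates low-reward constant runs by construction.** In
  the synthetic mixture, a 4-trial constant-action context with low or
  steeply falling rewards is produced almost exclusively by pattern agents
  and by hybrids in pattern mode — softmax Q-learners essentially never
  sit on a clearly bad arm for four straight trials. The empirical
  probability of "stay" after such contexts is ≈ 1.0 in the training
  distribution, so a well-trained exploratory net correctly predicts
  staying, i.e. it converges with the *reward-oblivious* model in the
  (constant action, descending reward) probe cell. Human players in the
  reference study evidently do abandon repeatedly-chosen options after
  steep declines, which is why the corresponding cell converges the other
  way there. This is a real property of the synthetic population (its
  pattern agents are reward-oblivious *by definition*), not an artefact of
  training: it persists from 40 to 300 epochs and is predicted by the
  generative stay statistics. Conclusions about where the black box
  converges with the Q-model therefore transfer to real data only in cells
  where the synthetic and human context distributions agree.
- Steep probe reward ramps (e.g. 80–60–40–20) are far outside the σ = 2.8
  drift of the training task — about 7 per-step standard deviations — so
  recurrent-model probe outputs there are extrapolations.
- The LSTM is trained full-batch-shuffled with a fixed epoch count; no
  early stopping or validation monitoring is performed (none is prescribed
  by the training recipe being followed).
- The group-level (α, β) fit pools heterogeneous agents; on mixtures the
  recovered parameters are a population compromise, not an estimate of any
  agent's true parameters (homogeneous-population recovery is what the
  recovery check verifies).
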