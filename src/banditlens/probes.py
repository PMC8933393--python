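"""Probe-based characterisation of the black-box policy model.

Hand-designed 4-step action-reward contexts ("probes") are fed to every
model and the resulting fifth-choice probability distributions are compared
pairwise with a symmetric Kullback-Leibler distance. Probes cross three
action patterns (constant a-a-a-a, alternating a-b-a-b, all-different
a-b-c-d) with three reward patterns (constant, ascending, descending),
giving nine category cells; within a cell, variants differ in which options
play the pattern roles and in the concrete reward levels. Averaging the
pairwise distances per cell shows where the black-box model's predictions
converge with the reward-oriented model and where with the reward-oblivious
one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import N_OPTIONS

ACTION_CATEGORIES = ("constant", "alternating", "all_different")
REWARD_CATEGORIES = ("constant", "ascending", "descending")

KL_EPS = 1e-10

#: reward levels used when enumerating probe variants; constant cells use
#: each level alone (covering both below- and above-midpoint values),
#: ordered cells use the full ramp
DEFAULT_REWARD_LEVELS = (20.0, 30.0, 40.0, 60.0, 70.0, 80.0)


@dataclass(frozen=True)
class Probe:
    probe_id: str
    action_category: str
    reward_category: str
    actions: tuple[int, int, int, int]
    rewards: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        a = self.actions
        if self.action_category == "constant" and len(set(a)) != 1:
            raise ValueError("constant action probe must repeat one option")
        if self.action_category == "alternating" and not (
            a[0] == a[2] and a[1] == a[3] and a[0] != a[1]
        ):
            raise ValueError("alternating probe must be a-b-a-b with a != b")
        if self.action_category == "all_different" and len(set(a)) != 4:
            raise ValueError("all-different probe must use each option once")
        r = self.rewards
        if self.reward_category == "constant" and len(set(r)) != 1:
            raise ValueError("constant reward probe must repeat one level")
        if self.reward_category == "ascending" and not all(
            r[i] < r[i + 1] for i in range(3)
        ):
            raise ValueError("ascending probe needs r1 < r2 < r3 < r4")
        if self.reward_category == "descending" and not all(
            r[i] > r[i + 1] for i in range(3)
        ):
            raise ValueError("descending probe needs r1 > r2 > r3 > r4")
        if min(r) < 1 or max(r) > 98:
            raise ValueError("rewards must lie within [1, 98]")

    @property
    def pattern_completion(self) -> int:
        """The action that continues the motor pattern.

        constant: the repeated option; alternating: the option due next in
        the a-b swap; all-different: the cycle wraps to the first action.
        """
        if self.action_category == "constant":
            return self.actions[0]
        if self.action_category == "alternating":
            return self.actions[0]  # ...a-b-a-b -> a
        return self.actions[0]  # a-b-c-d -> a


def _action_variants(category: str, assignments: list[tuple[int, ...]]):
    for opts in assignments:
        if category == "constant":
            yield (opts[0],) * 4
        elif category == "alternating":
            a, b = opts[0], opts[1]
            yield (a, b, a, b)
        else:
            yield tuple(opts[:4])


def _reward_variants(category: str, levels: tuple[float, ...]):
    levels = tuple(sorted(set(levels)))
    if len(levels) < 4 and category != "constant":
        raise ValueError("need >= 4 distinct reward levels for ordered patterns")
    if category == "constant":
        for lv in levels:
            yield (lv,) * 4
    elif category == "ascending":
        yield tuple(levels[:2]) + tuple(levels[-2:])
        yield tuple(levels[:4])
        yield tuple(levels[-4:])
    else:
        for asc in (
            tuple(levels[:2]) + tuple(levels[-2:]),
            tuple(levels[:4]),
            tuple(levels[-4:]),
        ):
            yield tuple(reversed(asc))


def enumerate_probes(
    variants_per_cell: int = 8,
    reward_levels: tuple[float, ...] = DEFAULT_REWARD_LEVELS,
    action_assignments: list[tuple[int, ...]] | None = None,
    seed: int = 0,
) -> list[Probe]:
    """Enumerate probes covering all 9 action x reward category cells.

    ``action_assignments`` lists which options play roles a, b, c, d
    (default: the four rotations of 1-2-3-4); combined with the reward-level
    variants this yields a pool per cell, from which up to
    ``variants_per_cell`` probes are drawn deterministically by ``seed``.
    With ``variants_per_cell=1`` exactly one probe per cell (9 total) is
    returned, using the canonical assignment and mid-range rewards.
    """
    if min(reward_levels) < 1 or max(reward_levels) > 98:
        raise ValueError("reward levels must lie within [1, 98]")
    if action_assignments is None:
        base = tuple(range(1, N_OPTIONS + 1))
        action_assignments = [base[i:] + base[:i] for i in range(N_OPTIONS)]

    rng = np.random.default_rng(seed)
    probes = []
    for a_cat, r_cat in itertools.product(ACTION_CATEGORIES, REWARD_CATEGORIES):
        pool = [
            (acts, rews)
            for acts in _action_variants(a_cat, action_assignments)
            for rews in _reward_variants(r_cat, reward_levels)
        ]
        if variants_per_cell == 1:
            pool = [pool[len(pool) // 2]]
        elif len(pool) > variants_per_cell:
            keep = rng.choice(len(pool), size=variants_per_cell, replace=False)
            pool = [pool[i] for i in sorted(keep)]
        for j, (acts, rews) in enumerate(pool):
            probes.append(
                Probe(
                    probe_id=f"{a_cat}-{r_cat}-{j}",
                    action_category=a_cat,
                    reward_category=r_cat,
                    actions=acts,
                    rewards=rews,
                )
            )
    return probes


def collect_predictions(
    probes: list[Probe], models: dict[str, "object"]
) -> pd.DataFrame:
    """Score every probe with every model's fifth-choice distribution.

    Each model must expose ``probe_proba(actions, rewards) -> 4-vector``
    (see :func:`banditlens.pipeline.model_adapters` for the standard trio).
    Unscorable probes are recorded as missing with a warning.
    """
    rows = []
    for probe in probes:
        for name, model in models.items():
            try:
                p = np.asarray(model.probe_proba(probe.actions, probe.rewards), float)
            except Exception as exc:  # noqa: BLE001 - keep the run going
                warnings.warn(f"model {name!r} failed on probe {probe.probe_id}: {exc}")
                continue
            if p.shape != (N_OPTIONS,) or not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError(f"model {name!r} returned an invalid distribution")
            rows.append(
                {
                    "probe_id": probe.probe_id,
                    "action_category": probe.action_category,
                    "reward_category": probe.reward_category,
                    "model_name": name,
                    **{f"p{i + 1}": p[i] for i in range(N_OPTIONS)},
                    "argmax_action": int(p.argmax()) + 1,
                    "pattern_completion": probe.pattern_completion,
                }
            )
    return pd.DataFrame(rows)


def sym_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetric Kullback-Leibler distance in nats.

    0.5 * KL(p || q) + 0.5 * KL(q || p), with components floored at 1e-10
    before the logs as a safety net against exact zeros.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probabilities must be non-negative")
    p = np.clip(p, KL_EPS, None)
    q = np.clip(q, KL_EPS, None)
    return float(0.5 * np.sum(p * np.log(p / q)) + 0.5 * np.sum(q * np.log(q / p)))


def distance_matrix(predictions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise symmetric-KL distances per probe and their per-cell means.

    Returns ``(cells, per_probe)``: per_probe has one row per (model pair,
    probe); cells aggregates by (model pair, action category, reward
    category) with the arithmetic mean distance and the probe count.
    """
    pcols = [f"p{i + 1}" for i in range(N_OPTIONS)]
    models = sorted(predictions["model_name"].unique())
    rows = []
    for probe_id, grp in predictions.groupby("probe_id"):
        by_model = {r["model_name"]: r for _, r in grp.iterrows()}
        for a, b in itertools.combinations(models, 2):
            if a not in by_model or b not in by_model:
                continue
            d = sym_kl(
                by_model[a][pcols].to_numpy(float),
                by_model[b][pcols].to_numpy(float),
            )
            rows.append(
                {
                    "model_pair": f"{a}|{b}",
                    "probe_id": probe_id,
                    "action_category": by_model[a]["action_category"],
                    "reward_category": by_model[a]["reward_category"],
                    "distance": d,
                }
            )
    per_probe = pd.DataFrame(rows)
    if per_probe.empty:
        warnings.warn("no scored probe pairs")
        return per_probe, per_probe
    cells = (
        per_probe.groupby(["model_pair", "action_category", "reward_category"])[
            "distance"
        ]
        .agg(mean_distance="mean", n_probes="size")
        .reset_index()
    )
    return cells, per_probe


def classify_convergence(
    cells: pd.DataFrame,
    exploratory: str = "exploratory",
    q_model: str = "q_model",
    reward_oblivious: str = "reward_oblivious",
    both_tolerance: float = 0.05,
    neither_threshold: float = 1.0,
) -> pd.DataFrame:
    """Label each category cell by which explicit model the black box tracks.

    ``both`` when the two explicit models are themselves within
    ``both_tolerance`` nats of each other; ``neither`` when the black box is
    farther than ``neither_threshold`` from both; otherwise the nearer
    explicit model's label.
    """
    def pair(a: str, b: str) -> str:
        return "|".join(sorted([a, b]))

    wide = cells.pivot_table(
        index=["action_category", "reward_category"],
        columns="model_pair",
        values="mean_distance",
    )
    d_eq = pair(exploratory, q_model)
    d_er = pair(exploratory, reward_oblivious)
    d_qr = pair(q_model, reward_oblivious)
    out = []
    for (a_cat, r_cat), row in wide.iterrows():
        dq, dr, dqr = row[d_eq], row[d_er], row[d_qr]
        if dqr <= both_tolerance:
            label = "both"
        elif dq > neither_threshold and dr > neither_threshold:
            label = "neither"
        elif dr < dq:
            label = "reward_oblivious"
        else:
            label = "reward_oriented"
        out.append(
            {
                "action_category": a_cat,
                "reward_category": r_cat,
                "d_exploratory_q": dq,
                "d_exploratory_oblivious": dr,
                "d_q_oblivious": dqr,
                "label": label,
            }
        )
    return pd.DataFrame(out)
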