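"""Probe enumeration, symmetric KL distance, cell aggregation, labels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from banditlens.probes import (
    ACTION_CATEGORIES,
    REWARD_CATEGORIES,
    Probe,
    classify_convergence,
    collect_predictions,
    distance_matrix,
    enumerate_probes,
    sym_kl,
)
from banditlens.qlearning import QParams, simulate_probe


class TestEnumerate:
    def test_one_variant_gives_nine_cells(self):
        probes = enumerate_probes(variants_per_cell=1)
        assert len(probes) == 9
        cells = {(p.action_category, p.reward_category) for p in probes}
        assert cells == set(itertools.product(ACTION_CATEGORIES, REWARD_CATEGORIES))

    def test_default_enumeration_covers_all_cells(self):
        probes = enumerate_probes()
        for a_cat, r_cat in itertools.product(ACTION_CATEGORIES, REWARD_CATEGORIES):
            assert any(
                p.action_category == a_cat and p.reward_category == r_cat
                for p in probes
            )

    def test_templates_validated(self):
        for p in enumerate_probes():
            if p.action_category == "constant":
                assert len(set(p.actions)) == 1
            if p.reward_category == "ascending":
                assert all(p.rewards[i] < p.rewards[i + 1] for i in range(3))
            if p.reward_category == "descending":
                assert all(p.rewards[i] > p.rewards[i + 1] for i in range(3))
            assert 1 <= min(p.rewards) and max(p.rewards) <= 98

    def test_constant_cells_cover_low_and_high_levels(self):
        probes = enumerate_probes()
        consts = [p.rewards[0] for p in probes if p.reward_category == "constant"]
        assert min(consts) < 50 < max(consts)

    def test_invalid_probe_rejected(self):
        with pytest.raises(ValueError):
            Probe("x", "all_different", "ascending", (1, 2, 3, 4), (40, 40, 40, 40))
        with pytest.raises(ValueError):
            Probe("x", "constant", "constant", (1, 2, 1, 1), (40, 40, 40, 40))


class TestSymKL:
    def test_zero_on_identical(self):
        p = np.array([0.7, 0.1, 0.1, 0.1])
        assert sym_kl(p, p) == 0.0

    def test_hand_computed_value(self):
        p = np.array([0.7, 0.1, 0.1, 0.1])
        q = np.full(4, 0.25)
        # 0.5*sum p log p/q + 0.5*sum q log q/p, evaluated by hand
        expected = 0.5 * (
            0.7 * np.log(0.7 / 0.25) + 3 * 0.1 * np.log(0.1 / 0.25)
        ) + 0.5 * (0.25 * np.log(0.25 / 0.7) + 3 * 0.25 * np.log(0.25 / 0.1))
        assert expected == pytest.approx(0.4378, abs=5e-4)
        assert sym_kl(p, q) == pytest.approx(expected, abs=1e-12)

    @given(
        a=st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
        b=st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric_and_non_negative(self, a, b):
        p = np.array(a) / np.sum(a)
        q = np.array(b) / np.sum(b)
        d = sym_kl(p, q)
        assert d >= 0
        assert d == pytest.approx(sym_kl(q, p), rel=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sym_kl(np.array([-0.1, 0.5, 0.3, 0.3]), np.full(4, 0.25))


class _FixedModel:
    """Probe adapter returning a fixed distribution (optionally action-keyed)."""

    def __init__(self, dist=None, fn=None):
        self.dist = dist
        self.fn = fn

    def probe_proba(self, actions, rewards):
        if self.fn is not None:
            return self.fn(actions, rewards)
        return self.dist


class TestDistanceMatrix:
    def test_self_pair_is_zero_everywhere(self):
        probes = enumerate_probes(variants_per_cell=2)
        dist = np.array([0.4, 0.3, 0.2, 0.1])
        preds = collect_predictions(
            probes, {"m1": _FixedModel(dist), "m2": _FixedModel(dist.copy())}
        )
        cells, per_probe = distance_matrix(preds)
        assert np.allclose(cells["mean_distance"], 0.0)

    def test_cell_mean_is_arithmetic_mean(self):
        probes = enumerate_probes(variants_per_cell=3)
        q = QParams(0.3, 0.15)
        models = {
            "q_model": _FixedModel(fn=lambda a, r: simulate_probe(tuple(a), tuple(r), q)),
            "uniform": _FixedModel(np.full(4, 0.25)),
        }
        preds = collect_predictions(probes, models)
        cells, per_probe = distance_matrix(preds)
        for _, row in cells.iterrows():
            sub = per_probe[
                (per_probe["action_category"] == row["action_category"])
                & (per_probe["reward_category"] == row["reward_category"])
                & (per_probe["model_pair"] == row["model_pair"])
            ]
            assert row["mean_distance"] == pytest.approx(sub["distance"].mean())
            assert row["n_probes"] == len(sub)

    def test_q_model_uniform_on_all_different_equal_rewards(self):
        """Analytic anchor: every option tried once at the same reward leaves
        the values tied, so the Q probe distribution is uniform."""
        probes = [
            p for p in enumerate_probes()
            if p.action_category == "all_different" and p.reward_category == "constant"
        ]
        for p in probes:
            for params in [QParams(0.2, 0.1), QParams(0.8, 0.9)]:
                assert np.allclose(
                    simulate_probe(p.actions, p.rewards, params), 0.25, atol=1e-12
                )


class TestClassifyConvergence:
    def _cells(self, d_eq, d_er, d_qr):
        rows = []
        for pair, d in [
            ("exploratory|q_model", d_eq),
            ("exploratory|reward_oblivious", d_er),
            ("q_model|reward_oblivious", d_qr),
        ]:
            rows.append(
                {
                    "model_pair": pair,
                    "action_category": "constant",
                    "reward_category": "constant",
                    "mean_distance": d,
                    "n_probes": 4,
                }
            )
        return pd.DataFrame(rows)

    def test_nearer_explicit_model_wins(self):
        labels = classify_convergence(self._cells(0.90, 0.05, 0.85))
        assert labels.loc[0, "label"] == "reward_oblivious"
        labels = classify_convergence(self._cells(0.05, 0.90, 0.85))
        assert labels.loc[0, "label"] == "reward_oriented"

    def test_both_when_explicit_models_agree(self):
        labels = classify_convergence(self._cells(0.02, 0.03, 0.01))
        assert labels.loc[0, "label"] == "both"

    def test_neither_when_far_from_both(self):
        labels = classify_convergence(self._cells(1.5, 1.4, 0.9))
        assert labels.loc[0, "label"] == "neither"


class TestRewardObliviousInvariance:
    def test_outputs_depend_only_on_actions(self, desk_models):
        model = desk_models["reward_oblivious"]
        for actions in [(1, 1, 1, 1), (1, 2, 1, 2), (1, 2, 3, 4)]:
            base = model.predict_proba([(a, 40.0) for a in actions])
            for rewards in [(20, 30, 70, 80), (80, 60, 40, 20)]:
                other = model.predict_proba(list(zip(actions, rewards)))
                assert np.array_equal(base, other)
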