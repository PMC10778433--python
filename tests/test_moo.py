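import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sweetdry as sd
from sweetdry.moo import (OBJECTIVE_NAMES, ParetoFront, _flag_dominated,
                          orient, repair)


class TestObjectiveVector:
    def test_extracts_in_order(self, study):
        row = study.sample(10)
        obj = sd.objective_vector(row)
        assert obj[0] == 1677.76          # phenols
        assert obj[2] == 10083.37         # abts
        assert obj[-1] == 2.97            # moisture
        assert len(obj) == 8

    def test_missing_field_raises(self):
        with pytest.raises(KeyError, match="moisture"):
            sd.objective_vector(pd.Series({"phenols": 1.0}))


class TestDominance:
    def test_hand_built_front(self):
        A = np.array([2.0, 2.0, 2.0])
        B = np.array([1.0, 2.0, 1.0])      # dominated by A
        C = np.array([3.0, 0.0, 1.0])      # incomparable with A
        flags = _flag_dominated(np.vstack([A, B, C]))
        assert flags.tolist() == [False, True, False]

    def test_single_candidate_front(self):
        assert _flag_dominated(np.array([[1.0, 2.0]])).tolist() == [False]

    def test_equal_vectors_do_not_dominate(self):
        a = np.array([1.0, 1.0])
        assert not sd.dominates(a, a)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10),
                              st.floats(-10, 10)),
                    min_size=2, max_size=8))
    def test_strict_partial_order(self, rows):
        vecs = [np.array(r) for r in rows]
        for a in vecs:
            assert not sd.dominates(a, a)               # irreflexive
        for a in vecs:
            for b in vecs:
                if sd.dominates(a, b):
                    assert not sd.dominates(b, a)       # antisymmetric
                for c in vecs:
                    if sd.dominates(a, b) and sd.dominates(b, c):
                        assert sd.dominates(a, c)       # transitive


class TestEnumeration:
    def test_front_is_mutually_non_dominated(self, planted):
        model, _ = planted
        front = sd.pareto_enumerate(model)
        F = orient(front.objectives.to_numpy())
        idx = front.front_indices
        for i in idx:
            for j in idx:
                assert not sd.dominates(F[j], F[i]) or i == j

    def test_excluded_cells_are_dominated_by_a_member(self, planted):
        model, _ = planted
        front = sd.pareto_enumerate(model)
        F = orient(front.objectives.to_numpy())
        members = front.front_indices
        for i in np.flatnonzero(front.dominated):
            assert any(sd.dominates(F[j], F[i]) for j in members)

    def test_covers_all_twelve_cells(self, planted):
        model, _ = planted
        front = sd.pareto_enumerate(model)
        assert len(front) == 12
        assert len({(d.variety, d.method) for d in front.designs}) == 12


class TestRepairAndGA:
    def test_repair_yields_feasible_one_hot(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            z = repair(rng.random(7))
            assert z[:4].sum() == 1 and z[4:].sum() == 1

    def test_ga_front_equals_enumeration(self, planted):
        model, _ = planted
        cfg = sd.GAConfig(generations=80, population=60, seed=5)
        ga_front = sd.ga_optimize(model, cfg)
        enum_front = sd.pareto_enumerate(model)
        ga = {(d.variety, d.method) for d in ga_front.front_designs}
        ex = {(d.variety, d.method) for d in enum_front.front_designs}
        assert ga == ex

    def test_ga_deterministic_given_seed(self, planted):
        model, _ = planted
        cfg = sd.GAConfig(generations=15, population=24, seed=9)
        a = sd.ga_optimize(model, cfg)
        b = sd.ga_optimize(model, cfg)
        assert [(d.variety, d.method) for d in a.front_designs] \
            == [(d.variety, d.method) for d in b.front_designs]

    def test_ga_front_bounded_by_feasible_space(self, planted):
        model, _ = planted
        front = sd.ga_optimize(model, sd.GAConfig(generations=10,
                                                  population=20, seed=2))
        assert len(front.front_designs) <= 12

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            sd.GAConfig(generations=0)


def _toy_front(objs):
    designs = sd.all_design_points()[:len(objs)]
    obj_df = pd.DataFrame(objs, columns=list(OBJECTIVE_NAMES))
    preds = obj_df.copy()
    flags = _flag_dominated(orient(obj_df.to_numpy()))
    return ParetoFront(designs, preds, obj_df, flags)


class TestCompromiseSelection:
    def test_single_member(self):
        front = _toy_front([[1, 1, 1, 1, 1, 1, 1, 5.0]])
        sel = sd.select_compromise(front)
        assert sel.design == front.designs[0]
        assert sel.distance == pytest.approx(0.0)

    def test_ideal_member_wins(self):
        rows = [[2, 2, 2, 2, 2, 2, 2, 1.0],     # best everywhere
                [1, 1, 1, 1, 1, 1, 1, 2.0]]
        # second candidate incomparable? no - dominated; front has one member
        sel = sd.select_compromise(_toy_front(rows))
        assert sel.design == sd.all_design_points()[0]

    def test_moisture_is_minimized(self):
        rows = [[1, 1, 1, 1, 1, 1, 1, 9.0],
                [1, 1, 1, 1, 1, 1, 1.5, 1.0]]
        sel = sd.select_compromise(_toy_front(rows))
        assert sel.design == sd.all_design_points()[1]

    def test_normalized_selection_scale_invariant(self):
        rng = np.random.default_rng(21)
        rows = rng.uniform(1, 10, (6, 8))
        front = _toy_front(rows.tolist())
        base = sd.select_compromise(front, normalize=True).design
        for j, scale in [(0, 1000.0), (4, 0.01)]:
            scaled = rows.copy()
            scaled[:, j] = scaled[:, j] * scale + 3.0
            again = sd.select_compromise(_toy_front(scaled.tolist()),
                                         normalize=True).design
            assert again == base

    def test_empty_front_raises(self):
        front = _toy_front([[1, 1, 1, 1, 1, 1, 1, 1.0]])
        front.dominated[:] = True
        with pytest.raises(ValueError, match="empty"):
            sd.select_compromise(front)

    def test_attaches_measured_row(self, study, planted):
        model, _ = planted
        front = sd.pareto_enumerate(model)
        sel = sd.select_compromise(front, dataset=study)
        assert sel.measured is not None
        assert sel.sample_id in set(study.ids)
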