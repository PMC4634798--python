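"""Greedy forward selection: objective catalog, step optimality, synergy."""

import numpy as np
import pytest

from otufs.greedy import (
    OBJECTIVE_NAMES,
    SelectionState,
    greedy_select,
    make_objective,
    objective_score,
)
from otufs.infotheory import DiscreteVector, discretize, mutual_information
from otufs.io import LabelVector, extract_labels
from otufs.synthetic import SyntheticSpec, generate


def small_study(seed=0, **kw):
    spec = SyntheticSpec(**{"K": 25, "M": 80, "n_informative": 5, "seed": seed, **kw})
    table, metadata, truth = generate(spec)
    table, labels = extract_labels(table, metadata, "class")
    return table, labels, truth


def discretized(table):
    return [discretize(row) for row in table.counts]


class TestMakeObjective:
    def test_named_parameterizations(self):
        jmi = make_objective("jmi")
        assert jmi.alpha_rule(4) == pytest.approx(0.25)
        assert jmi.beta_rule(4) == pytest.approx(0.25)
        mrmr = make_objective("mRMR")
        assert mrmr.alpha_rule(4) == pytest.approx(0.25)
        assert mrmr.beta_rule(4) == 0.0
        mim = make_objective("MIM")
        assert mim.alpha_rule(3) == 0.0 and mim.beta_rule(3) == 0.0
        cife = make_objective("cife")
        assert cife.alpha_rule(7) == 1.0 and cife.beta_rule(7) == 1.0

    def test_unknown_name_lists_catalog(self):
        with pytest.raises(ValueError, match="mim.*mrmr|valid names"):
            make_objective("bogus")

    def test_catalog_has_nine_criteria(self):
        assert len(OBJECTIVE_NAMES) == 9


class TestObjectiveScore:
    def test_empty_set_gives_marginal_mi_for_all_criteria(self):
        table, labels, _ = small_study()
        feats = discretized(table)
        y = DiscreteVector(labels.as_states(), len(labels.classes))
        state = SelectionState(remaining=set(range(len(feats))))
        expected = mutual_information(feats[3], y)
        for name in OBJECTIVE_NAMES:
            score = objective_score(3, feats, y, state, make_objective(name))
            assert score == pytest.approx(expected, abs=1e-12), name

    def test_mim_ignores_selected_set(self):
        table, labels, _ = small_study()
        feats = discretized(table)
        y = DiscreteVector(labels.as_states(), len(labels.classes))
        state = SelectionState(selected=[0, 1], remaining=set(range(2, len(feats))))
        assert objective_score(5, feats, y, state, make_objective("mim")) == (
            pytest.approx(mutual_information(feats[5], y), abs=1e-12)
        )

    def test_jmi_single_selected_hand_sum(self):
        # 6-sample toy: each term of the JMI score validated by direct MI calls
        x = DiscreteVector(np.array([0, 0, 1, 1, 0, 1]), 2)
        xp = DiscreteVector(np.array([0, 1, 1, 0, 0, 1]), 2)
        y = DiscreteVector(np.array([0, 0, 0, 1, 1, 1]), 2)
        feats = [x, xp]
        from otufs.infotheory import conditional_mutual_information

        expected = (
            mutual_information(x, y)
            - mutual_information(x, xp)
            + conditional_mutual_information(x, xp, y)
        )
        state = SelectionState(selected=[1], remaining={0})
        got = objective_score(0, feats, y, state, make_objective("jmi"))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_already_selected_rejected(self):
        table, labels, _ = small_study()
        feats = discretized(table)
        y = DiscreteVector(labels.as_states(), 2)
        state = SelectionState(selected=[2], remaining=set(range(3, 25)))
        with pytest.raises(ValueError, match="already selected"):
            objective_score(2, feats, y, state, make_objective("jmi"))

    def test_xor_synergy_rewarded_by_conditional_redundancy(self):
        # with one XOR member selected, JMI scores its partner far above noise
        table, labels, truth = small_study(
            K=22, M=200, n_informative=0, n_xor_pairs=1, seed=0
        )
        m1, m2 = truth["xor_pairs"][0]
        feats = discretized(table)
        y = DiscreteVector(labels.as_states(), 2)
        state = SelectionState(
            selected=[m1], remaining=set(range(22)) - {m1}
        )
        jmi = make_objective("jmi")
        partner = objective_score(m2, feats, y, state, jmi)
        noise_best = max(
            objective_score(j, feats, y, state, jmi) for j in truth["noise"]
        )
        assert partner > noise_best + 0.5  # ~1 bit of conditional redundancy


class TestGreedySelect:
    @pytest.mark.parametrize("name", ["mim", "mrmr", "jmi", "cife", "cmim", "icap", "disr", "condmi", "mifs"])
    def test_every_step_attains_exhaustive_argmax(self, name):
        table, labels, _ = small_study(seed=2)
        params = make_objective(name)
        k = 6
        result = greedy_select(table, labels, k, params)
        feats = discretized(table)
        y = DiscreteVector(labels.as_states(), len(labels.classes))
        state = SelectionState(remaining=set(range(table.n_features)))
        for step, chosen in enumerate(result.feature_indices):
            scores = {
                j: objective_score(j, feats, y, state, params)
                for j in sorted(state.remaining)
            }
            best = max(scores.values())
            assert scores[chosen] == pytest.approx(best, abs=1e-10)
            # lowest-index tie-break
            assert chosen == min(j for j, s in scores.items() if s >= best - 1e-12)
            assert result.scores[step] == pytest.approx(scores[chosen], abs=1e-10)
            state.selected.append(chosen)
            state.remaining.discard(chosen)

    def test_k1_picks_max_marginal_mi_for_every_criterion(self):
        table, labels, _ = small_study(seed=3)
        feats = discretized(table)
        y = DiscreteVector(labels.as_states(), len(labels.classes))
        mis = [mutual_information(f, y) for f in feats]
        expected = int(np.argmax(mis))
        for name in OBJECTIVE_NAMES:
            result = greedy_select(table, labels, 1, make_objective(name))
            assert result.feature_indices == [expected], name

    def test_mim_full_ranking_sorts_marginal_mi(self):
        table, labels, _ = small_study(seed=4)
        feats = discretized(table)
        y = DiscreteVector(labels.as_states(), len(labels.classes))
        mis = np.array([mutual_information(f, y) for f in feats])
        expected = np.lexsort((np.arange(len(mis)), -mis))
        result = greedy_select(table, labels, table.n_features, make_objective("mim"))
        np.testing.assert_array_equal(result.feature_indices, expected)

    def test_prefix_property(self):
        table, labels, _ = small_study(seed=5)
        for name in ("mrmr", "jmi"):
            params = make_objective(name)
            r5 = greedy_select(table, labels, 5, params)
            r8 = greedy_select(table, labels, 8, params)
            assert r8.feature_indices[:5] == r5.feature_indices

    def test_duplicate_feature_penalized_by_redundancy_terms(self):
        table, labels, _ = small_study(seed=6)
        counts = table.counts.copy()
        counts[10] = counts[0]  # exact copy of a strong feature
        from otufs.io import AbundanceTable

        dup_table = AbundanceTable(
            counts, table.feature_ids, table.sample_ids, table.taxonomy
        )
        feats = discretized(dup_table)
        y = DiscreteVector(labels.as_states(), len(labels.classes))
        state = SelectionState(selected=[0], remaining=set(range(1, 25)))
        standalone = mutual_information(feats[10], y)
        for name in ("mrmr", "jmi"):
            score = objective_score(10, feats, y, state, make_objective(name))
            self_red = mutual_information(feats[10], feats[0])
            assert score <= standalone - self_red + (
                self_red if name == "jmi" else 0.0
            ) + 1e-12
        mim_score = objective_score(10, feats, y, state, make_objective("mim"))
        assert mim_score == pytest.approx(standalone, abs=1e-12)

    def test_k_out_of_range_and_single_class(self):
        table, labels, _ = small_study()
        with pytest.raises(ValueError, match="out of range"):
            greedy_select(table, labels, table.n_features + 1, make_objective("mim"))

    def test_selection_order_is_recorded(self):
        table, labels, _ = small_study(seed=7)
        result = greedy_select(table, labels, 4, make_objective("jmi"))
        assert len(result.feature_indices) == 4
        assert len(set(result.feature_indices)) == 4
        assert result.method == "JMI"
        assert result.k == 4
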