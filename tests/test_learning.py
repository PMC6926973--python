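"""CPT estimation, scoring, hill climbing and Markov-blanket selection."""
import numpy as np
import pandas as pd
import pytest

import bnwhatif as bw
from bnwhatif.bn import DAGStructure
from bnwhatif.errors import DegenerateInputError, UncleanDataError, UnknownNodeError
from bnwhatif.learn import LearnerConfig, variables_from_data


def two_col_frame(rows):
    return pd.DataFrame(rows, columns=["P", "C"])


class TestEstimateCpts:
    def test_laplace_smoothing_hand_arithmetic(self):
        # parent state p0 observed with child counts (3, 1); alpha = 1
        data = two_col_frame(
            [("p0", "c0")] * 3 + [("p0", "c1")] + [("p1", "c0")] * 2 + [("p1", "c1")] * 2
        )
        structure = DAGStructure(("C", "P"), (("P", "C"),))
        net = bw.estimate_cpts(structure, data, smoothing_alpha=1.0)
        np.testing.assert_allclose(net.cpts["C"].values[0], [4 / 6, 2 / 6])

    def test_unseen_parent_combination_uniform_at_alpha_zero(self):
        data = two_col_frame([("p0", "c0"), ("p0", "c1")])
        variables = (
            bw.CategoricalVariable("P", ("p0", "p1")),
            bw.CategoricalVariable("C", ("c0", "c1")),
        )
        structure = DAGStructure(("C", "P"), (("P", "C"),))
        net = bw.estimate_cpts(structure, data, 0.0, variables)
        np.testing.assert_allclose(net.cpts["C"].values[1], [0.5, 0.5])

    def test_missing_values_rejected(self):
        data = pd.DataFrame({"A": ["x", None], "B": ["y", "z"]})
        structure = DAGStructure(("A", "B"), ())
        with pytest.raises(UncleanDataError):
            bw.estimate_cpts(structure, data, 1.0)

    def test_recovers_toy3_cpts_at_large_n(self, toy3_net):
        data = bw.ancestral_sample(toy3_net, 100_000, seed=21)
        net = bw.estimate_cpts(toy3_net.structure, data, 0.0, toy3_net.variables)
        for name in toy3_net.node_names:
            true_rows = toy3_net.cpts[name].values.reshape(-1, toy3_net.card(name))
            est_rows = net.cpts[name].values.reshape(-1, toy3_net.card(name))
            tv = 0.5 * np.abs(true_rows - est_rows).sum(axis=1)
            assert tv.max() < 0.01

    def test_cpt_error_shrinks_with_sample_size(self, toy3_net):
        def max_tv(n):
            data = bw.ancestral_sample(toy3_net, n, seed=77)
            net = bw.estimate_cpts(toy3_net.structure, data, 0.0, toy3_net.variables)
            return max(
                0.5
                * np.abs(
                    toy3_net.cpts[v].values.reshape(-1, toy3_net.card(v))
                    - net.cpts[v].values.reshape(-1, toy3_net.card(v))
                )
                .sum(axis=1)
                .max()
                for v in toy3_net.node_names
            )

        errs = [max_tv(n) for n in (500, 5_000, 50_000)]
        assert errs[0] > errs[2]


@pytest.fixture(scope="module")
def indep_data():
    rng = np.random.default_rng(6)
    return pd.DataFrame({c: rng.choice(["a", "b", "c"], size=5000) for c in "WXYZ"})


class TestNetworkScore:
    def test_noise_edge_lowers_bic(self, indep_data):
        config = LearnerConfig(score="bic")
        empty = DAGStructure(tuple("WXYZ"), ())
        with_edge = DAGStructure(tuple("WXYZ"), (("W", "X"),))
        assert bw.network_score(with_edge, indep_data, config) < bw.network_score(
            empty, indep_data, config
        )

    def test_score_decomposes_into_family_terms(self, indep_data):
        config = LearnerConfig()
        structure = DAGStructure(tuple("WXYZ"), (("W", "X"), ("X", "Y")))
        total = bw.network_score(structure, indep_data, config)
        parts = 0.0
        for node in structure.nodes:
            family = DAGStructure(
                structure.nodes,
                tuple(e for e in structure.edges if e[1] == node),
            )
            # family score of `node` = score difference against its no-parent form
            parts += bw.network_score(family, indep_data, config)
        empty = bw.network_score(DAGStructure(tuple("WXYZ"), ()), indep_data, config)
        assert total == pytest.approx(parts - 3 * empty, rel=1e-12)

    def test_score_invariant_to_row_order(self, indep_data):
        config = LearnerConfig()
        structure = DAGStructure(tuple("WXYZ"), (("W", "X"),))
        shuffled = indep_data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert bw.network_score(structure, indep_data, config) == pytest.approx(
            bw.network_score(structure, shuffled, config), rel=1e-12
        )


class TestLearnStructure:
    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(
            {c: rng.choice(["a", "b"], size=4000) for c in ("U", "V", "W")}
        )
        net = bw.learn_structure(data, LearnerConfig(score="bic", seed=0))
        assert net.structure.edges == ()

    def test_skeleton_recovery_on_chain(self):
        truth = bw.random_network(5, seed=42, edge_prob=0.5)
        data = bw.ancestral_sample(truth, 20_000, seed=8)
        learned = bw.learn_structure(data, LearnerConfig(seed=1))
        report = bw.recovery_report(truth, learned)
        assert report.edge_f1 >= 0.8

    def test_deterministic_for_fixed_seed(self, survey11_net):
        data = bw.ancestral_sample(survey11_net, 2000, seed=4)
        a = bw.learn_structure(data, LearnerConfig(seed=12, restarts=2))
        b = bw.learn_structure(data, LearnerConfig(seed=12, restarts=2))
        assert a.structure.edges == b.structure.edges
        for n in a.node_names:
            np.testing.assert_array_equal(a.cpts[n].values, b.cpts[n].values)

    def test_single_column_rejected(self):
        with pytest.raises(DegenerateInputError):
            bw.learn_structure(pd.DataFrame({"A": ["x", "y"]}), LearnerConfig())

    def test_score_of_learned_at_least_empty_graph(self, survey11_net):
        """Hill climbing only accepts improving moves, so the final score
        cannot fall below the starting (empty-graph) score."""
        data = bw.ancestral_sample(survey11_net, 3000, seed=5)
        config = LearnerConfig(seed=2, restarts=0)
        learned = bw.learn_structure(data, config)
        variables = variables_from_data(data)
        empty = DAGStructure(tuple(sorted(data.columns)), ())
        assert bw.network_score(
            learned.structure, data, config, variables
        ) >= bw.network_score(empty, data, config, variables)


class TestMarkovBlanket:
    def _structure(self, nodes, edges):
        return DAGStructure(tuple(nodes), tuple(edges))

    def test_chain_blanket_is_neighbours(self):
        s = self._structure("ABC", [("A", "B"), ("B", "C")])
        assert bw.markov_blanket(s, "B").blanket == {"A", "C"}

    def test_collider_includes_co_parent(self):
        s = self._structure("ABC", [("A", "C"), ("B", "C")])
        sel = bw.markov_blanket(s, "A")
        assert sel.blanket == {"B", "C"}
        assert sel.discarded == set()

    def test_naive_bayes_star_blanket_is_all_features(self):
        s = self._structure("CXYZ", [("C", "X"), ("C", "Y"), ("C", "Z")])
        assert bw.markov_blanket(s, "C").blanket == {"X", "Y", "Z"}

    def test_unknown_node(self):
        s = self._structure("AB", [("A", "B")])
        with pytest.raises(UnknownNodeError):
            bw.markov_blanket(s, "Q")

    def test_partition_covers_all_nodes(self, survey11_net):
        sel = bw.markov_blanket(survey11_net.structure, "Obesity_Level")
        assert sel.blanket | sel.discarded | {"Obesity_Level"} == set(
            survey11_net.node_names
        )
        assert "Obesity_Level" not in sel.blanket

    def test_blanket_screens_off_rest(self, survey11_net):
        """Given full-blanket evidence, evidence on a non-blanket node does
        not move the target posterior (d-separation)."""
        sel = bw.markov_blanket(survey11_net.structure, "Obesity_Level")
        row = bw.ancestral_sample(survey11_net, 1, seed=30).iloc[0]
        blanket_ev = {n: row[n] for n in sorted(sel.blanket)}
        base = bw.infer_posterior(survey11_net, "Obesity_Level", blanket_ev)
        for extra in sorted(sel.discarded):
            more = bw.infer_posterior(
                survey11_net, "Obesity_Level", {**blanket_ev, extra: row[extra]}
            )
            np.testing.assert_allclose(more, base, atol=1e-10)


class TestGbnMbClassifier:
    def test_noise_columns_discarded(self, naive4_with_noise):
        _truth, data = naive4_with_noise
        _net, sel = bw.gbn_mb_classifier(data, "Class", LearnerConfig(seed=2))
        assert {"N1", "N2"} <= sel.discarded

    def test_restricted_blanket_subset_of_original(self, naive4_with_noise):
        _truth, data = naive4_with_noise
        net, sel = bw.gbn_mb_classifier(data, "Class", LearnerConfig(seed=2))
        inner = bw.markov_blanket(net.structure, "Class")
        assert inner.blanket <= sel.blanket

    def test_restricted_prediction_matches_full_given_blanket(self, survey11_net):
        """With the ground-truth model, conditioning on the full blanket
        makes the restricted and full networks agree (checked against the
        brute-force oracle)."""
        sel = bw.markov_blanket(survey11_net.structure, "Obesity_Level")
        row = bw.ancestral_sample(survey11_net, 1, seed=31).iloc[0]
        ev = {n: row[n] for n in sorted(sel.blanket)}
        full = bw.brute_force_posterior(survey11_net, "Obesity_Level", ev)
        ve = bw.infer_posterior(survey11_net, "Obesity_Level", ev)
        np.testing.assert_allclose(full, ve, atol=1e-10)
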