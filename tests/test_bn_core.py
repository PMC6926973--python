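"""Network representation, joint probability, exact inference, sampling."""
import json

import numpy as np
import pytest

import bnwhatif as bw
from bnwhatif.bn import net_from_dict, net_to_dict
from bnwhatif.errors import (
    IncompleteAssignmentError,
    InconsistentEvidenceError,
    InvalidQueryError,
    InvalidSizeError,
    TooLargeError,
    UnknownStateError,
)
from conftest import random_net_and_row


def make_single_node(p=1.0):
    return bw.build_fixture(
        bw.FixtureSpec(
            "single",
            (("X", ("true", "false")),),
            (),
            cpt_source="explicit",
            explicit_cpts={"X": np.array([p, 1 - p])},
        )
    )


class TestJointProbability:
    def test_degenerate_single_node(self):
        net = make_single_node(1.0)
        assert bw.joint_probability(net, {"X": "true"}) == 1.0

    def test_toy3_product_of_cpt_entries(self, toy3_net):
        p = bw.joint_probability(
            toy3_net, {"Wealth": "Low", "Pocket_Money": "Med", "Obesity": "Obese"}
        )
        assert p == pytest.approx(0.4 * 0.4 * 0.4, abs=1e-12)

    def test_zero_entry_annihilates(self):
        net = make_single_node(1.0)
        assert bw.joint_probability(net, {"X": "false"}) == 0.0

    def test_incomplete_assignment_rejected(self, toy3_net):
        with pytest.raises(IncompleteAssignmentError):
            bw.joint_probability(toy3_net, {"Wealth": "Low"})

    def test_illegal_state_rejected(self, toy3_net):
        with pytest.raises(UnknownStateError):
            bw.joint_probability(
                toy3_net,
                {"Wealth": "Rich", "Pocket_Money": "Med", "Obesity": "Obese"},
            )


class TestInference:
    def test_toy3_prior_marginal(self, toy3_net):
        post = bw.infer_posterior(toy3_net, "Obesity", {})
        assert post[1] == pytest.approx(0.234, abs=1e-12)

    def test_toy3_evidence_reads_cpt(self, toy3_net):
        post = bw.infer_posterior(toy3_net, "Obesity", {"Pocket_Money": "Med"})
        assert post[1] == pytest.approx(0.400, abs=1e-12)

    def test_query_in_evidence_rejected(self, toy3_net):
        with pytest.raises(InvalidQueryError):
            bw.infer_posterior(toy3_net, "Obesity", {"Obesity": "Obese"})

    def test_zero_probability_evidence_raises(self):
        # a 2-node chain with deterministic CPTs: B=b1 is impossible
        chain = bw.build_fixture(
            bw.FixtureSpec(
                "det",
                (("A", ("a0", "a1")), ("B", ("b0", "b1"))),
                (("A", "B"),),
                cpt_source="explicit",
                explicit_cpts={
                    "A": np.array([1.0, 0.0]),
                    "B": np.array([[1.0, 0.0], [0.0, 1.0]]),
                },
            )
        )
        with pytest.raises(InconsistentEvidenceError):
            bw.infer_posterior(chain, "A", {"B": "b1"})

    def test_posterior_sums_to_one_given_deep_evidence(self, survey11_net):
        post = bw.infer_posterior(
            survey11_net,
            "Obesity_Level",
            {"Education_Father": "low", "Smartphone_Time": "long"},
        )
        assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bayes_identity(self, toy3_net):
        """P(A|B=b) == P(B=b|A=a) P(A=a) / P(B=b), assembled separately."""
        p_w = bw.infer_posterior(toy3_net, "Wealth", {})
        p_ob = bw.infer_posterior(toy3_net, "Obesity", {})
        lhs = bw.infer_posterior(toy3_net, "Wealth", {"Obesity": "Obese"})
        states = toy3_net.variable("Wealth").states
        for i, a in enumerate(states):
            like = bw.infer_posterior(toy3_net, "Obesity", {"Wealth": a})[1]
            assert lhs[i] == pytest.approx(like * p_w[i] / p_ob[1], abs=1e-12)


class TestBruteForceOracle:
    def test_single_node_returns_prior(self):
        net = make_single_node(0.7)
        assert bw.brute_force_posterior(net, "X", {}) == pytest.approx([0.7, 0.3])

    def test_toy3_agrees_with_elimination(self, toy3_net):
        for ev in ({}, {"Wealth": "Low"}, {"Wealth": "High", "Obesity": "Obese"}):
            for q in toy3_net.node_names:
                if q in ev:
                    continue
                np.testing.assert_allclose(
                    bw.infer_posterior(toy3_net, q, ev),
                    bw.brute_force_posterior(toy3_net, q, ev),
                    atol=1e-12,
                )

    def test_enumeration_guard(self):
        net = bw.random_network(18, seed=0, max_states=3)
        if int(np.prod([net.card(n) for n in net.node_names])) > 10**7:
            with pytest.raises(TooLargeError):
                bw.full_joint_table(net)

    @pytest.mark.parametrize("seed", range(25))
    def test_agreement_on_random_networks(self, seed):
        """Variable elimination equals full-joint enumeration, with and
        without evidence drawn from a sampled (hence possible) row."""
        net, row = random_net_and_row(seed, n_nodes=6)
        names = list(net.node_names)
        rng = np.random.default_rng(seed)
        ev_vars = [n for n in names if rng.random() < 0.4]
        evidence = {n: row[n] for n in ev_vars}
        for q in names:
            if q in evidence:
                continue
            np.testing.assert_allclose(
                bw.infer_posterior(net, q, evidence),
                bw.brute_force_posterior(net, q, evidence),
                atol=1e-10,
            )

    def test_fully_observed_conditional_matches_joint_ratio(self, toy3_net):
        """Evidence on all other nodes: posterior equals the normalized
        joint_probability over completions of the query."""
        ev = {"Wealth": "Low", "Pocket_Money": "High"}
        post = bw.infer_posterior(toy3_net, "Obesity", ev)
        states = toy3_net.variable("Obesity").states
        joints = np.array(
            [bw.joint_probability(toy3_net, {**ev, "Obesity": s}) for s in states]
        )
        np.testing.assert_allclose(post, joints / joints.sum(), atol=1e-12)


class TestAncestralSampling:
    def test_deterministic_network_forces_assignment(self):
        chain = bw.build_fixture(
            bw.FixtureSpec(
                "det",
                (("A", ("a0", "a1")), ("B", ("b0", "b1"))),
                (("A", "B"),),
                cpt_source="explicit",
                explicit_cpts={
                    "A": np.array([0.0, 1.0]),
                    "B": np.array([[1.0, 0.0], [0.0, 1.0]]),
                },
            )
        )
        df = bw.ancestral_sample(chain, 50, seed=1)
        assert (df["A"] == "a1").all() and (df["B"] == "b1").all()

    def test_empirical_marginal_near_exact(self, toy3_net):
        n = 100_000
        df = bw.ancestral_sample(toy3_net, n, seed=123)
        p_hat = (df["Obesity"] == "Obese").mean()
        se = np.sqrt(0.234 * 0.766 / n)
        assert abs(p_hat - 0.234) < 3 * se

    def test_same_seed_identical(self, toy3_net):
        a = bw.ancestral_sample(toy3_net, 500, seed=9)
        b = bw.ancestral_sample(toy3_net, 500, seed=9)
        assert a.equals(b)

    def test_invalid_size(self, toy3_net):
        with pytest.raises(InvalidSizeError):
            bw.ancestral_sample(toy3_net, 0, seed=1)

    def test_zero_prior_state_never_sampled(self):
        net = make_single_node(1.0)
        df = bw.ancestral_sample(net, 200, seed=5)
        assert (df["X"] == "true").all()


class TestSerialization:
    def test_json_round_trip_preserves_inference(self, survey11_net, tmp_path):
        path = tmp_path / "net.json"
        bw.save_network(survey11_net, path)
        loaded = bw.load_network(path)
        np.testing.assert_allclose(
            bw.infer_posterior(loaded, "Obesity_Level", {"Wealth": "low"}),
            bw.infer_posterior(survey11_net, "Obesity_Level", {"Wealth": "low"}),
            atol=1e-12,
        )
        assert loaded.structure.edges == survey11_net.structure.edges

    def test_cpt_rows_are_odometer_ordered(self, toy3_net):
        payload = net_to_dict(toy3_net)
        pm = next(c for c in payload["cpts"] if c["child"] == "Pocket_Money")
        # rows follow the Wealth state order (Low, High)
        assert pm["table"][0] == pytest.approx([0.5, 0.4, 0.1])
        assert pm["table"][1] == pytest.approx([0.2, 0.4, 0.4])
        rebuilt = net_from_dict(json.loads(json.dumps(payload)))
        assert bw.joint_probability(
            rebuilt, {"Wealth": "Low", "Pocket_Money": "Med", "Obesity": "Obese"}
        ) == pytest.approx(0.064, abs=1e-12)

    def test_xmlbif_export(self, toy3_net, tmp_path):
        path = tmp_path / "net.xml"
        bw.write_xmlbif(toy3_net, path)
        text = path.read_text()
        assert "<BIF VERSION" in text and text.count("<DEFINITION>") == 3
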