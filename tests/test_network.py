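"""Bayesian-network core: validation, joint factorization, belief updating."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from hrubnet import (
    CPT,
    BayesianNetwork,
    ImpossibleEvidenceError,
    NetworkError,
    NetworkStructure,
    default_scheme,
    default_study_network,
    evidence_probability,
    from_xmlbif,
    joint_probability,
    load_network,
    marginals,
    network_from_dict,
    network_to_dict,
    posterior,
    posterior_by_enumeration,
    save_network,
    to_xmlbif,
    validate,
)
from hrubnet.simulate import default_ground_truth

from conftest import make_network, random_network


class TestStructure:
    def test_default_study_dag_edges(self):
        s = default_study_network()
        assert set(s.parents["HRUB"]) == {
            "Experience",
            "MaritalStatus",
            "PreviousAccident",
            "Training",
            "EducationalLevel",
            "Weekday",
            "Daytime",
        }
        assert len(s.parents["HRUB"]) == 7
        assert s.parents["Age"] == ()
        assert set(s.children("Age")) == {"Experience", "MaritalStatus"}
        assert s.parents["Training"] == ("PreviousAccident",)
        assert "Age" not in s.parents["HRUB"]

    def test_cycle_rejected(self):
        s = default_study_network()
        with pytest.raises(NetworkError, match="cycle"):
            NetworkStructure(
                nodes=s.nodes,
                parents={**s.parents, "Age": ("HRUB",)},
            )

    def test_unknown_parent_rejected(self):
        with pytest.raises(NetworkError):
            NetworkStructure(nodes=("A",), parents={"A": ("B",)})


class TestValidate:
    def test_ground_truth_network_is_valid(self):
        assert validate(default_ground_truth()) == []

    def test_unnormalized_row_reported(self, chain_ab):
        bad = {
            "A": chain_ab.cpts["A"],
            "B": CPT(child="B", parents=("A",), values=[[0.5, 0.4], [0.2, 0.8]]),
        }
        candidate = type("N", (), {})()
        candidate.scheme = chain_ab.scheme
        candidate.structure = chain_ab.structure
        candidate.cpts = bad
        problems = validate(candidate)
        assert any("sums to" in p for p in problems)


class TestJointProbability:
    def test_chain_product(self, chain_ab):
        # P(a0) * P(b0 | a0) = 0.3 * 0.5
        assert joint_probability(chain_ab, {"A": "a0", "B": "b0"}) == pytest.approx(
            0.15
        )

    def test_deterministic_network_consistent_assignment(self):
        net = make_network(
            {
                "A": {"states": ["a0", "a1"], "cpt": [1.0, 0.0]},
                "B": {
                    "states": ["b0", "b1"],
                    "parents": ["A"],
                    "cpt": [[1.0, 0.0], [0.0, 1.0]],
                },
            }
        )
        assert joint_probability(net, {"A": "a0", "B": "b0"}) == 1.0

    def test_incomplete_assignment_rejected(self, chain_ab):
        with pytest.raises(NetworkError, match="cover"):
            joint_probability(chain_ab, {"A": "a0"})

    def test_log_variant_matches(self, chain_ab):
        p = joint_probability(chain_ab, {"A": "a1", "B": "b1"})
        lp = joint_probability(chain_ab, {"A": "a1", "B": "b1"}, log=True)
        assert lp == pytest.approx(np.log(p))

    def test_joint_sums_to_one_over_all_assignments(self):
        net = default_ground_truth()
        scheme = net.scheme
        total = 0.0
        for combo in itertools.product(
            *(range(scheme[n].n_states) for n in net.structure.nodes)
        ):
            assignment = {
                n: scheme[n].states[i] for n, i in zip(net.structure.nodes, combo)
            }
            total += joint_probability(net, assignment)
        assert total == pytest.approx(1.0, abs=1e-9)


class TestPosterior:
    def test_root_prior_without_evidence(self, chain_ab):
        np.testing.assert_allclose(posterior(chain_ab, "A"), [0.3, 0.7])

    def test_evidenced_query_is_point_mass(self, chain_ab):
        np.testing.assert_allclose(
            posterior(chain_ab, "A", {"A": "a1"}), [0.0, 1.0]
        )

    def test_bayes_rule_by_hand(self, chain_ab):
        # P(a0|b0) = P(b0|a0)P(a0) / P(b0) = 0.5*0.3 / (0.5*0.3 + 0.2*0.7)
        expected = 0.15 / (0.15 + 0.14)
        np.testing.assert_allclose(
            posterior(chain_ab, "A", {"B": "b0"})[0], expected
        )

    def test_impossible_evidence_raises(self):
        net = make_network(
            {
                "A": {"states": ["a0", "a1"], "cpt": [1.0, 0.0]},
                "B": {
                    "states": ["b0", "b1"],
                    "parents": ["A"],
                    "cpt": [[1.0, 0.0], [0.5, 0.5]],
                },
            }
        )
        with pytest.raises(ImpossibleEvidenceError):
            posterior(net, "A", {"B": "b1"})

    def test_elimination_matches_enumeration_on_random_networks(self):
        # oracle equivalence on 100 seeded random networks with random evidence
        rng = np.random.default_rng(2024)
        for _ in range(100):
            net = random_network(rng)
            nodes = list(net.structure.nodes)
            n_ev = int(rng.integers(0, len(nodes)))
            ev_vars = list(rng.choice(nodes, size=n_ev, replace=False))
            query = str(rng.choice([n for n in nodes if n not in ev_vars]))
            evidence = {}
            for v in ev_vars:
                states = net.scheme[v].states
                evidence[v] = states[int(rng.integers(0, len(states)))]
            try:
                fast = posterior(net, query, evidence)
            except ImpossibleEvidenceError:
                with pytest.raises(ImpossibleEvidenceError):
                    posterior_by_enumeration(net, query, evidence)
                continue
            slow = posterior_by_enumeration(net, query, evidence)
            np.testing.assert_allclose(fast, slow, atol=1e-9)
            assert fast.sum() == pytest.approx(1.0, abs=1e-9)

    def test_conditioning_consistency(self):
        # P(q|e) * P(e) equals the enumerated joint P(q, e)
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_network(rng, max_nodes=4)
            nodes = list(net.structure.nodes)
            q, e = nodes[0], nodes[-1]
            if q == e:
                continue
            e_state = net.scheme[e].states[0]
            try:
                post = posterior(net, q, {e: e_state})
            except ImpossibleEvidenceError:
                continue
            pe = evidence_probability(net, {e: e_state})
            for i, q_state in enumerate(net.scheme[q].states):
                pqe = evidence_probability(net, {q: q_state, e: e_state})
                assert post[i] * pe == pytest.approx(pqe, abs=1e-12)

    def test_marginals_sum_to_one_everywhere(self):
        net = default_ground_truth()
        for name, dist in marginals(net).items():
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_marginals_on_deterministic_chain(self):
        net = make_network(
            {
                "A": {"states": ["a0", "a1"], "cpt": [0.0, 1.0]},
                "B": {
                    "states": ["b0", "b1"],
                    "parents": ["A"],
                    "cpt": [[1.0, 0.0], [0.0, 1.0]],
                },
            }
        )
        m = marginals(net)
        np.testing.assert_allclose(m["A"], [0.0, 1.0])
        np.testing.assert_allclose(m["B"], [0.0, 1.0])


class TestSerialization:
    def test_dict_round_trip_is_bit_exact(self):
        net = default_ground_truth()
        back = network_from_dict(network_to_dict(net))
        for n in net.structure.nodes:
            np.testing.assert_array_equal(back.cpts[n].values, net.cpts[n].values)

    @pytest.mark.parametrize("suffix", ["yaml", "json"])
    def test_file_round_trip(self, tmp_path, suffix, chain_ab):
        path = tmp_path / f"net.{suffix}"
        save_network(chain_ab, path)
        back = load_network(path)
        np.testing.assert_allclose(
            posterior(back, "A", {"B": "b0"}), posterior(chain_ab, "A", {"B": "b0"})
        )

    def test_xmlbif_round_trip(self, chain_ab):
        text = to_xmlbif(chain_ab)
        back = from_xmlbif(text, target="B")
        assert back.structure.parents["B"] == ("A",)
        for n in chain_ab.structure.nodes:
            np.testing.assert_array_equal(
                back.cpts[n].values, chain_ab.cpts[n].values
            )
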