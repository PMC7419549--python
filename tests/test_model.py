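"""Model core: validation, structural evaluation, joints, sampling, IO."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twindiag import (
    Assignment,
    Evidence,
    ExogenousState,
    IncompleteNoiseError,
    Intervention,
    ModelSchemaError,
    NodeRef,
    NoisyOrCPT,
    NoisyOrNetwork,
    forward_sample,
    joint_probability,
    read_model,
    structural_eval,
    validate,
    write_model,
)
from twindiag.fixtures import single_link_network

from _oracles import full_joint_table, iter_exogenous_states, joint_via_noise
from conftest import small_random_case


def all_off_noise(net):
    """Every leak and every edge activation fails; all risk draws zero."""
    return ExogenousState(
        {r: 0 for r in net.risks},
        {e: 1 for e in net.edges()},
        {c: 1 for c in list(net.disease_cpts) + list(net.symptom_cpts)},
    )


class TestValidate:
    def test_well_formed_single_link(self, single_link):
        assert validate(single_link) == []

    def test_layer_order_violation(self):
        net = single_link_network()
        net.disease_cpts["D"] = NoisyOrCPT("D", {"S": 0.5}, 0.8)
        msgs = validate(net)
        assert any("layer-order" in m for m in msgs)

    def test_probability_range_violation(self):
        net = single_link_network()
        net.symptom_cpts["S"] = NoisyOrCPT("S", {"D": 1.3}, 0.9)
        msgs = validate(net)
        assert any("probability-range" in m for m in msgs)

    def test_duplicate_id_and_missing_cpt(self):
        net = NoisyOrNetwork(
            nodes=[NodeRef("X", "disease"), NodeRef("X", "disease")],
            disease_cpts={"X": NoisyOrCPT("X", {}, 0.5)},
        )
        msgs = validate(net)
        assert any("duplicate id" in m for m in msgs)


class TestStructuralEval:
    def test_all_leaks_fail_all_off(self, single_link):
        world = structural_eval(single_link, all_off_noise(single_link))
        assert all(v == 0 for v in world.values.values())

    def test_forced_disease_activates_symptom(self, single_link):
        noise = ExogenousState({}, {("D", "S"): 0}, {"D": 1, "S": 1})
        on = structural_eval(single_link, noise, Intervention(targets={"D": 1}))
        assert on["S"] == 1
        off = structural_eval(single_link, noise, Intervention(targets={"D": 0}))
        assert off["S"] == 0

    def test_leak_off_intervention_removes_leak_activation(self, single_link):
        noise = ExogenousState({}, {("D", "S"): 1}, {"D": 1, "S": 0})
        assert structural_eval(single_link, noise)["S"] == 1  # leak fires
        world = structural_eval(
            single_link, noise, Intervention(leak_off=frozenset({"S"}))
        )
        assert world["S"] == 0

    def test_incomplete_noise_names_missing_entries(self, single_link):
        with pytest.raises(IncompleteNoiseError, match=r"edge_noise\[\(D, S\)\]"):
            structural_eval(single_link, ExogenousState({}, {}, {"D": 0, "S": 0}))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), flip=st.data())
    def test_monotone_in_causes(self, seed, flip):
        """Switching on a disease can never switch off a symptom: flipping
        any non-intervened parent 0 -> 1 with noise fixed never flips a
        noisy-OR child 1 -> 0."""
        net, _, _ = small_random_case(seed)
        noise, world = forward_sample(net, seed)
        candidates = net.risks + net.diseases
        node = flip.draw(st.sampled_from(candidates))
        forced = structural_eval(net, noise, Intervention(targets={node: 1}))
        for child in net.diseases + net.symptoms:
            if child == node:
                continue
            assert forced[child] >= world[child]


class TestJointProbability:
    def test_single_link_worked_values(self, single_link):
        cases = {(0, 0): 0.72, (1, 0): 0.072, (0, 1): 0.08, (1, 1): 0.128}
        for (d, s), expected in cases.items():
            a = Assignment({"D": d, "S": s})
            assert joint_probability(single_link, a) == pytest.approx(expected, abs=1e-12)
            # independent route: sum over the 8 exogenous states
            assert joint_via_noise(single_link, a) == pytest.approx(expected, abs=1e-12)

    def test_partial_assignment_rejected(self, single_link):
        with pytest.raises(ValueError, match="partial"):
            joint_probability(single_link, Assignment({"D": 1}))

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_normalises_to_one(self, seed):
        net, _, _ = small_random_case(seed)
        ids = sorted(net.node_ids())
        total = sum(
            joint_probability(net, Assignment(dict(zip(ids, bits))))
            for bits in itertools.product((0, 1), repeat=len(ids))
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_matches_noise_enumeration(self, seed):
        """The product factorisation equals the SCM semantics: summing
        P(u) over exogenous states that evaluate to the assignment."""
        rng = np.random.default_rng(seed)
        net = single_link_network(
            prior=rng.uniform(0.1, 0.9),
            lam=rng.uniform(0.0, 1.0),
            leak_failure=rng.uniform(0.5, 1.0),
        )
        for d in (0, 1):
            for s in (0, 1):
                a = Assignment({"D": d, "S": s})
                assert joint_probability(net, a) == pytest.approx(
                    joint_via_noise(net, a), abs=1e-12
                )


class TestForwardSample:
    def test_seed_determinism(self, single_link):
        a = forward_sample(single_link, 42)
        b = forward_sample(single_link, 42)
        assert a[0] == b[0] and a[1] == b[1]

    def test_degenerate_probabilities_all_off(self):
        net = single_link_network(prior=0.0, lam=0.5, leak_failure=1.0)
        for seed in range(10):
            _, world = forward_sample(net, seed)
            assert all(v == 0 for v in world.values.values())

    def test_empirical_symptom_rate_matches_closed_form(self, single_link):
        n = 100_000
        rng = np.random.default_rng(2024)
        hits = sum(forward_sample(single_link, rng)[1]["S"] for _ in range(n))
        p = 1 - 0.9 * (1 - 0.2 * 0.6)  # 0.208
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_frequencies_fit_joint_distribution(self, single_link):
        """Chi-square goodness of fit of sampled assignments against the
        exact joint is not rejected at alpha = 0.001."""
        from scipy.stats import chisquare

        n = 100_000
        rng = np.random.default_rng(7)
        counts = {}
        for _ in range(n):
            _, world = forward_sample(single_link, rng)
            key = (world["D"], world["S"])
            counts[key] = counts.get(key, 0) + 1
        table = full_joint_table(single_link)
        keys = sorted(table)
        expected = [table[k] * n for k in keys]
        observed = [counts.get(tuple(v for _, v in k), 0) for k in keys]
        assert chisquare(observed, expected).pvalue > 0.001


class TestModelIO:
    def test_round_trip_identity(self, tmp_path, single_link):
        path = tmp_path / "model.json"
        write_model(path, single_link)
        assert read_model(path) == single_link

    def test_round_trip_random_networks(self, tmp_path):
        for seed in (3, 4):
            net, _, _ = small_random_case(seed)
            path = tmp_path / f"net{seed}.json"
            write_model(path, net)
            assert read_model(path) == net

    def test_duplicate_node_id_rejected(self, tmp_path):
        doc = {
            "nodes": [{"id": "D", "layer": "disease"}, {"id": "D", "layer": "disease"}],
            "risk_priors": {},
            "cpts": [{"child": "D", "parents": {}, "leak_failure": 0.5}],
        }
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelSchemaError, match="duplicate node id"):
            read_model(path)

    def test_missing_leak_failure_names_field(self, tmp_path):
        doc = {
            "nodes": [{"id": "D", "layer": "disease"}],
            "risk_priors": {},
            "cpts": [{"child": "D", "parents": {}}],
        }
        path = tmp_path / "missing.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelSchemaError, match="leak_failure"):
            read_model(path)

    def test_unknown_field_strict_vs_lenient(self, tmp_path, single_link):
        path = tmp_path / "model.json"
        write_model(path, single_link)
        doc = json.loads(path.read_text())
        doc["extra"] = 1
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelSchemaError, match="unknown fields"):
            read_model(path, strict=True)
        with pytest.warns(UserWarning, match="unknown fields"):
            assert read_model(path, strict=False) == single_link
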