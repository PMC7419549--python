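"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive: full enumeration over exogenous
noise states (via the package's deterministic structural evaluation) or
over total assignments (with its own transcription of the noisy-OR
conditional), so that the exact-inference and counterfactual code paths
can be checked against an implementation that shares none of their
algebra (no inclusion–exclusion, no factorisation, no vectorisation).
"""

import itertools

from twindiag.model import Assignment, ExogenousState, Intervention, structural_eval


def iter_exogenous_states(network):
    """All exogenous states of a (tiny) network with their probabilities."""
    risk_ids = network.risks
    edges = network.edges()
    children = sorted(list(network.disease_cpts) + list(network.symptom_cpts))
    probs = (
        [network.risk_priors[r] for r in risk_ids]
        + [
            network.cpt(c).parent_failures[p]
            for (p, c) in edges
        ]
        + [network.cpt(c).leak_failure for c in children]
    )
    n = len(probs)
    for bits in itertools.product((0, 1), repeat=n):
        p = 1.0
        for b, q in zip(bits, probs):
            p *= q if b else 1.0 - q
        nr = len(risk_ids)
        ne = len(edges)
        state = ExogenousState(
            risk_draws=dict(zip(risk_ids, bits[:nr])),
            edge_noise=dict(zip(edges, bits[nr : nr + ne])),
            leak_noise=dict(zip(children, bits[nr + ne :])),
        )
        yield state, p


def joint_via_noise(network, assignment):
    """P(assignment) by summing noise states that evaluate to it."""
    total = 0.0
    target = dict(assignment.values)
    for state, p in iter_exogenous_states(network):
        if structural_eval(network, state).values == target:
            total += p
    return total


def full_joint_table(network):
    """{total assignment (sorted tuple of (id, value)): probability}.

    Uses its own noisy-OR product, written scalar and independent of the
    package's joint_probability.
    """
    ids = sorted(network.node_ids())
    table = {}
    for bits in itertools.product((0, 1), repeat=len(ids)):
        vals = dict(zip(ids, bits))
        p = 1.0
        for r in network.risks:
            p *= network.risk_priors[r] if vals[r] else 1.0 - network.risk_priors[r]
        for cpts in (network.disease_cpts, network.symptom_cpts):
            for child, cpt in cpts.items():
                off = cpt.leak_failure
                for parent, lam in cpt.parent_failures.items():
                    if vals[parent]:
                        off *= lam
                p *= (1.0 - off) if vals[child] else off
        table[tuple(sorted(vals.items()))] = p
    return table


def _consistent(vals, risk_evidence, positives=(), negatives=(), on_disease=None, off=()):
    d = dict(vals)
    if any(d[r] != v for r, v in risk_evidence.items()):
        return False
    if any(d[s] != 1 for s in positives):
        return False
    if any(d[s] != 0 for s in negatives):
        return False
    if on_disease is not None and d[on_disease] != 1:
        return False
    if any(d[s] != 0 for s in off):
        return False
    return True


def brute_evidence_likelihood(network, evidence):
    table = full_joint_table(network)
    re = evidence.risk_evidence
    num = sum(
        p
        for vals, p in table.items()
        if _consistent(vals, re, evidence.positive_symptoms, evidence.negative_symptoms)
    )
    den = sum(p for vals, p in table.items() if _consistent(vals, re))
    return num / den if den > 0 else 0.0


def brute_posterior(network, evidence, disease_id):
    table = full_joint_table(network)
    re = evidence.risk_evidence
    num = sum(
        p
        for vals, p in table.items()
        if _consistent(
            vals, re, evidence.positive_symptoms, evidence.negative_symptoms, disease_id
        )
    )
    den = sum(
        p
        for vals, p in table.items()
        if _consistent(vals, re, evidence.positive_symptoms, evidence.negative_symptoms)
    )
    return num / den


def brute_negated_subset(network, evidence, disease_id, Z):
    table = full_joint_table(network)
    re = evidence.risk_evidence
    num = sum(
        p
        for vals, p in table.items()
        if _consistent(
            vals, re, (), evidence.negative_symptoms, disease_id, off=tuple(Z)
        )
    )
    den = sum(p for vals, p in table.items() if _consistent(vals, re))
    return num / den if den > 0 else 0.0


def abduction_by_hand(network, evidence, intervention, count):
    """Scalar abduction–action–prediction for tiny networks.

    ``count(cf_assignment)`` maps the re-evaluated counterfactual world to
    the quantity being averaged (an indicator or a symptom count).
    """
    total_w = 0.0
    total = 0.0
    re = evidence.risk_evidence
    for state, p in iter_exogenous_states(network):
        if any(state.risk_draws[r] != v for r, v in re.items()):
            continue
        world = structural_eval(network, state)
        if any(world[s] != 1 for s in evidence.positive_symptoms):
            continue
        if any(world[s] != 0 for s in evidence.negative_symptoms):
            continue
        total_w += p
        cf = structural_eval(network, state, intervention)
        total += p * count(cf)
    return total / total_w
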