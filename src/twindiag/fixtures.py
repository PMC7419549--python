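"""Hand-built reference networks used in tests, examples and docs.

These encode the canonical causal shapes that motivate counterfactual
diagnosis: a direct cause, a pure confounder (where the posterior ranks a
disease that cannot have caused the symptom), the mixed case, and the
symmetric two-disease network that exercises the simplicity desideratum.
All shapes respect the three-layer constraint (risk → disease → symptom),
so the classic "R → D, R → S" confounder is realised with a mediating
disease carrying R's influence onto S.
"""

from __future__ import annotations

from .model import NodeRef, NoisyOrCPT, NoisyOrNetwork

__all__ = [
    "single_link_network",
    "confounded_network",
    "symmetric_explainer_network",
]


def single_link_network(
    prior: float = 0.2, lam: float = 0.4, leak_failure: float = 0.9
) -> NoisyOrNetwork:
    """One disease, one symptom, one edge: D → S.

    The disease has no risk parents, so its prior is encoded by its leak:
    ``P(D=1) = prior`` via ``λ₀ = 1 − prior``.  With the defaults
    (prior 0.2, λ 0.4, symptom leak-failure 0.9) the worked quantities are
    P(S=1) = 0.208, P(D=1|S=1) = 0.128/0.208, expected sufficiency
    0.12/0.208 and expected disablement 0.108/0.208.
    """
    return NoisyOrNetwork(
        nodes=[NodeRef("D", "disease"), NodeRef("S", "symptom")],
        risk_priors={},
        disease_cpts={"D": NoisyOrCPT("D", {}, 1.0 - prior)},
        symptom_cpts={"S": NoisyOrCPT("S", {"D": lam}, leak_failure)},
    )


def confounded_network(shape: str = "confounded") -> NoisyOrNetwork:
    """The three causal shapes relating a candidate disease to a symptom.

    ``"direct"``     — D_cand → S only (D_cand is a genuine cause).
    ``"confounded"`` — R → D_cand and R → D_med → S: D_cand is strongly
        correlated with S through the shared risk factor R but has no
        directed path to S, so it cannot have caused it.  A weak independent
        cause D_weak → S is included so that the posterior's causality
        violation is observable: given S, the posterior ranks D_cand above
        D_weak, while any causal measure must score D_cand exactly zero.
    ``"mixed"``      — both: R → D_cand → S and R → D_med → S.
    """
    if shape not in ("direct", "confounded", "mixed"):
        raise ValueError(f"unknown shape {shape!r}")
    nodes = [
        NodeRef("R", "risk"),
        NodeRef("Dcand", "disease", "candidate disease"),
        NodeRef("Dmed", "disease", "mediating disease"),
        NodeRef("Dweak", "disease", "weak independent cause"),
        NodeRef("S", "symptom"),
    ]
    risk_priors = {"R": 0.3}
    disease_cpts = {
        "Dcand": NoisyOrCPT("Dcand", {"R": 0.05}, 0.999),
        "Dmed": NoisyOrCPT("Dmed", {"R": 0.05}, 0.999),
        "Dweak": NoisyOrCPT("Dweak", {}, 0.95),
    }
    s_parents = {"Dmed": 0.2, "Dweak": 0.5}
    if shape in ("direct", "mixed"):
        s_parents["Dcand"] = 0.2
    if shape == "direct":
        # no confounding path: D_cand independent of R, D_med detached from S
        disease_cpts["Dcand"] = NoisyOrCPT("Dcand", {}, 0.7)
        s_parents = {"Dcand": 0.2, "Dweak": 0.5}
    symptom_cpts = {"S": NoisyOrCPT("S", s_parents, 0.98)}
    return NoisyOrNetwork(nodes, risk_priors, disease_cpts, symptom_cpts)


def symmetric_explainer_network(
    prior: float = 0.3, lam: float = 0.3, leak_failure: float = 0.95
) -> NoisyOrNetwork:
    """Two interchangeable diseases; D_A explains two present symptoms,
    D_B only one.  Equal priors, equal λ, equal leaks — any measure
    honouring the simplicity desideratum must rank D_A strictly above D_B
    when all three symptoms are present."""
    nodes = [
        NodeRef("DA", "disease"),
        NodeRef("DB", "disease"),
        NodeRef("S1", "symptom"),
        NodeRef("S2", "symptom"),
        NodeRef("S3", "symptom"),
    ]
    disease_cpts = {
        "DA": NoisyOrCPT("DA", {}, 1.0 - prior),
        "DB": NoisyOrCPT("DB", {}, 1.0 - prior),
    }
    symptom_cpts = {
        "S1": NoisyOrCPT("S1", {"DA": lam}, leak_failure),
        "S2": NoisyOrCPT("S2", {"DA": lam}, leak_failure),
        "S3": NoisyOrCPT("S3", {"DB": lam}, leak_failure),
    }
    return NoisyOrNetwork(nodes, {}, disease_cpts, symptom_cpts)
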