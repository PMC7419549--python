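"""Counterfactual diagnostic measures on noisy-OR twin networks.

Two measures quantify how well a disease hypothesis *causally explains* the
positively evidenced symptoms S₊, beyond being merely correlated with them:

* **expected disablement** — the expected number of present symptoms that
  would switch off had we intervened to cure the disease, ``do(D=0)``
  (necessary-cause flavour);
* **expected sufficiency** — the expected number of present symptoms that
  would persist had we switched off every *other* possible cause — all other
  disease parents of S₊ and the leak ("exogenous") parents of S₊ — leaving
  only D to sustain them (sufficient-cause flavour).

Both are counterfactuals: the hypothetical world shares its exogenous noise
with the factual world that produced the evidence.  They are computed two
independent ways, which must agree:

1. ``closed_form`` — the exact inclusion–exclusion expression over subsets
   ``Z ⊆ S₊``::

       measure(D_k) = Σ_{Z⊆S₊} (−1)^{|Z|} P(S₋=0, Z=0, D_k=1 | R) τ(k,Z)
                      / P(S± | R)

   with ``τ(k,Z) = Σ_{S∈S₊∖Z} (1−λ_{k,S})`` for sufficiency and
   ``τ(k,Z) = Σ_{S∈Z} (1−1/λ_{k,S})`` for disablement (λ taken as 1 when the
   edge is absent).  The disablement τ divides by λ; the joint it multiplies
   itself contains a factor λ_{k,S} for ``S∈Z`` with ``D_k=1``, so the
   implementation cancels it analytically and never divides by zero.

2. ``twin_def`` — the definitional route: build the twin network (factual
   and counterfactual copies of affected nodes sharing exogenous noise),
   condition the factual half on the evidence, apply the intervention to the
   counterfactual half, and take the expectation of the symptom count by
   exact enumeration.  Per twin family, the joint of a factual child and its
   counterfactual copy given both parent sets is obtained by marginalising
   the shared noise in closed form.

A third route, abduction–action–prediction by exhaustive noise enumeration,
lives in :mod:`twindiag.oracle` and serves as the reference oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np

from .errors import ZeroEvidenceError
from .inference import Evidence, QuickscoreEngine, _subsets
from .model import Intervention, NoisyOrNetwork

MAX_TWIN_BITS = 22

__all__ = [
    "CounterfactualQuery",
    "TwinNetwork",
    "build_twin_network",
    "counterfactual_probability",
    "expected_disablement",
    "expected_sufficiency",
    "sufficiency_intervention",
]


@dataclass(frozen=True)
class CounterfactualQuery:
    """``P(target = value | factual evidence, do(intervention))``."""

    evidence: Evidence
    intervention: Intervention
    target: Tuple[str, int]


@dataclass(frozen=True)
class TwinNetwork:
    """Factual + counterfactual halves of a network under one intervention.

    ``copies`` lists the endogenous nodes whose counterfactual value may
    differ from the factual one: the intervened nodes (including children
    whose leak is switched off) and all their descendants.  Every other node
    is shared between the halves; copies share their family's exogenous
    noise with the factual original.
    """

    base: NoisyOrNetwork
    copies: FrozenSet[str]
    intervention: Intervention


def _affected(network: NoisyOrNetwork, intervention: Intervention) -> FrozenSet[str]:
    g = network.graph()
    roots = set(intervention.targets) | set(intervention.leak_off)
    for t in roots:
        if t not in g:
            raise ValueError(f"intervention targets unknown node {t!r}")
    out = set()
    for t in roots:
        out.add(t)
        out |= nx.descendants(g, t)
    return frozenset(out)


def build_twin_network(
    network: NoisyOrNetwork, intervention: Intervention
) -> TwinNetwork:
    """Counterfactual copies exist exactly for intervention-affected nodes;
    an empty intervention collapses the twin onto the factual network."""
    return TwinNetwork(network, _affected(network, intervention), intervention)


# ---------------------------------------------------------------------------
# twin-network exact enumeration


def _noisy_or_off(parent_cols, lams, leak: float):
    """P(child = 0 | parents) as a vector over rows; ``leak`` is λ₀ or 1.0
    when the leak parent has been intervened away."""
    out = leak
    for col, lam in zip(parent_cols, lams):
        out = out * (1.0 - col + col * lam)
    return out


def _pair_factor(x, y, q_f, q_c, q_fc):
    """P(factual child = x, counterfactual child = y) given the two off
    probabilities and the shared-noise joint-off probability."""
    return (
        (1.0 - x) * (1.0 - y) * q_fc
        + (1.0 - x) * y * (q_f - q_fc)
        + x * (1.0 - y) * (q_c - q_fc)
        + x * y * (1.0 - q_f - q_c + q_fc)
    )


def _marginal_factor(x, q):
    return (1.0 - x) * q + x * (1.0 - q)


class _TwinEnumeration:
    """Exact joint over the twin network, restricted to relevant nodes.

    Enumerated bits: unobserved risk factors, all factual diseases, the
    counterfactual disease copies, and factual/counterfactual values of the
    requested target symptoms.  Unevidenced, untargeted symptoms contribute
    no factor (exact marginalisation).  Evidenced nodes are clamped to the
    evidence, so the total weight is ``P(S±, targets | R)`` row by row.
    """

    def __init__(
        self,
        network: NoisyOrNetwork,
        evidence: Evidence,
        intervention: Intervention,
        targets: Sequence[str],
    ):
        evidence.validate_against(network)
        self.network = network
        copies = _affected(network, intervention)
        clamp = intervention.targets
        evid_value: Dict[str, float] = {s: 1.0 for s in evidence.positive_symptoms}
        evid_value.update({s: 0.0 for s in evidence.negative_symptoms})

        bit_specs: List[Tuple[str, str, float]] = []  # (kind, node, prob-if-relevant)
        free_risks = [r for r in network.risks if r not in evidence.risk_evidence]
        for r in free_risks:
            bit_specs.append(("risk", r, network.risk_priors[r]))
        for d in network.diseases:
            bit_specs.append(("disease_f", d, np.nan))
        cf_disease_bits = [
            d for d in network.diseases if d in copies and d not in clamp
        ]
        for d in cf_disease_bits:
            bit_specs.append(("disease_c", d, np.nan))
        target_symptoms = [t for t in targets if t in network.symptom_cpts]
        cf_symptom_bits = [
            s for s in sorted(set(target_symptoms)) if s in copies and s not in clamp
        ]
        for s in cf_symptom_bits:
            bit_specs.append(("symptom_c", s, np.nan))
        fact_symptom_bits = [
            s
            for s in sorted(set(target_symptoms))
            if s not in copies and s not in clamp and s not in evid_value
        ]
        for s in fact_symptom_bits:
            bit_specs.append(("symptom_f", s, np.nan))

        if len(bit_specs) > MAX_TWIN_BITS:
            raise ValueError(
                f"twin-network enumeration needs {len(bit_specs)} bits, above the "
                f"exact-evaluation contract of {MAX_TWIN_BITS}; use the closed form "
                "for networks of this size"
            )
        n_rows = 1 << len(bit_specs)
        idx = np.arange(n_rows, dtype=np.int64)
        cols = {
            (kind, node): ((idx >> i) & 1).astype(float)
            for i, (kind, node, _) in enumerate(bit_specs)
        }

        weights = np.ones(n_rows)

        # risk layer: factual values, prior factors for free risks only
        fact_risk: Dict[str, Union[float, np.ndarray]] = {}
        for r in network.risks:
            if r in evidence.risk_evidence:
                fact_risk[r] = float(evidence.risk_evidence[r])
            else:
                col = cols[("risk", r)]
                fact_risk[r] = col
                p = network.risk_priors[r]
                weights *= np.where(col == 1.0, p, 1.0 - p)
        cf_risk = {
            r: (float(clamp[r]) if r in clamp else fact_risk[r])
            for r in network.risks
        }

        # disease layer
        fact_dis: Dict[str, Union[float, np.ndarray]] = {}
        cf_dis: Dict[str, Union[float, np.ndarray]] = {}
        for d in network.diseases:
            cpt = network.disease_cpts[d]
            parents = sorted(cpt.parent_failures)
            lams = [cpt.parent_failures[p] for p in parents]
            x = cols[("disease_f", d)]
            fact_dis[d] = x
            A = [fact_risk[p] for p in parents]
            q_f = _noisy_or_off(A, lams, cpt.leak_failure)
            if d in clamp:
                cf_dis[d] = float(clamp[d])
                weights *= _marginal_factor(x, q_f)
            elif d in copies:
                y = cols[("disease_c", d)]
                cf_dis[d] = y
                B = [cf_risk[p] for p in parents]
                cf_leak = cpt.leak_failure if d not in intervention.leak_off else 1.0
                q_c = _noisy_or_off(B, lams, cf_leak)
                both = [a + b - a * b for a, b in zip(A, B)]
                q_fc = _noisy_or_off(both, lams, cpt.leak_failure)
                weights *= _pair_factor(x, y, q_f, q_c, q_fc)
            else:
                cf_dis[d] = x
                weights *= _marginal_factor(x, q_f)

        # symptom layer: only evidenced or targeted families contribute
        cf_val: Dict[str, Union[float, np.ndarray]] = {}
        for s in network.symptoms:
            cpt = network.symptom_cpts[s]
            parents = sorted(cpt.parent_failures)
            lams = [cpt.parent_failures[p] for p in parents]
            evidenced = s in evid_value
            needed_cf = s in set(target_symptoms)
            if s in clamp:
                cf_val[s] = float(clamp[s])
                if evidenced:
                    A = [fact_dis[p] for p in parents]
                    weights *= _marginal_factor(
                        evid_value[s], _noisy_or_off(A, lams, cpt.leak_failure)
                    )
                continue
            in_copies = s in copies
            if not (evidenced or needed_cf):
                continue
            A = [fact_dis[p] for p in parents]
            q_f = _noisy_or_off(A, lams, cpt.leak_failure)
            x = evid_value[s] if evidenced else None
            if needed_cf and in_copies:
                y = cols[("symptom_c", s)]
                cf_val[s] = y
                B = [cf_dis[p] for p in parents]
                cf_leak = cpt.leak_failure if s not in intervention.leak_off else 1.0
                q_c = _noisy_or_off(B, lams, cf_leak)
                if evidenced:
                    both = [a + b - a * b for a, b in zip(A, B)]
                    q_fc = _noisy_or_off(both, lams, cpt.leak_failure)
                    weights *= _pair_factor(x, y, q_f, q_c, q_fc)
                else:
                    weights *= _marginal_factor(y, q_c)
            else:
                # counterfactual value coincides with the factual one
                if evidenced:
                    cf_val[s] = x
                    weights *= _marginal_factor(x, q_f)
                else:
                    x = cols[("symptom_f", s)]
                    cf_val[s] = x
                    weights *= _marginal_factor(x, q_f)

        self.weights = weights
        self._cf_val = cf_val
        self._cf_dis = cf_dis
        self._cf_risk = cf_risk
        self._clamp = clamp

    def cf_value(self, node: str) -> Union[float, np.ndarray]:
        if node in self._cf_val:
            return self._cf_val[node]
        if node in self._cf_dis:
            return self._cf_dis[node]
        if node in self._cf_risk:
            return self._cf_risk[node]
        raise KeyError(node)


def counterfactual_probability(
    network: NoisyOrNetwork, query: CounterfactualQuery
) -> float:
    """Exact ``P(target=value | evidence, do(intervention))`` on the twin
    network.  Equals the abduction–action–prediction computation by
    construction of the shared-noise family joints."""
    node, value = query.target
    if node not in set(network.node_ids()):
        raise ValueError(f"unknown target node {node!r}")
    enum = _TwinEnumeration(
        network, query.evidence, query.intervention, targets=[node]
        if node in network.symptom_cpts
        else [],
    )
    denom = float(enum.weights.sum())
    if denom <= 0.0:
        raise ZeroEvidenceError()
    col = enum.cf_value(node)
    if np.isscalar(col) or np.ndim(col) == 0:
        return 1.0 if int(col) == int(value) else 0.0
    hit = col == float(value)
    return float(enum.weights[hit].sum()) / denom


def sufficiency_intervention(
    network: NoisyOrNetwork, positive_symptoms: FrozenSet[str], disease_id: str
) -> Intervention:
    """The sufficient-cause intervention ``do(Pa(S₊) ∖ D = 0)``: switch off
    every other disease parent of the present symptoms and the present
    symptoms' leak parents, leaving only D as a possible cause."""
    other_parents = set()
    for s in positive_symptoms:
        other_parents |= set(network.symptom_cpts[s].parent_failures)
    other_parents.discard(disease_id)
    return Intervention(
        targets={d: 0 for d in sorted(other_parents)},
        leak_off=frozenset(positive_symptoms),
    )


def _measure_twin_def(
    network: NoisyOrNetwork, evidence: Evidence, disease_id: str, kind: str
) -> float:
    pos = sorted(evidence.positive_symptoms)
    if kind == "sufficiency":
        intervention = sufficiency_intervention(
            network, evidence.positive_symptoms, disease_id
        )
    else:
        intervention = Intervention(targets={disease_id: 0})
    enum = _TwinEnumeration(network, evidence, intervention, targets=pos)
    denom = float(enum.weights.sum())
    if denom <= 0.0:
        raise ZeroEvidenceError()
    count = np.zeros_like(enum.weights)
    for s in pos:
        col = enum.cf_value(s)
        col = np.broadcast_to(np.asarray(col, dtype=float), enum.weights.shape)
        count = count + (col if kind == "sufficiency" else 1.0 - col)
    return float((enum.weights * count).sum()) / denom


def _measure_closed_form(
    network: NoisyOrNetwork,
    evidence: Evidence,
    disease_id: str,
    kind: str,
    engine: Optional[QuickscoreEngine],
) -> float:
    engine = engine or QuickscoreEngine(network, evidence.risk_evidence)
    denom = engine.evidence_likelihood(evidence)
    if denom <= 0.0:
        raise ZeroEvidenceError()
    pos = tuple(sorted(evidence.positive_symptoms))
    neg = frozenset(evidence.negative_symptoms)
    cpt_lam = {
        s: network.symptom_cpts[s].parent_failures.get(disease_id, 1.0) for s in pos
    }
    num = 0.0
    for z in _subsets(pos):
        sign = (-1) ** len(z)
        if kind == "sufficiency":
            tau = sum(1.0 - cpt_lam[s] for s in pos if s not in z)
            if tau == 0.0:
                continue
            num += sign * tau * engine.off_probability(z | neg, disease_id)
        else:
            # τ = Σ_{S∈Z} (1 − 1/λ); multiply each summand against the joint
            # with its λ cancelled analytically so λ = 0 stays finite
            for s in z:
                lam = cpt_lam[s]
                if lam == 1.0:
                    continue
                num += (
                    sign
                    * (lam - 1.0)
                    * engine.off_probability(
                        z | neg, disease_id, excluded_edge=(disease_id, s)
                    )
                )
    return num / denom


def _measure(
    network: NoisyOrNetwork,
    evidence: Evidence,
    disease_id: str,
    kind: str,
    method: str,
    engine: Optional[QuickscoreEngine],
) -> float:
    if disease_id not in network.disease_cpts:
        raise ValueError(f"unknown disease {disease_id!r}")
    if method not in ("closed_form", "twin_def"):
        raise ValueError(f"unknown method {method!r}")
    if not evidence.positive_symptoms:
        # no present symptoms: nothing to explain, both measures vanish
        return 0.0
    if method == "twin_def":
        return _measure_twin_def(network, evidence, disease_id, kind)
    return _measure_closed_form(network, evidence, disease_id, kind, engine)


def expected_sufficiency(
    network: NoisyOrNetwork,
    evidence: Evidence,
    disease_id: str,
    method: str = "closed_form",
    engine: Optional[QuickscoreEngine] = None,
) -> float:
    """Expected number of present symptoms persisting under
    ``do(Pa(S₊)∖D = 0)`` (all other causes, including the symptoms' leaks,
    switched off), given the factual evidence."""
    return _measure(network, evidence, disease_id, "sufficiency", method, engine)


def expected_disablement(
    network: NoisyOrNetwork,
    evidence: Evidence,
    disease_id: str,
    method: str = "closed_form",
    engine: Optional[QuickscoreEngine] = None,
) -> float:
    """Expected number of present symptoms switched off under the cure
    ``do(D = 0)``, given the factual evidence."""
    return _measure(network, evidence, disease_id, "disablement", method, engine)
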