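"""Abduction–action–prediction by exhaustive noise enumeration.

The reference oracle for every counterfactual quantity in the package.  It
follows the three textbook steps literally:

1. **abduction** — enumerate every assignment of the exogenous noise terms
   ``u`` (risk draws, edge failures, leak failures), evaluate the structural
   equations, and weight each ``u`` by ``P(u)`` restricted to consistency
   with the factual evidence;
2. **action** — apply the do-intervention by severing the intervened
   mechanisms;
3. **prediction** — re-evaluate the structural equations under the same
   noise and average the query over the noise posterior.

Cost is ``2^{#noise terms}``, so the oracle is restricted by contract to
test-size networks (hard cap on enumerated bits).  Noise families that can
influence neither the evidence nor the queried nodes (the families of
unevidenced, unqueried symptoms) are skipped — exact marginalisation, not an
approximation.  Everything is vectorised over the noise table, but the
propagation is a direct transcription of the structural equations and shares
no code with the closed form or the twin-network evaluator.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np

from .counterfactual import CounterfactualQuery, sufficiency_intervention
from .errors import ZeroEvidenceError
from .inference import Evidence
from .model import Intervention, NoisyOrNetwork

MAX_ORACLE_BITS = 22

__all__ = [
    "NoiseEnumerationOracle",
    "abduction_counterfactual_probability",
    "abduction_expected_disablement",
    "abduction_expected_sufficiency",
]


class NoiseEnumerationOracle:
    """Noise-posterior table for one (network, evidence) pair.

    The factual propagation, evidence mask and noise weights are built once;
    each counterfactual query then only re-propagates the hypothetical half.

    Parameters
    ----------
    network, evidence :
        The model and the factual evidence conditioned on.
    extra_symptoms :
        Unevidenced symptoms whose noise families must still be enumerated
        because a query will read their counterfactual value.
    """

    def __init__(
        self,
        network: NoisyOrNetwork,
        evidence: Evidence,
        extra_symptoms: Iterable[str] = (),
    ):
        evidence.validate_against(network)
        self.network = network
        self.evidence = evidence
        relevant_symptoms = sorted(
            set(evidence.positive_symptoms)
            | set(evidence.negative_symptoms)
            | set(extra_symptoms)
        )
        for s in relevant_symptoms:
            if s not in network.symptom_cpts:
                raise ValueError(f"unknown symptom {s!r}")
        self._relevant_symptoms = relevant_symptoms

        bits: List[Tuple[Tuple, float]] = []  # (key, P(bit = 1))
        free_risks = [r for r in network.risks if r not in evidence.risk_evidence]
        for r in free_risks:
            bits.append((("draw", r), network.risk_priors[r]))
        for d in network.diseases:
            cpt = network.disease_cpts[d]
            bits.append((("leak", d), cpt.leak_failure))
            for p in sorted(cpt.parent_failures):
                bits.append((("edge", p, d), cpt.parent_failures[p]))
        for s in relevant_symptoms:
            cpt = network.symptom_cpts[s]
            bits.append((("leak", s), cpt.leak_failure))
            for p in sorted(cpt.parent_failures):
                bits.append((("edge", p, s), cpt.parent_failures[p]))
        if len(bits) > MAX_ORACLE_BITS:
            raise ValueError(
                f"noise enumeration needs {len(bits)} bits, above the oracle "
                f"contract of {MAX_ORACLE_BITS} (test-size networks only)"
            )
        idx = np.arange(1 << len(bits), dtype=np.int64)
        self._u: Dict[Tuple, np.ndarray] = {}
        weights = np.ones(idx.shape[0])
        for i, (key, p) in enumerate(bits):
            col = ((idx >> i) & 1).astype(bool)
            self._u[key] = col
            weights *= np.where(col, p, 1.0 - p)

        # factual propagation (structural equations, no intervention)
        risk_vals: Dict[str, np.ndarray] = {}
        n_rows = idx.shape[0]
        for r in network.risks:
            if r in evidence.risk_evidence:
                risk_vals[r] = np.full(n_rows, bool(evidence.risk_evidence[r]))
            else:
                risk_vals[r] = self._u[("draw", r)]
        self._fact_risk = risk_vals
        self._fact_dis = self._propagate_layer(
            network.disease_cpts, network.diseases, risk_vals, Intervention.none()
        )
        fact_sym = self._propagate_layer(
            network.symptom_cpts, relevant_symptoms, self._fact_dis, Intervention.none()
        )
        self._fact_sym = fact_sym

        mask = np.ones(n_rows, dtype=bool)
        for s in evidence.positive_symptoms:
            mask &= fact_sym[s]
        for s in evidence.negative_symptoms:
            mask &= ~fact_sym[s]
        self.posterior_weights = np.where(mask, weights, 0.0)
        self.evidence_probability = float(self.posterior_weights.sum())

    def _propagate_layer(
        self,
        cpts,
        children: Iterable[str],
        parent_vals: Mapping[str, np.ndarray],
        intervention: Intervention,
    ) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        n_rows = self.posterior_weights.shape[0] if hasattr(self, "posterior_weights") else None
        for child in children:
            if child in intervention.targets:
                val = bool(intervention.targets[child])
                ref = next(iter(parent_vals.values()), None)
                size = ref.shape[0] if ref is not None else n_rows
                out[child] = np.full(size, val)
                continue
            cpt = cpts[child]
            if child in intervention.leak_off:
                on = np.zeros_like(self._u[("leak", child)])
            else:
                on = ~self._u[("leak", child)]
            for p in sorted(cpt.parent_failures):
                on = on | (parent_vals[p] & ~self._u[("edge", p, child)])
            out[child] = on
        return out

    # -- queries ------------------------------------------------------------

    def counterfactual_values(
        self, intervention: Intervention, symptoms: Iterable[str]
    ) -> Dict[str, np.ndarray]:
        """Re-propagate the hypothetical world under ``intervention`` (same
        noise) and return the requested symptom columns."""
        symptoms = list(symptoms)
        missing = [s for s in symptoms if s not in self._relevant_symptoms]
        if missing:
            raise ValueError(
                f"symptom families not enumerated: {missing}; pass them as "
                "extra_symptoms when building the oracle"
            )
        cf_risk = {
            r: (
                np.full_like(col, bool(intervention.targets[r]))
                if r in intervention.targets
                else col
            )
            for r, col in self._fact_risk.items()
        }
        cf_dis = self._propagate_layer(
            self.network.disease_cpts, self.network.diseases, cf_risk, intervention
        )
        cf_sym = self._propagate_layer(
            self.network.symptom_cpts, symptoms, cf_dis, intervention
        )
        return cf_sym

    def _require_evidence(self) -> None:
        if self.evidence_probability <= 0.0:
            raise ZeroEvidenceError()

    def expectation(self, intervention: Intervention, count_on: bool) -> float:
        """Posterior expectation over S₊ of counterfactually-on symptoms
        (``count_on=True``) or counterfactually-disabled ones."""
        self._require_evidence()
        pos = sorted(self.evidence.positive_symptoms)
        if not pos:
            return 0.0
        cf = self.counterfactual_values(intervention, pos)
        count = np.zeros_like(self.posterior_weights)
        for s in pos:
            count += cf[s] if count_on else ~cf[s]
        return float((self.posterior_weights * count).sum()) / self.evidence_probability

    def probability(self, intervention: Intervention, target: Tuple[str, int]) -> float:
        self._require_evidence()
        node, value = target
        if node in self.network.symptom_cpts:
            col = self.counterfactual_values(intervention, [node])[node]
        elif node in self.network.disease_cpts:
            cf_risk = {
                r: (
                    np.full_like(c, bool(intervention.targets[r]))
                    if r in intervention.targets
                    else c
                )
                for r, c in self._fact_risk.items()
            }
            col = self._propagate_layer(
                self.network.disease_cpts, [node], cf_risk, intervention
            )[node]
        elif node in self.network.risk_priors:
            col = (
                np.full_like(self._fact_risk[node], bool(intervention.targets[node]))
                if node in intervention.targets
                else self._fact_risk[node]
            )
        else:
            raise ValueError(f"unknown target node {node!r}")
        hit = col == bool(value)
        return float(self.posterior_weights[hit].sum()) / self.evidence_probability


def abduction_counterfactual_probability(
    network: NoisyOrNetwork, query: CounterfactualQuery
) -> float:
    """``P(target | evidence, do(intervention))`` by abduction over noise."""
    node, _ = query.target
    extra = [node] if node in network.symptom_cpts else []
    oracle = NoiseEnumerationOracle(network, query.evidence, extra_symptoms=extra)
    return oracle.probability(query.intervention, query.target)


def abduction_expected_disablement(
    network: NoisyOrNetwork, evidence: Evidence, disease_id: str
) -> float:
    """Expected disablement by literal abduction–action–prediction."""
    if disease_id not in network.disease_cpts:
        raise ValueError(f"unknown disease {disease_id!r}")
    oracle = NoiseEnumerationOracle(network, evidence)
    return oracle.expectation(Intervention(targets={disease_id: 0}), count_on=False)


def abduction_expected_sufficiency(
    network: NoisyOrNetwork, evidence: Evidence, disease_id: str
) -> float:
    """Expected sufficiency by literal abduction–action–prediction."""
    if disease_id not in network.disease_cpts:
        raise ValueError(f"unknown disease {disease_id!r}")
    oracle = NoiseEnumerationOracle(network, evidence)
    intervention = sufficiency_intervention(
        network, evidence.positive_symptoms, disease_id
    )
    return oracle.expectation(intervention, count_on=True)
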