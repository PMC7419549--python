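"""Exact associative inference on three-layer noisy-OR networks.

The quantities computed here are the evidence likelihood ``P(S± | R)``, the
disease posterior ``P(D=1 | S±, R)`` used by the associative ranking, and
the "switched-off subset" joints ``P(S− = 0, Z = 0, D_k = 1 | R)`` that the
closed-form counterfactual measures are built from.

Strategy
--------
Negative symptom evidence factorises across diseases in a noisy-OR network,
and positive evidence is reduced to negative evidence by inclusion–exclusion
over subsets ``Z ⊆ S₊`` (the classic quickscore decomposition)::

    P(S₊=1, S₋=0 | R) = Σ_{Z⊆S₊} (−1)^{|Z|} P(Z=0, S₋=0 | R)

For a fixed "off" set of symptoms, diseases are conditionally independent
given a risk-layer configuration, so each term is a small product that we
evaluate exactly, marginalising unobserved risk factors by enumerating risk
configurations (vectorised; observed risks are clamped and conditioned on).
Unobserved symptoms are marginalised, never treated as negative.

This is exact; cost is ``2^{|S₊|} · 2^{#unobserved risks}`` per query, which
is the intended operating regime (tens of relevant diseases, a handful of
positive symptoms).  Hard caps raise clear errors beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from .errors import ZeroEvidenceError
from .model import NoisyOrNetwork

MAX_POSITIVE_SYMPTOMS = 16
MAX_FREE_RISKS = 16

__all__ = [
    "Evidence",
    "evidence_likelihood",
    "posterior_disease",
    "negated_subset_likelihood",
    "posterior_ranking",
    "QuickscoreEngine",
]


@dataclass(frozen=True)
class Evidence:
    """Clinical evidence: risk-factor values plus symptom findings.

    ``positive_symptoms`` (S₊) are observed present, ``negative_symptoms``
    (S₋) observed absent; symptoms in neither set are unobserved.  Risk
    evidence may be partial; unobserved risk factors are marginalised using
    their priors.
    """

    risk_evidence: Mapping[str, int] = field(default_factory=dict)
    positive_symptoms: FrozenSet[str] = frozenset()
    negative_symptoms: FrozenSet[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "risk_evidence", {k: int(v) for k, v in dict(self.risk_evidence).items()}
        )
        object.__setattr__(self, "positive_symptoms", frozenset(self.positive_symptoms))
        object.__setattr__(self, "negative_symptoms", frozenset(self.negative_symptoms))
        overlap = self.positive_symptoms & self.negative_symptoms
        if overlap:
            raise ValueError(
                f"symptoms cannot be both present and absent: {sorted(overlap)}"
            )

    def validate_against(self, network: NoisyOrNetwork) -> None:
        for rid in self.risk_evidence:
            if rid not in network.risk_priors:
                raise ValueError(f"risk evidence names unknown risk factor {rid!r}")
        symptom_set = set(network.symptom_cpts)
        for sid in self.positive_symptoms | self.negative_symptoms:
            if sid not in symptom_set:
                raise ValueError(f"symptom evidence names unknown symptom {sid!r}")


def _subsets(items: Tuple[str, ...]):
    n = len(items)
    for mask in range(1 << n):
        yield frozenset(items[i] for i in range(n) if mask >> i & 1)


class QuickscoreEngine:
    """Memoising exact-inference workhorse for one (network, risk evidence).

    Precomputes, per risk-layer configuration ``r``, the disease activation
    probabilities ``p_j(r) = 1 − λ₀ⱼ Π_{i: rᵢ=1} λ_{ij}`` and the
    configuration weights, then answers "off-set" joints

        ``P(all symptoms in O off [, D_k = 1] | R)``

    by per-disease products, memoised per off-set within the query.
    """

    def __init__(self, network: NoisyOrNetwork, risk_evidence: Mapping[str, int]):
        self.network = network
        self.risk_evidence = {k: int(v) for k, v in dict(risk_evidence).items()}
        for rid in self.risk_evidence:
            if rid not in network.risk_priors:
                raise ValueError(f"risk evidence names unknown risk factor {rid!r}")
        self.diseases = network.diseases
        self._dindex = {d: i for i, d in enumerate(self.diseases)}

        free = [r for r in network.risks if r not in self.risk_evidence]
        if len(free) > MAX_FREE_RISKS:
            raise ValueError(
                f"{len(free)} unobserved risk factors exceed the exact-inference "
                f"cap of {MAX_FREE_RISKS}"
            )
        n_cfg = 1 << len(free)
        bits = (np.arange(n_cfg)[:, None] >> np.arange(len(free))) & 1
        risk_value: Dict[str, np.ndarray] = {}
        weights = np.ones(n_cfg)
        for i, rid in enumerate(free):
            col = bits[:, i].astype(float)
            risk_value[rid] = col
            p = network.risk_priors[rid]
            weights *= np.where(col == 1.0, p, 1.0 - p)
        for rid, val in self.risk_evidence.items():
            risk_value[rid] = np.full(n_cfg, float(val))
        self.weights = weights

        # activation probability of each disease per risk configuration
        P = np.empty((n_cfg, len(self.diseases)))
        for j, d in enumerate(self.diseases):
            cpt = network.disease_cpts[d]
            off = np.full(n_cfg, cpt.leak_failure)
            for parent, lam in cpt.parent_failures.items():
                col = risk_value[parent]
                off = off * (1.0 - col + col * lam)
            P[:, j] = 1.0 - off
        self.P = P
        self._memo_off: Dict[FrozenSet[str], Tuple[float, np.ndarray, np.ndarray]] = {}

    def _off_components(self, off_set: FrozenSet[str]):
        """leak factor, per-disease survival vector m, and G matrix for an off-set."""
        cached = self._memo_off.get(off_set)
        if cached is not None:
            return cached
        leak = 1.0
        m = np.ones(len(self.diseases))
        for s in off_set:
            cpt = self.network.symptom_cpts[s]
            leak *= cpt.leak_failure
            for parent, lam in cpt.parent_failures.items():
                m[self._dindex[parent]] *= lam
        # G_j = P(disease j's contribution keeps the off-set off)
        G = (1.0 - self.P) + self.P * m[None, :]
        result = (leak, m, G)
        self._memo_off[off_set] = result
        return result

    def off_probability(
        self,
        off_set: FrozenSet[str],
        on_disease: Optional[str] = None,
        excluded_edge: Optional[Tuple[str, str]] = None,
    ) -> float:
        """Exact ``P(all of off_set = 0 [, D_k = 1] | R)``.

        With ``excluded_edge=(k, s)`` the failure probability λ_{k,s} is
        divided out of disease k's survival product analytically — used by
        the expected-disablement closed form, whose τ factor ``1 − 1/λ``
        would otherwise divide by zero for deterministic links.
        """
        leak, m, G = self._off_components(off_set)
        if on_disease is None:
            vals = G.prod(axis=1)
        else:
            k = self._dindex[on_disease]
            mk = m[k]
            if excluded_edge is not None:
                kd, s = excluded_edge
                if kd != on_disease:
                    raise ValueError("excluded edge must leave the constrained disease")
                mk = 1.0
                for t in off_set:
                    if t == s:
                        continue
                    lam = self.network.symptom_cpts[t].parent_failures.get(on_disease)
                    if lam is not None:
                        mk *= lam
                leak_excl = self.network.symptom_cpts[s].parent_failures.get(kd)
                if leak_excl is None:
                    raise ValueError(f"no edge {kd}->{s} to exclude")
            Gmod = G.copy()
            Gmod[:, k] = self.P[:, k] * mk
            vals = Gmod.prod(axis=1)
        return float(leak * (self.weights @ vals))

    # -- evidence-level queries --------------------------------------------

    def _check_symptoms(self, evidence: Evidence) -> Tuple[str, ...]:
        evidence.validate_against(self.network)
        pos = tuple(sorted(evidence.positive_symptoms))
        if len(pos) > MAX_POSITIVE_SYMPTOMS:
            raise ValueError(
                f"{len(pos)} positive symptoms exceed the inclusion-exclusion "
                f"cap of {MAX_POSITIVE_SYMPTOMS}"
            )
        return pos

    def evidence_likelihood(self, evidence: Evidence) -> float:
        pos = self._check_symptoms(evidence)
        neg = frozenset(evidence.negative_symptoms)
        total = 0.0
        for z in _subsets(pos):
            total += (-1) ** len(z) * self.off_probability(z | neg)
        return total

    def disease_joint(self, evidence: Evidence, disease_id: str) -> float:
        """``P(S₊=1, S₋=0, D_k=1 | R)`` — the posterior's numerator."""
        pos = self._check_symptoms(evidence)
        neg = frozenset(evidence.negative_symptoms)
        total = 0.0
        for z in _subsets(pos):
            total += (-1) ** len(z) * self.off_probability(z | neg, disease_id)
        return total


def evidence_likelihood(
    network: NoisyOrNetwork,
    evidence: Evidence,
    engine: Optional[QuickscoreEngine] = None,
) -> float:
    """Exact ``P(S₊ = 1, S₋ = 0 | R)``, marginalising everything unobserved.

    Returns 0.0 for impossible evidence (a legal value that callers
    conditioning on the evidence must check).
    """
    engine = engine or QuickscoreEngine(network, evidence.risk_evidence)
    return engine.evidence_likelihood(evidence)


def posterior_disease(
    network: NoisyOrNetwork,
    evidence: Evidence,
    disease_id: str,
    engine: Optional[QuickscoreEngine] = None,
) -> float:
    """Exact posterior ``P(D = 1 | S±, R)``; equals the prior marginal under
    empty evidence.  Raises :class:`ZeroEvidenceError` on null evidence."""
    if disease_id not in network.disease_cpts:
        raise ValueError(f"unknown disease {disease_id!r}")
    engine = engine or QuickscoreEngine(network, evidence.risk_evidence)
    denom = engine.evidence_likelihood(evidence)
    if denom <= 0.0:
        raise ZeroEvidenceError()
    return engine.disease_joint(evidence, disease_id) / denom


def negated_subset_likelihood(
    network: NoisyOrNetwork,
    evidence: Evidence,
    disease_id: str,
    Z: Iterable[str],
    engine: Optional[QuickscoreEngine] = None,
) -> float:
    """Exact ``P(S₋ = 0, Z = 0, D_k = 1 | R)`` for ``Z ⊆ S₊``.

    These are the joints the counterfactual closed form sums by
    inclusion–exclusion; the value is monotone non-increasing in Z.
    """
    Zset = frozenset(Z)
    if not Zset <= evidence.positive_symptoms:
        raise ValueError(
            f"Z must be a subset of the positive symptoms; offending ids: "
            f"{sorted(Zset - evidence.positive_symptoms)}"
        )
    if disease_id not in network.disease_cpts:
        raise ValueError(f"unknown disease {disease_id!r}")
    evidence.validate_against(network)
    engine = engine or QuickscoreEngine(network, evidence.risk_evidence)
    return engine.off_probability(Zset | evidence.negative_symptoms, disease_id)


def posterior_ranking(network: NoisyOrNetwork, evidence: Evidence):
    """All diseases ranked by exact posterior (associative diagnosis)."""
    from .ranking import rank_diseases

    return rank_diseases(network, evidence, "posterior")
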