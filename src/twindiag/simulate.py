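"""Synthetic noisy-OR networks and clinical vignettes.

The generator emulates the generative structure the evaluation assumes: a
layered risk → disease → symptom DAG, noisy-OR activation with independent
edge failures and leaks, and vignettes produced by forward-sampling the SCM
with the true disease forced on, then revealing only part of the sampled
world (vignettes are non-exhaustive lists of evidence).

Defaults are one fixed set of desk-scale "realistic" conditions: moderate
layer sizes, sparse bipartite edges, rare-ish disease leaks, and partial
evidence reveal; see docs/methods.md for the rationale.  Everything is
seed-reproducible: a master seed drives per-vignette derived seeds, and
cohort files are written in a canonical byte-stable JSON form.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ModelSchemaError
from .inference import Evidence
from .model import (
    ExogenousState,
    Intervention,
    NodeRef,
    NoisyOrCPT,
    NoisyOrNetwork,
    structural_eval,
    validate,
)

REJECTION_CAP = 10_000

__all__ = [
    "GeneratorConfig",
    "Vignette",
    "generate_network",
    "generate_vignette",
    "generate_cohort",
    "read_vignettes",
    "write_vignettes",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic networks and vignettes.

    Probabilities/densities are in [0,1]; parameter ranges are sampled
    uniformly.  ``reveal_*`` control how much of the sampled world makes it
    into the vignette evidence; unrevealed symptoms become *unobserved*,
    never negative.  ``k_mean`` is the mean differential size (k is drawn as
    1 + Poisson(k_mean − 1)).
    """

    n_risk: int = 5
    n_disease: int = 10
    n_symptom: int = 15
    risk_disease_density: float = 0.35
    disease_symptom_density: float = 0.3
    lambda_range: Tuple[float, float] = (0.2, 0.9)
    disease_leak_range: Tuple[float, float] = (0.9, 0.995)
    symptom_leak_range: Tuple[float, float] = (0.9, 0.995)
    risk_prior_range: Tuple[float, float] = (0.05, 0.5)
    reveal_positive_symptom: float = 0.8
    reveal_negative_symptom: float = 0.2
    reveal_risk: float = 0.8
    k_mean: float = 2.58
    true_disease_weighting: str = "uniform"  # or "prior"
    seed: int = 0

    def check(self) -> None:
        for name in (
            "risk_disease_density",
            "disease_symptom_density",
            "reveal_positive_symptom",
            "reveal_negative_symptom",
            "reveal_risk",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in (
            "lambda_range",
            "disease_leak_range",
            "symptom_leak_range",
            "risk_prior_range",
        ):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an ordered range within [0,1]")
        if min(self.n_risk, 0) < 0 or self.n_disease < 1 or self.n_symptom < 0:
            raise ValueError("layer counts must be non-negative (>=1 disease)")
        if self.k_mean < 1.0:
            raise ValueError("k_mean must be >= 1")
        if self.true_disease_weighting not in ("uniform", "prior"):
            raise ValueError("true_disease_weighting must be 'uniform' or 'prior'")


@dataclass(frozen=True)
class Vignette:
    """A simulated case: masked true disease plus partial evidence."""

    id: str
    true_disease: str
    evidence: Evidence
    k: Optional[int] = None
    provenance: Dict[str, object] = field(default_factory=dict)


def _ids(prefix: str, n: int) -> List[str]:
    return [f"{prefix}{i:03d}" for i in range(1, n + 1)]


def generate_network(config: GeneratorConfig) -> NoisyOrNetwork:
    """Random layered noisy-OR network honouring the configured densities.

    Every symptom receives at least one disease parent (a topping-up draw
    when the density puts none); diseases may be leak-only.  Identical
    configs (including seed) give identical networks.
    """
    config.check()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x6E65)))
    risks = _ids("R", config.n_risk)
    diseases = _ids("D", config.n_disease)
    symptoms = _ids("S", config.n_symptom)
    if config.n_symptom > 0 and config.n_disease == 0:
        raise ValueError("symptoms need at least one disease to parent them")

    nodes = (
        [NodeRef(r, "risk") for r in risks]
        + [NodeRef(d, "disease") for d in diseases]
        + [NodeRef(s, "symptom") for s in symptoms]
    )
    lo, hi = config.risk_prior_range
    priors = {r: float(rng.uniform(lo, hi)) for r in risks}

    def lam() -> float:
        return float(rng.uniform(*config.lambda_range))

    disease_cpts = {}
    for d in diseases:
        parents = [r for r in risks if rng.random() < config.risk_disease_density]
        disease_cpts[d] = NoisyOrCPT(
            d,
            {r: lam() for r in parents},
            float(rng.uniform(*config.disease_leak_range)),
        )
    symptom_cpts = {}
    for s in symptoms:
        parents = [d for d in diseases if rng.random() < config.disease_symptom_density]
        if not parents:
            parents = [diseases[int(rng.integers(len(diseases)))]]
        symptom_cpts[s] = NoisyOrCPT(
            s,
            {d: lam() for d in parents},
            float(rng.uniform(*config.symptom_leak_range)),
        )
    network = NoisyOrNetwork(nodes, priors, disease_cpts, symptom_cpts)
    violations = validate(network)
    if violations:  # pragma: no cover - construction honours the invariants
        raise RuntimeError("generator produced invalid network: " + "; ".join(violations))
    return network


def _draw_noise(network: NoisyOrNetwork, rng: np.random.Generator) -> ExogenousState:
    risk_draws = {r: int(rng.random() < network.risk_priors[r]) for r in network.risks}
    edge_noise, leak_noise = {}, {}
    for cpts in (network.disease_cpts, network.symptom_cpts):
        for child in sorted(cpts):
            cpt = cpts[child]
            leak_noise[child] = int(rng.random() < cpt.leak_failure)
            for parent in sorted(cpt.parent_failures):
                edge_noise[(parent, child)] = int(rng.random() < cpt.parent_failures[parent])
    return ExogenousState(risk_draws, edge_noise, leak_noise)


def _marginal_disease_priors(network: NoisyOrNetwork) -> Dict[str, float]:
    from .inference import QuickscoreEngine

    engine = QuickscoreEngine(network, {})
    return {
        d: engine.off_probability(frozenset(), on_disease=d) for d in network.diseases
    }


def generate_vignette(
    network: NoisyOrNetwork, config: GeneratorConfig, seed: int
) -> Vignette:
    """Simulate one patient presentation of a (known) true disease.

    The true disease is forced on (do-style) and the world is re-sampled
    until at least one of its child symptoms comes out positive — a disease
    with no symptom children cannot present and is excluded from the draw.
    Evidence is then revealed per the configured probabilities; if the
    reveal hides every positive symptom, one positive child of the true
    disease is force-revealed so that the vignette has a complaint.
    """
    config.check()
    if not network.diseases:
        raise ValueError("network has no diseases")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7669, seed)))
    candidates = [d for d in network.diseases if network.symptom_children(d)]
    if not candidates:
        raise ValueError(
            "no disease has symptom children; increase disease_symptom_density"
        )
    if config.true_disease_weighting == "prior":
        priors = _marginal_disease_priors(network)
        w = np.array([priors[d] for d in candidates])
        if w.sum() <= 0:
            raise ValueError("all candidate diseases have prior zero")
        true_disease = candidates[int(rng.choice(len(candidates), p=w / w.sum()))]
    else:
        true_disease = candidates[int(rng.integers(len(candidates)))]

    children = set(network.symptom_children(true_disease))
    force = Intervention(targets={true_disease: 1})
    for attempt in range(REJECTION_CAP):
        noise = _draw_noise(network, rng)
        world = structural_eval(network, noise, force)
        positive_children = [s for s in children if world[s] == 1]
        if positive_children:
            break
    else:
        raise RuntimeError(
            f"no positive child symptom for {true_disease} after {REJECTION_CAP} "
            "draws; loosen lambda/leak ranges or densities"
        )

    risk_evidence = {
        r: world[r] for r in network.risks if rng.random() < config.reveal_risk
    }
    positive, negative = set(), set()
    for s in network.symptoms:
        if world[s] == 1:
            if rng.random() < config.reveal_positive_symptom:
                positive.add(s)
        elif rng.random() < config.reveal_negative_symptom:
            negative.add(s)
    if not positive:
        positive.add(positive_children[int(rng.integers(len(positive_children)))])
    k = 1 + int(rng.poisson(config.k_mean - 1.0))
    return Vignette(
        id=f"v{seed:06d}",
        true_disease=true_disease,
        evidence=Evidence(risk_evidence, frozenset(positive), frozenset(negative)),
        k=k,
        provenance={
            "master_seed": config.seed,
            "vignette_seed": seed,
            "rejections": attempt,
        },
    )


def generate_cohort(
    network: NoisyOrNetwork,
    config: GeneratorConfig,
    n: int,
    path: Optional[Union[str, Path]] = None,
) -> List[Vignette]:
    """n vignettes with per-vignette derived seeds (master seed, index).

    Reproducible: the same master seed yields a byte-identical cohort file.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    out = []
    for i in range(n):
        try:
            out.append(generate_vignette(network, config, seed=i))
        except Exception as exc:
            raise RuntimeError(f"vignette {i} failed: {exc}") from exc
    if path is not None:
        write_vignettes(path, out)
    return out


# ---------------------------------------------------------------------------
# vignette JSON:
#   {"id","true_disease","risk_evidence":{id:bool},
#    "symptoms":{"positive":[ids],"negative":[ids]},"k":int?,"provenance":{}}


def vignette_to_dict(v: Vignette) -> dict:
    d = {
        "id": v.id,
        "true_disease": v.true_disease,
        "risk_evidence": {
            r: bool(val) for r, val in sorted(v.evidence.risk_evidence.items())
        },
        "symptoms": {
            "positive": sorted(v.evidence.positive_symptoms),
            "negative": sorted(v.evidence.negative_symptoms),
        },
        "provenance": v.provenance,
    }
    if v.k is not None:
        d["k"] = int(v.k)
    return d


_VIGNETTE_KEYS = {"id", "true_disease", "risk_evidence", "symptoms", "k", "provenance"}


def vignette_from_dict(data: dict, where: str = "$") -> Vignette:
    if not isinstance(data, dict):
        raise ModelSchemaError(where, "vignette must be a JSON object")
    extra = set(data) - _VIGNETTE_KEYS
    if extra:
        raise ModelSchemaError(where, f"unknown fields {sorted(extra)}")
    for key in ("id", "true_disease", "symptoms"):
        if key not in data:
            raise ModelSchemaError(where, f"missing required field {key!r}")
    sym = data["symptoms"]
    if not isinstance(sym, dict) or set(sym) - {"positive", "negative"}:
        raise ModelSchemaError(
            f"{where}.symptoms", 'must be {"positive": [...], "negative": [...]}'
        )
    pos = frozenset(sym.get("positive", []))
    neg = frozenset(sym.get("negative", []))
    if pos & neg:
        raise ModelSchemaError(
            f"{where}.symptoms", f"ids both positive and negative: {sorted(pos & neg)}"
        )
    if not pos:
        raise ModelSchemaError(f"{where}.symptoms.positive", "must be non-empty")
    risk_ev = {
        r: int(bool(val)) for r, val in dict(data.get("risk_evidence", {})).items()
    }
    k = data.get("k")
    if k is not None and (not isinstance(k, int) or k < 1):
        raise ModelSchemaError(f"{where}.k", "must be a positive integer")
    return Vignette(
        id=str(data["id"]),
        true_disease=str(data["true_disease"]),
        evidence=Evidence(risk_ev, pos, neg),
        k=k,
        provenance=dict(data.get("provenance", {})),
    )


def write_vignettes(path: Union[str, Path], vignettes: Sequence[Vignette]) -> None:
    payload = [vignette_to_dict(v) for v in vignettes]
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_vignettes(path: Union[str, Path]) -> List[Vignette]:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelSchemaError("$", f"invalid JSON: {exc}") from exc
    if isinstance(data, dict):
        data = [data]
    if not isinstance(data, list):
        raise ModelSchemaError("$", "cohort file must be a JSON array of vignettes")
    return [vignette_from_dict(v, where=f"$[{i}]") for i, v in enumerate(data)]
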