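"""Three-layer noisy-OR diagnostic networks as structural causal models.

The networks modelled here have three layers of binary nodes: risk factors
(medical history, demographics), diseases, and symptoms.  Edges run only
risk → disease and disease → symptom.  Every disease and symptom follows a
noisy-OR mechanism: each parent that is "on" independently attempts to
activate the child, the attempt failing with an edge-specific probability
``λ``; in addition an always-on *leak* parent captures unmodelled causes and
fails with probability ``λ₀``.  Writing ``u = 1`` for a failed activation,
the structural equation for a child ``Y`` with parents ``X₁…Xₙ`` is::

    Y = OR_i (Xᵢ AND NOT uᵢ)  OR  (NOT u₀),    P(uᵢ=1) = λᵢ,  P(u₀=1) = λ₀

which makes the network a structural causal model: once every exogenous term
``u`` is fixed, every node is a deterministic function of its parents, and
interventions simply replace mechanisms.  A disease with no risk-factor
parents is parameterised purely by its leak, with prior ``1 − λ₀``.

This module provides the data types, validation, deterministic structural
evaluation, exact joint probabilities, forward sampling and JSON
(de)serialisation.  Inference and counterfactual queries live in
:mod:`twindiag.inference` and :mod:`twindiag.counterfactual`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import networkx as nx
import numpy as np

from .errors import IncompleteNoiseError, ModelSchemaError

LAYERS = ("risk", "disease", "symptom")

__all__ = [
    "LAYERS",
    "NodeRef",
    "NoisyOrCPT",
    "NoisyOrNetwork",
    "ExogenousState",
    "Assignment",
    "Intervention",
    "validate",
    "structural_eval",
    "joint_probability",
    "forward_sample",
    "read_model",
    "write_model",
]


@dataclass(frozen=True)
class NodeRef:
    """A node in the network: unique ``id``, layer, optional display label."""

    id: str
    layer: str
    label: Optional[str] = None


@dataclass(frozen=True)
class NoisyOrCPT:
    """Noisy-OR mechanism for one child node.

    ``parent_failures`` maps each parent id to the probability λ that the
    parent's activation attempt fails; ``leak_failure`` is λ₀, the failure
    probability of the always-on leak parent.  ``1 − λ₀`` is the child's
    activation probability when every modelled parent is off.
    """

    child: str
    parent_failures: Mapping[str, float]
    leak_failure: float

    def __post_init__(self):
        object.__setattr__(self, "parent_failures", dict(self.parent_failures))


@dataclass
class NoisyOrNetwork:
    """A three-layer noisy-OR diagnostic network.

    Attributes
    ----------
    nodes : list of NodeRef
        All nodes; ids must be unique.
    risk_priors : mapping risk-id -> probability
        Marginal prior of each risk factor (risk nodes have no parents).
    disease_cpts : mapping disease-id -> NoisyOrCPT
        Noisy-OR mechanisms of diseases; parents are risk factors.
    symptom_cpts : mapping symptom-id -> NoisyOrCPT
        Noisy-OR mechanisms of symptoms; parents are diseases.
    """

    nodes: List[NodeRef]
    risk_priors: Dict[str, float] = field(default_factory=dict)
    disease_cpts: Dict[str, NoisyOrCPT] = field(default_factory=dict)
    symptom_cpts: Dict[str, NoisyOrCPT] = field(default_factory=dict)

    # -- structural helpers -------------------------------------------------

    def node_ids(self) -> List[str]:
        return [n.id for n in self.nodes]

    def layer_of(self, node_id: str) -> str:
        for n in self.nodes:
            if n.id == node_id:
                return n.layer
        raise KeyError(node_id)

    @property
    def risks(self) -> List[str]:
        return sorted(n.id for n in self.nodes if n.layer == "risk")

    @property
    def diseases(self) -> List[str]:
        return sorted(n.id for n in self.nodes if n.layer == "disease")

    @property
    def symptoms(self) -> List[str]:
        return sorted(n.id for n in self.nodes if n.layer == "symptom")

    def cpt(self, child: str) -> NoisyOrCPT:
        if child in self.disease_cpts:
            return self.disease_cpts[child]
        if child in self.symptom_cpts:
            return self.symptom_cpts[child]
        raise KeyError(child)

    def parents_of(self, node_id: str) -> List[str]:
        layer = self.layer_of(node_id)
        if layer == "risk":
            return []
        return sorted(self.cpt(node_id).parent_failures)

    def symptom_children(self, disease_id: str) -> List[str]:
        """Symptoms that have ``disease_id`` among their noisy-OR parents."""
        return sorted(
            s for s, cpt in self.symptom_cpts.items()
            if disease_id in cpt.parent_failures
        )

    def edges(self) -> List[Tuple[str, str]]:
        out = []
        for cpts in (self.disease_cpts, self.symptom_cpts):
            for child, cpt in sorted(cpts.items()):
                out.extend((p, child) for p in sorted(cpt.parent_failures))
        return out

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids())
        g.add_edges_from(self.edges())
        return g


@dataclass(frozen=True)
class ExogenousState:
    """One complete assignment of the SCM's exogenous noise terms.

    ``risk_draws`` gives the latent Bernoulli draw of every risk factor,
    ``edge_noise[(parent, child)] = 1`` means that activation fails, and
    ``leak_noise[child] = 1`` means the leak fails to activate the child.
    """

    risk_draws: Mapping[str, int]
    edge_noise: Mapping[Tuple[str, str], int]
    leak_noise: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "risk_draws", dict(self.risk_draws))
        object.__setattr__(self, "edge_noise", dict(self.edge_noise))
        object.__setattr__(self, "leak_noise", dict(self.leak_noise))


@dataclass(frozen=True)
class Assignment:
    """A (total) 0/1 assignment of endogenous nodes."""

    values: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, node_id: str) -> int:
        return self.values[node_id]


@dataclass(frozen=True)
class Intervention:
    """A do-intervention: forced node values plus leaks switched off.

    ``targets`` maps node ids to forced 0/1 values (their incoming mechanism
    is severed).  ``leak_off`` lists child ids whose always-on leak parent is
    forced off — needed to express "switch off all exogenous influences" in
    the sufficient-cause intervention.
    """

    targets: Mapping[str, int] = field(default_factory=dict)
    leak_off: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "targets", dict(self.targets))
        object.__setattr__(self, "leak_off", frozenset(self.leak_off))

    @classmethod
    def none(cls) -> "Intervention":
        return cls()

    def is_empty(self) -> bool:
        return not self.targets and not self.leak_off


# ---------------------------------------------------------------------------
# validation


def _prob_ok(p) -> bool:
    return isinstance(p, (int, float)) and not isinstance(p, bool) and 0.0 <= p <= 1.0


def validate(network: NoisyOrNetwork) -> List[str]:
    """Check all structural invariants; return a list of violations.

    Returns an empty list iff the network is well formed.  Never raises on
    content: every problem is reported as a human-readable string naming the
    offending node or edge and the rule violated.
    """
    v: List[str] = []
    seen = set()
    layer = {}
    for n in network.nodes:
        if n.id in seen:
            v.append(f"node {n.id}: duplicate id")
        seen.add(n.id)
        if n.layer not in LAYERS:
            v.append(f"node {n.id}: unknown layer {n.layer!r}")
        layer[n.id] = n.layer

    for rid, p in network.risk_priors.items():
        if rid not in layer:
            v.append(f"risk prior {rid}: unknown node")
        elif layer[rid] != "risk":
            v.append(f"risk prior {rid}: node is not in the risk layer")
        if not _prob_ok(p):
            v.append(f"risk prior {rid}: probability-range violation ({p!r})")
    for n in network.nodes:
        if n.layer == "risk" and n.id not in network.risk_priors:
            v.append(f"node {n.id}: risk node missing prior")

    for cpts, child_layer, parent_layer in (
        (network.disease_cpts, "disease", "risk"),
        (network.symptom_cpts, "symptom", "disease"),
    ):
        for child, cpt in cpts.items():
            where = f"cpt {child}"
            if cpt.child != child:
                v.append(f"{where}: cpt child field {cpt.child!r} mismatches key")
            if child not in layer:
                v.append(f"{where}: unknown node")
                continue
            if layer[child] != child_layer:
                v.append(f"{where}: node is not in the {child_layer} layer")
            if not _prob_ok(cpt.leak_failure):
                v.append(
                    f"{where}: leak_failure probability-range violation "
                    f"({cpt.leak_failure!r})"
                )
            for pid, lam in cpt.parent_failures.items():
                if pid not in layer:
                    v.append(f"edge {pid}->{child}: unknown parent")
                elif layer[pid] != parent_layer:
                    v.append(
                        f"edge {pid}->{child}: layer-order violation "
                        f"(parent of a {child_layer} must be a {parent_layer})"
                    )
                if not _prob_ok(lam):
                    v.append(
                        f"edge {pid}->{child}: probability-range violation ({lam!r})"
                    )
        for n in network.nodes:
            if n.layer == child_layer and n.id not in cpts:
                v.append(f"node {n.id}: {child_layer} node missing CPT")

    # layers already enforce acyclicity when the layer rules hold; this guard
    # catches malformed inputs where layer checks were themselves violated
    try:
        if not nx.is_directed_acyclic_graph(network.graph()):
            v.append("graph: contains a directed cycle")
    except Exception:  # pragma: no cover - graph construction on broken input
        v.append("graph: could not be constructed")
    return v


# ---------------------------------------------------------------------------
# structural evaluation


def _check_noise_complete(network: NoisyOrNetwork, noise: ExogenousState) -> None:
    missing = []
    for r in network.risks:
        if r not in noise.risk_draws:
            missing.append(f"risk_draws[{r}]")
    for child, cpt in list(network.disease_cpts.items()) + list(
        network.symptom_cpts.items()
    ):
        if child not in noise.leak_noise:
            missing.append(f"leak_noise[{child}]")
        for p in cpt.parent_failures:
            if (p, child) not in noise.edge_noise:
                missing.append(f"edge_noise[({p}, {child})]")
    if missing:
        raise IncompleteNoiseError(sorted(missing))


def structural_eval(
    network: NoisyOrNetwork,
    noise: ExogenousState,
    intervention: Optional[Intervention] = None,
) -> Assignment:
    """Deterministically evaluate the SCM for one exogenous state.

    Risk nodes take their latent draws; every child is the noisy-OR of its
    parents' surviving activations plus the leak.  Intervened nodes take
    their forced values and their incoming mechanism is ignored; children in
    ``intervention.leak_off`` lose the leak term.
    """
    intervention = intervention or Intervention.none()
    _check_noise_complete(network, noise)
    values: Dict[str, int] = {}

    for r in network.risks:
        values[r] = (
            intervention.targets[r]
            if r in intervention.targets
            else int(noise.risk_draws[r])
        )

    for layer_cpts in (network.disease_cpts, network.symptom_cpts):
        for child in sorted(layer_cpts):
            if child in intervention.targets:
                values[child] = int(intervention.targets[child])
                continue
            cpt = layer_cpts[child]
            on = 0
            if child not in intervention.leak_off and noise.leak_noise[child] == 0:
                on = 1
            else:
                for p in cpt.parent_failures:
                    if values[p] == 1 and noise.edge_noise[(p, child)] == 0:
                        on = 1
                        break
            values[child] = on
    return Assignment(values)


def joint_probability(network: NoisyOrNetwork, assignment: Assignment) -> float:
    """Exact probability of a *total* assignment under the network.

    Factorises over nodes: priors for risks and, for each child, the
    noisy-OR conditional ``P(child=0 | parents) = λ₀ · Π_{parents on} λ``.
    """
    vals = assignment.values
    missing = [n for n in network.node_ids() if n not in vals]
    if missing:
        raise ValueError(f"partial assignment; missing nodes: {sorted(missing)}")
    p = 1.0
    for r in network.risks:
        prior = network.risk_priors[r]
        p *= prior if vals[r] == 1 else 1.0 - prior
    for layer_cpts in (network.disease_cpts, network.symptom_cpts):
        for child in sorted(layer_cpts):
            cpt = layer_cpts[child]
            off = cpt.leak_failure
            for parent, lam in cpt.parent_failures.items():
                if vals[parent] == 1:
                    off *= lam
            p *= (1.0 - off) if vals[child] == 1 else off
    return p


def forward_sample(
    network: NoisyOrNetwork, seed: Union[int, np.random.Generator]
) -> Tuple[ExogenousState, Assignment]:
    """Draw one exogenous state and its induced assignment.

    Noise entries are drawn independently (risk priors; edge λ; leak λ₀) in
    sorted node/edge id order from a single generator, so a fixed seed gives
    an identical sample on any platform.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    risk_draws = {
        r: int(rng.random() < network.risk_priors[r]) for r in network.risks
    }
    edge_noise: Dict[Tuple[str, str], int] = {}
    leak_noise: Dict[str, int] = {}
    for layer_cpts in (network.disease_cpts, network.symptom_cpts):
        for child in sorted(layer_cpts):
            cpt = layer_cpts[child]
            leak_noise[child] = int(rng.random() < cpt.leak_failure)
            for parent in sorted(cpt.parent_failures):
                edge_noise[(parent, child)] = int(
                    rng.random() < cpt.parent_failures[parent]
                )
    noise = ExogenousState(risk_draws, edge_noise, leak_noise)
    return noise, structural_eval(network, noise)


# ---------------------------------------------------------------------------
# JSON (de)serialisation
#
# Schema (strict):
#   {"nodes":   [{"id": str, "layer": str, "label"?: str}, ...],
#    "risk_priors": {id: prob, ...},
#    "cpts":    [{"child": str, "parents": {id: lambda, ...},
#                 "leak_failure": prob}, ...]}

_NODE_KEYS = {"id", "layer", "label"}
_CPT_KEYS = {"child", "parents", "leak_failure"}
_TOP_KEYS = {"nodes", "risk_priors", "cpts"}


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ModelSchemaError(path, msg)


def _check_unknown(obj: dict, allowed: set, path: str, strict: bool) -> None:
    extra = set(obj) - allowed
    if extra:
        msg = f"unknown fields {sorted(extra)}"
        if strict:
            raise ModelSchemaError(path, msg)
        warnings.warn(f"{path}: {msg}", stacklevel=3)


def network_to_dict(network: NoisyOrNetwork) -> dict:
    nodes = []
    for n in network.nodes:
        d = {"id": n.id, "layer": n.layer}
        if n.label is not None:
            d["label"] = n.label
        nodes.append(d)
    cpts = []
    for layer_cpts in (network.disease_cpts, network.symptom_cpts):
        for child in sorted(layer_cpts):
            cpt = layer_cpts[child]
            cpts.append(
                {
                    "child": child,
                    "parents": {p: cpt.parent_failures[p] for p in sorted(cpt.parent_failures)},
                    "leak_failure": cpt.leak_failure,
                }
            )
    return {
        "nodes": nodes,
        "risk_priors": {r: network.risk_priors[r] for r in sorted(network.risk_priors)},
        "cpts": cpts,
    }


def network_from_dict(data: dict, strict: bool = True) -> NoisyOrNetwork:
    _require(isinstance(data, dict), "$", "model document must be a JSON object")
    _check_unknown(data, _TOP_KEYS, "$", strict)
    for key in ("nodes", "risk_priors", "cpts"):
        _require(key in data, "$", f"missing required field {key!r}")
    _require(isinstance(data["nodes"], list), "$.nodes", "must be an array")
    _require(isinstance(data["risk_priors"], dict), "$.risk_priors", "must be an object")
    _require(isinstance(data["cpts"], list), "$.cpts", "must be an array")

    nodes: List[NodeRef] = []
    seen = set()
    for i, nd in enumerate(data["nodes"]):
        path = f"$.nodes[{i}]"
        _require(isinstance(nd, dict), path, "must be an object")
        _check_unknown(nd, _NODE_KEYS, path, strict)
        for key in ("id", "layer"):
            _require(key in nd, path, f"missing required field {key!r}")
            _require(isinstance(nd[key], str), f"{path}.{key}", "must be a string")
        _require(nd["id"] not in seen, f"{path}.id", f"duplicate node id {nd['id']!r}")
        _require(
            nd["layer"] in LAYERS, f"{path}.layer", f"must be one of {list(LAYERS)}"
        )
        seen.add(nd["id"])
        nodes.append(NodeRef(nd["id"], nd["layer"], nd.get("label")))
    layer = {n.id: n.layer for n in nodes}

    priors: Dict[str, float] = {}
    for rid, p in data["risk_priors"].items():
        path = f"$.risk_priors.{rid}"
        _require(rid in layer, path, "unknown node id")
        _require(_prob_ok(p), path, "must be a probability in [0,1]")
        priors[rid] = float(p)

    disease_cpts: Dict[str, NoisyOrCPT] = {}
    symptom_cpts: Dict[str, NoisyOrCPT] = {}
    for i, cd in enumerate(data["cpts"]):
        path = f"$.cpts[{i}]"
        _require(isinstance(cd, dict), path, "must be an object")
        _check_unknown(cd, _CPT_KEYS, path, strict)
        for key in ("child", "parents", "leak_failure"):
            _require(key in cd, path, f"missing required field {key!r}")
        child = cd["child"]
        _require(isinstance(child, str), f"{path}.child", "must be a string")
        _require(child in layer, f"{path}.child", f"unknown node id {child!r}")
        _require(isinstance(cd["parents"], dict), f"{path}.parents", "must be an object")
        _require(
            _prob_ok(cd["leak_failure"]),
            f"{path}.leak_failure",
            "must be a probability in [0,1]",
        )
        parents: Dict[str, float] = {}
        for pid, lam in cd["parents"].items():
            ppath = f"{path}.parents.{pid}"
            _require(pid in layer, ppath, "unknown node id")
            _require(_prob_ok(lam), ppath, "must be a probability in [0,1]")
            parents[pid] = float(lam)
        cpt = NoisyOrCPT(child, parents, float(cd["leak_failure"]))
        target = disease_cpts if layer.get(child) == "disease" else symptom_cpts
        _require(child not in target, f"{path}.child", f"duplicate CPT for {child!r}")
        target[child] = cpt

    network = NoisyOrNetwork(nodes, priors, disease_cpts, symptom_cpts)
    violations = validate(network)
    if violations:
        raise ModelSchemaError("$", "; ".join(violations))
    return network


def write_model(path: Union[str, Path], network: NoisyOrNetwork) -> None:
    """Serialise a validated network to canonical JSON (UTF-8, sorted keys)."""
    violations = validate(network)
    if violations:
        raise ValueError("refusing to write invalid network: " + "; ".join(violations))
    Path(path).write_text(
        json.dumps(network_to_dict(network), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_model(path: Union[str, Path], strict: bool = True) -> NoisyOrNetwork:
    """Load a network from JSON, raising :class:`ModelSchemaError` with the
    offending JSON path on any schema violation."""
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelSchemaError("$", f"invalid JSON: {exc}") from exc
    return network_from_dict(data, strict=strict)
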