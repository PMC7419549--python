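"""Disease rankings and cohort-level evaluation statistics.

A diagnosis is delivered as a full ranking of all modelled diseases under
one of three measures: the associative ``posterior`` or the counterfactual
``expected_disablement`` / ``expected_sufficiency``.  Rankings are
deterministic: ties are broken by higher posterior, then lexicographic
disease id.  Rank positions are 1-based.  For mean-rank summaries tied
scores share the better (minimum) position; the orderings delivered to
top-k accuracy use the deterministic tie-break.

Cohort evaluation reproduces the standard protocol: top-k accuracy curves,
relative error reduction ``1 − e_c/e_a``, mean position of the true
disease, win/draw/loss counts between measures, stratification by disease
rarity (the true disease's prior given the risk evidence), and per-vignette
matched differential sizes k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .counterfactual import expected_disablement, expected_sufficiency
from .errors import ZeroEvidenceError
from .inference import Evidence, QuickscoreEngine
from .model import NoisyOrNetwork

logger = logging.getLogger(__name__)

MEASURES = ("posterior", "expected_disablement", "expected_sufficiency")

#: Non-canonical rarity band edges on P(D=1 | R); configurable everywhere.
DEFAULT_BAND_EDGES = (1e-4, 1e-3, 1e-2, 5e-2, 2e-1)

__all__ = [
    "MEASURES",
    "DEFAULT_BAND_EDGES",
    "DiagnosisRanking",
    "CohortResult",
    "rank_diseases",
    "evaluate_cohort",
    "top_k_accuracy",
    "error_reduction",
    "rank_comparison",
    "stratify_by_rarity",
    "matched_differential_evaluation",
]


@dataclass(frozen=True)
class DiagnosisRanking:
    """Ordered (disease, score) pairs under one measure; scores non-increasing."""

    measure_name: str
    entries: Tuple[Tuple[str, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple((d, float(s)) for d, s in self.entries))

    def position(self, disease_id: str) -> int:
        """1-based position in the delivered (deterministic) ordering."""
        for i, (d, _) in enumerate(self.entries):
            if d == disease_id:
                return i + 1
        raise KeyError(disease_id)

    def tie_aware_position(self, disease_id: str) -> int:
        """1-based position where tied scores share the minimum position."""
        score = dict(self.entries)[disease_id]
        return 1 + sum(1 for _, s in self.entries if s > score)

    def score(self, disease_id: str) -> float:
        return dict(self.entries)[disease_id]

    def top(self, k: int) -> Tuple[str, ...]:
        return tuple(d for d, _ in self.entries[:k])


def rank_diseases(
    network: NoisyOrNetwork,
    evidence: Evidence,
    measure: str,
    engine: Optional[QuickscoreEngine] = None,
) -> DiagnosisRanking:
    """Full ranking of all modelled diseases under ``measure``.

    Deterministic: sorted by score descending, ties broken by higher
    posterior then lexicographic id.  Raises :class:`ZeroEvidenceError`
    when the evidence has probability zero.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    engine = engine or QuickscoreEngine(network, evidence.risk_evidence)
    denom = engine.evidence_likelihood(evidence)
    if denom <= 0.0:
        raise ZeroEvidenceError()
    posteriors = {
        d: engine.disease_joint(evidence, d) / denom for d in network.diseases
    }
    if measure == "posterior":
        scores = posteriors
    elif measure == "expected_disablement":
        scores = {
            d: expected_disablement(network, evidence, d, engine=engine)
            for d in network.diseases
        }
    else:
        scores = {
            d: expected_sufficiency(network, evidence, d, engine=engine)
            for d in network.diseases
        }
    order = sorted(network.diseases, key=lambda d: (-scores[d], -posteriors[d], d))
    return DiagnosisRanking(measure, tuple((d, scores[d]) for d in order))


@dataclass
class CohortResult:
    """Per-vignette ranks plus everything the summaries are computed from.

    ``table`` has one row per successfully evaluated vignette with columns
    ``vignette_id, true_disease, k, band, prior`` and per measure
    ``rank_<m>`` (deterministic order position) and ``tiepos_<m>``
    (tie-aware position used for mean ranks and win counts).
    """

    table: pd.DataFrame
    measures: Tuple[str, ...]
    n_diseases: int
    band_edges: Tuple[float, ...]
    failures: List[Tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def ranks(self, measure: str, tie_aware: bool = False) -> np.ndarray:
        col = ("tiepos_" if tie_aware else "rank_") + measure
        if col not in self.table.columns:
            raise ValueError(f"measure {measure!r} was not computed on this cohort")
        return self.table[col].to_numpy()

    def subset(self, mask) -> "CohortResult":
        return CohortResult(
            self.table[mask].reset_index(drop=True),
            self.measures,
            self.n_diseases,
            self.band_edges,
        )


def _band_label(edges: Sequence[float], value: float) -> int:
    """Index of the half-open band ``(e_{i-1}, e_i]`` that ``value`` falls in."""
    return int(np.searchsorted(np.asarray(edges), value, side="left"))


def evaluate_cohort(
    network: NoisyOrNetwork,
    vignettes: Iterable,
    measures: Sequence[str] = MEASURES,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
) -> CohortResult:
    """Rank every vignette under every measure and collect rank positions.

    Vignettes whose evidence has probability zero under the model are
    recorded in ``failures`` (id, reason) and excluded from the table; the
    evaluation continues.
    """
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}")
    edges = tuple(band_edges)
    if any(not 0.0 < e < 1.0 for e in edges) or list(edges) != sorted(set(edges)):
        raise ValueError("band edges must be strictly increasing within (0,1)")
    rows = []
    failures: List[Tuple[str, str]] = []
    for v in vignettes:
        engine = QuickscoreEngine(network, v.evidence.risk_evidence)
        try:
            row: Dict[str, object] = {
                "vignette_id": v.id,
                "true_disease": v.true_disease,
                "k": v.k if v.k is not None else np.nan,
            }
            prior = engine.disease_joint(
                Evidence(risk_evidence=v.evidence.risk_evidence), v.true_disease
            )
            row["prior"] = prior
            row["band"] = _band_label(edges, prior)
            for m in measures:
                ranking = rank_diseases(network, v.evidence, m, engine=engine)
                row[f"rank_{m}"] = ranking.position(v.true_disease)
                row[f"tiepos_{m}"] = ranking.tie_aware_position(v.true_disease)
            rows.append(row)
        except ZeroEvidenceError as exc:
            logger.warning("vignette %s skipped: %s", v.id, exc)
            failures.append((v.id, str(exc)))
    table = pd.DataFrame(rows)
    return CohortResult(table, tuple(measures), len(network.diseases), edges, failures)


def top_k_accuracy(ranks: Union[CohortResult, Sequence[int], np.ndarray], k: int, measure: Optional[str] = None) -> float:
    """Fraction of vignettes whose true disease sits within the top k."""
    if isinstance(ranks, CohortResult):
        if measure is None:
            raise ValueError("measure required when passing a CohortResult")
        arr = ranks.ranks(measure)
    else:
        arr = np.asarray(list(ranks))
    if arr.size == 0:
        raise ValueError("empty cohort")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.mean(arr <= k))


def error_reduction(acc_assoc: float, acc_cf: float) -> float:
    """Relative error reduction ``1 − e_c/e_a`` with ``e = 1 − accuracy``.

    Negative when the counterfactual ranking does worse; undefined (raises)
    when the associative accuracy is already 1.
    """
    if acc_assoc >= 1.0:
        raise ValueError("error reduction undefined: associative error rate is zero")
    return 1.0 - (1.0 - acc_cf) / (1.0 - acc_assoc)


def rank_comparison(
    result: CohortResult, measure_a: str, measure_b: str
) -> Dict[str, float]:
    """Wins/draws/losses and mean true-disease positions of two measures.

    A win for a measure is a strictly smaller (better) tie-aware position of
    the true disease on the same vignette.
    """
    a = result.ranks(measure_a, tie_aware=True)
    b = result.ranks(measure_b, tie_aware=True)
    return {
        "n": int(len(result)),
        f"wins_{measure_a}": int(np.sum(a < b)),
        f"wins_{measure_b}": int(np.sum(b < a)),
        "draws": int(np.sum(a == b)),
        f"mean_rank_{measure_a}": float(np.mean(a)) if len(a) else float("nan"),
        f"mean_rank_{measure_b}": float(np.mean(b)) if len(b) else float("nan"),
    }


def stratify_by_rarity(
    network: NoisyOrNetwork,
    result: CohortResult,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
) -> Dict[int, CohortResult]:
    """Partition a cohort by the true disease's prior given risk evidence.

    Band ``i`` collects vignettes whose prior falls in ``(e_{i-1}, e_i]``;
    band 0 is below the first edge, band ``len(edges)`` above the last.
    The union of the bands is the whole cohort.
    """
    edges = tuple(band_edges)
    if any(not 0.0 < e < 1.0 for e in edges) or list(edges) != sorted(set(edges)):
        raise ValueError("band edges must be strictly increasing within (0,1)")
    priors = result.table["prior"].to_numpy()
    labels = np.array([_band_label(edges, p) for p in priors], dtype=int)
    return {
        band: result.subset(labels == band)
        for band in range(len(edges) + 1)
        if np.any(labels == band)
    }


def matched_differential_evaluation(
    result: CohortResult, measures: Optional[Sequence[str]] = None
) -> Dict[str, float]:
    """Accuracy when each vignette uses its own differential size k.

    A vignette counts as correct under a measure when the true disease sits
    within that vignette's top-k.  Raises if any vignette lacks k.
    """
    measures = tuple(measures or result.measures)
    if len(result) == 0:
        raise ValueError("empty cohort")
    ks = result.table["k"].to_numpy(dtype=float)
    missing = result.table.loc[np.isnan(ks), "vignette_id"].tolist()
    if missing:
        raise ValueError(f"vignettes missing differential size k: {missing}")
    out = {}
    for m in measures:
        out[m] = float(np.mean(result.ranks(m) <= ks))
    return out
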