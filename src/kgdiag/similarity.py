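"""Patient–patient similarity on the knowledge graph.

The central score is the weighted common-neighbor score: every 2-hop path
query → shared entity → candidate contributes the shared entity's combined
weight toward the candidate's (known) syndrome. Three classic unweighted
link-prediction scores — common neighbors, Adamic-Adar, resource
allocation — serve as baselines.

Scoring neighborhoods are restricted to feature entities: patient- and
syndrome-typed nodes never act as the shared middle node *h*, since the
weight table only defines weights for symptom/attribute entities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .graph import KnowledgeGraph
from .weighting import WeightTable

_SCORING_EXCLUDED_ETYPES = frozenset({"patient", "syndrome"})

MODES = ("candidate-syndrome", "both-hops", "unweighted")


@dataclass(frozen=True)
class SimilarityScore:
    """One scored pair: the shared-entity count, the total score, and the
    per-entity contribution breakdown that makes the score auditable."""

    query_id: str
    candidate_id: str
    cn_count: int
    score: float
    breakdown: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.cn_count != len(self.breakdown):
            raise ValueError("cn_count must equal the number of breakdown entries")
        if abs(self.score - sum(w for _, w in self.breakdown)) > 1e-9:
            raise ValueError("score must equal the sum of breakdown contributions")


def _scoring_neighbors(graph: KnowledgeGraph, node: str) -> set[str]:
    return {
        n
        for n in graph.neighbors(node)
        if graph.entity(n).etype not in _SCORING_EXCLUDED_ETYPES
    }


def candidate_syndrome(graph: KnowledgeGraph, candidate_id: str) -> str:
    syn = graph.neighbors(candidate_id, etype="syndrome")
    if len(syn) != 1:
        raise ValueError(
            f"candidate {candidate_id!r} must have exactly one syndrome "
            f"(found {len(syn)})"
        )
    return next(iter(syn))


def wcn_score(
    graph: KnowledgeGraph,
    query_id: str,
    candidate_id: str,
    table: WeightTable | None = None,
    mode: str = "candidate-syndrome",
) -> SimilarityScore:
    """Weighted common-neighbor score between a query patient and a labeled
    candidate patient.

    Modes: ``candidate-syndrome`` (default) — each shared entity h
    contributes its combined weight toward the candidate's syndrome;
    ``both-hops`` — that weight is credited once per hop of the 2-hop path,
    doubling each term; ``unweighted`` — each shared entity counts 1.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    shared = sorted(
        _scoring_neighbors(graph, query_id) & _scoring_neighbors(graph, candidate_id)
    )
    if mode == "unweighted":
        breakdown = tuple((h, 1.0) for h in shared)
    else:
        if table is None:
            raise ValueError(f"mode {mode!r} requires a weight table")
        syndrome = candidate_syndrome(graph, candidate_id)
        factor = 2.0 if mode == "both-hops" else 1.0
        breakdown = tuple(
            (h, factor * table.lookup(graph.entity(h).label, syndrome)) for h in shared
        )
    return SimilarityScore(
        query_id=query_id,
        candidate_id=candidate_id,
        cn_count=len(shared),
        score=float(sum(w for _, w in breakdown)),
        breakdown=breakdown,
    )


def common_neighbors_score(graph: KnowledgeGraph, a: str, b: str) -> float:
    """|CN(a, b)| over scoring (feature-entity) neighborhoods."""
    return float(len(_scoring_neighbors(graph, a) & _scoring_neighbors(graph, b)))


def adamic_adar_score(graph: KnowledgeGraph, a: str, b: str) -> float:
    """Σ 1/log(deg h) over common neighbors, natural log. Any common
    neighbor has degree ≥ 2 (it is adjacent to both a and b), so the log
    never vanishes."""
    shared = _scoring_neighbors(graph, a) & _scoring_neighbors(graph, b)
    return float(sum(1.0 / math.log(graph.degree(h)) for h in shared))


def resource_allocation_score(graph: KnowledgeGraph, a: str, b: str) -> float:
    """Σ 1/deg(h) over common neighbors."""
    shared = _scoring_neighbors(graph, a) & _scoring_neighbors(graph, b)
    return float(sum(1.0 / graph.degree(h) for h in shared))


def sort_scores(scores: Sequence[SimilarityScore]) -> list[SimilarityScore]:
    """Descending by score; ties broken by common-neighbor count (desc),
    then candidate id (asc) — a total, deterministic order."""
    return sorted(scores, key=lambda s: (-s.score, -s.cn_count, s.candidate_id))


def score_all(
    graph: KnowledgeGraph,
    query_id: str,
    candidate_ids: Sequence[str],
    table: WeightTable | None = None,
    mode: str = "candidate-syndrome",
) -> list[SimilarityScore]:
    """Score the query against every candidate and return the ranked list."""
    if not candidate_ids:
        raise ValueError("empty candidate set")
    return sort_scores(
        [wcn_score(graph, query_id, c, table, mode) for c in candidate_ids]
    )
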