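"""Turn a ranked similarity list into a syndrome prediction.

The classifier is a top-k vote (k = 20 by default): the query is scored
against every labeled patient, the list is sorted descending, and the modal
syndrome among the k best-scoring patients is the recommendation. Because
the evidence is a list of concrete shared clinical findings with weights,
each prediction can be rendered as a human-auditable explanation report.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from typing import Mapping, Sequence

from .graph import Entity, KnowledgeGraph, Relation
from .ingest import PatientRecord
from .similarity import SimilarityScore, score_all
from .weighting import WeightTable

logger = logging.getLogger(__name__)

DEFAULT_K = 20


@dataclass(frozen=True)
class DiagnosisResult:
    query_id: str
    predicted: str
    k_used: int
    votes: dict[str, int]
    class_scores: dict[str, float]
    top_list: tuple[SimilarityScore, ...]

    def __post_init__(self) -> None:
        if sum(self.votes.values()) != self.k_used:
            raise ValueError("votes must sum to k_used")
        total = sum(self.class_scores.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_scores sum to {total}, not 1")


def _resolve_votes(
    top: Sequence[SimilarityScore], labels: Mapping[str, str]
) -> tuple[dict[str, int], dict[str, float]]:
    votes: dict[str, int] = {}
    score_sums: dict[str, float] = {}
    for s in top:
        lab = labels[s.candidate_id]
        votes[lab] = votes.get(lab, 0) + 1
        score_sums[lab] = score_sums.get(lab, 0.0) + s.score
    return votes, score_sums


def top_k_vote(
    sorted_scores: Sequence[SimilarityScore],
    labels: Mapping[str, str],
    k: int = DEFAULT_K,
) -> DiagnosisResult:
    """Modal syndrome among the top min(k, n) candidates. Vote ties break by
    the larger summed similarity score, then lexicographic label."""
    if not sorted_scores:
        raise ValueError("empty similarity list")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    top = list(sorted_scores[: min(k, len(sorted_scores))])
    votes, score_sums = _resolve_votes(top, labels)
    predicted = min(votes, key=lambda s: (-votes[s], -score_sums[s], s))
    return DiagnosisResult(
        query_id=top[0].query_id,
        predicted=predicted,
        k_used=len(top),
        votes=votes,
        class_scores=class_scores(sorted_scores, labels, k),
        top_list=tuple(top),
    )


def class_scores(
    sorted_scores: Sequence[SimilarityScore],
    labels: Mapping[str, str],
    k: int = DEFAULT_K,
) -> dict[str, float]:
    """Per-syndrome share of the top-k similarity-score mass, normalized to
    sum 1. When every top-k score is zero, falls back to vote fractions.
    Supplies the continuous score a ROC analysis needs for a vote-based
    classifier."""
    if not sorted_scores:
        raise ValueError("empty similarity list")
    top = list(sorted_scores[: min(k, len(sorted_scores))])
    votes, score_sums = _resolve_votes(top, labels)
    total = sum(score_sums.values())
    if total > 0:
        return {s: score_sums[s] / total for s in score_sums}
    return {s: votes[s] / len(top) for s in votes}


def diagnose(
    graph: KnowledgeGraph,
    query_record: PatientRecord,
    table: WeightTable,
    k: int = DEFAULT_K,
    mode: str = "candidate-syndrome",
    on_unknown_feature: str = "warn",
) -> DiagnosisResult:
    """Diagnose one query patient against every labeled patient in the graph.

    The query node is attached transiently (its features only — no syndrome
    edge) and removed afterwards. Query features absent from the graph
    vocabulary are skipped with a warning by default (``"error"`` for strict
    mode): live patients present vocabulary drift.
    """
    if on_unknown_feature not in ("warn", "error"):
        raise ValueError(f"invalid on_unknown_feature {on_unknown_feature!r}")
    label_to_id = {e.label: e.id for e in graph.entities if e.etype not in ("patient",)}
    known, unknown = [], []
    for feat in sorted(query_record.features):
        (known if feat in label_to_id else unknown).append(feat)
    if unknown:
        if on_unknown_feature == "error":
            raise ValueError(f"unknown query features: {unknown}")
        logger.warning(
            "query %s: skipping %d unknown feature(s): %s",
            query_record.patient_id,
            len(unknown),
            unknown,
        )
    if not known:
        raise ValueError(
            f"query {query_record.patient_id!r} has no features known to the graph"
        )
    candidates = [
        pid
        for pid in graph.entity_ids("patient")
        if pid != query_record.patient_id
        and graph.neighbors(pid, etype="syndrome")
    ]
    if not candidates:
        raise ValueError("graph contains no labeled candidate patients")

    labels = {c: next(iter(graph.neighbors(c, etype="syndrome"))) for c in candidates}
    query_node = query_record.patient_id
    transient = query_node not in graph
    if not transient:
        raise ValueError(f"query id {query_record.patient_id!r} already in graph")
    graph.upsert_entity(Entity(query_node, query_record.patient_id, "patient"))
    try:
        for feat in known:
            graph.upsert_relation(Relation(query_node, label_to_id[feat], "has_finding"))
        ranked = score_all(graph, query_node, candidates, table, mode)
        return top_k_vote(ranked, labels, k)
    finally:
        _remove_patient(graph, query_node)


def _remove_patient(graph: KnowledgeGraph, node_id: str) -> None:
    # internal: drop a transiently attached query node and its edges
    graph._adj.remove_node(node_id)
    del graph._entities[node_id]
    for key in [k for k in graph._relations if node_id in (k[0], k[1])]:
        del graph._relations[key]


def explain(result: DiagnosisResult, max_breakdowns: int | None = None) -> str:
    """Render a diagnosis as a Markdown report: the ranked top-k table
    (patient id / shared-neighbor count / score) followed by each
    candidate's shared-entity list with the weight it contributed."""
    lines = [
        f"# Diagnosis for patient {result.query_id}",
        "",
        f"Predicted syndrome: **{result.predicted}** "
        f"(votes over top {result.k_used}: "
        + ", ".join(f"{s}={n}" for s, n in sorted(result.votes.items()))
        + ")",
        "",
        "| Patient ID | Neighbors | Neighbors score |",
        "|---|---|---|",
    ]
    for s in result.top_list:
        lines.append(f"| {s.candidate_id} | {s.cn_count} | {s.score:.2f} |")
    lines.append("")
    shown = result.top_list if max_breakdowns is None else result.top_list[:max_breakdowns]
    for s in shown:
        lines.append(f"## Shared entities with patient {s.candidate_id}")
        for entity, weight in s.breakdown:
            lines.append(f"- {entity}: {weight:.4f}")
        lines.append(f"- total: {s.score:.4f}")
        lines.append("")
    return "\n".join(lines)


def explanation_tsv(result: DiagnosisResult) -> str:
    """TSV twin of the report's top-k table."""
    rows = ["candidate_id\tcn_count\tscore"]
    for s in result.top_list:
        rows.append(f"{s.candidate_id}\t{s.cn_count}\t{s.score!r}")
    return "\n".join(rows) + "\n"
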