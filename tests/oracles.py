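"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (explicit path
enumeration, joint-frequency formulas, exhaustive pair counting) without
touching the package's own scoring code paths.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from kgdiag.graph import KnowledgeGraph


def adjacency_from_relations(graph: KnowledgeGraph) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = defaultdict(set)
    for r in graph.relations:
        adj[r.source].add(r.target)
        adj[r.target].add(r.source)
    for e in graph.entities:
        adj.setdefault(e.id, set())
    return adj


def two_hop_paths(graph: KnowledgeGraph, a: str, b: str) -> list[str]:
    """All middle nodes h with an explicit path a-h-b, restricted to
    feature entities (the scoring rule: h is a symptom/attribute node)."""
    adj = adjacency_from_relations(graph)
    etype = {e.id: e.etype for e in graph.entities}
    return sorted(
        h
        for h in adj[a]
        if b in adj[h] and etype[h] not in ("patient", "syndrome")
    )


def brute_force_score(
    graph: KnowledgeGraph,
    a: str,
    b: str,
    rule: str,
    table=None,
    syndrome: str | None = None,
) -> float:
    """Score by explicit 2-hop path enumeration. ``rule`` in
    {"wcn", "cn", "aa", "ra"}; for "wcn", each path contributes the middle
    entity's combined weight toward ``syndrome`` (the candidate's label)."""
    adj = adjacency_from_relations(graph)
    label = {e.id: e.label for e in graph.entities}
    total = 0.0
    for h in two_hop_paths(graph, a, b):
        if rule == "cn":
            total += 1.0
        elif rule == "aa":
            total += 1.0 / math.log(len(adj[h]))
        elif rule == "ra":
            total += 1.0 / len(adj[h])
        elif rule == "wcn":
            total += table.lookup(label[h], syndrome)
        else:
            raise ValueError(rule)
    return total


def mutual_information_bits(joint_counts: np.ndarray) -> float:
    """I(X;Y) = Σ p(x,y) log2 p(x,y)/(p(x)p(y)) from a contingency table."""
    joint = np.asarray(joint_counts, dtype=float)
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / (px @ py)[mask])).sum())


def pairwise_auc(pos_scores, neg_scores) -> float:
    """Probability a positive outranks a negative, ties counted 1/2,
    by exhaustive pair enumeration."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos_scores) * len(neg_scores))
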