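from __future__ import annotations

import numpy as np
import pytest

from kgdiag.graph import Entity, KnowledgeGraph, Relation
from kgdiag.ingest import SYNDROMES, PatientRecord
from kgdiag.weighting import WeightTable


def make_random_clinical_graph(
    rng: np.random.Generator,
    n_patients: int = 8,
    n_symptoms: int = 15,
    edge_prob: float = 0.35,
) -> tuple[KnowledgeGraph, WeightTable]:
    """A random patient–symptom–syndrome graph (≤ 50 nodes) plus a random
    weight table covering every (symptom, syndrome) pair. Every patient gets
    at least one symptom and exactly one syndrome."""
    graph = KnowledgeGraph()
    symptoms = [f"sym{j:02d}" for j in range(n_symptoms)]
    for s in SYNDROMES:
        graph.upsert_entity(Entity(s, s, "syndrome"))
    for sym in symptoms:
        graph.upsert_entity(Entity(sym, sym.upper(), "symptom"))
    for i in range(n_patients):
        pid = f"p{i:02d}"
        graph.upsert_entity(Entity(pid, pid, "patient"))
        present = [sym for sym in symptoms if rng.random() < edge_prob]
        if not present:
            present = [symptoms[int(rng.integers(n_symptoms))]]
        for sym in present:
            graph.upsert_relation(Relation(pid, sym, "has_finding"))
        syndrome = SYNDROMES[int(rng.integers(len(SYNDROMES)))]
        graph.upsert_relation(Relation(pid, syndrome, "diagnosed_as"))
    combined = {
        (sym.upper(), s): float(rng.uniform(0.1, 3.0))
        for sym in symptoms
        for s in SYNDROMES
    }
    return graph, WeightTable(combined=combined)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240610)


@pytest.fixture
def star_graph() -> KnowledgeGraph:
    """Center patient connected to 4 symptom leaves."""
    g = KnowledgeGraph()
    g.upsert_entity(Entity("center", "center", "patient"))
    for i in range(4):
        g.upsert_entity(Entity(f"leaf{i}", f"leaf{i}", "symptom"))
        g.upsert_relation(Relation("center", f"leaf{i}", "has_finding"))
    g.upsert_entity(Entity("isolated", "isolated", "symptom"))
    return g


@pytest.fixture
def small_clinic() -> tuple[KnowledgeGraph, WeightTable]:
    """Hand-enumerable fixture: two patients sharing exactly two symptoms.

    p1: cough, fever, headache + syndrome KED
    p2: cough, fever, rash     + syndrome QDSS
    """
    g = KnowledgeGraph()
    for s in ("KED", "QDSS"):
        g.upsert_entity(Entity(s, s, "syndrome"))
    for sym in ("cough", "fever", "headache", "rash"):
        g.upsert_entity(Entity(sym, sym, "symptom"))
    for pid, feats, syn in (
        ("p1", ("cough", "fever", "headache"), "KED"),
        ("p2", ("cough", "fever", "rash"), "QDSS"),
    ):
        g.upsert_entity(Entity(pid, pid, "patient"))
        for f in feats:
            g.upsert_relation(Relation(pid, f, "has_finding"))
        g.upsert_relation(Relation(pid, syn, "diagnosed_as"))
    combined = {
        (sym, s): w
        for sym, weights in {
            "cough": {"KED": 1.2, "QDSS": 0.4},
            "fever": {"KED": 0.8, "QDSS": 0.6},
            "headache": {"KED": 0.5, "QDSS": 0.9},
            "rash": {"KED": 0.3, "QDSS": 1.1},
        }.items()
        for s, w in weights.items()
    }
    return g, WeightTable(combined=combined)


@pytest.fixture
def toy_cohort() -> list[PatientRecord]:
    """12 labeled patients over 3 syndromes with a hand-checkable
    feature/syndrome contingency structure."""
    rows = [
        ("t01", {"a", "b"}, "KED"),
        ("t02", {"a", "c"}, "KED"),
        ("t03", {"a"}, "KED"),
        ("t04", {"a", "b", "c"}, "KED"),
        ("t05", {"b", "c"}, "LFBU"),
        ("t06", {"b"}, "LFBU"),
        ("t07", {"b", "d"}, "LFBU"),
        ("t08", {"b", "a"}, "LFBU"),
        ("t09", {"c", "d"}, "QDSS"),
        ("t10", {"d"}, "QDSS"),
        ("t11", {"c", "d", "a"}, "QDSS"),
        ("t12", {"d", "b"}, "QDSS"),
    ]
    return [PatientRecord(pid, frozenset(f), s) for pid, f, s in rows]
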