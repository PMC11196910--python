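import numpy as np
import pytest

from kgdiag.diagnosis import class_scores, diagnose, explain, top_k_vote
from kgdiag.estimators import NeighborVoteClassifier
from kgdiag.ingest import PatientRecord, build_graph
from kgdiag.similarity import SimilarityScore
from kgdiag.synthetic import default_config, generate_cohort
from kgdiag.weighting import compute_weight_table


def make_scores(rows):
    """rows: (candidate_id, cn_count, score) with uniform breakdown."""
    out = []
    for cid, cn, score in rows:
        breakdown = tuple((f"e{i}", score / cn) for i in range(cn)) if cn else ()
        out.append(SimilarityScore("q", cid, cn, score, breakdown))
    return out


class TestTopKVote:
    def test_unanimous(self):
        scores = make_scores([("a", 2, 3.0), ("b", 1, 2.0), ("c", 1, 1.0)])
        labels = {"a": "KED", "b": "KED", "c": "KED"}
        assert top_k_vote(scores, labels, k=20).predicted == "KED"

    def test_k_truncates_to_list_length(self):
        scores = make_scores([("a", 1, 3.0), ("b", 1, 2.0), ("c", 1, 1.0)])
        labels = {"a": "KED", "b": "QDSS", "c": "KED"}
        result = top_k_vote(scores, labels, k=20)
        assert result.k_used == 3
        assert sum(result.votes.values()) == 3

    def test_vote_tie_broken_by_summed_score(self):
        scores = make_scores(
            [("a1", 1, 1.6), ("b1", 1, 1.5), ("a2", 1, 1.5), ("b2", 1, 1.4)]
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        # votes A:2 B:2; summed scores A=3.1 > B=2.9
        assert top_k_vote(scores, labels, k=4).predicted == "A"

    def test_full_tie_broken_lexicographically(self):
        scores = make_scores([("a1", 1, 1.0), ("b1", 1, 1.0)])
        labels = {"a1": "QDSS", "b1": "KED"}
        assert top_k_vote(scores, labels, k=2).predicted == "KED"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            top_k_vote([], {}, k=5)

    def test_prediction_invariant_under_candidate_duplication(self):
        scores = make_scores([("a", 1, 2.0), ("b", 1, 1.5), ("c", 1, 1.0)])
        labels = {"a": "KED", "b": "QDSS", "c": "KED"}
        base = top_k_vote(scores, labels, k=20).predicted
        dup = scores + make_scores([("a2", 1, 2.0), ("b2", 1, 1.5), ("c2", 1, 1.0)])
        labels2 = {**labels, "a2": "KED", "b2": "QDSS", "c2": "KED"}
        from kgdiag.similarity import sort_scores

        assert top_k_vote(sort_scores(dup), labels2, k=20).predicted == base


class TestClassScores:
    def test_single_class_gets_full_mass(self):
        scores = make_scores([("a", 1, 2.0), ("b", 1, 1.0)])
        labels = {"a": "KED", "b": "KED"}
        assert class_scores(scores, labels, k=2) == {"KED": 1.0}

    def test_normalized_score_mass(self):
        scores = make_scores([("a", 1, 3.0), ("b", 1, 1.0)])
        labels = {"a": "KED", "b": "QDSS"}
        cs = class_scores(scores, labels, k=2)
        assert cs == pytest.approx({"KED": 0.75, "QDSS": 0.25})

    def test_zero_scores_fall_back_to_vote_fractions(self):
        scores = make_scores([("a", 0, 0.0), ("b", 0, 0.0), ("c", 0, 0.0)])
        labels = {"a": "KED", "b": "KED", "c": "QDSS"}
        cs = class_scores(scores, labels, k=3)
        assert cs == pytest.approx({"KED": 2 / 3, "QDSS": 1 / 3})

    def test_normalization_against_hand_sums(self, rng):
        rows = [(f"c{i}", 1, float(rng.uniform(0, 3))) for i in range(20)]
        scores = make_scores(rows)
        labels = {f"c{i}": ("KED" if i % 2 else "QDSS") for i in range(20)}
        cs = class_scores(scores, labels, k=20)
        tot = sum(s for _, _, s in rows)
        ked = sum(s for cid, _, s in rows if labels[cid] == "KED")
        assert cs["KED"] == pytest.approx(ked / tot)
        assert sum(cs.values()) == pytest.approx(1.0, abs=1e-9)


class TestDiagnose:
    @pytest.fixture
    def cohort(self):
        cfg = default_config()
        cfg.class_sizes = {s: 30 for s in cfg.class_sizes}
        return generate_cohort(cfg, seed=7)

    def test_clone_query_recovers_its_syndrome(self, cohort):
        graph = build_graph(cohort)
        table = compute_weight_table(cohort)
        target = cohort[0]
        query = PatientRecord("query-clone", target.features)
        result = diagnose(graph, query, table, k=20)
        assert result.predicted == target.syndrome

    def test_query_node_not_persisted(self, cohort):
        graph = build_graph(cohort)
        table = compute_weight_table(cohort)
        before = (graph.n_entities, graph.n_relations)
        diagnose(graph, PatientRecord("q", cohort[0].features), table)
        assert (graph.n_entities, graph.n_relations) == before
        assert "q" not in graph

    def test_unknown_features_skipped_with_warning(self, cohort, caplog):
        graph = build_graph(cohort)
        table = compute_weight_table(cohort)
        feats = set(list(cohort[0].features)[:3]) | {"never-seen-finding"}
        with caplog.at_level("WARNING"):
            diagnose(graph, PatientRecord("q", frozenset(feats)), table)
        assert "never-seen-finding" in caplog.text

    def test_strict_mode_errors_on_unknown(self, cohort):
        graph = build_graph(cohort)
        table = compute_weight_table(cohort)
        with pytest.raises(ValueError, match="unknown"):
            diagnose(
                graph,
                PatientRecord("q", frozenset({"never-seen", *list(cohort[0].features)[:1]})),
                table,
                on_unknown_feature="error",
            )

    def test_all_features_unknown_is_error(self, cohort):
        graph = build_graph(cohort)
        table = compute_weight_table(cohort)
        with pytest.raises(ValueError, match="no features"):
            diagnose(graph, PatientRecord("q", frozenset({"nope"})), table)

    def test_matches_vectorized_estimator(self, cohort):
        """The per-pair graph traversal and the estimator's matrix path are
        the same classifier."""
        graph = build_graph(cohort)
        table = compute_weight_table(cohort)
        clf = NeighborVoteClassifier().fit(cohort)
        rng = np.random.default_rng(0)
        cfg = default_config()
        cfg.class_sizes = {s: 4 for s in cfg.class_sizes}
        queries = generate_cohort(cfg, seed=99)
        for q in queries:
            query = PatientRecord("q-" + q.patient_id, q.features)
            graph_result = diagnose(graph, query, table, k=20)
            est_result = clf.diagnose_one(query)
            assert graph_result.predicted == est_result.predicted
            est_scores = {s.candidate_id: s.score for s in est_result.top_list}
            graph_scores = {s.candidate_id: s.score for s in graph_result.top_list}
            assert set(est_scores) == set(graph_scores)
            for cid in est_scores:
                assert est_scores[cid] == pytest.approx(graph_scores[cid], abs=1e-9)

    def test_end_to_end_holdout_accuracy(self):
        """With strong signatures, held-out queries recover their generating
        syndrome nearly always."""
        cfg = default_config()
        cfg.class_sizes = {s: 20 for s in cfg.class_sizes}
        train = generate_cohort(cfg, seed=11)
        test = generate_cohort(cfg, seed=12)
        clf = NeighborVoteClassifier().fit(train)
        queries = [PatientRecord("q" + r.patient_id, r.features) for r in test]
        pred = clf.predict(queries)
        truth = np.array([r.syndrome for r in test])
        assert (pred == truth).mean() >= 0.95


class TestExplain:
    def test_report_contains_table_and_breakdowns(self, rng):
        cfg = default_config()
        cfg.class_sizes = {s: 10 for s in cfg.class_sizes}
        cohort = generate_cohort(cfg, seed=5)
        clf = NeighborVoteClassifier(k=5).fit(cohort)
        result = clf.diagnose_one(PatientRecord("q1", cohort[3].features))
        report = explain(result)
        assert "| Patient ID | Neighbors | Neighbors score |" in report
        assert f"Predicted syndrome: **{result.predicted}**" in report
        for s in result.top_list:
            assert s.candidate_id in report

    def test_breakdown_sums_to_reported_score(self, rng):
        cfg = default_config()
        cfg.class_sizes = {s: 15 for s in cfg.class_sizes}
        cohort = generate_cohort(cfg, seed=6)
        clf = NeighborVoteClassifier().fit(cohort)
        for rec in generate_cohort(cfg, seed=8)[:10]:
            result = clf.diagnose_one(PatientRecord("q" + rec.patient_id, rec.features))
            for s in result.top_list:
                assert s.score == pytest.approx(
                    sum(w for _, w in s.breakdown), abs=1e-9
                )
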