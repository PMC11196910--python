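import math

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from kgdiag.ingest import PatientRecord
from kgdiag.weighting import (
    WeightTable,
    compute_weight_table,
    conditional_entropy,
    information_gain,
    load_reference_weights,
    lookup_weight,
    shannon_entropy,
    syndrome_conditional_prob,
)

from oracles import mutual_information_bits


class TestEntropy:
    @pytest.mark.parametrize(
        "dist,expected",
        [
            ([0.2] * 5, math.log2(5)),
            ([1, 0, 0, 0, 0], 0.0),
            ([0.5, 0.5], 1.0),
        ],
    )
    def test_closed_forms(self, dist, expected):
        assert shannon_entropy(dist) == pytest.approx(expected, abs=1e-12)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.5, 0.4])

    def test_bounded_by_log_support(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(k))
            h = shannon_entropy(p)
            assert -1e-12 <= h <= math.log2(k) + 1e-12


class TestConditionalEntropy:
    def test_constant_feature_is_uninformative(self):
        labels = ["A", "A", "B", "B", "C"]
        counts = np.array([2, 2, 1]) / 5
        assert conditional_entropy([1] * 5, labels) == pytest.approx(
            shannon_entropy(counts)
        )

    def test_perfect_predictor_gives_zero(self):
        labels = ["A", "B", "A", "B"]
        feature = [1, 0, 1, 0]
        assert conditional_entropy(feature, labels) == pytest.approx(0.0, abs=1e-12)

    def test_eight_patient_table_matches_enumeration(self):
        # joint counts: X=1: {A:2, B:1}; X=0: {A:1, B:4}
        feature = [1, 1, 1, 0, 0, 0, 0, 0]
        labels = ["A", "A", "B", "A", "B", "B", "B", "B"]
        h1 = -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)
        h0 = -(1 / 5) * math.log2(1 / 5) - (4 / 5) * math.log2(4 / 5)
        expected = (3 / 8) * h1 + (5 / 8) * h0
        assert conditional_entropy(feature, labels) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            conditional_entropy([1, 0], ["A"])


class TestInformationGain:
    def test_independent_feature_zero_gain(self):
        # product joint: feature balanced and independent of labels
        feature = [1, 0, 1, 0]
        labels = ["A", "A", "B", "B"]
        assert information_gain(feature, labels) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_predictor_gains_full_bit(self):
        feature = [1, 1, 0, 0]
        labels = ["A", "A", "B", "B"]
        assert information_gain(feature, labels) == pytest.approx(1.0)

    def test_relabeling_feature_values_invariant(self):
        feature = [1, 1, 0, 1, 0, 0]
        labels = ["A", "B", "A", "A", "B", "B"]
        flipped = [1 - x for x in feature]
        assert information_gain(feature, labels) == pytest.approx(
            information_gain(flipped, labels)
        )

    def test_identity_with_joint_frequency_mi_oracle(self, rng):
        """H(Y) − H(Y|X) equals the joint-count MI formula (and sklearn's
        nat-based MI) on random 2×k contingency tables."""
        for _ in range(200):
            k = int(rng.integers(2, 6))
            joint = rng.integers(0, 12, size=(2, k))
            joint[0, 0] += 1  # non-empty
            feature, labels = [], []
            for x in (0, 1):
                for y in range(k):
                    feature += [x] * int(joint[x, y])
                    labels += [f"c{y}"] * int(joint[x, y])
            gain = information_gain(feature, labels)
            assert gain == pytest.approx(mutual_information_bits(joint), abs=1e-9)
            assert gain == pytest.approx(
                mutual_info_score(feature, labels) / math.log(2), abs=1e-9
            )


class TestSyndromeConditionalProb:
    def test_simple_fractions(self, toy_cohort):
        w = syndrome_conditional_prob(toy_cohort)
        # feature "a" in 4/4 KED, 1/4 LFBU, 1/4 QDSS patients
        assert w[("a", "KED")] == pytest.approx(1.0)
        assert w[("a", "LFBU")] == pytest.approx(0.25)
        assert w[("d", "KED")] == pytest.approx(0.0)
        assert w[("d", "QDSS")] == pytest.approx(1.0)

    def test_alpha_smoothing(self, toy_cohort):
        w = syndrome_conditional_prob(toy_cohort, alpha=1.0)
        assert w[("d", "KED")] == pytest.approx(1 / 6)  # (0+1)/(4+2)

    def test_zero_patient_syndrome_named(self, toy_cohort):
        with pytest.raises(ValueError, match="WFAI"):
            syndrome_conditional_prob(toy_cohort, syndromes=["KED", "WFAI"])

    def test_unlabeled_record_rejected(self):
        with pytest.raises(ValueError):
            syndrome_conditional_prob([PatientRecord("q", frozenset({"a"}))])


class TestWeightTable:
    def test_toy_cohort_matches_hand_recomputation(self, toy_cohort):
        table = compute_weight_table(toy_cohort)
        labels = [r.syndrome for r in toy_cohort]
        for e in ("a", "b", "c", "d"):
            presence = [e in r.features for r in toy_cohort]
            expected_gain = information_gain(presence, labels)
            assert table.w_if[e] == pytest.approx(expected_gain, abs=1e-12)
            for s in ("KED", "LFBU", "QDSS"):
                assert table.combined[(e, s)] == pytest.approx(
                    table.w_if[e] + table.w_sd[(e, s)], abs=1e-9
                )

    def test_same_entity_two_syndromes_same_wif_different_wsd(self, toy_cohort):
        table = compute_weight_table(toy_cohort)
        # "a": present in all KED, 1/4 of LFBU -> same w_if, different combined
        assert table.combined[("a", "KED")] != table.combined[("a", "LFBU")]
        assert table.combined[("a", "KED")] - table.w_sd[("a", "KED")] == pytest.approx(
            table.combined[("a", "LFBU")] - table.w_sd[("a", "LFBU")]
        )

    def test_duplicating_cohort_leaves_weights_unchanged(self, toy_cohort):
        doubled = toy_cohort + [
            PatientRecord(r.patient_id + "x", r.features, r.syndrome)
            for r in toy_cohort
        ]
        t1 = compute_weight_table(toy_cohort)
        t2 = compute_weight_table(doubled)
        for key, val in t1.combined.items():
            assert t2.combined[key] == pytest.approx(val, abs=1e-12)

    def test_label_permutation_drives_gain_down(self, rng):
        """Shuffling labels across patients destroys the feature-label
        association, so every w_if collapses toward 0 in expectation."""
        from kgdiag.synthetic import default_config, generate_cohort

        cfg = default_config()
        cfg.class_sizes = {s: 60 for s in cfg.class_sizes}
        records = generate_cohort(cfg, seed=3)
        t_true = compute_weight_table(records)
        labels = [r.syndrome for r in records]
        perm = rng.permutation(len(labels))
        shuffled = [
            PatientRecord(r.patient_id, r.features, labels[perm[i]])
            for i, r in enumerate(records)
        ]
        t_shuf = compute_weight_table(shuffled)
        sig = [e for e in t_true.w_if if t_true.w_if[e] > 0.1]
        assert np.mean([t_shuf.w_if[e] for e in sig]) < 0.1 * np.mean(
            [t_true.w_if[e] for e in sig]
        )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            compute_weight_table([])

    def test_tsv_roundtrip(self, toy_cohort, tmp_path):
        table = compute_weight_table(toy_cohort)
        path = tmp_path / "w.tsv"
        table.to_tsv(path)
        loaded = WeightTable.from_tsv(path)
        assert loaded.combined == table.combined
        assert loaded.w_if == table.w_if
        assert loaded.w_sd == table.w_sd

    def test_inconsistent_combined_rejected(self):
        with pytest.raises(ValueError, match="w_if"):
            WeightTable(
                combined={("a", "KED"): 2.0},
                w_if={"a": 0.5},
                w_sd={("a", "KED"): 0.3},
            )


class TestReferenceTable:
    def test_published_lookups(self):
        table = load_reference_weights()
        assert lookup_weight(table, "Fine pulse", "KED") == 1.1448
        assert lookup_weight(table, "Duration", "KED") == 0.6991
        assert lookup_weight(table, "Fine pulse", "QDSS") == 1.0782

    def test_absent_pair_names_both_keys(self):
        table = load_reference_weights()
        with pytest.raises(KeyError, match="Fine pulse.*LFBU"):
            table.lookup("Fine pulse", "LFBU")

    def test_all_values_obey_bound(self):
        """Every combined weight is below log2(5) + 1, the cap for a
        5-class information gain plus a probability."""
        table = load_reference_weights()
        assert len(table.combined) == 50
        cap = math.log2(5) + 1
        assert all(0 < v <= cap for v in table.combined.values())
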