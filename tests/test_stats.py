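"""Accuracy, confusion matrices, per-class F1, Cohen's kappa."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pollenholo import (AgreementResult, ConfusionMatrix, DegenerateInputError,
                        EvaluationRecord, InvalidArgumentError, POLLEN_CLASSES,
                        accuracy_percent, build_confusion, cohen_kappa,
                        per_class_f1, pooled_accuracy, summarize_study,
                        reference_study_records)


def make_records(n_correct, n_total, modality="DIHM", evaluator="e1",
                 wrong_to="hazel", true_cls="silver_birch"):
    """n_total single-class records of which n_correct are right."""
    recs = []
    for i in range(n_total):
        assigned = true_cls if i < n_correct else wrong_to
        recs.append(EvaluationRecord(f"img_{i}", modality, evaluator,
                                     true_cls, assigned))
    return recs


def kappa_oracle(a, b):
    """From-definition kappa in exact rational arithmetic."""
    n = len(a)
    p_o = Fraction(sum(x == y for x, y in zip(a, b)), n)
    labels = set(a) | set(b)
    p_e = sum(Fraction(a.count(c), n) * Fraction(b.count(c), n) for c in labels)
    if p_e == 1:
        return 1.0 if p_o == 1 else None
    return float((p_o - p_e) / (1 - p_e))


class TestAccuracy:
    @pytest.mark.parametrize("correct,total,expected", [
        (47, 48, 97.9),   # 97.9166... rounds to the printed per-expert value
        (48, 48, 100.0),
        (45, 48, 93.8),   # 93.75 rounds half-up
        (46, 48, 95.8),
    ])
    def test_rounding_half_up_to_one_decimal(self, correct, total, expected):
        assert accuracy_percent(make_records(correct, total)) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(DegenerateInputError):
            accuracy_percent([])

    def test_pooled_from_counts_not_averaged_percentages(self):
        # (97.9 + 93.8)/2 = 95.85 but the pooled 92/96 prints as 95.8
        sets = [make_records(47, 48), make_records(45, 48)]
        assert pooled_accuracy(sets) == 95.8

    def test_pooled_optical_value(self):
        assert pooled_accuracy([make_records(46, 48), make_records(47, 48)]) == 96.9

    def test_pooling_identical_sets_is_idempotent(self):
        s = make_records(40, 48)
        assert pooled_accuracy([s, s]) == accuracy_percent(s)


class TestConfusion:
    def test_all_correct_is_identity(self):
        recs = [EvaluationRecord(f"{c}_{i}", "DIHM", "e1", c, c)
                for c in POLLEN_CLASSES for i in range(3)]
        cm = build_confusion(recs)
        np.testing.assert_array_equal(cm.counts, np.eye(6, dtype=int) * 3)
        np.testing.assert_allclose(build_confusion(recs, normalise=True), np.eye(6))

    def test_single_birch_to_hazel_error(self):
        recs = [EvaluationRecord(f"{c}_{i}", "DIHM", "e1", c, c)
                for c in POLLEN_CLASSES for i in range(16)]
        recs[POLLEN_CLASSES.index("silver_birch") * 16] = EvaluationRecord(
            "silver_birch_0", "DIHM", "e1", "silver_birch", "hazel")
        norm = build_confusion(recs, normalise=True)
        i, j = POLLEN_CLASSES.index("silver_birch"), POLLEN_CLASSES.index("hazel")
        assert norm[i, i] == pytest.approx(15 / 16)
        assert norm[i, j] == pytest.approx(1 / 16)
        np.testing.assert_allclose(norm.sum(axis=1), 1.0)

    def test_unknown_label_rejected(self):
        recs = [EvaluationRecord("x", "DIHM", "e1", "silver_birch", "oak")]
        with pytest.raises(InvalidArgumentError):
            build_confusion(recs)

    def test_accuracy_equals_trace_over_total(self):
        recs = reference_study_records()
        cm = build_confusion(recs)
        assert accuracy_percent(recs) == pytest.approx(
            round(100 * np.trace(cm.counts) / cm.counts.sum(), 1))


class TestF1:
    def test_perfect_class(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[32, 0], [0, 32]]))
        assert per_class_f1(cm)["a"] == 1.0

    def test_birch_like_counts(self):
        # TP=28, FP=3, FN=4 -> 56/63 = 0.888... -> 0.889
        counts = np.zeros((6, 6), int)
        counts[2, 2] = 28
        counts[2, 3] = 2
        counts[2, 5] = 2
        counts[3, 2] = 2
        counts[4, 2] = 1
        cm = ConfusionMatrix(POLLEN_CLASSES, counts)
        assert per_class_f1(cm)["silver_birch"] == 0.889

    def test_empty_class_flagged_zero(self):
        counts = np.zeros((2, 2), int)
        counts[0, 0] = 5
        with pytest.warns(UserWarning):
            f1 = per_class_f1(ConfusionMatrix(("a", "b"), counts))
        assert f1["b"] == 0.0

    def test_micro_f1_equals_accuracy(self):
        # single-label micro-averaged F1 coincides with overall accuracy
        recs = reference_study_records()
        cm = build_confusion(recs)
        tp = np.trace(cm.counts)
        fp = cm.counts.sum() - tp  # == fn for single-label problems
        micro_f1 = 2 * tp / (2 * tp + 2 * fp)
        assert micro_f1 == pytest.approx(
            sum(r.true_species == r.assigned_species for r in recs) / len(recs))


class TestKappa:
    def test_identical_vectors(self):
        res = cohen_kappa(["x", "y", "z", "x"], ["x", "y", "z", "x"])
        assert res.kappa == 1.0
        assert res.n_pairs == 4

    def test_chance_level(self):
        res = cohen_kappa(list("xxyy"), list("xyxy"))
        assert res.observed_agreement == 0.5
        assert res.expected_agreement == 0.5
        assert res.kappa == 0.0

    def test_hand_computed_example(self):
        res = cohen_kappa(list("xxxy"), list("xxyy"))
        assert res.observed_agreement == 0.75
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.5)

    def test_degenerate_constant_raters(self):
        # p_e = 1 only when both raters are constant on the same label,
        # in which case p_o = 1 too and kappa is 1 by convention
        assert cohen_kappa(["x"] * 4, ["x"] * 4).kappa == 1.0
        with pytest.raises(InvalidArgumentError):
            cohen_kappa(["x"], ["x", "y"])
        with pytest.raises(InvalidArgumentError):
            cohen_kappa([], [])

    def test_exhaustive_binary_pairs_match_definition_oracle(self):
        labels = ("a", "b")
        for bits_a in itertools.product(range(2), repeat=6):
            a = [labels[i] for i in bits_a]
            for bits_b in itertools.product(range(2), repeat=6):
                b = [labels[i] for i in bits_b]
                expected = kappa_oracle(a, b)
                if expected is None:
                    with pytest.raises(DegenerateInputError):
                        cohen_kappa(a, b)
                else:
                    assert abs(cohen_kappa(a, b).kappa - expected) < 1e-12

    def test_matches_sklearn_on_random_vectors(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = list(rng.choice(list("abcd"), 30))
            b = list(rng.choice(list("abcd"), 30))
            ours = cohen_kappa(a, b).kappa
            theirs = sklearn_metrics.cohen_kappa_score(a, b)
            assert ours == pytest.approx(theirs, abs=1e-12)

    @given(st.lists(st.sampled_from("abc"), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_range_and_self_agreement(self, a):
        rng = np.random.default_rng(len(a))
        b = list(rng.permutation(a))
        try:
            forward = cohen_kappa(a, b)
            backward = cohen_kappa(b, a)
        except DegenerateInputError:
            return
        assert -1.0 - 1e-12 <= forward.kappa <= 1.0 + 1e-12
        assert forward.kappa == pytest.approx(backward.kappa, abs=1e-12)
        if len(set(a)) > 1:
            assert cohen_kappa(a, a).kappa == 1.0


class TestSummarizeStudy:
    def test_identity_study_all_perfect(self):
        from pollenholo import EvaluationStudySpec, generate_study_records
        records = generate_study_records(EvaluationStudySpec(seed=0))
        table = summarize_study(records)
        acc = table[table.metric == "accuracy_percent"]
        assert (acc.value == 100.0).all()
        kap = table[table.metric.str.startswith("kappa")]
        assert (kap.value == 1.0).all()

    def test_single_evaluator_has_no_kappa_rows(self):
        recs = make_records(10, 12)
        table = summarize_study(recs)
        assert not table.metric.str.startswith("kappa_inter_observer").any()
        assert (table.metric == "accuracy_percent").any()

    def test_reference_study_reproduces_published_summary(self):
        table = summarize_study(reference_study_records()).set_index(
            ["metric", "modality", "evaluator"]).value
        acc = "accuracy_percent"
        assert table[(acc, "DIHM", "expert_1")] == 97.9
        assert table[(acc, "DIHM", "expert_2")] == 93.8
        assert table[(acc, "optical", "expert_1")] == 95.8
        assert table[(acc, "optical", "expert_2")] == 97.9
        assert table[(acc, "DIHM", "pooled")] == 95.8
        assert table[(acc, "optical", "pooled")] == 96.9
        assert table[(acc, "pooled", "expert_1")] == 96.9
        assert table[(acc, "pooled", "expert_2")] == 95.8
        assert table[("kappa_inter_observer", "DIHM", "expert_1|expert_2")] == 0.90
        assert table[("kappa_inter_observer", "optical", "expert_1|expert_2")] == 0.93
        assert table[("kappa_inter_observer", "pooled", "expert_1|expert_2")] == 0.91
        assert table[("kappa_inter_modality", "DIHM|optical", "pooled")] == 0.91

    def test_reference_study_per_class_f1(self):
        cm = build_confusion(reference_study_records())
        f1 = per_class_f1(cm)
        assert f1["timothy_grass"] == 1.0
        assert f1["common_ragweed"] == 1.0
        assert f1["silver_birch"] == 0.889
        assert f1["common_alder"] == 0.938
        assert f1["olive_tree"] == 0.984
        assert f1["hazel"] == 0.970
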