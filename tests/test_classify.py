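from __future__ import annotations

import numpy as np
import pytest

from spermwave.classify import (
    SvmConfig,
    alpha_sweep,
    build_fused_features,
    ellipse_classify,
    evaluate,
    find_dividing_line,
    joint_criterion,
    knn_classify,
    representative_split,
    svm_train_test,
)
from spermwave.rankcode import RankProfile, rank_binarize, word_histogram

from tests._oracles import brute_dividing_line, draw_ellipse_mask


def gray_profile(rng, n=300):
    return word_histogram(rank_binarize(rng.uniform(0, 1, n)), 8)


class TestJointCriterion:
    def test_alpha_one_is_dard(self):
        assert joint_criterion(123.4, 0.9, 1.0) == 123.4

    def test_alpha_zero_is_scaled_p(self):
        assert joint_criterion(50.0, 0.4, 0.0) == pytest.approx(102.0)

    def test_weighted_mix(self):
        assert joint_criterion(100.0, 0.268, 0.8) == pytest.approx(93.668)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            joint_criterion(10.0, 0.5, 1.5)
        with pytest.raises(ValueError):
            joint_criterion(10.0, 1.5, 0.5)


class TestFindDividingLine:
    def test_separable_midpoint(self):
        values = [1.0, 2.0, 8.0, 9.0]
        labels = ["normal", "normal", "abnormal", "abnormal"]
        dl, acc = find_dividing_line(values, labels)
        assert acc == 1.0
        assert dl == pytest.approx(5.0)

    def test_interleaved_accuracy_half(self):
        values = [1.0, 2.0]
        labels = ["abnormal", "normal"]
        dl, acc = find_dividing_line(values, labels)
        assert acc == 0.5

    def test_flipped_labels_with_reversed_direction(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 10, 30).tolist()
        labels = ["normal" if v < 5 else "abnormal" for v in values]
        flipped = ["abnormal" if lab == "normal" else "normal" for lab in labels]
        _, acc = find_dividing_line(values, labels, direction="below")
        _, acc_flip = find_dividing_line(values, flipped, direction="above")
        assert acc == acc_flip

    def test_accuracy_at_least_class_prior(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            values = rng.uniform(0, 1, 20)
            labels = ["normal" if rng.random() < 0.7 else "abnormal" for _ in values]
            if len(set(labels)) < 2:
                continue
            prior = max(labels.count("normal"), labels.count("abnormal")) / len(labels)
            _, acc = find_dividing_line(values, labels)
            assert acc >= prior

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            values = rng.integers(0, 8, 12).astype(float).tolist()
            labels = [rng.choice(["normal", "abnormal"]) for _ in values]
            if len(set(labels)) < 2:
                continue
            dl, acc = find_dividing_line(values, labels)
            bdl, bacc = brute_dividing_line(values, labels)
            assert acc == pytest.approx(bacc)
            assert dl == pytest.approx(bdl)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            find_dividing_line([1.0, 2.0], ["normal", "normal"])


class TestAlphaSweep:
    def test_separable_perfect_everywhere(self):
        dards = np.array([10.0, 12.0, 90.0, 95.0])
        ps = np.array([0.1, 0.12, 0.8, 0.85])
        labels = ["normal", "normal", "abnormal", "abnormal"]
        table = alpha_sweep(dards, ps, labels)
        assert (table["accuracy"] == 1.0).all()

    def test_default_grid_shape(self):
        dards = np.array([10.0, 90.0])
        ps = np.array([0.1, 0.8])
        table = alpha_sweep(dards, ps, ["normal", "abnormal"])
        assert len(table) == 9
        assert table["alpha"].tolist() == pytest.approx(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        )

    def test_informative_p_beats_noisy_dard_at_low_alpha(self):
        rng = np.random.default_rng(3)
        n = 40
        labels = ["normal"] * (n // 2) + ["abnormal"] * (n // 2)
        ps = np.concatenate([rng.uniform(0.1, 0.3, n // 2), rng.uniform(0.5, 0.8, n // 2)])
        dards = rng.uniform(0, 200, n)  # uninformative
        table = alpha_sweep(dards, ps, labels)
        acc = dict(zip(table["alpha"].round(1), table["accuracy"]))
        assert acc[0.1] == 1.0
        assert acc[0.1] > acc[0.9]

    def test_endpoints_reproduce_single_feature_rules(self):
        rng = np.random.default_rng(4)
        n = 30
        dards = rng.uniform(0, 300, n)
        ps = rng.uniform(0, 1, n)
        labels = [rng.choice(["normal", "abnormal"]) for _ in range(n)]
        table = alpha_sweep(dards, ps, labels, alphas=(0.0, 1.0))
        _, acc_p = find_dividing_line(255 * ps, labels)
        _, acc_d = find_dividing_line(dards, labels)
        assert table.loc[table["alpha"] == 0.0, "accuracy"].iloc[0] == pytest.approx(acc_p)
        assert table.loc[table["alpha"] == 1.0, "accuracy"].iloc[0] == pytest.approx(acc_d)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            alpha_sweep(np.array([1.0]), np.array([0.5]), ["normal"], alphas=())


class TestFusedFeatures:
    def test_shape_and_rank_permutation(self):
        rng = np.random.default_rng(5)
        profiles = [gray_profile(rng) for _ in range(6)]
        feats = build_fused_features(profiles, np.arange(6, dtype=float))
        assert feats.shape == (6, 257)
        for row in feats[:, :256]:
            assert sorted(row.tolist()) == list(range(1, 257))

    def test_identical_profiles_differ_only_in_dard(self):
        rng = np.random.default_rng(6)
        p = gray_profile(rng)
        feats = build_fused_features([p, p], np.array([10.0, 20.0]))
        assert np.array_equal(feats[0, :256], feats[1, :256])
        assert feats[0, 256] != feats[1, 256]

    def test_wrong_m_rejected(self):
        bad = word_histogram(rank_binarize(np.random.default_rng(0).uniform(0, 1, 50)), 5)
        with pytest.raises(ValueError):
            build_fused_features([bad], np.array([1.0]))


class TestSvm:
    def test_separable_features_perfect(self):
        rng = np.random.default_rng(7)
        n = 30
        X = np.vstack([rng.normal(0, 0.2, (n, 5)), rng.normal(4, 0.2, (n, 5))])
        labels = ["normal"] * n + ["abnormal"] * n
        train = np.concatenate([np.arange(5), np.arange(n, n + 5)])
        report = svm_train_test(X, labels, train)
        assert report.accuracy == 1.0
        assert report.n_total == 2 * n - 10

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (40, 10))
        labels = ["normal" if i % 2 == 0 else "abnormal" for i in range(40)]
        train = np.arange(12)
        r1 = svm_train_test(X, labels, train)
        r2 = svm_train_test(X, labels, train)
        assert r1.accuracy == r2.accuracy
        assert r1.per_class == r2.per_class

    def test_single_class_train_rejected(self):
        X = np.zeros((10, 3))
        labels = ["normal"] * 5 + ["abnormal"] * 5
        with pytest.raises(ValueError):
            svm_train_test(X, labels, np.arange(5))

    def test_config_echo(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (20, 4))
        labels = ["normal", "abnormal"] * 10
        report = svm_train_test(X, labels, np.arange(10), SvmConfig(cost=2.0))
        assert report.config_echo["cost"] == 2.0
        assert report.config_echo["gamma_effective"] == pytest.approx(0.25)

    def test_representative_split_counts(self):
        rng = np.random.default_rng(10)
        profiles = [gray_profile(rng) for _ in range(16)]
        labels = ["normal"] * 8 + ["abnormal"] * 8
        train = representative_split(profiles, labels, per_class=5)
        assert len(train) == 10
        train_labels = [labels[i] for i in train]
        assert train_labels.count("normal") == 5
        assert train_labels.count("abnormal") == 5


class TestKnn:
    def test_identical_reference_wins_k1(self):
        rng = np.random.default_rng(11)
        refs = [(rng.integers(0, 256, (8, 8)).astype(np.uint8), "abnormal") for _ in range(5)]
        target = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        refs.append((target, "normal"))
        assert knn_classify(target, refs, k=1) == "normal"

    def test_single_class_references(self):
        rng = np.random.default_rng(12)
        refs = [(rng.integers(0, 256, (8, 8)).astype(np.uint8), "normal") for _ in range(4)]
        test = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert knn_classify(test, refs, k=3) == "normal"

    def test_published_cut_at_k10(self):
        # 4 normal neighbours of 10 is already "normal" under the >3 cut
        rng = np.random.default_rng(13)
        base = rng.integers(100, 110, (8, 8)).astype(np.uint8)
        refs = []
        for i in range(4):
            refs.append((base + i % 2, "normal"))
        for i in range(6):
            refs.append((base + 1 + i % 2, "abnormal"))
        assert knn_classify(base, refs, k=10, normal_cut=3) == "normal"
        assert knn_classify(base, refs, k=10, normal_cut=None) == "abnormal"

    def test_k_bounds(self):
        refs = [(np.zeros((4, 4), dtype=np.uint8), "normal")]
        with pytest.raises(ValueError):
            knn_classify(np.zeros((4, 4), dtype=np.uint8), refs, k=2)

    def test_mixed_sizes_resampled(self):
        rng = np.random.default_rng(14)
        refs = [
            (rng.integers(0, 256, (6 + i, 9 - i)).astype(np.uint8), "normal")
            for i in range(3)
        ]
        label = knn_classify(rng.integers(0, 256, (12, 5)).astype(np.uint8), refs, k=1)
        assert label == "normal"


class TestEllipseClassify:
    def test_axis_aligned_ellipse_normal(self):
        mask = draw_ellipse_mask((41, 51), (20, 25), 15, 10)
        ovality, label = ellipse_classify(mask)
        assert ovality == pytest.approx(1.5, abs=0.05)
        assert label == "normal"

    def test_circle_abnormal(self):
        mask = draw_ellipse_mask((41, 41), (20, 20), 15, 15)
        ovality, label = ellipse_classify(mask)
        assert ovality == pytest.approx(1.0, abs=0.05)
        assert label == "abnormal"

    def test_slim_abnormal(self):
        mask = draw_ellipse_mask((51, 91), (25, 45), 20, 10)
        ovality, label = ellipse_classify(mask)
        assert ovality == pytest.approx(2.0, abs=0.08)
        assert label == "abnormal"

    def test_rotation_invariance(self):
        for a, b, tol in [(24, 16, 0.05), (18, 12, 0.06)]:
            ovalities = [
                ellipse_classify(draw_ellipse_mask((71, 71), (35, 35), a, b, ang))[0]
                for ang in np.linspace(0, np.pi, 9)
            ]
            spread = (max(ovalities) - min(ovalities)) / np.mean(ovalities)
            assert spread < tol

    def test_degenerate_line_abnormal(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 2:9] = True
        ovality, label = ellipse_classify(mask)
        assert ovality == float("inf")
        assert label == "abnormal"

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ellipse_classify(np.zeros((5, 5), dtype=bool))


class TestEvaluate:
    def test_identical_lists(self):
        report = evaluate(["normal", "abnormal"], ["normal", "abnormal"])
        assert report.accuracy == 1.0

    def test_fully_opposed(self):
        report = evaluate(["normal", "normal"], ["abnormal", "abnormal"])
        assert report.accuracy == 0.0

    def test_accuracy_is_correct_over_total(self):
        # 123 correct of 160
        pred = ["normal"] * 160
        truth = ["normal"] * 123 + ["abnormal"] * 37
        report = evaluate(pred, truth)
        assert report.accuracy == pytest.approx(0.76875)

    def test_confusion_counts(self):
        report = evaluate(
            ["normal", "abnormal", "normal"], ["normal", "normal", "abnormal"]
        )
        assert report.per_class["normal"] == {"normal": 1, "abnormal": 1}
        assert report.per_class["abnormal"] == {"normal": 1}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["normal"], ["normal", "abnormal"])
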