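import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shadowcyte.classifier import (CLASSES, StandardVectors, classify,
                                   differential_count, euclidean_distance,
                                   feature_probabilities, size_class,
                                   size_probabilities, train_standards)


def make_standards(neu=None, mon=None, lym=None):
    base = {"Neu": neu, "Mon": mon, "Lym": lym}
    return StandardVectors({c: (np.zeros(64) if v is None else np.asarray(v, float))
                            for c, v in base.items()})


class TestEuclidean:
    def test_identity(self):
        v = np.arange(64, dtype=float)
        assert euclidean_distance(v, v) == 0.0

    def test_3_4_5(self):
        assert euclidean_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0

    def test_matches_elementwise_loop(self, rng):
        x = rng.random(64)
        y = rng.random(64)
        acc = sum((a - b) ** 2 for a, b in zip(x, y)) ** 0.5
        assert euclidean_distance(x, y) == pytest.approx(acc, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.zeros(3), np.zeros(4))


class TestTraining:
    def test_single_exemplar_is_the_standard(self, rng):
        vecs = [rng.random(64) for _ in range(3)]
        std = train_standards(vecs, ["Neu", "Mon", "Lym"])
        for v, c in zip(vecs, CLASSES):
            np.testing.assert_allclose(std.vectors[c], v)

    def test_midpoint_of_two(self):
        std = train_standards([np.zeros(64), np.full(64, 2.0),
                               np.ones(64), np.ones(64)],
                              ["Neu", "Neu", "Mon", "Lym"])
        np.testing.assert_allclose(std.vectors["Neu"], np.ones(64))

    def test_mean_matches_accumulation_oracle(self, rng):
        vecs = [rng.random(64) for _ in range(30)]
        labels = [CLASSES[i % 3] for i in range(30)]
        std = train_standards(vecs, labels)
        for c in CLASSES:
            group = [v for v, l in zip(vecs, labels) if l == c]
            acc = np.zeros(64)
            for v in group:
                acc += v
            np.testing.assert_allclose(std.vectors[c], acc / len(group))

    def test_missing_class_named_in_error(self, rng):
        with pytest.raises(ValueError, match="Lym"):
            train_standards([rng.random(64)] * 2, ["Neu", "Mon"])

    def test_median_aggregate(self):
        std = train_standards([np.zeros(64), np.zeros(64), np.full(64, 9.0),
                               np.ones(64), np.ones(64)],
                              ["Neu", "Neu", "Neu", "Mon", "Lym"],
                              aggregate="median")
        np.testing.assert_allclose(std.vectors["Neu"], np.zeros(64))

    def test_json_roundtrip(self, tmp_path, rng):
        std = train_standards([rng.random(64) for _ in range(3)],
                              list(CLASSES), provenance="demo")
        std.to_json(tmp_path / "std.json")
        back = StandardVectors.from_json(tmp_path / "std.json")
        for c in CLASSES:
            np.testing.assert_allclose(back.vectors[c], std.vectors[c])
        assert back.provenance == "demo"


class TestFeatureProbabilities:
    def test_normalization_arithmetic(self):
        # Distances (3, 4, 5) to the three standards.
        v = np.zeros(64)
        std = make_standards(neu=[3] + [0] * 63, mon=[4] + [0] * 63,
                             lym=[5] + [0] * 63)
        d_p, d_m, p_m = feature_probabilities(v, std)
        np.testing.assert_allclose(d_p, [3, 4, 5])
        np.testing.assert_allclose(d_m, [0.6, 0.8, 1.0])
        np.testing.assert_allclose(p_m, [0.4, 0.2, 0.0])

    def test_self_match_wins(self, rng):
        std = make_standards(neu=rng.random(64), mon=rng.random(64) + 2,
                             lym=rng.random(64) + 4)
        d_p, _, p_m = feature_probabilities(std.vectors["Neu"], std)
        assert d_p[0] == 0.0
        assert p_m[0] == max(p_m) and p_m[0] > p_m[1] and p_m[0] > p_m[2]

    def test_equal_distances_collapse_to_zero(self):
        v = np.zeros(64)
        one = np.zeros(64); one[0] = 1
        two = np.zeros(64); two[1] = 1
        three = np.zeros(64); three[2] = 1
        _, _, p_m = feature_probabilities(v, make_standards(one, two, three))
        np.testing.assert_allclose(p_m, [0, 0, 0])

    def test_degenerate_all_zero_distances(self):
        std = make_standards()
        d_p, d_m, p_m = feature_probabilities(np.zeros(64), std)
        np.testing.assert_allclose(d_m, 0)
        np.testing.assert_allclose(p_m, 1)

    def test_exactly_one_unit_normalized_distance(self, rng):
        std = make_standards(neu=rng.random(64), mon=rng.random(64),
                             lym=rng.random(64))
        _, d_m, _ = feature_probabilities(rng.random(64), std)
        assert np.sum(d_m == 1.0) == 1


class TestSizePrior:
    @pytest.mark.parametrize("d, expected", [
        (7, "Lym"), (12, "Neu"), (20, "Mon"),
        (5, "Lym"), (10, "Neu"), (14, "Mon"), (25, "Mon"),
        (4.9, None), (30, None),
    ])
    def test_bins(self, d, expected):
        assert size_class(d) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            size_class(0)

    @pytest.mark.parametrize("t, expected", [
        ("Neu", (1, 0, 0)), ("Mon", (0, 1, 0)), ("Lym", (0, 0, 1)),
        (None, (0, 0, 0)),
    ])
    def test_indicator(self, t, expected):
        np.testing.assert_allclose(size_probabilities(t), expected)


class TestClassify:
    def test_fused_arithmetic(self):
        # P_m = (0.4, 0.2, 0) and a 12 um cell: T = (0.46, 0.18, 0).
        v = np.zeros(64)
        std = make_standards(neu=[3] + [0] * 63, mon=[4] + [0] * 63,
                             lym=[5] + [0] * 63)
        scores = classify(v, 12.0, std)
        np.testing.assert_allclose(scores.t_m, [0.46, 0.18, 0.0])
        assert scores.label == "Neu"

    def test_size_prior_alone_decides(self):
        one = np.zeros(64); one[0] = 1
        two = np.zeros(64); two[1] = 1
        three = np.zeros(64); three[2] = 1
        scores = classify(np.zeros(64), 7.0, make_standards(one, two, three))
        np.testing.assert_allclose(scores.t_m, [0, 0, 0.1])
        assert scores.label == "Lym"

    def test_pure_feature_weighting_ignores_size(self, rng):
        std = make_standards(neu=rng.random(64), mon=rng.random(64) + 1,
                             lym=rng.random(64) + 2)
        v = std.vectors["Mon"] + 0.01
        scores = classify(v, 7.0, std, w_feature=1.0, w_size=0.0)
        assert scores.label == CLASSES[int(np.argmax(scores.p_m))]

    def test_tie_breaks_by_smaller_distance(self):
        # Equidistant pair with no size evidence: all T equal, lower D_p wins.
        one = np.zeros(64); one[0] = 3
        two = np.zeros(64); two[1] = 4
        three = np.zeros(64); three[2] = 4
        scores = classify(np.zeros(64), 30.0, make_standards(one, two, three),
                          w_feature=0.0, w_size=1.0)
        assert (scores.t_m == 0).all()
        assert scores.label == "Neu"  # D_p = (3, 4, 4), min wins

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            classify(np.zeros(64), 7.0, make_standards(), w_feature=0.8, w_size=0.1)

    def test_scale_invariance_of_distances(self, rng):
        v = rng.random(64) * 10
        std_v = {c: v + rng.random(64) * 5 for c in CLASSES}  # offsets >= 0
        a = classify(v, 12.0, StandardVectors(dict(std_v)))
        scaled = StandardVectors({c: v + 3 * (std_v[c] - v) for c in CLASSES})
        b = classify(v, 12.0, scaled)  # all D_p multiplied by 3
        np.testing.assert_allclose(a.d_m, b.d_m, atol=1e-12)
        assert a.label == b.label


class TestDifferential:
    def test_direct_count(self):
        out = differential_count(["Neu", "Neu", "Lym", "Mon"])
        assert out == {"Neu": 50.0, "Mon": 25.0, "Lym": 25.0}

    def test_single_class(self):
        out = differential_count(["Neu"] * 7)
        assert out == {"Neu": 100.0, "Mon": 0.0, "Lym": 0.0}

    def test_sampled_mix_within_binomial_bound(self):
        gen = np.random.default_rng(42)
        labels = gen.choice(CLASSES, size=1000, p=[0.6, 0.1, 0.3])
        out = differential_count(labels.tolist())
        assert abs(out["Neu"] - 60) < 5
        assert abs(out["Mon"] - 10) < 5
        assert abs(out["Lym"] - 30) < 5

    def test_percentages_sum_to_100(self, rng):
        labels = rng.choice(CLASSES, size=37).tolist()
        assert sum(differential_count(labels).values()) == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            differential_count([])
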