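import numpy as np
import pytest
from scipy import stats

from ternmeth import (
    DegenerateInputError,
    auc,
    build_roc,
    delong_test,
    optimal_threshold,
)
from ternmeth.roc_analysis import HIGHER, LOWER


def brute_force_points(scores, labels, direction=HIGHER):
    """Oracle: sens/spec at every cut-point by direct counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    distinct = np.unique(scores)
    thr = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))
    out = []
    for t in thr:
        if direction == HIGHER:
            sens = np.mean(scores[labels] > t)
            spec = np.mean(scores[~labels] <= t)
        else:
            sens = np.mean(scores[labels] < t)
            spec = np.mean(scores[~labels] >= t)
        out.append((t, sens, spec))
    return out


def pair_count_auc(scores, labels):
    """Oracle: concordant pairs + half ties, counted one pair at a time."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    cases, controls = scores[labels], scores[~labels]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestBuildRoc:
    def test_perfect_separation_contains_perfect_point(self):
        curve = build_roc([1, 2, 3, 4], [False, False, True, True], HIGHER)
        d = np.hypot(1 - curve.sensitivities, 1 - curve.specificities)
        assert d.min() == 0.0

    def test_constant_scores_give_only_trivial_points(self):
        curve = build_roc([5.0] * 6, [True, False] * 3, HIGHER)
        pts = set(zip(curve.sensitivities, curve.specificities))
        assert pts == {(1.0, 0.0), (0.0, 1.0)}

    def test_operating_points_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 11)
            scores = rng.integers(0, 5, n).astype(float)  # force ties
            labels = np.zeros(n, bool)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            curve = build_roc(scores, labels, HIGHER)
            oracle = brute_force_points(scores, labels, HIGHER)
            assert len(curve.thresholds) == len(oracle)
            for (t, se, sp), ct, cs, cp in zip(
                oracle, curve.thresholds, curve.sensitivities, curve.specificities
            ):
                assert t == ct
                assert se == pytest.approx(cs)
                assert sp == pytest.approx(cp)

    def test_sensitivity_non_increasing_under_higher_is_case(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        curve = build_roc(scores, labels, HIGHER)
        assert np.all(np.diff(curve.sensitivities) <= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_roc([1, 2, 3], [True, True, True])

    def test_auto_direction_flips_inverted_marker(self):
        # smokers LOWER than non-smokers, as for AHRR methylation
        scores = [0.2, 0.3, 0.8, 0.9]
        labels = [True, True, False, False]
        curve = build_roc(scores, labels, "auto")
        assert curve.direction == LOWER


class TestOptimalThreshold:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 11))
            scores = np.round(rng.normal(size=n), 1)
            labels = np.zeros(n, bool)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            curve = build_roc(scores, labels, HIGHER)
            pts = brute_force_points(scores, labels, HIGHER)
            finite = [(t, se, sp) for t, se, sp in pts if np.isfinite(t)]
            if not finite:
                continue
            dists = [np.hypot(1 - se, 1 - sp) for _, se, sp in finite]
            best = min(dists)
            expected = min(t for (t, _, _), d in zip(finite, dists) if d <= best)
            assert optimal_threshold(curve) == expected

    def test_perfect_separation_returns_group_midpoint(self):
        curve = build_roc([1, 2, 10, 20], [False, False, True, True], HIGHER)
        assert optimal_threshold(curve) == 6.0  # midpoint of 2 and 10

    def test_hand_picked_distances(self):
        # two finite candidates with distances 0.5 and 0.4: picks the second
        from ternmeth.roc_analysis import RocCurve

        curve = RocCurve(
            thresholds=np.array([-np.inf, 0.3, 0.7, np.inf]),
            sensitivities=np.array([1.0, 1.0, 0.6, 0.0]),
            specificities=np.array([0.0, 0.5, 1.0, 1.0]),
            direction=HIGHER,
        )
        assert optimal_threshold(curve) == 0.7

    def test_degenerate_curve_rejected(self):
        curve = build_roc([5.0] * 4, [True, False, True, False], HIGHER)
        with pytest.raises(DegenerateInputError, match="uninformative"):
            optimal_threshold(curve)


class TestAuc:
    def test_perfect_and_chance_hand_counts(self):
        assert auc([1, 2, 3, 4], [False, False, True, True]).auc == 1.0
        # cases (1, 4) vs controls (2, 3): 2 of 4 pairs concordant
        assert auc([1, 2, 3, 4], [True, False, False, True]).auc == 0.5

    def test_equals_pair_count_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            scores = rng.integers(0, 4, n).astype(float)
            labels = np.zeros(n, bool)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels).auc == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert 0.45 < auc(scores, labels).auc < 0.55

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        a1 = auc(scores, labels).auc
        a2 = auc(np.exp(3 * scores) + 7, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_negation_complements_auc(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        assert auc(scores, labels).auc + auc(-scores, labels).auc == pytest.approx(1.0)

    def test_ci_brackets_auc_and_variance_positive(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.repeat([True, False], 40)
        r = auc(scores, labels)
        assert r.variance > 0
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        assert 0.0 <= r.ci95[0] and r.ci95[1] <= 1.0


class TestDelong:
    def test_identical_scores_give_null_result(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        r = delong_test(s, s.copy(), y)
        assert r.z == 0.0
        assert r.p == 1.0

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(9)
        y = np.repeat([True, False], 30)
        sa = rng.normal(size=60) + y
        sb = rng.normal(size=60) + 0.5 * y
        r1 = delong_test(sa, sb, y, direction_a=HIGHER, direction_b=HIGHER)
        r2 = delong_test(sb, sa, y, direction_a=HIGHER, direction_b=HIGHER)
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)
        assert r1.auc_a == r2.auc_b

    def test_variance_positive_for_distinct_scores(self):
        rng = np.random.default_rng(10)
        y = np.repeat([True, False], 25)
        sa = rng.normal(size=50) + 2 * y
        sb = rng.normal(size=50)
        r = delong_test(sa, sb, y, direction_a=HIGHER, direction_b=HIGHER)
        assert np.isfinite(r.z) and 0 < r.p <= 1

    def test_single_model_variance_matches_paired_special_case(self):
        # comparing a score against pure noise: |z| grows with signal
        rng = np.random.default_rng(11)
        y = np.repeat([True, False], 40)
        noise = rng.normal(size=80)
        weak = rng.normal(size=80) + 0.3 * y
        strong = rng.normal(size=80) + 2.0 * y
        z_weak = abs(delong_test(weak, noise, y, HIGHER, HIGHER).z)
        z_strong = abs(delong_test(strong, noise, y, HIGHER, HIGHER).z)
        assert z_strong > z_weak
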